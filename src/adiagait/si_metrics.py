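"""Stride-interval variability, predictability and complexity indices.

The stride interval (SI) is the duration of one gait cycle (two consecutive
steps of the same foot). Healthy overground walking shows long-range
autocorrelated SI fluctuations (Hurst exponent typically 0.7-0.9), while
cueing a walker with a metronome pushes the dynamics toward anti-correlated,
more entropic fluctuations. This module provides the four indices used to
quantify that structure:

* coefficient of variation (CV) — magnitude of the fluctuations;
* Hurst exponent H via detrended fluctuation analysis (DFA) — predictability;
* Minkowski (box-counting) fractal dimension D — complexity of the series
  graph, estimated on the cumulative profile so that D ~ 2 - H for
  fractional-Gaussian-noise-like series;
* sample entropy S — irregularity (maximal for a random process).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

#: default minimum series length for the fractal estimators
FRACTAL_MIN_LENGTH = 64


@dataclass(frozen=True)
class StrideSeries:
    """Ordered stride intervals T_i in seconds (all positive)."""

    strides: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.strides, dtype=float)
        object.__setattr__(self, "strides", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ParameterError("strides must be a non-empty 1-D array")
        if not np.all(vals > 0):
            raise ParameterError("all stride intervals must be positive")

    def __len__(self) -> int:
        return self.strides.size


@dataclass(frozen=True)
class SIMetrics:
    """Summary indices for one stride-interval series."""

    si_mean: float      # mean stride interval, s
    cv: float           # SD/mean, dimensionless
    hurst: float        # DFA scaling exponent
    fractal_dim: float  # box-counting dimension of the profile graph
    sampen: float       # sample entropy (m=2, r=0.2 SD by default)

    def as_dict(self) -> dict[str, float]:
        return {
            "SI": self.si_mean,
            "CV": self.cv,
            "H": self.hurst,
            "D": self.fractal_dim,
            "S": self.sampen,
        }


def _as_array(T: StrideSeries | np.ndarray) -> np.ndarray:
    if isinstance(T, StrideSeries):
        return T.strides
    return np.asarray(T, dtype=float)


def coefficient_of_variation(T: StrideSeries | np.ndarray) -> float:
    """CV = SD(T)/mean(T), with the sample SD (n-1 denominator)."""
    x = _as_array(T)
    if x.size < 2:
        raise InsufficientDataError("CV needs at least 2 strides")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise DegenerateDataError("CV undefined for zero-mean series")
    return float(np.std(x, ddof=1) / mean)


def _dfa_fluctuation(profile: np.ndarray, size: int, order: int) -> float:
    """RMS detrending residual over non-overlapping windows of a given size."""
    n_seg = profile.size // size
    segs = profile[: n_seg * size].reshape(n_seg, size)
    t = np.arange(size, dtype=float)
    # one polynomial design shared by every window of this size
    design = np.vander(t, order + 1)
    coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
    resid = segs.T - design @ coef
    return float(np.sqrt(np.mean(resid**2)))


def hurst_dfa(
    T: StrideSeries | np.ndarray,
    win_min: int = 16,
    win_max: int | None = None,
    order: int = 1,
    n_sizes: int = 20,
    return_fluctuations: bool = False,
):
    """Hurst exponent by detrended fluctuation analysis.

    The profile is the cumulative sum of the mean-centred series. Window
    sizes are log-spaced in [win_min, win_max] (default win_max = n//9),
    windows are non-overlapping with the tail remainder discarded, each
    window is detrended with an order-1 polynomial, and H is the
    least-squares slope of log F(n) versus log n.
    """
    x = _as_array(T)
    n = x.size
    if win_max is None:
        win_max = n // 9
    if n < 9 * win_min or win_max <= win_min:
        raise InsufficientDataError(
            f"DFA needs at least {9 * win_min} samples (got {n}) "
            f"with win_min={win_min}"
        )
    profile = np.cumsum(x - np.mean(x))
    sizes = np.unique(
        np.rint(np.geomspace(win_min, win_max, n_sizes)).astype(int)
    )
    fluct = np.array([_dfa_fluctuation(profile, s, order) for s in sizes])
    keep = fluct > 0
    slope, _ = np.polyfit(np.log(sizes[keep]), np.log(fluct[keep]), 1)
    if return_fluctuations:
        return float(slope), sizes, fluct
    return float(slope)


def minkowski_dimension(
    T: StrideSeries | np.ndarray,
    profile: bool = True,
) -> float:
    """Box-counting (Minkowski) fractal dimension of the series graph.

    The graph is normalised to the unit square (index to [0, 1], value to
    [0, 1] by min-max). Dyadic grids delta = 2^-k, k = 1..floor(log2 n) - 2,
    are overlaid; for each grid the number of boxes intersected by the
    linearly interpolated graph is counted, and D is the slope of
    log N(delta) versus log(1/delta).

    By default the counting is applied to the cumulative profile of the
    mean-centred series, whose graph is a fractional-Brownian-type curve:
    the estimate then satisfies the duality D ~ 2 - H. Set ``profile=False``
    to count the raw series graph instead.
    """
    x = _as_array(T)
    n = x.size
    if n < FRACTAL_MIN_LENGTH:
        raise InsufficientDataError(
            f"box-counting needs >= {FRACTAL_MIN_LENGTH} samples, got {n}"
        )
    if profile:
        x = np.cumsum(x - np.mean(x))
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        logger.warning("constant series: graph is a line, returning D = 1")
        return 1.0
    ys = (x - lo) / (hi - lo)
    xs = np.linspace(0.0, 1.0, n)

    k_max = int(np.floor(np.log2(n))) - 2
    ks = np.arange(1, k_max + 1)
    counts = []
    for k in ks:
        m = 2**k
        delta = 1.0 / m
        edges = np.linspace(0.0, 1.0, m + 1)
        # function value at every column edge (linear interpolation)
        y_edges = np.interp(edges, xs, ys)
        total = 0
        for c in range(m):
            in_col = ys[(xs >= edges[c]) & (xs <= edges[c + 1])]
            y_lo = min(y_edges[c], y_edges[c + 1], *( [in_col.min()] if in_col.size else [] ))
            y_hi = max(y_edges[c], y_edges[c + 1], *( [in_col.max()] if in_col.size else [] ))
            i_lo = min(int(y_lo / delta), m - 1)
            i_hi = min(int(y_hi / delta), m - 1)
            total += i_hi - i_lo + 1
        counts.append(total)
    slope, _ = np.polyfit(ks * np.log(2.0), np.log(counts), 1)
    return float(slope)


def sample_entropy(
    T: StrideSeries | np.ndarray,
    m: int = 2,
    r_factor: float = 0.2,
) -> float:
    """Sample entropy S = -ln(A/B).

    B counts template pairs of length ``m`` within Chebyshev distance
    r = r_factor * SD(T) (self-matches excluded); A counts the same for
    length m+1, using the same n-m templates so the counts are comparable.
    Returns ``inf`` when no m+1 match exists.
    """
    x = _as_array(T)
    n = x.size
    if n < 50:
        raise InsufficientDataError("sample entropy needs >= 50 samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("sample entropy undefined for constant series")
    r = r_factor * sd

    def _count(length: int) -> int:
        n_templates = n - m  # same template count for both lengths
        tem = np.lib.stride_tricks.sliding_window_view(x, length)[:n_templates]
        # pairwise Chebyshev distances, upper triangle only
        d = np.max(np.abs(tem[:, None, :] - tem[None, :, :]), axis=-1)
        iu = np.triu_indices(n_templates, k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = _count(m)
    a = _count(m + 1)
    if b == 0:
        raise DegenerateDataError("no length-m template matches; r too small")
    if a == 0:
        logger.warning("no length-(m+1) matches: sample entropy is infinite")
        return float("inf")
    return float(-np.log(a / b))


def compute_all(
    T: StrideSeries | np.ndarray,
    dfa_kwargs: dict[str, Any] | None = None,
    sampen_kwargs: dict[str, Any] | None = None,
) -> SIMetrics:
    """All five indices for one stride series."""
    x = _as_array(T)
    return SIMetrics(
        si_mean=float(np.mean(x)),
        cv=coefficient_of_variation(x),
        hurst=hurst_dfa(x, **(dfa_kwargs or {})),
        fractal_dim=minkowski_dimension(x),
        sampen=sample_entropy(x, **(sampen_kwargs or {})),
    )
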