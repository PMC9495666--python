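"""Gait-cycle segmentation and per-cycle energetics of the COM motion.

A step is the stretch of samples between two successive maxima of Q(t);
a gait cycle is two consecutive steps. For each cycle i the duration T_i,
frequency f_i = 1/T_i and time-averaged kinetic energy per unit mass
Ebar_i = <P^2/2> are computed. Their ratio defines the per-condition
adiabatic invariant

    I = Ekm / (pi * fm),   Ekm = mean(Ebar_i),  fm = mean(f_i),

and the model predicts that the normalized pairs (f_i/fm, Ebar_i/Ekm)
fall on the line y = x with slope 1 and zero intercept. The averaged
phase-space cycle ("attractor") is obtained by normalizing every cycle to
unit duration, spline-resampling Q and P to 1200 equally spaced points,
and taking binwise mean and SD across cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .errors import InsufficientDataError, SegmentationError
from .signals import UniformSignal

ATTRACTOR_BINS = 1200


@dataclass(frozen=True)
class GaitCycleTable:
    """Per-cycle records plus the aggregate invariant.

    ``table`` columns: start, end (sample indices), T_s, f_hz, ekbar_jkg,
    f_norm = f_i/fm, ek_norm = Ebar_i/Ekm.
    """

    table: pd.DataFrame
    ekm: float          # mean per-cycle kinetic energy, J/kg
    fm: float           # mean cycle frequency, Hz
    invariant: float    # I = Ekm / (pi fm), J s/kg

    @property
    def pi_invariant(self) -> float:
        """pi * I — the convention used when reporting the invariant."""
        return float(np.pi * self.invariant)

    @property
    def n_cycles(self) -> int:
        return len(self.table)

    def normalized_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self.table["f_norm"].to_numpy(), self.table["ek_norm"].to_numpy()


@dataclass(frozen=True)
class Attractor:
    """1200-bin averaged phase-space cycle (mean and SD of Q and P)."""

    mean_q: np.ndarray
    sd_q: np.ndarray
    mean_p: np.ndarray
    sd_p: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.mean_q, self.sd_q, self.mean_p, self.sd_p):
            if arr.size != ATTRACTOR_BINS:
                raise ValueError(f"attractor must have exactly {ATTRACTOR_BINS} bins")
        if not (np.isfinite(self.mean_q).all() and np.isfinite(self.mean_p).all()):
            raise ValueError("attractor bin means must be finite")

    def enclosed_area(self) -> float:
        """Shoelace area of the mean (Q, P) loop."""
        q, p = self.mean_q, self.mean_p
        return float(0.5 * abs(np.sum(q * np.roll(p, -1) - p * np.roll(q, -1))))


def detect_steps(
    Q: UniformSignal,
    min_separation_factor: float = 0.5,
    prominence_iqr_factor: float = 0.1,
) -> np.ndarray:
    """Indices of the Q(t) maxima that delimit steps.

    A first unconstrained peak pass sets the scale: the second pass
    requires peak separation >= ``min_separation_factor`` times the median
    inter-peak interval and prominence >= ``prominence_iqr_factor`` times
    the interquartile range of Q.
    """
    vals = Q.values
    q75, q25 = np.percentile(vals, [75, 25])
    iqr = q75 - q25
    first_pass, _ = find_peaks(vals)
    if first_pass.size < 3 or iqr == 0.0:
        raise SegmentationError(
            f"found {first_pass.size} maxima; need >= 3 non-degenerate peaks"
        )
    median_gap = float(np.median(np.diff(first_pass)))
    peaks, _ = find_peaks(
        vals,
        distance=max(1.0, min_separation_factor * median_gap),
        prominence=prominence_iqr_factor * iqr,
    )
    if peaks.size < 3:
        raise SegmentationError(f"only {peaks.size} maxima after thresholding")
    return peaks


def segment_cycles(peaks: np.ndarray) -> list[tuple[int, int]]:
    """Pair steps into cycles: (p0, p2), (p2, p4), ...

    Cycles are anchored at the first detected maximum; a trailing unpaired
    step is discarded.
    """
    peaks = np.asarray(peaks)
    if peaks.size < 3:
        raise SegmentationError("cycle segmentation needs >= 3 maxima")
    n_cycles = (peaks.size - 1) // 2
    return [(int(peaks[2 * i]), int(peaks[2 * i + 2])) for i in range(n_cycles)]


def cycle_energetics(
    cycle: tuple[int, int],
    P: UniformSignal,
) -> tuple[float, float, float]:
    """(T_i, f_i, Ebar_i) for one cycle.

    Ebar_i is the arithmetic mean of P^2/2 over the cycle's samples
    [start, end), i.e. exactly one period for a periodic signal. Mass
    scale is 1, so the unit is J/kg.
    """
    start, end = cycle
    if end - start < 8:
        raise SegmentationError(f"cycle [{start}, {end}) spans < 8 samples")
    T = (end - start) / P.rate
    f = 1.0 / T
    ekbar = float(0.5 * np.mean(P.values[start:end] ** 2))
    return T, f, ekbar


def invariant_table(
    Q: UniformSignal,
    P: UniformSignal,
    cycles: list[tuple[int, int]],
) -> GaitCycleTable:
    """Aggregate per-cycle energetics into the invariant summary."""
    if len(cycles) < 2:
        raise InsufficientDataError("need >= 2 cycles for the invariant table")
    rows = [cycle_energetics(c, P) for c in cycles]
    df = pd.DataFrame(
        {
            "start": [c[0] for c in cycles],
            "end": [c[1] for c in cycles],
            "T_s": [r[0] for r in rows],
            "f_hz": [r[1] for r in rows],
            "ekbar_jkg": [r[2] for r in rows],
        }
    )
    ekm = float(df["ekbar_jkg"].mean())
    fm = float(df["f_hz"].mean())
    df["f_norm"] = df["f_hz"] / fm
    df["ek_norm"] = df["ekbar_jkg"] / ekm
    invariant = ekm / (np.pi * fm)
    return GaitCycleTable(table=df, ekm=ekm, fm=fm, invariant=float(invariant))


def mean_attractor(
    Q: UniformSignal,
    P: UniformSignal,
    cycles: list[tuple[int, int]],
    n_bins: int = ATTRACTOR_BINS,
) -> Attractor:
    """Duration-normalized, bin-averaged phase-space cycle.

    Every cycle (endpoint included so the loop closes) is mapped onto
    [0, 1] and spline-resampled to ``n_bins`` equally spaced points; the
    attractor is the binwise mean with SD across cycles.
    """
    if len(cycles) < 2:
        raise InsufficientDataError("need >= 2 cycles for an attractor")
    u = np.linspace(0.0, 1.0, n_bins)
    qs = np.empty((len(cycles), n_bins))
    ps = np.empty((len(cycles), n_bins))
    for i, (start, end) in enumerate(cycles):
        idx = np.arange(start, end + 1)
        s = (idx - start) / (end - start)
        qs[i] = CubicSpline(s, Q.values[idx])(u)
        ps[i] = CubicSpline(s, P.values[idx])(u)
    return Attractor(
        mean_q=qs.mean(axis=0),
        sd_q=qs.std(axis=0, ddof=1),
        mean_p=ps.mean(axis=0),
        sd_p=ps.std(axis=0, ddof=1),
    )


def analyze_signal(
    Q: UniformSignal,
    P: UniformSignal,
    **peak_kwargs,
) -> tuple[GaitCycleTable, Attractor]:
    """Convenience: detect steps, segment, tabulate and average."""
    peaks = detect_steps(Q, **peak_kwargs)
    cycles = segment_cycles(peaks)
    return invariant_table(Q, P, cycles), mean_attractor(Q, P, cycles)
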