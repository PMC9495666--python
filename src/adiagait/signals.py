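"""Core in-memory containers: evenly sampled signals and pelvic marker sets.

`UniformSignal` carries the vertical center-of-mass (COM) position Q(t) in
metres, or its derivative P(t) = dQ/dt in m/s, on an evenly spaced time grid.
`MarkerSet` carries the four pelvic marker vertical trajectories (mm) from
which Q is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ParameterError

#: Canonical pelvic marker labels (Plug-In-Gait convention).
MARKER_LABELS = ("RASI", "LASI", "RPSI", "LPSI")


@dataclass(frozen=True)
class UniformSignal:
    """Evenly sampled scalar time series.

    Parameters
    ----------
    values : array of float
        Samples (units depend on role: m for position, m/s for velocity).
    rate : float
        Sampling rate in Hz; must be positive.
    t0 : float, optional
        Time stamp of the first sample, seconds.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise ParameterError("UniformSignal values must be 1-D")
        if not self.rate > 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Span between first and last sample, seconds."""
        return (len(self) - 1) / self.rate if len(self) else 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate


@dataclass(frozen=True)
class MarkerSet:
    """Vertical trajectories (mm) of the four pelvic markers at a common rate."""

    data: dict[str, np.ndarray] = field(default_factory=dict)
    rate: float = 120.0

    def __post_init__(self) -> None:
        missing = [lab for lab in MARKER_LABELS if lab not in self.data]
        if missing:
            raise FormatError(f"missing marker label(s): {missing}")
        arrays = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        lengths = {a.size for a in arrays.values()}
        if len(lengths) != 1:
            raise FormatError(f"marker trajectories have unequal lengths: {lengths}")
        object.__setattr__(self, "data", arrays)
        if not self.rate > 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return next(iter(self.data.values())).size

    def stacked(self) -> np.ndarray:
        """(4, n) array in canonical label order."""
        return np.vstack([self.data[lab] for lab in MARKER_LABELS])
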