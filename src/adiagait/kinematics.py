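"""Marker trajectories -> filtered, upsampled COM position and velocity.

The whole-body COM vertical position Q(t) is estimated as the mean of the
four pelvic marker vertical coordinates. The raw estimate is low-pass
filtered with a 4th-order Butterworth whose cutoff is chosen per series so
that the retained band holds a given fraction (default 99.99%) of the
signal's power, upsampled tenfold by cubic spline to sharpen cycle timing,
and differentiated by finite differences to obtain P(t) = dQ/dt.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, periodogram, sosfiltfilt

from .errors import GapError, InsufficientDataError, ParameterError
from .signals import MarkerSet, UniformSignal

logger = logging.getLogger(__name__)

FILTER_ORDER = 4


def com_from_markers(markers: MarkerSet) -> UniformSignal:
    """Per-sample mean of the four pelvic marker verticals, mm -> m."""
    stacked = markers.stacked()
    if np.isnan(stacked).any():
        idx = int(np.flatnonzero(np.isnan(stacked).any(axis=0))[0])
        raise GapError(f"NaN sample in marker data at index {idx}")
    return UniformSignal(stacked.mean(axis=0) / 1000.0, markers.rate)


class FilterResult(NamedTuple):
    signal: UniformSignal
    cutoff_hz: float | None      # Butterworth cutoff applied (None: no filtering)
    power_fraction: float
    power_freq_hz: float | None = None  # frequency holding the power fraction


def adaptive_lowpass(
    x: UniformSignal,
    power_fraction: float = 0.9999,
    passband_margin: float = 2.5,
) -> FilterResult:
    """Butterworth low-pass whose passband retains a power fraction.

    The power frequency is the lowest frequency at which the cumulative
    periodogram of the mean-removed signal reaches ``power_fraction`` of
    total power (linear interpolation between periodogram bins). The
    4th-order Butterworth cutoff is placed ``passband_margin`` times above
    it so that the retained band is attenuated by < 0.1% even after the
    forward-backward (zero-phase, reflect-padded) pass, which squares the
    magnitude response. If the cutoff reaches Nyquist the input is
    returned unchanged with a warning.
    """
    n = len(x)
    if n < 8 * FILTER_ORDER:
        raise InsufficientDataError(
            f"need >= {8 * FILTER_ORDER} samples for order-{FILTER_ORDER} filtering"
        )
    if not 0.0 < power_fraction < 1.0:
        raise ParameterError("power_fraction must lie in (0, 1)")
    if not passband_margin >= 1.0:
        raise ParameterError("passband_margin must be >= 1")

    centred = x.values - x.values.mean()
    # Hann window: boxcar leakage from off-bin spectral lines would smear
    # >1e-4 of the power into the tail and defeat the 99.99% criterion
    freqs, pxx = periodogram(centred, fs=x.rate, window="hann", detrend=False)
    total = pxx.sum()
    if total == 0.0:  # constant signal: nothing to filter
        return FilterResult(x, None, power_fraction, None)
    cum = np.cumsum(pxx) / total
    target = power_fraction
    j = int(np.searchsorted(cum, target))
    if j >= freqs.size - 1:
        logger.warning("power cutoff at/above Nyquist; returning input unchanged")
        return FilterResult(x, None, power_fraction, float(freqs[-1]))
    if j == 0:
        power_freq = freqs[0]
    else:
        # linear interpolation between the bracketing periodogram bins
        c0, c1 = cum[j - 1], cum[j]
        f0, f1 = freqs[j - 1], freqs[j]
        power_freq = f0 + (f1 - f0) * (target - c0) / (c1 - c0) if c1 > c0 else f1
    nyq = x.rate / 2.0
    cutoff = passband_margin * power_freq
    if cutoff >= 0.999 * nyq:
        logger.warning("power cutoff at/above Nyquist; returning input unchanged")
        return FilterResult(x, None, power_fraction, float(power_freq))
    cutoff = max(cutoff, freqs[1] * 0.5)  # keep butter() away from 0
    sos = butter(FILTER_ORDER, cutoff / nyq, output="sos")
    # odd-reflect padding over one effective impulse-response length
    # (~rate/cutoff); antisymmetric extension keeps the slope continuous
    padlen = min(n - 1, int(round(3.0 * x.rate / cutoff)))
    filtered = sosfiltfilt(sos, x.values, padtype="odd", padlen=padlen)
    return FilterResult(
        UniformSignal(filtered, x.rate, x.t0),
        float(cutoff),
        power_fraction,
        float(power_freq),
    )


def upsample_spline(x: UniformSignal, factor: int = 10) -> UniformSignal:
    """Cubic-spline interpolation onto a ``factor`` times denser grid.

    Original samples are reproduced exactly at their time stamps; the
    spline uses not-a-knot boundaries, so polynomials up to cubic are
    reproduced exactly everywhere.
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError("factor must be a positive integer")
    factor = int(factor)
    if len(x) < 4:
        raise InsufficientDataError("spline upsampling needs >= 4 samples")
    if factor == 1:
        return x
    spline = CubicSpline(x.times, x.values)
    n_out = (len(x) - 1) * factor + 1
    t_out = x.t0 + np.arange(n_out) / (x.rate * factor)
    vals = spline(t_out)
    vals[::factor] = x.values  # knots are exact by construction; keep them bit-exact
    return UniformSignal(vals, x.rate * factor, x.t0)


def differentiate(x: UniformSignal) -> UniformSignal:
    """Finite-difference derivative: central interior, one-sided edges."""
    if len(x) < 3:
        raise InsufficientDataError("differentiation needs >= 3 samples")
    deriv = np.gradient(x.values, x.dt, edge_order=2)
    return UniformSignal(deriv, x.rate, x.t0)


def process_markers(
    markers: MarkerSet,
    power_fraction: float = 0.9999,
    upsample_factor: int = 10,
) -> tuple[UniformSignal, UniformSignal, dict]:
    """Full stage: markers -> (Q, P) plus processing metadata."""
    com = com_from_markers(markers)
    filt = adaptive_lowpass(com, power_fraction)
    q = upsample_spline(filt.signal, upsample_factor)
    p = differentiate(q)
    meta = {
        "cutoff_hz": filt.cutoff_hz,
        "power_freq_hz": filt.power_freq_hz,
        "power_fraction": power_fraction,
        "rate_in_hz": markers.rate,
        "rate_out_hz": q.rate,
        "upsample_factor": upsample_factor,
    }
    return q, p, meta
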