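"""Synthetic walking data: stochastic oscillator COM motion and fractal strides.

The vertical center-of-mass motion of a walker is modelled as a harmonic
oscillator whose angular frequency fluctuates slowly around a mean:

    Q''(t) = -omega(t)^2 Q(t),    omega(t) = omega0 * (1 + eps * xi(t)),

with xi(t) a unit-variance stochastic noise, realised here as an
Ornstein-Uhlenbeck (OU) process with correlation time ``tau`` so that the
slowness of the frequency drift is an explicit parameter. For slow noise
(tau much longer than one period) the action Ebar_k / (pi f) of each cycle
is an adiabatic invariant: it stays nearly constant even though Ebar_k and
f themselves wander. The mass scale is fixed to 1, so every energy is per
unit mass (J/kg).

Stride-interval series are generated as fractional Gaussian noise (fGn)
with a prescribed Hurst exponent, via exact Davies-Harte circulant
embedding (spectral synthesis as fallback), rescaled to a target mean and
coefficient of variation.

Marker synthesis wraps a Q trajectory into the four pelvic marker vertical
channels (mm, 120 Hz) that the kinematics stage expects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ParameterError
from .signals import MARKER_LABELS, MarkerSet, UniformSignal
from .si_metrics import StrideSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class OscillatorConfig:
    """Parameters of the frequency-modulated harmonic oscillator.

    omega0 : base angular frequency, rad/s
    epsilon : relative noise magnitude (0 <= eps << 1)
    tau : noise correlation time, s (controls how *slow* the drift is)
    amplitude0 : initial COM half-range, m
    duration : simulated time, s
    dt : integration step, s (must resolve >= 20 steps per period)
    seed : RNG seed
    noise_mode : "ou" (continuous OU drift) or "per_cycle"
        (noise redrawn once per nominal period, piecewise constant)
    integrator : "rk4" or "leapfrog"
    """

    omega0: float = 2.0 * math.pi * 0.85
    epsilon: float = 0.03
    tau: float = 12.0
    amplitude0: float = 0.02
    duration: float = 120.0
    dt: float = 1.0 / 1200.0
    seed: int = 0
    noise_mode: str = "ou"
    integrator: str = "rk4"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ParameterError("epsilon must be >= 0")
        if not self.tau > 0:
            raise ParameterError("tau must be positive")
        if not self.dt > 0 or not self.dt < 2.0 * math.pi / (20.0 * self.omega0):
            raise ParameterError(
                "dt must resolve at least 20 steps per period "
                f"(dt < {2.0 * math.pi / (20.0 * self.omega0):.4g} s)"
            )
        if self.duration < 10.0 * 2.0 * math.pi / self.omega0:
            raise ParameterError("duration must cover at least 10 periods")
        if self.noise_mode not in ("ou", "per_cycle"):
            raise ParameterError(f"unknown noise_mode {self.noise_mode!r}")
        if self.integrator not in ("rk4", "leapfrog"):
            raise ParameterError(f"unknown integrator {self.integrator!r}")


@dataclass(frozen=True)
class StrideGenConfig:
    """Parameters of the fractal stride-interval generator."""

    n_strides: int = 512
    hurst_target: float = 0.8
    mean_si: float = 1.18
    cv_target: float = 0.026
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 64:
            raise ParameterError("n_strides must be >= 64")
        if not 0.0 < self.hurst_target < 1.0:
            raise ParameterError("hurst_target must lie in (0, 1)")
        if self.cv_target < 0:
            raise ParameterError("cv_target must be >= 0")
        if not self.mean_si > 0:
            raise ParameterError("mean_si must be positive")


# ---------------------------------------------------------------------------
# noise


def ou_noise(
    n: int,
    dt: float,
    tau: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stationary unit-variance Ornstein-Uhlenbeck series.

    Exact AR(1) discretisation: lag-k autocorrelation exp(-k dt / tau).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not tau > 0 or not dt > 0:
        raise ParameterError("tau and dt must be positive")
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rho = math.exp(-dt / tau)
    innov_sd = math.sqrt(1.0 - rho * rho)
    shocks = rng.standard_normal(n)
    drive = innov_sd * shocks
    drive[0] = shocks[0]  # first sample from the stationary N(0, 1) law
    # AR(1) recursion x[i] = rho x[i-1] + drive[i] as an IIR filter
    return lfilter([1.0], [1.0, -rho], drive)


# ---------------------------------------------------------------------------
# oscillator integration


def _noise_on_half_grid(cfg: OscillatorConfig, n_steps: int) -> np.ndarray:
    """xi(t) sampled at dt/2 resolution (2*n_steps + 1 points)."""
    m = 2 * n_steps + 1
    rng = np.random.default_rng(cfg.seed)
    if cfg.epsilon == 0.0:
        return np.zeros(m)
    if cfg.noise_mode == "ou":
        return ou_noise(m, cfg.dt / 2.0, cfg.tau, rng)
    # per_cycle: one standard-normal draw per nominal oscillator period
    period = 2.0 * math.pi / cfg.omega0
    t_half = np.arange(m) * (cfg.dt / 2.0)
    cycle_idx = np.floor(t_half / period).astype(int)
    draws = rng.standard_normal(cycle_idx[-1] + 1)
    return draws[cycle_idx]


def simulate_oscillator(cfg: OscillatorConfig) -> tuple[UniformSignal, UniformSignal]:
    """Integrate Q'' = -omega(t)^2 Q; returns (Q, P = dQ/dt).

    Fixed-step RK4 by default (leapfrog/velocity-Verlet optional). For
    eps = 0 the total energy 0.5 P^2 + 0.5 omega0^2 Q^2 is conserved to
    relative 1e-6 over the run, which gates integrator quality.
    """
    n_steps = int(round(cfg.duration / cfg.dt))
    xi = _noise_on_half_grid(cfg, n_steps)
    w2 = (cfg.omega0 * (1.0 + cfg.epsilon * xi)) ** 2
    w2_list = w2.tolist()  # plain floats: the sequential loop is much faster
    dt = cfg.dt
    q, p = cfg.amplitude0, 0.0
    qs = np.empty(n_steps + 1)
    ps = np.empty(n_steps + 1)
    qs[0], ps[0] = q, p

    if cfg.integrator == "rk4":
        h2 = dt / 2.0
        for i in range(n_steps):
            w2a = w2_list[2 * i]
            w2b = w2_list[2 * i + 1]
            w2c = w2_list[2 * i + 2]
            k1q = p
            k1p = -w2a * q
            k2q = p + h2 * k1p
            k2p = -w2b * (q + h2 * k1q)
            k3q = p + h2 * k2p
            k3p = -w2b * (q + h2 * k2q)
            k4q = p + dt * k3p
            k4p = -w2c * (q + dt * k3q)
            q += dt / 6.0 * (k1q + 2.0 * k2q + 2.0 * k3q + k4q)
            p += dt / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            qs[i + 1], ps[i + 1] = q, p
    else:  # leapfrog (velocity Verlet)
        for i in range(n_steps):
            w2a = w2_list[2 * i]
            w2c = w2_list[2 * i + 2]
            p_half = p - 0.5 * dt * w2a * q
            q = q + dt * p_half
            p = p_half - 0.5 * dt * w2c * q
            qs[i + 1], ps[i + 1] = q, p

    rate = 1.0 / dt
    return UniformSignal(qs, rate), UniformSignal(ps, rate)


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def _fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn sample path via circulant embedding of the covariance.

    Falls back to spectral synthesis if the embedding is not non-negative
    definite (can occur for Hurst very close to 1).
    """
    gamma = _fgn_autocovariance(n, hurst)
    row = np.concatenate([gamma[:n], gamma[n:n + 1], gamma[n - 1:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        logger.warning("circulant embedding not PSD (H=%g); using spectral synthesis", hurst)
        return fgn_spectral(n, hurst, rng)
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    w = np.zeros(m, dtype=complex)
    w[0] = math.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = math.sqrt(lam[n] / m) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    coef = np.sqrt(lam[1:n] / (2.0 * m))
    w[1:n] = coef * (u + 1j * v)
    w[m - 1:n:-1] = np.conj(w[1:n])
    return np.fft.fft(w).real[:n]


def fgn_spectral(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Approximate fGn via spectral synthesis (power-law periodogram).

    Independent of the circulant-embedding path; used as a cross-check and
    as fallback. The fGn spectral density scales as f^(1 - 2H).
    """
    # synthesize on a 2n grid, then crop, to suppress circular wrap-around
    freqs = np.fft.rfftfreq(2 * n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** ((1.0 - 2.0 * hurst) / 2.0)
    phases = rng.uniform(0.0, 2.0 * math.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=2 * n)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_fgn_strides(cfg: StrideGenConfig) -> StrideSeries:
    """Fractal stride-interval series with prescribed Hurst, mean and CV.

    The fGn sample is rescaled to exact sample mean ``mean_si`` and SD
    ``cv_target * mean_si``; strides that would fall below mean/4 are
    clipped there (logged). Parameters implying a non-positive-stride
    probability above 1e-3 are rejected.
    """
    from scipy.stats import norm

    if cfg.cv_target > 0 and norm.cdf(-1.0 / cfg.cv_target) > 1e-3:
        raise ParameterError(
            f"cv_target={cfg.cv_target} gives non-positive strides with "
            "probability > 1e-3"
        )
    if cfg.cv_target == 0.0:
        return StrideSeries(np.full(cfg.n_strides, cfg.mean_si))
    rng = np.random.default_rng(cfg.seed)
    x = fgn_davies_harte(cfg.n_strides, cfg.hurst_target, rng)
    x = (x - x.mean()) / x.std(ddof=1)
    strides = cfg.mean_si + cfg.cv_target * cfg.mean_si * x
    floor = cfg.mean_si / 4.0
    n_clip = int(np.count_nonzero(strides < floor))
    if n_clip:
        logger.warning("clipped %d stride(s) at mean/4", n_clip)
        strides = np.clip(strides, floor, None)
    return StrideSeries(strides)


# ---------------------------------------------------------------------------
# marker synthesis

#: default constant vertical offsets (mm) per marker; mean is zero so the
#: four-marker average recovers Q exactly
DEFAULT_OFFSETS_MM = {"RASI": 15.0, "LASI": 10.0, "RPSI": -10.0, "LPSI": -15.0}


def synthesize_markers(
    Q: UniformSignal,
    rate_out: float = 120.0,
    marker_noise_sd: float = 0.5,
    seed: int = 0,
    offsets_mm: dict[str, float] | None = None,
) -> MarkerSet:
    """Wrap a COM trajectory into four pelvic marker channels (mm).

    Each marker = Q (converted to mm, resampled to ``rate_out``) + a
    constant vertical offset + i.i.d. Gaussian noise. Offsets must average
    to zero so the marker mean recovers Q.
    """
    if not rate_out > 0:
        raise ParameterError("rate_out must be positive")
    if Q.duration < 2.0:
        raise ParameterError("Q must span at least 2 s")
    offsets = dict(DEFAULT_OFFSETS_MM if offsets_mm is None else offsets_mm)
    if abs(sum(offsets[k] for k in MARKER_LABELS)) > 1e-9:
        raise ParameterError("marker offsets must average to zero")
    rng = np.random.default_rng(seed)
    n_out = int(round(Q.duration * rate_out)) if rate_out != Q.rate else len(Q)
    t_out = Q.t0 + np.arange(n_out) / rate_out
    if rate_out == Q.rate:
        q_mm = Q.values * 1000.0
    else:
        spline = CubicSpline(Q.times, Q.values)
        q_mm = spline(t_out) * 1000.0
    data = {}
    for lab in MARKER_LABELS:
        noise = marker_noise_sd * rng.standard_normal(n_out) if marker_noise_sd > 0 else 0.0
        data[lab] = q_mm + offsets[lab] + noise
    return MarkerSet(data=data, rate=rate_out)
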