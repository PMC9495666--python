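# Methods

## The model

The vertical whole-body COM excursion during steady walking is modelled
as a harmonic oscillator with a stochastically modulated frequency,

    Q''(t) = -omega(t)^2 Q(t),        omega(t) = omega0 (1 + eps * xi(t)),

with xi(t) a unit-variance noise and 0 <= eps << 1. When xi varies
slowly compared with one oscillation, the action of each cycle —
proportional to Ebar_k / f, the cycle's mean kinetic energy over its
frequency — is an adiabatic invariant: it fluctuates around a constant
value even though Ebar_k and f individually wander. Equivalently, the
normalized pairs (f_i/f_m, Ebar_i/E_m) of a long walk should lie on the
line y = x with zero intercept, which is the pipeline's central testable
prediction. Energies are per unit mass (mass scale fixed to 1), so the
invariant is reported in J·s/kg, conventionally as pi*I.

The model is *not* a gait model in the biomechanical sense: it has no
feet, no double support, no anteroposterior motion. It captures exactly
the two features the analysis relies on — a quasi-sinusoidal vertical COM
trace and slow frequency drift — and nothing else. Passing tests on this
generator therefore validate the estimators and the invariance machinery,
not any claim about real gait.

### Noise realisation

The model prescribes no spectrum for xi(t). We realise it as an
Ornstein–Uhlenbeck (OU) process with correlation time `tau` (default
12 s, i.e. roughly ten oscillation periods at omega0 = 2*pi*0.85 rad/s),
which makes "slow" an explicit, tunable quantity; a piecewise-constant
per-cycle mode (one fresh draw per nominal period) is available as
`noise_mode="per_cycle"`. The OU series is generated by the exact AR(1)
discretisation at half-step resolution so the integrator sees noise
values at its stage times.

### Integration

Fixed-step classical Runge–Kutta 4 on (Q, P), with velocity-Verlet
(leapfrog) as an option. At the default dt = 1/1200 s the RK4 relative
energy drift at eps = 0 is below 1e-10 per 100 s, comfortably inside the
1e-6 quality gate asserted in the tests. Leapfrog, being symplectic,
shows a bounded O((omega*dt)^2) energy oscillation (~7e-6 at dt = 1/1200)
with no secular drift; the 1e-6 *drift* gate therefore applies to the
default integrator only.

### How much does the invariant actually drift?

Under stochastic (rather than periodic) frequency modulation the action
is not strictly bounded: it performs a slow random walk. Empirically, at
eps = 0.03 and tau = 12 s over 500 cycles the relative SD of the
per-cycle action is ~0.12, scaling roughly linearly in eps (0.03 at
eps = 0.01, 0.13 at eps = 0.05). This is the scale the tests freeze; the
slope of the normalized energy–frequency law is insensitive to it and
stays within 0.004 of 1 on 500 cycles.

## Default generator conditions

| parameter | default | why |
|---|---|---|
| omega0 | 2*pi*0.85 rad/s | preferred cycle cadence of healthy adults (~1.18 s stride) |
| eps | 0.03 | matches the CV scale of healthy stride series, which estimates the noise magnitude |
| tau | 12 s | ~10 periods: safely in the adiabatic (slow) regime |
| amplitude0 | 0.02 m | typical vertical COM half-excursion in walking |
| dt | 1/1200 s | matches the 1200 Hz analysis rate; 1e-6 energy gate holds |
| stride generator | H = 0.8, SI = 1.18 s, CV = 0.026, n = 512 | healthy-adult values for fractal stride series |
| marker offsets | +15/+10/−10/−15 mm | arbitrary constant pelvic offsets averaging to zero |
| marker noise | 0.2 mm SD (CLI default) | typical optical-capture jitter; keeps the noise floor below the 1e-4 spectral tail the filter criterion must resolve |

One gait cycle is defined as the span between alternate maxima of Q(t)
(two steps). For the single-frequency oscillator this means a cycle
covers two oscillations, so the cycle frequency is omega0/(4*pi); all
normalized quantities are unaffected by this convention.

## Kinematics stage

* **COM estimate**: arithmetic mean of the four pelvic marker verticals,
  mm converted to m. NaNs are rejected with the offending index — gap
  filling belongs upstream.
* **Adaptive low-pass**: the power frequency is where the cumulative
  Hann-windowed periodogram of the mean-removed signal reaches 99.99% of
  total power (linear interpolation between bins). The Hann window
  matters: with a boxcar, sidelobe leakage from an off-bin spectral line
  exceeds 1e-4 of total power and pushes the criterion into the noise
  tail. The 4th-order Butterworth cutoff is then placed 2.5x above the
  power frequency: the forward–backward (zero-phase) pass squares the
  magnitude response, so a cutoff *at* the band edge would attenuate the
  retained band by ~3 dB, whereas the 2.5x margin keeps in-band
  distortion below 0.1%. Zero-phase filtering is essential because cycle
  timing feeds the segmentation. Padding is odd-reflect over ~3
  impulse-response lengths (antisymmetric extension keeps the slope
  continuous at the ends; even reflection leaves percent-level edge
  error). If the cutoff would reach Nyquist, the input is returned
  unchanged with a warning.
* **Upsampling**: cubic spline (not-a-knot boundaries) onto a 10x denser
  grid. Not-a-knot is chosen over natural boundaries so that polynomials
  up to cubic are reproduced exactly, which is also what the exactness
  tests assert; knot samples are kept bit-identical.
* **Differentiation**: central differences in the interior and
  second-order one-sided stencils at the edges (first-order edge stencils
  would leave O(h) errors three orders larger than the interior).

## Cycle segmentation and energetics

Maxima of Q(t) are detected in two passes: an unconstrained pass sets the
scale (median inter-peak interval), then peaks are re-detected requiring
separation >= 0.5x that median and prominence >= 10% of the signal IQR
(both configurable; the thresholds are a package choice, stated here
because no standard exists). Cycles pair alternate maxima starting at the
first, discarding a trailing unpaired step; Ebar_i is the arithmetic mean
of P^2/2 over the cycle's samples (trapezoidal quadrature differs
negligibly at 1200 Hz). The averaged attractor maps every cycle
(endpoints included) onto [0, 1], spline-resamples Q and P to 1200 equally
spaced points, and takes binwise mean and SD (ddof = 1) across cycles.
For a noiseless sinusoid the attractor is an ellipse with semi-axes A and
2*pi*f*A; its shoelace area matches pi*A*(2*pi*f*A) within 1%, which the
tests assert.

## Stride-interval metrics

* **CV**: sample SD (n−1) over mean.
* **DFA**: profile = cumulative sum of the mean-centred series;
  non-overlapping windows, ~20 log-spaced sizes in [16, n/9], order-1
  polynomial detrending per window, tail remainder discarded; H is the
  log–log slope of the RMS fluctuation. Calibration at n = 512 over 50
  replicates: white noise 0.506, fGn with H in {0.3, 0.5, 0.8} recovered
  within 0.01–0.03.
* **Minkowski dimension**: box counting on dyadic grids delta = 2^-k,
  k = 1..floor(log2 n)−2, of the linearly interpolated graph normalized
  to the unit square. By default the counting is applied to the
  *cumulative profile* of the series: the profile of fGn is an
  fBm-like self-affine curve whose graph dimension obeys D = 2 − H, so
  the estimator lands at ~1.5 for white noise and complements the DFA
  exponent. (Counting the raw stationary series graph instead — available
  via `profile=False` — measures interpolation roughness and tends
  towards 2 for uncorrelated data.) Known limitation: at the finest
  dyadic scale each column holds only ~4 samples, so very rough profiles
  (H < 0.4) are under-resolved and D is biased low by ~0.1–0.2.
* **Sample entropy**: m = 2, r = 0.2*SD, Chebyshev distance,
  self-matches excluded, with the same n−m template count for lengths m
  and m+1 (Richman–Moorman convention). The vectorized implementation is
  asserted equal to a literal O(n^2) enumeration for n <= 200. Because
  the convention drops one end-window, S is reversal-invariant only to
  ~1%, unlike CV (exact) and H/D (estimator-level).

## Statistics

Paired condition comparisons run Shapiro–Wilk on the differences at
alpha = 0.05; the normal branch uses the paired t-test, otherwise
Wilcoxon signed rank (zeros dropped; exact null for n <= 25, corrected
normal approximation above). Type-I calibration is verified by simulation
under the no-shift matched-pairs null (shared baseline plus independent
condition noise) — note that permuting one sample of a *paired* design
yields mean difference exactly zero and is not a usable null. The
zero-intercept slope is the closed form sum(xy)/sum(x^2) with a
t(n−1) confidence interval and R^2 against the zero-intercept null; the
ANCOVA fits y = k*x + k_delta*(x*1[group B]) without intercept and tests
k_delta, treating numerically-zero-residual fits as p = 1 when k_delta
vanishes. DTW z-normalizes both inputs and uses the classic symmetric
step pattern with absolute local cost; an optional Sakoe–Chiba band
bounds warping for long inputs. DTW is intended for the 1200-point
attractor traces, not raw 10-minute series.

## Problem sizes and determinism

The default test and acceptance runs simulate 500 gait cycles at
dt = 1/600 s for the slope law (a few seconds of CPU), 150–200 cycles at
dt = 1/300 s for drift-monotonicity and ANCOVA-null replicates, and 50
replicates of length-512 series for the DFA calibrations. All stochastic
stages accept integer seeds and are bit-reproducible for a fixed seed,
which the end-to-end CLI test asserts at file level.

## What the synthetic data do not show

The generator has a single spectral line plus slow drift; real COM
signals contain step-frequency harmonics, asymmetries between left and
right steps, treadmill station-keeping drift, and marker soft-tissue
artefacts. The stride generator produces exact-Gaussian fGn, while real
SI series show crossovers in their scaling and occasional outliers.
Passing tests therefore demonstrate estimator correctness and internal
consistency of the invariant machinery, not robustness to every
real-world artefact. Group-level empirical values (condition means,
significance patterns) depend on real cohorts and are out of scope here.
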