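# adiagait

Adiabatic-invariant analysis of human walking dynamics.

Human gait is globally stereotyped yet locally variable: the stride
interval (SI, the duration of one gait cycle) fluctuates from cycle to
cycle with long-range autocorrelations in healthy adults. `adiagait`
implements a pipeline that quantifies both sides of this picture from the
vertical motion of the whole-body center of mass (COM):

* **Global stability** via an adiabatic invariant. Treating the vertical
  COM excursion Q(t) as a harmonic oscillator whose frequency drifts
  slowly, each gait cycle *i* yields a frequency *fᵢ* and a mean kinetic
  energy per unit mass *Ēₖᵢ* = ⟨½Q̇²⟩. The action

  &nbsp;&nbsp;&nbsp;&nbsp;*I* = *Eₖₘ* / (π *fₘ*), with *Eₖₘ* = mean(*Ēₖᵢ*), *fₘ* = mean(*fᵢ*),

  is approximately conserved under slow perturbations, and the model
  predicts that the normalized pairs (*fᵢ*/*fₘ*, *Ēₖᵢ*/*Eₖₘ*) fall on the
  line *y* = *x* (slope 1, zero intercept).
* **Local variability** of the SI series through the coefficient of
  variation (CV), the Hurst exponent H estimated by detrended fluctuation
  analysis (DFA), the Minkowski (box-counting) fractal dimension D, and
  sample entropy S.
* **Statistics**: Shapiro-gated paired t / Wilcoxon comparisons between
  conditions, zero-intercept regression and ANCOVA for the slope law, and
  dynamic time warping distances between phase-space traces.
* **Synthetic data**: a stochastic frequency-modulated oscillator
  (Q̈ = −ω(t)²Q with ω(t) = ω₀(1 + ε ξ(t)), ξ an Ornstein–Uhlenbeck
  process) and a fractional-Gaussian-noise stride generator with
  prescribed Hurst exponent, so every stage is testable without
  motion-capture recordings.

Intended users: movement scientists and biomechanists analysing pelvic
marker trajectories (vertical coordinate of RASI/LASI/RPSI/LPSI, mm,
120 Hz) and stride-interval series, and anyone studying fractal gait
variability with synthetic benchmarks.

## Worked example

Generate two minutes of synthetic walking (markers at 120 Hz, 512
fractal strides), process the markers, and compute the SI metrics:

```sh
adiagait simulate --out demo --seed 7 --duration 120 --n-strides 512
adiagait process demo/markers.csv --out demo/proc
adiagait metrics demo/strides.csv --out demo/metrics.json
```

The `process` step prints

```
50 cycles; piI = 0.00596481 J s/kg
```

i.e. 50 gait cycles were segmented from the Q(t) maxima and the invariant
(reported as π·*I*) is ≈ 0.006 J·s/kg. For the default generator
(amplitude 0.02 m, oscillator frequency 0.85 Hz, one gait cycle = two
oscillations) the noise-free closed form is
π·*I* = 2π²·0.85·0.02² ≈ 0.0067 J·s/kg; the simulated value wanders a few
percent below it because the ε = 0.03 frequency noise makes the action
drift slowly. The `metrics` step prints

```
{"CV": 0.026, "D": 1.249, "H": 0.768, "S": 2.061, "SI": 1.18}
```

matching the generator's targets (SI = 1.18 s, CV = 0.026, Hurst 0.8;
D ≈ 2 − H for fractal stride series). `demo/proc/` also contains the
per-cycle table (`cycles.csv`), the filtered Q/P signals (`qp.csv`) and
the 1200-bin averaged phase-space attractor (`attractor.csv`).

Two condition tables (one row per subject with columns
`subject,SI,CV,H,D,S`) can be compared with
`adiagait compare ctrl.csv metro.csv --out report/`, which writes a
Markdown table and JSON with the gated paired tests.

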