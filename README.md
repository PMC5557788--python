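# tempsf — temporal structure function analysis for spike trains and time series

`tempsf` computes the **temporal structure function**

```
S_q(τ) = ⟨ |I_t − I_{t+τ}|^q ⟩
```

of a time series — typically a sequence of interspike intervals (ISI)
recorded from a single neuron — and reads its shape to decide whether the
underlying dynamics are **random**, **oscillatory**, or **nonlinearly
correlated** (chaos-like, with a finite memory).

## The scientific problem

Spike trains from real neurons often look irregular, yet the irregularity
can hide structure: a basal-ganglia neuron may fire with intervals that
are correlated over hundreds of spikes, or oscillate at a few hertz under
broadband noise. Classical tools (ISI histograms, autocorrelation) miss
or under-resolve this. The structure function — borrowed from turbulence
analysis — averages the q-th absolute moment of increments at every lag
τ, and its shape is diagnostic:

- **Random (uncorrelated) signals.** S(τ) is flat: increments look the
  same at every lag, so the log-log slope ζ(q) ≈ 0.
- **Oscillatory signals.** S(τ) itself oscillates in τ with the signal's
  period; the oscillation survives heavy additive noise because noise
  only offsets the curve. The signal frequency is recovered from the
  SF's own periodicity.
- **Nonlinear / chaotic signals.** S(τ) rises as a power law τ^ζ up to a
  **breakpoint τ₁** — the memory horizon of the dynamics — and then
  saturates into a **plateau of height S_p**. Both τ₁ and S_p are
  physically meaningful: τ₁ measures how long the past constrains the
  future, and the normalized S_p drops when uncorrelated noise is mixed
  in, making it a noise-contamination (or, in behavioural data, an
  arousal-state) index.

All structure functions are **normalized to S(τ=1) = 1**, so different
cells, sessions and noise levels are directly comparable.

## Worked example

Simulate a Lorenz-attractor x-series (the canonical nonlinear test
signal), then characterize it — with the `sf` command line:

```console
$ sf simulate lorenz --seed 3 --out lorenz.csv
[sf] simulate lorenz: 0.01s
[sf] wrote lorenz.csv (10000 samples) and lorenz.json
$ sf characterize lorenz.csv
{
  "label": "nonlinear",
  "tau1": 41,
  "slope_pre": 0.5508882608146947,
  "sp": 28.20536485615882,
  "sp_window": [100, 200],
  "omega_signal": 0.015,
  "mean_zeta": 0.2050537245190159,
  "flags": {"nonlinear": true, "oscillatory": true, "random": false}
}
```

The same analysis from Python:

```python
from tempsf import (LorenzParams, ScaleRange, simulate_lorenz,
                    structure_function, normalize_sf, detect_breakpoint,
                    fit_scaling_exponent, classify_signal)

series = simulate_lorenz(LorenzParams(seed=3))
sf = normalize_sf(structure_function(series, ScaleRange(1, 1000)))
bp = detect_breakpoint(sf)
print("tau1 =", bp.tau1, " slope_pre = %.3f" % bp.slope_pre)
fit = fit_scaling_exponent(sf, fit_range=ScaleRange(1, bp.tau1))
print("zeta(1) below tau1 = %.3f" % fit.zeta)
print("label:", classify_signal(sf).label)
```

printing

```
tau1 = 41  slope_pre = 0.551
zeta(1) below tau1 = 0.842
label: nonlinear
```

The two contrasting toy signals behave as the theory predicts. A 1 Hz
sinusoid sampled at 100 Hz is recognized through the SF's own period:

```console
$ sf simulate sine --seed 0 --out sine.csv && sf characterize sine.csv --samp 100
{
  "label": "oscillatory",
  ...
  "omega_signal": 1.0,
  ...
}
```

and an ensemble of 30 i.i.d. Gaussian signals (N(1, 0.1²), 10⁴ samples
each) has a mean SF regression slope indistinguishable from zero:

```python
>>> from tempsf import random_slope_study
>>> res = random_slope_study(seed=2017)
>>> print("mean slope = %.3e  sd = %.3e" % (res.mean_slope, res.sd_slope))
mean slope = -3.303e-07  sd = 1.458e-06
```

## Command-line interface

```
sf compute        S_q(τ) of a single-column CSV series → TSV + JSON sidecar
sf characterize   classify a series; breakpoint, plateau, frequency → JSON
sf simulate       generate toy signals (normal | sine | lorenz) → CSV
sf experiment     scripted validation studies (random-slopes | sine-noise |
                  lorenz-noise | segments) → TSV / JSON
sf isi            convert a spike-time list to an ISI series CSV
```

Run `sf <command> --help` for options. Stage timings are logged to
stderr; all data outputs go to files or stdout as plain text.

## Scope

The package analyses one series at a time and ships synthetic
generators; it does not do spike sorting, multifractal (multi-q
intermittency) analysis, or provide recorded neural data. See
`docs/methods.md` for estimator design, default calibrations and known
limitations.
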