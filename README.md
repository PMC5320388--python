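# misoarx

Single-trial evoked-potential (EP) extraction by **multiple-input
single-output ARX modelling** (MISO-ARX) with sparse-coding latency
pre-estimation.

Evoked potentials are stereotyped brain responses time-locked to a
stimulus, buried in ongoing EEG at signal-to-noise ratios below 0 dB.
Conventional single-trial estimators (Cerutti-style ARX) filter an
averaged reference EP (AREP) through an identified ARX model, but they
assume the trial is time-aligned with the template — when a component's
latency varies, which is exactly the clinically interesting case, the
estimate collapses.  `misoarx` models each EP component separately:

* the EP complex is a superposition of Q components, each an
  ARMA-filtered, delayed copy of a **subtemplate** (a windowed slice of
  the AREP isolating one deflection):

  `s(t) = Σ_q B̄_q(z⁻¹) u_q(t) / A(z⁻¹)`,  `B̄_q(z⁻¹) = z^(−d̄_q) Σ_j b̄_j^q z^(−j)`

* the background EEG is an AR process driven by white noise,
  `e(t) = w(t) / A(z⁻¹)`, sharing the denominator `A`;
* each component's integer delay `d̄_q` is **pre-estimated by sparse
  coding** the epoch over a dictionary of shift-translated subtemplate
  atoms (orthogonal matching pursuit; for the benchmark, a
  component-ordered pursuit with AR-prewhitening), then refined by a
  bounded search;
* multiplying through by `A(z⁻¹)` makes the model linear in
  `(a, b̄)`, so one ordinary-least-squares fit per trial identifies all
  parameters simultaneously; the EP and its per-component parts are
  reconstructed by ARMA filtering the subtemplates.

The package ships the full simulation benchmark it is validated on: a
three-lobe sinc reference EP whose third (largest) wave moves with a
latency parameter `l`, near-unit-root AR(4) background EEG, and
SNR-controlled trial mixtures, together with the Monte-Carlo harness
that measures latency-tracking accuracy and output SNR for MISO-ARX and
the classical ARX baseline.

## Worked example

`examples/01_extract_single_trial.py` builds one 0 dB trial whose third
wave arrives 0.75 time units early (`l = 3`), and runs the pipeline:

```
template decomposed into 3 components, peaks at [2.08, 4.12, 5.98] time units
observation SNR: +0.00 dB
estimated component lags (samples): [-156, 49, -68]
third-wave latency: estimated 5.420 vs true 5.250 time units (error 0.170)
reconstruction output SNR: +2.60 dB
```

The tracked (third, largest) component's lag is estimated at −68
samples against its analytic shift of −75; after the model fit and
refinement its reconstructed peak lands within the 0.25-time-unit hit
tolerance.  The two small early components are at the noise floor in a
single 0 dB trial, so their lags are individually unreliable — the
method's claim is about the component being tracked.  A positive output
SNR means the reconstruction error carries less power than the EP
itself.

`examples/02_latency_tracking_benchmark.py` prints the accuracy grid of
both estimators (10 trials/cell):

```
 snr_db     l  true lat  miso_arx    arx
      0     7      4.25      1.00   0.00
      0     3      5.25      1.00   0.00
      0    -1      6.25      1.00   1.00
      0    -5      7.25      1.00   0.00
    -10     7      4.25      0.90   0.00
    ...
```

The lag-zero ARX baseline only scores when the true latency happens to
sit at the template position (`l = −1`); MISO-ARX tracks every shift.

There is also a thin CLI (`misoarx simulate | decompose | lags |
estimate | evaluate`) that writes delimited-text waveforms with JSON
sidecars and a `config.json` capturing the exact settings and seed of
every run; `misoarx --help` lists the stages.

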