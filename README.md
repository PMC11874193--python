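# isochron

Simulation and analysis of EEG responses to isochronous tone sequences:
how the brain encodes temporal regularity, and how that encoding
changes with age.

When tones arrive every 650 ms (stimulation frequency
Sf = 1/0.65 ≈ 1.54 Hz), neural activity shows a tone-locked evoked
response (the auditory N100), a spectral peak at Sf once the 1/f
background is removed, and phase alignment across trials. `isochron`
implements the full analysis chain for this paradigm —

* **N100 peak metrics** — single-trial amplitude/latency in a 60 ms
  window centred 100 ms post-onset, fronto-central cluster, tone
  positions 3–7, plus intra-individual variability;
* **spectral parametrization** — Hann-tapered spectra of 8 s sequence
  segments on an Sf-anchored 0.2 Hz grid, decomposed into an aperiodic
  ("fractal") component `log10 P(f) = offset − χ·log10 f` and the
  oscillatory residual, whose value at Sf indexes entrainment;
* **inter-trial phase coherence** — `ITPC(f) = |mean(c/|c|)|` over
  trials (1 = locked, √π/(2√N) under uniform phases);
* **time-resolved ITPC** — the same statistic on single-trial 3-cycle
  Morlet coefficients, band-averaged, with its linear build-up slope
  fitted from the 3rd to the 8th tone onset (1.3–4.55 s);
* **group inference** — label-permutation tests (1000 permutations,
  add-one two-sided p) and a closed-form balanced random-intercept
  estimator for `endpoint ~ 1 + Group + (1 | participant)`;

and, because the human recordings behind the paradigm are not publicly
deposited, a **synthetic-data generator** that emulates the experiment
with known, recoverable ground truth: tone-locked evoked kernels with
latency jitter, entrained oscillations whose phase concentration and
within-sequence build-up are parameters, 1/f backgrounds, and an
endogenous alpha rhythm. Every analysis stage is validated against the
generator and against independent oracles (exhaustive permutation
enumeration, Welch periodograms, MNE's wavelet transform, closed-form
complex arithmetic).

## Worked example

`examples/05_group_study.py` simulates a young and an older cohort
(8 subjects per group, 24 sequences each — the desk-scale profile of
the 18/96 reference design), runs preprocessing, all four analyses and
the permutation tests, and prints:

```
endpoint                  old - young        p  expectation
n100_amplitude                -0.4565   0.0110  old - young < 0  [ok]
fractal_power                 +0.2095   0.0020  old - young > 0  [ok]
itpc_sf                       -0.0850   0.0010  old - young < 0  [ok]
titpc_slope_delta             -0.0136   0.0210  old - young < 0  [ok]
titpc_slope_theta             -0.0150   0.0010  old - young < 0  [ok]
titpc_slope_alpha             -0.0057   0.1099  no difference    [ok]
titpc_slope_beta              -0.0040   0.2188  no difference    [ok]

full aging pattern reproduced: True
```

Reading the table: the older group's N100 is 0.46 units deeper (more
negative) and its 1/f fractal component 0.21 log10-power units
stronger, while the younger group holds higher phase coherence at the
stimulation frequency (ITPC difference 0.085) and a steeper coherence
build-up in the delta and theta bands; the alpha/beta slopes — where
no entrainment exists — show no significant difference. Each p comes
from a 1000-permutation group-label test.

The other examples are single-capability walk-throughs:
`01_simulate_paradigm.py` (stimulus schedule and raw signal),
`02_n100_peaks.py` (cleaning chain + peak extraction),
`03_spectral_decomposition.py` (1/f fit and Sf residual),
`04_phase_coherence.py` (ITPC and the t-ITPC slope). Each runs from
the repository root and prints what it computes with one line on what
the numbers mean. Cohort runs can also be configured from YAML via
`isochron.load_config`.

## Layout

```
src/isochron/
  paradigm.py     stimulus schedules (ParadigmSpec, make_paradigm)
  synth.py        synthetic EEG generator (SubjectParams, synth_subject, synth_cohort)
  preprocess.py   filters, channel rejection, artifact suppression, segmentation
  erp.py          N100 peak amplitude/latency/variability
  spectral.py     Sf-anchored spectra, aperiodic fit, oscillatory residual
  phase.py        ITPC, Morlet transform, t-ITPC and its slope
  stats.py        permutation tests, balanced random-intercept estimator
  pipeline.py     run_all: simulate -> clean -> analyze -> test
  io.py           events TSV, manifests, EDF reading via MNE
```

`docs/methods.md` documents the generative model, every analysis
choice and its rationale, numerical details, and known limitations.
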