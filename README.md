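# vmdcm — hierarchical visuomotor-control analysis

`vmdcm` is a reusable, tested implementation of a hierarchical analysis of
visuomotor control: how the primary motor cortex (ML), visual cortex (VL)
and cerebellum (CBR) interact while a person tracks a moving target with
and without visual feedback of their own hand. It is written for
researchers who want to run — or interrogate — this kind of
effective-connectivity pipeline end to end on data with *known ground
truth* before trusting it on recordings.

The pipeline couples three data streams:

* **tracking behavior** (30 Hz target/cursor traces): performance is
  `RMSE = sqrt((1/T) Σ_t (z_t − y_t)²)` pixels; the per-subject
  improvement from feedback, `RMSE(TTNF) − RMSE(TT)`, z-scored, is a
  group covariate;
* **surface EMG** (8 muscles, 2 kHz): notch + band-pass filtering,
  segmentation into reciprocating-movement repetitions, per-repetition
  median frequency (the bin that halves the periodogram's power) and RMS
  amplitude, normalized per subject × muscle by the no-feedback
  repetition mean — which forces the no-feedback average of every
  normalized feature to exactly 1.000;
* **ROI BOLD fMRI**: a three-region bilinear dynamic causal model,
  `dx/dt = (A + u₂B)x + Cu`, with log-scaled self-connections
  (`−0.5·e^σ`), a balloon–Windkessel hemodynamic observation model, and
  subject-level inversion by variational Laplace (Gauss–Newton ascent on
  the free energy with Levenberg–Marquardt damping).

Subject posteriors feed a group-level **parametric empirical Bayes** model
with the two covariates, pruned by **Bayesian model reduction** (greedy
search with a 3-nat positive-evidence margin) and summarized by
**Bayesian model averaging** (posterior means and posterior probabilities
per connection × covariate), plus **leave-one-out cross-validation** that
predicts each held-out subject's covariate from designated connections
with 90 % credible intervals.

A first-class synthetic-data module generates the whole study — block
design, target kinematics, tracking noise, EMG spectra, BOLD — from a
single seed with known group-level ground truth, so every stage is
falsifiable. See `docs/methods.md` for the models, default parameters and
their rationale, and what the generator does and does not emulate.

## Worked example

Run the default synthetic study end to end (14 subjects, 3 sessions;
about 4 minutes on one CPU):

```
vmdcm all --seed 7 --out demo
```

`behavior_test.json` shows the behavioral effect of visual feedback —
tracking error is reliably lower with the cursor visible:

```
{"t": 3.736, "p": 0.0025, "n": 14}
```

`report/emg_mdf.tsv` is the normalized median-frequency table:

```
row        FCR    ECRL   BR     BCM    TCM    ADS    PD     SFT    Mean
TTNF mean  1.000  1.000  1.000  1.000  1.000  1.000  1.000  1.000  1.000
TT mean    1.009  1.008  1.007  1.009  1.009  1.009  1.008  1.007  1.008
```

The no-feedback row is exactly 1.000 by the normalization identity; the
feedback row sits above 1 because this cohort's EMG spectra shift up
during feedback tracking. `report/connectivity.tsv` lists each
connection's group-average strength in Hz with its posterior probability
in parentheses (dashes mark effects pruned by the model search), e.g.
for this run

```
param  mean            mean_mdf
a11    -0.667 (1.00)   -
a21     0.321 (1.00)   -0.130 (0.97)
```

— the cerebellar self-inhibition and the cerebellum→motor connection are
retained with full posterior probability. `report/loocv_summary.json`
holds the LOOCV correlations and interval coverage per designated
connection. A caution that is itself a result: at the default noise the
*between-subject* signal in the feedback modulations is at the edge of
what ~230 scans per subject can identify, so several modulations are
pruned at the group level and the LOOCV correlations for them are
unreliable (differential shrinkage can even invert their sign); see the
limitations section of `docs/methods.md` before interpreting those
columns on data of this size.

Everything is also callable as a library; the same run is

```python
from vmdcm import load_config, run_pipeline
cfg = load_config(None, seed=7)
manifest = run_pipeline(cfg, "demo")
```

and the stages (`simulate`, `behavior`, `emg`, `invert`, `peb`, `loocv`,
`report`) can be run individually on an existing run directory.

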