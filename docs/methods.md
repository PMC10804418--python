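# Methods

This note documents the models, the synthetic cohort, the numerical
choices, and the known limits of `vmdcm`. It is the package's own account
of its science; every number quoted here is computed by the test suite or
the acceptance script, not asserted from memory.

## The experiment being emulated

Subjects track a vertically reciprocating target with a hand controller
under two conditions: **TT** (the cursor is visible — closed-loop tracking
with visual feedback) and **TTNF** (the cursor is hidden — open-loop
tracking; the base condition). Each of 3 sessions holds three 21-s blocks
of each condition in random order with 15-s rests. Three observables are
analysed:

* **behavior** — target and cursor positions at 30 Hz; performance is the
  root mean square error over a block, `RMSE = sqrt(mean((z_t - y_t)^2))`
  in pixels; the per-subject *improvement* `RMSE(TTNF) − RMSE(TT)` is the
  first group covariate;
* **EMG** — 8 upper-limb muscles at 2 kHz; per-repetition median frequency
  (MDF) and RMS amplitude, normalized per subject × muscle by the TTNF
  repetition mean; the across-muscle mean normalized MDF during TT is the
  second covariate;
* **BOLD fMRI** — ROI time series of right cerebellum (CBR), left primary
  motor cortex (ML) and left visual cortex (VL) at a repetition time of
  1.91 s, modelled by a bilinear dynamic causal model (DCM).

## The DCM

Neuronal dynamics: `dx/dt = (A + u2·B) x + C u`, with `u1`/`u2` box-cars
for TTNF/TT blocks. TTNF is the base condition, so its modulation matrix
is structurally zero; only the TT input modulates connectivity.

**Self-connections** use the log-scaling convention: the effective
self-connection of region *j* is `−0.5·exp(A_jj + u2·B_jj)` Hz. We
verified numerically that reading the reported self-connection values as
literal Hz rates yields an unstable system in *both* conditions (leading
eigenvalues +0.18 Hz in TTNF and +1.32 Hz in TT, i.e. divergence within a
block), while the log convention gives stable dynamics in both (−0.22 and
−0.25 Hz). The log convention is also what standard DCM software uses,
and is the only reading under which a positive self-modulation means
"stronger self-inhibition". Off-diagonal and driving-input entries are
literal Hz. A `linear` mode (the textbook bilinear equation, diagonal
included) is available for didactic and oracle-test use.

**Hemodynamics**: the balloon–Windkessel cascade per region — vasodilatory
signal (decay κ = 0.64 s⁻¹, autoregulation γ = 0.32 s⁻¹), blood flow,
venous volume (transit time τ = 2 s, stiffness α = 0.32) and
deoxyhemoglobin (resting extraction E₀ = 0.4) — with the nonlinear BOLD
equation at TE = 31 ms and V₀ = 0.04, in percent signal change. Flow,
volume and dHb are integrated in log space so they remain positive for
arbitrary parameter proposals; the derivative evaluation clamps the log
states to ±6 because beyond that range the balloon model is out of its
regime and 1/f-type terms are numerically singular. Per-region log-transit
times are free parameters (prior sd 1/8); the other hemodynamic constants
are fixed.

**Integration**: fixed-step RK4 on a microtime grid of TR/16 ≈ 0.119 s
(Euler available). Block edges are quantized to the schedule's native
microtime grid so that refining the grid refines the integrator, not the
stimulus: halving the step changes the noise-free prediction by well under
0.1 % RMS, while the Euler-vs-RK4 difference at the default step is about
0.5 % of the signal range (Euler's first-order error on the fast
feedback-condition mode dominates).

**Priors** (zero-mean Gaussians): variance 1/4 for all A entries
(including self log-scalings), 1 for B and C entries, 1/64 for log-transit
times. These are weakly informative at the scale of the effects the model
is meant to carry (average connections a few tenths of a Hz, modulations
up to ~1.8). We initially used much tighter connectivity priors (variance
1/16) and found the free energy at the *generating* parameters to be about
100 nats below that of a collapsed fit — the prior penalty of a 1.8-unit
modulation at sd 0.25 alone is ~26 nats — so tight priors make parameter
recovery impossible by construction; the broad scales fix that while
leaving genuinely absent connections prunable at the group level.

**Inversion** is variational Laplace: iterated Gauss–Newton ascent on the
free energy with Levenberg–Marquardt damping, observation noise i.i.d.
Gaussian per region with a log-precision hyperparameter updated by a
closed-form (EM) fixed point (capped at e²⁴ so noiseless data cannot
produce infinite precision). Candidate steps are screened with a cheap
single forward integration (re-using the current Jacobian for the
curvature-dependent free-energy terms) and *confirmed* with a fresh
Jacobian, so the accepted free-energy sequence is non-decreasing by
construction. Step acceptance retries damping over ~10 octaves and
extrapolates along accepted directions. Jacobians are one-sided finite
differences (step 1e-4) computed in a single batched integration, which
is what makes subject fits take seconds rather than minutes. The
likelihood is multimodal; the default fit is therefore *staged* — a
modulation-free (B ≡ 0) model is fitted first and seeds the full fit —
and extra randomized starts are available. Convergence: |ΔF| < 0.01 on
three consecutive accepted steps, or 128 iterations. Confounds: the data
and predictions are both projected against per-session constant
regressors, which makes the fit exactly invariant to per-session offsets.

## Group level

**PEB**: subject posterior means enter a hierarchical Gaussian model
`θ_i = (x_iᵀ ⊗ I) β + ε_i` with design rows `x_i` = (1, covariates…),
covariates mean-centered and z-scored (sample sd). The between-subject
covariance is `exp(−γ)·(prior variance/16)`, with the scalar γ set by
maximizing the marginal likelihood (empirical Bayes); β then has an exact
Gaussian posterior. The /16 convention (random effects an order of
magnitude tighter than the prior) matters: using the prior variance
directly inflates the LOOCV predictive intervals four-fold and pushes
interval coverage to 100 %.

**Bayesian model reduction** is the exact Gaussian identity for a model
whose prior pins selected effects to a point mass (variance 1e-8) at zero;
it is validated in the tests against explicit re-fits of reduced linear
models (agreement to ≪ 0.1 nats).

**Greedy search** repeatedly evaluates switching off each candidate group
effect (all B and C entries and off-diagonal A for the group-mean column,
everything for covariate columns; self-connections in the mean are always
retained) and discards, in batches, those whose removal costs less than
**3 nats** of evidence. The 3-nat "positive evidence" margin is needed
because with ~50 candidate covariate effects, ~3σ null fluctuations
carrying a nat or two of apparent evidence are expected in half of all
cohorts; without the margin the search keeps one or two spurious
covariate effects in about 50 % of null runs, with it the null cohort is
cleaned in ≥ 90 %.

**BMA**: all 2^k on/off combinations of the ≤ 8 surviving candidates are
scored by reduction; posterior model probabilities are the softmax of the
evidences; a parameter's posterior probability (PP) is the summed weight
of models containing it, and parameters with PP < 0.5 are reported as
pruned.

**LOOCV**: for each left-out subject, a PEB (mean + one covariate) is
fitted to the rest using only the designated connections; the left-out
covariate is predicted through the posterior predictive density
`p(x|m) ∝ N(x;0,1)·N(m; μ_m + μ_c x, Σ_b + S_loo + V(x))`, where `V(x)`
propagates the group-effect posterior covariance. The density is
evaluated on a fixed grid (x ∈ [−6, 6], 601 points), giving the
expectation and the central 90 % interval; predictions are mapped from
the training fold's covariate scale back to the full-sample z-scale
(without this, fold-wise re-standardization systematically mispredicts
the extreme subjects, which is exactly where interval coverage is
decided). The whole report is a deterministic function of the data.
The reported Pearson r under a *null* covariate does not concentrate near
zero at n = 14 — its sampling sd alone is 1/√13 ≈ 0.28 and leave-one-out
adds a negative bias — so the meaningful null property, and the one we
test, is discriminability: null runs essentially never reach the r that
injected couplings produce reliably.

## The synthetic cohort (and what it does not emulate)

The generator's defaults are the study conditions:

* schedule constants as above; target steps of 25 px plus half-normal
  jitter (scale 1 px, clipped to [0, 2]) at one step per 30 Hz sample,
  bounded to [200, 600] px with reversal at the bounds (cadence is a
  config knob; the bound-to-bound sweep takes ~0.5 s);
* tracking error: TT cursor = target + white noise; TTNF cursor
  additionally accumulates a per-block random walk (open-loop drift).
  Per-subject noise scales are calibrated so that the group means are
  ≈ 81.5 px (TT) and ≈ 120.8 px (TTNF, split evenly between white noise
  and drift variance), with between-subject sds of 14.4 px and an
  improvement sd of 25 px;
* EMG: stationary band-limited (20–150 Hz) Gaussian noise per channel
  with a Gaussian spectral envelope centred at 80 Hz (width 30 Hz), the
  centre shifted up and the RMS scaled during TT blocks (subject-level
  TT/TTNF MDF ratio ~ N(1.014, 0.044²), amplitude ratio 1.068), plus
  mains sinusoids at 60/120/180/240 Hz;
* connectivity: group means fixed at the reported three-region values;
  between-subject sd 0.0625 Hz on every parameter (the prior-variance/16
  convention); covariate effects injected only on the connections
  reported to carry them — improvement on the motor self- and
  visuomotor modulations (+0.577, +0.189 per z), mean MDF on the
  cerebellar self-modulation (+0.960 per z) — so group-level recovery is
  falsifiable;
* subjects are drawn by rejection sampling restricted to dynamically
  admissible parameter sets: strictly stable in both condition regimes,
  no mode faster than 20 Hz, steady-state neuronal gain below 3, and
  steady-state activity above −0.25 (sustained deactivation beyond
  −γ = −0.32 has no positive-flow equilibrium in the balloon model). If
  a subject's covariate-shifted mean itself is inadmissible, the whole
  deviation is attenuated stepwise toward the group mean. This
  stability truncation slightly bends the covariate→parameter linearity
  for extreme subjects;
* BOLD observation noise: sd 0.5 (percent-signal units) against a signal
  of sd ≈ 2.6 — a validation regime in which subject fits explain ~90 %
  of variance, chosen so that recovery failures indict the estimator
  rather than the noise. Real ROI recordings are far noisier; explained
  variance near 36 % corresponds to noise ≈ 3.5 in these units and can
  be requested in the config.

Randomness: one master seed fans out per stream and subject as
`default_rng([seed, stream_code, subject])`; stream codes are in
`synthetic_data.STREAMS`.

Real data differ in ways the generator does not attempt: no physiological
confounds or scanner drift in the BOLD (so explained variance is not
comparable to real fits), no muscle synergies, fatigue or motion artifacts
in the EMG (channels are independent), no biomechanics linking the three
observables, and sessions are dynamically independent. Passing tests
therefore demonstrate that the estimators recover the structure the model
family can express, not that they would recover it from recorded data.

## Problem sizes used by the test suite

Chosen so the default run completes comfortably on one CPU: the group
parameter-recovery Monte Carlo runs 20 replicates of 14 subjects with 2
sessions each and single-start inversions capped at 48 iterations; the
covariate-recovery/LOOCV Monte Carlo runs 100 cohorts at the
subject-posterior level (ground-truth parameters plus estimation noise of
sd 0.1), which is the exact unit the group stages consume; statistical
calibrations use 2000 replicates at the subject-level-feature unit; EMG
Monte Carlos use shortened two-block sessions. The full default pipeline
(14 subjects, 3 sessions, all stages) runs in a few minutes.

## Known limitations

* Subject-level recovery of all 24 connectivity parameters from ~230
  scans is fundamentally limited: the posterior has ridges among the
  cerebellum-bound modulations (b112/b122/b132 and the TT input to CBR
  trade off), and at the default noise the free energies of the
  generating parameters and of a ridge solution differ by only a few
  nats. Group-mean recovery correlations measured under the test
  conditions are ~0.75–0.85, below the 0.9 aspiration, and the sign of
  the weak cerebellum-bound modulation is the least stable.
* Between-subject *differences* in the motor self-modulation are subject
  to differential shrinkage: a larger true modulation means stronger
  feedback-condition self-inhibition, hence a weaker (lower-SNR) response
  and an estimate that shrinks harder toward zero. Noise-free fits track
  the modulation monotonically, but at the default noise this
  shrinkage can invert the between-subject slope, so end-to-end
  covariate prediction through full inversion is unreliable (and can be
  significantly anticorrelated) even though the group-level
  PEB/BMR/LOOCV machinery is correct and calibrated when given
  subject posteriors of ordinary quality. The pipeline reports
  correlations exactly as computed.
* The greedy search's 3-nat margin trades a small loss of sensitivity
  (genuine effects below ~3 nats of evidence are pruned) for null
  specificity.
* The LOOCV interval-coverage calibration (measured ≈ 0.95–0.98 mean
  coverage at nominal 0.90) is slightly conservative because the
  predictive marginalizes group-effect uncertainty on top of a
  well-specified generator.
* The variational optimizer is local; the staged fit removes most but
  not all basin sensitivity (noiseless fits reach > 99 % explained
  variance quickly yet can keep crawling along near-degenerate
  directions for hundreds of iterations).
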