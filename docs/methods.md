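# Methods

This note records the models, conventions and design choices behind
`neuroasym`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and R2 extraction

A blink-reflex sweep is modelled as a stimulus artifact at each stimulus
onset, an early ipsilateral R1 burst (10–16 ms), and a late R2 burst
measured as the raw peak-to-peak amplitude inside a latency window locked to
the relevant stimulus. The **R2 window defaults to 27–87 ms** post-stimulus
— conventional clinical values, configurable because protocols differ. For a
conditioned (paired-stimulation) sweep the conditioned R2 is measured
relative to the *test* (second) stimulus; ISIs at or below 100 ms are
flagged in curve metadata as potentially overlapping late
conditioning-response activity, and the overlap is accepted rather than
corrected, matching clinical practice. No filtering or rectification is
applied: recording-time filters are treated as properties of the input.

Trials at one ISI are combined by **ratio of mean amplitudes** (default)
rather than mean of per-trial ratios: the former stays stable when single
conditioned trials are near zero. Missing battery cells raise a protocol
error naming the absent ISIs; nothing is imputed.

The recovery cycle is the map ISI → 100 × conditioned/unconditioned
peak-to-peak ratio over the battery {100, 150, 200, 300, 400, 500, 750} ms.
Ratios may exceed 100% (facilitation). All ratios are scale-invariant in the
raw signal, a property the tests enforce.

## Asymmetry indices

AI(s₁, s₂) = |s₁ − s₂|/(s₁ + s₂), undefined when both sides are zero
(raised, not imputed). For the recovery cycle the sides are the
MAS-stimulation and LAS-stimulation ratios at one ISI; AIs are reported for
ISIs 100/150/200 (the short-ISI range where group differences live), with
**ISI 100 as the default classification feature** — under the binormal
identity, the ISI-100 group summaries are the ones consistent with the
published single-marker AUC. For MRI the sides are hemispheric metrics of
the hemispheres *contralateral* to the clinical MAS and LAS; hemispheric GM
volume (mm³) is the default metric, mean cortical thickness (mm) an
accepted alternative, because published tables are ambiguous between the
two. AI values are kept unrounded internally; rounding happens only in
reporting.

## Diagnostic evaluation

- **ROC**: empirical curve (ties collapse to one threshold step),
  trapezoidal AUC; equals the Mann–Whitney pair-counting statistic, which
  the tests verify exhaustively for n ≤ 30.
- **Youden cutoff**: maximises J over observed threshold steps, compared in
  exact integer arithmetic (tp·N − fp·P) so float rounding cannot scramble
  ties; among equal-J thresholds the more specific one wins; the reported
  cutoff is the midpoint between adjacent observed scores (±∞ at the ends).
- **Cutoff semantics**: strictly greater-than, per the clinical phrasing
  "cutoff greater than …"; midpoint cutoffs make strict/non-strict
  equivalent on observed data.
- **Confidence intervals**: Clopper–Pearson exact intervals from Beta
  quantiles (`scipy.stats.binomtest(...).proportion_ci(method="exact")`).
  This method — rather than Wald or Wilson — reproduces published intervals
  of this literature to the printed decimal; conservatism (coverage ≥
  nominal) is property-tested.
- **Binormal bridge**: AUC = Φ(|μ₁ − μ₀|/√(σ₁² + σ₀²)) connects group
  mean ± SD summaries to an implied AUC.
- **Positive-class conventions**: PD is positive for the recovery-cycle AI
  (higher AI ⇒ PD), CBS for the MRI AI (higher AI ⇒ CBS).

### Combining the two AIs

Two modes are computed and reported side by side:

1. **Sequential rule** (transparent): PD if recovery-cycle AI > its cutoff;
   else CBS if MRI AI > its cutoff; else PD (the doubly-negative cell is
   PD-like: PD patients without reflex asymmetry also lack cortical
   asymmetry). Its signed margin serves as a degenerate score for ROC.
2. **Logistic score** (fitted): in-sample logistic regression on the two
   AIs, classified at the Youden cutoff of the fitted score.

A quadrant rule built from the two published cutoffs *cannot* be perfect on
a cohort with the published misclassification structure: the patients
misclassified by each single marker land in mixed cells of the 2×2 cutoff
plane (doubly-negative: 2 PD + 3 CBS; doubly-positive: 2 PD + 1 CBS), so no
assignment of labels to cells classifies everyone correctly. Perfect
combined accuracy is achievable only by a fitted score on the raw AI values
— which is also what period-typical ROC software did. Consequently the
perfect-combination headline is carried by the logistic mode; the
sequential rule is kept as the reproducible bedside approximation.

Under complete separation the logistic MLE does not exist; the package
detects this, flags the fit (`separable=True`), and obtains a finite
separating direction from a weakly ridge-penalised refit on standardised
features (C = 10³). The flag, not the Wald table, is the reportable result
in that case.

## Group statistics

Student and Welch t tests run from raw data or from (n, mean, SD)
summaries; Mann–Whitney uses the exact null distribution for tie-free
samples with combined n ≤ 20 and the tie-corrected normal approximation
otherwise (fully tied data give p = 1 by convention). Proportions use
chi-square, switching to Fisher's exact test when an expected cell is
below 5. Because the assignment of parametric vs non-parametric tests to
individual variables in published tables is generally unknowable, the
comparison table reports all variants side by side and no published
table-level p-value is asserted. The age-adjusted association uses a
maximum-likelihood logistic fit with Wald p-values; (quasi-)separation is
detected and flagged rather than reported as converged.

## Synthetic cohort generator

The generator emulates a two-group cohort (defaults: 14 PD, 10 CBS) with
the published demographic and marker summaries as defaults:
age 64.6 ± 7.5 vs 71.1 ± 5.9 y, duration 1.7 ± 1.3 vs 2.9 ± 1.4 y, motor
score 24.8 ± 11.8 vs 37.6 ± 15.2, H&Y 1.9 ± 0.3 vs 2.1 ± 0.5 (rounded to
the 0.5 grid), male proportion 0.50/0.40, right-MAS proportion 0.50/0.70
(the published percentages are used as proportions; the PD count/percent
cell is internally inconsistent in the source table, and the percentage is
taken as authoritative), recovery-cycle AI at ISI 100/150/200 of
0.86 ± 0.36 / 0.81 ± 0.37 / 0.42 ± 0.36 (PD) and 0.10 ± 0.32 / 0.10 ± 0.32 /
0.04 ± 0.10 (CBS), MRI AI 0.006 ± 0.005 vs 0.02 ± 0.02, total GM volume
402,387 ± 28,257 vs 346,242 ± 24,986 mm³.

**Truncation correction.** Printed mean ± SD pairs are incompatible with
bounded supports (0.86 ± 0.36 on [0,1] puts ~⅓ of the mass above 1; the
largest possible SD for a [0,1] variable with mean 0.86 is 0.347). Each
sampler therefore keeps the printed SD as the latent normal scale and
solves for the latent location such that the *truncated* mean equals the
printed mean, so empirical means converge to the configured targets as n
grows; the realised SD is necessarily below the printed SD. The analytic
truncated moments are exposed (`truncated_moments`) and used as the test
oracle.

**Hemispheres.** The generator draws the MRI AI and the total GM volume and
derives the hemisphere volumes as total·(1 ± AI)/2, with the atrophic
hemisphere contralateral to the MAS in CBS and on a random side in PD.
Drawing the MAS-hemisphere volume independently of the total would implant
hemispheric differences an order of magnitude larger than the published AI
distribution (E|AI| ≈ 0.08 vs 0.006), destroying the MRI marker; deriving
volumes from the AI preserves the quantity the analysis actually uses, and
the implied MAS-hemisphere marginal (≈ 201,000 mm³ PD / 170,000 mm³ CBS)
remains close to the published one, which is kept in the config as a
reference value.

**Trace mode.** Per patient and side, target recovery curves come from a
monotone saturating base profile (8% at ISI 100 rising to 100% at 750),
split by the drawn AI into base·(1 ± AI) — the elevated side being LAS
stimulation in PD and a random side in CBS. Sweeps are synthesized at
5 kHz: artifact, R1, and an R2 burst shaped as a Hann-windowed damped
50 Hz oscillation supported exactly on the extraction window and rescaled
so the discretized peak-to-peak equals the programmed amplitude
(unconditioned default 300 µV), plus additive white noise. Noise-free
extraction is therefore *exact* by construction, a tested invariant.

The default noise SD is 0.5 µV — a post-averaging surface-EMG noise level
chosen so that the peak-to-peak noise floor (≈ 6σ over the 60 ms window,
i.e. ~1% of the unconditioned amplitude) stays below the smallest
programmed conditioned responses. Peak-to-peak extraction has an
irreducible positive bias at near-zero amplitudes; the declared round-trip
contract is ±5 percentage points per battery cell, and the AI-level
tolerance used in tests is the mechanical propagation of that contract,
tol/base-ratio per ISI. This bias is a real feature of clinical
peak-to-peak measurement, not an artifact of the simulation.

What the generator does **not** emulate: realistic EMG spectra, habituation
across trials, R1/R2 latency variability, electrode artifacts beyond a
stylised stimulus spike, or any correlation between demographics and
markers. Passing round-trip tests therefore demonstrates correctness of the
extraction arithmetic under the stated signal model, not robustness to real
recording pathology. Trials per ISI default to 1 (the protocol's trial
count is not standardised; it is a config parameter).

**Fixture cohort.** `fixture_cohort()` is hand-placed, not sampled, so the
published misclassification structure holds exactly: 12/14 PD and 1/10 CBS
above the 0.75 recovery-cycle cutoff; 7/10 CBS and 2/14 PD above the 0.014
MRI cutoff; the two reflex-negative PD patients are MRI-negative and the
reflex-positive CBS patient is MRI-positive. Adjacent observed values are
arranged so the Youden midpoints land exactly on 0.75 (neighbours
0.72/0.78) and 0.014 (neighbours 0.013/0.015) and are unique J maxima, and
the cohort is linearly separable in the two-AI plane (witness direction
AI_reflex − 40·AI_MRI, asserted in tests). Demographics match the published
group means where arithmetic allows.

## Problem sizes and numerics

Summary-mode parameter recovery is tested at n = 10,000 per group;
trace-mode group-mean round trips at 60 per group with single trials — the
scale at which Monte-Carlo error is comfortably below the declared
tolerances. Degenerate inputs raise typed errors (configuration vs data)
mapped to CLI exit codes 2 and 3. The location solver for truncated
sampling brackets adaptively and solves to 1e-12; manifests checksum every
pipeline artifact with SHA-256, and CSV readers parse floats in round-trip
mode so that re-running a configuration reproduces identical checksums.

## Known limitations

- In-sample evaluation only (n = 24 mirrors the source design): no
  cross-validation or optimism correction, no AUC confidence intervals, no
  DeLong comparisons — deliberately out of scope.
- The logistic combination is fitted and evaluated on the same patients;
  with separable data its perfect accuracy is a property of the sample, not
  an expected out-of-sample performance.
- Published empirical single-marker AUCs depend on unpublished per-patient
  values and are not reproducible; the package reproduces the quantities
  that the misclassification counts and group summaries pin down
  (sensitivities, specificities, exact CIs, Youden cutoffs, the binormal
  AUC, and the perfect combined separation).
- The EDF reader maps channels by label and requires `mne`; it is a
  convenience path, exercised only lightly.
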