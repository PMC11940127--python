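# Methods

## The analysis in brief

`hoinet` quantifies *higher-order* functional connectivity between EEG
channels and asks whether a treatment changed it.  For a subset
X^n = (X_1, …, X_n) of band-limited channel signals it estimates three
information-theoretic quantities (all in bits):

- **Total correlation** TC(X^n) = Σ_j H(X_j) − H(X_1, …, X_n), the
  collective constraints — information that is *similar* across channels.
- **Dual total correlation (binding information)**
  DTC(X^n) = H(X_1, …, X_n) − Σ_j H(X_j | X_−j), the shared randomness —
  *complementary* information.
- **O-information** Ω = TC − DTC.  Positive Ω means the subset is
  redundancy-dominated, negative Ω synergy-dominated.

Estimation uses the Gaussian copula: each channel's time series is
rank-transformed to exact standard-normal marginals
(z_t = Φ⁻¹(r_t / (T + 1)), average ranks for ties), after which the
Gaussian entropy formulas apply to the empirical correlation matrix R:

    TC  = −1/2 log2 det R
    DTC = 1/2 [ Σ_j log2 det R_−j − (n − 1) log2 det R ]

These are lower bounds on the true quantities, exact when the copula is
Gaussian, and invariant under strictly increasing per-channel transforms.
No small-sample bias correction is applied: the estimates are used only in
*contrasts* between groups that share T, so the bias cancels from the
comparison by construction.

## Preprocessing

Epoched data (channels × time × trials) are (1) re-referenced to the
instantaneous channel average, (2) averaged over trials into one
representative stimulus-locked trial per participant-session, and
(3) band-filtered into delta (0.5–4 Hz), theta (4–8), alpha (8–12),
beta (12–30), and gamma (30–40 Hz).

The band filter is a zero-phase (forward–backward) order-3 Butterworth
band-pass.  A single band-pass design is used rather than a high-pass +
low-pass cascade: at order 3 the cascade's bidirectional response droops
to 0.78 in the middle of the narrow theta band, while the band-pass stays
above 0.999 and retains the 1–2 Hz delta content that the short epoch only
partially covers.  Epochs are mirror-padded by up to three settling
lengths of the low corner before filtering and trimmed afterwards, so the
0.5 Hz corner's transients stay out of the analysis window.  All three
preprocessing steps are linear, so their order is immaterial to the
result.

## Greedy discriminative search

For one band and one measure (TC, DTC, Ω, or −Ω), every subset at the
seeding order is scored with the between-group Cohen's d of its
per-participant follow-up values,

    d = (μ_treatment − μ_control) / s,
    s² = [(m_t − 1) s_t² + (m_c − 1) s_c²] / (m_t + m_c − 2),

and the best subset (largest d when maximizing, smallest when minimizing;
ties broken by the lexicographically smallest index set) is grown one
channel at a time up to order 16, scoring only the one-channel supersets
of the current best at each step.  TC and DTC seed at pairs; Ω and −Ω seed
at triplets because Ω ≡ 0 on pairs.  The search therefore evaluates
C(n, k₀) + Σ_k (n − k) subsets per participant instead of every C(n, k) —
the trace records this count so the complexity contract is testable.
Both directions are always run; maximizing −Ω finds maximally
*synergistic* discriminative networks and is verified to coincide with
minimizing Ω.

Because all subset measures are determinant functionals of the copula
correlation matrix, that matrix is computed once per participant and every
subset is scored from its submatrices.

## Baseline-adjusted inference

For each subset the search selected at follow-up, the identical measure is
recomputed from the baseline-session data ("back-computation"; the
measures are permutation-invariant, so only subset identity matters).
Each (band, order) model is the ANCOVA

    follow_up ~ intercept + group + baseline,

group coded control = 0 / treatment = 1; the group effect is the type-III
F test with df (1, m − 3).  White's test of homoskedasticity is reported
per model but never gates results.  FDR is controlled with
Benjamini–Hochberg separately within each (measure, direction) family
across all bands and orders; the per-family critical p values are outputs.

**Selection caveat.**  The tested subsets are chosen to *maximize* the
follow-up group difference, so the per-model p values are anti-conservative
by construction; no post-selection correction is applied, matching the
published procedure.  On null cohorts (no planted effects) the pipeline
consequently produces roughly 0.5–1.3 FDR-significant models per family
per run at reduced scale — far above the nominal q = 0.05 — and the
corresponding calibration test in the suite documents this honestly as a
failing property of selection-then-test inference.  Serialized outputs
carry a `selection_caveat` field.  Conclusions from this pipeline should
rest on effect recovery against known ground truth (which the suite
verifies), not on the nominal FDR level.

## Synthetic cohort

No participant EEG is distributed with the study design this package
targets, so validation runs on a synthetic cohort with known ground
truth: 17 treatment and 15 control participants, two sessions, 64 channels
at 1000 Hz (reduced to 8–16 channels in tests), 0–800 ms epochs, 576
trials/session (reduced to 32; trial count only affects the
trial-averaged noise floor, which is already negligible at 32).

Each channel is a trial-invariant "evoked-like" component — one
unit-variance band-limited Gaussian process per analysis band, summed —
plus independent white noise per trial (SD 1.0).  Trial averaging
suppresses the trial noise, leaving the evoked component, so structure
planted there survives preprocessing with known geometry:

- **common_driver**: one shared band-limited signal, gain a, added to all
  target channels → pairwise correlation a²/(1 + a²);
- **collider**: private signals on all but the first target, their scaled
  sum on the first (hub) → hub–private correlation
  a²/(√(k−1)(1 + a²)), zero between privates.  This motif has negative Ω
  (synergy-dominated).

Amplitude 0 reproduces the null cohort bit-exactly.  Every
participant-session draws from its own seeded stream, so cohorts are
deterministic, regenerable one participant at a time (bounding memory to
a single epoch set), and unaffected in their background draws by adding
or removing plants.

Validation plants are set at the strong end of each motif's attainable
correlation (common driver ρ = 0.7; collider hub ρ = 0.65) so that a
recovery failure indicates a pipeline defect rather than a statistical
power limit; the closed-form oracle tests use the canonical geometries
ρ = 0.5 and ρ = 1/√3 instead.  An optional per-participant gain factor
(SD 10%) models amplitude stability across sessions; note it is provably
inert for the copula measures, which are scale-invariant per channel.

What the generator does *not* emulate: 1/f background spectra, artifacts
(blinks, muscle, line noise), volume conduction / a forward head model,
non-Gaussian marginals, or genuine within-participant stability of
connectivity across sessions.  Passing tests therefore demonstrate the
correctness of the estimators, the search, and the inference machinery on
second-order ground truth — not robustness to the full physics of real
EEG.

A practical consequence of the real study geometry that the synthetic
cohort reproduces faithfully: an 800 ms epoch contains only a handful of
effective delta-band samples, so single-participant delta estimates are
very noisy, and the average reference redistributes a planted signal
across the montage with weight k·a/n.  At 64 channels that leakage is
negligible; at the 8-channel test scale it is not, so the search-logic
oracle tests run on band trials without re-referencing (the generator
emits source-like channels), while the default pipeline keeps the average
reference.

## Behavioral analysis

Trials with RT < 300 ms (fast guesses) or > 1200 ms (attentional lapses)
are discarded from RT analyses; boundary values are kept, since the
discard rule is a strict inequality.  Timeouts (deadline 1.25 s) have no
RT and count as incorrect.  Per participant, session, and trial class
(all / easy = 37.5% coherence / hard = 32.5% / face / car): median RT over
valid correct trials and percentage correct over all class trials.
Between groups: two-sided Mann–Whitney U.  Within participants: a
two-sided rank-sum test on valid correct-trial RTs, baseline vs follow-up,
at α = 0.05 feeds a Bayesian prevalence estimate of the population
fraction γ with a true effect: hit rate θ = α + γ(1 − α), posterior
Beta(k + 1, n − k + 1) on θ under a uniform prior, mapped to γ and
truncated at zero.  MAP = max(0, (k/n − α)/(1 − α)); the 95% credible
interval comes from 10,000 Monte Carlo posterior draws.

The synthetic RT model is log-normal (median 620 ms, σ = 0.22, shifted
+10 ms for treatment and +30 ms for control at follow-up) with accuracy
0.90 / 0.82 for easy / hard trials — conventions chosen to sit in the
reported qualitative ranges (accuracy > 80%, median RT 550–700 ms), not
calibrated values.

## Numerical choices and degenerate inputs

- Units: bits (log base 2) throughout.
- Constant channels are a hard error, never silently dropped; ties get
  average ranks.
- Correlation matrices with an eigenvalue below 1e−9 get one 1e−10
  diagonal ridge; if still below tolerance they are treated as rank
  deficient and raise an error naming the subset.  This rescues
  rounding-level indefiniteness but refuses duplicated/collinear channels.
- Ω is computed as TC − DTC *on the same copula matrix*, making the
  identity exact to floating-point.
- Zero pooled SD with unequal means yields a signed-infinity Cohen's d
  with a warning; a zero-residual ANCOVA fit is flagged degenerate with an
  infinite-F sentinel instead of raising, so batch sweeps complete.
- Search ties are broken toward the lexicographically smallest channel
  set for determinism.

## Problem sizes

Full scale (64 channels, 5 bands, 4 measures, orders to 16) is supported;
the test suite and the reproduction script run a reduced montage
(8–16 channels, 2 bands, 32 trials, orders to 8), which preserves every
qualitative property of the analysis while keeping a complete run in
seconds per cohort.
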