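# Methods

## Biomarker panel

Each patient is represented by up to eleven quantitative MRI biomarkers.
The atrophy indices are derived from midsagittal/axial geometry:

* pons-to-midbrain ratio `PM = A_pons / A_midbrain` (dimensionless;
  elevated when the midbrain atrophies, as in PSP);
* `MRPI = PM × (w̄_MCP / w̄_SCP)`, where `w̄` is the arithmetic mean of the
  left and right peduncle widths — the left/right averaging follows the
  convention of the MRPI literature;
* `MRPI2 = MRPI × (w_TV / w_FH)` (third-ventricle over frontal-horn width),
  which adds the ventricular-widening signal.

SWI biomarkers are region means normalised to the white-matter mean,
`SWI_roi = S_roi / S_WM`; values below 1 indicate signal loss from iron
deposition/mineralisation. FA biomarkers are region averages of fractional
anisotropy kept on the ×1000 reporting scale on which the group statistics
are published; a `fa_scale="native"` flag accepts [0, 1] FA. All ratio
biomarkers are strictly positive; a missing biomarker is represented as
absent, never as zero — zero is a syntactically legal but physically wrong
value for a ratio, so absence is explicit.

The type for the geometric inputs stores areas (mm²) for pons and midbrain;
only the ratio enters any biomarker, so tables using linear measures can be
loaded by declaring units at the I/O boundary.

## Synthetic cohorts

The generator emulates the published per-group biomarker distributions: for
each diagnosis group (sizes 38 PD / 25 MSA / 10 PSP by default) each
biomarker has a published mean and SD, and draws are Gaussian and
independent across biomarkers within a group — means and SDs are the only
published parameterisation, so independent Gaussians are the minimal
consistent model. A per-group correlation-matrix hook exists (real atrophy
markers co-vary; MRPI2 is literally built from MRPI) but the default is
independence.

Ratio biomarkers must stay positive. Naive rejection of draws at or below
the positivity floor would *bias* the realised moments wherever the mean
sits only ~2 SDs above zero (MRPI2: PD mean 2.40 SD above zero, MSA 1.99),
shifting the sample mean by up to ~0.9 units — orders of magnitude beyond
the Monte-Carlo error at large n. The independent-case sampler therefore
draws from **moment-matched truncated normals**: the proposal location and
scale are solved (Powell hybrid root-finding on the truncated-normal mean
and SD) so that the truncated distribution reproduces the published mean
and SD exactly; for targets more than 5 SDs above the floor the correction
is below 2 × 10⁻⁶ SD and the identity is used. The correlated case keeps
plain multivariate-normal rejection (a correlation-preserving truncation
has no closed form) and documents the residual marginal bias; rejection
rates above 99 % raise a generation error naming the offending biomarker.

Seeding: one root seed; each group gets an independent child stream
(`SeedSequence(seed, spawn_key=(group_index,))`), so adding a group never
perturbs another group's draws. Everything is bit-reproducible given the
seed.

What passing tests on this generator do **not** show: real biomarkers are
correlated, non-Gaussian in the tails, and occasionally missing; the
synthetic cohort is complete, independent and exactly Gaussian (after
truncation), which makes the classification problem easier than the real
one. Structural properties (which class is easiest, how intervals scale
with the number of bootstrap iterations, convergence behaviour) transfer;
absolute accuracy values do not.

## Group screening

Classical fixed-effects one-way ANOVA per biomarker,

    F = [Σ n_g (m_g − m̄)² / (k−1)] / [Σ (n_g−1) s_g² / (N−k)],

with the p-value from the upper tail of F(k−1, N−k). Two routes: the
individual-level route delegates to `scipy.stats.f_oneway`; the
summary-statistic route evaluates the formula directly from per-group
`(n, mean, sd)` and is algebraically identical — the test suite enforces
agreement to 1 × 10⁻¹⁰ relative on random data, which is the module's
primary correctness surface. The summary route is what lets the published
F-values be recomputed without patient-level data.

Selection retains biomarkers with `p < α`; α defaults to 0.05 (the
conventional threshold; configurable) and the output preserves a fixed
canonical order (atrophy, SWI, FA). p-values below 10⁻³ are displayed as
upper bounds (`<10^-4` style) alongside the raw float. Directional labels
(e.g. `PSP > PD > MSA`) are reported purely descriptively as the ordering
of group means when F is significant; no post-hoc test is implemented. No
multiple-testing correction is applied across the eleven biomarkers, by
design of the screening procedure being reproduced.

One published inconsistency is preserved deliberately: the red-nucleus SWI
row's printed F (10.289) cannot be recovered from its own printed
summaries, which give ≈13.72 by the standard formula (every other row
reproduces within 1 %, eight of them at printed precision). The likely
cause is a different effective sample for that row (e.g. missing values);
the package reports the recomputed value.

## Bayesian classification

Diagonal-covariance Gaussian Bayes: per class c and feature f a Gaussian
`N(μ_cf, σ_cf)`, posteriors computed in log space and normalised with
log-sum-exp. Missing features are skipped, which marginalises them out
under the independence assumption. Fitting uses sample means and SDs
(denominator n−1) per class; each SD is floored at 10⁻⁶ × the feature's
pooled SD (10⁻¹² absolute if every class is degenerate) so a constant
column cannot produce infinite densities.

Priors are uniform by default: the class imbalance (38/25/10) is exactly
what the balanced bootstrap is designed to neutralise, so building it into
the priors would double-count it. Empirical priors (proportional to class
counts) are available behind a flag.

* **Model I**: one three-class posterior over {PD, MSA, PSP} on the
  retained feature set.
* **Model II**: stage 1 separates PSP from the pooled rest on the atrophy
  features; stage 2 separates MSA from PD and is fitted on MSA/PD patients
  only. Its features default to SWI *plus* atrophy: the atrophy markers
  carry some MSA-vs-PD signal as well, and folding them into stage 2 as
  features (rather than as a separate hard cut-off) keeps the model fully
  probabilistic. Stage-2 features are configurable for the SWI-only
  reading. The combined posterior follows the chain rule
  `P(PSP)=p₁, P(MSA)=(1−p₁)p₂, P(PD)=(1−p₁)(1−p₂)`.

Prediction is the arg-max posterior; ties break deterministically in the
canonical class order PD, MSA, PSP. Probabilities are reported as
percentages with two decimals in per-patient tables. The default
evaluation protocol is resubstitution (fit and classify the same cohort),
matching the procedure being reproduced; leave-one-out is available and
reported separately, since resubstitution is optimistically biased.
Whether the original analysis used shared or per-class variances is
unstated; this implementation uses per-class variances (the published
per-group SDs are per-class) and exposes the fitted parameters for
inspection.

## Evaluation

One-vs-rest metrics per class from the 3×3 confusion matrix:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N after
pooling the two non-positive classes. Metrics with an empty margin are
flagged undefined (NaN) and excluded from bootstrap averages with a
counted warning.

The class-balanced bootstrap draws `group_size` (default 10) patients with
replacement from each class — all three classes are resampled by default;
a flag holds the full PSP group fixed instead, covering the alternative
reading in which only the two larger groups are resampled — refits the
chosen topology on the balanced sample and evaluates it on that same
sample (resubstitution per iteration; an out-of-bag mode evaluates the
patients not drawn). Defaults: B = 25,000 iterations, matching the
published protocol.

Two 95 % intervals are computed. The primary interval is the standard
error of the mean, `mean ± 1.96 sd/√B`, whose width shrinks as 1/√B; at
B = 25,000 it is a few units in the third decimal, which matches the
narrowness of the published intervals and is why it is labeled primary
(recorded as an inference, not a fact — the published interval method is
unstated). The 2.5/97.5 percentile interval of the per-iteration metric
distribution is also reported; it describes per-resample spread, does not
shrink with B, and is wider wherever the metric distribution is not a
point mass. Running means are recorded every 100 iterations; the
convergence check passes when every post-burn-in running mean stays within
a tolerance (default 0.005) of the final mean.

Exact published performance values cannot be reproduced without the
confidential cohort; the suite verifies the procedure's structural
properties instead (interval scaling, convergence by iteration 15,000,
PSP classified best).

## Outlier flagging

The original outlier calls were visual. The mechanised stand-in is a
robust z-score per group and biomarker, `z = (x − median)/(1.4826 × MAD)`
(1.4826 makes MAD consistent with the Gaussian SD), flagging `|z| >
threshold` with default 2.5 — a conventional robust cut. Groups with zero
MAD or fewer than three present values are skipped with a warning. Flags
are invariant under per-biomarker affine rescaling and monotone in the
threshold. This is an artifact convention: no quantitative criterion for
"far from the rest of the group" exists in the source analysis.

## Numerical and design notes

* Posteriors are computed in log space; brute-force density-product
  oracles in the tests confirm 1 × 10⁻¹⁰ agreement, and sklearn's
  `GaussianNB` serves as an independent cross-check of the posterior
  arithmetic (never as the implementation).
* The bootstrap inner loop is vectorised numpy (fit + classify of the
  30-patient balanced sample as array operations); B = 25,000 with the
  default cohort runs in seconds on one core. Problem sizes used by the
  test suite — 100,000 per group for estimator-consistency checks, 50,000
  draws per class for the closed-form error-rate check, B = 25,000 for the
  bootstrap — were chosen to make the statistical bounds (4 SE, 3 binomial
  SE, 1/√B scaling) sharp.
* Degenerate inputs have defined behaviour throughout: zero-variance
  ANOVA raises a degenerate-variance error, constant fitted columns hit
  the SD floor, B = 1 bootstraps give zero-width SE intervals, MAD = 0
  groups are skipped.
* CSV round-trips are bit-exact (repr-precision floats on write, pandas
  `round_trip` parser on read).
* Known limitations: independence of biomarkers within group (both in the
  generator's default and in the likelihood) understates real covariance;
  resubstitution protocols are optimistic; the outlier rule is a
  convention, not a validated criterion; MSA subtypes are collapsed to a
  single MSA class (the published analysis had too few cerebellar-subtype
  patients to model them separately).
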