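# Methods

## Setting

A face-identification proficiency test presents *n* 1-to-1 image
comparisons (the default emulates a 20-item test with 13 same-person and
7 different-people pairs, with photo time gaps of 0–2, 2–8 and 8+ years
on 3, 13 and 4 items).  Human observers respond on the 11-point forensic
conclusion scale −5 … +5, where sign encodes the conclusion, magnitude
encodes strength of support, and 0 is an explicit "inconclusive"
non-decision.  DNN observers return one real-valued similarity score per
item.  Observers belong to groups: novices, super-recognizers, forensic
examiners, forensic laboratories (one pooled decision per team), DNNs.

## Accuracy: rating-scale AUC

Per-observer accuracy is the area under the rating-scale ROC,

    AUC = [ #(s, d) pairs with r_s > r_d + ½·#ties ] / (n_s · n_d),

computed from mid-ranks (the normalized Mann–Whitney U).  Ties contribute
½ per tied pair; under this convention the rank statistic equals the
trapezoidal area under the ROC traced by sweeping a cutoff across the
rating values, and the package computes both (the rank formula as the
primary path, `sklearn.metrics.roc_curve` + trapezoid as the second
route) and tests their agreement to 1e−12.  AUC depends only on
within-observer rank order, so raw DNN scores need no rescaling here.
Missing responses drop the item for that observer only; an observer with
an entire truth class missing has no defined AUC and is skipped with a
warning.  AUC is a proportion everywhere in the library; percentages
appear only in presentation output.

## Signal-detection profiling

Ratings are binarized by sign (+ → "same", − → "different", 0 →
inconclusive).  Under the default policy, inconclusive responses are
non-decisions: they leave both the numerator and denominator of the hit
rate H = P("same" | same-person) and false-alarm rate F = P("same" |
different-people).  A sensitivity toggle (`inconclusive_policy:
as_different`) instead counts 0 as a "different people" decision, since
conventions differ between laboratories.  When a raw rate is 0 or 1 the
log-linear correction adds 0.5 to every cell and 1 to each denominator
(both classes, keeping H and F comparable); a `clamp` toggle offers the
1/(2N) rule instead.  Corrections are flagged per observer in the output.

Sensitivity and bias follow the equal-variance Gaussian model:
d′ = z(H) − z(F), c = −(z(H) + z(F))/2, with z = Φ⁻¹.  Negative c is a
liberal bias toward "same person".  By construction c(H, F) =
−c(1−F, 1−H): relabeling the classes mirrors the criterion, which the
suite checks as an identity.

Response profiles count usage of each of the 11 scale points (over
non-missing responses), the error distribution over scale points (an
error is a decisive response on the wrong side of the truth; 0 is never
an error), the inconclusive rate, and the share of errors that are +4/+5
responses to different-people items — the high-confidence
misidentifications that matter most in casework.

**Ceiling compression.** On a 13/7-item test, a strongly liberal, highly
accurate observer often scores 13/13 hits; the correction caps the
estimate at H = 13.5/14, so z(H) ≤ 1.80 and the measured group-mean
criterion of observers generated with c* = −1.08 comes out near −0.8.
This is a property of the estimator at this test length, not of the
generator; at 200 items the criterion is recovered with MAE ≤ 0.1.

## Similarity structure

For each trial type (same-person / different-people items separately) the
pipeline computes the observer × observer Spearman correlation of
responses.  With at most 11 distinct values over ≤ 13 items ties are
heavy, so the tie-aware mid-rank definition (Pearson correlation of
mid-ranks) is used; with complete data all rows are ranked once and
correlated in a single vectorized pass (equality with
`scipy.stats.spearmanr` is tested), with a pairwise-complete fallback
when cells are missing.  Observers with fewer than two non-missing
responses or a single distinct value for a trial type have no defined
rank order there and are excluded, with the reason recorded in the
result object.  Group-level agreement is the plain average of ρ over a
block (off-diagonal only within a group); no Fisher transform is applied
because the block summaries are reported as plain average ρ.  Heatmaps
use a diverging red/yellow/blue palette over [−1, 1] with group-ordered
axes.

## Fusion by resampled nominal groups

A fusion composition maps group names (members drawn at random) and/or
named observers (fixed members, e.g. a specific top-performing DNN) to
member counts.  Each of `n_samples` (default 1000) draws selects distinct
observers per entry (without replacement within a draw, independently
across draws), averages their per-item scores element-wise — DNN rows are
first min–max rescaled per observer onto [−5, 5], once, over the analyzed
item set, so member scores do not depend on the draw — and computes the
rating AUC of the fused vector.  Missing cells are averaged over the
members that responded.  The fused score stays real-valued (rounding to
the ordinal grid would discard rank information).  Results are summarized
per composition by the median and min–max range of the resample AUCs; a
comparison table also exposes the range of medians across compositions,
so "fused AUC range" can be read either way.  Runs are bit-reproducible
from the seed.  Averaging is plain — no weights, no vote — because the
averaging-of-judgments procedure is itself the object of study.

## Synthetic observer generator

Equal-variance Gaussian signal detection generates latent evidence for
human observer *j* on item *i*:

    e_ij = d*_j·[same_i] + λ_j·u_i + √(1 − λ_j²)·ε_ij ,

with u_i ~ N(0,1) a shared item component (it makes some items hard for
everyone, inducing inter-observer correlation with evidence-level
magnitude λ_j·λ_k) and ε idiosyncratic.  Marginal class variance is 1,
so the latent AUC is Φ(d*/√2).

Evidence becomes a rating through a response boundary k_j = d*_j/2 + c*_j
— placed so the measured SDT criterion recovers c*_j — and four
confidence cutoffs on each side of k at cumulative offsets
δ_m = Σ_{t<m} w·κ_j^{−t} with base width w = 0.5 z-units.  κ > 1 shrinks
the outer bands, piling mass on ±4/±5 (confidence extremeness); κ < 1
spreads mass over the midscale.  When |e − k| < δ_1 the observer emits 0
with probability p_inconclusive.  Because category probabilities are
normal integrals, the expected rating AUC and expected inconclusive rate
have exact closed forms (`expected_rating_auc`,
`expected_inconclusive_rate`); discretization attenuates the rating AUC
below Φ(d*/√2) (by < 0.01 for a neutral κ = 1 observer, more for extreme
styles), which the tests account for explicitly.

DNN scorers return continuous scores

    s_ij = d*_j·[same_i] + a·u_i·[same_i] + (a − ν_j)·u_i·[different_i] + σ·ε_ij .

At ν = 0 the scorer is human-aligned on both trial types; as ν grows past
the alignment a, its different-pair scores progressively anti-correlate
with human ratings while same-pair agreement is untouched.  This
decoupling is deliberate: human/DNN comparisons in this field show
agreement on same-person pairs alongside disagreement on
different-people pairs, and the generator must be able to produce that
signature (and, at ν = 0, its absence).  The expected DNN AUC is
Φ(d*/√(var_same + var_diff)).

### Default study-conditions cohort

`study_cohort_config()` builds the cohort the acceptance checks and the
acceptance script use: 20 items (13/7), group sizes 106/37/16/19/10
(novices / super-recognizers / examiners / laboratories / DNNs), and per
group:

| group | target AUC | c* | κ | inconclusive target | λ |
|---|---|---|---|---|---|
| forensic_examiner | 0.910 | −0.10 | 0.75 | 9.1 % | 0.6 |
| super_recognizer | 0.880 | −1.08 | 2.0 | 0.3 % | 0.6 |
| forensic_laboratory | 0.974 | −0.10 | 0.75 | 7.5 % | 0.6 |
| novice | 0.762 | −0.30 | 1.0 | 4 % | 0.45 |
| dnn | 0.876 | — | — | — | a = 0.55, ν = 0.8, σ = 0.6 |

Group AUC targets, the two expert criteria and the two expert
inconclusive rates are the observed study-level conditions; d* and
p_inconclusive are solved jointly from the exact closed forms
(fixed-point iteration), so those expectations hold exactly by
construction.  The remaining values are one-time design choices: κ
contrasts the documented extreme-ends vs midscale usage styles; the
laboratory and novice inconclusive targets are plausible interpolations
(laboratories examiner-like, novices midway); λ = 0.6 puts expert–expert
rank agreement near 0.25 after attenuation; a = 0.55 and ν = 0.8 place
the human×DNN evidence correlation at +0.40 on same-person and −0.24 on
different-people items, giving block-average Spearman ρ of roughly +0.27
and −0.19 after rank/discretization attenuation.  Examiners and
laboratories are marked as offline (casework-style) participants,
novices and super-recognizers online, mirroring typical administration.

### What the generator does and does not emulate

It reproduces: group accuracy levels and ordering, response-bias and
scale-usage contrasts, inconclusive-use contrasts, positive inter-human
agreement, the same/different human–DNN agreement asymmetry, and the
fusion benefit of diverse members.  It does not emulate: item-specific
difficulty beyond one shared component (real tests have identifiable
hard items with time-gap structure), trial-type-specific human agreement
(one λ governs both trial types), heterogeneity within groups (all
members of a group share parameters, so between-observer spread is
purely sampling noise), DNN–DNN diversity (all DNNs share one parameter
set), or missing responses.  Passing tests therefore demonstrate that
the pipeline measures these constructs correctly where they are present
by construction — not that real cohorts have these parameter values.

## Numerical and design choices

- Problem sizes: acceptance-style checks use 8 replicate cohorts at full
  study size (fast: ~0.5 s each); recovery uses 40 observers × 200 items,
  the regime where 130/70 decisive trials resolve H and F away from the
  boundaries (|c*| ≤ 0.8, d* ≤ 2.0 in the design grid); closed-form AUC
  checks use 2000 items with the Hanley–McNeil SE for the Monte-Carlo
  band.
- Monte-Carlo test bands were calibrated once from oversized pilot runs
  and then frozen; stochastic tests use fixed seeds.
- Degenerate inputs are errors, not silent NaNs: all-identical scores
  cannot be rescaled, a truth class with no usable response has no
  AUC/rates, zero-variance vectors have no rank correlation, and empty
  groups or oversized fusion draws raise sampling errors.
- Ratings at exactly the response boundary (measure zero) break toward
  "same"; the tie rule in AUC is the ½ convention throughout.
- The 0-item matrix, mismatched keys, and out-of-range or non-integer
  ordinal cells are rejected at load time with cell-level coordinates.

## Known limitations

- The criterion estimate at 20 items is ceiling-compressed for extreme
  observers (see above); comparisons of group criterion means at short
  test lengths understate true bias differences.
- Per-observer AUC on 20 items is coarse (granularity 1/91) and noisy
  (SE ≈ 0.07–0.10); single-seed group means move by a few points, which
  is why replicate averages are used wherever a level (not an identity)
  is checked.
- `run_fusion` recomputes nothing per draw except membership and the
  fused AUC; it assumes the rating matrix fits in memory, which is
  trivially true at proficiency-test scales.
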