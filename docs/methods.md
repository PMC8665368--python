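# Methods

## Agreement model

All agreement statistics are computed from the per-lesion category tallies
r_ik (lesion i, category k), the sufficient statistic for multi-rater
agreement with unequal panel sizes.  With agreement weights w_kl and
weighted tallies r*_ik = Σ_l w_kl r_il:

    p_a|i = Σ_k r_ik (r*_ik − 1) / (r_i (r_i − 1))        for r_i ≥ 2
    p_a   = mean of p_a|i over the n′ lesions with r_i ≥ 2
    π_k   = (1/n) Σ_i r_ik / r_i                           over all n lesions
    p_e   = T_w / (q (q − 1)) · Σ_k π_k (1 − π_k),  T_w = Σ_kl w_kl
    AC    = (p_a − p_e) / (1 − p_e)

Identity weights give the unweighted coefficient (AC1); any non-trivial
weights give the weighted form (AC2).  The report always labels the scheme
explicitly.  Unlike the kappa family, the chance term depends on prevalence
imbalance rather than rater marginals, which keeps the coefficient stable
when one class dominates — the usual situation in diagnostic panels.

Lesions with a single rating contribute to the prevalences π_k but not to
p_a; they are counted and logged.  p_e = 1 (a single effective category
under the weights) is a degenerate-scale error.

### The MOLEM ordinal mapping

Quadratic weights w_kl = 1 − (v_k − v_l)² / (v_max − v_min)² are built from
mapped category values v = (1, 2, 3, 4, 2) for classes (I, II, III, IV, V).
Class V (nonmelanoma cancer) shares its suggested-management tier with
class II, so it sits one mapped step from class I instead of four.
Consequences worth knowing: w(II, V) = 1, so a II-vs-V disagreement earns
full weighted credit (it is still reported as *level-discordant*, never as
concordant, in the concordance block); w(I, V) = 8/9; T_w = 173/9.  The
weights are invariant to affine transformations of the value vector.  The
confidence scale (below) is a distinct ordinal object and uses face values
1..5.

### Uncertainty

The study design fixes a small rater panel and samples lesions, so
inference is conditional on raters: the default standard error is a
delete-one-lesion jackknife over the n′ agreement lesions (single-rating
lesions stay in every replicate's prevalence term), with a t-based CI on
n′ − 1 degrees of freedom.  The upper CI bound is clipped at 1; the lower
bound is not (chance-corrected coefficients can be negative).  A lesion
bootstrap (2000 replicates, seeded, percentile CI) is provided as a
cross-check; the two agree to the expected order on simulated data.  With
n′ < 2 the point estimate is returned with the SE flagged unavailable.
Whether any published CI for this kind of analysis is closed-form or
resampling-based is generally unstated, so reproduction of specific CI
widths is not claimed.

### Strength bands

poor ≤ 0.20 < slight ≤ 0.40 < fair ≤ 0.60 < substantial ≤ 0.80 <
almost perfect ≤ 1.00.  The conventional printed bands leave (0.20, 0.21)
uncovered; the half-open convention above closes the gap.  Negative
coefficients band as poor; values above 1 are rejected as input errors.

## Majority reference and concordance

The reference diagnosis of a lesion is its modal class; among tied modal
classes the most severe wins.  No severity order is canonical for MOLEM
because class V's mapped value equals class II's while its risk tier is
high: the default rank I < II < V < III < IV follows the risk-of-progression
text, and the order is configurable (`SeverityOrder`, CLI
`--severity-order`).  The rater under evaluation is included in the
majority (one fixed panel reference, no leave-one-out), matching how a
single published majority diagnosis is defined.

Every rating is then partitioned against its lesion's reference class into
exactly one of: concordant, overcall (mapped value above the reference's),
undercall (below), or level-discordant (equal mapped value, different
class, i.e. II vs V).  Melanoma overdiagnosis is the fraction of ratings on
benign-reference (I/II) lesions that call melanoma (III/IV);
underdiagnosis is the fraction of ratings on melanoma-reference lesions
that call benign.  The benign/melanoma split {I,II} vs {III,IV} is an
inference from the arithmetic of the published denominators (797 = 677+120,
678 = 564+114) and is configurable.  Class-V-reference lesions are excluded
from both denominators; class V ratings sit in denominators but never in
numerators.  Empty denominators report an undefined rate, not 0.

## Confidence analysis

Confidence is scored per rating from 1 (most confident) to 5 (least).
Summaries are sample means and SDs (n − 1 denominator, the reporting
convention) per reference class and overall; ratings without a confidence
score are dropped and counted.  Agreement of the confidence scores
themselves is the same weighted AC machinery on the 1..5 scale.  The
confidence-vs-discordance association is the Spearman rank correlation
between per-lesion mean confidence score and the fraction of ratings
matching the reference, with a 2000-permutation p-value; Spearman with a
permutation null was chosen because the relationship is only ever claimed
qualitatively, so a distribution-free direction test is the honest
instrument.  A negative correlation means raters are least confident where
they agree least (remember: a higher score is *less* confident).

## Synthetic panel generator

`simulate_panel` emulates the structure of a 217-lesion, 9-pathologist
reading study: lesion true classes are drawn from the majority-class mix
95/16/82/16/8 (I–V); a uniform 5–9 of the 9 raters read each lesion; each
rater's class is drawn from a truth-conditional confusion matrix shared by
all raters (the emulated study publishes no rater-level accuracies that
would support heterogeneity; per-rater matrices are accepted); confidence
is drawn from one distribution when the assignment matches truth
(0.80/0.15/0.05/0/0 over scores 1..5) and a flatter, worse one when it does
not (0.25/0.35/0.25/0.10/0.05), producing the observed
confidence-tracks-agreement pattern.

`calibrated_default()` fixes the confusion matrices so that the simulated
per-majority-class concordance at large n reproduces the study-scale
profile 88.6 / 50.8 / 76.2 / 77.2 / 74.5 percent (I–V) to within a few
points, with class II the minimum and class I the maximum.  Miscall mass
sits on mapped-adjacent classes, and class II's splits evenly between I and
III (the borderline-lesion failure mode).  Calibration note: concordance is
measured against the *majority*, which conditions on the modal draw and so
runs above the confusion diagonal — the class II diagonal (0.34) is
therefore well below its target rate (0.508).

What the generator does **not** emulate: rater heterogeneity, lesion-level
difficulty beyond the class mix, correlated errors between raters viewing
the same morphology, and any image content.  Tests passing on simulated
panels therefore validate the statistical machinery and its calibration
contract, not claims about real pathologists.

`fixture_from_counts` is the deterministic counterpart used to reproduce
printed summary tables exactly: given per-class (lesions, concordant,
discordant-breakdown) counts it spreads concordant ratings round-robin and
discordant ratings with a stagger so each lesion's intended class is the
strict mode, and fails construction if a majority would flip.  The packaged
`RESULTS_COUNTS` reproduce every published aggregate (600/677, 61/120 with
29 over + 30 under, 430/564, 88/114, 41/55, melanoma 44/797 and 123/678);
where the discordant mass's split among specific classes is unpublished it
is a fixed package choice consistent with all of those aggregates.  Two
published totals are carried unreconciled, as in the source: the per-class
ratings sum to 1530 while the headline diagnosis total is 1516; the class
assignment shares (677 → 44.7%) use the headline total.

## Numerical and design choices

* Fixed category order (I, II, III, IV, V) everywhere; empty categories are
  retained — prevalence lives on the full 5-simplex.
* Per-reference-class agreement re-estimates π_k within each stratum: each
  stratum row is a self-contained analysis.
* Display rounding is one decimal for percentages, two for coefficients;
  JSON keeps full precision, and percentages are recomputed from counts at
  render time.
* Problem sizes in the test suite and acceptance script (5000-lesion
  calibration runs, 2000-lesion null panels, 200 random oracle tables) were
  chosen so Monte-Carlo noise is an order of magnitude below the margins
  being checked while a full run stays interactive.
* Known limitations: no rater-level diagnostics or latent-class modeling;
  no kappa-family coefficients beyond the cross-check oracle; confidence is
  analyzed descriptively, not as a calibrated predictor.
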