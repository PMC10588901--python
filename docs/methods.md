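# Methods note

This note defines the statistical model implemented by `sevcms`, records the
numerical choices and their rationale, delimits what the synthetic generator
does and does not emulate, and lists known limitations. Empirical statements
below are restricted to quantities computed by the shipped test suite and
`scripts/acceptance.py`.

## 1. Data model

A dataset is an animals × parameters matrix with per-animal metadata
(`animal_id`, `model`, `group`, `age_bracket`, `sex`). Missing cells are NaN
throughout and never imputed as zero. Multi-subproject studies are combined
by column union; an animal shared between subprojects (e.g. a common naive
control group) is deduplicated by `animal_id`, with conflicting metadata or
conflicting non-missing measurements treated as hard errors rather than
silently resolved.

## 2. Parameter preselection

A parameter is removed when its missingness fraction strictly exceeds the
cutoff (default 0.2; a parameter with exactly 20% missing cells is retained)
or when the study configuration lists it with a manual exclusion reason.
Rows are never removed at this stage. Every removal is logged with reason
and observed missingness.

## 3. Correlation screening and redundancy pruning

Spearman correlations are computed on pairwise-complete observations with
mid-ranks (tie-corrected product-moment correlation of rank vectors). Pairs
with fewer than 3 complete observations or a constant member are flagged
undefined. Two-sided p-values use the large-sample t approximation, except
for pairs with ≤ 8 complete observations, where the exact permutation
distribution over all n! orderings is enumerated; at the crossover (n = 8)
the two routes agree within 0.05 on random data (tested).

A pair is *significant* when |r| > 0.5 and p < 0.05, *redundant* when
additionally |r| > 0.7; both comparisons are strict. Pruning is greedy: while
any redundant pair survives, the least-protected member is dropped —
protection given by an ordered keep-preference list, ties broken by larger
total |r| over redundant pairs, then lexicographically. Configured
post-correlation exclusions (assays judged less sensitive) are applied after,
with reasons recorded. Post-condition (tested): the surviving set contains no
redundant pair.

## 4. ROC screening

Burden labels map each group to 1 (with burden: treated / epileptic /
mutant), 0 (without burden: sham / wild-type) or excluded (naive); an
unmapped group is a hard error. The AUC is the Mann–Whitney pair-counting
statistic (concordant pairs plus half the ties over all positive × negative
pairs), computed via rank sums; the ROC curve is emitted over all distinct
thresholds and its trapezoidal area equals the pair-count AUC to numerical
precision (tested). Both the raw AUC (larger score ⇒ burden) and the
oriented AUC max(AUC, 1 − AUC) are reported with a flip flag, since welfare
parameters may shift in either direction.

## 5. Normalization

Per parameter: shift by 1 − min (observed minimum maps to 1, giving strictly
positive support), Box-Cox transform with λ maximizing the profile
log-likelihood on the grid [−2, 2] in steps of 0.01 (vectorized; validated
against `scipy.stats.boxcox_llf`), then standardize to mean 0 / SD 1 with
the sample SD (ddof = 1). The conventional description of the order
(standardize, then Box-Cox) is
not well-defined because Box-Cox requires positive input; the implemented
order preserves the intent — symmetrize each marginal, then put all
parameters on a common scale. New data transformed through a fitted
normalizer are floored at a small positive constant if they fall below the
training minimum after shifting. Constant parameters are hard errors.

## 6. PCA and component selection

The PCA is an eigendecomposition of the sample covariance (ddof = 1) of the
normalized matrix, with residual missing cells imputed by the training-set
median of the normalized values. Components are ordered by SD descending
with a deterministic sign convention (largest-|loading| entry positive).
Invariants tested: loadings orthonormal, Σ SD² = number of parameters on
standardized data, explained fractions sum to 1, and the closed form 1 ± r
for two parameters. Components with SD strictly greater than 1 are retained;
retaining none is an error.

## 7. Resampled parameter ranking

For each of 100 resamples, a random 80% training subset is drawn without
replacement, stratified by group (a stratum shrinking below 2 animals is an
error; stratification can be disabled). Normalizer and PCA are refitted per
draw and components re-selected per draw (optionally frozen from a full-data
fit). Within every retained component, parameters are ranked by |loading|
descending; all per-(run, component) rank permutations are kept.

**Headline aggregation.** The workflow's goal is to find the parameters
spanning the burden axis, but at realistic problem sizes the burden axis is
not reliably the first principal component: with p parameters and n training
rows, sampling-noise eigenvalues reach approximately (1 + √(p/n))² (e.g.
≈ 2.25 at p = 15, n = 48), which can exceed the eigenvalue of a moderate
planted group effect (≈ 1.7 for 3 of 15 parameters shifted by 1.5 SD between
two groups of 30). A flat mean of a parameter's ranks over all retained
components fares even worse, because the informative parameters hold good
ranks on only one component and near-random ranks (~p/2) on the others.
Therefore, when burden labels are configured, the headline ranking uses a
per-run *burden-aligned* direction: the centered burden indicator is
regressed on the retained component scores, the per-component coefficients
are mapped back to parameter space through the loadings, and parameters are
ranked by the magnitude of the combined direction. This reduces to the
loading ranking of the burden-correlated component when the signal lies in a
single component, and reassembles it when sampling noise splits it across
components. Without burden labels the headline falls back to the ranks on
the leading retained component; a flat all-components average is also
available. Measured on the recovery design (3 informative of 15, effect 1.5,
n = 60, seeds 0–29): burden-aligned 30/30 seeds with all three planted
parameters in the top 5, best burden-correlated single component 28/30,
leading component 27/30, flat average 0/10.

## 8. Composite severity score

A reference PCA is fitted on the full pruned table. Each retained component
is oriented so its training scores covary non-negatively with the burden
indicator (explicit per-component signs may be supplied instead; data
without any burden labels require them). Under the default `rank_sum`
variant, each animal's oriented component score is mapped through the
mid-rank empirical CDF of the training scores — (#less + ½·#equal)/n,
clipped into (0, 1] — and the fractions are summed over the m retained
components, giving a composite in (0, m]. An animal at the training median
of two components scores exactly 0.5 + 0.5 = 1.0. A variance-weighted
`score_sum` variant is provided as an alternative.

## 9. Severity clustering

Severity levels are a total order, so clustering operates on the 1-D
composite score, where the optimal k-means partition is contiguous on the
sorted scores and a dynamic program finds the global optimum exactly
(validated against exhaustive partition enumeration and never worse than
Lloyd's algorithm). Boundaries are midpoints of adjacent sorted centers,
which reproduce nearest-center assignment exactly in 1-D. Thresholds are
refitted on 100 bootstrap resamples; the model reports mean boundaries and
percentile confidence borders (default 95%). Non-monotone mean boundaries
are a hard error (clusters unstable at that k). A score exactly on a
boundary goes to the higher cluster: cluster = 1 + #(thresholds ≤ s).
When k is not configured, an elbow suggestion from the scree curve is used:
the 1-based index maximizing the discrete second difference
x[i] − 2x[i+1] + x[i+2]. Group allocation tables report each (model, group)'s
percentage distribution over clusters (rows sum to 100) plus the combined
percentage in the top clusters; a pooled variant assigns each animal once
per resampled threshold set, reflecting threshold uncertainty.

Severity levels are relative to the models analyzed and are not transferable
to Directive 2010/63/EU severity categories; this disclaimer is attached to
every fitted cluster model.

## 10. Synthetic generator: scope

`sevcms.simulate` draws groups of unit-variance normal parameters with
planted standardized mean shifts, equicorrelated blocks realized through
shared latent factors (negative correlation restricted to pairs, where it is
positive-definite), optional lognormal marginals (a strictly monotone
transform leaving all rank-based statistics unchanged), and
missing-completely-at-random cells. Ground truth carries the informative
parameter names, the planted severity order (groups sorted by total planted
shift), the generator's missing mask, and the closed-form expected AUC
Φ(d/√2) for a shift of d between unit-variance normal classes.

The generator emulates *structure*, not biology: no animal-level covariance
beyond the specified blocks, no missingness mechanisms other than MCAR, no
measurement floors/ceilings, no longitudinal correlation. The recovery
experiments use a two-class design (control vs treated shifted 1.5 SD on 3
of 15 parameters, 30 animals per group). In a three-group design whose sham
group is shifted by only a third of the effect on the same parameters, the
sham-vs-naive sub-ordering of group-mean composites is *not* recovered
reliably (5/10 seeds measured): that contrast (0.5 SD on 3 of 15 parameters)
is diluted by the ~6–7 retained components of which only one carries it.
This is a sensitivity limit of the composite at that effect size, not a
defect; the treated group ranks highest in every measured seed.

## 11. Structural replication

Shipped configurations encode two study designs: a combined adult
induced-epilepsy dataset (three subprojects of 28 + 41 + 44 animals with 15
naive animals shared between two of them, combining to 98; 30 raw parameters
of which 22 survive preselection — the grimace scale exceeds 20%
missingness — and 17 survive redundancy pruning; k = 6) and young
genetic-model datasets (13 parameters after preselection in early
adolescence, 14 in late; 11/12 after pruning; k = 4). The test suite
reproduces these counts on synthetic tables carrying the studies' exact
column inventories, group structures and missingness patterns. Replicating
the studies' numeric outputs (explained variance, allocation percentages)
requires the deposited measurements, which need a download and are outside
the offline test scope.

## 12. Reproducibility and numerics

Every random stage derives its own seed from the global seed by XOR with a
CRC32 stage tag, modulo 2³¹ − 1; identical input + config + seed give a
byte-identical report bundle (tested), with wall-clock timings written to a
separate file. Box-Cox grid search, PCA and the k-means DP are deterministic;
PCA signs follow a fixed convention so results do not depend on the LAPACK
backend's eigenvector signs.

## 13. Limitations

- The burden-aligned headline ranking requires configured burden labels;
  purely unlabeled datasets fall back to leading-component ranks, which are
  less robust at small n/p ratios (section 7).
- The composite weights all retained components equally under `rank_sum`;
  weak contrasts carried by a single component are diluted (section 10).
- The exact Spearman permutation p-value is limited to n ≤ 8 pairs (8!
  orderings); beyond that the t approximation is used.
- Bootstrap threshold confidence borders are percentile intervals; no BCa
  correction.
- The elbow suggestion is a simple second-difference heuristic; a configured
  k always overrides it.
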