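# sevcms — composite-measure severity assessment for laboratory animal welfare data

`sevcms` implements an evidence-based severity-assessment workflow for
multidimensional animal-welfare datasets. Starting from a table of behavioral
and biochemical readouts (one row per animal), it builds a composite measure
scheme: it screens and prunes the parameter battery, ranks parameters by how
much of the shared variance they carry, condenses the battery into a single
composite severity score per animal, and partitions the animals into ordered
severity clusters with resampled confidence borders.

The workflow is the kind used to grade the burden of disease models (e.g.
epilepsy models or genetic mouse lines) relative to their controls, as
required for severity classification under EU Directive 2010/63/EU. The
resulting severity levels are **relative to the models analyzed** and carry no
regulatory severity-category meaning on their own; every fitted model carries
this disclaimer.

## The workflow

1. **Preselection** (`sevcms.preselect`) — parameters with more than 20%
   missing cells are dropped (strict: exactly 20% is retained), along with
   configured manual exclusions; every removal is logged with its reason.
2. **Correlation screening** (`sevcms.correlate`) — pairwise-complete Spearman
   matrix with mid-ranks. Pairs with |r| > 0.5 and p < 0.05 are *significant*,
   |r| > 0.7 additionally *redundant*. For pairs with ≤ 8 complete
   observations the p-value is an exact permutation enumeration rather than
   the t approximation. Redundant parameters are pruned under an ordered
   keep-preference list until no redundant pair survives.
3. **ROC screening** (`sevcms.discriminate`) — per model, each parameter's
   discriminatory power for the binary burden classifier (1 = treated /
   epileptic / mutant, 0 = sham / wild-type; naive animals excluded). AUC is
   computed by the Mann–Whitney pair-counting identity; curves come from all
   distinct thresholds and their trapezoidal area equals the pair-count AUC
   exactly.
4. **Resampled PCA ranking** (`sevcms.ranking`) — each parameter is shifted to
   positive support, Box-Cox transformed (λ by profile likelihood on a grid
   over [−2, 2]), and standardized; a PCA is fitted on 100 random stratified
   80% training draws; components with SD > 1 are retained per draw, and
   parameters are ranked by loading magnitude. The headline ranking uses the
   per-run burden-aligned direction within the retained subspace (see
   `docs/methods.md`).
5. **Composite score** — every retained component of a reference PCA is
   oriented to increase with burden and each animal's component score is
   mapped through the mid-rank empirical CDF of the training scores; the
   fractions are summed, giving a score in (0, m] for m retained components.
6. **Severity clustering** (`sevcms.clustering`) — globally optimal 1-D
   k-means on the composite score via dynamic programming (no Lloyd restarts,
   no local minima); thresholds are midpoints of adjacent sorted centers,
   averaged over 100 bootstrap resamples with 95% percentile confidence
   borders. Cluster k is the highest severity; animals are allocated and each
   group's percentage distribution over clusters is tabulated.

A built-in generator (`sevcms.simulate`) draws synthetic datasets with planted
group effects, correlated parameter blocks, lognormal marginals and MCAR
missingness, together with the ground truth (informative parameters, planted
severity order, closed-form expected AUC Φ(d/√2)) for oracle-style testing.

## Worked example

Fit the full workflow on a synthetic three-group study (naive / sham /
treated, 30 animals each, 15 parameters of which 3 are shifted in the treated
group):

```python
from sevcms import CompositeSeverityModel, StudyConfig
from sevcms.simulate import default_three_group_spec, generate_dataset

table, truth = generate_dataset(default_three_group_spec(seed=0))
config = StudyConfig(
    group_burden_map={"naive": "exclude", "sham": 0, "treated": 1},
    k=3, seed=0)
results = CompositeSeverityModel(table, config).fit()
print(results.summary())
```

Output:

```
Composite severity workflow
================================================================
animals: 90    seed: 0
parameters: 15 input -> 15 after preselection -> 15 after redundancy pruning

Retained principal components (SD > 1):
  PC1: SD 1.453, 14.9% of variance
  PC2: SD 1.296, 11.8% of variance
  PC3: SD 1.211, 10.3% of variance
  PC4: SD 1.140, 9.2% of variance
  PC5: SD 1.056, 7.9% of variance
  PC6: SD 1.032, 7.5% of variance

Top-ranked parameters (mean rank over resampled PCAs):
  1. param_03  (mean rank 1.11)
  2. param_02  (mean rank 2.69)
  3. param_01  (mean rank 2.77)
  4. param_14  (mean rank 3.99)
  5. param_09  (mean rank 7.07)

Severity clusters: k = 3 (elbow suggestion: 1)
  threshold 1|2: 2.676  [2.361, 2.925] 95% CI
  threshold 2|3: 3.588  [3.159, 3.932] 95% CI

Cluster allocation (% of group, cluster 3 = highest severity):
  synthetic/naive (n=30):  50.0   50.0    0.0
  synthetic/sham (n=30):  43.3   53.3    3.3
  synthetic/treated (n=30):   6.7   43.3   50.0

ROC screening (AUC, oriented):
  synthetic: param_02=0.847, param_01=0.807, param_03=0.754
```

The three planted parameters (`param_01..03`) occupy the top three ranking
positions, and half the treated group lands in the highest severity cluster
versus 3% of shams. `results.write_report("results/")` writes the full CSV/
JSON bundle plus plots (correlation heatmap, ROC curves, scree plot, PC1×PC2
scatter, stacked allocation bars).

## Command line

Every stage is also a subcommand of the `sevcms` CLI:

```sh
sevcms simulate --out demo.csv --truth truth.json --seed 0
sevcms run -i demo.csv -c config.yaml -o results/ --seed 0
sevcms preselect -i demo.csv
sevcms correlate -i demo.csv
sevcms roc -i demo.csv -c config.yaml
sevcms rank -i demo.csv -c config.yaml
sevcms cluster --scores results/composite_scores.csv --k 3
```

`sevcms run --dry-run` validates the inputs without fitting. Multiple `-i`
inputs are combined with column union and shared-animal deduplication (an
animal appearing in two subprojects is kept once; conflicting metadata or
measurements are hard errors).

Two example configurations ship under `src/sevcms/examples/`: a combined
adult induced-epilepsy study (`adult_epilepsy.yaml`, k = 6) and a young
genetic-model study (`young_genetic.yaml`, k = 4). `sevcms.studies` also
provides synthetic tables with these studies' exact column inventories, group
structures (28 + 41 + 44 adult animals with 15 shared naive mice combining to
98) and missingness patterns, so the structural behavior of the pipeline can
be exercised without any external data.

## Reproduction

All randomness flows from a single seed; per-stage seeds are derived from it,
and a re-run with the same input, config and seed is byte-identical (wall
-clock timings are written to a separate `timings.json` for this reason).

```sh
python -m pytest -q tests/                                  # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite covers, among others: dual-route oracle checks (pair-counting
AUC vs brute-force pair enumeration, Spearman permutation p vs exhaustive
enumeration, DP k-means vs exhaustive contiguous partitions, Box-Cox profile
likelihood vs `scipy.stats.boxcox_llf`, PCA eigenvalues vs the 1 ± r closed
form), planted-parameter and planted-severity recovery over 20 seeds, null
behavior (AUC ≈ 0.5, allocation independent of group), byte-level
determinism, and the structural parameter counts of the shipped study
configurations. `scripts/acceptance.py` recomputes the headline quantities
from a given seed and writes them as JSON.

See `docs/methods.md` for the methods note: model definition, numerical
choices, synthetic-generator scope, and known limitations.
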