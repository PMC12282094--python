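# phenoscreen

Cross-condition image-based phenotypic profiling of bacterial deletion-strain
screens: robust deviation scoring against parent-strain replicates,
nutrient-independent outlier detection, phenoprint correlation networks with
empirical significance thresholds, and demograph construction — plus a
synthetic screen generator with a planted ground-truth manifest for
validating every stage.

## The problem

Image-based profiling screens extract many population-averaged cellular
features (cell and nucleoid morphology, divisome formation, DNA-replication
timing, growth) for hundreds of gene-deletion strains, typically across
several nutrient conditions.  Most deviating phenotypes turn out to be
nutrient-dependent, which complicates genotype→phenotype inference but also
creates two opportunities this package exploits:

1. **Nutrient-independent outliers** — features that deviate consistently
   across conditions point to genuine genetic determinants of that feature.
2. **Phenoprint correlations** — strains whose full cross-condition score
   vectors correlate strongly (positively or negatively) are candidates for
   shared or opposing gene function, which is particularly useful for genes
   of unknown function (*y-genes*).

## The model

For feature *i* of a mutant strain in one nutrient condition, the normalized
score is

```
s = 1.35 × (F_i − median(F_i^parent)) / iqr(F_i^parent)
```

where `F_i^parent` are the parent (wild-type) replicate measurements
(≥ 115 per condition) and `iqr` is the interquartile range.  Since the IQR of
a normal distribution is 1.35 σ, `s` reads as "standard deviations from the
parent median" while remaining robust to outlying replicates.  Derived
coefficient-of-variation features (sd/mean of a cellular property) extend the
feature set; at defaults, 96 features × 4 conditions give a 384-entry
**phenoprint** per strain.

On top of the scores:

* a cell deviates when |s| ≥ 3;
* a (strain, feature) pair is a **nutrient-independent outlier** when
  s > 3 (or s < −3) in at least one condition and s > 1.5 (or s < −1.5, same
  sign) in every other evaluated condition;
* pairwise Spearman correlations between phenoprints of strains sampled in
  all conditions are thresholded by the empirical interval that excludes the
  middle 99.7% of all coefficients (the analogue of ±3 SD); pairs outside it
  form a signed, weighted connection network.  A permutation null
  (10,000 shuffles) is available as an alternative threshold source.

**Demographs** summarise subcellular protein localisation: per-cell axial
fluorescence profiles (integrated across the short axis of each segmented
cell), resampled to relative cell length and stacked as rows sorted by cell
length.

## Worked example

```python
import numpy as np
from phenoscreen import (
    compute_score, default_screen_spec, generate_parent_reference,
    generate_mutant_library, score_table, call_deviations,
    assemble_phenoprints, pairwise_spearman, empirical_thresholds,
)

# one cell: parent replicates {8, 9, 10, 11, 12} have median 10 and IQR 2,
# so a mutant value of 12 scores exactly one IQR above the median:
print(compute_score(12.0, np.array([8., 9., 10., 11., 12.])))  # -> 1.35

# a full synthetic screen at study scale, with planted ground truth
spec = default_screen_spec(seed=1)           # 806 strains x 4 conditions
ref = generate_parent_reference(spec)        # 115 replicates per (cond, feat)
table, truth = generate_mutant_library(spec)
scores = score_table(table, ref)
pheno = assemble_phenoprints(scores, complete_only=True)
print(len(pheno.strains), len(pheno.axis))   # -> 773 384
thr = empirical_thresholds(pairwise_spearman(pheno))
print(round(thr.lower, 3), round(thr.upper, 3))  # -> -0.166 0.191
```

773 of 806 strains were sampled in all four conditions and enter the
correlation analysis with 384-entry phenoprints; on this synthetic screen the
middle-99.7% significance interval is [−0.166, 0.191], and the ten planted
strain pairs (target ρ = 0.9) all fall outside it.

The same stages are available from the shell:

```
phenoscreen simulate --seed 1 --out bundle/
phenoscreen run-all --seed 1 --out run/
phenoscreen demograph --labels labels.png --fluor fluor.png --out demo.tsv
```

`run-all` writes scores, deviation-breadth tables, the condition-subset
partition, outlier records, the correlation matrix, thresholds, and the
significant-connection network (edge-list TSV + GraphML), with a provenance
record; reruns with the same config and seed are byte-identical.

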