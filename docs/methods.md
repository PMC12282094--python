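# Methods

## Robust deviation scores

Each mutant measurement is compared to the parent-strain replicate
distribution for the same (condition, feature):
`s = 1.35 × (value − median(parent)) / iqr(parent)`.  The factor 1.35 is the
IQR/SD ratio of a normal distribution (2·Φ⁻¹(0.75) ≈ 1.3490, used at the
printed two-decimal precision), so `s` is interpretable in SD units while
median/IQR keep the baseline robust to contaminated replicates.

Quantile convention.  The IQR depends on the quantile interpolation rule;
the package defaults to linear interpolation between order statistics (the
common default across numerical environments) and records the rule in every
`ScoreMatrix` for provenance.  Any numpy quantile method name can be
selected (`scoring.quantile_rule`); this matters when matching thresholds
computed elsewhere on the same data.

Degenerate references.  A zero-IQR parent vector (e.g. a constant feature)
yields a MISSING score plus a logged warning — never an infinity.  MISSING
propagates: undefined (condition, feature) pairs, unsampled conditions, and
unparseable cells all score MISSING, and MISSING never counts as deviating.

Deviation calls use |s| ≥ 3 (inclusive).

## Coefficient-of-variation features

Cellular properties measured as population mean + SD contribute a derived
CV feature (sd/mean), a readout of how tightly the property is controlled.
The default catalogue has 19 such properties, expanding 77 base features to
96.  CV features are scored like any other feature, against per-replicate
parent CVs (each parent replicate is itself a population average, so its CV
replicate is its own sd/mean quotient).  A CV cell is MISSING when either
input is MISSING or |mean| < ε (default 1e−9).

Because a CV is a ratio of two noisy estimates, its null score distribution
has slightly heavier tails than normal even under a fully normal generative
model; on the synthetic screen the null |s| ≥ 3 rate is ≈ 2× the base-feature
rate (≈ 1% vs ≈ 0.5%).  This is a property of the statistic, not a defect,
and the test suite bounds it separately from the normal-theory oracle.

## Nutrient-independent outliers

A (strain, feature) pair is an outlier when sign·s > 3 in ≥ 1 evaluated
condition and sign·s > 1.5 in every other evaluated condition for one sign.
Sign consistency is required by default — the rule targets phenotypes that
persist with the same direction across conditions — and can be relaxed to a
pure magnitude rule (`same_sign=False`).  Features undefined in one
condition (e.g. replication-timing under overlapping replication rounds in
the richest medium) are evaluated over the remaining conditions;
`min_conditions` (default 3) prevents single- or two-condition calls from
passing as "nutrient-independent".  Every emitted record re-verifies its
defining inequality on replay, and raising the secondary threshold can only
shrink the record set.

## Phenoprints, correlations, thresholds

Phenoprints are laid out condition-major ((condition, feature), 384 entries
at defaults).  The correlation analysis defaults to strains sampled in all
conditions (`complete_only=True`); pairwise Spearman uses average ranks for
ties and pairwise-complete overlap, with coefficients undefined below
`min_overlap` (default: half the axis length) or for zero-variance overlap.
Axis entries missing in every strain (not-determined features) belong to no
overlap and are dropped up front; when no missingness remains the
implementation ranks once and correlates by matrix product, otherwise it
falls back to pairwise-complete re-ranking.

Significance thresholds are the empirical quantiles that exclude the middle
99.7% of all defined upper-triangle coefficients (each unordered pair
counted once), mirroring ±3 SD coverage of a normal.  The permutation
alternative shuffles the axis entries of one member of a random strain pair
per draw (destroying alignment, preserving marginals; the specific scheme is
an explicit modelling choice, since several are defensible) and takes the
same quantiles of the pooled null.  On data with genuine positive structure
the permutation interval is narrower — i.e. less stringent as a cutoff —
which is why the empirical interval is the default.

Connection networks keep every pair outside the interval as a signed edge
weighted by |ρ|; an optional focus set (e.g. y-gene deletions) restricts to
incident edges and reports per-focus connection counts.  Export formats are
edge-list TSV and GraphML; graph layout is left to downstream viewers.

## Synthetic screen generator

The generator emulates the data structure the analysis assumes, at study
scale by default: 806 strains × 4 conditions × 96 features, 115 parent
replicates per (condition, feature), four replication-timing features not
determined in the richest condition, and ~6% of strains missing one
condition (so ≈ 760–770 complete strains).  Parent distributions are
Normal(μ, σ) with μ per feature drawn once from [5, 50] (condition factors
0.7–1.3) and σ = (5–20%)·μ; null strains draw every cell from the parent
distribution, which calibrates their scores to ≈ N(0, 1) (empirical null SD
≈ 1.05, the excess coming from median/IQR estimation on 115 replicates and
from CV-feature tails).

Planted structure, recorded in a ground-truth manifest:

* **Outliers** — 100 (strain, feature) pairs shifted by (4.5, 2.5, 2.5, 2.5)
  parent-SD with randomized primary condition and alternating sign.  Under
  the additive-noise model the detection probability of such a plant is
  P(all four scores clear 1.5, one clears 3) = Φ(3)·Φ(1)³·(1 − 0.017) ≈ 0.58;
  the recovery tests assert a binomial band around this closed form.
* **Modules** — ten two-strain groups sharing a latent effect vector with
  amplitude √(ρ/(1−ρ)) for target ρ = 0.9 (five with negated loadings,
  giving negative edges).  Realized phenoprint correlations land near ±0.85
  and far outside the empirical thresholds.
* **Pleiotropic strains** — five strains with 45 features shifted by a
  constant signed 3.5–6 SD across conditions, populating the >40-features
  outlier-count bin.

Missing conditions are assigned among unplanted (null) strains only, so the
planted structures remain evaluable and the manifest semantics stay clean.
Features are conditionally independent given planted effects; the generator
does not emulate the covariance structure of real image features, real
(non-normal) replicate noise beyond an optional heavy-tail switch, or
batch/plate effects — so passing recovery tests demonstrate correctness of
the analysis under its stated model, not robustness to everything real data
can do.  One seed determines the whole bundle byte-for-byte.

## Demographs

The cell axis is the major eigenvector of the mask's second-order moment
tensor — adequate for near-straight rods and deterministic; curved-cell
medial-axis unbending is out of scope.  Near-circular moment tensors break
the tie toward the image x-axis.  In-mask fluorescence is summed across the
short axis into equal-length axial bins (a partition of mask pixels, so
total signal is conserved exactly); per-cell profiles are resampled to a
common relative-position axis in [0, 1] and stacked sorted by length
(ties broken by cell id, making assembly order-invariant).  Per-cell
normalization defaults to divide-by-mean, preserving relative enrichment;
min–max and none are selectable.  Pole orientation is not defined without a
polarity marker, so profiles are reported pole-to-pole as extracted.

The synthetic rod generator places capsule cells on a jittered grid
(non-overlap by construction), with uniform / septal / subpolar / polar
fluorescence patterns (Gaussian bands, σ = 0.05 relative length, amplitude
3× baseline) and optional pixel noise; it renders populations of several
thousand cells in seconds.

## Pipeline and determinism

`run_pipeline` executes read/simulate → CV augmentation → scoring →
deviation calls → breadth/partition/outliers/robustness → phenoprints →
correlations → thresholds → network, writing TSV/JSON/GraphML outputs plus a
provenance record (config hash, versions, seed).  Per-stage seeds are
derived from the single top-level seed via SHA-256, so stages are
independently reproducible and a rerun with the same config and seed is
byte-identical.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` run the generator at full study
scale (806 strains; a few seconds end to end), null-calibration checks at
10,000+ score cells, the permutation null at 2,000 draws in tests (the
analysis default is 10,000), and demograph population checks at 60–400 cells
with a 2,048-cell generation exercised during development; these sizes give
stable statistics while keeping routine runs fast.

## Known limitations

* Reproducing the published screen's exact counts and thresholds requires
  the original score table, which this repository cannot redistribute; the
  reproduction path (`tests/test_acceptance.py::test_published_score_table_reproduction`)
  is wired to `data/published_scores.tsv` and the exact thresholds are
  additionally sensitive to the quantile rule (see Quantile convention).
* Under the generator's additive-noise model, planted outliers at
  (4.5, 2.5, 2.5, 2.5) SD are detected at ≈ 0.58 sensitivity — the secondary
  conditions sit only 1 SD above the 1.5 cutoff.  Near-certain recovery
  requires secondary effects ≳ 3.4 SD; the recovery-monotonicity test shows
  sensitivity > 0.95 at 1.6× effects.
* Spearman is assumed for both the phenoprint analysis and the
  cross-condition robustness matrix (Pearson selectable for the latter);
  correlation-method choices change threshold values on real data.
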