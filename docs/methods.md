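# Methods

## Statistical model and procedure

### Units of inference

The emulated design pools tissue from two animals per sample, with four
biological pools per (group, sex) condition and three technical LC-MS
injections per pool. Technical replicates are averaged to the pool level
*before* any statistic is computed, so the biological pool (n = 4 per
condition) is the unit of inference. This avoids pseudo-replication:
treating the 12 injections per condition as independent samples would
triple the apparent sample size while adding only technical variance. The
original acquisition software's unit of replication is not documented, so
this is a deliberate, conservative choice.

### Hi3 quantification

A protein's relative abundance in a run is the arithmetic mean of its
`min(3, available)` most intense peptides in that run. Cells with fewer
than three observed peptides use the mean of those available (≥ 1) rather
than being dropped — the identification filter already guarantees two
peptides per protein globally, and keeping partial cells maximises the
information available to the presence filter. Missing observations are
absent rows, never zeros, and are never imputed. Hi3 is scale-equivariant
and bounded by the cell's min and max peptide intensity; both properties
are tested.

### The differential-expression cascade

Filters run in a fixed order and each protein records the first filter
that removed it:

| filter     | rule                                                   | default |
|------------|--------------------------------------------------------|---------|
| presence   | observed in ≥ `presence_min` of `presence_of` pools in **both** conditions | 3 of 4 |
| CV         | sample SD / mean over pool values ≤ `cv_max` in **both** conditions | 0.30 |
| fold change| max(mean_A, mean_B) / min(mean_A, mean_B) **strictly >** `fc_min` | 1.5 |
| ANOVA      | one-way, two levels, on pool values; p **strictly <** `alpha` | 0.05 |

Decisions the procedure leaves open, resolved here:

- **CV scope.** The CV rule is applied per condition over its pool-level
  values and must hold in both conditions — the most conservative
  symmetric reading.
- **Fold change scale.** Ratios of raw (untransformed) condition means,
  matching the Progenesis-style definition. A `use_log` switch computes
  geometric-mean ratios and runs the ANOVA on natural-log abundances; it is
  off by default.
- **Degenerate variance.** When all pool values are equal in both groups,
  F = 0 and p = 1; when means differ with zero within-group variance,
  F = ∞ and p = 0. This keeps zero-noise synthetic data from crashing and
  gives the intuitively right calls.
- **No multiple-testing correction** is applied to the calls, mirroring the
  stated p < 0.05 procedure; a Benjamini–Hochberg column is emitted in the
  per-comparison export for transparency but never used.
- With fewer than two pools in a condition the CV and ANOVA are undefined;
  the record is flagged (`stats_ok=False`) rather than raised.

### Marker set logic

The comparison lattice orders groups CT < NIC < PCP < PCPNIC; every
unordered pair is compared once, with the earlier group as reference. Two
marker definitions are implemented:

- `plain_intersection`: proteins deregulated in all three comparisons
  involving the group.
- `exclusivity_refined` (default for the combined group): within each
  family of comparisons sharing a reference (the three vs-CT comparisons,
  the two vs-NIC comparisons), the group's DE set is first reduced to its
  *exclusive* Venn region before intersecting. For the pair family with a
  single member (PCPNIC vs PCP) the plain DE set is used.

The two published phrasings of the combined-insult marker rule differ
(commonly-deregulated vs exclusively-deregulated inputs); the
exclusivity-refined construction is the one whose inputs are spelled out
numerically, so it is the default, with the plain intersection exposed as a
mode. Refined markers are provably a subset of plain markers (tested).

Direction (Up/Down for the focal group) is attached per comparison but
**not** required to be consistent for membership — the published marker
tables happen to be direction-consistent, but no such rule is stated, so
consistency is reported as a flag instead. Set membership ignores
direction everywhere.

The sex-exclusivity fraction uses as denominator the union of proteins
deregulated in at least one comparison of at least one sex; the numerator
counts those deregulated in exactly one sex. The published figure does not
define its denominator; this one is recorded as the package's definition.

### Pathway frequency

Ranking is by raw count of query proteins per pathway (the reproduced bar
summaries plot counts), not by an overrepresentation statistic — none was
reported. Ties at the k-th rank break lexicographically by pathway id for
determinism. Pathways with zero hits are dropped.

### Interactome analysis

Edge confidences on the STRING 0–1000 scale are auto-detected (any value
> 1) and divided by 1000. The threshold comparison is **inclusive**
(≥ 0.4), matching the "medium confidence" convention. Markers without a
qualifying edge are excluded from the map but reported as `unmapped` —
this mirrors the published drop from 16 markers to 12 mapped proteins in
males. Subnetworks are the maximal same-label node sets within a connected
component; a subnetwork is *isolated* when its component contains no other
label. Functional labels come from a user-supplied category map (packaged
for the fixtures); no automatic naming is attempted. Centrality is
unnormalised shortest-path betweenness with ties broken by degree then
name.

The packaged fixture edge lists are **synthetic reconstructions**: the
published interactome figures are not machine-readable, so edges were laid
out to be consistent with the textual connectivity statements (the Amph
hub position in males; the isolated energy-metabolism pair; Fkbp1a,
Hspa1b and Eno2 central and interconnected in females; the isolated
septin-cytoskeleton and cell-cycle pairs). Tests treat them as fixtures of
this package, not as ground truth about the real interactome.

## The synthetic-data generator

### What it emulates

- Protein base abundances: log-normal, ln-scale mean 11.5 and SD 1.0
  (intensities ~10⁵ spanning ~2 orders of magnitude, typical of LFQ).
- Peptide count per protein: 2 + Poisson(mean − 2); the floor of two makes
  the identification filter satisfiable by design and is configurable to
  create sub-threshold proteins. Default mean 10.7 gives ≈ 3594 expected
  peptides over 337 proteins.
- Peptide ionization efficiency: log-normal, ln-SD 1.0, fixed per peptide.
- Biological pool-to-pool noise: mean-one log-normal, CV 0.15 (default).
- Technical injection noise: mean-one log-normal, CV 0.10 (default).
- Planted effects: multiplicative fold changes per (protein, sex, group)
  relative to the first (control) group; values < 1 encode downregulation.
- Missingness: an observation is dropped with logistic probability
  decreasing in log-intensity (midpoint ln 6.9, slope 1.2), giving a few
  percent of intensity-dependent dropout under the defaults.

The source study reports no variance or missingness estimates, so the
noise defaults were chosen once for realism and testability, not fitted.
Log-normal multiplicative noise at both levels is the standard LFQ
assumption and makes the CV parameters directly interpretable.

### What it does not emulate

No spectra, retention times, m/z values, peptide-spectrum matching, or
identification FDR; no shared/razor peptides (every peptide maps to one
protein); no between-run normalisation drift; no correlated missingness
beyond the intensity-dependent mechanism. Passing tests therefore
demonstrate correctness of the inference chain under the stated noise
model, not robustness to the full messiness of real acquisitions.

### Ground truth

`GroundTruth` carries the planted effects, peptide→protein map, ionization
factors, per-protein base abundances and the *expected marker sets*
obtained by applying the exclusivity-refined set logic directly to the
planted fold-change matrix (deregulation = planted ratio > 1.5). That
derivation is implemented independently of the analysis modules, so
parameter-recovery tests compare two separate routes to the same answer.

## Numerical choices

- ANOVA F is computed explicitly from sums of squares (with the degenerate
  cases above); the p-value uses the F(1, n−2) survival function. Tests
  cross-check against `scipy.stats.f_oneway` and the F = t² identity.
- CVs use the sample SD (ddof = 1).
- Hi3 sorting is stable; ties at the top-3 boundary cannot change the mean.
- All random generation flows through `numpy.random.default_rng` seeds;
  identical (config, effects, seed) give byte-identical outputs.

## Problem sizes used in the shipped checks

Unit and property tests run on toy tables (tens of proteins). The
acceptance checks use: the two packaged fixture maps (12 and 35 proteins);
a 100-protein simulation with ten planted 4-fold combined-insult effects
at 5% CVs for exact marker recovery; a 5000-protein two-group null
simulation (two peptides per protein, no dropout) for the type-I-error
calibration of the ANOVA stage; and one default-size simulation
(337 proteins, ≈ 3594 peptides, 96 runs) for the design dimensions.

## Known limitations

- The real study's deposited raw data are not used; published
  whole-dataset DE counts (e.g. 169 deregulated proteins in the combined
  group) depend on those data and are not reproduced here.
- The published supplementary protein lists are not packaged, so the
  16-marker male intersection and the 49.8% sex-exclusivity figure are
  exercised only through the set-algebra machinery on synthetic lists.
- The comparison lattice generalises to other group vocabularies (the
  hierarchy is inferred from focal/reference roles), but the refined
  marker rule is only meaningful when comparison families share references
  as in the four-group design.
- Betweenness on weighted graphs ignores confidences (unweighted shortest
  paths), matching the qualitative use of centrality in the reproduced
  analysis.
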