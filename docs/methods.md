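# Methods

This note records the models, conventions and numerical choices behind
`concord`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design and data model

The pipeline targets a longitudinal paired-omics design: *D* collection
dates (default 8) × *R* technical replicates (default 3), with two
abundance layers over a shared ORF namespace.

* **Gene layer** — read counts per ORF per replicate, normalized to
  counts per million (CPM): `x̂ = 1e6 · x / Σx` per sample column.
  Features absent from a sample are explicit zeros after CPM: a
  non-detected gene contributed zero reads, so zero is its observed
  abundance on the count scale.
* **Protein layer** — normalized summed reporter signal-to-noise per
  protein per sample (dimensionless). Absences stay *missing* (`NaN`)
  and are excluded from means and correlations: a protein missing from a
  TMT plex was not measured, and zero would be a biased imputation.

This asymmetry (pad genes, exclude proteins) is the central missing-data
decision and propagates everywhere: replicate collapse uses sums for the
gene layer (count semantics; missing = 0) and means for the protein
layer (ratio semantics; missing cells ignored), and whole-community
analyses (Bray-Curtis, PCoA) use only features quantified in every
sample, because missingness in multiplexed proteomics is structured by
plex and would otherwise create ordination artifacts.

CPM is applied per replicate and dates are collapsed afterwards; the
order is configurable but per-replicate normalization is the default
because library sizes differ per replicate.

## TMT quantification

PSM filters, in order (each rejection is charged to the first failing
rule, so the per-rule log partitions the rejected set): confidence must
be `high` (moderate-confidence rejected), not `ambiguous`, isolation
interference ≤ 25 %, mean reporter S/N ≥ 10 over all channels of the
plex (bridges included — nothing in the quantity's definition restricts
the channel set). Proteins left with a single surviving PSM remain
quantifiable. Boundary values (exactly 25 %, exactly 10) pass.

Shared-peptide resolution is a deterministic greedy pass in input order:
a peptide matching several proteins goes to a candidate that already
holds an assigned peptide (lexicographically smallest if several),
otherwise to the longest candidate, ties broken lexicographically by
protein id. Unique-candidate peptides seed the prior-evidence set before
the pass. Exact duplicates — identical (sequence, plex, charge) — are
collapsed to the first occurrence. These tie-break rules are the
package's own choices where the underlying convention is ambiguous; they
make the assignment a pure function of the input.

Bridge normalization: each plex carries two bridge channels (labels
`126`/`131` by default, configurable, 10- or 11-plex layouts supported)
with a pooled composite sample. Per protein *p* and sample channel *c*
in a plex, with bridge *b*:

    r_b(p, c) = SN(p, c) / SN(p, b)

Each bridge's ratio matrix is divided by its plex-wide median (computed
over present entries of that plex only), the two rescaled ratios are
averaged arithmetically, plexes are stitched (a protein absent from a
plex is missing for that plex's samples), and the stitched table is
divided by its global median, fixing the final global median at 1.
Consequences, all under test:

* multiplying any plex's entire matrix by a positive constant leaves the
  output unchanged — the defining purpose of bridging;
* with zero measurement noise the output equals the bridge-relative
  truth `A(p, s) / mean_s A(p, s)` up to one global scale factor;
* a protein with zero bridge signal in a plex cannot be ratioed there;
  it is flagged missing for that plex and logged, not imputed.

The mean-S/N filter applies to raw S/N before bridge division, and the
per-bridge median rescaling is per plex; both points are configurable
conventions, not identities.

LCA adjustment: a peptide matched to several proteins receives the
deepest taxonomic rank shared by all candidates (domain → species
prefix); a protein's lineage is then the LCA over its peptides' labels.
Peptides whose candidates share no rank become unclassified (empty
lineage).

## Concordance statistics

Per-feature Spearman ρ is computed across date-collapsed samples over
complete pairs (both layers present), with average ranks for ties;
features with fewer than 3 complete pairs, or a constant profile in
either layer, are omitted and counted. Correlations use the *D* = 8
date-collapsed columns rather than the 24 replicate columns — replicate
triplets are technical, not biological, and would triple the apparent
sample size; the choice is configurable by collapsing or not before the
call.

Category rollups sum abundances over annotated features (missing cells
contribute 0; a feature with several GO terms contributes to each;
unannotated features are dropped and counted). Category-level
concordance comes in two modes: one ρ per category from rolled-up
tables, or per-feature ρ grouped by category (the box-plot view).

Dynamic range is max/min over present values. An item whose minimum
present value is 0 uses its smallest nonzero value instead and is
flagged: dropping the item would discard exactly the most dynamic
features, and an infinite ratio is unusable downstream. All-zero items
are undefined and excluded. Standard deviations use the n−1 denominator,
optionally on log10 values (raw values are the default; the log axis is
a display convention, not a definition).

## Biomarker association

Each feature is regressed (ordinary least squares) on each biomarker
series over complete pairs; the effect size is the Pearson r (sign
matching the slope). Selection is by effect size only, |r| > τ with
τ = 0.7 by default — no multiple-testing correction, deliberately:
the analysis contrasts the *composition* of the strongly associated
sets, not individual significance claims; p-values are reported but
unused.

Composition log ratio per category *c*:

    f⁺(c) = n⁺(c) / |pos|,  f⁻(c) = n⁻(c) / |neg|,
    LR(c) = log2( (f⁺ + ε) / (f⁻ + ε) ),   ε = 0.5 / max(|pos|, |neg|)

where counts are of features (not abundance mass — the contrast is over
how many associated features each category contributes), fractions are
over annotated features (unannotated features are excluded from the
denominators and reported), and the half-count pseudocount keeps the
ratio finite while vanishing as the sets grow. The statistic is exactly
antisymmetric under swapping the two sets. The log base is configurable.
Gram-stain grouping is the same statistic at the Gram level, with
`unknown` reported as its own class.

Association overlap counts strong (feature, biomarker, sign) triples
unique to each layer and shared; the overall shared fraction uses the
union of both layers' triples as denominator, and a second fraction
restricts both sets to the shared quantified namespace.

The microbial dysbiosis index operates on a taxon-level table (e.g. a
species rollup): per sample, `log2((Σ increased + ε) / (Σ decreased + ε))`
with ε half the smallest nonzero value in the table. Default lists:
increased in Crohn's disease — *Escherichia coli*, *Fusobacterium
nucleatum*; decreased — *Faecalibacterium prausnitzii*, *Eubacterium
rectale*, *Bacteroides vulgatus*. Taxa are matched by exact species
string; unmatched list entries are logged, and a list with no
representative at all raises. The index is antisymmetric under swapping
the lists and strictly increasing in any increased-taxon abundance.

## Ordination and permutation statistics

All implemented directly (they are small, and owning them makes the
permutation machinery seedable and bitwise reproducible); scipy and
scikit-bio serve as independent cross-checks in the test suite only.

* **Bray-Curtis**: `d(i,j) = 1 − 2·Σ min(x_i, x_j) / (Σx_i + Σx_j)`;
  requires complete tables; two all-zero samples raise.
* **PCoA**: double-center `−½D²`, symmetric eigendecomposition, keep
  positive-eigenvalue axes scaled by √λ. Negative eigenvalues
  (non-Euclidean input) are reported, not corrected — no
  Lingoes/Cailliez adjustment, the simplest defensible default.
* **Procrustes**: both configurations centered and scaled to unit
  Frobenius norm, optimal rotation/reflection from the SVD of `YᵀX`,
  optimal scale = Σ singular values; `M² = 1 − (Σσ)² ∈ [0, 1]`.
* **Mantel**: Pearson correlation of upper triangles; rows/columns of
  the second matrix permuted jointly; one-sided (greater).
* **PERMANOVA**: `pseudo-F = (SS_A/(a−1)) / (SS_W/(n−a))` from sums of
  squared distances; group labels permuted; groups must have ≥ 2
  members.
* **Friedman**: average ranks within blocks, tie-corrected χ²,
  asymptotic p with k−1 df. All-constant blocks give statistic 0 with a
  warning (the tie correction degenerates).

Permutation p-values use `(1 + count) / (n_perm + 1)` with
n_perm = 999 by default; ties with the observed statistic count towards
the numerator (within 1e-12), making the estimate conservative. Passing
`n_perm=None` enumerates all permutations and returns the exact fraction
(small n only). Every permutation test takes an explicit seed.

## Synthetic data generator

The generator defines the study conditions; everything it plants is
recorded in a `StudyTruth` JSON that round-trips losslessly.

**Abundance marginals** are log-normal in both layers — heavy-tailed,
matching the orders-of-magnitude max/min ranges real gene and protein
profiles show. Gene counts are rounded to integers at a 2×10⁴ scale
(large enough that rounding almost never creates rank ties).

**Gene–protein coupling.** Each feature couples the layers through a
shared latent Gaussian: gene log-abundance uses latent `z`, protein
log-abundance uses `ρ·z + √(1−ρ²)·ε`. Because both layers are monotone
transforms of bivariate normal latents, the expected *sample* Spearman
coefficient at n complete pairs has the exact closed form

    E[r_s] = 6/(π(n+1)) · ( asin(ρ) + (n−2)·asin(ρ/2) )

which is inverted numerically (Brent) per feature at that feature's
complete-pair count, so the planted per-feature Spearman targets — and
their mean — are unbiased under planted missingness. Per-feature targets
are drawn N(ρ*, 0.15) with ρ* = 0.32 by default; requesting |target| = 1
short-circuits to perfect coupling. Planted eggNOG categories can carry
their own targets (200 features per category by default).

**Missingness** is planted per (feature, date) — a detection event
shared by the technical replicates — at rate 0.33 for genes and 0.06
for proteins. Over 8 dates these give ≈ 4 % complete-case genes and
≈ 60 % complete-case proteins, the qualitative contrast between sparse
shotgun detection and multiplexed TMT quantification. Missing gene dates
are written as `NA` in the counts table; CPM padding converts them to
zeros for compositional analyses, while rank correlations treat
non-detection as information-free and use complete pairs.

**PSM-level experiments** mirror the plex structure: each of 3 plexes
measures one replicate of all 8 dates on the 8 non-bridge channels of a
TMT 10-plex (random channel assignment); bridges carry the per-protein
mean over all samples. Per-plex scale factors, per-channel loading
errors, per-PSM flyability factors and log-normal measurement noise are
all configurable; filter violations are planted on disjoint PSMs with
counts recorded, and legitimate PSMs are kept clear of the mean-S/N
threshold so the planted counts are recovered exactly. Shared peptides
list the true protein plus a shorter homolog with no independent
evidence, so greedy resolution is exercised without corrupting the
quantification truth.

**Biomarker structure.** The five biomarker series follow a requested
correlation matrix (default from a one-factor model with
calprotectin–lactoferrin ≈ 0.96 and calprotectin–S-IgA ≈ 0.50; a
non-positive-semidefinite request raises). Planted tracker features are
affine in the tracked biomarker — so zero-noise trackers regress at
|r| = 1 exactly — half positive, half negative, fully observed. Genus
labels are allocated by largest-remainder proportions rather than
multinomial sampling: the enrichment fold (default 8× for *Akkermansia*
among positive trackers, 40 % vs 5 %) is a study condition, and
deterministic allocation realizes it exactly at any set size instead of
adding sampling noise around it. Calprotectin is inserted as two subunit
rows (S100A8 + S100A9) whose sum is the series.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: compositional closure coupling between
features (features are generated independently, so CPM induces only
weak cross-feature dependence); phylogenetic correlation of abundances
within genera; database-search errors and FDR structure; peptide-level
quantification interference between co-eluting species;
depth-of-coverage differences driving the gene layer's larger dynamic
range; and any real relationship between inflammation state and
community composition (the high/low labels are planted). Recovery of
planted truth validates the estimators' correctness and calibration,
not biological conclusions.

## Validation problem sizes

The statistical-oracle checks use ≤ 200 features × 8 samples with
tolerance 1e-9 (machine-precision agreement in practice). TMT recovery
uses 150 proteins × 3 plexes; the zero-noise reconstruction must match
truth to ≤ 1e-6 relative after removing one global scale. Concordance
calibration uses 2,000 features (mean within ±0.05 of ρ* = 0.32) and
200 features per planted category (means within ±0.1 of {0.0, 0.6}).
Association recovery uses 500 trackers over 1,000 background features
(≥ 95 % retrieved with correct sign; enriched-genus log₂ ratio within
3 ± 0.5). The Mantel null calibration runs 600–1,200 independent
replicates at 199 permutations each; the type-I rate at α = 0.05 must
lie in [0.03, 0.07]. These sizes make the full suite run in well under a
minute per module while keeping Monte-Carlo intervals tight enough for
the stated bands.

## Known limitations

* The Friedman p-value is asymptotic; at very small block counts a
  permutation version would be preferable.
* PERMANOVA permutes raw labels (no restriction/strata support).
* Bray-Curtis/PCoA require complete-case tables by design; imputation
  strategies are out of scope.
* The LCA adjustment uses the annotation lineages as given; it cannot
  recover ranks the annotation lacks.
* Dysbiosis-index taxon matching is by exact species string; fuzzy or
  synonym-aware matching is not attempted.
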