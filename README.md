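# concord

Gene–protein concordance analysis for paired metagenome / metaproteome
time series.

Shotgun metagenomics measures which microbial genes are present in a
community and how abundant they are; metaproteomics (here, TMT-multiplexed
LC-MS³) measures how much of the corresponding proteins is actually
expressed. When both layers are quantified against a shared ORF namespace
over the same longitudinal samples — e.g. stool collected repeatedly from
one inflammatory-bowel-disease patient alongside immune biomarkers such as
fecal calprotectin — a set of recurring questions appears:

* How well do gene copy-number fluctuations predict protein fluctuations,
  per ORF and per functional category (GO / KO / eggNOG)?
* Which taxa and functions track immune biomarkers, and do the two omic
  layers agree on them?
* Do the layers share community-level structure (ordination), and do
  compositions differ across time points?

`concord` implements that analysis as a tested, reusable pipeline for
anyone comparing paired gene/protein abundance tables, together with a
synthetic-data module that generates every input with known ground truth.

## What it computes

**TMT quantification.** PSM-level records are filtered (high confidence
only, isolation interference ≤ 25 %, mean reporter S/N ≥ 10; proteins
with a single surviving PSM are kept), shared peptides are resolved
(prefer proteins with prior evidence, else the longest candidate), summed
per protein, and bridge-normalized: with bridge channels *b*₁, *b*₂
carrying a pooled composite in every plex,

    r_b(p, c) = SN(p, c) / SN(p, b),  value = mean_b [ r_b / median(r_b) ],

then the stitched table is divided by its global median. This cancels
per-plex scale factors exactly. Peptide-level lowest-common-ancestor (LCA)
taxonomy adjustment is available.

**Concordance.** Per-feature Spearman ρ between date-collapsed gene CPM
(counts per million) and protein relative abundance; rollups and ρ at
category level; max/min dynamic-range and standard-deviation profiles.

**Association.** OLS of every feature against each biomarker series
(calprotectin = S100A8 + S100A9, CRP, lysozyme, lactoferrin, S-IgA);
large-effect selection at |r| > 0.7; composition log ratios
log₂((f⁺+ε)/(f⁻+ε)) contrasting positively vs negatively associated
features per genus / phylum / eggNOG category / Gram class; gene–protein
association overlap counts; and the microbial dysbiosis index
log₂(Σ CD-increased taxa / Σ CD-decreased taxa) per sample.

**Ordination statistics** (self-contained implementations): Bray-Curtis
dissimilarity, classical PCoA, Procrustes M², Mantel test, PERMANOVA
pseudo-F with permutation p-values (the `(1+count)/(n_perm+1)` estimator,
seeded and reproducible), and the tie-corrected Friedman test.

## Worked example

```python
from concord import (OmicsSimConfig, BiomarkerSimConfig,
                     simulate_paired_omics, simulate_biomarker_structure,
                     collapse_replicates, subset_shared_features,
                     paired_feature_spearman, extract_biomarkers,
                     regress_features_vs_biomarker, select_strong,
                     composition_log_ratio)
from concord.data_model import FeatureTable

base = simulate_paired_omics(OmicsSimConfig(n_features=1000), seed=7)
genes = collapse_replicates(FeatureTable(base.gene_counts, "gene"),
                            base.metadata, "mean")
proteins = collapse_replicates(base.protein_table, base.metadata, "mean")
rho = paired_feature_spearman(subset_shared_features(genes, proteins))
print(f"mean Spearman rho = {rho.mean:.3f} (sd {rho.sd:.3f})")

study = simulate_biomarker_structure(base, BiomarkerSimConfig(n_strong=400),
                                     seed=8)
proteins = collapse_replicates(study.protein_table, study.metadata, "mean")
biomarkers = extract_biomarkers(proteins, study.biomarker_map)
res, _ = regress_features_vs_biomarker(proteins, biomarkers["calprotectin"],
                                       "calprotectin")
pos, neg = select_strong(res, tau=0.7)
ratios, _ = composition_log_ratio(pos, neg, study.annotations, "genus")
top = max(ratios, key=lambda r: r.log_ratio)
print(f"{len(pos)} positive / {len(neg)} negative; most enriched genus: "
      f"{top.category} (log2 ratio {top.log_ratio:.2f})")
```

prints

```
mean Spearman rho = 0.325 (sd 0.484)
270 positive / 207 negative; most enriched genus: Akkermansia (log2 ratio 2.43)
```

The generator planted a mean gene–protein coupling of ρ* = 0.32 and an
8-fold *Akkermansia* enrichment (log₂ ≈ 3, attenuated here by background
features that cross the |r| > 0.7 threshold by chance at n = 8 dates) —
both recovered by the pipeline. The per-feature spread (sd ≈ 0.48) is
dominated by rank-correlation sampling noise at 8 time points, not by the
planted dispersion.

The same stages run from the shell:

```sh
concord simulate biomarkers --seed 3 --out study/
concord run --config config.yaml     # full pipeline + checksum manifest
```

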