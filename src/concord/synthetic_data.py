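"""Synthetic study generators with recorded ground truth.

Every input the pipeline consumes can be generated here with known
truth: PSM-level TMT experiments (for the quantification stages) and
paired gene/protein study tables with planted gene-protein concordance,
immune-biomarker associations, genus-level enrichment among associated
features, and layer-specific missingness.

The default study shape mirrors the design the pipeline targets: eight
collection dates, three technical replicates, three TMT 10-plexes with
two bridge channels (126/131) each carrying a pooled composite of all
samples.  Abundance marginals are log-normal (heavy-tailed, matching the
wide max/min ranges of real gene and protein profiles).

All outputs are pure functions of ``(config, seed)``; the recorded
:class:`StudyTruth` round-trips losslessly through JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .data_model import (AnnotationTable, BIOMARKERS, FeatureTable, RANKS,
                         SampleMetadata)
from .tmt import (DEFAULT_BRIDGES, MIN_MEAN_SN, PlexDesign, PSMRecord,
                  TMT10_CHANNELS, write_plex_designs_tsv,
                  write_protein_lengths_tsv, write_psms_tsv)

#: Default collection dates (longitudinal, multi-year span).
DEFAULT_DATES = ("2011-12-28", "2012-06-15", "2013-01-10", "2013-08-20",
                 "2014-03-05", "2014-11-18", "2015-07-02", "2016-05-22")

#: Dates planted as high-inflammation states.
DEFAULT_HIGH_INFLAMMATION = ("2011-12-28", "2013-01-10",
                             "2014-11-18", "2016-05-22")

#: Genus -> (domain..family lineage, Gram stain) used for annotations.
GENUS_TAXONOMY: dict[str, tuple[tuple[str, ...], str]] = {
    "Escherichia": (("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     "Enterobacterales", "Enterobacteriaceae"), "negative"),
    "Bacteroides": (("Bacteria", "Bacteroidetes", "Bacteroidia",
                     "Bacteroidales", "Bacteroidaceae"), "negative"),
    "Alistipes": (("Bacteria", "Bacteroidetes", "Bacteroidia",
                   "Bacteroidales", "Rikenellaceae"), "negative"),
    "Faecalibacterium": (("Bacteria", "Firmicutes", "Clostridia",
                          "Eubacteriales", "Oscillospiraceae"), "positive"),
    "Anaerostipes": (("Bacteria", "Firmicutes", "Clostridia",
                      "Eubacteriales", "Lachnospiraceae"), "positive"),
    "Butyricicoccus": (("Bacteria", "Firmicutes", "Clostridia",
                        "Eubacteriales", "Butyricicoccaceae"), "positive"),
    "Lachnospira": (("Bacteria", "Firmicutes", "Clostridia",
                     "Eubacteriales", "Lachnospiraceae"), "positive"),
    "Eubacterium": (("Bacteria", "Firmicutes", "Clostridia",
                     "Eubacteriales", "Eubacteriaceae"), "positive"),
    "Blautia": (("Bacteria", "Firmicutes", "Clostridia",
                 "Eubacteriales", "Lachnospiraceae"), "positive"),
    "Fusobacterium": (("Bacteria", "Fusobacteria", "Fusobacteriia",
                       "Fusobacteriales", "Fusobacteriaceae"), "negative"),
    "Akkermansia": (("Bacteria", "Verrucomicrobia", "Verrucomicrobiae",
                     "Verrucomicrobiales", "Akkermansiaceae"), "negative"),
    "Roseburia": (("Bacteria", "Firmicutes", "Clostridia",
                   "Eubacteriales", "Lachnospiraceae"), "positive"),
}

#: Species planted so the dysbiosis index lists resolve.
SPECIES_OF_GENUS: dict[str, tuple[str, ...]] = {
    "Escherichia": ("Escherichia coli",),
    "Fusobacterium": ("Fusobacterium nucleatum",),
    "Faecalibacterium": ("Faecalibacterium prausnitzii",),
    "Eubacterium": ("Eubacterium rectale",),
    "Bacteroides": ("Bacteroides vulgatus",),
}

GO_POOL = tuple(f"GO:{7000000 + 13 * i}" for i in range(30))
EGGNOG_POOL = ("Energy production and conversion",
               "Carbohydrate transport and metabolism",
               "Amino acid transport and metabolism",
               "Translation, ribosomal structure and biogenesis",
               "Cell wall/membrane/envelope biogenesis",
               "Posttranslational modification, protein turnover, chaperones",
               "Nucleotide transport and metabolism",
               "Inorganic ion transport and metabolism",
               "Cell cycle control, cell division",
               "Replication, recombination and repair")


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# StudyTruth
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def frame_to_obj(df: pd.DataFrame) -> dict:
    return {"index": [str(i) for i in df.index],
            "columns": [str(c) for c in df.columns],
            "data": _jsonable(df.to_numpy())}


def obj_to_frame(obj: dict) -> pd.DataFrame:
    data = [[np.nan if v is None else v for v in row] for row in obj["data"]]
    return pd.DataFrame(data, index=obj["index"], columns=obj["columns"],
                        dtype=float)


@dataclass
class StudyTruth:
    """Ground-truth record of one simulation (config, seed, planted values)."""

    config: dict
    seed: int
    data: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {"config": _jsonable(self.config), "seed": int(self.seed),
                   "data": _jsonable(self.data)}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StudyTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(payload["config"], payload["seed"], payload["data"])


def _sample_id(date: str, replicate: int) -> str:
    return f"{date}_r{replicate}"


def default_metadata(dates: Sequence[str], n_replicates: int,
                     high_dates: Sequence[str] = DEFAULT_HIGH_INFLAMMATION
                     ) -> SampleMetadata:
    rows = []
    for date in dates:
        state = "high" if date in high_dates else "low"
        for rep in range(1, n_replicates + 1):
            rows.append({"sample_id": _sample_id(date, rep), "date": date,
                         "replicate": rep, "inflammation": state})
    return SampleMetadata(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# PSM-level TMT experiment
# ---------------------------------------------------------------------------


@dataclass
class PSMSimConfig:
    """Conditions for the PSM-level simulation.

    Each plex measures one technical replicate of every date; bridge
    channels carry the pooled composite (the per-protein mean over all
    samples) scaled only by plex/channel factors, so bridging is the
    ground-truth route to cross-plex comparability.
    """

    n_plexes: int = 3
    n_proteins: int = 200
    psms_per_protein: int = 4
    shared_peptide_fraction: float = 0.1
    n_dates: int = 8
    sigma_protein: float = 1.0       # ln-scale spread of protein baselines
    sigma_sample: float = 1.2        # ln-scale per-date abundance deviation
    psm_scale: float = 200.0         # S/N units per abundance unit
    psm_factor_sigma: float = 0.5    # ln-scale PSM flyability spread
    noise_sd: float = 0.0            # ln-scale measurement noise per channel
    plex_scale_range: tuple[float, float] = (1.0, 1.0)
    channel_loading_range: tuple[float, float] = (1.0, 1.0)
    violations: dict = field(default_factory=lambda: {
        "confidence": 0, "ambiguity": 0, "interference": 0, "low_sn": 0})

    def __post_init__(self) -> None:
        if self.n_dates != len(TMT10_CHANNELS) - 2:
            raise SimulationError(
                "n_dates must equal the number of sample channels (8)")


@dataclass
class PSMExperiment:
    psms: list[PSMRecord]
    designs: dict[str, PlexDesign]
    protein_lengths: dict[str, int]
    metadata: SampleMetadata
    truth: StudyTruth

    def write(self, outdir) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        write_psms_tsv(self.psms, TMT10_CHANNELS, f"{outdir}/psms.tsv")
        write_plex_designs_tsv(self.designs, f"{outdir}/plex_design.tsv")
        write_protein_lengths_tsv(self.protein_lengths,
                                  f"{outdir}/protein_lengths.tsv")
        self.metadata.write_tsv(f"{outdir}/metadata.tsv")
        self.truth.to_json(f"{outdir}/truth.json")


def simulate_psm_experiment(config: PSMSimConfig | None = None,
                            seed: int = 0) -> PSMExperiment:
    """Generate a multi-plex TMT experiment with known relative abundances.

    With zero noise and zero planted violations, running the TMT pipeline
    (filter, resolve, rollup, bridge-normalize) on the output reproduces
    the recorded bridge-relative truth up to one global scale.
    """
    cfg = config or PSMSimConfig()
    rng = np.random.default_rng(seed)
    dates = list(DEFAULT_DATES[:cfg.n_dates])
    meta = default_metadata(dates, cfg.n_plexes)

    proteins = [f"ORF{i:05d}" for i in range(cfg.n_proteins)]
    lengths = {p: int(rng.integers(150, 1000)) for p in proteins}
    decoys = {p: f"HOM{i:05d}" for i, p in enumerate(proteins)}
    for p, d in decoys.items():
        lengths[d] = max(60, lengths[p] - 50)

    base = rng.normal(0.0, cfg.sigma_protein, cfg.n_proteins)
    z = rng.normal(0.0, 1.0, (cfg.n_proteins, cfg.n_dates))
    abundance = np.exp(base[:, None] + cfg.sigma_sample * z)  # protein x date
    bridge = abundance.mean(axis=1)                           # pooled composite

    plex_scales = {}
    loadings = {}
    designs = {}
    sample_channels = [c for c in TMT10_CHANNELS if c not in DEFAULT_BRIDGES]
    for k in range(cfg.n_plexes):
        pid = f"plex{k + 1}"
        plex_scales[pid] = float(rng.uniform(*cfg.plex_scale_range))
        loadings[pid] = {c: float(rng.uniform(*cfg.channel_loading_range))
                         for c in TMT10_CHANNELS}
        perm = rng.permutation(cfg.n_dates)
        sample_of_channel = {c: _sample_id(dates[perm[j]], k + 1)
                             for j, c in enumerate(sample_channels)}
        designs[pid] = PlexDesign(pid, TMT10_CHANNELS, DEFAULT_BRIDGES,
                                  sample_of_channel)

    psms: list[PSMRecord] = []
    for k in range(cfg.n_plexes):
        pid = f"plex{k + 1}"
        design = designs[pid]
        date_of_channel = {c: design.sample_of_channel[c].rsplit("_r", 1)[0]
                           for c in design.sample_channels}
        for i, prot in enumerate(proteins):
            for j in range(cfg.psms_per_protein):
                factor = float(np.exp(rng.normal(0.0, cfg.psm_factor_sigma)))
                channel_sn = {}
                for c in TMT10_CHANNELS:
                    if c in DEFAULT_BRIDGES:
                        a = bridge[i]
                    else:
                        a = abundance[i, dates.index(date_of_channel[c])]
                    sn = cfg.psm_scale * a * plex_scales[pid] * \
                        loadings[pid][c] * factor
                    if cfg.noise_sd > 0:
                        sn *= float(np.exp(rng.normal(0.0, cfg.noise_sd)))
                    channel_sn[c] = sn
                # keep legitimate PSMs clear of the mean-S/N filter so the
                # planted violation counts are recovered exactly
                mean_sn = float(np.mean(list(channel_sn.values())))
                if mean_sn < MIN_MEAN_SN * 1.2:
                    boost = MIN_MEAN_SN * 1.2 / mean_sn
                    channel_sn = {c: v * boost for c, v in channel_sn.items()}
                shared = rng.random() < cfg.shared_peptide_fraction
                cands = (prot, decoys[prot]) if shared else (prot,)
                psms.append(PSMRecord(
                    peptide=f"PEP_{prot}_{pid}_{j}",
                    candidate_proteins=cands,
                    confidence="high",
                    interference_pct=float(rng.uniform(0.0, 20.0)),
                    channel_sn=channel_sn,
                    plex_id=pid))

    # plant filter violations on distinct PSMs
    order = rng.permutation(len(psms))
    cursor = 0
    planted = {r: int(cfg.violations.get(r, 0))
               for r in ("confidence", "ambiguity", "interference", "low_sn")}
    if sum(planted.values()) > len(psms):
        raise SimulationError("more planted violations than PSMs")
    for rule, count in planted.items():
        for _ in range(count):
            psm = psms[order[cursor]]
            cursor += 1
            if rule == "confidence":
                psm.confidence = "moderate"
            elif rule == "ambiguity":
                psm.confidence = "ambiguous"
            elif rule == "interference":
                psm.interference_pct = float(rng.uniform(26.0, 90.0))
            else:
                target = float(rng.uniform(2.0, 8.0))
                shrink = target / psm.mean_sn
                psm.channel_sn = {c: v * shrink
                                  for c, v in psm.channel_sn.items()}

    sample_ids = [_sample_id(d, k + 1)
                  for k in range(cfg.n_plexes) for d in dates]
    rel = pd.DataFrame(
        {s: abundance[:, dates.index(s.rsplit("_r", 1)[0])] / bridge
         for s in sample_ids}, index=proteins)
    truth = StudyTruth(asdict(cfg), seed, {
        "relative_abundance": frame_to_obj(rel),
        "plex_scales": plex_scales,
        "channel_loadings": loadings,
        "planted_violations": planted,
    })
    return PSMExperiment(psms, designs, lengths, meta, truth)


# ---------------------------------------------------------------------------
# Paired omics study
# ---------------------------------------------------------------------------


def expected_spearman(rho: float, n: int) -> float:
    """Exact expectation of the sample Spearman coefficient for a
    bivariate normal with Pearson correlation ``rho`` at sample size ``n``."""
    return 6.0 / (math.pi * (n + 1)) * (
        math.asin(rho) + (n - 2) * math.asin(rho / 2.0))


def invert_spearman_target(target: float, n: int) -> float:
    """Latent Pearson correlation whose expected sample Spearman at size
    ``n`` equals ``target``."""
    if not -1.0 < target < 1.0:
        raise SimulationError(f"Spearman target {target} outside (-1, 1)")
    return float(optimize.brentq(
        lambda r: expected_spearman(r, n) - target, -0.999999, 0.999999))


@dataclass
class OmicsSimConfig:
    """Conditions for the paired gene/protein study simulation."""

    n_features: int = 2000
    n_dates: int = 8
    n_replicates: int = 3
    rho_star: float = 0.32            # target mean per-feature Spearman
    rho_dispersion: float = 0.15      # spread of per-feature targets
    category_targets: dict = field(default_factory=dict)  # eggNOG -> target
    features_per_category: int = 200
    category_dispersion: float = 0.05
    gene_missing_rate: float = 0.33   # per (feature, date); ~4% complete
    protein_missing_rate: float = 0.06  # per (feature, date); ~60% complete
    sigma_gene: float = 1.0           # ln-scale spread across dates
    sigma_protein: float = 1.0
    replicate_noise_sd: float = 0.05  # ln-scale technical replicate noise
    gene_count_scale: float = 2e4


@dataclass
class PairedOmicsStudy:
    gene_counts: pd.DataFrame          # features x samples, NaN = missing
    protein_table: FeatureTable
    annotations: AnnotationTable
    metadata: SampleMetadata
    truth: StudyTruth
    biomarkers: dict | None = None     # filled by simulate_biomarker_structure
    biomarker_map: dict | None = None

    def write(self, outdir) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        out = self.gene_counts.copy()
        out.index.name = "feature_id"
        out.to_csv(f"{outdir}/gene_counts.tsv", sep="\t", na_rep="NA")
        self.protein_table.write_tsv(f"{outdir}/protein_table.tsv")
        self.annotations.write_tsv(f"{outdir}/annotations.tsv")
        self.metadata.write_tsv(f"{outdir}/metadata.tsv")
        self.truth.to_json(f"{outdir}/truth.json")


def _assign_taxonomy(rng: np.random.Generator, feature_ids: Sequence[str]
                     ) -> AnnotationTable:
    """Genus/species/GO/KO/eggNOG annotations over a fixed genus pool."""
    genera = list(GENUS_TAXONOMY)
    weights = np.exp(rng.normal(0.0, 1.0, len(genera)))
    weights /= weights.sum()
    rows = {}
    species_features = [(g, s) for g, specs in SPECIES_OF_GENUS.items()
                        for s in specs]
    for i, fid in enumerate(feature_ids):
        if i < 5 * len(species_features):
            genus, species = species_features[i % len(species_features)]
        else:
            genus = genera[rng.choice(len(genera), p=weights)]
            specs = SPECIES_OF_GENUS.get(genus, ())
            species = specs[0] if (specs and rng.random() < 0.3) else ""
        lineage, gram = GENUS_TAXONOMY[genus]
        row = dict(zip(RANKS[:5], lineage))
        row["genus"] = genus
        row["species"] = species
        n_go = int(rng.integers(1, 4))
        row["go_terms"] = ";".join(
            sorted(rng.choice(GO_POOL, size=n_go, replace=False)))
        row["ko"] = f"K{int(rng.integers(1, 500)):05d}"
        row["eggnog"] = ""  # filled by the caller
        row["gram"] = gram
        rows[fid] = row
    return AnnotationTable(pd.DataFrame.from_dict(rows, orient="index"))


def simulate_paired_omics(config: OmicsSimConfig | None = None,
                          seed: int = 0) -> PairedOmicsStudy:
    """Paired gene-count and protein tables with planted Spearman targets.

    Each feature couples the two layers through a shared latent Gaussian;
    the latent Pearson correlation is calibrated per feature by inverting
    the exact small-sample Spearman expectation at that feature's
    complete-pair count, so the planted per-feature targets (and their
    mean) are recovered by the concordance stage in expectation.
    """
    cfg = config or OmicsSimConfig()
    rng = np.random.default_rng(seed)
    dates = list(DEFAULT_DATES[:cfg.n_dates])
    meta = default_metadata(dates, cfg.n_replicates)
    n, d = cfg.n_features, cfg.n_dates

    fids = [f"ORF{i:05d}" for i in range(n)]
    ann = _assign_taxonomy(rng, fids)

    # per-feature Spearman targets; planted categories first
    if cfg.rho_dispersion == 0:
        targets = np.full(n, cfg.rho_star)
    else:
        targets = np.clip(rng.normal(cfg.rho_star, cfg.rho_dispersion, n),
                          -0.9, 0.95)
    eggnog = list(rng.choice(EGGNOG_POOL, size=n))
    pos = 0
    planted_categories = {}
    for cat, rho_t in cfg.category_targets.items():
        idx = list(range(pos, pos + cfg.features_per_category))
        if idx and idx[-1] >= n:
            raise SimulationError("not enough features for category targets")
        for i in idx:
            eggnog[i] = cat
            targets[i] = float(np.clip(
                rng.normal(rho_t, cfg.category_dispersion), -0.9, 0.95))
        planted_categories[cat] = {"target": rho_t,
                                   "features": [fids[i] for i in idx]}
        pos += cfg.features_per_category
    ann.table["eggnog"] = eggnog

    # planted missingness at (feature, date) level
    gene_missing = rng.random((n, d)) < cfg.gene_missing_rate
    prot_missing = rng.random((n, d)) < cfg.protein_missing_rate

    # latent coupling calibrated at each feature's complete-pair count
    n_complete = (~gene_missing & ~prot_missing).sum(axis=1)
    rho_latent = np.zeros(n)
    cache: dict[tuple[float, int], float] = {}
    for i in range(n):
        nf = int(n_complete[i])
        if nf < 3:
            continue
        t = float(targets[i])
        if abs(t) >= 0.9999:       # perfect coupling requested
            rho_latent[i] = math.copysign(1.0, t)
            continue
        key = (round(t, 6), nf)
        if key not in cache:
            cache[key] = invert_spearman_target(t, nf)
        rho_latent[i] = cache[key]

    zg = rng.normal(0.0, 1.0, (n, d))
    eps = rng.normal(0.0, 1.0, (n, d))
    zp = rho_latent[:, None] * zg + \
        np.sqrt(1.0 - rho_latent[:, None] ** 2) * eps

    a = rng.normal(0.0, 1.0, n)
    b = rng.normal(0.0, 1.0, n)
    gene_date = np.exp(a[:, None] + cfg.sigma_gene * zg)
    prot_date = np.exp(b[:, None] + cfg.sigma_protein * zp)

    gene_cols = {}
    prot_cols = {}
    for j, date in enumerate(dates):
        for rep in range(1, cfg.n_replicates + 1):
            sid = _sample_id(date, rep)
            gnoise = np.exp(rng.normal(0.0, cfg.replicate_noise_sd, n))
            pnoise = np.exp(rng.normal(0.0, cfg.replicate_noise_sd, n))
            g = np.round(gene_date[:, j] * gnoise * cfg.gene_count_scale)
            g = np.maximum(g, 1.0)
            g[gene_missing[:, j]] = np.nan
            p = prot_date[:, j] * pnoise
            p[prot_missing[:, j]] = np.nan
            gene_cols[sid] = g
            prot_cols[sid] = p
    gene_counts = pd.DataFrame(gene_cols, index=fids)
    proteins = FeatureTable(pd.DataFrame(prot_cols, index=fids), "protein")

    truth = StudyTruth(asdict(cfg), seed, {
        "spearman_targets": dict(zip(fids, targets.astype(float))),
        "latent_pearson": dict(zip(fids, rho_latent.astype(float))),
        "n_complete_pairs": dict(zip(fids, n_complete.astype(int))),
        "planted_categories": planted_categories,
        "gene_missing_rate": cfg.gene_missing_rate,
        "protein_missing_rate": cfg.protein_missing_rate,
        "high_inflammation_dates": list(DEFAULT_HIGH_INFLAMMATION),
    })
    return PairedOmicsStudy(gene_counts, proteins, ann, meta, truth)


# ---------------------------------------------------------------------------
# Biomarker structure
# ---------------------------------------------------------------------------


def default_biomarker_correlation() -> pd.DataFrame:
    """Positive-semidefinite biomarker correlation matrix built from a
    one-factor model; calprotectin-lactoferrin ~ 0.96, calprotectin-S-IgA
    ~ 0.50 by choice of loadings."""
    loadings = {"calprotectin": 0.99, "lactoferrin": 0.9697,
                "S-IgA": 0.5051, "CRP": 0.60, "lysozyme": 0.40}
    names = list(BIOMARKERS)
    lam = np.array([loadings[n] for n in names])
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


@dataclass
class BiomarkerSimConfig:
    """Conditions for planting biomarker series and tracking features."""

    correlation: pd.DataFrame | None = None   # default factor-model matrix
    n_strong: int = 500
    fraction_positive: float = 0.5
    tracker_noise_sd: float = 0.0     # ln-scale noise on tracker profiles
    track_biomarker: str = "calprotectin"
    enriched_genus: str = "Akkermansia"
    enrichment_fold: float = 8.0
    enriched_pos_fraction: float = 0.4
    biomarker_scale: float = 0.4      # ln-scale amplitude of the series


def _allocate_counts(total: int, fractions: Mapping[str, float]
                     ) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` items to categories."""
    raw = {k: total * f for k, f in fractions.items()}
    out = {k: int(math.floor(v)) for k, v in raw.items()}
    remainder = total - sum(out.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - out[k]), k))
    for k in order[:remainder]:
        out[k] += 1
    return out


def simulate_biomarker_structure(study: PairedOmicsStudy,
                                 config: BiomarkerSimConfig | None = None,
                                 seed: int = 1) -> PairedOmicsStudy:
    """Plant biomarker series and strongly-tracking features into a study.

    Biomarker series follow the requested pairwise Pearson structure (a
    non-positive-semidefinite request raises).  Planted trackers are
    affine in the tracked biomarker (so zero-noise trackers regress at
    |r| = 1), half positive and half negative, and their genus labels are
    allocated by exact largest-remainder proportions so the requested
    enrichment fold of the enriched genus among positive vs negative
    trackers is realized deterministically.
    """
    cfg = config or BiomarkerSimConfig()
    rng = np.random.default_rng(seed)
    corr = cfg.correlation if cfg.correlation is not None \
        else default_biomarker_correlation()
    names = list(corr.index)
    try:
        L = np.linalg.cholesky(corr.to_numpy())
    except np.linalg.LinAlgError as exc:
        raise SimulationError(
            "biomarker correlation matrix is not positive semidefinite"
        ) from exc

    dates = study.metadata.dates
    n_dates = len(dates)
    latent = L @ rng.normal(0.0, 1.0, (len(names), n_dates))
    series = {name: pd.Series(np.exp(cfg.biomarker_scale * latent[i]),
                              index=dates)
              for i, name in enumerate(names)}

    # biomarker protein rows (calprotectin = two subunits summing to it)
    from .association import DEFAULT_BIOMARKER_MAP
    sample_ids = list(study.protein_table.sample_ids)

    def tile(profile: pd.Series) -> np.ndarray:
        return np.array([profile[s.rsplit("_r", 1)[0]] for s in sample_ids])

    new_rows: dict[str, np.ndarray] = {}
    for name, prot_ids in DEFAULT_BIOMARKER_MAP.items():
        if name not in series:
            continue
        split = np.linspace(1.0, 2.0, len(prot_ids))
        split /= split.sum()
        for w, pid in zip(split, prot_ids):
            new_rows[pid] = w * tile(series[name])

    # tracker profiles, affine in the tracked biomarker
    b = series[cfg.track_biomarker]
    rngspan = float(b.max() - b.min())
    n_pos = int(round(cfg.n_strong * cfg.fraction_positive))
    n_neg = cfg.n_strong - n_pos
    tracker_ids, signs = [], {}
    gene_rows: dict[str, np.ndarray] = {}
    for i in range(cfg.n_strong):
        fid = f"TRK{i:05d}"
        sign = "+" if i < n_pos else "-"
        if sign == "+":
            profile = (b - b.min() + 0.1 * rngspan)
        else:
            profile = (b.max() - b + 0.1 * rngspan)
        scale = float(np.exp(rng.normal(0.0, 1.0)))
        prof = scale * tile(profile)
        if cfg.tracker_noise_sd > 0:
            prof = prof * np.exp(rng.normal(0.0, cfg.tracker_noise_sd,
                                            len(prof)))
        new_rows[fid] = prof
        gene_rows[fid] = np.maximum(np.round(prof * 1e4), 1.0)
        tracker_ids.append(fid)
        signs[fid] = sign

    # genus labels with exact planted enrichment among annotated trackers
    others = [g for g in GENUS_TAXONOMY if g != cfg.enriched_genus]
    p_pos = cfg.enriched_pos_fraction
    p_neg = p_pos / cfg.enrichment_fold
    frac_pos = {cfg.enriched_genus: p_pos,
                **{g: (1.0 - p_pos) / len(others) for g in others}}
    frac_neg = {cfg.enriched_genus: p_neg,
                **{g: (1.0 - p_neg) / len(others) for g in others}}
    counts_pos = _allocate_counts(n_pos, frac_pos)
    counts_neg = _allocate_counts(n_neg, frac_neg)

    def genus_sequence(counts: dict[str, int]) -> list[str]:
        seq = []
        for g in sorted(counts):
            seq.extend([g] * counts[g])
        return seq

    genus_of: dict[str, str] = {}
    for fid, genus in zip(tracker_ids[:n_pos], genus_sequence(counts_pos)):
        genus_of[fid] = genus
    for fid, genus in zip(tracker_ids[n_pos:], genus_sequence(counts_neg)):
        genus_of[fid] = genus

    ann_rows = {}
    for fid in tracker_ids:
        genus = genus_of[fid]
        lineage, gram = GENUS_TAXONOMY[genus]
        row = dict(zip(RANKS[:5], lineage))
        row.update(genus=genus, species="",
                   go_terms=";".join(
                       sorted(rng.choice(GO_POOL, 2, replace=False))),
                   ko="", eggnog=str(rng.choice(EGGNOG_POOL)), gram=gram)
        ann_rows[fid] = row
    for pid in new_rows:
        if pid.startswith("HUMAN_"):
            ann_rows[pid] = {r: "" for r in RANKS} | {
                "go_terms": "", "ko": "", "eggnog": "", "gram": "unknown"}

    prot_values = study.protein_table.values.copy()
    for fid, prof in new_rows.items():
        prot_values.loc[fid] = prof
    gene_values = study.gene_counts.copy()
    for fid, prof in gene_rows.items():
        gene_values.loc[fid] = prof

    ann_table = pd.concat([study.annotations.table,
                           pd.DataFrame.from_dict(ann_rows, orient="index")])
    truth = StudyTruth(
        dict(study.truth.config), seed,
        dict(study.truth.data) | {
            "biomarker_series": frame_to_obj(pd.DataFrame(series).T),
            "biomarker_correlation_target": frame_to_obj(corr),
            "tracker_ids": tracker_ids,
            "tracker_signs": signs,
            "tracker_genus": genus_of,
            "enriched_genus": cfg.enriched_genus,
            "enrichment_fold": cfg.enrichment_fold,
            "track_biomarker": cfg.track_biomarker,
        })
    return PairedOmicsStudy(gene_values,
                            FeatureTable(prot_values, "protein"),
                            AnnotationTable(ann_table),
                            study.metadata, truth,
                            biomarkers={k: v for k, v in series.items()},
                            biomarker_map=dict(DEFAULT_BIOMARKER_MAP))
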