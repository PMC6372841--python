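"""Feature-biomarker association and compositional enrichment summaries.

Every gene/protein profile is regressed (ordinary least squares) against
each immune-biomarker series (calprotectin, CRP, lysozyme, lactoferrin,
S-IgA); associations with a large effect size (|r| > 0.7 by default) are
classed positive or negative, and the taxonomic / functional composition
of the two classes is contrasted as log ratios.  Also implements the
gene-protein association overlap counts, Gram-stain grouping, biomarker
cross-correlation, and the microbial dysbiosis index (log ratio of taxa
increased vs decreased in Crohn's disease).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnnotationTable, FeatureTable

#: Default large-effect-size threshold on |r|.
DEFAULT_TAU = 0.7

MIN_PAIRS = 3


class AssociationError(ValueError):
    pass


#: Default biomarker -> protein-id map (calprotectin is the S100A8/S100A9
#: heterodimer; the others are single gene products).
DEFAULT_BIOMARKER_MAP: dict[str, tuple[str, ...]] = {
    "calprotectin": ("HUMAN_S100A8", "HUMAN_S100A9"),
    "CRP": ("HUMAN_CRP",),
    "lysozyme": ("HUMAN_LYZ",),
    "lactoferrin": ("HUMAN_LTF",),
    "S-IgA": ("HUMAN_IGHA1",),
}


# ---------------------------------------------------------------------------
# Biomarker extraction
# ---------------------------------------------------------------------------


def extract_biomarkers(proteins: FeatureTable,
                       id_map: Mapping[str, Sequence[str]] | None = None
                       ) -> dict[str, pd.Series]:
    """Per-sample biomarker series as sums of their mapped protein rows."""
    if id_map is None:
        id_map = DEFAULT_BIOMARKER_MAP
    present = set(proteins.feature_ids)
    out: dict[str, pd.Series] = {}
    for name, ids in id_map.items():
        hit = [i for i in ids if i in present]
        if not hit:
            warnings.warn(f"biomarker {name!r}: no mapped protein present")
            continue
        out[name] = proteins.values.loc[hit].fillna(0.0).sum(axis=0)
    return out


# ---------------------------------------------------------------------------
# Regression and selection
# ---------------------------------------------------------------------------


def regress_features_vs_biomarker(table: FeatureTable,
                                  biomarker: pd.Series,
                                  biomarker_name: str = "",
                                  tau: float = DEFAULT_TAU
                                  ) -> tuple[pd.DataFrame, int]:
    """OLS of every feature on a biomarker series.

    Returns a DataFrame with columns ``feature_id``, ``biomarker``,
    ``slope``, ``intercept``, ``r`` (Pearson, sign matching the slope),
    ``p_value``, ``n``, ``assoc_class`` (positive / negative / none at
    threshold ``tau``), plus the count of features skipped for having
    fewer than three complete pairs.
    """
    b = biomarker.reindex(table.sample_ids).to_numpy(float)
    bmask = ~np.isnan(b)
    if bmask.sum() >= 2 and np.nanstd(b) == 0:
        raise AssociationError(
            f"biomarker {biomarker_name or biomarker.name!r} has zero variance")
    rows = []
    skipped = 0
    vals = table.values.to_numpy(float)
    for i, fid in enumerate(table.feature_ids):
        y = vals[i]
        ok = bmask & ~np.isnan(y)
        if ok.sum() < MIN_PAIRS:
            skipped += 1
            continue
        if np.std(y[ok]) == 0:
            slope, intercept, r, p = 0.0, float(np.mean(y[ok])), 0.0, 1.0
        else:
            res = stats.linregress(b[ok], y[ok])
            slope, intercept, r, p = (float(res.slope), float(res.intercept),
                                      float(res.rvalue), float(res.pvalue))
        cls = "positive" if r > tau else "negative" if r < -tau else "none"
        rows.append({"feature_id": fid, "biomarker": biomarker_name,
                     "slope": slope, "intercept": intercept, "r": r,
                     "p_value": p, "n": int(ok.sum()), "assoc_class": cls})
    return (pd.DataFrame(rows, columns=["feature_id", "biomarker", "slope",
                                        "intercept", "r", "p_value", "n",
                                        "assoc_class"]),
            skipped)


def associate_all(table: FeatureTable,
                  biomarkers: Mapping[str, pd.Series],
                  tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Concatenated regression results for every biomarker."""
    parts = []
    for name in biomarkers:
        res, _ = regress_features_vs_biomarker(table, biomarkers[name],
                                               name, tau)
        parts.append(res)
    return pd.concat(parts, ignore_index=True)


def select_strong(results: pd.DataFrame, tau: float = DEFAULT_TAU
                  ) -> tuple[list[str], list[str]]:
    """Partition features of one biomarker's results by effect size.

    Returns (positively associated ids, negatively associated ids) at
    |r| > tau.
    """
    if not 0 < tau < 1:
        raise AssociationError(f"tau must be in (0, 1), got {tau}")
    pos = list(results.loc[results["r"] > tau, "feature_id"])
    neg = list(results.loc[results["r"] < -tau, "feature_id"])
    return pos, neg


# ---------------------------------------------------------------------------
# Composition log ratios
# ---------------------------------------------------------------------------


@dataclass
class CompositionLogRatio:
    """Per-category composition contrast between positive and negative sets."""

    category: str
    f_pos: float
    f_neg: float
    log_ratio: float
    n_pos: int
    n_neg: int


def composition_log_ratio(pos: Sequence[str], neg: Sequence[str],
                          ann: AnnotationTable, level: str,
                          log_base: float = 2.0
                          ) -> tuple[list[CompositionLogRatio], dict]:
    """Log ratio of category compositions of the two association classes.

    Fractions are over annotated features in each set (unannotated
    features are excluded and reported); the pseudocount is
    ``eps = 0.5 / max(|pos|, |neg|)`` over annotated counts.
    """
    if not pos or not neg:
        raise AssociationError("both association sets must be nonempty")
    cat_map = ann.category_map(level)

    def counts(ids: Sequence[str]) -> tuple[dict[str, int], int, int]:
        c: dict[str, int] = {}
        annotated = 0
        for fid in ids:
            cats = cat_map.get(fid, ())
            if not cats:
                continue
            annotated += 1
            for cat in cats:
                c[cat] = c.get(cat, 0) + 1
        return c, annotated, len(ids) - annotated

    cpos, npos, drop_pos = counts(pos)
    cneg, nneg, drop_neg = counts(neg)
    if npos == 0 or nneg == 0:
        raise AssociationError("an association set has no annotated features")
    eps = 0.5 / max(npos, nneg)
    out = []
    for cat in sorted(set(cpos) | set(cneg)):
        fp = cpos.get(cat, 0) / npos
        fn = cneg.get(cat, 0) / nneg
        lr = float(np.log((fp + eps) / (fn + eps)) / np.log(log_base))
        out.append(CompositionLogRatio(cat, fp, fn, lr,
                                       cpos.get(cat, 0), cneg.get(cat, 0)))
    info = {"n_pos_annotated": npos, "n_neg_annotated": nneg,
            "n_pos_unannotated": drop_pos, "n_neg_unannotated": drop_neg,
            "eps": eps}
    return out, info


def gram_stain_summary(pos: Sequence[str], neg: Sequence[str],
                       ann: AnnotationTable, log_base: float = 2.0
                       ) -> tuple[list[CompositionLogRatio], dict]:
    """Composition log ratios grouped by Gram stain class.

    Features without a Gram label fall in the ``unknown`` category, which
    is reported like any other.
    """
    return composition_log_ratio(pos, neg, ann, "gram", log_base)


def log_ratios_to_frame(ratios: Sequence[CompositionLogRatio]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in ratios])


# ---------------------------------------------------------------------------
# Overlap statistics
# ---------------------------------------------------------------------------


def association_overlap(gene_results: pd.DataFrame,
                        protein_results: pd.DataFrame,
                        tau: float = DEFAULT_TAU,
                        shared_features: Sequence[str] | None = None) -> dict:
    """Count strong associations unique to / shared between the layers.

    A strong association is a (feature, biomarker, sign) triple with
    |r| > tau.  Returns per-biomarker Venn counts, the shared fraction
    over the union of all strong associations, and — when the shared
    quantified namespace is given — the same fraction restricted to
    features quantified in both layers.
    """

    def strong(results: pd.DataFrame) -> set[tuple[str, str, str]]:
        sel = results[np.abs(results["r"]) > tau]
        return {(r.feature_id, r.biomarker, "+" if r.r > 0 else "-")
                for r in sel.itertuples()}

    gset, pset = strong(gene_results), strong(protein_results)
    shared = gset & pset
    union = gset | pset
    venn = {}
    for bm in sorted({t[1] for t in union}):
        g = {t for t in gset if t[1] == bm}
        p = {t for t in pset if t[1] == bm}
        venn[bm] = {"gene_only": len(g - p), "protein_only": len(p - g),
                    "shared": len(g & p)}
    out = {
        "n_gene_strong": len(gset),
        "n_protein_strong": len(pset),
        "n_shared": len(shared),
        "shared_fraction_all": (len(shared) / len(union)) if union else 0.0,
        "per_biomarker": venn,
    }
    if shared_features is not None:
        ns = set(shared_features)
        g2 = {t for t in gset if t[0] in ns}
        p2 = {t for t in pset if t[0] in ns}
        u2 = g2 | p2
        out["n_shared_namespace_strong"] = len(u2)
        out["shared_fraction_shared_namespace"] = (
            len(g2 & p2) / len(u2)) if u2 else 0.0
    return out


# ---------------------------------------------------------------------------
# Dysbiosis index
# ---------------------------------------------------------------------------

#: Taxa increased / decreased in Crohn's disease used by the default
#: microbial dysbiosis index.
CD_INCREASED_SPECIES = ("Escherichia coli", "Fusobacterium nucleatum")
CD_DECREASED_SPECIES = ("Faecalibacterium prausnitzii",
                        "Eubacterium rectale", "Bacteroides vulgatus")


@dataclass
class DysbiosisIndex:
    """Per-sample log ratio of CD-increased vs CD-decreased taxon abundance."""

    values: pd.Series
    increased_used: list[str]
    decreased_used: list[str]
    increased_missing: list[str] = field(default_factory=list)
    decreased_missing: list[str] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        out = self.values.rename("dysbiosis_index").to_frame()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


def dysbiosis_index(table: FeatureTable,
                    increased: Sequence[str] = CD_INCREASED_SPECIES,
                    decreased: Sequence[str] = CD_DECREASED_SPECIES,
                    log_base: float = 2.0) -> DysbiosisIndex:
    """Microbial dysbiosis index on a taxon-level abundance table.

    ``table`` rows are taxa (e.g. a species-level rollup); per sample the
    index is ``log2((sum increased + eps) / (sum decreased + eps))`` with
    ``eps`` half the smallest nonzero value in the table.  A taxon list
    with no representative present raises, naming the missing taxa.
    """
    present = set(table.feature_ids)
    inc = [t for t in increased if t in present]
    dec = [t for t in decreased if t in present]
    if not inc:
        raise AssociationError(
            f"no increased-list taxon present; missing: {list(increased)}")
    if not dec:
        raise AssociationError(
            f"no decreased-list taxon present; missing: {list(decreased)}")
    vals = table.values.fillna(0.0)
    arr = vals.to_numpy()
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise AssociationError("taxon table is entirely zero")
    eps = float(nonzero.min()) / 2.0
    up = vals.loc[inc].sum(axis=0)
    down = vals.loc[dec].sum(axis=0)
    idx = np.log((up + eps) / (down + eps)) / np.log(log_base)
    return DysbiosisIndex(idx, inc, dec,
                          [t for t in increased if t not in present],
                          [t for t in decreased if t not in present])


# ---------------------------------------------------------------------------
# Biomarker cross-correlation
# ---------------------------------------------------------------------------


def biomarker_crosscorrelation(series: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Symmetric Pearson matrix across biomarker series (unit diagonal).

    Zero-variance series yield NaN off-diagonal entries.
    """
    names = list(series)
    df = pd.DataFrame({n: series[n] for n in names})
    if len(df) < MIN_PAIRS:
        raise AssociationError("need at least 3 samples for cross-correlation")
    mat = df.corr(method="pearson")
    arr = mat.to_numpy()
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=mat.index, columns=mat.columns)
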