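"""Inter-omic concordance statistics on paired gene/protein tables.

Given date-collapsed gene (CPM) and protein (relative abundance) tables
aligned over shared ORFs, this module computes per-feature Spearman
correlations between the two layers, rollups and correlations at
annotation-category level (GO / KO / eggNOG / taxon), and dynamic-range
(max/min) and standard-deviation fluctuation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnnotationTable, FeatureTable, PairedTables

MIN_PAIRS = 3  # minimum complete sample pairs for a correlation


class ConcordanceError(ValueError):
    pass


@dataclass
class CorrelationSummary:
    """Per-item correlation coefficients plus distribution summaries."""

    rho: pd.Series               # item -> Spearman rho
    n_omitted: int = 0           # items dropped (too few pairs / constant)

    @property
    def mean(self) -> float:
        return float(self.rho.mean())

    @property
    def sd(self) -> float:
        return float(self.rho.std(ddof=1))

    def histogram(self, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.rho.to_numpy(), bins=bins, range=(-1.0, 1.0))

    def write_tsv(self, path) -> None:
        out = self.rho.rename("rho").to_frame()
        out.index.name = "item"
        out.to_csv(path, sep="\t")


@dataclass
class FluctuationProfile:
    """Per-item max/min ratios and/or standard deviations."""

    ratio: pd.Series | None = None       # max/min over present values
    sd: pd.Series | None = None          # sample standard deviation
    zero_min_items: list[str] = field(default_factory=list)
    n_excluded: int = 0                  # all-zero or too-sparse items

    def write_tsv(self, path) -> None:
        parts = {}
        if self.ratio is not None:
            parts["max_min_ratio"] = self.ratio
        if self.sd is not None:
            parts["sd"] = self.sd
        out = pd.DataFrame(parts)
        out.index.name = "item"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def _spearman_rows(g: pd.DataFrame, p: pd.DataFrame
                   ) -> tuple[pd.Series, int]:
    """Per-row Spearman over complete (both-present) sample pairs."""
    rhos: dict[str, float] = {}
    omitted = 0
    gv, pv = g.to_numpy(float), p.to_numpy(float)
    for i, fid in enumerate(g.index):
        x, y = gv[i], pv[i]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < MIN_PAIRS:
            omitted += 1
            continue
        xs, ys = x[ok], y[ok]
        if np.all(xs == xs[0]) or np.all(ys == ys[0]):
            omitted += 1  # constant profile: rho undefined
            continue
        rho = stats.spearmanr(xs, ys).statistic
        rhos[fid] = float(rho)
    return pd.Series(rhos, dtype=float), omitted


def paired_feature_spearman(paired: PairedTables) -> CorrelationSummary:
    """Per-feature Spearman rho between gene and protein profiles.

    Uses average ranks for ties; features with fewer than three complete
    sample pairs (or a constant profile) are omitted and counted.
    """
    rho, omitted = _spearman_rows(paired.genes.values, paired.proteins.values)
    if rho.empty:
        raise ConcordanceError("no feature had enough complete sample pairs")
    return CorrelationSummary(rho, omitted)


def rollup_by_category(table: FeatureTable, ann: AnnotationTable,
                       level: str) -> tuple[FeatureTable, int]:
    """Sum feature abundances into annotation categories.

    Missing cells contribute zero; a feature with several GO terms
    contributes to each of them; unannotated features are dropped and
    counted (returned alongside the rolled-up table).
    """
    cat_map = ann.category_map(level)
    vals = table.values.fillna(0.0)
    acc: dict[str, np.ndarray] = {}
    n_unannotated = 0
    for fid in table.feature_ids:
        cats = cat_map.get(fid, ())
        if not cats:
            n_unannotated += 1
            continue
        row = vals.loc[fid].to_numpy()
        for c in cats:
            if c in acc:
                acc[c] += row
            else:
                acc[c] = row.copy()
    out = pd.DataFrame.from_dict(acc, orient="index",
                                 columns=table.sample_ids).sort_index()
    return FeatureTable(out, table.layer), n_unannotated


def category_concordance(paired: PairedTables, ann: AnnotationTable,
                         level: str, mode: str = "category_summed"):
    """Gene-protein concordance at annotation-category level.

    ``mode="category_summed"`` correlates category-rolled-up tables and
    returns one :class:`CorrelationSummary` over categories.
    ``mode="per_feature_grouped"`` returns a DataFrame of per-feature rho
    labelled with the feature's category (one row per feature-category
    pair), as used for eggNOG box plots.
    """
    if mode == "category_summed":
        g, _ = rollup_by_category(paired.genes, ann, level)
        p, _ = rollup_by_category(paired.proteins, ann, level)
        shared = [c for c in g.feature_ids if c in set(p.feature_ids)]
        rho, omitted = _spearman_rows(g.values.loc[shared],
                                      p.values.loc[shared])
        return CorrelationSummary(rho, omitted)
    if mode == "per_feature_grouped":
        per_feature = paired_feature_spearman(paired)
        cat_map = ann.category_map(level)
        rows = []
        for fid, rho in per_feature.rho.items():
            for cat in cat_map.get(fid, ()):
                rows.append({"feature_id": fid, "category": cat, "rho": rho})
        return pd.DataFrame(rows, columns=["feature_id", "category", "rho"])
    raise ConcordanceError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Fluctuation profiles
# ---------------------------------------------------------------------------


def dynamic_range(table: FeatureTable) -> FluctuationProfile:
    """Max/min ratio of each item's present values.

    Items whose minimum present value is zero use the smallest nonzero
    value instead and are flagged; all-zero items are undefined and
    excluded; constant items give ratio 1.
    """
    ratios: dict[str, float] = {}
    flagged: list[str] = []
    excluded = 0
    for fid in table.feature_ids:
        x = table.values.loc[fid].dropna().to_numpy(float)
        if len(x) < 2:
            excluded += 1
            continue
        mx = x.max()
        if mx <= 0:
            excluded += 1
            continue
        mn = x.min()
        if mn <= 0:
            mn = x[x > 0].min()
            flagged.append(fid)
        ratios[fid] = float(mx / mn)
    return FluctuationProfile(ratio=pd.Series(ratios, dtype=float),
                              zero_min_items=flagged, n_excluded=excluded)


def sd_profile(table: FeatureTable, log_transform: bool = False
               ) -> FluctuationProfile:
    """Per-item sample standard deviation (n-1), optionally on log10 values."""
    sds: dict[str, float] = {}
    excluded = 0
    for fid in table.feature_ids:
        x = table.values.loc[fid].dropna().to_numpy(float)
        if len(x) < 2:
            excluded += 1
            continue
        if log_transform:
            if (x <= 0).any():
                excluded += 1
                continue
            x = np.log10(x)
        sds[fid] = float(np.std(x, ddof=1))
    return FluctuationProfile(sd=pd.Series(sds, dtype=float),
                              n_excluded=excluded)


def top_fluctuating_categories(profile: FluctuationProfile,
                               k: int) -> list[tuple[str, float]]:
    """Top-k categories by max/min ratio; ties broken by label."""
    if profile.ratio is None:
        raise ConcordanceError("profile carries no max/min ratios")
    items = sorted(profile.ratio.items(), key=lambda kv: (-kv[1], kv[0]))
    return items[:k]
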