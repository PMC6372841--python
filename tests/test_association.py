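import numpy as np
import pandas as pd
import pytest

from concord.association import (AssociationError, association_overlap,
                                 biomarker_crosscorrelation,
                                 composition_log_ratio, dysbiosis_index,
                                 extract_biomarkers, gram_stain_summary,
                                 regress_features_vs_biomarker, select_strong)
from concord.data_model import AnnotationTable, FeatureTable


def table(rows, index=None, columns=None, layer="protein"):
    return FeatureTable(pd.DataFrame(rows, index=index, columns=columns,
                                     dtype=float), layer)


def genus_annotation(mapping):
    lineage = {"domain": "Bacteria", "phylum": "Firmicutes",
               "class": "Clostridia", "order": "Eubacteriales",
               "family": "Lachnospiraceae"}
    rows = {f: dict(lineage, genus=g) for f, g in mapping.items()}
    return AnnotationTable(pd.DataFrame.from_dict(rows, orient="index"))


class TestExtractBiomarkers:
    def test_single_protein_biomarker(self):
        t = table([[1.0, 2.0]], index=["HUMAN_CRP"])
        out = extract_biomarkers(t, {"CRP": ["HUMAN_CRP"]})
        assert out["CRP"].tolist() == [1.0, 2.0]

    def test_two_subunits_summed(self):
        t = table([[1.0, 2.0], [3.0, 4.0]],
                  index=["HUMAN_S100A8", "HUMAN_S100A9"])
        out = extract_biomarkers(
            t, {"calprotectin": ["HUMAN_S100A8", "HUMAN_S100A9"]})
        assert out["calprotectin"].tolist() == [4.0, 6.0]

    def test_unmapped_biomarker_warns_and_omits(self):
        t = table([[1.0]], index=["HUMAN_CRP"])
        with pytest.warns(UserWarning, match="lysozyme"):
            out = extract_biomarkers(t, {"CRP": ["HUMAN_CRP"],
                                         "lysozyme": ["HUMAN_LYZ"]})
        assert set(out) == {"CRP"}


class TestRegression:
    b = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                  index=[f"s{i}" for i in range(5)])

    def test_proportional_feature(self):
        t = table([self.b.to_numpy() * 3], columns=self.b.index)
        res, _ = regress_features_vs_biomarker(t, self.b, "x")
        assert res.iloc[0]["r"] == pytest.approx(1.0)
        assert res.iloc[0]["slope"] == pytest.approx(3.0)
        assert res.iloc[0]["assoc_class"] == "positive"

    def test_anti_proportional_feature(self):
        t = table([6.0 - self.b.to_numpy()], columns=self.b.index)
        res, _ = regress_features_vs_biomarker(t, self.b, "x")
        assert res.iloc[0]["r"] == pytest.approx(-1.0)
        assert res.iloc[0]["assoc_class"] == "negative"

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 5, (100, 5))
        t = table(X, columns=self.b.index)
        res, _ = regress_features_vs_biomarker(t, self.b, "x")
        b = self.b.to_numpy()
        bc = b - b.mean()
        for i in range(100):
            y = X[i]
            slope = (bc * (y - y.mean())).sum() / (bc ** 2).sum()
            intercept = y.mean() - slope * b.mean()
            r = (bc * (y - y.mean())).sum() / np.sqrt(
                (bc ** 2).sum() * ((y - y.mean()) ** 2).sum())
            assert res.iloc[i]["slope"] == pytest.approx(slope, abs=1e-10)
            assert res.iloc[i]["intercept"] == pytest.approx(intercept,
                                                             abs=1e-10)
            assert res.iloc[i]["r"] == pytest.approx(r, abs=1e-10)

    def test_too_few_pairs_skipped(self):
        t = table([[1.0, np.nan, np.nan, np.nan, 5.0]],
                  columns=self.b.index)
        res, skipped = regress_features_vs_biomarker(t, self.b, "x")
        assert len(res) == 0 and skipped == 1

    def test_zero_variance_biomarker_errors(self):
        flat = pd.Series([2.0] * 5, index=self.b.index)
        with pytest.raises(AssociationError, match="variance"):
            regress_features_vs_biomarker(table([[1, 2, 3, 4, 5]],
                                                columns=self.b.index),
                                          flat, "flat")


class TestSelectStrong:
    def _results(self, rs):
        return pd.DataFrame({"feature_id": [f"f{i}" for i in range(len(rs))],
                             "biomarker": "x", "r": rs})

    def test_threshold_rule(self):
        pos, neg = select_strong(self._results([0.75, -0.8, 0.0, 0.7]), 0.7)
        assert pos == ["f0"]    # 0.7 itself is not > 0.7
        assert neg == ["f1"]

    def test_sets_shrink_as_tau_increases(self):
        rng = np.random.default_rng(3)
        res = self._results(rng.uniform(-1, 1, 200))
        sizes = []
        for tau in (0.3, 0.5, 0.7, 0.9):
            pos, neg = select_strong(res, tau)
            sizes.append(len(pos) + len(neg))
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_tau(self):
        with pytest.raises(AssociationError):
            select_strong(self._results([0.5]), 1.5)


class TestCompositionLogRatio:
    def test_identical_compositions_are_zero(self):
        ann = genus_annotation({f"f{i}": ("A" if i % 2 else "B")
                                for i in range(8)})
        pos = [f"f{i}" for i in range(4)]
        neg = [f"f{i}" for i in range(4, 8)]
        ratios, _ = composition_log_ratio(pos, neg, ann, "genus")
        for r in ratios:
            assert r.log_ratio == pytest.approx(0.0, abs=1e-12)

    def test_forty_vs_five_percent_near_three(self):
        mapping = {}
        for i in range(100):          # positives: 40 of genus G
            mapping[f"p{i}"] = "G" if i < 40 else "other"
        for i in range(100):          # negatives: 5 of genus G
            mapping[f"n{i}"] = "G" if i < 5 else "other"
        ann = genus_annotation(mapping)
        ratios, info = composition_log_ratio(
            [f"p{i}" for i in range(100)], [f"n{i}" for i in range(100)],
            ann, "genus")
        byg = {r.category: r for r in ratios}
        assert byg["G"].log_ratio == pytest.approx(
            np.log2((0.40 + info["eps"]) / (0.05 + info["eps"])))
        assert abs(byg["G"].log_ratio - 3.0) < 0.2
        assert byg["G"].n_pos == 40 and byg["G"].n_neg == 5

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(9)
        mapping = {f"f{i}": rng.choice(["A", "B", "C"]) for i in range(60)}
        ann = genus_annotation(mapping)
        pos = [f"f{i}" for i in range(30)]
        neg = [f"f{i}" for i in range(30, 60)]
        fwd, _ = composition_log_ratio(pos, neg, ann, "genus")
        rev, _ = composition_log_ratio(neg, pos, ann, "genus")
        rev_by = {r.category: r.log_ratio for r in rev}
        for r in fwd:
            assert r.log_ratio == pytest.approx(-rev_by[r.category],
                                                abs=1e-12)

    def test_fractions_sum_to_one(self):
        ann = genus_annotation({"a": "A", "b": "B", "c": "A", "d": "B"})
        ratios, _ = composition_log_ratio(["a", "b"], ["c", "d"], ann,
                                          "genus")
        assert sum(r.f_pos for r in ratios) == pytest.approx(1.0)
        assert sum(r.f_neg for r in ratios) == pytest.approx(1.0)

    def test_empty_set_errors(self):
        ann = genus_annotation({"a": "A"})
        with pytest.raises(AssociationError):
            composition_log_ratio([], ["a"], ann, "genus")


class TestGramSummary:
    def test_planted_fourfold_enrichment(self):
        rows = {}
        for i in range(100):
            rows[f"p{i}"] = {"gram": "negative" if i < 80 else "positive"}
        for i in range(100):
            rows[f"n{i}"] = {"gram": "negative" if i < 20 else "positive"}
        ann = AnnotationTable(pd.DataFrame.from_dict(rows, orient="index"))
        ratios, _ = gram_stain_summary([f"p{i}" for i in range(100)],
                                       [f"n{i}" for i in range(100)], ann)
        neg = {r.category: r for r in ratios}["negative"]
        assert neg.log_ratio == pytest.approx(2.0, abs=0.05)

    def test_missing_labels_grouped_as_unknown(self):
        ann = AnnotationTable(pd.DataFrame.from_dict(
            {"a": {"gram": "positive"}, "b": {"gram": ""}}, orient="index"))
        ratios, _ = gram_stain_summary(["a", "b"], ["a", "b"], ann)
        assert {"positive", "unknown"} == {r.category for r in ratios}


class TestOverlap:
    def _results(self, triples):
        return pd.DataFrame([{"feature_id": f, "biomarker": b, "r": r}
                             for f, b, r in triples])

    def test_identical_sets_share_everything(self):
        res = self._results([("f1", "cal", 0.9), ("f2", "cal", -0.8)])
        out = association_overlap(res, res.copy(), 0.7)
        assert out["shared_fraction_all"] == 1.0
        assert out["n_shared"] == 2

    def test_disjoint_sets_share_nothing(self):
        g = self._results([("f1", "cal", 0.9)])
        p = self._results([("f2", "cal", 0.9)])
        assert association_overlap(g, p, 0.7)["shared_fraction_all"] == 0.0

    def test_opposite_signs_do_not_match(self):
        g = self._results([("f1", "cal", 0.9)])
        p = self._results([("f1", "cal", -0.9)])
        assert association_overlap(g, p, 0.7)["n_shared"] == 0

    def test_planted_overlap_counts_exact(self):
        shared = [(f"s{i}", "cal", 0.9) for i in range(10)]
        gene_only = [(f"g{i}", "cal", 0.9) for i in range(60)]
        prot_only = [(f"p{i}", "cal", -0.9) for i in range(30)]
        g = self._results(shared + gene_only)
        p = self._results(shared + prot_only)
        out = association_overlap(g, p, 0.7,
                                  shared_features=[t[0] for t in shared])
        assert out["n_shared"] == 10
        assert out["per_biomarker"]["cal"] == {"gene_only": 60,
                                               "protein_only": 30,
                                               "shared": 10}
        assert out["shared_fraction_all"] == 10 / 100
        assert out["shared_fraction_shared_namespace"] == 1.0


class TestDysbiosisIndex:
    cols = ["s1", "s2"]

    def _table(self, up, down, extra=1.0):
        return table([[up, up], [down, down], [extra, extra]],
                     index=["Escherichia coli", "Faecalibacterium prausnitzii",
                            "Bacteroides vulgatus"],
                     columns=self.cols, layer="gene")

    def test_equal_sums_give_zero(self):
        t = self._table(4.0, 3.0)
        out = dysbiosis_index(t, ["Escherichia coli"],
                              ["Faecalibacterium prausnitzii",
                               "Bacteroides vulgatus"])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_eight_vs_two_near_two(self):
        # the tiny third row keeps the pseudocount small
        t = table([[8.0], [2.0], [0.01]],
                  index=["Escherichia coli", "Faecalibacterium prausnitzii",
                         "Bacteroides vulgatus"],
                  columns=["s1"], layer="gene")
        out = dysbiosis_index(t, ["Escherichia coli"],
                              ["Faecalibacterium prausnitzii"])
        assert out.values.iloc[0] == pytest.approx(
            np.log2(8.005 / 2.005), abs=1e-12)
        assert out.values.iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_monotone_in_increased_taxa(self):
        t = self._table(4.0, 3.0)
        doubled = FeatureTable(t.values.copy(), "gene")
        doubled.values.loc["Escherichia coli"] *= 2
        a = dysbiosis_index(t, ["Escherichia coli"],
                            ["Faecalibacterium prausnitzii"]).values
        b = dysbiosis_index(doubled, ["Escherichia coli"],
                            ["Faecalibacterium prausnitzii"]).values
        assert (b > a).all()

    def test_antisymmetric_under_list_swap(self):
        t = self._table(5.0, 2.0)
        inc, dec = ["Escherichia coli"], ["Faecalibacterium prausnitzii"]
        fwd = dysbiosis_index(t, inc, dec).values
        rev = dysbiosis_index(t, dec, inc).values
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_absent_list_errors_with_names(self):
        t = self._table(1.0, 1.0)
        with pytest.raises(AssociationError, match="Fusobacterium"):
            dysbiosis_index(t, ["Fusobacterium nucleatum"],
                            ["Faecalibacterium prausnitzii"])

    def test_missing_list_members_logged(self):
        t = self._table(1.0, 1.0)
        out = dysbiosis_index(t)
        assert out.increased_missing == ["Fusobacterium nucleatum"]
        assert out.decreased_missing == ["Eubacterium rectale"]


class TestCrossCorrelation:
    def test_self_and_negation(self):
        s = pd.Series([1.0, 3.0, 2.0, 5.0])
        out = biomarker_crosscorrelation({"a": s, "b": -s + 10, "c": s * 2})
        assert out.loc["a", "a"] == 1.0
        assert out.loc["a", "b"] == pytest.approx(-1.0)
        assert out.loc["a", "c"] == pytest.approx(1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(23)
        x = pd.Series(rng.normal(size=10))
        y = pd.Series(rng.normal(size=10))
        out = biomarker_crosscorrelation({"x": x, "y": y})
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert out.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(24)
        series = {k: pd.Series(rng.normal(size=8)) for k in "abc"}
        out = biomarker_crosscorrelation(series)
        np.testing.assert_allclose(out.to_numpy(), out.to_numpy().T)
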