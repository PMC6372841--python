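"""End-to-end orchestration with a config file and deterministic outputs.

Stage order follows the study workflow: TMT quantification (optional,
when PSM-level inputs are given) -> normalization/collapsing ->
gene-protein concordance -> biomarker association (incl. the dysbiosis
index) -> ordination statistics.  Every artifact is written under the
run directory and listed in a checksum manifest; identical config + seed
yields an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import concordance as conc
from . import ordination as ordn
from . import tmt
from .data_model import (AnnotationTable, FeatureTable, SampleMetadata,
                         collapse_replicates, cpm_normalize,
                         filter_complete_features, read_biomarkers_tsv,
                         subset_shared_features, write_biomarkers_tsv)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


DEFAULTS = {
    "tau": 0.7,
    "log_base": 2.0,
    "n_perm": 999,
    "seed": 0,
    "collapse_gene": "sum",
    "collapse_protein": "mean",
    "sd_log_transform": False,
}


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute all stages; return the output-checksum manifest.

    ``config`` keys: ``out_dir`` (required); inputs ``gene_counts``,
    ``protein_table`` or (``psms`` + ``plex_design`` +
    ``protein_lengths``), ``annotations``, ``metadata``, optional
    ``biomarkers`` (TSV of series, else extracted from the protein
    table); parameters as in :data:`DEFAULTS` plus optional
    ``dysbiosis_increased`` / ``dysbiosis_decreased`` taxon-list files.
    """
    cfg = {**DEFAULTS, **config}
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logged_cfg = {k: v for k, v in cfg.items() if k != "out_dir"}
    log_lines: list[str] = [
        f"config: {json.dumps(logged_cfg, sort_keys=True, default=str)}"]
    stage = "setup"

    def fail(exc: Exception):
        (out / f"FAILED_{stage}").write_text(str(exc))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    try:
        meta = SampleMetadata.read_tsv(cfg["metadata"])
        ann = AnnotationTable.read_tsv(cfg["annotations"])
    except Exception as exc:       # noqa: BLE001 - abort names the stage
        fail(exc)

    # ---- tmt_quant ------------------------------------------------------
    stage = "tmt_quant"
    try:
        if "psms" in cfg:
            psms = tmt.read_psms_tsv(cfg["psms"])
            designs = tmt.read_plex_designs_tsv(cfg["plex_design"])
            lengths = tmt.read_protein_lengths_tsv(cfg["protein_lengths"])
            protein_raw, rej_log, zero_log = tmt.quantify(psms, designs,
                                                          lengths)
            protein_raw.write_tsv(out / "protein_table.tsv")
            pd.DataFrame([{"rule": k, "n_rejected": v}
                          for k, v in rej_log.items()]
                         ).to_csv(out / "psm_rejections.tsv", sep="\t",
                                  index=False)
            log_lines.append(
                f"tmt_quant: {len(psms)} PSMs -> "
                f"{len(protein_raw.feature_ids)} proteins; "
                f"rejections {rej_log}")
        else:
            protein_raw = FeatureTable.read_tsv(cfg["protein_table"],
                                                "protein")
            log_lines.append(
                f"tmt_quant: skipped (protein table supplied, "
                f"{len(protein_raw.feature_ids)} proteins)")
    except PipelineError:
        raise
    except Exception as exc:
        fail(exc)

    # ---- normalize ------------------------------------------------------
    stage = "normalize"
    try:
        gene_counts = pd.read_csv(cfg["gene_counts"], sep="\t", index_col=0,
                                  na_values=["NA"], keep_default_na=False)
        gene_cpm = cpm_normalize(gene_counts)
        genes = collapse_replicates(gene_cpm, meta, cfg["collapse_gene"])
        proteins = collapse_replicates(protein_raw, meta,
                                       cfg["collapse_protein"])
        genes.write_tsv(out / "genes_by_date.tsv")
        proteins.write_tsv(out / "proteins_by_date.tsv")
        log_lines.append(
            f"normalize: genes {len(genes.feature_ids)} x "
            f"{len(genes.sample_ids)}, proteins "
            f"{len(proteins.feature_ids)} x {len(proteins.sample_ids)}")
    except PipelineError:
        raise
    except Exception as exc:
        fail(exc)

    # ---- concordance ----------------------------------------------------
    stage = "concordance"
    try:
        paired = subset_shared_features(genes, proteins)
        spearman = conc.paired_feature_spearman(paired)
        spearman.write_tsv(out / "per_feature_spearman.tsv")
        go = conc.category_concordance(paired, ann, "GO", "category_summed")
        go.write_tsv(out / "go_summed_spearman.tsv")
        dr_gene = conc.dynamic_range(genes)
        dr_prot = conc.dynamic_range(proteins)
        sd_gene = conc.sd_profile(genes, cfg["sd_log_transform"])
        sd_prot = conc.sd_profile(proteins, cfg["sd_log_transform"])
        dr_gene.write_tsv(out / "gene_dynamic_range.tsv")
        dr_prot.write_tsv(out / "protein_dynamic_range.tsv")
        sd_gene.write_tsv(out / "gene_sd.tsv")
        sd_prot.write_tsv(out / "protein_sd.tsv")
        summary = {
            "n_shared_features": paired.n_features,
            "n_correlated_features": int(len(spearman.rho)),
            "n_omitted_features": spearman.n_omitted,
            "mean_spearman": spearman.mean,
            "sd_spearman": spearman.sd,
            "go_mean_spearman": go.mean,
            "go_sd_spearman": go.sd,
            "gene_max_min_median": float(dr_gene.ratio.median()),
            "protein_max_min_median": float(dr_prot.ratio.median()),
        }
        _write_json(summary, out / "concordance_summary.json")
        log_lines.append(f"concordance: {summary['n_correlated_features']} "
                         f"features, mean rho {summary['mean_spearman']:.4f}")
    except PipelineError:
        raise
    except Exception as exc:
        fail(exc)

    # ---- association ----------------------------------------------------
    stage = "association"
    try:
        if "biomarkers" in cfg:
            biomarkers = read_biomarkers_tsv(cfg["biomarkers"])
        else:
            biomarkers = assoc.extract_biomarkers(proteins)
        write_biomarkers_tsv(biomarkers, out / "biomarkers.tsv")
        cross = assoc.biomarker_crosscorrelation(biomarkers)
        cross.to_csv(out / "biomarker_crosscorrelation.tsv", sep="\t")
        tau = cfg["tau"]
        gene_res = assoc.associate_all(genes, biomarkers, tau)
        prot_res = assoc.associate_all(proteins, biomarkers, tau)
        gene_res.to_csv(out / "gene_associations.tsv", sep="\t", index=False)
        prot_res.to_csv(out / "protein_associations.tsv", sep="\t",
                        index=False)
        ratios_out = []
        for bm in biomarkers:
            sub = prot_res[prot_res["biomarker"] == bm]
            pos, neg = assoc.select_strong(sub, tau)
            if pos and neg:
                for level in ("genus", "phylum", "eggNOG", "gram"):
                    ratios, _ = assoc.composition_log_ratio(
                        pos, neg, ann, level, cfg["log_base"])
                    df = assoc.log_ratios_to_frame(ratios)
                    df.insert(0, "level", level)
                    df.insert(0, "biomarker", bm)
                    ratios_out.append(df)
        if ratios_out:
            pd.concat(ratios_out, ignore_index=True).to_csv(
                out / "composition_log_ratios.tsv", sep="\t", index=False)
        overlap = assoc.association_overlap(gene_res, prot_res, tau,
                                            paired.feature_ids)
        _write_json(overlap, out / "association_overlap.json")
        # dysbiosis index on species-level rollups of each layer
        increased = _read_taxa(cfg.get("dysbiosis_increased"),
                               assoc.CD_INCREASED_SPECIES)
        decreased = _read_taxa(cfg.get("dysbiosis_decreased"),
                               assoc.CD_DECREASED_SPECIES)
        for layer, table in (("gene", genes), ("protein", proteins)):
            species, _ = conc.rollup_by_category(table, ann, "species")
            try:
                idx = assoc.dysbiosis_index(species, increased, decreased,
                                            cfg["log_base"])
            except assoc.AssociationError as exc:
                log_lines.append(f"association: dysbiosis ({layer}) "
                                 f"skipped: {exc}")
                continue
            idx.write_tsv(out / f"dysbiosis_{layer}.tsv")
        log_lines.append(
            f"association: {len(gene_res)} gene + {len(prot_res)} protein "
            f"regressions, {overlap['n_shared']} shared strong")
    except PipelineError:
        raise
    except Exception as exc:
        fail(exc)

    # ---- ordination -----------------------------------------------------
    stage = "ordination"
    try:
        seed = int(cfg["seed"])
        n_perm = int(cfg["n_perm"])
        g_complete = filter_complete_features(genes)
        p_complete = filter_complete_features(proteins)
        dg = ordn.bray_curtis(g_complete)
        dp = ordn.bray_curtis(p_complete)
        dg.write_tsv(out / "gene_bray_curtis.tsv")
        dp.write_tsv(out / "protein_bray_curtis.tsv")
        og = ordn.pcoa(dg)
        op = ordn.pcoa(dp)
        og.write_tsv(out / "gene_pcoa.tsv")
        op.write_tsv(out / "protein_pcoa.tsv")
        k = min(og.coordinates.shape[1], op.coordinates.shape[1])
        m2, _ = ordn.procrustes(og.coordinates[:, :k], op.coordinates[:, :k])
        mantel_res = ordn.mantel(dg, dp, n_perm, seed)
        groups = {d: s for d, s in
                  SampleMetadata.read_tsv(cfg["metadata"])
                  .inflammation_by_date().items()}
        grouping = {s: groups.get(s, "unknown") for s in dg.ids}
        perma = {}
        for layer, dm in (("gene", dg), ("protein", dp)):
            try:
                perma[layer] = ordn.permanova(dm, grouping, n_perm,
                                              seed).to_dict()
            except ordn.OrdinationError as exc:
                perma[layer] = {"error": str(exc)}
        friedman_res = {}
        for layer, table in (("gene", genes), ("protein", proteins)):
            genus, _ = conc.rollup_by_category(table, ann, "genus")
            comp = genus.values.fillna(0.0)
            comp = comp / comp.sum(axis=0)
            friedman_res[layer] = ordn.friedman(comp.T.to_numpy()).to_dict()
        _write_json({
            "procrustes_m2": m2,
            "mantel": mantel_res.to_dict(),
            "permanova": perma,
            "friedman_genus": friedman_res,
        }, out / "ordination_stats.json")
        log_lines.append(f"ordination: procrustes M2 {m2:.4f}, "
                         f"mantel r {mantel_res.statistic:.4f} "
                         f"p {mantel_res.p_value:.4f}")
    except PipelineError:
        raise
    except Exception as exc:
        fail(exc)

    # ---- manifest -------------------------------------------------------
    stage = "manifest"
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.name not in ("manifest.json",) and p.is_file()}
    _write_json(manifest, out / "manifest.json")
    return manifest


def _read_taxa(path, default):
    if path is None:
        return list(default)
    taxa = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                taxa.append(line)
    return taxa
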