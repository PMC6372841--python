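"""PSM-level TMT quantification -> normalized protein abundance table.

Isobaric (tandem mass tag) experiments quantify each peptide-spectrum
match (PSM) through per-channel reporter-ion signal-to-noise (S/N).  Two
channels per plex (by default the 126 and 131 reagents) carry a pooled
composite "bridge" sample that is identical across plexes; dividing every
protein's channel signal by its bridge signal cancels run-to-run scale
differences so plexes can be stitched into one study-wide table.

Stages implemented here, in pipeline order:

1. :func:`filter_psms` — confidence / ambiguity / isolation-interference /
   mean-S/N filters with a per-rule rejection log.
2. :func:`resolve_shared_peptides` — deterministic greedy assignment of
   shared peptides (prefer proteins with prior evidence, else the longest
   candidate) plus exact-duplicate PSM removal.
3. :func:`rollup_psms_to_proteins` — per-protein sums of channel S/N.
4. :func:`bridge_normalize` — two-bridge ratio normalization, per-bridge
   median rescaling, plex stitching and a final global-median scaling.
5. :func:`lca_adjust_taxonomy` — lowest-common-ancestor reassignment of
   peptide (and then protein) taxonomy for peptides shared across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import RANKS, AnnotationTable, FeatureTable, NA_TOKEN

#: Default TMT 10-plex channel labels.
TMT10_CHANNELS = ("126", "127N", "127C", "128N", "128C",
                  "129N", "129C", "130N", "130C", "131")

#: Default bridge (pooled standard) channel labels.
DEFAULT_BRIDGES = ("126", "131")

#: PSM filter thresholds (isolation interference %, mean channel S/N).
MAX_INTERFERENCE_PCT = 25.0
MIN_MEAN_SN = 10.0

#: Order in which filter rules are checked; a rejected PSM is charged to
#: the first failing rule only.
FILTER_RULES = ("confidence", "ambiguity", "interference", "low_sn")


class TMTError(ValueError):
    pass


@dataclass
class PSMRecord:
    """One quantified peptide-spectrum match."""

    peptide: str
    candidate_proteins: tuple[str, ...]
    confidence: str                      # high / moderate / ambiguous
    interference_pct: float
    channel_sn: dict[str, float]         # channel label -> S/N
    plex_id: str
    charge: int = 2
    assigned_protein: str | None = None

    def __post_init__(self) -> None:
        if not self.candidate_proteins:
            raise TMTError(f"PSM {self.peptide!r} has no candidate proteins")
        if not 0.0 <= self.interference_pct <= 100.0:
            raise TMTError(
                f"PSM {self.peptide!r}: interference {self.interference_pct} "
                "outside [0, 100]")
        if any(v < 0 for v in self.channel_sn.values()):
            raise TMTError(f"PSM {self.peptide!r}: negative channel S/N")

    @property
    def mean_sn(self) -> float:
        return float(np.mean(list(self.channel_sn.values())))


@dataclass
class PlexDesign:
    """Channel layout of one plex: two bridges, the rest sample channels."""

    plex_id: str
    channels: tuple[str, ...] = TMT10_CHANNELS
    bridges: tuple[str, str] = DEFAULT_BRIDGES
    sample_of_channel: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bridges) != 2:
            raise TMTError(f"plex {self.plex_id}: exactly 2 bridge channels "
                           f"required, got {len(self.bridges)}")
        for b in self.bridges:
            if b not in self.channels:
                raise TMTError(f"plex {self.plex_id}: bridge {b!r} not a channel")
        for c in self.sample_channels:
            if c not in self.sample_of_channel:
                raise TMTError(
                    f"plex {self.plex_id}: sample channel {c!r} unassigned")

    @property
    def sample_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c not in self.bridges)


# ---------------------------------------------------------------------------
# 1. PSM filtering
# ---------------------------------------------------------------------------


def filter_psms(psms: Sequence[PSMRecord]
                ) -> tuple[list[PSMRecord], dict[str, int]]:
    """Apply the quantification filters; return kept PSMs + rejection log.

    Rules, in order (a PSM is charged to the first that fails):
    moderate confidence, ambiguous assignment, isolation interference
    above 25%, mean channel S/N below 10.  Proteins left with a single
    surviving high-confidence PSM remain quantifiable downstream.
    """
    kept: list[PSMRecord] = []
    log = {rule: 0 for rule in FILTER_RULES}
    for psm in psms:
        if psm.confidence == "moderate":
            log["confidence"] += 1
        elif psm.confidence == "ambiguous":
            log["ambiguity"] += 1
        elif psm.interference_pct > MAX_INTERFERENCE_PCT:
            log["interference"] += 1
        elif psm.mean_sn < MIN_MEAN_SN:
            log["low_sn"] += 1
        elif psm.confidence != "high":
            raise TMTError(f"unknown confidence {psm.confidence!r}")
        else:
            kept.append(psm)
    return kept, log


# ---------------------------------------------------------------------------
# 2. Shared-peptide resolution
# ---------------------------------------------------------------------------


def resolve_shared_peptides(psms: Sequence[PSMRecord],
                            protein_lengths: Mapping[str, int]
                            ) -> list[PSMRecord]:
    """Assign every PSM to one protein; drop exact-duplicate records.

    Deterministic greedy pass in input order: a shared peptide goes to a
    candidate that already holds an assigned peptide (lexicographically
    smallest if several), otherwise to the longest candidate (ties broken
    lexicographically by protein id).  Exact duplicates — same (peptide
    sequence, plex, charge) — collapse to the first occurrence.
    """
    for psm in psms:
        for prot in psm.candidate_proteins:
            if prot not in protein_lengths:
                raise TMTError(f"no length known for candidate {prot!r}")

    seen: set[tuple[str, str, int]] = set()
    deduped: list[PSMRecord] = []
    for psm in psms:
        key = (psm.peptide, psm.plex_id, psm.charge)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(psm)

    # proteins with unique-peptide evidence seed the "prior" set
    has_prior: set[str] = {p.candidate_proteins[0] for p in deduped
                           if len(p.candidate_proteins) == 1}
    out: list[PSMRecord] = []
    for psm in deduped:
        cands = psm.candidate_proteins
        if len(cands) == 1:
            chosen = cands[0]
        else:
            withprior = sorted(c for c in cands if c in has_prior)
            if withprior:
                chosen = withprior[0]
            else:
                chosen = sorted(cands,
                                key=lambda c: (-protein_lengths[c], c))[0]
        has_prior.add(chosen)
        rec = PSMRecord(psm.peptide, psm.candidate_proteins, psm.confidence,
                        psm.interference_pct, dict(psm.channel_sn),
                        psm.plex_id, psm.charge, assigned_protein=chosen)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# 3. Rollup
# ---------------------------------------------------------------------------


def rollup_psms_to_proteins(psms: Sequence[PSMRecord],
                            plex: PlexDesign) -> pd.DataFrame:
    """Sum channel S/N over each protein's PSMs in one plex."""
    rows: dict[str, np.ndarray] = {}
    for psm in psms:
        if psm.plex_id != plex.plex_id:
            continue
        if psm.assigned_protein is None:
            raise TMTError(f"PSM {psm.peptide!r} not assigned to a protein")
        vec = np.array([psm.channel_sn[c] for c in plex.channels], float)
        if psm.assigned_protein in rows:
            rows[psm.assigned_protein] += vec
        else:
            rows[psm.assigned_protein] = vec.copy()
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(plex.channels))
    return df.sort_index()


# ---------------------------------------------------------------------------
# 4. Bridge normalization
# ---------------------------------------------------------------------------


def bridge_normalize(plex_matrices: Mapping[str, pd.DataFrame],
                     designs: Mapping[str, PlexDesign]
                     ) -> tuple[FeatureTable, dict[str, list[str]]]:
    """Normalize per-plex protein x channel matrices into one protein table.

    Per protein and plex, each sample channel's S/N is divided by each
    bridge channel's S/N; each bridge's ratio matrix is rescaled by its
    plex-wide median; the channel value is the mean of the two rescaled
    ratios.  Plexes are then stitched (a protein absent from a plex is
    missing for that plex's samples) and the full table is divided by its
    global median, so the final table has global median 1.

    Returns the protein :class:`FeatureTable` and a log of proteins
    flagged missing per plex because a bridge channel read zero.
    """
    per_plex: dict[str, pd.DataFrame] = {}
    zero_bridge_log: dict[str, list[str]] = {}
    for plex_id, mat in plex_matrices.items():
        design = designs[plex_id]
        b1, b2 = design.bridges
        bad = mat.index[(mat[b1] <= 0) | (mat[b2] <= 0)]
        zero_bridge_log[plex_id] = list(bad)
        mat = mat.drop(index=bad)
        samp_cols = list(design.sample_channels)
        if mat.empty:
            per_plex[plex_id] = pd.DataFrame(
                columns=[design.sample_of_channel[c] for c in samp_cols])
            continue
        combined = np.zeros((len(mat), len(samp_cols)))
        for b in (b1, b2):
            ratios = mat[samp_cols].div(mat[b], axis=0)
            med = float(np.nanmedian(ratios.to_numpy()))
            combined += ratios.to_numpy() / med
        combined /= 2.0
        out = pd.DataFrame(combined, index=mat.index,
                           columns=[design.sample_of_channel[c]
                                    for c in samp_cols])
        per_plex[plex_id] = out

    stitched = pd.concat(per_plex.values(), axis=1)
    vals = stitched.to_numpy(float)
    present = vals[~np.isnan(vals)]
    if present.size == 0:
        raise TMTError("no quantified proteins after bridge normalization")
    stitched = stitched / float(np.median(present))
    stitched = stitched.sort_index()
    return FeatureTable(stitched, "protein"), zero_bridge_log


def quantify(psms: Sequence[PSMRecord],
             designs: Mapping[str, PlexDesign],
             protein_lengths: Mapping[str, int]
             ) -> tuple[FeatureTable, dict[str, int], dict[str, list[str]]]:
    """Full PSM -> protein table pipeline (filter, resolve, rollup, bridge)."""
    kept, log = filter_psms(psms)
    resolved = resolve_shared_peptides(kept, protein_lengths)
    matrices = {pid: rollup_psms_to_proteins(resolved, d)
                for pid, d in designs.items()}
    table, zero_log = bridge_normalize(matrices, designs)
    return table, log, zero_log


# ---------------------------------------------------------------------------
# 5. LCA taxonomy adjustment
# ---------------------------------------------------------------------------


def _lineage_lca(lineages: Sequence[tuple[str, ...]]) -> tuple[str, ...]:
    """Deepest common prefix of lineages (root -> species order)."""
    if not lineages:
        return ()
    out: list[str] = []
    for level in zip(*lineages):
        if all(v == level[0] and v != "" for v in level):
            out.append(level[0])
        else:
            break
    return tuple(out)


def lca_adjust_taxonomy(psms: Sequence[PSMRecord],
                        annotations: AnnotationTable) -> AnnotationTable:
    """Reassign taxonomy by lowest common ancestor of shared peptides.

    Each peptide's taxon is the deepest rank shared by all of its
    candidate proteins; each protein's lineage becomes the LCA over the
    labels of its assigned peptides.  Proteins whose candidates carry no
    annotation end up with an empty ("unknown") lineage.
    """
    ann_lineages: dict[str, tuple[str, ...]] = {
        f: annotations.lineage(f) for f in annotations.feature_ids}

    peptide_taxon: dict[str, tuple[str, ...]] = {}
    protein_peptides: dict[str, set[str]] = {}
    for psm in psms:
        prot = psm.assigned_protein or psm.candidate_proteins[0]
        protein_peptides.setdefault(prot, set()).add(psm.peptide)
        if psm.peptide not in peptide_taxon:
            lins = [ann_lineages.get(c, ()) for c in psm.candidate_proteins]
            lins = [l for l in lins if l]
            peptide_taxon[psm.peptide] = _lineage_lca(lins)

    rows = {}
    for prot, peptides in protein_peptides.items():
        labels = [peptide_taxon[p] for p in sorted(peptides)]
        labels = [l for l in labels if l]
        lca = _lineage_lca(labels)
        row = {r: "" for r in RANKS}
        for rank, value in zip(RANKS, lca):
            row[rank] = value
        if prot in annotations.feature_ids:
            old = annotations.table.loc[prot]
            row.update(go_terms=old["go_terms"], ko=old["ko"],
                       eggnog=old["eggnog"], gram=old["gram"])
        rows[prot] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return AnnotationTable(table)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def write_psms_tsv(psms: Sequence[PSMRecord], channels: Sequence[str],
                   path) -> None:
    rows = []
    for p in psms:
        row = {"peptide": p.peptide,
               "proteins": ";".join(p.candidate_proteins),
               "confidence": p.confidence,
               "interference_pct": p.interference_pct,
               "plex": p.plex_id,
               "charge": p.charge}
        for c in channels:
            row[f"sn_{c}"] = p.channel_sn.get(c, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_psms_tsv(path) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN],
                     keep_default_na=False)
    sn_cols = [c for c in df.columns if c.startswith("sn_")]
    out = []
    for _, row in df.iterrows():
        channel_sn = {c[3:]: float(row[c]) for c in sn_cols
                      if pd.notna(row[c])}
        out.append(PSMRecord(
            peptide=str(row["peptide"]),
            candidate_proteins=tuple(str(row["proteins"]).split(";")),
            confidence=str(row["confidence"]),
            interference_pct=float(row["interference_pct"]),
            channel_sn=channel_sn,
            plex_id=str(row["plex"]),
            charge=int(row.get("charge", 2))))
    return out


def write_plex_designs_tsv(designs: Mapping[str, PlexDesign], path) -> None:
    rows = []
    for pid in sorted(designs):
        d = designs[pid]
        for c in d.channels:
            role = "bridge" if c in d.bridges else "sample"
            rows.append({"plex": pid, "channel": c, "role": role,
                         "sample": d.sample_of_channel.get(c, "")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_plex_designs_tsv(path) -> dict[str, PlexDesign]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    designs = {}
    for pid, grp in df.groupby("plex", sort=True):
        channels = tuple(grp["channel"].astype(str))
        bridges = tuple(grp.loc[grp["role"] == "bridge", "channel"].astype(str))
        samples = {str(r["channel"]): str(r["sample"])
                   for _, r in grp.iterrows() if r["role"] == "sample"}
        designs[str(pid)] = PlexDesign(str(pid), channels, bridges, samples)
    return designs


def read_protein_lengths_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return dict(zip(df["protein_id"].astype(str), df["length"].astype(int)))


def write_protein_lengths_tsv(lengths: Mapping[str, int], path) -> None:
    pd.DataFrame({"protein_id": list(lengths), "length": list(lengths.values())}
                 ).to_csv(path, sep="\t", index=False)
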