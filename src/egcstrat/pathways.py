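"""Pathway-instability (PI) scoring.

A PI score summarizes, per patient and per pathway, how disrupted the
pathway's genes are by non-benign somatic alterations measured on the panel.
The normative scheme here is a panel-restricted weighted altered-gene
fraction:

    PI(p, w) = sum_{g in genes(w) ∩ panel} weight_p(g) / |genes(w) ∩ panel|

where a gene's weight for patient p is the maximum over its alterations:
1.0 for a pathogenic/likely-pathogenic variant or any copy-number event,
``vus_weight`` (default 0.5) for a variant of uncertain significance, and 0
otherwise. Benign and likely-benign calls never contribute. Scores therefore
lie in [0, 1], reaching 1 only when every measurable gene of the pathway
carries a pathogenic/CNV alteration.

Gene sets are read from GMT files; each pathway carries a top-level label
(the root of its hierarchy, e.g. "Immune System") used for pooled
comparisons across patient groups.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import BENIGN_CLASSES, PATHOGENIC_CLASSES, CNVCall, VariantCall

logger = logging.getLogger(__name__)

WEIGHT_SCHEMES = ("default",)
DEFAULT_VUS_WEIGHT = 0.5


@dataclass(frozen=True)
class PathwayDef:
    """A gene set with a top-level hierarchy label."""

    pathway_id: str
    name: str
    genes: frozenset[str]
    top_level: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty gene set")


@dataclass(frozen=True)
class AlterationProfile:
    """Per-patient map gene -> alteration weight in [0, 1].

    Genes whose only calls are benign/likely benign are absent from the map.
    """

    patient_id: str
    altered_genes: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, w in self.altered_genes.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight for {g} outside [0, 1]: {w}")


def load_gene_sets(
    gmt_path: str | Path, top_level_map_path: str | Path
) -> list[PathwayDef]:
    """Load pathway gene sets from GMT plus a 2-column top-level map TSV.

    GMT lines are ``pathway_id<TAB>description<TAB>gene1<TAB>gene2...`` with
    at least one gene; duplicate gene symbols within a line are deduplicated.
    Every pathway id must appear in the top-level map (pathway_id, top_level).
    """
    gmt_path, map_path = Path(gmt_path), Path(top_level_map_path)
    top_level: dict[str, str] = {}
    with open(map_path, newline="") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{map_path}:{i}: expected 2 tab-separated fields, got {len(parts)}"
                )
            top_level[parts[0]] = parts[1]

    out: list[PathwayDef] = []
    seen: set[str] = set()
    with open(gmt_path, newline="") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{gmt_path}:{i}: malformed GMT line (need id, description "
                    f"and >= 1 gene; got {len(parts)} fields)"
                )
            pid, name = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{gmt_path}:{i}: pathway {pid!r} has no genes")
            if pid in seen:
                raise ValueError(f"{gmt_path}:{i}: duplicate pathway id {pid!r}")
            if pid not in top_level:
                raise ValueError(
                    f"pathway {pid!r} missing from top-level map {map_path}"
                )
            seen.add(pid)
            out.append(PathwayDef(pid, name, genes, top_level[pid]))
    return out


def write_gene_sets(
    pathways: Sequence[PathwayDef], gmt_path: str | Path, map_path: str | Path
) -> None:
    """Write pathways as a GMT file plus the top-level map TSV."""
    with open(gmt_path, "w", newline="") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.genes)]) + "\n")
    with open(map_path, "w", newline="") as fh:
        for p in pathways:
            fh.write(f"{p.pathway_id}\t{p.top_level}\n")


def build_alteration_profiles(
    variants: Sequence[VariantCall],
    cnvs: Sequence[CNVCall] = (),
    weight_scheme: str = "default",
    vus_weight: float = DEFAULT_VUS_WEIGHT,
    patient_ids: Sequence[str] | None = None,
) -> list[AlterationProfile]:
    """Collapse filtered variants and CNVs to per-patient gene weights.

    Default scheme: weight 1.0 for a gene with >= 1 pathogenic/likely
    pathogenic variant or any CNV; ``vus_weight`` when its only non-benign
    alterations are VUS; benign-only genes get nothing. A gene's weight is
    the max over its alterations, so redundant calls never inflate it.

    ``patient_ids`` optionally forces the output to cover exactly these
    patients (adding empty profiles for patients with no alterations).
    """
    if weight_scheme not in WEIGHT_SCHEMES:
        raise ValueError(
            f"unknown weight scheme {weight_scheme!r} (available: {WEIGHT_SCHEMES})"
        )
    weights: dict[str, dict[str, float]] = {}
    if patient_ids is not None:
        for pid in patient_ids:
            weights[pid] = {}
    for v in variants:
        if v.acmg in BENIGN_CLASSES:
            continue
        w = 1.0 if v.acmg in PATHOGENIC_CLASSES else vus_weight
        genes = weights.setdefault(v.patient_id, {})
        genes[v.gene] = max(genes.get(v.gene, 0.0), w)
    for c in cnvs:
        genes = weights.setdefault(c.patient_id, {})
        genes[c.gene] = max(genes.get(c.gene, 0.0), 1.0)
    return [
        AlterationProfile(pid, dict(weights[pid])) for pid in sorted(weights)
    ]


def compute_pi_matrix(
    profiles: Sequence[AlterationProfile],
    pathways: Sequence[PathwayDef],
    panel_genes: Iterable[str],
) -> pd.DataFrame:
    """Patients x pathways PI score matrix.

    Each pathway is first restricted to the genes actually measured by the
    panel; pathways left with no measurable gene are dropped with a warning
    rather than scored 0 (an unmeasurable pathway is not a stable one). Rows
    are ordered by patient id, columns by pathway id.
    """
    panel = frozenset(panel_genes)
    if not panel:
        raise ValueError("panel_genes must be non-empty")
    kept: list[tuple[PathwayDef, frozenset[str]]] = []
    for p in sorted(pathways, key=lambda p: p.pathway_id):
        restricted = p.genes & panel
        if restricted:
            kept.append((p, restricted))
        else:
            logger.warning(
                "pathway %s has no genes on the panel; dropped", p.pathway_id
            )
    if not kept:
        raise ValueError("no pathway has any gene on the panel")
    pids = sorted(p.patient_id for p in profiles)
    if len(pids) != len(set(pids)):
        raise ValueError("duplicate patient ids in profiles")
    by_pid = {p.patient_id: p.altered_genes for p in profiles}
    data = {
        pw.pathway_id: [
            sum(by_pid[pid].get(g, 0.0) for g in genes) / len(genes)
            for pid in pids
        ]
        for pw, genes in kept
    }
    return pd.DataFrame(data, index=pd.Index(pids, name="patient_id"))


def pool_top_level(
    pi: pd.DataFrame,
    pathways: Sequence[PathwayDef],
    patient_groups: Mapping[str, str],
) -> pd.DataFrame:
    """Pool PI scores by (top-level pathway, patient group).

    Each pooled observation is the PI score of one patient for one pathway in
    the top level, so a group of m patients and a top level of k scored
    pathways pool m*k points. Patients without a group label are excluded
    (their count is logged). Returns a tidy frame with columns
    ``top_level, group, patient_id, pathway_id, score``.
    """
    top_of = {p.pathway_id: p.top_level for p in pathways}
    unknown = [c for c in pi.columns if c not in top_of]
    if unknown:
        raise ValueError(f"pathways missing top-level labels: {unknown[:5]}")
    missing = [pid for pid in pi.index if pid not in patient_groups]
    if missing:
        logger.info("%d patients have no group label; excluded from pooling", len(missing))
    long = pi.loc[[pid for pid in pi.index if pid in patient_groups]].stack()
    long.index.names = ["patient_id", "pathway_id"]
    df = long.rename("score").reset_index()
    df["top_level"] = df["pathway_id"].map(top_of)
    df["group"] = df["patient_id"].map(patient_groups)
    return df[["top_level", "group", "patient_id", "pathway_id", "score"]]
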