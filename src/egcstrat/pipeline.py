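"""End-to-end orchestration: one config in, a report bundle of plain TSV
files out.

Stages run in the order of the underlying analysis: variant filtering ->
TMB/MSI biomarker calling -> alteration profiles -> PI score matrix ->
pooled top-level comparisons -> t-SNE embedding -> DBSCAN clustering ->
cluster characterization -> clinical-by-cluster tests -> univariate Cox
forest -> Kaplan-Meier/log-rank by cluster -> oncoprint -> variant summary.
Every output file is written atomically (temp file + rename); a manifest
records the config, master seed and package version, so a rerun with the
same manifest reproduces the bundle byte-for-byte (timestamps live only in
the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import (
    DEFAULT_PANEL_SIZE_MB,
    MsiSiteData,
    biomarker_table,
    read_msi_table,
    write_biomarker_table,
)
from .clustering import characterize, cluster, compare_clinical, embed
from .pathways import (
    build_alteration_profiles,
    compute_pi_matrix,
    load_gene_sets,
    pool_top_level,
    write_gene_sets,
)
from .simulate import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_gene_sets,
    generate_tcga_like,
)
from .stats import (
    TestResult,
    bh_adjust,
    clinical_to_frame,
    cox_univariate,
    km_logrank,
    read_clinical_table,
    wilcoxon_rank_sum,
)
from .variants import (
    BENIGN_CLASSES,
    CNVCall,
    FilterConfig,
    VariantCall,
    filter_variants,
    read_cnv_table,
    read_variant_table,
    summarize_variants,
    variants_by_patient,
    write_variant_table,
)

logger = logging.getLogger(__name__)

#: Alteration categories of an oncoprint cell, in precedence order
#: (a cell with several co-occurring alterations shows the first match).
ONCOPRINT_CATEGORIES = ("cnv", "pathogenic", "vus", "none")


@dataclass
class PipelineConfig:
    """Everything one run needs. Exactly one of the real-input path block
    (``variants_path`` et al.) and the synthetic block must be active."""

    output_dir: str = "egcstrat_out"
    seed: int = 0
    log_level: str = "INFO"
    # --- real-input mode ---
    variants_path: str | None = None
    variants_dialect: str = "annovar_tsv"
    cnvs_path: str | None = None
    clinical_path: str | None = None
    msi_path: str | None = None
    gmt_path: str | None = None
    top_level_map_path: str | None = None
    panel_genes: list[str] | None = None
    # --- synthetic mode ---
    synthetic: SyntheticCohortConfig | None = None
    n_pathways: int = 218
    n_top_levels: int = 8
    # --- stage parameters ---
    min_depth: int = 100
    min_vaf: float = 0.05
    panel_size_mb: float = DEFAULT_PANEL_SIZE_MB
    tmb_cutoff: float = 10.0
    msi_fraction_cutoff: float = 0.20
    msi_min_usable: int = 40
    tmb_count_benign: bool = True
    vus_weight: float = 0.5
    perplexity: float | None = None
    dbscan_eps: float | None = None
    dbscan_min_samples: int = 3
    oncoprint_min_patients: int = 4
    alpha: float = 0.05

    @property
    def real_mode(self) -> bool:
        return self.synthetic is None

    def filter_config(self) -> FilterConfig:
        return FilterConfig(min_depth=self.min_depth, min_vaf=self.min_vaf)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file; unknown keys are
    rejected so typos fail loudly."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = PipelineConfig(**raw)
    if syn is not None:
        syn_known = {f.name for f in dataclasses.fields(SyntheticCohortConfig)}
        syn_unknown = set(syn) - syn_known
        if syn_unknown:
            raise ValueError(
                f"unknown synthetic config key(s): {', '.join(sorted(syn_unknown))}"
            )
        if "panel" in syn:
            syn["panel"] = tuple(syn["panel"])
        for key in ("acmg_mixture", "effect_mixture"):
            if key in syn:
                syn[key] = tuple(syn[key])
        cfg.synthetic = SyntheticCohortConfig(**syn)
    return cfg


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Collect every violated invariant (not fail-fast); empty list = valid."""
    errors: list[str] = []
    real_paths = [cfg.variants_path, cfg.clinical_path, cfg.gmt_path,
                  cfg.top_level_map_path]
    any_real = any(p is not None for p in real_paths)
    if cfg.synthetic is not None and any_real:
        errors.append("config sets both real input paths and a synthetic block; "
                      "exactly one mode must be active")
    if cfg.synthetic is None:
        for name, p in (("variants_path", cfg.variants_path),
                        ("clinical_path", cfg.clinical_path),
                        ("gmt_path", cfg.gmt_path),
                        ("top_level_map_path", cfg.top_level_map_path)):
            if p is None:
                errors.append(f"real-input mode requires {name}")
            elif not Path(p).exists():
                errors.append(f"{name} does not exist: {p}")
        if cfg.panel_genes is not None and not cfg.panel_genes:
            errors.append("panel_genes must be non-empty when given")
    if cfg.min_depth <= 0:
        errors.append(f"min_depth must be > 0, got {cfg.min_depth}")
    if not 0.0 < cfg.min_vaf < 1.0:
        errors.append(f"min_vaf must be in (0, 1), got {cfg.min_vaf}")
    if cfg.panel_size_mb <= 0:
        errors.append(f"panel_size_mb must be > 0, got {cfg.panel_size_mb}")
    if cfg.msi_min_usable < 1:
        errors.append(f"msi_min_usable must be >= 1, got {cfg.msi_min_usable}")
    if not 0.0 <= cfg.msi_fraction_cutoff <= 1.0:
        errors.append("msi_fraction_cutoff must be in [0, 1]")
    if not 0.0 <= cfg.vus_weight <= 1.0:
        errors.append(f"vus_weight must be in [0, 1], got {cfg.vus_weight}")
    if cfg.dbscan_min_samples < 1:
        errors.append("dbscan_min_samples must be >= 1")
    if cfg.oncoprint_min_patients < 1:
        errors.append("oncoprint_min_patients must be >= 1")
    if not 0.0 < cfg.alpha < 1.0:
        errors.append(f"alpha must be in (0, 1), got {cfg.alpha}")
    out_parent = Path(cfg.output_dir).resolve().parent
    if not out_parent.exists():
        errors.append(f"output directory parent does not exist: {out_parent}")
    return errors


def build_oncoprint(
    variants: Sequence[VariantCall],
    cnvs: Sequence[CNVCall] = (),
    min_patients: int = 4,
    patient_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene x patient alteration-category matrix for recurrently altered
    genes.

    Benign/likely-benign variants are excluded. A gene row is kept iff it is
    altered (non-benign variant or CNV) in at least ``min_patients`` distinct
    patients. When a patient has several alterations in one gene, the cell
    shows the highest-precedence category: cnv > pathogenic (incl. likely
    pathogenic) > vus. Rows are ordered by decreasing number of altered
    patients (ties by gene symbol), columns by patient id.
    """
    rank = {c: i for i, c in enumerate(ONCOPRINT_CATEGORIES)}
    cells: dict[tuple[str, str], str] = {}
    for v in variants:
        if v.acmg in BENIGN_CLASSES:
            continue
        cat = "pathogenic" if v.is_pathogenic else "vus"
        key = (v.gene, v.patient_id)
        if key not in cells or rank[cat] < rank[cells[key]]:
            cells[key] = cat
    for c in cnvs:
        cells[(c.gene, c.patient_id)] = "cnv"
    counts: dict[str, set[str]] = {}
    for gene, pid in cells:
        counts.setdefault(gene, set()).add(pid)
    kept = sorted(
        (g for g, pids in counts.items() if len(pids) >= min_patients),
        key=lambda g: (-len(counts[g]), g),
    )
    if patient_ids is None:
        patient_ids = sorted({pid for _, pid in cells})
    data = {
        pid: [cells.get((g, pid), "none") for g in kept] for pid in patient_ids
    }
    return pd.DataFrame(data, index=pd.Index(kept, name="gene"),
                        columns=list(patient_ids))


def _atomic_write(path: Path, write_fn) -> None:
    """Write via a temp file in the same directory, then rename."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_df(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    _atomic_write(
        path, lambda p: df.to_csv(p, sep="\t", index=index, float_format="%.6g",
                                  lineterminator="\n")
    )


def _config_dict(cfg: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    if cfg.synthetic is not None:
        syn = dataclasses.asdict(cfg.synthetic)
        syn["panel"] = list(syn["panel"])
        syn["acmg_mixture"] = list(syn["acmg_mixture"])
        syn["effect_mixture"] = list(syn["effect_mixture"])
        syn["gene_rates"] = dict(syn["gene_rates"])
        d["synthetic"] = syn
    return d


class StageError(RuntimeError):
    """An error in one pipeline stage, tagged with the stage name and the
    provenance of its inputs."""

    def __init__(self, stage: str, provenance: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed on {provenance}: {cause}")
        self.stage = stage


def _load_inputs(cfg: PipelineConfig):
    """Read or generate the raw inputs for a run."""
    if cfg.real_mode:
        variants = read_variant_table(cfg.variants_path, cfg.variants_dialect)
        cnvs = read_cnv_table(cfg.cnvs_path) if cfg.cnvs_path else []
        clinical = read_clinical_table(cfg.clinical_path)
        msi = read_msi_table(cfg.msi_path) if cfg.msi_path else {}
        pathways = load_gene_sets(cfg.gmt_path, cfg.top_level_map_path)
        panel = (set(cfg.panel_genes) if cfg.panel_genes
                 else {v.gene for v in variants} | {c.gene for c in cnvs})
        provenance = f"inputs at {cfg.variants_path}"
    else:
        syn = cfg.synthetic
        clin_main, var_main, cnv_main, msi_list = generate_cohort(syn)
        clin_aug, var_aug, cnv_aug = generate_tcga_like(syn)
        ids_main = {r.patient_id for r in clin_main}
        collisions = ids_main & {r.patient_id for r in clin_aug}
        if collisions:
            raise ValueError(f"patient id collision across cohorts: {sorted(collisions)[:3]}")
        variants = var_main + var_aug
        cnvs = cnv_main + cnv_aug
        clinical = clinical_to_frame(clin_main + clin_aug)
        msi = {m.patient_id: m for m in msi_list}
        pathways = generate_gene_sets(syn, cfg.n_pathways, cfg.n_top_levels)
        panel = set(syn.panel)
        provenance = f"synthetic cohort (seed {syn.seed})"
    return variants, cnvs, clinical, msi, pathways, panel, provenance


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write the report bundle; returns the bundle dir.

    Any stage failure aborts the run with the stage name and input
    provenance in the message. Output files are deterministic for a fixed
    (config, seed); wall-clock timestamps appear only in the manifest.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name: str, provenance: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise StageError(name, provenance, exc) from exc
        logger.info("stage %-22s done", name)
        return result

    variants, cnvs, clinical, msi, pathways, panel, prov = stage(
        "load_inputs", "configured inputs", lambda: _load_inputs(cfg)
    )
    logger.info("inputs: %d variants, %d CNVs, %d patients, %d pathways",
                len(variants), len(cnvs), len(clinical), len(pathways))

    if not cfg.real_mode:
        # persist the generated inputs so a real-mode rerun can consume them
        stage("write_synthetic_inputs", prov, lambda: (
            _atomic_write(out / "input_variants.tsv",
                          lambda p: write_variant_table(variants, p)),
            _atomic_write(out / "input_cnvs.tsv", lambda p: _write_cnvs(cnvs, p)),
            _write_df(clinical, out / "input_clinical.tsv", index=False),
            _atomic_write(out / "input_msi.tsv",
                          lambda p: _write_msi(list(msi.values()), p)),
            write_gene_sets(pathways, out / "input_pathways.gmt",
                            out / "input_top_levels.tsv"),
        ))

    fcfg = cfg.filter_config()
    filtered = stage("filter_variants", prov, lambda: filter_variants(variants, fcfg))
    logger.info("filter: %d of %d variants retained", len(filtered), len(variants))
    filtered_set = set(filtered)
    retained_idx = {i for i, v in enumerate(variants) if v in filtered_set}
    _atomic_write(out / "filtered_variants.tsv",
                  lambda p: write_variant_table(variants, p, retained=retained_idx))

    summary = stage("summarize_variants", prov, lambda: summarize_variants(filtered))
    _write_df(_summary_frame(summary), out / "variant_summary.tsv", index=False)

    by_patient = variants_by_patient(filtered)
    all_ids = list(clinical["patient_id"])
    for pid in all_ids:
        by_patient.setdefault(pid, [])
    biomarkers = stage("biomarkers", prov, lambda: biomarker_table(
        by_patient, msi, cfg.panel_size_mb, cfg.tmb_cutoff,
        cfg.msi_fraction_cutoff, cfg.msi_min_usable, cfg.tmb_count_benign,
    ))
    # the per-patient biomarker report covers the Kodama-labelled main series
    # (the augmentation cohort carries no microsatellite data); TMB classes
    # of all patients still feed the grouped comparisons below
    labelled = set(clinical.loc[clinical["kodama"].isin(["pen_a", "pen_b"]),
                                "patient_id"])
    reported = [b for b in biomarkers if b.patient_id in labelled] or biomarkers
    _atomic_write(out / "biomarkers.tsv", lambda p: write_biomarker_table(reported, p))

    profiles = stage("alteration_profiles", prov, lambda: build_alteration_profiles(
        filtered, cnvs, vus_weight=cfg.vus_weight, patient_ids=all_ids,
    ))
    pi = stage("pi_matrix", prov, lambda: compute_pi_matrix(profiles, pathways, panel))
    _write_df(pi, out / "pi_matrix.tsv")

    top_tests = stage("top_level_tests", prov,
                      lambda: _top_level_tests(pi, pathways, clinical, biomarkers))
    _write_df(top_tests, out / "top_level_tests.tsv", index=False)

    emb = stage("embed", prov, lambda: embed(pi, cfg.perplexity, seed=cfg.seed))
    _write_df(emb.to_frame(), out / "embedding.tsv")
    assignment = stage("cluster", prov, lambda: cluster(
        emb, cfg.dbscan_eps, cfg.dbscan_min_samples))
    _write_df(assignment.to_frame(), out / "clusters.tsv")
    logger.info("clusters: %d (plus %d noise points)",
                len(assignment.cluster_labels), assignment.n_noise)

    if len(assignment.cluster_labels) >= 2:
        profiles_by_cluster = stage("characterize", prov, lambda: characterize(
            pi, assignment, profiles, cfg.alpha))
        clin_tests = stage("clinical_by_cluster", prov,
                           lambda: compare_clinical(assignment, clinical))
    else:  # a single dense cluster: nothing to contrast against
        logger.info("fewer than 2 clusters; characterization and clinical "
                    "comparisons are empty")
        profiles_by_cluster = []
        clin_tests = pd.DataFrame(
            columns=["covariate", "method", "statistic", "p_value"])
    _write_df(_cluster_profile_frame(profiles_by_cluster),
              out / "cluster_profiles.tsv", index=False)
    _write_df(clin_tests, out / "clinical_by_cluster.tsv", index=False)

    cox_table = stage("cox_forest", prov,
                      lambda: _cox_forest(clinical, by_patient))
    _write_df(cox_table, out / "cox_univariate.tsv", index=False)

    km_table = stage("km_by_cluster", prov,
                     lambda: _km_by_cluster(clinical, assignment))
    _write_df(km_table, out / "km_logrank.tsv", index=False)

    main_ids = [r for r in all_ids if str(r).startswith("EGC")] or all_ids
    main_variants = [v for v in filtered if v.patient_id in set(main_ids)]
    main_cnvs = [c for c in cnvs if c.patient_id in set(main_ids)]
    onco = stage("oncoprint", prov, lambda: build_oncoprint(
        main_variants, main_cnvs, cfg.oncoprint_min_patients, main_ids))
    _write_df(onco, out / "oncoprint.tsv")

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "config_sha256": hashlib.sha256(
            json.dumps(_config_dict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "n_variants_in": len(variants),
        "n_variants_retained": len(filtered),
        "n_patients": len(clinical),
        "n_pathways_scored": int(pi.shape[1]),
        "n_clusters": len(assignment.cluster_labels),
        "n_noise": assignment.n_noise,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    _atomic_write(out / "manifest.json",
                  lambda p: p.write_text(json.dumps(manifest, indent=2) + "\n"))
    return out


# --------------------------------------------------------------------------
# helpers for report tables
# --------------------------------------------------------------------------

def _write_cnvs(cnvs: Sequence[CNVCall], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tgene\tkind\n")
        for c in cnvs:
            fh.write(f"{c.patient_id}\t{c.gene}\t{c.kind.value}\n")


def _write_msi(msi: Sequence[MsiSiteData], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tusable_sites\tunstable_sites\n")
        for m in msi:
            fh.write(f"{m.patient_id}\t{m.usable_sites}\t{m.unstable_sites}\n")


def _summary_frame(summary) -> pd.DataFrame:
    rows = [("n_total", summary.n_total), ("n_snv", summary.n_snv),
            ("ts_fraction", summary.ts_fraction),
            ("tv_fraction", summary.tv_fraction)]
    rows += [(f"acmg_{k.value}", v) for k, v in sorted(summary.acmg_fractions.items())]
    rows += [(f"effect_{k.value}", v) for k, v in sorted(summary.effect_fractions.items())]
    return pd.DataFrame(rows, columns=["quantity", "value"])


def _cluster_profile_frame(profiles) -> pd.DataFrame:
    rows = []
    for cp in profiles:
        for pw, direction, q in cp.defining_pathways:
            rows.append({"cluster": cp.label, "size": cp.size, "kind": "pathway",
                         "name": pw, "direction": direction, "value": q})
        for gene, freq in sorted(cp.gene_frequencies.items(),
                                 key=lambda kv: (-kv[1], kv[0]))[:25]:
            rows.append({"cluster": cp.label, "size": cp.size, "kind": "gene",
                         "name": gene, "direction": "", "value": freq})
    return pd.DataFrame(rows, columns=["cluster", "size", "kind", "name",
                                       "direction", "value"])


def _top_level_tests(pi, pathways, clinical, biomarkers) -> pd.DataFrame:
    """Pooled top-level PI comparisons across the study groupings: Kodama
    class (labelled patients only), relapse status, and TMB class; rank-sum
    p-values BH-adjusted within each grouping."""
    groupings: dict[str, Mapping[str, str]] = {}
    kod = {r.patient_id: r.kodama for r in clinical.itertuples()
           if r.kodama in ("pen_a", "pen_b")}
    if len(set(kod.values())) == 2:
        groupings["kodama"] = kod
    relapse = {r.patient_id: ("relapsed" if r.event else "disease_free")
               for r in clinical.itertuples()}
    if len(set(relapse.values())) == 2:
        groupings["relapse"] = relapse
    tmb = {b.patient_id: b.tmb_class.value for b in biomarkers}
    if len(set(tmb.values())) == 2:
        groupings["tmb_class"] = tmb

    rows = []
    for gname, groups in groupings.items():
        pooled = pool_top_level(pi, pathways, groups)
        levels = sorted(set(groups.values()))
        pvals, meta = [], []
        for top in sorted(pooled["top_level"].unique()):
            sub = pooled[pooled["top_level"] == top]
            x = sub.loc[sub["group"] == levels[0], "score"].to_numpy()
            y = sub.loc[sub["group"] == levels[1], "score"].to_numpy()
            if len(x) == 0 or len(y) == 0 or np.ptp(np.r_[x, y]) == 0:
                continue
            res = wilcoxon_rank_sum(x, y)
            pvals.append(res.p_value)
            meta.append((top, float(np.median(x)), float(np.median(y))))
        qvals = bh_adjust(pvals)
        for (top, med_x, med_y), p, q in zip(meta, pvals, qvals):
            rows.append({"grouping": gname, "group1": levels[0], "group2": levels[1],
                         "top_level": top, "median1": med_x, "median2": med_y,
                         "p_value": p, "p_adjusted": q})
    return pd.DataFrame(rows, columns=["grouping", "group1", "group2", "top_level",
                                       "median1", "median2", "p_value", "p_adjusted"])


#: Covariates of the univariate DFS forest, with reference levels.
COX_COVARIATES: tuple[tuple[str, str | None], ...] = (
    ("age", None), ("sex", "F"), ("kodama", "pen_b"), ("location", "lower"),
    ("lauren", "intestinal"), ("grade", "g1_g2"), ("pn_status", "pn0"),
    ("lvi", None), ("tumor_size", None), ("ln_ratio", None),
)


def _cox_forest(clinical: pd.DataFrame, by_patient) -> pd.DataFrame:
    """Univariate Cox DFS fits on the labelled (main-series) patients, one
    row per covariate, plus LRP1B mutation status derived from the filtered
    variants."""
    main = clinical[clinical["kodama"].isin(["pen_a", "pen_b"])]
    if len(main) < 4 or main["event"].sum() < 2:
        main = clinical
    df = main.copy()
    lrp1b = {pid for pid, vs in by_patient.items()
             if any(v.gene == "LRP1B" for v in vs)}
    df["lrp1b_mut"] = df["patient_id"].isin(lrp1b)
    rows = []
    for cov, ref in COX_COVARIATES + (("lrp1b_mut", None),):
        try:
            fit = cox_univariate(df, cov, ref)
        except Exception as exc:
            logger.info("cox covariate %s skipped: %s", cov, exc)
            continue
        rows.append({"covariate": fit.covariate, "hazard_ratio": fit.hazard_ratio,
                     "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                     "p_value": fit.p_value, "schoenfeld_p": fit.schoenfeld_p,
                     "n": fit.n, "n_events": fit.n_events})
    return pd.DataFrame(rows, columns=["covariate", "hazard_ratio", "ci_low",
                                       "ci_high", "p_value", "schoenfeld_p",
                                       "n", "n_events"])


def _km_by_cluster(clinical: pd.DataFrame, assignment) -> pd.DataFrame:
    """Log-rank comparison of DFS across clusters plus per-cluster event
    summaries."""
    groups = {p: str(l) for p, l in assignment.labels.items() if l != -1}
    try:
        curves, res = km_logrank(clinical, groups)
    except ValueError as exc:
        logger.info("KM by cluster skipped: %s", exc)
        return pd.DataFrame(columns=["group", "n", "n_events", "median_dfs",
                                     "logrank_p"])
    rows = []
    for c in curves:
        below = c.times[c.survival <= 0.5]
        median = float(below[0]) if below.size else float("nan")
        rows.append({"group": c.group, "n": c.n, "n_events": c.n_events,
                     "median_dfs": median, "logrank_p": res.p_value})
    return pd.DataFrame(rows, columns=["group", "n", "n_events", "median_dfs",
                                       "logrank_p"])
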