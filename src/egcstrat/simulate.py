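"""Synthetic tumor-cohort generation.

Produces cohorts with the statistical structure the downstream analysis
assumes, so every pipeline stage can be exercised and tested without access
to patient-level data:

* a main early-gastric-cancer series of 13 Pen A + 14 Pen B patients with
  clinical covariates, annotated panel variants, gene-level CNVs,
  microsatellite site counts, and disease-free-survival outcomes;
* an optional stage-I augmentation cohort (default 54 patients) without
  submucosal-penetration (Kodama) labels, mirroring a public-registry
  add-on;
* gene-set collections (default 218 pathways under 8 top-level labels)
  sampled from the panel.

The generator encodes the associations the analysis is designed to detect,
each behind an explicit knob: ARID1A carriers concentrated in Pen A
(``arid1a_pen_a_enrichment``), an elevated relapse hazard for LRP1B carriers
(``lrp1b_hazard_ratio``), and hypermutation in microsatellite-unstable
patients (``msi_tmb_coupling`` — at 1.0 every MSI patient is TMB-high by
construction). ACMG-class and protein-effect mixtures default to fractions
typical of a gastric-cancer panel screen. All randomness flows from one
master seed through named substreams (clinical, variants, msi, pathways), so
a fixed config is byte-reproducible and each block can be regenerated
independently.

Variant genomic coordinates and alleles are synthesized arbitrarily but
validly (ACGT, 1-based); no downstream stage uses position beyond the
transition/transversion split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .biomarkers import MsiSiteData
from .pathways import PathwayDef
from .stats import ClinicalRecord, Kodama
from .variants import Acmg, CNVCall, CnvKind, Effect, VariantCall

#: Gastric-cancer-relevant genes of a targeted oncology panel (subset of a
#: 500-gene pan-cancer design; recurrently altered GC genes listed first).
DEFAULT_PANEL: tuple[str, ...] = (
    "TP53", "PTPRT", "RNF43", "FBXW7", "ARID1A", "SPTA1", "LRP1B", "ERBB2",
    "CCNE1", "APC", "ARID2", "ANKRD11", "RHOA", "EPHA5", "PIK3CA", "KRAS",
    "CDH1", "SMAD4", "CTNNB1", "MUC16", "KMT2D", "KMT2C", "FAT4", "PREX2",
    "ZFHX3", "GNAS", "ERBB3", "ATM", "BRCA2", "NOTCH1", "PTEN", "MSH6",
    "MLH1", "CDKN2A", "EGFR", "MET", "FGFR2", "MYC", "CCND1", "SOX9",
    "ELF3", "PLB1", "DNAH5", "CSMD3", "PCLO", "LRRK2", "TGFBR2", "ACVR2A",
    "POLE", "POLD1", "BCOR", "STK11", "SMARCA4", "NF1", "RB1", "AXIN1",
    "KDM6A", "TET2", "SETD2", "CREBBP",
)

#: Per-gene carrier probabilities for the background mutation process.
#: Key genes follow frequencies typical of early gastric cancer; unlisted
#: panel genes fall back to ``default_gene_rate``. ARID1A and LRP1B are
#: handled by their dedicated knobs and excluded from the background draw.
DEFAULT_GENE_RATES: Mapping[str, float] = {
    "TP53": 0.52, "PTPRT": 0.30, "RNF43": 0.26, "FBXW7": 0.26, "SPTA1": 0.22,
    "MUC16": 0.26, "APC": 0.15, "ARID2": 0.11, "ANKRD11": 0.11, "RHOA": 0.07,
    "EPHA5": 0.15, "KMT2D": 0.15, "FAT4": 0.15, "CSMD3": 0.15, "PCLO": 0.12,
}

#: Reactome-style top-level pathway labels for generated gene sets.
DEFAULT_TOP_LEVELS: tuple[str, ...] = (
    "Disease", "Immune System", "Signal Transduction", "DNA Repair",
    "Cellular responses to stimuli", "Metabolism of proteins",
    "Gene expression (Transcription)", "Programmed Cell Death",
)

#: ACMG mixture: 22.1% pathogenic/likely pathogenic, 41.2% VUS, 36.7%
#: benign/likely benign, with each pair split between its two tiers.
DEFAULT_ACMG_MIXTURE: tuple[float, ...] = (0.070, 0.151, 0.412, 0.180, 0.187)
_ACMG_ORDER = (Acmg.PATHOGENIC, Acmg.LIKELY_PATHOGENIC, Acmg.VUS,
               Acmg.LIKELY_BENIGN, Acmg.BENIGN)

#: Protein-effect mixture over filter-eligible variants: missense 79.8%,
#: frameshift 11.4%, splice 4.0%, nonsense 3.0%, in-frame 1.9% (rounded to
#: sum to 1).
_EFFECT_ORDER = (Effect.MISSENSE, Effect.FRAMESHIFT_INDEL, Effect.SPLICE,
                 Effect.NONSENSE, Effect.INFRAME_INDEL)
DEFAULT_EFFECT_MIXTURE: tuple[float, ...] = (0.798, 0.114, 0.040, 0.029, 0.019)

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All generator knobs. Defaults are the study conditions the analysis
    is designed for; see the module docstring for what each knob encodes."""

    n_pen_a: int = 13
    n_pen_b: int = 14
    n_tcga_like: int = 54
    seed: int = 0
    panel: tuple[str, ...] = DEFAULT_PANEL
    panel_size_mb: float = 1.33
    n_msi_sites: int = 130
    arid1a_pen_a_enrichment: float = 1.0
    arid1a_rate: float = 0.22
    lrp1b_hazard_ratio: float = 2.73
    lrp1b_rate: float = 0.30
    msi_tmb_coupling: float = 1.0
    msi_rate: float = 0.15
    gene_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_RATES)
    )
    default_gene_rate: float = 0.06
    acmg_mixture: tuple[float, ...] = DEFAULT_ACMG_MIXTURE
    effect_mixture: tuple[float, ...] = DEFAULT_EFFECT_MIXTURE
    ts_fraction: float = 0.734
    tmb_cutoff: float = 10.0
    #: median mut/Mb of the baseline (non-hypermutated) burden distribution
    baseline_tmb_median: float = 5.5
    baseline_tmb_sigma: float = 0.65
    #: median mut/Mb of the hypermutated (MSI-coupled) burden distribution
    msi_tmb_median: float = 25.0
    msi_tmb_sigma: float = 0.35
    #: monthly baseline hazard of relapse/death; ~0.0074 gives ~59% events
    #: over a 120-month follow-up
    baseline_hazard: float = 0.0074
    censoring_rate: float = 0.40
    followup_months: float = 120.0

    def __post_init__(self) -> None:
        if min(self.n_pen_a, self.n_pen_b, self.n_tcga_like) < 0:
            raise ValueError("cohort sizes must be >= 0")
        for name in ("acmg_mixture", "effect_mixture"):
            v = getattr(self, name)
            if abs(sum(v) - 1.0) > 1e-9 or min(v) < 0:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if not 0.0 <= self.arid1a_pen_a_enrichment <= 1.0:
            raise ValueError("arid1a_pen_a_enrichment must be in [0, 1]")
        if not 0.0 <= self.msi_tmb_coupling <= 1.0:
            raise ValueError("msi_tmb_coupling must be in [0, 1]")
        if self.lrp1b_hazard_ratio <= 0:
            raise ValueError("lrp1b_hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.panel_size_mb <= 0:
            raise ValueError("panel_size_mb must be > 0")
        panel = set(self.panel)
        stray = [g for g in self.gene_rates if g not in panel]
        if stray:
            raise ValueError(
                f"gene_rates mentions genes absent from the panel: {stray[:5]}"
            )
        for g in ("ARID1A", "LRP1B"):
            if g not in panel:
                raise ValueError(f"panel must include {g} (it has a dedicated knob)")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named child generators off one master seed, in a fixed spawn order."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("clinical", "variants", "msi", "pathways")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_snv_alleles(rng: np.random.Generator, ts_fraction: float) -> tuple[str, str]:
    ref = "ACGT"[rng.integers(4)]
    if rng.random() < ts_fraction:
        return ref, _TRANSITIONS[ref]
    return ref, _TRANSVERSIONS[ref][rng.integers(2)]


def _draw_variant(
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
    patient_id: str,
    gene: str,
    effect: Effect | None = None,
    acmg: Acmg | None = None,
    eligible: bool = True,
) -> VariantCall:
    """One valid variant record; ``eligible=False`` makes it fail the
    standard depth/VAF/effect filter in a randomly chosen way."""
    if effect is None:
        effect = _EFFECT_ORDER[rng.choice(len(_EFFECT_ORDER), p=cfg.effect_mixture)]
    if acmg is None:
        acmg = _ACMG_ORDER[rng.choice(len(_ACMG_ORDER), p=cfg.acmg_mixture)]
    depth = int(rng.integers(120, 1500))
    vaf = float(np.clip(0.05 + 0.9 * rng.beta(2.0, 5.0), 0.05, 1.0))
    if not eligible:
        mode = rng.integers(3)
        if mode == 0:
            effect = Effect.SYNONYMOUS if rng.random() < 0.5 else Effect.NONCODING
        elif mode == 1:
            depth = int(rng.integers(10, 100))
        else:
            vaf = float(rng.uniform(0.005, 0.045))
    if effect in (Effect.FRAMESHIFT_INDEL, Effect.INFRAME_INDEL):
        base = "ACGT"[rng.integers(4)]
        extra = "".join("ACGT"[rng.integers(4)] for _ in range(int(rng.integers(1, 4))))
        ref, alt = base + extra, base  # deletion
    else:
        ref, alt = _draw_snv_alleles(rng, cfg.ts_fraction)
    return VariantCall(
        patient_id=patient_id,
        gene=gene,
        chrom=str(int(rng.integers(1, 23))),
        pos=int(rng.integers(1, 50_000_000)),
        ref=ref,
        alt=alt,
        effect=effect,
        depth=depth,
        vaf=vaf,
        acmg=acmg,
    )


def _background_gene_distribution(
    cfg: SyntheticCohortConfig,
) -> tuple[list[str], np.ndarray]:
    """Rate-weighted gene draw for non-dedicated variants."""
    genes = [g for g in cfg.panel if g not in ("ARID1A", "LRP1B")]
    weights = np.array(
        [cfg.gene_rates.get(g, cfg.default_gene_rate) for g in genes], dtype=float
    )
    return genes, weights / weights.sum()


def _allocate_arid1a(
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
    patient_ids: Sequence[str],
    pen_a_ids: Sequence[str],
) -> list[str]:
    """Choose ARID1A carriers; a carrier lands in Pen A with probability
    e + (1 - e) * |Pen A| / n, so e = 1 forces every carrier into Pen A."""
    n = len(patient_ids)
    n_carriers = int(rng.binomial(n, cfg.arid1a_rate))
    pool_a = list(pen_a_ids)
    pool_o = [p for p in patient_ids if p not in set(pool_a)]
    rng.shuffle(pool_a)
    rng.shuffle(pool_o)
    e = cfg.arid1a_pen_a_enrichment
    p_pen_a = e + (1.0 - e) * (len(pool_a) / n) if n else 0.0
    carriers: list[str] = []
    for _ in range(n_carriers):
        prefer_a = rng.random() < p_pen_a
        if prefer_a or not pool_o:
            if pool_a:
                carriers.append(pool_a.pop())
            elif pool_o and e < 1.0:
                carriers.append(pool_o.pop())
            # e == 1 with Pen A exhausted: drop the carrier rather than leak
        elif pool_o:
            carriers.append(pool_o.pop())
    return carriers


def _patient_variants(
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
    pid: str,
    is_msi_coupled: bool,
    is_arid1a: bool,
    is_lrp1b: bool,
    bg_genes: list[str],
    bg_weights: np.ndarray,
) -> list[VariantCall]:
    min_high = math.ceil(cfg.tmb_cutoff * cfg.panel_size_mb)
    if is_msi_coupled:
        tmb = rng.lognormal(math.log(cfg.msi_tmb_median), cfg.msi_tmb_sigma)
        n_eligible = max(min_high, round(tmb * cfg.panel_size_mb))
    else:
        tmb = rng.lognormal(math.log(cfg.baseline_tmb_median), cfg.baseline_tmb_sigma)
        n_eligible = max(1, round(tmb * cfg.panel_size_mb))
    out: list[VariantCall] = []
    if is_arid1a:
        # carriers mostly harbor likely-pathogenic frameshifts, the rest VUS
        if rng.random() < 2 / 3:
            out.append(_draw_variant(rng, cfg, pid, "ARID1A",
                                     Effect.FRAMESHIFT_INDEL, Acmg.LIKELY_PATHOGENIC))
        else:
            out.append(_draw_variant(rng, cfg, pid, "ARID1A", acmg=Acmg.VUS))
    if is_lrp1b:
        out.append(_draw_variant(rng, cfg, pid, "LRP1B"))
    n_rest = max(0, n_eligible - len(out))
    for gene in rng.choice(len(bg_genes), size=n_rest, p=bg_weights):
        out.append(_draw_variant(rng, cfg, pid, bg_genes[gene]))
    # sub-threshold extras that the standard filter must remove
    for _ in range(int(rng.poisson(3.0))):
        gene = bg_genes[int(rng.choice(len(bg_genes), p=bg_weights))]
        out.append(_draw_variant(rng, cfg, pid, gene, eligible=False))
    return out


def _patient_cnvs(
    rng: np.random.Generator, pid: str
) -> list[CNVCall]:
    out = []
    for gene, kind, p in (
        ("ERBB2", CnvKind.AMPLIFICATION, 0.18),
        ("CCNE1", CnvKind.AMPLIFICATION, 0.15),
        ("EGFR", CnvKind.AMPLIFICATION, 0.05),
        ("CDKN2A", CnvKind.DELETION, 0.08),
    ):
        if rng.random() < p:
            out.append(CNVCall(pid, gene, kind))
    return out


def _msi_sites(
    rng: np.random.Generator, cfg: SyntheticCohortConfig, pid: str, is_msi: bool
) -> MsiSiteData:
    usable = int(rng.binomial(cfg.n_msi_sites, 0.9))
    if is_msi:
        frac = rng.uniform(0.25, 0.45)
        unstable = max(int(rng.binomial(usable, frac)),
                       math.floor(0.20 * usable) + 1)
    else:
        unstable = int(rng.binomial(usable, rng.uniform(0.0, 0.12)))
        unstable = min(unstable, math.floor(0.20 * usable))  # keep MSS below cutoff
    return MsiSiteData(pid, usable, min(unstable, usable))


def _clinical_record(
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
    pid: str,
    kodama: Kodama,
    is_lrp1b: bool,
) -> ClinicalRecord:
    age = float(np.clip(rng.normal(67.0, 11.7), 40.0, 90.0))
    pn_pos = rng.random() < 0.30
    hazard = cfg.baseline_hazard * (cfg.lrp1b_hazard_ratio if is_lrp1b else 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        rate_c = cfg.baseline_hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        t_censor = rng.exponential(1.0 / rate_c)
    else:
        t_censor = math.inf
    horizon = min(t_censor, cfg.followup_months)
    return ClinicalRecord(
        patient_id=pid,
        kodama=kodama,
        age=round(age, 1),
        sex="F" if rng.random() < 0.556 else "M",
        location="upper_middle" if rng.random() < 0.482 else "lower",
        lauren="intestinal" if rng.random() < 0.852 else "diffuse_mixed",
        grade="g1_g2" if rng.random() < 0.54 else "g3",
        pn_status="pn_pos" if pn_pos else "pn0",
        ln_ratio=round(float(rng.uniform(0.02, 0.45)), 3) if pn_pos else 0.0,
        lvi=rng.random() < 0.148,
        tumor_size=round(float(np.clip(rng.lognormal(math.log(2.2), 0.35), 1.0, 6.0)), 1),
        dfs_time=round(min(t_event, horizon), 2),
        event=t_event <= horizon,
    )


def _generate(
    cfg: SyntheticCohortConfig,
    patient_ids: list[str],
    pen_a_ids: list[str],
    kodama_of: Mapping[str, Kodama],
    rngs: Mapping[str, np.random.Generator],
    with_msi_sites: bool,
) -> tuple[list[ClinicalRecord], list[VariantCall], list[CNVCall], list[MsiSiteData]]:
    rng_c, rng_v, rng_m = rngs["clinical"], rngs["variants"], rngs["msi"]
    bg_genes, bg_weights = _background_gene_distribution(cfg)

    msi_status = {pid: rng_m.random() < cfg.msi_rate for pid in patient_ids}
    coupled = {
        pid: msi_status[pid] and rng_m.random() < cfg.msi_tmb_coupling
        for pid in patient_ids
    }
    arid1a_carriers = set(_allocate_arid1a(rng_v, cfg, patient_ids, pen_a_ids))
    lrp1b_carriers = {pid for pid in patient_ids if rng_v.random() < cfg.lrp1b_rate}

    variants: list[VariantCall] = []
    cnvs: list[CNVCall] = []
    msi_data: list[MsiSiteData] = []
    clinical: list[ClinicalRecord] = []
    for pid in patient_ids:
        variants.extend(
            _patient_variants(rng_v, cfg, pid, coupled[pid],
                              pid in arid1a_carriers, pid in lrp1b_carriers,
                              bg_genes, bg_weights)
        )
        cnvs.extend(_patient_cnvs(rng_v, pid))
        if with_msi_sites:
            msi_data.append(_msi_sites(rng_m, cfg, pid, msi_status[pid]))
        clinical.append(
            _clinical_record(rng_c, cfg, pid, kodama_of[pid], pid in lrp1b_carriers)
        )
    return clinical, variants, cnvs, msi_data


def generate_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[list[ClinicalRecord], list[VariantCall], list[CNVCall], list[MsiSiteData]]:
    """The main submucosal-penetrating series: ``n_pen_a + n_pen_b`` patients
    with clinical records, variants, CNVs and microsatellite site counts.

    Reproducible for a fixed config: the same (config, seed) yields identical
    output. Every generated record satisfies the invariants of its consuming
    module.
    """
    n = cfg.n_pen_a + cfg.n_pen_b
    ids = [f"EGC{i + 1:03d}" for i in range(n)]
    rngs = _substreams(cfg.seed)
    order = list(range(n))
    rngs["clinical"].shuffle(order)
    pen_a_ids = [ids[i] for i in order[: cfg.n_pen_a]]
    kodama_of = {
        pid: (Kodama.PEN_A if pid in set(pen_a_ids) else Kodama.PEN_B) for pid in ids
    }
    return _generate(cfg, ids, pen_a_ids, kodama_of, rngs, with_msi_sites=True)


def generate_tcga_like(
    cfg: SyntheticCohortConfig,
) -> tuple[list[ClinicalRecord], list[VariantCall], list[CNVCall]]:
    """The stage-I augmentation cohort: ``n_tcga_like`` patients whose
    Kodama class is unknown and who carry no microsatellite site data.

    Ids are disjoint from the main cohort by construction (distinct prefix).
    ARID1A carriers are allocated without Pen enrichment (there are no Pen
    labels to enrich into).
    """
    ids = [f"TCGA{i + 1:03d}" for i in range(cfg.n_tcga_like)]
    # independent substreams: different master-stream branch than the main cohort
    rngs = _substreams(cfg.seed + 2_000_003)
    kodama_of = {pid: Kodama.UNKNOWN for pid in ids}
    no_enrich = replace(cfg, arid1a_pen_a_enrichment=0.0)
    clinical, variants, cnvs, _ = _generate(
        no_enrich, ids, [], kodama_of, rngs, with_msi_sites=False
    )
    return clinical, variants, cnvs


def generate_gene_sets(
    cfg: SyntheticCohortConfig,
    n_pathways: int = 218,
    n_top_levels: int = 8,
    seed: int | None = None,
    min_genes: int = 4,
    max_genes: int = 20,
) -> list[PathwayDef]:
    """Pathway gene sets sampled from the panel, each under one top-level
    label; every top level is used at least once."""
    if n_top_levels > n_pathways:
        raise ValueError("n_top_levels cannot exceed n_pathways")
    if not cfg.panel:
        raise ValueError("panel must be non-empty")
    rng = (
        np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
        if seed is None
        else np.random.default_rng(seed)
    )
    tops = list(DEFAULT_TOP_LEVELS[:n_top_levels])
    tops += [f"Top Level {i + 1}" for i in range(len(tops), n_top_levels)]
    out: list[PathwayDef] = []
    panel = list(cfg.panel)
    hi = min(max_genes, len(panel))
    for i in range(n_pathways):
        size = int(rng.integers(min(min_genes, hi), hi + 1))
        genes = frozenset(rng.choice(panel, size=size, replace=False).tolist())
        top = tops[i] if i < n_top_levels else tops[int(rng.integers(n_top_levels))]
        out.append(
            PathwayDef(
                pathway_id=f"PW{i + 1:04d}",
                name=f"Synthetic pathway {i + 1}",
                genes=genes,
                top_level=top,
            )
        )
    return out
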