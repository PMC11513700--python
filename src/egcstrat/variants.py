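"""Annotated somatic small-variant and copy-number calls: reading, validation,
filtering, and cohort-level summaries.

The unit of data is one annotated somatic variant in one patient, as produced
by an upstream annotation pipeline for a targeted oncology panel. Variants
carry a protein-effect class, sequencing depth, variant allele fraction (VAF)
and an ACMG/AMP interpretation tier. Filtering follows the conventions of
targeted-panel tumor profiling: minimum depth 100x, minimum VAF 5% (both
inclusive), and exclusion of synonymous and non-exonic/non-splicing calls;
splice-site variants are retained.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Effect(str, Enum):
    """Protein-level consequence class of a small variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


class Acmg(str, Enum):
    """ACMG/AMP clinical interpretation tier."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: Tiers that never contribute to pathway scores, oncoprints or TMB in
#: benign-excluding mode.
BENIGN_CLASSES = frozenset({Acmg.BENIGN, Acmg.LIKELY_BENIGN})

#: Tiers treated as (likely) pathogenic downstream.
PATHOGENIC_CLASSES = frozenset({Acmg.PATHOGENIC, Acmg.LIKELY_PATHOGENIC})


class CnvKind(str, Enum):
    AMPLIFICATION = "amplification"
    DELETION = "deletion"


class VariantTableError(ValueError):
    """Raised for malformed variant/CNV input with the offending row number."""


@dataclass(frozen=True)
class VariantCall:
    """One annotated somatic small variant in one patient.

    Coordinates are 1-based and fully closed (VCF convention). ``vaf`` is a
    fraction in [0, 1], not a percentage.
    """

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect: Effect
    depth: int
    vaf: float
    acmg: Acmg

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r} twice")
        if self.pos < 1:
            raise ValueError(f"pos is 1-based, got {self.pos}")

    @property
    def is_benign(self) -> bool:
        return self.acmg in BENIGN_CLASSES

    @property
    def is_pathogenic(self) -> bool:
        return self.acmg in PATHOGENIC_CLASSES


@dataclass(frozen=True)
class CNVCall:
    """One gene-level copy-number call (amplification or deletion)."""

    patient_id: str
    gene: str
    kind: CnvKind


@dataclass(frozen=True)
class FilterConfig:
    """Variant retention thresholds.

    Thresholds are inclusive: a variant at exactly ``min_depth`` or exactly
    ``min_vaf`` is retained. VAF comparison absorbs a 1e-12 tolerance so that
    text percentages converted to fractions (e.g. "5%" -> 0.05) compare as
    intended.
    """

    min_depth: int = 100
    min_vaf: float = 0.05
    excluded_effects: frozenset[Effect] = frozenset(
        {Effect.SYNONYMOUS, Effect.NONCODING}
    )

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError(f"min_depth must be > 0, got {self.min_depth}")
        if not 0.0 < self.min_vaf < 1.0:
            raise ValueError(f"min_vaf must be in (0, 1), got {self.min_vaf}")


@dataclass(frozen=True)
class VariantSummary:
    """Cohort-level composition of a variant list.

    Fraction maps are over all input variants; the transition/transversion
    split is over single-nucleotide substitutions only (0.0/0.0 when there are
    none). Each fraction map sums to 1 when its denominator is positive.
    """

    n_total: int
    acmg_fractions: dict[Acmg, float]
    effect_fractions: dict[Effect, float]
    n_snv: int
    ts_fraction: float
    tv_fraction: float


_VAF_TOL = 1e-12

_TSV_COLUMNS = [
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "effect",
    "depth",
    "vaf",
    "acmg",
]

_CNV_COLUMNS = ["patient_id", "gene", "kind"]


def _parse_enum(enum_cls, label: str, row: int, column: str):
    try:
        return enum_cls(label.strip().lower())
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise VariantTableError(
            f"row {row}: unknown {column} label {label!r} (allowed: {allowed})"
        ) from None


def _parse_number(cast, value: str, row: int, column: str):
    try:
        return cast(value)
    except (TypeError, ValueError):
        raise VariantTableError(
            f"row {row}: unparseable {column} value {value!r}"
        ) from None


def _read_annovar_tsv(path: Path) -> list[VariantCall]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in _TSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise VariantTableError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        out: list[VariantCall] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                call = VariantCall(
                    patient_id=row["patient_id"].strip(),
                    gene=row["gene"].strip(),
                    chrom=row["chrom"].strip(),
                    pos=_parse_number(int, row["pos"], i, "pos"),
                    ref=row["ref"].strip().upper(),
                    alt=row["alt"].strip().upper(),
                    effect=_parse_enum(Effect, row["effect"], i, "effect"),
                    depth=_parse_number(int, row["depth"], i, "depth"),
                    vaf=_parse_number(float, row["vaf"], i, "vaf"),
                    acmg=_parse_enum(Acmg, row["acmg"], i, "acmg"),
                )
            except ValueError as exc:
                if isinstance(exc, VariantTableError):
                    raise
                raise VariantTableError(f"row {i}: {exc}") from None
            out.append(call)
    return out


#: INFO keys consumed by the VCF dialect. PATIENT and GENE are strings,
#: EFFECT and ACMG must be labels of the closed enums, VAF a fraction, DP an
#: integer read depth.
VCF_INFO_KEYS = ("PATIENT", "GENE", "EFFECT", "ACMG", "VAF", "DP")


def _read_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    out: list[VariantCall] = []
    for i, rec in enumerate(VCF(str(path)), start=1):
        info = {k: rec.INFO.get(k) for k in VCF_INFO_KEYS}
        missing = [k for k, v in info.items() if v is None]
        if missing:
            raise VariantTableError(
                f"record {i}: missing INFO key(s): {', '.join(missing)}"
            )
        if not rec.ALT:
            raise VariantTableError(f"record {i}: no ALT allele")
        try:
            call = VariantCall(
                patient_id=str(info["PATIENT"]),
                gene=str(info["GENE"]),
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF.upper(),
                alt=rec.ALT[0].upper(),
                effect=_parse_enum(Effect, str(info["EFFECT"]), i, "effect"),
                depth=int(info["DP"]),
                vaf=float(info["VAF"]),
                acmg=_parse_enum(Acmg, str(info["ACMG"]), i, "acmg"),
            )
        except ValueError as exc:
            if isinstance(exc, VariantTableError):
                raise
            raise VariantTableError(f"record {i}: {exc}") from None
        out.append(call)
    return out


def read_variant_table(path: str | Path, dialect: str = "annovar_tsv") -> list[VariantCall]:
    """Read annotated variant calls from ``path``.

    Parameters
    ----------
    path:
        Input file. For ``annovar_tsv``, a tab-separated file with header
        columns ``patient_id, gene, chrom, pos, ref, alt, effect, depth, vaf,
        acmg``. For ``vcf``, a VCF v4.x file carrying the per-variant INFO
        keys listed in :data:`VCF_INFO_KEYS`.
    dialect:
        ``"annovar_tsv"`` or ``"vcf"``.

    Unknown effect or ACMG labels are rejected with the offending row number;
    they are never silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"variant table not found: {path}")
    if dialect == "annovar_tsv":
        return _read_annovar_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r} (use 'annovar_tsv' or 'vcf')")


def read_cnv_table(path: str | Path) -> list[CNVCall]:
    """Read gene-level CNV calls from a 3-column TSV (patient_id, gene, kind)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CNV table not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in _CNV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise VariantTableError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        return [
            CNVCall(
                patient_id=row["patient_id"].strip(),
                gene=row["gene"].strip(),
                kind=_parse_enum(CnvKind, row["kind"], i, "kind"),
            )
            for i, row in enumerate(reader, start=2)
        ]


def write_variant_table(
    variants: Iterable[VariantCall],
    path: str | Path,
    retained: set[int] | None = None,
) -> None:
    """Write variants as TSV in the ``annovar_tsv`` schema.

    With ``retained`` (a set of indices into the iteration order), an extra
    boolean ``retained`` provenance column is appended (audit mode).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = list(_TSV_COLUMNS) + (["retained"] if retained is not None else [])
        writer.writerow(header)
        for i, v in enumerate(variants):
            row = [
                v.patient_id, v.gene, v.chrom, v.pos, v.ref, v.alt,
                v.effect.value, v.depth, f"{v.vaf:.6g}", v.acmg.value,
            ]
            if retained is not None:
                row.append(str(i in retained).lower())
            writer.writerow(row)


def filter_variants(
    variants: Sequence[VariantCall], cfg: FilterConfig | None = None
) -> list[VariantCall]:
    """Apply depth/VAF/effect retention thresholds; order-preserving and pure.

    A variant is retained iff ``depth >= min_depth`` and ``vaf >= min_vaf``
    (both inclusive) and its effect class is not excluded. Idempotent by
    construction.
    """
    cfg = cfg or FilterConfig()
    return [
        v
        for v in variants
        if v.depth >= cfg.min_depth
        and v.vaf >= cfg.min_vaf - _VAF_TOL
        and v.effect not in cfg.excluded_effects
    ]


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as ``"transition"``, ``"transversion"`` or
    ``"not_snv"``.

    Transitions exchange purine for purine (A<->G) or pyrimidine for
    pyrimidine (C<->T); transversions cross the two classes. Any multi-base
    allele is ``not_snv``.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if len(ref) != 1 or len(alt) != 1:
        return "not_snv"
    ref, alt = ref.upper(), alt.upper()
    for base in (ref, alt):
        if base not in "ACGT":
            raise ValueError(f"non-ACGT base in single-nucleotide allele: {base!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if (ref in _PURINES) == (alt in _PURINES):
        return "transition"
    return "transversion"


def summarize_variants(variants: Sequence[VariantCall]) -> VariantSummary:
    """Compute ACMG/effect composition and the Ts/Tv split.

    Fractions are over the variants given (callers typically pass the
    filtered list); Ts/Tv is over single-nucleotide substitutions only. An
    empty input yields ``n_total == 0`` with empty maps.
    """
    n = len(variants)
    if n == 0:
        return VariantSummary(0, {}, {}, 0, 0.0, 0.0)
    acmg_counts: dict[Acmg, int] = {}
    effect_counts: dict[Effect, int] = {}
    n_ts = n_tv = 0
    for v in variants:
        acmg_counts[v.acmg] = acmg_counts.get(v.acmg, 0) + 1
        effect_counts[v.effect] = effect_counts.get(v.effect, 0) + 1
        kind = classify_substitution(v.ref, v.alt)
        if kind == "transition":
            n_ts += 1
        elif kind == "transversion":
            n_tv += 1
    n_snv = n_ts + n_tv
    return VariantSummary(
        n_total=n,
        acmg_fractions={k: c / n for k, c in acmg_counts.items()},
        effect_fractions={k: c / n for k, c in effect_counts.items()},
        n_snv=n_snv,
        ts_fraction=n_ts / n_snv if n_snv else 0.0,
        tv_fraction=n_tv / n_snv if n_snv else 0.0,
    )


def variants_by_patient(
    variants: Iterable[VariantCall],
) -> dict[str, list[VariantCall]]:
    """Group variants by patient id, preserving input order within patients."""
    out: dict[str, list[VariantCall]] = {}
    for v in variants:
        out.setdefault(v.patient_id, []).append(v)
    return out
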