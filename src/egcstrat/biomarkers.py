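"""Per-patient tumor mutational burden (TMB) and microsatellite instability
(MSI) calling from filtered panel variants and microsatellite site counts.

TMB is eligible mutations per megabase of panel territory; the high/low cutoff
(default 10 mut/Mb) is inclusive. MSI is the fraction of usable microsatellite
sites called unstable; the MSI cutoff (default 20%) is strict, and patients
with fewer than 40 usable sites are left undetermined.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .variants import BENIGN_CLASSES, VariantCall

#: Default effective panel footprint in megabases. TMB is per-Mb by
#: definition, so this must be explicit; override it to match the panel used.
DEFAULT_PANEL_SIZE_MB = 1.33

TMB_CUTOFF = 10.0  # mut/Mb, inclusive
MSI_FRACTION_CUTOFF = 0.20  # strict
MSI_MIN_USABLE_SITES = 40


class TmbClass(str, Enum):
    HIGH = "high"
    LOW = "low"


class MsiClass(str, Enum):
    MSI = "msi"
    MSS = "mss"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class MsiSiteData:
    """Counts of usable and unstable microsatellite sites for one patient."""

    patient_id: str
    usable_sites: int
    unstable_sites: int

    def __post_init__(self) -> None:
        if self.usable_sites < 0:
            raise ValueError(f"usable_sites must be >= 0, got {self.usable_sites}")
        if not 0 <= self.unstable_sites <= self.usable_sites:
            raise ValueError(
                f"unstable_sites must be in [0, usable_sites], got "
                f"{self.unstable_sites} of {self.usable_sites}"
            )


@dataclass(frozen=True)
class BiomarkerResult:
    """TMB value/class and MSI fraction/class for one patient."""

    patient_id: str
    tmb: float
    tmb_class: TmbClass
    msi_fraction: float | None
    msi_class: MsiClass
    usable_sites: int


def compute_tmb(
    eligible_mutation_count: int,
    panel_size_mb: float = DEFAULT_PANEL_SIZE_MB,
    cutoff: float = TMB_CUTOFF,
) -> tuple[float, TmbClass]:
    """TMB in mutations per megabase and its high/low class.

    The class is high iff ``tmb >= cutoff`` (the boundary value itself is
    high).
    """
    if panel_size_mb <= 0:
        raise ValueError(f"panel_size_mb must be > 0, got {panel_size_mb}")
    if eligible_mutation_count < 0:
        raise ValueError("eligible_mutation_count must be >= 0")
    tmb = eligible_mutation_count / panel_size_mb
    return tmb, TmbClass.HIGH if tmb >= cutoff else TmbClass.LOW


def classify_msi(
    site_data: MsiSiteData,
    fraction_cutoff: float = MSI_FRACTION_CUTOFF,
    min_usable: int = MSI_MIN_USABLE_SITES,
) -> tuple[float | None, MsiClass]:
    """MSI fraction and class from site counts.

    Undetermined when fewer than ``min_usable`` sites are usable; otherwise
    MSI iff the unstable fraction strictly exceeds ``fraction_cutoff`` (a
    patient exactly at the cutoff is MSS).
    """
    if site_data.usable_sites < min_usable:
        return None, MsiClass.UNDETERMINED
    frac = site_data.unstable_sites / site_data.usable_sites
    return frac, MsiClass.MSI if frac > fraction_cutoff else MsiClass.MSS


def biomarker_table(
    variants_by_patient: Mapping[str, Sequence[VariantCall]],
    msi_by_patient: Mapping[str, MsiSiteData],
    panel_size_mb: float = DEFAULT_PANEL_SIZE_MB,
    tmb_cutoff: float = TMB_CUTOFF,
    msi_fraction_cutoff: float = MSI_FRACTION_CUTOFF,
    msi_min_usable: int = MSI_MIN_USABLE_SITES,
    count_benign: bool = True,
) -> list[BiomarkerResult]:
    """One :class:`BiomarkerResult` per patient in either input.

    Variants are assumed already filtered. By default every filtered variant
    counts toward TMB regardless of ACMG tier; with ``count_benign=False``,
    benign/likely-benign variants are excluded from the numerator. Patients
    missing MSI data get class undetermined.
    """
    patients = sorted(set(variants_by_patient) | set(msi_by_patient))
    out: list[BiomarkerResult] = []
    for pid in patients:
        variants = variants_by_patient.get(pid, [])
        if count_benign:
            n_eligible = len(variants)
        else:
            n_eligible = sum(1 for v in variants if v.acmg not in BENIGN_CLASSES)
        tmb, tmb_class = compute_tmb(n_eligible, panel_size_mb, tmb_cutoff)
        site = msi_by_patient.get(pid)
        if site is None:
            frac, msi_class, usable = None, MsiClass.UNDETERMINED, 0
        else:
            frac, msi_class = classify_msi(site, msi_fraction_cutoff, msi_min_usable)
            usable = site.usable_sites
        out.append(BiomarkerResult(pid, tmb, tmb_class, frac, msi_class, usable))
    return out


def read_msi_table(path: str | Path) -> dict[str, MsiSiteData]:
    """Read MSI site counts from a TSV (patient_id, usable_sites,
    unstable_sites); duplicate patient ids are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MSI table not found: {path}")
    out: dict[str, MsiSiteData] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = ["patient_id", "usable_sites", "unstable_sites"]
        if reader.fieldnames is None:
            return out
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"].strip()
            if pid in out:
                raise ValueError(f"row {i}: duplicate patient id {pid!r}")
            out[pid] = MsiSiteData(
                pid, int(row["usable_sites"]), int(row["unstable_sites"])
            )
    return out


def write_biomarker_table(results: Iterable[BiomarkerResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["patient_id", "tmb", "tmb_class", "msi_fraction", "msi_class", "usable_sites"]
        )
        for r in results:
            writer.writerow([
                r.patient_id,
                f"{r.tmb:.6g}",
                r.tmb_class.value,
                "" if r.msi_fraction is None else f"{r.msi_fraction:.6g}",
                r.msi_class.value,
                r.usable_sites,
            ])
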