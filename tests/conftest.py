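"""Shared fixtures: tiny hand-built variant sets and file-backed inputs."""

from __future__ import annotations

import pytest
from hypothesis import settings

from egcstrat.variants import Acmg, CNVCall, CnvKind, Effect, VariantCall

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_variant(
    patient_id: str = "P1",
    gene: str = "TP53",
    chrom: str = "17",
    pos: int = 7_578_406,
    ref: str = "C",
    alt: str = "T",
    effect: Effect = Effect.MISSENSE,
    depth: int = 500,
    vaf: float = 0.30,
    acmg: Acmg = Acmg.PATHOGENIC,
) -> VariantCall:
    return VariantCall(patient_id, gene, chrom, pos, ref, alt, effect, depth, vaf, acmg)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def small_variant_tsv(tmp_path):
    """Three well-formed rows in the documented TSV schema."""
    path = tmp_path / "variants.tsv"
    path.write_text(
        "patient_id\tgene\tchrom\tpos\tref\talt\teffect\tdepth\tvaf\tacmg\n"
        "P1\tTP53\t17\t7578406\tC\tT\tmissense\t500\t0.32\tpathogenic\n"
        "P1\tARID1A\t1\t27023003\tAG\tA\tframeshift_indel\t240\t0.18\tlikely_pathogenic\n"
        "P2\tRNF43\t17\t56435161\tG\tA\tnonsense\t150\t0.09\tvus\n"
    )
    return path


@pytest.fixture
def gene_set_files(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text(
        "PW1\tWNT signaling\tAPC\tRNF43\tCTNNB1\n"
        "PW2\tChromatin remodeling\tARID1A\tARID2\tSMARCA4\tKMT2D\n"
    )
    tmap = tmp_path / "toplevel.tsv"
    tmap.write_text("PW1\tSignal Transduction\nPW2\tGene expression (Transcription)\n")
    return gmt, tmap
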