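from __future__ import annotations

import numpy as np
import pytest

from epimap.io import (
    CloneRecord,
    Frame,
    PBSCategory,
    ReferenceORF,
    ScreenTable,
    Sense,
)

STOPS = {"TAA", "TAG", "TGA"}
CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]


def random_cds(n_codons: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "ATG" + "".join(
        CODONS[k] for k in rng.integers(0, len(CODONS), size=n_codons - 1)
    )


def make_orf(gene_id: str = "orf1", n_codons: int = 208, seed: int = 42, **kw) -> ReferenceORF:
    seq = random_cds(n_codons, seed)
    return ReferenceORF(
        id=gene_id,
        accession=f"ACC_{gene_id}",
        mrna_seq=seq,
        cds_start=kw.get("cds_start", 1),
        cds_stop=kw.get("cds_stop", len(seq)),
    )


def make_record(
    nt_start: int,
    nt_stop: int,
    clone_id: str = "c1",
    prey_name: str = "orf1",
    sense: Sense = Sense.SENSE,
    frame: Frame = Frame.IF,
    pbs: PBSCategory = PBSCategory.NA,
) -> CloneRecord:
    return CloneRecord(
        clone_id=clone_id,
        prey_name=prey_name,
        accession=f"ACC_{prey_name}",
        nt_start=nt_start,
        nt_stop=nt_stop,
        frame=frame,
        sense=sense,
        pbs=pbs,
    )


@pytest.fixture
def rab_sized_orf() -> ReferenceORF:
    """A 208-codon fully coding reference (small-GTPase sized)."""
    return make_orf()


@pytest.fixture
def tiny_screen(rab_sized_orf) -> ScreenTable:
    records = [
        make_record(37, 522, "c1"),
        make_record(4, 618, "c2"),
        make_record(38, 300, "c3"),  # OOF: starts mid-codon
    ]
    return ScreenTable("tiny", "bait", records)
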