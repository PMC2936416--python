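"""Synthetic stand-ins for the published screen tables.

The original per-screen clone lists are not publicly deposited, so these
generators rebuild screens of the same shape from the numbers the figures
print: clone totals per screen, per-gene clone counts, and the SID bounds.
Reference sequences are random-codon ORFs of the real proteins' lengths;
clone nucleotide coordinates are drawn deterministically so that the
package's mapping arithmetic — not the table itself — produces the printed
residue intervals.  Everything here is synthetic and is labelled as such;
it exercises the full analysis path on realistically shaped inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    CloneRecord,
    Frame,
    FragmentInterval,
    PBSCategory,
    ReferenceORF,
    ScreenTable,
    Sense,
)

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_orf(gene_id: str, protein_length: int, seed: int) -> ReferenceORF:
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        _CODONS[k] for k in rng.integers(0, len(_CODONS), size=protein_length - 1)
    ]
    seq = "".join(codons)
    return ReferenceORF(
        id=gene_id,
        accession=f"SYN_{gene_id}",
        mrna_seq=seq,
        cds_start=1,
        cds_stop=len(seq),
    )


def _if_clone(
    clone_id: str,
    gene: ReferenceORF,
    aa_start: int,
    aa_stop: int,
    extra_nt: int = 0,
) -> CloneRecord:
    """In-frame clone whose mapped interval is exactly [aa_start, aa_stop].

    ``extra_nt`` in {0,1,2} appends a partial codon at the 3' end (dropped
    by the floor rule) when it fits on the mRNA.
    """
    nt_start = 3 * (aa_start - 1) + gene.cds_start
    nt_stop = gene.cds_start - 1 + 3 * aa_stop
    nt_stop = min(nt_stop + extra_nt, len(gene.mrna_seq))
    return CloneRecord(
        clone_id=clone_id,
        prey_name=gene.id,
        accession=gene.accession,
        nt_start=nt_start,
        nt_stop=nt_stop,
        frame=Frame.IF,
        sense=Sense.SENSE,
        pbs=PBSCategory.NA,
    )


def _misc_clone(clone_id: str, index: int) -> CloneRecord:
    """Background clone on a prey gene outside the reference set."""
    return CloneRecord(
        clone_id=clone_id,
        prey_name=f"misc{index:03d}",
        accession=f"MISC{index:06d}",
        nt_start=50 + 7 * index,
        nt_stop=50 + 7 * index + 500,
        frame=Frame.OOF if index % 3 else Frame.IF,
        sense=Sense.ANTISENSE if index % 5 == 0 else Sense.SENSE,
        pbs=PBSCategory.NA,
    )


def _cluster_clones(
    gene: ReferenceORF,
    n: int,
    sid_start: int,
    sid_stop: int,
    prefix: str,
    seed: int,
) -> list[CloneRecord]:
    """n in-frame clones whose intervals all contain and intersect exactly to
    [sid_start, sid_stop]."""
    rng = np.random.default_rng(seed)
    L = gene.protein_length
    records = [
        _if_clone(f"{prefix}-001", gene, sid_start, min(L, sid_stop + max(0, (L - sid_stop) // 2))),
        _if_clone(f"{prefix}-002", gene, max(1, sid_start - (sid_start - 1) // 2), sid_stop),
    ]
    for i in range(2, n):
        a = int(rng.integers(1, sid_start + 1))
        b = int(rng.integers(sid_stop, L + 1))
        records.append(_if_clone(f"{prefix}-{i + 1:03d}", gene, a, b, extra_nt=int(rng.integers(0, 3))))
    return records[:n]


@dataclass
class FigureScreen:
    """A synthetic screen plus its references and the expected SID bounds."""

    references: list[ReferenceORF]
    screen: ScreenTable
    target_gene: str
    expected_sid: tuple[int, int]


def rab6_human_screen() -> FigureScreen:
    """Anti-Rab6 conformational-sensor screen, human library (synthetic).

    3 retained clones, 2 of them on Rab6 (208-aa protein); the two Rab6
    isoform clones intersect to the full core, residues 13-174.
    """
    rab6 = _random_orf("RAB6", 208, seed=601)
    records = [
        _if_clone("h-001", rab6, 13, 174),  # nt 37..522
        _if_clone("h-002", rab6, 2, 206),
        _misc_clone("h-003", 1),
    ]
    return FigureScreen(
        references=[rab6],
        screen=ScreenTable("aa2-human-synthetic", "AA2", records),
        target_gene="RAB6",
        expected_sid=(13, 174),
    )


def rab6_drosophila_screen() -> FigureScreen:
    """Anti-Rab6 screen against the fly library (synthetic): 8 clones, 4 on
    the 208-aa fly Rab6 homologue, full-core SID."""
    drab6 = _random_orf("dRAB6", 208, seed=602)
    records = _cluster_clones(drab6, 4, 13, 174, "d", seed=603)
    records += [_misc_clone(f"d-m{i}", i + 10) for i in range(4)]
    return FigureScreen(
        references=[drab6],
        screen=ScreenTable("aa2-drosophila-synthetic", "AA2", records),
        target_gene="dRAB6",
        expected_sid=(13, 174),
    )


def rab1_screen() -> FigureScreen:
    """Anti-Rab1 conformational-sensor screen (synthetic): 191 retained
    clones, 152 on the 205-aa Rab1 protein, full-core SID at residues 2-178."""
    rab1 = _random_orf("RAB1", 205, seed=101)
    records = _cluster_clones(rab1, 152, 2, 178, "r", seed=102)
    records += [_misc_clone(f"r-m{i:03d}", i + 20) for i in range(39)]
    return FigureScreen(
        references=[rab1],
        screen=ScreenTable("rof7-human-synthetic", "ROF7", records),
        target_gene="RAB1",
        expected_sid=(2, 178),
    )


GIANTIN_LENGTH = 3259  # aa, human
TA10_SID = (1300, 1549)  # 250-aa central region bracketing the binding site
TA10_NARROWED = (1462, 1540)  # 79-aa region left after tiling deconvolution


def ta10_screen() -> FigureScreen:
    """Anti-giantin screen (synthetic): 60 retained clones; the single
    high-confidence cluster holds 7 giantin clones intersecting to a 250-aa
    central SID."""
    giantin = _random_orf("GIANTIN", GIANTIN_LENGTH, seed=1001)
    records = _cluster_clones(giantin, 7, *TA10_SID, prefix="A", seed=1002)
    records += [_misc_clone(f"A-m{i:03d}", i + 30) for i in range(53)]
    return FigureScreen(
        references=[giantin],
        screen=ScreenTable("ta10-human-synthetic", "TA10", records),
        target_gene="GIANTIN",
        expected_sid=TA10_SID,
    )


def ta10_tiling_region() -> FragmentInterval:
    """Span of the smallest giantin prey clone used for gap-repair tiling."""
    return FragmentInterval("GIANTIN", TA10_SID[0], TA10_SID[1], clone_id="A-135")


MYOSIN_SID_LENGTHS = {"MYH9": 35, "MYH10": 33, "MYH11": 70}
MYOSIN_CLONE_COUNTS = {"MYH9": 196, "MYH10": 55, "MYH11": 61}
MYOSIN_PROTEIN_LENGTHS = {"MYH9": 1960, "MYH10": 1976, "MYH11": 1938}
# SID positions in a shared tail-alignment coordinate system
MYOSIN_ALIGNED_SIDS = {"MYH9": (10, 44), "MYH10": (16, 48), "MYH11": (5, 74)}
# offset of alignment column 1 on each protein (tail region placement)
_MYOSIN_TAIL_OFFSET = {"MYH9": 1720, "MYH10": 1735, "MYH11": 1700}


def sf9_screen() -> FigureScreen:
    """Anti-myosin screen (synthetic): 352 clones; 196 on non-muscle myosin
    IIA and 116 on two close homologues, yielding SIDs of 35, 33 and 70 aa."""
    rng_seed = 2001
    references, records = [], []
    for k, gene_id in enumerate(MYOSIN_SID_LENGTHS):
        orf = _random_orf(gene_id, MYOSIN_PROTEIN_LENGTHS[gene_id], seed=rng_seed + k)
        references.append(orf)
        a0, b0 = MYOSIN_ALIGNED_SIDS[gene_id]
        off = _MYOSIN_TAIL_OFFSET[gene_id]
        records += _cluster_clones(
            orf,
            MYOSIN_CLONE_COUNTS[gene_id],
            off + a0,
            off + b0,
            prefix=gene_id,
            seed=rng_seed + 10 + k,
        )
    records += [_misc_clone(f"s-m{i:03d}", i + 40) for i in range(40)]
    return FigureScreen(
        references=references,
        screen=ScreenTable("sf9-human-synthetic", "SF9", records),
        target_gene="MYH9",
        expected_sid=(
            _MYOSIN_TAIL_OFFSET["MYH9"] + MYOSIN_ALIGNED_SIDS["MYH9"][0],
            _MYOSIN_TAIL_OFFSET["MYH9"] + MYOSIN_ALIGNED_SIDS["MYH9"][1],
        ),
    )


def myosin_sid_peptides() -> dict[str, str]:
    """Synthetic homologue SID peptides sharing a near-identical 29-aa block.

    The three SIDs are windows of one master tail peptide (so the common
    block aligns without gaps); one conservative substitution inside the
    MYH10 block leaves the pairwise block identity above 93%.
    """
    rng = np.random.default_rng(77)
    master = "".join(_AA20[k] for k in rng.integers(0, 20, size=80))
    out = {}
    for gene_id, (a, b) in MYOSIN_ALIGNED_SIDS.items():
        pep = master[a - 1 : b]
        if gene_id == "MYH10":
            block_lo, block_hi = common_block()
            pos = (block_lo + 14) - a  # 0-based within this SID
            repl = "A" if pep[pos] != "A" else "G"
            pep = pep[:pos] + repl + pep[pos + 1 :]
        out[gene_id] = pep
    return out


def common_block() -> tuple[int, int]:
    """Common SID bounds in the shared alignment coordinates (29 aa)."""
    lo = max(a for a, _ in MYOSIN_ALIGNED_SIDS.values())
    hi = min(b for _, b in MYOSIN_ALIGNED_SIDS.values())
    return lo, hi
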