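"""Placing prey clones onto reference ORFs in residue coordinates.

Frame is defined relative to the source ORF: a fragment whose first base
inside the CDS starts mid-codon cannot restore the target's reading frame
downstream of the activation-domain fusion (the AD linker is assumed
frame-neutral), so it is out of frame (OOF).  Antisense inserts are OOF by
definition.  Partial codons at the fragment ends are dropped, never padded:
only fully encoded residues can contribute to an epitope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .errors import (
    DegenerateFragmentError,
    OutOfCDSError,
    UsageError,
    ValidationError,
)
from .io import CloneRecord, Frame, FragmentInterval, ReferenceORF, Sense

_SEED_K = 15
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MappingPolicy:
    """How clone sequences are placed onto references.

    mode 'coordinates' trusts the nt_start/nt_stop already in the clone
    table; 'exact_match' places the longest exact substring; 'seeded_match'
    uses 15-mer seeds with ungapped mismatch-tolerant extension.
    """

    mode: str = "coordinates"
    min_match_nt: int = 30
    allow_antisense: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("coordinates", "exact_match", "seeded_match"):
            raise UsageError(f"unknown mapping mode {self.mode!r}")
        if self.min_match_nt < 30:
            raise ValidationError("min_match_nt must be >= 30")


class Placement(NamedTuple):
    orf_id: str
    nt_start: int  # 1-based inclusive, on the reference mRNA
    nt_stop: int
    sense: Sense


def _clamp_to_cds(record: CloneRecord, orf: ReferenceORF) -> tuple[int, int]:
    """Clamp clone nt coordinates to the CDS; error if no overlap at all."""
    if record.nt_stop > len(orf.mrna_seq):
        raise ValidationError(
            f"clone {record.clone_id}: nt_stop {record.nt_stop} beyond "
            f"{orf.id} mRNA length {len(orf.mrna_seq)}"
        )
    lo = max(record.nt_start, orf.cds_start)
    hi = min(record.nt_stop, orf.cds_stop)
    if lo > hi:
        raise OutOfCDSError(
            f"clone {record.clone_id} lies entirely outside the CDS of {orf.id}"
        )
    return lo, hi


def classify_frame(record: CloneRecord, orf: ReferenceORF) -> Frame:
    """IF iff the insert is sense and starts on a codon boundary of the CDS.

    The comparison uses the clone's first base inside the CDS (fragments
    reaching into the 5' UTR are clamped to the first codon).
    """
    lo, _hi = _clamp_to_cds(record, orf)
    if record.sense is Sense.ANTISENSE:
        return Frame.OOF
    return Frame.IF if (lo - orf.cds_start) % 3 == 0 else Frame.OOF


def to_residue_interval(record: CloneRecord, orf: ReferenceORF) -> FragmentInterval:
    """Translate an in-frame clone's nt coordinates to a residue interval.

    With o = clamped nt_start - cds_start: aa_start = o/3 + 1 and the length
    is the number of complete codons in the clamped insert.
    """
    if classify_frame(record, orf) is not Frame.IF:
        raise ValidationError(
            f"clone {record.clone_id} is out of frame on {orf.id}; "
            "no residue interval exists"
        )
    lo, hi = _clamp_to_cds(record, orf)
    offset = lo - orf.cds_start
    aa_start = offset // 3 + 1
    aa_len = (hi - lo + 1) // 3
    if aa_len == 0:
        raise DegenerateFragmentError(
            f"clone {record.clone_id}: no complete codon within the CDS of {orf.id}"
        )
    return FragmentInterval(
        orf_id=orf.id,
        aa_start=aa_start,
        aa_stop=aa_start + aa_len - 1,
        clone_id=record.clone_id,
    )


# ---------------------------------------------------------------------------
# sequence placement (local replacement for a database search)
# ---------------------------------------------------------------------------

def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _extend_exact(frag: str, ref: str, fpos: int, rpos: int) -> tuple[int, int, int]:
    """Maximal exact run through the seed at (fpos, rpos).

    Returns (ref_start0, ref_stop0_exclusive, length).
    """
    i, j = fpos, rpos
    while i > 0 and j > 0 and frag[i - 1] == ref[j - 1]:
        i -= 1
        j -= 1
    fe, je = fpos, rpos
    n = min(len(frag) - fe, len(ref) - je)
    while fe - fpos < n and frag[fe] == ref[je]:
        fe += 1
        je += 1
    start_r = rpos - (fpos - i)
    return start_r, je, je - start_r


def _extend_scored(frag: str, ref: str, fpos: int, rpos: int, xdrop: int = 12):
    """Ungapped +1/-1 extension with an X-drop stop; returns best window."""
    # right extension (includes seed start position)
    best = 0
    score = 0
    best_right = -1  # offset of last included base, relative to fpos
    off = 0
    while fpos + off < len(frag) and rpos + off < len(ref):
        score += 1 if frag[fpos + off] == ref[rpos + off] else -1
        if score > best:
            best, best_right = score, off
        if score < best - xdrop:
            break
        off += 1
    # left extension
    lbest = 0
    score = 0
    best_left = 0  # negative offset of first included base
    off = 1
    while fpos - off >= 0 and rpos - off >= 0:
        score += 1 if frag[fpos - off] == ref[rpos - off] else -1
        if score > lbest:
            lbest, best_left = score, off
        if score < lbest - xdrop:
            break
        off += 1
    start_r = rpos - best_left
    stop_r = rpos + best_right + 1  # exclusive
    return start_r, stop_r, stop_r - start_r


def assign_prey(
    record_seq: str,
    references: Sequence[ReferenceORF],
    policy: MappingPolicy,
) -> Optional[Placement]:
    """Place a clone sequence on the best-matching reference.

    Returns a :class:`Placement` or ``None`` when no placement reaches
    ``policy.min_match_nt``.  Ties by matched length are broken by lowest
    orf_id, then lowest nt_start.
    """
    if policy.mode == "coordinates":
        raise UsageError("assign_prey requires a sequence-matching policy mode")
    if not references:
        raise UsageError("assign_prey needs a non-empty reference set")
    frag = record_seq.upper()
    strands = [(frag, Sense.SENSE)]
    if policy.allow_antisense:
        strands.append((revcomp(frag), Sense.ANTISENSE))
    extend = _extend_exact if policy.mode == "exact_match" else _extend_scored

    best: Optional[tuple[int, str, int, Sense]] = None  # (-len, orf_id, start, sense)
    for orf in references:
        ref = orf.mrna_seq.upper()
        ref_index = _seed_index(ref, _SEED_K)
        for query, sense in strands:
            if len(query) < _SEED_K:
                continue
            seen_diags: set[int] = set()
            for fpos in range(len(query) - _SEED_K + 1):
                for rpos in ref_index.get(query[fpos : fpos + _SEED_K], ()):
                    diag = rpos - fpos
                    if diag in seen_diags:
                        continue
                    seen_diags.add(diag)
                    start_r, stop_r, length = extend(query, ref, fpos, rpos)
                    cand = (-length, orf.id, start_r + 1, sense)
                    if best is None or cand < best:
                        best = cand
    if best is None or -best[0] < policy.min_match_nt:
        return None
    length, orf_id, nt_start, sense = -best[0], best[1], best[2], best[3]
    return Placement(orf_id=orf_id, nt_start=nt_start, nt_stop=nt_start + length - 1, sense=sense)


def map_screen(
    screen,
    references: Sequence[ReferenceORF],
) -> tuple[list[FragmentInterval], dict[str, Frame]]:
    """Map every clone of a screen to residue space (coordinates mode).

    Returns the residue intervals of all in-frame sense clones plus the
    frame classification of every clone (recomputed from coordinates; the
    table's frame column is not trusted).  Clones on prey genes absent from
    the reference set are skipped.
    """
    by_id = {orf.id: orf for orf in references}
    by_acc = {orf.accession: orf for orf in references}
    intervals: list[FragmentInterval] = []
    frames: dict[str, Frame] = {}
    for rec in screen.records:
        orf = by_id.get(rec.prey_name) or by_acc.get(rec.accession)
        if orf is None:
            continue
        frame = classify_frame(rec, orf)
        frames[rec.clone_id] = frame
        if frame is Frame.IF:
            try:
                intervals.append(to_residue_interval(rec, orf))
            except DegenerateFragmentError:
                continue
    return intervals, frames
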