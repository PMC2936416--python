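"""Tiling deconvolution of a binding region and homologue SID comparison.

Gap-repair tiling: sub-fragments of the smallest positive prey clone are
tested individually for interaction.  The binding region must lie inside
every positive tile, and no residue covered by a negative tile can belong
to it (a non-binding fragment that fully contained the region would have
bound).  The narrowed domain is the longest contiguous run left after
removing negative residues from the positive intersection.

Homologue comparison: the SIDs obtained on closely related proteins are
aligned; their intersection in alignment coordinates is the common SID and
the pairwise identity quantifies its conservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .errors import (
    InconsistentNegativesError,
    InconsistentPositivesError,
    UsageError,
    ValidationError,
)
from .io import FragmentInterval

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TilingCall:
    """One gap-repair interaction test: a tile and its reporter outcome."""

    interval: FragmentInterval
    positive: bool


@dataclass(frozen=True)
class NarrowedDomain:
    orf_id: str
    aa_start: int
    aa_stop: int
    n_positive: int
    n_negative: int

    @property
    def length(self) -> int:
        return self.aa_stop - self.aa_start + 1


def narrow_domain(calls: Sequence[TilingCall]) -> NarrowedDomain:
    """Intersect positive tiles, subtract negative residues, keep longest run.

    Raises :class:`InconsistentPositivesError` when the positives share no
    residue and :class:`InconsistentNegativesError` when negatives cover
    the whole positive intersection.
    """
    positives = [c.interval for c in calls if c.positive]
    negatives = [c.interval for c in calls if not c.positive]
    if not positives:
        raise ValidationError("narrow_domain needs at least one positive call")
    orf_ids = {c.interval.orf_id for c in calls}
    if len(orf_ids) != 1:
        raise ValidationError(f"calls span several ORFs: {sorted(orf_ids)}")
    (orf_id,) = orf_ids
    lo = max(p.aa_start for p in positives)
    hi = min(p.aa_stop for p in positives)
    if lo > hi:
        raise InconsistentPositivesError(
            "positive tiles share no residue; no single binding region fits them"
        )
    alive = np.ones(hi - lo + 1, dtype=bool)
    for n in negatives:
        a = max(n.aa_start, lo) - lo
        b = min(n.aa_stop, hi) - lo
        if a <= b:
            alive[a : b + 1] = False
    if not alive.any():
        raise InconsistentNegativesError(
            "negative tiles cover the entire positive intersection"
        )
    # longest contiguous run of surviving residues, leftmost on ties
    best_len, best_start = 0, 0
    run_len, run_start = 0, 0
    for i, ok in enumerate(alive):
        if ok:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    return NarrowedDomain(
        orf_id=orf_id,
        aa_start=lo + best_start,
        aa_stop=lo + best_start + best_len - 1,
        n_positive=len(positives),
        n_negative=len(negatives),
    )


def design_tiling(
    region: FragmentInterval,
    n_tiles: int,
    min_len: int,
    overlap_frac: float = 0.5,
    seed: int = 0,
) -> list[FragmentInterval]:
    """Deterministic set of overlapping tiles of varied length covering a region.

    Tile starts are spread evenly from the region start; every tile is at
    least ``min_len`` long, consecutive tiles overlap, the first tile
    starts at the region start and the last ends at the region stop, so the
    union equals the region.  ``overlap_frac`` bounds the extra length
    drawn on top of ``min_len``.
    """
    if n_tiles < 2:
        raise UsageError("need at least 2 tiles")
    region_len = len(region)
    if min_len > region_len:
        raise UsageError(
            f"min_len {min_len} exceeds the region length {region_len}"
        )
    if not 0.0 <= overlap_frac < 1.0:
        raise UsageError("overlap_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    span = region_len - min_len
    starts = [region.aa_start + round(i * span / (n_tiles - 1)) for i in range(n_tiles)]
    tiles: list[FragmentInterval] = []
    max_extra = max(1, int(min_len * overlap_frac))
    for i, s in enumerate(starts):
        length = min_len + int(rng.integers(0, max_extra + 1))
        stop = min(region.aa_stop, s + length - 1)
        if i == n_tiles - 1:
            stop = region.aa_stop
        # no gap to the next tile: extend to cover up to its start
        if i + 1 < n_tiles and stop < starts[i + 1] - 1:
            stop = starts[i + 1] - 1
        tiles.append(
            FragmentInterval(
                orf_id=region.orf_id, aa_start=s, aa_stop=stop, clone_id=f"tile{i + 1:02d}"
            )
        )
    return tiles


def simulate_tiling_calls(
    tiles: Sequence[FragmentInterval],
    epitope: FragmentInterval,
) -> list[TilingCall]:
    """Score tiles against a known epitope the way a reporter assay would.

    A tile binds (positive) only when it carries the whole epitope; a tile
    disjoint from the epitope is a clean negative.  Tiles covering part of
    the epitope give equivocal signals in practice and are omitted — under
    residue subtraction a partial-overlap "negative" would wrongly erase
    true epitope residues.
    """
    calls: list[TilingCall] = []
    for t in tiles:
        if t.contains(epitope):
            calls.append(TilingCall(interval=t, positive=True))
        elif not t.overlaps(epitope):
            calls.append(TilingCall(interval=t, positive=False))
    return calls


# ---------------------------------------------------------------------------
# homologue SID comparison
# ---------------------------------------------------------------------------

def _aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    return a


def _pair_identity(a_row: str, b_row: str) -> float:
    matches = cols = 0
    for x, y in zip(a_row, b_row):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == y and x != "-":
            matches += 1
    return round(100.0 * matches / cols, 1) if cols else 0.0


def align_sids(
    sid_seqs: Sequence[str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[list[str], np.ndarray]:
    """Globally align SID peptides; return the alignment and identity matrix.

    Identity is matches over aligned columns excluding dual gaps, in
    percent with one decimal.  With more than two sequences a center-star
    multiple alignment is built around the most central sequence; the
    identity matrix always comes from the pairwise global alignments.
    """
    if len(sid_seqs) < 2:
        raise ValidationError("need at least two sequences")
    seqs = [s.upper() for s in sid_seqs]
    for s in seqs:
        bad = set(s) - AMINO_ACIDS
        if bad:
            raise ValidationError(f"non-amino-acid symbol(s) {sorted(bad)}")
    aligner = _aligner(match, mismatch, gap)

    n = len(seqs)
    ident = np.full((n, n), 100.0)
    pair_rows: dict[tuple[int, int], tuple[str, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]  # first optimal; deterministic
            ri, rj = str(aln[0]), str(aln[1])
            pair_rows[(i, j)] = (ri, rj)
            ident[i, j] = ident[j, i] = _pair_identity(ri, rj)

    if n == 2:
        ri, rj = pair_rows[(0, 1)]
        return [ri, rj], ident

    # center-star MSA: merge pairwise alignments through the center sequence
    center = int(np.argmax(ident.sum(axis=1)))
    msa = [seqs[center]]
    members = [center]
    for j in range(n):
        if j == center:
            continue
        key = (center, j) if center < j else (j, center)
        rc, rj = pair_rows[key] if center < j else pair_rows[key][::-1]
        msa = _merge_into_msa(msa, rc, rj)
        members.append(j)
    order = np.argsort(members)
    return [msa[k] for k in order], ident


def _merge_into_msa(msa: list[str], center_row: str, new_row: str) -> list[str]:
    """Merge one pairwise alignment (center_row/new_row) into an MSA whose
    first row is the (gapped) center sequence."""
    merged: list[list[str]] = [[] for _ in range(len(msa) + 1)]
    i = 0  # column in existing msa
    j = 0  # column in pairwise alignment
    msa_center = msa[0]
    while i < len(msa_center) or j < len(center_row):
        c_msa = msa_center[i] if i < len(msa_center) else None
        c_pair = center_row[j] if j < len(center_row) else None
        if c_msa == "-" and (c_pair != "-" or c_pair is None):
            for k, row in enumerate(msa):
                merged[k].append(row[i])
            merged[-1].append("-")
            i += 1
        elif c_pair == "-" and (c_msa != "-" or c_msa is None):
            for k in range(len(msa)):
                merged[k].append("-")
            merged[-1].append(new_row[j])
            j += 1
        else:
            for k, row in enumerate(msa):
                merged[k].append(row[i] if i < len(row) else "-")
            merged[-1].append(new_row[j] if j < len(new_row) else "-")
            i += 1
            j += 1
    return ["".join(r) for r in merged]


def common_sid(sids: Sequence[FragmentInterval]) -> Optional[tuple[int, int]]:
    """Intersection of SID intervals in one shared coordinate system.

    Returns (start, stop) 1-based inclusive, or ``None`` when disjoint.
    """
    if len(sids) < 2:
        raise ValidationError("need at least two intervals")
    lo = max(s.aa_start for s in sids)
    hi = min(s.aa_stop for s in sids)
    if lo > hi:
        return None
    return lo, hi
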