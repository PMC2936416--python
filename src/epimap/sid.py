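"""Clustering of overlapping prey fragments and SID computation.

A cluster is a connected component of fragments from the same gene under
interval overlap (at least one shared residue).  The selected interacting
domain (SID) of a cluster is the region shared by all its fragments; it
brackets the epitope-containing region.  When chained fragments share no
single residue (a case never exhibited by real screens of this kind) the
deepest-coverage plateau is reported instead, flagged as partial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import Frame, FragmentInterval, ReferenceORF, ScreenTable
from .mapping import map_screen


@dataclass
class Cluster:
    """Connected set of overlapping fragments from one gene."""

    orf_id: str
    members: list[FragmentInterval]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster needs at least one member")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SIDResult:
    """Selected interacting domain of one cluster.

    ``complete`` is true when every member covers the interval; otherwise
    the interval is the leftmost deepest-coverage plateau and ``support``
    is its depth.
    """

    orf_id: str
    aa_start: int
    aa_stop: int
    support: int
    complete: bool

    @property
    def length(self) -> int:
        return self.aa_stop - self.aa_start + 1


def cluster_fragments(intervals: Iterable[FragmentInterval]) -> list[Cluster]:
    """Partition fragments into per-gene connected components under overlap.

    Abutting intervals ([1,10] and [11,20]) do not overlap.  Output is
    ordered by (orf_id, leftmost member start).
    """
    by_orf: dict[str, list[FragmentInterval]] = {}
    for iv in intervals:
        by_orf.setdefault(iv.orf_id, []).append(iv)
    clusters: list[Cluster] = []
    for orf_id in sorted(by_orf):
        ivs = sorted(by_orf[orf_id], key=lambda v: (v.aa_start, v.aa_stop, v.clone_id))
        current: list[FragmentInterval] = [ivs[0]]
        reach = ivs[0].aa_stop
        for iv in ivs[1:]:
            if iv.aa_start <= reach:  # shares >= 1 residue with the component
                current.append(iv)
                reach = max(reach, iv.aa_stop)
            else:
                clusters.append(Cluster(orf_id=orf_id, members=current))
                current, reach = [iv], iv.aa_stop
        clusters.append(Cluster(orf_id=orf_id, members=current))
    return clusters


def compute_sid(cluster: Cluster) -> SIDResult:
    """Intersection of all member fragments, or the deepest plateau.

    Complete case: [max of starts, min of stops] when non-empty, supported
    by every member.  Partial fallback: the leftmost interval of maximal
    coverage depth.
    """
    starts = [m.aa_start for m in cluster.members]
    stops = [m.aa_stop for m in cluster.members]
    lo, hi = max(starts), min(stops)
    if lo <= hi:
        return SIDResult(
            orf_id=cluster.orf_id,
            aa_start=lo,
            aa_stop=hi,
            support=len(cluster.members),
            complete=True,
        )
    # coverage sweep over member boundaries
    events: dict[int, int] = {}
    for m in cluster.members:
        events[m.aa_start] = events.get(m.aa_start, 0) + 1
        events[m.aa_stop + 1] = events.get(m.aa_stop + 1, 0) - 1
    depth = 0
    best_depth = 0
    best: tuple[int, int] | None = None
    positions = sorted(events)
    for pos, nxt in zip(positions, positions[1:] + [positions[-1] + 1]):
        depth += events[pos]
        if depth > best_depth:
            best_depth = depth
            best = (pos, nxt - 1)
        elif depth == best_depth and best is not None and pos == best[1] + 1:
            best = (best[0], nxt - 1)  # plateau continues across a net-zero event
    assert best is not None
    return SIDResult(
        orf_id=cluster.orf_id,
        aa_start=best[0],
        aa_stop=best[1],
        support=best_depth,
        complete=False,
    )


def percent_of_screen(gene_clones: int, total_clones: int) -> int:
    """Share of retained clones, rounded half-up to an integer percent."""
    if total_clones == 0:
        return 0
    return int(math.floor(100.0 * gene_clones / total_clones + 0.5))


def sid_report(
    screen: ScreenTable,
    references: Sequence[ReferenceORF],
    pbs_min: str | None = None,
) -> pd.DataFrame:
    """Per-gene summary: clone counts, percent of screen, and the SID.

    SIDs are computed from in-frame sense fragments only; out-of-frame and
    antisense clones count toward totals but not toward the domain.  When a
    gene yields several clusters the best-supported one (leftmost on ties)
    provides the reported SID.  ``pbs_min`` optionally restricts the SID to
    clones at or above a table-supplied category (A < B < ... < F).
    """
    order = "ABCDEF"
    if pbs_min is not None:
        keep = {
            r.clone_id
            for r in screen.records
            if r.pbs.value in order and order.index(r.pbs.value) <= order.index(pbs_min)
        }
    else:
        keep = None

    intervals, frames = map_screen(screen, references)
    if keep is not None:
        intervals = [iv for iv in intervals if iv.clone_id in keep]

    by_name: dict[str, ReferenceORF] = {o.id: o for o in references}
    by_acc = {o.accession: o for o in references}
    total = len(screen.records)
    gene_of: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    for rec in screen.records:
        orf = by_name.get(rec.prey_name) or by_acc.get(rec.accession)
        gene = orf.id if orf is not None else rec.prey_name
        gene_of[rec.clone_id] = gene
        c = counts.setdefault(gene, {"n_clones": 0, "n_if": 0})
        c["n_clones"] += 1
        if frames.get(rec.clone_id) is Frame.IF:
            c["n_if"] += 1

    best_sid: dict[str, SIDResult] = {}
    for cl in cluster_fragments(intervals):
        sid = compute_sid(cl)
        prev = best_sid.get(cl.orf_id)
        if prev is None or sid.support > prev.support:
            best_sid[cl.orf_id] = sid

    rows = []
    for gene in sorted(counts, key=lambda g: (-counts[g]["n_clones"], g)):
        sid = best_sid.get(gene)
        rows.append(
            {
                "orf_id": gene,
                "n_clones": counts[gene]["n_clones"],
                "n_if": counts[gene]["n_if"],
                "percent": percent_of_screen(counts[gene]["n_clones"], total),
                "sid_start": sid.aa_start if sid else pd.NA,
                "sid_stop": sid.aa_stop if sid else pd.NA,
                "sid_length": sid.length if sid else pd.NA,
                "sid_support": sid.support if sid else pd.NA,
                "sid_complete": sid.complete if sid else pd.NA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "orf_id",
            "n_clones",
            "n_if",
            "percent",
            "sid_start",
            "sid_stop",
            "sid_length",
            "sid_support",
            "sid_complete",
        ],
    )
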