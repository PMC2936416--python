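"""Pipeline driver: map -> cluster -> SID -> score -> report.

Produces the per-screen summary a screen analyst reads: clone totals, one
row per prey gene with its share of the screen, independent-fragment count,
confidence category and SID, plus a text sketch of the fragments aligned
under the ORF ruler.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import Frame, FragmentInterval, ReferenceORF, ScreenTable
from .mapping import map_screen
from .pbs import (
    DEFAULT_TAU,
    DEFAULT_THRESHOLDS,
    NullModel,
    PBSResult,
    score_gene,
)
from .sid import SIDResult, cluster_fragments, compute_sid, percent_of_screen

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "orf_id",
    "n_clones",
    "n_if",
    "percent",
    "n_independent",
    "pbs_category",
    "evalue",
    "sid_start",
    "sid_stop",
    "sid_length",
    "sid_support",
    "sid_complete",
]


@dataclass
class PipelineConfig:
    """Scoring knobs of one pipeline run (mapping is coordinates-based)."""

    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    tau: float = DEFAULT_TAU
    mc_draws: int = 20_000
    seed: int = 0
    artifacts: frozenset[str] = frozenset()
    connectivity: Optional[Mapping[str, float]] = None
    pbs_min: Optional[str] = None
    trust_pbs: bool = False  # keep table-supplied categories instead of rescoring


@dataclass
class ScreenReport:
    screen_id: str
    bait_name: str
    totals: dict[str, int]
    table: pd.DataFrame
    sketch: str = ""

    def top_gene(self) -> Optional[str]:
        if self.table.empty:
            return None
        return str(self.table.iloc[0]["orf_id"])


def fragment_sketch(
    orf: ReferenceORF,
    intervals: Sequence[FragmentInterval],
    sid: Optional[SIDResult] = None,
    width: int = 72,
) -> str:
    """Text ruler of fragments aligned under one ORF, SID marked with '='."""
    L = orf.protein_length
    scale = width / L

    def col(aa: int) -> int:
        return min(width - 1, int((aa - 1) * scale))

    lines = [f"{orf.id}  1{'-' * (width - len(str(L)) - 1)}{L}"]
    for iv in sorted(intervals, key=lambda v: (v.aa_start, v.aa_stop)):
        a, b = col(iv.aa_start), col(iv.aa_stop)
        bar = " " * a + "#" * max(1, b - a + 1)
        lines.append(f"{bar:<{width}}  {iv.clone_id} [{iv.aa_start},{iv.aa_stop}]")
    if sid is not None:
        a, b = col(sid.aa_start), col(sid.aa_stop)
        bar = " " * a + "=" * max(1, b - a + 1)
        lines.append(
            f"{bar:<{width}}  SID [{sid.aa_start},{sid.aa_stop}] "
            f"support={sid.support} {'complete' if sid.complete else 'partial'}"
        )
    return "\n".join(lines)


def run_pipeline(
    references: Sequence[ReferenceORF],
    screen: ScreenTable,
    config: PipelineConfig | None = None,
) -> ScreenReport:
    """Full analysis of one screen; deterministic under config.seed."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()

    intervals, frames = map_screen(screen, references)
    if config.pbs_min is not None:
        order = "ABCDEF"
        keep = {
            r.clone_id
            for r in screen.records
            if r.pbs.value in order
            and order.index(r.pbs.value) <= order.index(config.pbs_min)
        }
        intervals = [iv for iv in intervals if iv.clone_id in keep]
    logger.info(
        "mapped %d/%d clones in frame (%.2fs)",
        sum(1 for f in frames.values() if f is Frame.IF),
        len(screen.records),
        time.perf_counter() - t0,
    )

    clusters = cluster_fragments(intervals)
    null = NullModel.from_references(
        references,
        total_clones=max(len(screen.records), 1),
        mc_draws=config.mc_draws,
        seed=config.seed,
    )

    # best cluster per gene = most members, leftmost on ties
    best: dict[str, tuple] = {}
    for cl in clusters:
        key = (-len(cl.members), min(m.aa_start for m in cl.members))
        if cl.orf_id not in best or key < best[cl.orf_id][0]:
            best[cl.orf_id] = (key, cl)

    by_id = {o.id: o for o in references}
    by_acc = {o.accession: o for o in references}
    counts: dict[str, dict[str, int]] = {}
    for rec in screen.records:
        orf = by_id.get(rec.prey_name) or by_acc.get(rec.accession)
        gene = orf.id if orf is not None else rec.prey_name
        c = counts.setdefault(gene, {"n_clones": 0, "n_if": 0})
        c["n_clones"] += 1
        if frames.get(rec.clone_id) is Frame.IF:
            c["n_if"] += 1

    # table-supplied categories (best letter per gene), used with trust_pbs
    table_pbs: dict[str, str] = {}
    if config.trust_pbs:
        for rec in screen.records:
            orf = by_id.get(rec.prey_name) or by_acc.get(rec.accession)
            gene = orf.id if orf is not None else rec.prey_name
            if rec.pbs.value in "ABCDEF":
                cur = table_pbs.get(gene)
                if cur is None or rec.pbs.value < cur:
                    table_pbs[gene] = rec.pbs.value

    total = len(screen.records)
    rows = []
    sids: dict[str, SIDResult] = {}
    scores: dict[str, PBSResult] = {}
    for gene, (_, cl) in best.items():
        sids[gene] = compute_sid(cl)
        scores[gene] = score_gene(
            cl,
            null,
            artifacts=config.artifacts,
            connectivity=config.connectivity,
            thresholds=config.thresholds,
            tau=config.tau,
        )
    for gene in counts:
        sid = sids.get(gene)
        sc = scores.get(gene)
        rows.append(
            {
                "orf_id": gene,
                "n_clones": counts[gene]["n_clones"],
                "n_if": counts[gene]["n_if"],
                "percent": percent_of_screen(counts[gene]["n_clones"], total),
                "n_independent": sc.n_independent if sc else 0,
                "pbs_category": table_pbs.get(gene, sc.category if sc else "NA")
                if config.trust_pbs
                else (sc.category if sc else "NA"),
                "evalue": sc.evalue if sc else float("nan"),
                "sid_start": sid.aa_start if sid else pd.NA,
                "sid_stop": sid.aa_stop if sid else pd.NA,
                "sid_length": sid.length if sid else pd.NA,
                "sid_support": sid.support if sid else pd.NA,
                "sid_complete": sid.complete if sid else pd.NA,
            }
        )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if not table.empty:
        table = table.sort_values(
            ["evalue", "orf_id"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)

    n_if = sum(1 for f in frames.values() if f is Frame.IF)
    totals = {
        "clones": total,
        "if": n_if,
        "oof": sum(1 for f in frames.values() if f is Frame.OOF),
        "unmapped": total - len(frames),
    }
    sketch = ""
    top = table.iloc[0]["orf_id"] if not table.empty else None
    if top in by_id and top in best:
        sketch = fragment_sketch(by_id[top], best[top][1].members, sids.get(top))
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return ScreenReport(
        screen_id=screen.screen_id,
        bait_name=screen.bait_name,
        totals=totals,
        table=table,
        sketch=sketch,
    )


def write_report_tsv(report: ScreenReport, path) -> None:
    """Byte-stable TSV emission of a report table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# screen: {report.screen_id}\tbait: {report.bait_name}\n")
        fh.write(
            "# totals: clones={clones} if={if} oof={oof} unmapped={unmapped}\n".format(
                **report.totals
            )
        )
        df = report.table.copy()
        if not df.empty:
            df["evalue"] = df["evalue"].map(lambda v: f"{v:.6e}")
        df.to_csv(fh, sep="\t", index=False)
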