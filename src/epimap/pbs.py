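"""Confidence scoring of prey genes under a competition-for-bait null model.

In a saturated screen of a random-primed fragment library, every retained
clone is one draw from a pool in which prey genes compete for the bait.
Under the null hypothesis that retention is unspecific, a gene collects
clones in proportion to its length and the clones' positions are
independent and uniform.  A specific interaction shows up as (i) more
independent fragments of one gene than the length-weighted null predicts
and (ii) those fragments piling up over a common region.  The score
combines both signals:

    evalue = G * P(X >= n_d)             * P(common overlap)
             ^    X ~ Binomial(N, w_g)     n_d random placements
             Bonferroni over G genes

Small e-values are binned into categories A (best) through D; E marks
promiscuous prey recurring across unrelated screens, and F marks
experimentally established two-hybrid artifacts.  Fragments sharing a 5'
start are treated as replication duplicates of one cDNA event, so n_d
counts distinct starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, UnknownGeneError, ValidationError
from .io import FragmentInterval, ReferenceORF
from .sid import Cluster

DEFAULT_THRESHOLDS = (1e-10, 1e-5, 1e-2)  # tA, tB, tC on the e-value
DEFAULT_TAU = 0.25  # connectivity fraction that flags category E
ENUMERATION_LIMIT = 10**6


@dataclass
class NullModel:
    """Length-weighted null for clone retention in one screen."""

    gene_lengths: dict[str, int]
    total_clones: int
    mc_draws: int = 20_000
    seed: int = 0
    gene_weights: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.total_clones < 1:
            raise ValidationError("total_clones must be >= 1")
        if self.mc_draws < 1000:
            raise ValidationError("mc_draws must be >= 1000")
        total = float(sum(self.gene_lengths.values()))
        if total <= 0:
            raise ValidationError("need at least one gene with positive length")
        self.gene_weights = {g: l / total for g, l in self.gene_lengths.items()}
        assert abs(sum(self.gene_weights.values()) - 1.0) < 1e-9

    @property
    def n_genes(self) -> int:
        return len(self.gene_lengths)

    @classmethod
    def from_references(
        cls,
        references: Sequence[ReferenceORF],
        total_clones: int,
        mc_draws: int = 20_000,
        seed: int = 0,
    ) -> "NullModel":
        return cls(
            gene_lengths={o.id: o.protein_length for o in references},
            total_clones=total_clones,
            mc_draws=mc_draws,
            seed=seed,
        )


@dataclass(frozen=True)
class PBSResult:
    orf_id: str
    n_independent: int
    p_count: float
    p_overlap: float
    evalue: float
    category: str


def count_independent(members: Iterable[FragmentInterval]) -> int:
    """Distinct 5' starts among a gene's fragments (independent cDNA events)."""
    return len({m.aa_start for m in members})


def binomial_upper_tail(n_d: int, n_clones: int, weight: float) -> float:
    """P(X >= n_d) for X ~ Binomial(n_clones, weight); 1.0 when n_d <= 0."""
    if n_d <= 0:
        return 1.0
    return float(stats.binom.sf(n_d - 1, n_clones, weight))


def overlap_probability(
    lengths: Sequence[int],
    protein_length: int,
    mc_draws: int = 20_000,
    seed: int = 0,
) -> float:
    """Probability that independently placed fragments share >= 1 residue.

    Fragment i of length l_i starts uniformly on {1..L-l_i+1}; the event is
    max(starts) <= min(stops).  Exhaustive enumeration when the start-tuple
    space is at most 10^6, Monte Carlo otherwise (estimate floored at
    1/mc_draws so downstream e-values stay positive).
    """
    if not lengths:
        raise ValidationError("need at least one fragment length")
    lengths = [int(l) for l in lengths]
    for l in lengths:
        if l < 1 or l > protein_length:
            raise ValidationError(
                f"fragment length {l} invalid on a protein of {protein_length} aa"
            )
    if len(lengths) == 1:
        return 1.0
    ranges = [protein_length - l + 1 for l in lengths]
    space = 1
    for r in ranges:
        space *= r
    if space <= ENUMERATION_LIMIT:
        hits = 0
        for starts in product(*(range(1, r + 1) for r in ranges)):
            if max(starts) <= min(s + l - 1 for s, l in zip(starts, lengths)):
                hits += 1
        return hits / space
    rng = np.random.default_rng(seed)
    starts = np.column_stack(
        [rng.integers(1, r + 1, size=mc_draws) for r in ranges]
    )
    stops = starts + np.asarray(lengths) - 1
    hits = int(np.sum(starts.max(axis=1) <= stops.min(axis=1)))
    return max(hits, 1) / mc_draws


def representative_fragments(
    members: Sequence[FragmentInterval],
) -> list[FragmentInterval]:
    """Longest fragment per distinct 5' start (duplicates collapsed)."""
    best: dict[int, FragmentInterval] = {}
    for m in members:
        cur = best.get(m.aa_start)
        if cur is None or len(m) > len(cur):
            best[m.aa_start] = m
    return [best[s] for s in sorted(best)]


def assign_category(
    evalue: float,
    n_independent: int,
    gene: str,
    artifacts: Iterable[str] = (),
    connectivity: Mapping[str, float] | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    tau: float = DEFAULT_TAU,
) -> str:
    """Category letter: registry overrides first, then e-value bins.

    F = known artifact registry; E = connectivity >= tau across screens;
    D = single independent fragment (no multiplicity evidence) or weak
    e-value; A/B/C = e-value at or below tA/tB/tC.
    """
    t_a, t_b, t_c = thresholds
    if not t_a < t_b < t_c:
        raise ValidationError("thresholds must satisfy tA < tB < tC")
    if gene in set(artifacts):
        return "F"
    if connectivity is not None and connectivity.get(gene, 0.0) >= tau:
        return "E"
    if n_independent <= 1:
        return "D"
    if evalue <= t_a:
        return "A"
    if evalue <= t_b:
        return "B"
    if evalue <= t_c:
        return "C"
    return "D"


def score_gene(
    cluster: Cluster,
    null: NullModel,
    artifacts: Iterable[str] = (),
    connectivity: Mapping[str, float] | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    tau: float = DEFAULT_TAU,
) -> PBSResult:
    """Score one cluster against the screen's null model."""
    gene = cluster.orf_id
    if gene not in null.gene_lengths:
        raise UnknownGeneError(f"gene {gene!r} absent from the null model")
    reps = representative_fragments(cluster.members)
    n_d = len(reps)
    p_count = binomial_upper_tail(n_d, null.total_clones, null.gene_weights[gene])
    p_overlap = overlap_probability(
        [len(r) for r in reps],
        null.gene_lengths[gene],
        mc_draws=null.mc_draws,
        seed=null.seed,
    )
    evalue = null.n_genes * p_count * p_overlap
    category = assign_category(
        evalue, n_d, gene, artifacts, connectivity, thresholds, tau
    )
    return PBSResult(
        orf_id=gene,
        n_independent=n_d,
        p_count=p_count,
        p_overlap=p_overlap,
        evalue=evalue,
        category=category,
    )


def read_artifact_registry(path) -> set[str]:
    """One gene id per line; '#' comments allowed."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                if "\t" in line:
                    raise FormatError(f"{path}: artifact registry is one id per line")
                genes.add(line)
    return genes


def connectivity_from_registry(path) -> dict[str, float]:
    """Fraction of registered screens in which each prey gene recurs.

    TSV with columns screen_id and orf_id, one row per (screen, gene).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "screen_id" not in df.columns or "orf_id" not in df.columns:
        raise FormatError(f"{path}: registry needs columns screen_id and orf_id")
    n_screens = df["screen_id"].nunique()
    if n_screens == 0:
        return {}
    per_gene = df.drop_duplicates().groupby("orf_id")["screen_id"].nunique()
    return {g: c / n_screens for g, c in per_gene.items()}
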