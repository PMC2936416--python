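"""Synthetic two-hybrid screens with the statistical structure the analysis assumes.

The simulator emulates a saturated screen of a random-primed cDNA library:
fragment 5' ends fall uniformly along transcripts, insert lengths follow a
truncated lognormal with a mean of 750 nt (real libraries of this kind
average 700-800 bp), and genes contribute material in proportion to their
length.  Selection is a hard containment rule: a retained on-target clone
must be in frame and its residue interval must contain the epitope (linear
mode) or the whole folding core (conformational mode); a fraction ``beta``
of retained clones is unselected background.  This minimal mechanism
produces the two regimes real screens show — tight SIDs around linear
epitopes, and full-core SIDs for conformational sensors.

What it does not model: mating efficiency, colony counts, affinity,
sequencing errors, or biologically structured background (the background is
length-weighted uniform).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import UsageError, ValidationError
from .io import (
    CloneRecord,
    Frame,
    FragmentInterval,
    PBSCategory,
    ReferenceORF,
    ScreenTable,
    Sense,
)
from .mapping import classify_frame

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults mirror a scaled-down random-primed library screen: 100 genes
    of 120-600 aa, inserts lognormal around 750 nt truncated to
    [150, 3000] nt, and a 5% unselected background.
    """

    n_genes: int = 100
    gene_length_range: tuple[int, int] = (120, 600)  # aa
    target_orf_id: str = "target"
    epitope: FragmentInterval = field(
        default_factory=lambda: FragmentInterval("target", 300, 320)
    )
    mode: str = "linear"  # or "conformational"
    core: Optional[FragmentInterval] = None  # required region in conformational mode
    n_clones_retained: int = 30
    background_rate: float = 0.05
    insert_len_mean_nt: float = 750.0
    insert_len_sigma: float = 0.5
    insert_len_bounds: tuple[int, int] = (150, 3000)
    frame_random: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "conformational"):
            raise UsageError(f"unknown mode {self.mode!r}")
        if self.mode == "conformational" and self.core is None:
            raise ValidationError("conformational mode needs a core interval")
        if not 0.0 <= self.background_rate < 1.0:
            raise ValidationError("background_rate must be in [0, 1)")
        lo, hi = self.insert_len_bounds
        if lo >= hi:
            raise ValidationError("insert_len_bounds must be ordered")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValidationError("gene_length_range must be ordered")
        if self.n_genes < 1 or self.n_clones_retained < 1:
            raise ValidationError("n_genes and n_clones_retained must be >= 1")
        region = self.required_region
        if region.orf_id != self.target_orf_id:
            raise ValidationError("epitope/core must lie on the target ORF")

    @property
    def required_region(self) -> FragmentInterval:
        return self.core if (self.mode == "conformational" and self.core) else self.epitope


def simulate_transcriptome(config: SimConfig) -> list[ReferenceORF]:
    """Random-codon reference ORFs (no internal stops), deterministic under seed.

    The target ORF is first in file order and long enough to carry the
    epitope/core; all sequences are fully coding (cds_start = 1).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    region = config.required_region
    orfs: list[ReferenceORF] = []
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        if i == 0:
            gene_id = config.target_orf_id
            length = max(length, region.aa_stop)
        else:
            gene_id = f"gene{i:04d}"
        codons = ["ATG"] + [
            _CODONS[k] for k in rng.integers(0, len(_CODONS), size=length - 1)
        ]
        seq = "".join(codons)
        orfs.append(
            ReferenceORF(
                id=gene_id,
                accession=f"SYN{i:06d}",
                mrna_seq=seq,
                cds_start=1,
                cds_stop=len(seq),
            )
        )
    return orfs


def sample_insert_lengths(
    n: int,
    mean_nt: float = 750.0,
    sigma: float = 0.5,
    bounds: tuple[int, int] = (150, 3000),
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> np.ndarray:
    """Truncated lognormal insert lengths with the requested (untruncated) mean.

    The underlying normal has mu = ln(mean) - sigma^2/2 so the lognormal
    mean equals ``mean_nt``; draws outside ``bounds`` are resampled.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mu = np.log(mean_nt) - sigma**2 / 2.0
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mean=mu, sigma=sigma, size=max(n - filled, 64))
        keep = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = np.round(keep[:take]).astype(int)
        filled += take
    return out


def _draw_fragment(
    rng: np.random.Generator,
    orfs: Sequence[ReferenceORF],
    weights: np.ndarray,
    config: SimConfig,
) -> tuple[ReferenceORF, int, int]:
    gene = orfs[int(rng.choice(len(orfs), p=weights))]
    mrna_len = len(gene.mrna_seq)
    start = int(rng.integers(1, mrna_len + 1))
    length = int(
        sample_insert_lengths(
            1,
            config.insert_len_mean_nt,
            config.insert_len_sigma,
            config.insert_len_bounds,
            rng=rng,
        )[0]
    )
    stop = min(start + length - 1, mrna_len)
    return gene, start, stop


def simulate_screen(
    config: SimConfig, references: Sequence[ReferenceORF]
) -> ScreenTable:
    """Draw exactly ``n_clones_retained`` clones by rejection sampling.

    With probability 1-beta a draw is repeated until it is an in-frame
    sense fragment of the target whose residue interval contains the
    required region; with probability beta any fragment of any gene (either
    orientation) is retained as background.  The emitted schema matches the
    clone-table reader's.
    """
    by_id = {o.id: o for o in references}
    if config.target_orf_id not in by_id:
        raise ValidationError(f"references lack the target {config.target_orf_id!r}")
    region = config.required_region
    if 3 * len(region) > config.insert_len_bounds[1]:
        raise ValidationError(
            "required region is longer than the largest possible insert; "
            "the retention rule cannot be satisfied"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lengths_nt = np.array([len(o.mrna_seq) for o in references], dtype=float)
    weights = lengths_nt / lengths_nt.sum()
    target = by_id[config.target_orf_id]

    records: list[CloneRecord] = []
    for i in range(config.n_clones_retained):
        clone_id = f"clone{i + 1:04d}"
        if rng.random() < config.background_rate:
            gene, start, stop = _draw_fragment(rng, references, weights, config)
            sense = Sense.SENSE if rng.random() < 0.5 else Sense.ANTISENSE
        else:
            # Rejection sampling conditioned on retention.  Given retention
            # the clone is on the target, so the gene draw is skipped (start
            # and length are independent of gene identity); the remaining
            # rejection enforces in-frame placement containing the region.
            gene, sense = target, Sense.SENSE
            mrna_len = len(target.mrna_seq)
            while True:
                start = int(rng.integers(1, mrna_len + 1))
                length = int(
                    sample_insert_lengths(
                        1,
                        config.insert_len_mean_nt,
                        config.insert_len_sigma,
                        config.insert_len_bounds,
                        rng=rng,
                    )[0]
                )
                stop = min(start + length - 1, mrna_len)
                if (start - target.cds_start) % 3 != 0:
                    continue
                aa_start = (start - target.cds_start) // 3 + 1
                aa_stop = aa_start + (min(stop, target.cds_stop) - start + 1) // 3 - 1
                if aa_start <= region.aa_start and aa_stop >= region.aa_stop:
                    break
        frame = _frame_label(rng, config, gene, start, stop, sense, clone_id)
        records.append(
            CloneRecord(
                clone_id=clone_id,
                prey_name=gene.id,
                accession=gene.accession,
                nt_start=start,
                nt_stop=stop,
                frame=frame,
                sense=sense,
                pbs=PBSCategory.NA,
            )
        )
    return ScreenTable(
        screen_id=f"sim-{config.mode}-seed{config.seed}",
        bait_name="synthetic-bait",
        records=records,
    )


def _frame_label(rng, config, gene, start, stop, sense, clone_id) -> Frame:
    """Frame column of the emitted table.

    Normally recomputed from the coordinates; with ``frame_random`` the
    label is drawn uniformly over the three frames instead (emulating
    annotation noise — the label then decouples from the coordinates).
    """
    if config.frame_random:
        return Frame.IF if rng.integers(0, 3) == 0 else Frame.OOF
    probe = CloneRecord(
        clone_id=clone_id,
        prey_name=gene.id,
        accession=gene.accession,
        nt_start=start,
        nt_stop=stop,
        frame=Frame.IF,
        sense=sense,
        pbs=PBSCategory.NA,
    )
    return classify_frame(probe, gene)


def write_truth(config: SimConfig, path) -> None:
    """Planted ground truth for recovery scoring (JSON)."""
    region = config.required_region
    payload = {
        "target": config.target_orf_id,
        "mode": config.mode,
        "epitope": [config.epitope.aa_start, config.epitope.aa_stop],
        "required_region": [region.aa_start, region.aa_stop],
        "background_rate": config.background_rate,
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
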