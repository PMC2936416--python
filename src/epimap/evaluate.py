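"""Batch recovery experiments on simulated screens.

These drive the whole pipeline over many seeded simulations and measure how
often the analysis recovers the planted truth: SID containment of the
epitope, confidence category of the planted target, full-core SIDs in
conformational mode, and tiling deconvolution accuracy.
"""

from __future__ import annotations

from dataclasses import replace

from .io import FragmentInterval
from .narrowing import design_tiling, narrow_domain, simulate_tiling_calls
from .pipeline import PipelineConfig, run_pipeline
from .simulate import SimConfig, simulate_screen, simulate_transcriptome


def _target_sid_row(report, target: str):
    t = report.table
    rows = t[t["orf_id"] == target]
    if rows.empty or rows.iloc[0].isna()["sid_start"]:
        return None
    return rows.iloc[0]


def screen_recovery(
    n_runs: int,
    base_seed: int,
    config: SimConfig | None = None,
) -> dict[str, float]:
    """Simulate ``n_runs`` screens and score pipeline recovery of the truth.

    Returns rates in percent: ``containment`` (target SID covers the
    required region), ``category_a`` (planted target scored A), and
    ``background_d_or_worse`` (no background gene scored better than D).
    Run i uses seed ``base_seed + i``.
    """
    config = config or SimConfig()
    region = config.required_region
    contained = cat_a = bg_clean = 0
    for i in range(n_runs):
        cfg = replace(config, seed=base_seed + i)
        refs = simulate_transcriptome(cfg)
        screen = simulate_screen(cfg, refs)
        report = run_pipeline(refs, screen, PipelineConfig(seed=cfg.seed))
        row = _target_sid_row(report, cfg.target_orf_id)
        if row is not None and (
            row["sid_start"] <= region.aa_start and row["sid_stop"] >= region.aa_stop
        ):
            contained += 1
        t = report.table
        target_rows = t[t["orf_id"] == cfg.target_orf_id]
        if not target_rows.empty and target_rows.iloc[0]["pbs_category"] == "A":
            cat_a += 1
        bg = t[(t["orf_id"] != cfg.target_orf_id) & (t["pbs_category"] != "NA")]
        if (bg["pbs_category"].isin(["D", "E", "F"])).all():
            bg_clean += 1
    return {
        "containment": 100.0 * contained / n_runs,
        "category_a": 100.0 * cat_a / n_runs,
        "background_d_or_worse": 100.0 * bg_clean / n_runs,
        "n_runs": n_runs,
    }


def tiling_recovery(
    n_runs: int,
    base_seed: int,
    region: FragmentInterval | None = None,
    epitope_len: int = 21,
    n_tiles: int = 17,
    min_len: int = 60,
) -> dict[str, float]:
    """Tile a region, score tiles against a planted epitope, narrow, and
    check that the narrowed domain contains the epitope and avoids every
    negative tile.  Rates in percent over ``n_runs`` seeded runs."""
    import numpy as np

    region = region or FragmentInterval("orf", 1, 243)
    ok_contain = ok_disjoint = 0
    for i in range(n_runs):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        epi_start = int(rng.integers(region.aa_start, region.aa_stop - epitope_len + 2))
        epitope = FragmentInterval(region.orf_id, epi_start, epi_start + epitope_len - 1)
        tiles = design_tiling(region, n_tiles=n_tiles, min_len=min_len, seed=seed)
        calls = simulate_tiling_calls(tiles, epitope)
        dom = narrow_domain(calls)
        if dom.aa_start <= epitope.aa_start and dom.aa_stop >= epitope.aa_stop:
            ok_contain += 1
        negatives = [c.interval for c in calls if not c.positive]
        if all(
            n.aa_stop < dom.aa_start or n.aa_start > dom.aa_stop for n in negatives
        ):
            ok_disjoint += 1
    return {
        "containment": 100.0 * ok_contain / n_runs,
        "negative_disjoint": 100.0 * ok_disjoint / n_runs,
        "n_runs": n_runs,
    }
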