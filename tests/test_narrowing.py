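from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimap.errors import (
    InconsistentNegativesError,
    InconsistentPositivesError,
    UsageError,
    ValidationError,
)
from epimap.io import FragmentInterval
from epimap.narrowing import (
    TilingCall,
    align_sids,
    common_sid,
    design_tiling,
    narrow_domain,
    simulate_tiling_calls,
)


def iv(a, b, orf="gtn"):
    return FragmentInterval(orf, a, b)


def call(a, b, positive, orf="gtn"):
    return TilingCall(interval=iv(a, b, orf), positive=positive)


def oracle_narrow(calls):
    """Residue-set oracle for the narrowed domain (longest surviving run)."""
    positives = [c.interval for c in calls if c.positive]
    lo = max(p.aa_start for p in positives)
    hi = min(p.aa_stop for p in positives)
    residues = set(range(lo, hi + 1))
    for c in calls:
        if not c.positive:
            residues -= set(range(c.interval.aa_start, c.interval.aa_stop + 1))
    runs = []
    for r in sorted(residues):
        if runs and r == runs[-1][1] + 1:
            runs[-1][1] = r
        else:
            runs.append([r, r])
    if not runs:
        return None
    return max(runs, key=lambda ab: (ab[1] - ab[0], -ab[0]))


class TestNarrowDomain:
    def test_negative_control_leaves_79_residue_region(self):
        calls = [
            call(1400, 1600, True),
            call(1462, 1560, True),
            call(1300, 1540, True),
            call(1399, 1461, False),  # upstream negative control
        ]
        dom = narrow_domain(calls)
        assert (dom.aa_start, dom.aa_stop, dom.length) == (1462, 1540, 79)
        assert (dom.n_positive, dom.n_negative) == (3, 1)

    def test_internal_negative_keeps_longest_run(self):
        dom = narrow_domain(
            [call(100, 200, True), call(150, 250, True), call(160, 170, False)]
        )
        assert (dom.aa_start, dom.aa_stop) == (171, 200)

    def test_negative_covering_everything_is_inconsistent(self):
        with pytest.raises(InconsistentNegativesError):
            narrow_domain([call(10, 50, True), call(5, 60, False)])

    def test_disjoint_positives_are_inconsistent(self):
        with pytest.raises(InconsistentPositivesError):
            narrow_domain([call(1, 10, True), call(20, 30, True)])

    def test_needs_a_positive_call(self):
        with pytest.raises(ValidationError):
            narrow_domain([call(1, 10, False)])

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_residue_set_oracle_and_shrinks_monotonically(self, data):
        n_pos = data.draw(st.integers(1, 4))
        positives = []
        for _ in range(n_pos):
            a = data.draw(st.integers(1, 80))
            positives.append(call(a, a + data.draw(st.integers(40, 120)), True))
        negatives = []
        for _ in range(data.draw(st.integers(0, 4))):
            a = data.draw(st.integers(1, 180))
            negatives.append(call(a, a + data.draw(st.integers(0, 30)), False))
        calls = positives + negatives
        lo = max(c.interval.aa_start for c in positives)
        hi = min(c.interval.aa_stop for c in positives)
        if lo > hi:
            with pytest.raises(InconsistentPositivesError):
                narrow_domain(calls)
            return
        expect = oracle_narrow(calls)
        if expect is None:
            with pytest.raises(InconsistentNegativesError):
                narrow_domain(calls)
            return
        dom = narrow_domain(calls)
        assert [dom.aa_start, dom.aa_stop] == expect
        # adding calls never grows the domain
        extra = call(1, 250, True)
        dom2 = narrow_domain(calls + [extra])
        assert dom2.length <= dom.length or (dom2.aa_start, dom2.aa_stop) == (
            dom.aa_start,
            dom.aa_stop,
        )


class TestDesignTiling:
    def test_union_covers_the_region(self):
        region = iv(1, 100)
        tiles = design_tiling(region, n_tiles=4, min_len=25, overlap_frac=0.25)
        covered = set()
        for t in tiles:
            covered |= set(range(t.aa_start, t.aa_stop + 1))
        assert covered == set(range(1, 101))

    def test_seventeen_tiles_over_243_residues(self):
        tiles = design_tiling(iv(1300, 1542), n_tiles=17, min_len=60, seed=1)
        assert len(tiles) == 17
        assert tiles[0].aa_start == 1300 and tiles[-1].aa_stop == 1542

    def test_infeasible_min_len_is_usage_error(self):
        with pytest.raises(UsageError):
            design_tiling(iv(1, 50), n_tiles=3, min_len=60)

    def test_deterministic_under_seed(self):
        a = design_tiling(iv(1, 200), 8, 30, seed=9)
        b = design_tiling(iv(1, 200), 8, 30, seed=9)
        c = design_tiling(iv(1, 200), 8, 30, seed=10)
        assert a == b
        assert a != c


class TestTilingRecovery:
    @pytest.mark.parametrize("seed", range(12))
    def test_narrowed_region_contains_epitope_and_avoids_negatives(self, seed):
        region = iv(1, 243)
        rng = np.random.default_rng(seed)
        a = int(rng.integers(1, 243 - 21 + 2))
        epitope = iv(a, a + 20)
        tiles = design_tiling(region, n_tiles=17, min_len=60, seed=seed)
        calls = simulate_tiling_calls(tiles, epitope)
        assert any(c.positive for c in calls)
        dom = narrow_domain(calls)
        assert dom.aa_start <= epitope.aa_start and dom.aa_stop >= epitope.aa_stop
        for c in calls:
            if not c.positive:
                assert not c.interval.overlaps(
                    FragmentInterval("gtn", dom.aa_start, dom.aa_stop)
                )


class TestAlignSids:
    def test_identical_sequences_are_100_percent(self):
        _, ident = align_sids(["ACDEFGHIK", "ACDEFGHIK"])
        assert ident[0, 1] == 100.0

    def test_one_mismatch_in_five(self):
        _, ident = align_sids(["ACDEF", "ACDFF"])
        assert ident[0, 1] == 80.0

    def test_identity_matrix_is_symmetric(self):
        _, ident = align_sids(["ACDEFGHIKL", "ACDEFGHIKV", "ACDEWGHIKL"])
        assert np.allclose(ident, ident.T)
        assert np.all(np.diag(ident) == 100.0)

    def test_gap_columns_count_against_identity(self):
        _, ident = align_sids(["ACDEFGHIKL", "ACDEFGHIKLMNP"])
        assert ident[0, 1] == pytest.approx(round(100 * 10 / 13, 1))

    def test_msa_rows_share_width_and_degap_to_inputs(self):
        msa, _ = align_sids(["ACDEFGHIKL", "ACDEFGHIKLMNP", "CDEFGHIKL"])
        assert len({len(row) for row in msa}) == 1
        assert [row.replace("-", "") for row in msa] == [
            "ACDEFGHIKL",
            "ACDEFGHIKLMNP",
            "CDEFGHIKL",
        ]

    def test_non_amino_acid_symbol_rejected(self):
        with pytest.raises(ValidationError, match="non-amino-acid"):
            align_sids(["ACDEF", "ACD1F"])

    def test_needs_two_sequences(self):
        with pytest.raises(ValidationError):
            align_sids(["ACDEF"])


class TestCommonSid:
    def test_three_homologue_intersection_is_29_residues(self):
        sids = [iv(10, 44, "aln"), iv(16, 48, "aln"), iv(5, 74, "aln")]
        lo, hi = common_sid(sids)
        assert (lo, hi) == (16, 44)
        assert hi - lo + 1 == 29

    def test_disjoint_intervals_have_no_common_sid(self):
        assert common_sid([iv(1, 10), iv(20, 30)]) is None

    def test_single_shared_residue(self):
        assert common_sid([iv(10, 20), iv(20, 30)]) == (20, 20)
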