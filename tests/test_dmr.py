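"""The sliding-window DMR caller, stage by stage and end to end."""

import numpy as np
import pandas as pd
import pytest

import windmr as w
from windmr.dmr import (
    DmrParams,
    assemble_dmrs,
    call_dmcs,
    classify_direction,
    generate_windows,
    merge_spans,
    paired_sites,
    select_candidate_windows,
    test_windows as run_window_tests,
    union_candidates,
)

from conftest import make_track


class TestGenerateWindows:
    @pytest.mark.parametrize(
        "chrom_len,expected",
        [(1000, 17), (200, 1), (199, 0), (249, 1), (250, 2)],
    )
    def test_window_counts(self, chrom_len, expected):
        assert len(generate_windows(chrom_len, 200, 50)) == expected

    def test_starts_are_step_multiples(self):
        starts = generate_windows(1000, 200, 50)
        assert starts[0] == 0
        assert np.all(np.diff(starts) == 50)
        assert starts[-1] <= 1000 - 200

    def test_bad_parameters_error(self):
        with pytest.raises(ValueError):
            generate_windows(1000, 50, 200)  # step > size
        with pytest.raises(ValueError):
            generate_windows(1000, 200, 0)


class TestTestWindows:
    def test_pooled_table_arithmetic(self):
        a = make_track([("c", 10, "+", "CG", 8, 10), ("c", 20, "+", "CG", 2, 10)], "A")
        b = make_track([("c", 10, "+", "CG", 1, 10), ("c", 20, "+", "CG", 0, 10)], "B")
        tests = run_window_tests(a, b, "CG", {"c": np.array([0])}, window_size=200)
        row = tests.iloc[0]
        assert (row.m_a, row.u_a, row.m_b, row.u_b) == (10, 10, 1, 19)
        assert row.level_a == 0.5 and row.level_b == 0.05
        assert row.n_sites == 2

    def test_windows_without_common_sites_skipped(self):
        a = make_track([("c", 10, "+", "CG", 8, 10)], "A")
        b = make_track([("c", 500, "+", "CG", 1, 10)], "B")
        tests = run_window_tests(a, b, "CG", {"c": np.array([0, 400])}, window_size=200)
        assert len(tests) == 0

    def test_identical_tracks_give_p_one(self):
        rows = [("c", i * 7, "+", "CG", i % 5, 8) for i in range(40)]
        a, b = make_track(rows, "A"), make_track(rows, "B")
        tests = run_window_tests(a, b, "CG", {"c": generate_windows(300, 200, 50)})
        assert np.allclose(tests["p"], 1.0)
        assert np.allclose(tests["q"], 1.0)

    def test_low_coverage_sites_excluded(self):
        a = make_track([("c", 10, "+", "CG", 3, 3), ("c", 20, "+", "CG", 2, 10)], "A")
        b = make_track([("c", 10, "+", "CG", 0, 10), ("c", 20, "+", "CG", 0, 10)], "B")
        tests = run_window_tests(a, b, "CG", {"c": np.array([0])}, min_coverage=4)
        assert tests.iloc[0]["n_sites"] == 1  # the 3x site is out


class TestSelectCandidates:
    def _frame(self, level_a, level_b, q):
        return pd.DataFrame(
            {
                "chrom": "c", "start": [0], "end": [200], "n_sites": [5],
                "m_a": [1], "u_a": [1], "m_b": [1], "u_b": [1],
                "level_a": [level_a], "level_b": [level_b], "p": [q], "q": [q],
            }
        )

    @pytest.mark.parametrize(
        "la,lb,q,kept",
        [
            (0.5, 0.1, 0.001, True),  # fold 5
            (0.5, 0.25, 0.001, False),  # fold 2 <= 2.5
            (0.2, 0.0, 0.001, True),  # infinite fold
            (0.5, 0.1, 0.5, False),  # not significant
            (0.25, 0.1, 0.001, False),  # fold exactly 2.5: strict
        ],
    )
    def test_q_and_fold_rules(self, la, lb, q, kept):
        out = select_candidate_windows(self._frame(la, lb, q))
        assert (len(out) == 1) == kept

    def test_direction_assigned(self):
        out = select_candidate_windows(self._frame(0.1, 0.5, 0.001))
        assert out.iloc[0]["direction"] == "hyper"


class TestUnionCandidates:
    def _cand(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "q"])

    def test_overlapping_same_direction_merge(self):
        out = union_candidates(self._cand([("c", 0, 200, "hyper", 0.001), ("c", 50, 250, "hyper", 0.002)]))
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 250)
        assert out.iloc[0]["qmin"] == 0.001

    def test_opposite_directions_never_merge(self):
        out = union_candidates(self._cand([("c", 0, 200, "hyper", 0.001), ("c", 150, 350, "hypo", 0.001)]))
        assert len(out) == 2

    def test_single_window_is_itself(self):
        out = union_candidates(self._cand([("c", 100, 300, "hypo", 0.01)]))
        assert [(r.start, r.end) for r in out.itertuples()] == [(100, 300)]

    def test_bookended_windows_merge(self):
        out = union_candidates(self._cand([("c", 0, 200, "hyper", 0.01), ("c", 200, 400, "hyper", 0.01)]))
        assert len(out) == 1


class TestCallDmcs:
    def test_extreme_site_is_dmc(self):
        a = make_track([("c", 50, "+", "CG", 10, 10)], "A")
        b = make_track([("c", 50, "+", "CG", 0, 10)], "B")
        regions = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [200],
                                "direction": ["hypo"], "qmin": [0.001]})
        dmcs = call_dmcs(a, b, regions, "CG")
        assert len(dmcs) == 1
        assert dmcs.iloc[0]["p"] == pytest.approx(2 / 184756, rel=1e-7)

    def test_equal_site_is_not_dmc(self):
        a = make_track([("c", 50, "+", "CG", 2, 4)], "A")
        b = make_track([("c", 50, "+", "CG", 2, 4)], "B")
        regions = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [200],
                                "direction": ["hypo"], "qmin": [0.001]})
        assert len(call_dmcs(a, b, regions, "CG")) == 0

    def test_low_coverage_site_excluded(self):
        a = make_track([("c", 50, "+", "CG", 4, 4)], "A")
        b = make_track([("c", 50, "+", "CG", 0, 3)], "B")  # 3x in B
        regions = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [200],
                                "direction": ["hypo"], "qmin": [0.001]})
        assert len(call_dmcs(a, b, regions, "CG", min_coverage=4)) == 0


def _region_with_dmcs(n_dmc, start=100, end=300, chrom="c", direction="hypo"):
    regions = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end],
                            "direction": [direction], "qmin": [1e-4]})
    positions = np.linspace(start + 2, end - 2, n_dmc).astype(int) if n_dmc else []
    dmcs = pd.DataFrame(
        {
            "chrom": chrom, "pos": positions, "strand": "+", "context": "CG",
            "m_a": 8, "t_a": 8, "m_b": 0, "t_b": 8, "p": 1e-4, "region_id": 0,
        }
    )
    pairs = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(start, end, 10),
            "strand": "+", "context": "CG",
            "m_a": 8, "t_a": 8, "m_b": 0, "t_b": 8,
        }
    )
    return regions, dmcs, pairs


class TestAssembleDmrs:
    def test_seven_dmc_boundary(self):
        regions, dmcs, pairs = _region_with_dmcs(7)
        assert len(assemble_dmrs(regions, dmcs, pairs, "CG", dmc_min=7)) == 1
        regions, dmcs, pairs = _region_with_dmcs(6)
        assert len(assemble_dmrs(regions, dmcs, pairs, "CG", dmc_min=7)) == 0

    def test_dmr_keeps_region_extent_and_counts(self):
        regions, dmcs, pairs = _region_with_dmcs(9)
        (dmr,) = assemble_dmrs(regions, dmcs, pairs, "CG")
        assert (dmr.start, dmr.end) == (100, 300)
        assert dmr.n_dmc == 9
        assert dmr.level_a == 1.0 and dmr.level_b == 0.0
        assert np.isinf(dmr.fold_change)

    def test_gap_merging_boundaries(self):
        spans = [("c", 100, 300, "hypo", 0.01), ("c", 350, 500, "hypo", 0.02)]
        merged = merge_spans(spans, merge_gap=100)
        assert merged == [("c", 100, 500, "hypo", 0.01)]  # gap 50 merges
        spans = [("c", 100, 300, "hypo", 0.01), ("c", 401, 600, "hypo", 0.02)]
        assert len(merge_spans(spans, merge_gap=100)) == 2  # gap 101 does not

    def test_gap_exactly_merge_gap_merges(self):
        spans = [("c", 0, 100, "hyper", 0.01), ("c", 200, 300, "hyper", 0.01)]
        assert len(merge_spans(spans, merge_gap=100)) == 1

    def test_merging_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 15))
            spans = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                e = s + int(rng.integers(50, 400))
                spans.append(
                    (rng.choice(["c1", "c2"]), s, e,
                     rng.choice(["hyper", "hypo"]), float(rng.random()))
                )
            merged = merge_spans(spans, 100)
            assert merge_spans(merged, 100) == merged  # idempotent
            shuffled = [spans[i] for i in rng.permutation(n)]
            assert merge_spans(shuffled, 100) == merged  # order invariant
            # all remaining same-direction gaps exceed the merge gap
            for chrom, direction in {(s[0], s[3]) for s in merged}:
                grp = [s for s in merged if s[0] == chrom and s[3] == direction]
                for s1, s2 in zip(grp, grp[1:]):
                    assert s2[1] - s1[2] > 100


class TestDirectionAndSummary:
    def test_classify_direction(self):
        assert classify_direction(0.1, 0.5) == "hyper"
        assert classify_direction(0.5, 0.1) == "hypo"
        with pytest.raises(ValueError):
            classify_direction(0.3, 0.3)

    def test_direction_antisymmetric_under_sample_swap(self, small_sim):
        genome = small_sim["genome"]
        a, b = small_sim["track_a"], small_sim["track_b"]
        fwd = w.call_context_dmrs(a, b, genome, "CG")[0]
        rev = w.call_context_dmrs(b, a, genome, "CG")[0]
        assert len(fwd) > 0
        assert {(d.chrom, d.start, d.end) for d in fwd} == {(d.chrom, d.start, d.end) for d in rev}
        fwd_dirs = {(d.chrom, d.start): d.direction for d in fwd}
        for d in rev:
            assert d.direction != fwd_dirs[(d.chrom, d.start)]

    def test_summary_conservation(self, small_sim):
        dmrs = [
            d for ctx in w.CONTEXTS
            for d in w.call_context_dmrs(
                small_sim["track_a"], small_sim["track_b"], small_sim["genome"], ctx
            )[0]
        ]
        summary = w.dmr_summary(dmrs)
        assert (summary["hyper"] + summary["hypo"]).equals(summary["total"])
        assert (summary["n_delta_gt50"] + summary["n_delta_le50"]).equals(summary["total"])
        for row in summary.itertuples():
            sub = [d for d in dmrs if d.context == row.context]
            assert row.total_length_bp == sum(len(d) for d in sub)


class TestEndToEnd:
    def test_spiked_regions_recovered(self, small_sim):
        """Every spiked CG region overlaps a called CG-DMR of the right direction."""
        dmrs, _ = w.call_context_dmrs(
            small_sim["track_a"], small_sim["track_b"], small_sim["genome"], "CG"
        )
        truth = small_sim["truth"].regions
        truth = truth[truth["context"] == "CG"]
        for reg in truth.itertuples(index=False):
            hits = [
                d for d in dmrs
                if d.chrom == reg.chrom and d.start < reg.end and reg.start < d.end
            ]
            assert hits, f"missed truth region {reg.chrom}:{reg.start}-{reg.end}"
            assert all(h.direction == reg.direction for h in hits)

    def test_dmr_invariants(self, small_sim):
        dmrs, _ = w.call_context_dmrs(
            small_sim["track_a"], small_sim["track_b"], small_sim["genome"], "CG"
        )
        params = DmrParams()
        for d in dmrs:
            assert d.n_dmc >= params.dmc_min
            assert d.direction == classify_direction(d.level_a, d.level_b)
            assert d.fold_change > params.min_fold

    def test_relaxing_thresholds_never_reduces_dmr_count(self, small_sim):
        a, b, genome = small_sim["track_a"], small_sim["track_b"], small_sim["genome"]
        strict = w.call_context_dmrs(a, b, genome, "CG", DmrParams())[0]
        for relaxed in (
            DmrParams(q_max=0.5),
            DmrParams(min_fold=1.0),
            DmrParams(dmc_min=1),
            DmrParams(dmc_p=0.5),
        ):
            loose = w.call_context_dmrs(a, b, genome, "CG", relaxed)[0]
            assert len(loose) >= len(strict)

    def test_bed_roundtrip(self, small_sim, tmp_path):
        dmrs, _ = w.call_context_dmrs(
            small_sim["track_a"], small_sim["track_b"], small_sim["genome"], "CG"
        )
        path = tmp_path / "dmrs.bed"
        w.dmrs_to_bed(dmrs, path)
        back = w.read_dmr_bed(path)
        assert [(d.chrom, d.start, d.end, d.context, d.direction, d.n_dmc) for d in back] == [
            (d.chrom, d.start, d.end, d.context, d.direction, d.n_dmc) for d in dmrs
        ]
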