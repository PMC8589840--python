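import numpy as np
import pandas as pd
import pytest

from rtgloh import (
    HET,
    HOM_P1,
    HOM_P2,
    MISSING,
    GenomeLayout,
    apply_masks,
    breakpoint_regions,
    call_loh,
    compare_clone_sets,
    inter_marker_distances,
    reciprocity,
    segment_coordinates,
    summarize_clone,
)
from rtgloh.markers import ValidationError

from conftest import make_track

H, P1, P2, M = HET, HOM_P1, HOM_P2, MISSING


class TestCallLoh:
    def test_interstitial_run_grouped(self, toy_map, toy_layout):
        segs = call_loh(make_track([H, H, P1, P1, H, H, H, H, H]), toy_map, toy_layout)
        (s,) = segs
        assert (s.parent, s.n_markers, s.kind) == (P1, 2, "interstitial")
        assert (s.first, s.last) == (2_000, 4_000)

    def test_run_reaching_last_unmasked_marker_is_terminal(self, toy_map, toy_layout):
        segs = call_loh(make_track([H, H, H, H, H, H, H, P2, P2]), toy_map, toy_layout)
        (s,) = segs
        assert s.kind == "terminal" and s.parent == P2
        assert (s.first, s.last) == (9_000, 9_900)

    def test_single_marker_event_called(self, toy_map, toy_layout):
        segs = call_loh(make_track([H, P1, H, H, H, H, H, H, H]), toy_map, toy_layout)
        (s,) = segs
        assert s.n_markers == 1 and s.kind == "interstitial"

    def test_all_het_gives_no_events(self, toy_map, toy_layout):
        assert call_loh(make_track([H] * 9), toy_map, toy_layout) == []

    def test_missing_is_transparent_and_unsupported(self, toy_map, toy_layout):
        segs = call_loh(make_track([H, P1, M, P1, H, H, H, H, H]), toy_map, toy_layout)
        (s,) = segs
        assert s.n_markers == 2  # MISSING bridges but does not support
        assert (s.first, s.last) == (1_000, 4_000)

    def test_missing_only_run_is_no_event(self, toy_map, toy_layout):
        assert call_loh(make_track([H, M, M, H, H, H, H, H, H]), toy_map, toy_layout) == []

    def test_opposite_parent_runs_split(self, toy_map, toy_layout):
        segs = call_loh(make_track([H, P1, P1, P2, H, H, H, H, H]), toy_map, toy_layout)
        assert [s.parent for s in segs] == [P1, P2]
        # shared breakpoint at the midpoint of the adjacent opposite markers
        assert segs[0].end == segs[1].start == (2_000 + 4_000) // 2

    def test_max_gap_splits_bridged_run(self, toy_map, toy_layout):
        calls = [H, P1, M, P1, H, H, H, H, H]  # supporting markers 3 kb apart
        assert len(call_loh(make_track(calls), toy_map, toy_layout, max_gap=2_000)) == 2
        assert len(call_loh(make_track(calls), toy_map, toy_layout, max_gap=4_000)) == 1

    def test_masked_markers_excluded_from_calling(self, toy_map):
        layout = GenomeLayout(
            lengths={"chrT": 10_000},
            centromeres={"chrT": (5_000, 5_100)},
            mask_left={"chrT": 150},
            mask_right={"chrT": 150},
        )
        marker_map = apply_masks(toy_map, layout)
        # markers at 100 and 9,900 are masked: the masked P1 call at 100 is
        # no event, and the run at 9,000 (last unmasked marker) is terminal
        segs = call_loh(
            make_track([P1, H, H, H, H, H, H, P2, P2]), marker_map, layout
        )
        (s,) = segs
        assert s.kind == "terminal" and (s.first, s.last) == (9_000, 9_000)

    def test_whole_chromosome_homozygosity_flagged_not_split(self, toy_map, toy_layout):
        (s,) = call_loh(make_track([P1] * 9), toy_map, toy_layout)
        assert s.whole_chromosome and s.spans_centromere and s.terminal

    def test_track_map_length_mismatch_rejected(self, toy_map, toy_layout):
        with pytest.raises(ValidationError):
            call_loh(make_track([H, H]), toy_map, toy_layout)

    def test_segment_maximality(self, toy_map, toy_layout):
        # no two adjacent segments share a parent without an intervening
        # informative non-matching marker
        rng = np.random.default_rng(0)
        for _ in range(50):
            calls = rng.choice([H, P1, P2, M], size=9, p=[0.4, 0.25, 0.25, 0.1])
            segs = call_loh(make_track(calls), toy_map, toy_layout)
            for a, b in zip(segs, segs[1:]):
                if a.chrom == b.chrom and a.parent == b.parent:
                    between = toy_map.table.query(
                        "pos > @a.last and pos < @b.first"
                    ).index
                    assert any(calls[j] in (H, P1 + P2 - a.parent) for j in between)


class TestSegmentCoordinates:
    def _map(self, make_map, positions):
        return make_map(positions)

    def test_midpoint_start_end(self, make_map, toy_layout):
        m = make_map([100, 200, 300, 400])
        (s,) = call_loh(make_track([H, P1, P1, H]), m, toy_layout)
        assert (s.first, s.last) == (200, 300)
        assert (s.start, s.end) == (150, 350)
        assert segment_coordinates(s, m) == ((200, 300), (150, 350))

    def test_single_marker_segment(self, make_map, toy_layout):
        m = make_map([400, 500, 800])
        (s,) = call_loh(make_track([H, P1, H]), m, toy_layout)
        assert (s.first, s.last, s.start, s.end) == (500, 500, 450, 650)

    def test_terminal_segment_clamps_to_first_marker(self, make_map, toy_layout):
        m = make_map([100, 200, 300])
        (s,) = call_loh(make_track([P2, P2, H]), m, toy_layout)
        assert s.start == s.first == 100


class TestSummaries:
    def test_no_segments_all_zero(self, toy_map, toy_layout):
        s = summarize_clone("c", [], toy_map, toy_layout)
        assert (s.n_interstitial, s.n_terminal, s.frac_markers, s.frac_genome) == (0, 0, 0.0, 0.0)

    def test_marker_fraction(self, toy_map, toy_layout):
        segs = call_loh(make_track([H, H, P1, P1, H, H, H, H, H]), toy_map, toy_layout)
        s = summarize_clone("c", segs, toy_map, toy_layout)
        assert s.frac_markers == pytest.approx(2 / 9)

    def test_parent_fraction_additivity_and_symmetry(self, toy_map, toy_layout):
        rng = np.random.default_rng(1)
        for _ in range(30):
            calls = rng.choice([H, P1, P2], size=9)
            segs = call_loh(make_track(calls), toy_map, toy_layout)
            s = summarize_clone("c", segs, toy_map, toy_layout)
            assert s.frac_p1 + s.frac_p2 == pytest.approx(s.frac_markers)
            assert s.n_interstitial + s.n_terminal == len(segs)
        segs = call_loh(make_track([H, P1, H, P2, H, H, H, H, H]), toy_map, toy_layout)
        s = summarize_clone("c", segs, toy_map, toy_layout)
        assert s.frac_p1 == s.frac_p2


class TestBreakpointRegions:
    def test_interstitial_has_two_regions_terminal_one(self, toy_map, toy_layout):
        track = make_track([H, H, P1, P1, H, H, H, P2, P2])
        segs = call_loh(track, toy_map, toy_layout)
        by_kind = {s.kind: s for s in segs}
        regions = breakpoint_regions(segs, track, toy_map, k=5)
        n = {"interstitial": 0, "terminal": 0}
        for r in regions:
            n[r.segment.kind] += 1
        assert n == {"interstitial": 2, "terminal": 1}
        # region spans first homozygous marker <-> nearest flanking marker
        left = next(r for r in regions if r.segment.kind == "interstitial" and r.side == "left")
        assert (left.start, left.end) == (1_000, 2_000)

    def test_window_truncated_when_fewer_markers(self, toy_map, toy_layout):
        track = make_track([H, P1, P1, P1, H, H, H, H, H])
        segs = call_loh(track, toy_map, toy_layout)
        regions = breakpoint_regions(segs, track, toy_map, k=5)
        assert all(len(r.hom_positions) == 3 for r in regions)
        assert all(len(r.het_positions) <= 5 for r in regions)

    def test_k_must_be_positive(self, toy_map, toy_layout):
        with pytest.raises(ValidationError):
            breakpoint_regions([], make_track([H] * 9), toy_map, k=0)


class TestInterMarkerDistances:
    def test_consecutive_differences(self, make_map):
        assert list(inter_marker_distances(make_map([100, 200, 400]))) == [100, 200]

    def test_single_marker_empty(self, make_map):
        assert inter_marker_distances(make_map([100])).size == 0

    def test_marker_desert_at_breakpoint_inflates_window_distances(
        self, make_map, toy_layout
    ):
        # 50 kb gap right at a simulated breakpoint: window distances are
        # stochastically larger than the genome-wide background
        pos = list(range(1_000, 20_000, 1_000)) + list(range(70_000, 90_000, 1_000))
        m = make_map(pos)
        calls = [P1 if p < 20_000 else H for p in pos]
        track = make_track(calls)
        segs = call_loh(track, m, toy_layout)
        regions = breakpoint_regions(segs, track, m, k=5)
        window = inter_marker_distances(regions)
        genome = inter_marker_distances(m)
        assert np.median(window) >= np.median(genome)
        assert window.max() == 50_000 + 1_000

    def test_uniform_map_windows_indistinguishable_from_background(
        self, toy_layout
    ):
        # null calibration: on an evenly spaced map the window distances are a
        # subsample of the genome-wide ones; a rank test at alpha = 0.05
        # rejects at ~ alpha over repeated simulated tracks
        import scipy.stats as st

        pos = list(range(1_000, 100_000, 1_000))
        m = pd.DataFrame({"chrom": "chrT", "pos": pos, "allele1": "A", "allele2": "C"})
        from rtgloh import MarkerMap

        marker_map = MarkerMap(m)
        genome = inter_marker_distances(marker_map)
        rng = np.random.default_rng(0)
        rejections = 0
        n_runs = 200
        for _ in range(n_runs):
            start = rng.integers(5, 80)
            width = rng.integers(3, 10)
            calls = np.full(len(pos), H, dtype=np.int8)
            calls[start : start + width] = P1
            track = make_track(calls)
            segs = call_loh(track, marker_map, toy_layout)
            regions = breakpoint_regions(segs, track, marker_map, k=5)
            window = inter_marker_distances(regions)
            # jitter both samples identically to break the all-tied degeneracy
            noise = rng.normal(0, 1e-6)
            p = st.mannwhitneyu(
                window + rng.normal(0, 1e-9, window.size),
                genome + rng.normal(0, 1e-9, genome.size),
                alternative="greater",
            ).pvalue
            rejections += p < 0.05
        # binomial 95% CI around 0.05 at n=200
        assert 0.023 * n_runs <= rejections + 1  # not systematically below
        assert rejections <= 0.089 * n_runs + 1


class TestReciprocity:
    def test_all_het_pair_is_reciprocal(self, toy_map):
        assert reciprocity(make_track([H] * 9), make_track([H] * 9), toy_map) == 0

    def test_complementary_homozygosity_is_reciprocal(self, toy_map):
        a = make_track([H, H, P1, P1, H, H, H, H, H])
        b = make_track([H, H, P2, P2, H, H, H, H, H])
        assert reciprocity(a, b, toy_map) == 0

    def test_one_sided_conversion_counts_one_marker(self, toy_map):
        a = make_track([H, H, P1, H, H, H, H, H, H])
        b = make_track([H] * 9)
        assert reciprocity(a, b, toy_map) == 1

    def test_map_mismatch_rejected(self, toy_map):
        with pytest.raises(ValidationError):
            reciprocity(make_track([H]), make_track([H] * 9), toy_map)


class TestCompareCloneSets:
    def test_shifted_sets_detected_with_high_power(self):
        # one-tailed rank-sum at n = 24 vs 22, shift one SD
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            a = rng.normal(1.0, 1.0, size=24)
            b = rng.normal(0.0, 1.0, size=22)
            _, p = compare_clone_sets(a, b, alternative="greater")
            hits += p < 0.05
        assert hits >= 90

    def test_identical_samples_give_no_evidence_one_tailed(self):
        a = np.arange(10.0)
        _, p = compare_clone_sets(a, a, alternative="greater")
        assert p >= 0.5

    def test_all_tied_degenerate_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = compare_clone_sets([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_fligner_null_rejection_near_alpha(self):
        rng = np.random.default_rng(1)
        rej = 0
        n_runs = 200
        for _ in range(n_runs):
            a = rng.normal(0, 1, 24)
            b = rng.normal(0, 1, 22)
            _, p = compare_clone_sets(a, b, test="fligner")
            rej += p < 0.05
        assert 0.023 <= rej / n_runs <= 0.089

    def test_too_few_clones_rejected(self):
        with pytest.raises(ValidationError):
            compare_clone_sets([1.0], [2.0, 3.0])
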