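"""Unit and property tests for recentering, grid sampling and the arm callers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nbsomatic.copy_number import (
    EmptyOverlapError,
    SEGMENT_COLUMNS,
    SegmentProfile,
    UncenterableProfileError,
    arm_calls_table,
    call_11q13_gain,
    call_all_arms,
    call_arm_alteration,
    classify_9plus_wc,
    focal_amplification,
    recenter_profile,
    sample_copy_grid,
)
from nbsomatic.synthetic_cohort import CopyEvent, simulate_copy_profile

from conftest import make_profile, uniform_profile

MB = 1_000_000


class TestRecenter:
    def test_uniform_profile_shifted_to_diploid(self, toy_genome):
        profile = uniform_profile(toy_genome, copy=2.7)
        recentered, offset = recenter_profile(profile)
        assert offset == pytest.approx(-0.7)
        assert recentered.segments["copy"].unique() == pytest.approx(2.0)

    def test_idempotent(self, toy_genome):
        profile = uniform_profile(toy_genome, copy=2.7)
        once, offset1 = recenter_profile(profile)
        twice, offset2 = recenter_profile(once)
        assert offset2 == 0.0
        pd.testing.assert_frame_equal(once.segments, twice.segments)

    def test_loh_levels_excluded_from_baseline(self):
        # shifted triploid-dominant sample: haploid LOH at the lowest level,
        # a modest diploid non-LOH region, bulk at triploid
        profile = make_profile(
            [
                ("1", 1, 30 * MB, 1.6, True),     # haploid + offset, LOH
                ("1", 30 * MB + 1, 60 * MB, 2.6, False),  # presumed diploid
                ("2", 1, 200 * MB, 3.6, False),   # triploid bulk
            ]
        )
        recentered, offset = recenter_profile(profile)
        assert offset == pytest.approx(-0.6)
        diploid_seg = recentered.segments.iloc[1]
        assert diploid_seg["copy"] == pytest.approx(2.0)

    def test_all_loh_refused(self):
        profile = make_profile([("1", 1, MB, 1.0, True)])
        with pytest.raises(UncenterableProfileError):
            recenter_profile(profile)

    def test_noise_does_not_fragment_baseline(self, toy_genome, rng):
        # noisy diploid profile: baseline must stay 2.0 despite rounding spread
        rows = []
        for spec in toy_genome:
            bounds = np.linspace(1, spec.length, 9, dtype=int)
            for s, e in zip(bounds[:-1], bounds[1:] - 1):
                rows.append((spec.name, int(s), int(e), 2.0 + rng.normal(0, 0.05)))
        recentered, offset = recenter_profile(make_profile(rows))
        assert offset == 0.0


class TestGrid:
    def test_30mb_window_has_121_points(self):
        profile = make_profile([("1", 1, 60 * MB, 2.0)])
        grid = sample_copy_grid(profile, "1", (1, 1 + 30 * MB))
        assert len(grid) == 121

    def test_single_segment_constant(self):
        profile = make_profile([("1", 1, 60 * MB, 3.0)])
        grid = sample_copy_grid(profile, "1", (10 * MB, 20 * MB))
        assert np.all(grid == 3.0)

    def test_boundary_straddle_mixes_values(self):
        profile = make_profile([("1", 1, 10 * MB, 2.0), ("1", 10 * MB + 1, 30 * MB, 3.0)])
        grid = sample_copy_grid(profile, "1", (9 * MB, 12 * MB))
        assert set(np.unique(grid)) == {2.0, 3.0}

    def test_window_outside_extent_rejected(self):
        profile = make_profile([("1", 1, 10 * MB, 2.0)])
        with pytest.raises(ValueError, match="outside profile extent"):
            sample_copy_grid(profile, "1", (50 * MB, 60 * MB))


def _toy_event_profile(genome, chrom, arm, copy, loh=False, offset=0.0, noise=0.0, seed=0):
    events = [CopyEvent(f"arm_{'gain' if copy > 2 else 'loss'}", chrom, arm=arm, copy=copy, loh=loh)]
    observed, _ = simulate_copy_profile(
        genome, events, centering_offset=offset, noise_sd=noise, seed=seed
    )
    return observed


class TestArmCaller:
    def test_terminal_gain_called(self, toy_genome):
        profile = _toy_event_profile(toy_genome, "T1", "q", 3.0)
        call = call_arm_alteration(profile, "T1", "q", toy_genome)
        assert call.direction == "gain"
        assert call.window_median == pytest.approx(3.0)
        assert call.control_median == pytest.approx(2.0)

    def test_whole_chromosome_gain_excluded(self, toy_genome):
        # uniform 3.0 chromosome: control criterion must suppress the call
        rows = [("T1", 1, toy_genome["T1"].length, 3.0)]
        rows += [(s.name, 1, s.length, 2.0) for s in toy_genome if s.name != "T1"]
        profile = make_profile(rows)
        for arm in ("p", "q"):
            assert call_arm_alteration(profile, "T1", arm, toy_genome).direction == "none"

    def test_terminal_loss_called(self, toy_genome):
        profile = _toy_event_profile(toy_genome, "T1", "q", 1.6)
        call = call_arm_alteration(profile, "T1", "q", toy_genome)
        assert call.direction == "loss"

    def test_short_arm_uses_entire_arm(self, toy_genome):
        # T2 q arm is 20 Mb (< 30 Mb window): whole arm analyzed and callable
        profile = _toy_event_profile(toy_genome, "T2", "q", 3.0)
        call = call_arm_alteration(profile, "T2", "q", toy_genome)
        assert call.direction == "gain"
        assert call.window[1] - call.window[0] <= 20 * MB

    def test_acrocentric_q_window_shortened(self, toy_genome):
        profile = uniform_profile(toy_genome)
        call = call_arm_alteration(profile, "T3", "q", toy_genome)
        assert call.window[1] - call.window[0] == 20 * MB


class Test11q13:
    def test_focal_gain_called(self, grch37):
        events = [CopyEvent("region", "11", copy=4.0, start=68 * MB, end=70 * MB)]
        profile, _ = simulate_copy_profile(grch37, events, noise_sd=0.0, seed=0)
        call = call_11q13_gain(profile, grch37)
        assert call.direction == "gain"
        assert call.window_median == pytest.approx(4.0)

    def test_flat_profile_not_called(self, grch37):
        assert call_11q13_gain(uniform_profile(grch37), grch37).direction == "none"

    def test_whole_11q_gain_fails_control(self, grch37):
        q = grch37["11"].q
        events = [CopyEvent("region", "11", copy=3.0, start=q.start, end=q.end)]
        profile, _ = simulate_copy_profile(grch37, events, noise_sd=0.0, seed=0)
        assert call_11q13_gain(profile, grch37).direction == "none"


class TestWholeChromosome:
    def _wc_profile(self, genome, chroms, copy=3.0):
        rows = [
            (s.name, 1, s.length, copy if s.name in chroms else 2.0) for s in genome
        ]
        return make_profile(rows)

    def test_nine_gained_is_9plus(self, grch37):
        chroms = {str(c) for c in range(3, 12)}
        ploidy = classify_9plus_wc(self._wc_profile(grch37, chroms), grch37)
        assert ploidy.n_whole_chrom_gains == 9
        assert ploidy.is_9plus

    def test_eight_gained_is_not(self, grch37):
        chroms = {str(c) for c in range(3, 11)}
        ploidy = classify_9plus_wc(self._wc_profile(grch37, chroms), grch37)
        assert ploidy.n_whole_chrom_gains == 8
        assert not ploidy.is_9plus

    def test_single_arm_gain_not_whole_chromosome(self, grch37):
        profile = _toy_event_profile_grch37(grch37)
        ploidy = classify_9plus_wc(profile, grch37)
        assert not ploidy.chrom_gained["17"]


def _toy_event_profile_grch37(genome):
    events = [CopyEvent("arm_gain", "17", arm="q", copy=3.0)]
    observed, _ = simulate_copy_profile(genome, events, noise_sd=0.0, seed=0)
    return observed


class TestFocalAmplification:
    def test_high_copy_segment(self):
        profile = make_profile(
            [("2", 1, 15 * MB - 1, 2.0), ("2", 15 * MB, 16 * MB, 30.0), ("2", 16 * MB + 1, 100 * MB, 2.0)]
        )
        amplified, max_copy = focal_amplification(profile, ("2", 15 * MB, 16 * MB))
        assert amplified and max_copy == 30.0

    def test_exactly_eight_copies_not_amplified(self):
        profile = make_profile([("2", 1, 100 * MB, 8.0)])
        amplified, _ = focal_amplification(profile, ("2", 15 * MB, 16 * MB))
        assert not amplified

    def test_threshold_maps_to_eight_copies(self):
        profile = make_profile([("2", 1, 100 * MB, 8.01)])
        amplified, _ = focal_amplification(profile, ("2", 15 * MB, 16 * MB))
        assert amplified

    def test_empty_overlap_rejected(self):
        profile = make_profile([("2", 1, 10 * MB, 2.0)])
        with pytest.raises(EmptyOverlapError):
            focal_amplification(profile, ("3", 1, MB))


class TestCallAllArms:
    def test_flat_diploid_zero_calls(self, toy_genome):
        calls, ploidy = call_all_arms(uniform_profile(toy_genome), toy_genome)
        assert sum(c.is_call for c in calls) == 0
        assert ploidy.n_whole_chrom_gains == 0

    @pytest.mark.parametrize("level", [1.0, 2.0, 3.0, 4.0])
    def test_uniform_genome_any_level_zero_segmental_calls(self, toy_genome, level):
        calls, _ = call_all_arms(uniform_profile(toy_genome, copy=level), toy_genome)
        assert sum(c.is_call for c in calls) == 0

    def test_injected_events_recovered(self, toy_genome):
        events = [
            CopyEvent("arm_gain", "T1", arm="q", copy=3.0),
            CopyEvent("arm_loss", "T4", arm="p", copy=1.0, loh=True),
        ]
        observed, _ = simulate_copy_profile(toy_genome, events, noise_sd=0.05, seed=3)
        recentered, _ = recenter_profile(observed)
        calls, _ = call_all_arms(recentered, toy_genome)
        hits = {(c.chrom, c.arm): c.direction for c in calls if c.is_call}
        assert hits == {("T1", "q"): "gain", ("T4", "p"): "loss"}

    def test_joint_11q13_and_17q_events_both_called(self, grch37):
        events = [
            CopyEvent("region", "11", copy=4.0, start=67.5 * MB, end=70.5 * MB),
            CopyEvent("arm_gain", "17", arm="q", copy=3.0),
        ]
        observed, _ = simulate_copy_profile(grch37, events, noise_sd=0.05, seed=4)
        recentered, _ = recenter_profile(observed)
        calls, _ = call_all_arms(recentered, grch37)
        hits = {(c.chrom, c.arm) for c in calls if c.direction == "gain"}
        assert ("17", "q") in hits and ("11", "11q13.3") in hits

    def test_table_has_one_row_per_arm(self, toy_genome):
        calls, _ = call_all_arms(uniform_profile(toy_genome), toy_genome)
        table = arm_calls_table(calls)
        assert len(table) == 2 * len(toy_genome)


class TestCallerInvariants:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(split=st.integers(min_value=2, max_value=140))
    def test_segment_subdivision_invariance(self, toy_genome, split):
        """Splitting any segment at any point must not change any call."""
        events = [CopyEvent("arm_gain", "T1", arm="q", copy=3.0)]
        profile, _ = simulate_copy_profile(toy_genome, events, noise_sd=0.0, seed=0)
        split_pos = split * MB
        rows = []
        for row in profile.segments.itertuples(index=False):
            if row.chrom == "T1" and row.start < split_pos < row.end:
                rows.append(("T1", row.start, split_pos, row.copy, row.loh))
                rows.append(("T1", split_pos + 1, row.end, row.copy, row.loh))
            else:
                rows.append(tuple(row))
        split_profile = SegmentProfile("t", pd.DataFrame(rows, columns=SEGMENT_COLUMNS))
        base = [(c.chrom, c.arm, c.direction) for c in call_all_arms(profile, toy_genome)[0]]
        after = [(c.chrom, c.arm, c.direction) for c in call_all_arms(split_profile, toy_genome)[0]]
        assert base == after

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(extra=st.floats(min_value=0.0, max_value=3.0))
    def test_gain_monotone_under_raised_copy(self, toy_genome, extra):
        """Raising copy inside a called gain window never revokes the gain."""
        events = [CopyEvent("arm_gain", "T1", arm="q", copy=3.0 + extra)]
        profile, _ = simulate_copy_profile(toy_genome, events, noise_sd=0.0, seed=0)
        assert call_arm_alteration(profile, "T1", "q", toy_genome).direction == "gain"

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(deeper=st.floats(min_value=0.0, max_value=1.0))
    def test_loss_monotone_under_deepened_copy(self, toy_genome, deeper):
        events = [CopyEvent("arm_loss", "T1", arm="q", copy=max(1.0 - deeper, 0.0))]
        profile, _ = simulate_copy_profile(toy_genome, events, noise_sd=0.0, seed=0)
        assert call_arm_alteration(profile, "T1", "q", toy_genome).direction == "loss"
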