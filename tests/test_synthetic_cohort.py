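"""Tests for the cohort generator: determinism, spectrum/VAF consistency,
truth completeness and the linkage/hotspot constructs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nbsomatic.copy_number import classify_9plus_wc, recenter_profile
from nbsomatic.signatures import CONTEXT_CLASSES, build_spectrum, cosine_similarity
from nbsomatic.sv_integration import (
    Alteration,
    build_linkage_graph,
    classify_t11_17,
    independent_pair_filter,
)
from nbsomatic.synthetic_cohort import (
    CohortConfig,
    CopyEvent,
    SvPlanEntry,
    simulate_cohort,
    simulate_copy_profile,
    simulate_snvs,
    simulate_svs,
    write_cohort,
)

MB = 1_000_000


class TestCopyProfileSimulation:
    def test_no_events_is_flat_diploid(self, grch37):
        observed, clean = simulate_copy_profile(grch37, [], noise_sd=0.02, seed=1)
        assert np.allclose(clean.segments["copy"], 2.0)
        assert observed.segments["copy"].between(1.8, 2.2).all()

    def test_segments_tile_without_gaps(self, grch37):
        events = [CopyEvent("arm_gain", "17", arm="q", copy=3.0)]
        _, clean = simulate_copy_profile(grch37, events, seed=1)
        for spec in grch37:
            sub = clean.segments[clean.segments["chrom"] == spec.name]
            assert sub["start"].iloc[0] == 1
            assert sub["end"].iloc[-1] == spec.length
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1] + 1).all()

    def test_contradictory_events_rejected(self, grch37):
        events = [
            CopyEvent("region", "1", copy=3.0, start=1, end=10 * MB),
            CopyEvent("region", "1", copy=4.0, start=5 * MB, end=15 * MB),
        ]
        with pytest.raises(ValueError, match="contradictory"):
            simulate_copy_profile(grch37, events, seed=1)

    def test_nine_wc_events_classify_9plus(self, grch37):
        chroms = [str(c) for c in range(3, 12)]
        events = [CopyEvent("wc_gain", c, copy=3.0) for c in chroms]
        observed, _ = simulate_copy_profile(grch37, events, noise_sd=0.05, seed=2)
        recentered, _ = recenter_profile(observed)
        ploidy = classify_9plus_wc(recentered, grch37)
        assert ploidy.is_9plus and ploidy.n_whole_chrom_gains == 9

    def test_offset_recovered_by_recentering(self, grch37):
        observed, _ = simulate_copy_profile(
            grch37, [], centering_offset=0.7, noise_sd=0.05, seed=3
        )
        _, offset = recenter_profile(observed)
        assert offset == pytest.approx(-0.7, abs=0.02)


class TestSnvSimulation:
    def _flat3(self, grch37, chroms=("3", "4", "5")):
        events = [CopyEvent("wc_gain", c, copy=3.0) for c in chroms]
        _, clean = simulate_copy_profile(grch37, events, noise_sd=0.0, seed=0)
        return clean

    def test_pure_signature_spectrum_matches_definition(self, grch37, sigs):
        _, clean = simulate_copy_profile(grch37, [], noise_sd=0.0, seed=0)
        snvs = simulate_snvs({"SBS18": 500}, sigs, clean, 1.0, 0.0, 100, seed=5)
        spectrum, rejected = build_spectrum(snvs)
        assert rejected == 0
        assert cosine_similarity(
            spectrum.counts.to_numpy(), sigs["SBS18"].to_numpy()
        ) >= 0.95

    def test_spectrum_chi_square_goodness_of_fit(self, grch37, sigs):
        """Empirical 96-class counts converge to the exposure-weighted mixture
        (alpha = 0.001, n >= 2000)."""
        _, clean = simulate_copy_profile(grch37, [], noise_sd=0.0, seed=0)
        exposures = {"SBS1": 500, "SBS5": 700, "SBS18": 1000}
        n = sum(exposures.values())
        snvs = simulate_snvs(exposures, sigs, clean, 1.0, 0.0, 100, seed=6)
        spectrum, _ = build_spectrum(snvs)
        expected = sum(w * sigs[k] for k, w in exposures.items())
        # pool classes with small expectation for chi-square validity
        obs, exp = [], []
        pool_o = pool_e = 0.0
        for c in CONTEXT_CLASSES:
            if expected[c] >= 5:
                obs.append(spectrum.counts[c])
                exp.append(expected[c])
            else:
                pool_o += spectrum.counts[c]
                pool_e += expected[c]
        if pool_e > 0:
            obs.append(pool_o)
            exp.append(pool_e)
        _, p = stats.chisquare(obs, exp)
        assert p > 0.001

    def test_post_gain_vafs_at_one_third(self, grch37, sigs):
        """fraction_pre_gain = 0 at purity 1: every 3-copy mutation has
        expected VAF exactly 1/3."""
        clean = self._flat3(grch37)
        snvs = simulate_snvs({"SBS18": 2000}, sigs, clean, 1.0, 0.0, 200, seed=7)
        three = snvs[snvs["local_copies"] == 3]
        assert len(three) > 100
        assert np.allclose(three["expected_vaf"], 1 / 3)
        assert (three["multiplicity"] == 1).all()

    def test_all_pre_gain_half_on_single_allele(self, grch37, sigs):
        clean = self._flat3(grch37)
        snvs = simulate_snvs({"SBS18": 4000}, sigs, clean, 1.0, 1.0, 100, seed=8)
        three = snvs[snvs["local_copies"] == 3]
        frac_m1 = (three["multiplicity"] == 1).mean()
        se = np.sqrt(0.25 / len(three))
        assert abs(frac_m1 - 0.5) <= 3 * se

    def test_vaf_stratum_means_match_model(self, grch37, sigs):
        clean = self._flat3(grch37)
        purity, depth = 0.8, 150
        snvs = simulate_snvs({"SBS18": 5000}, sigs, clean, purity, 0.5, depth, seed=9)
        for (copies, mult), grp in snvs.groupby(["local_copies", "multiplicity"]):
            if len(grp) < 30:
                continue
            ev = grp["expected_vaf"].iloc[0]
            se = np.sqrt(ev * (1 - ev) / depth / len(grp))
            assert abs(grp["vaf"].mean() - ev) <= 3 * se

    def test_unknown_signature_rejected(self, grch37, sigs):
        _, clean = simulate_copy_profile(grch37, [], seed=0)
        with pytest.raises(ValueError, match="absent from matrix"):
            simulate_snvs({"SBS99": 10}, sigs, clean, 1.0, 0.5, 60)


class TestSvSimulation:
    def test_direct_join_marks_pair_non_independent(self):
        a = Alteration("A", (("11", 90 * MB),))
        b = Alteration("B", (("17", 50 * MB),))
        svs = simulate_svs(
            [SvPlanEntry("direct_join", boundary_a=("11", 90 * MB), boundary_b=("17", 50 * MB))],
            seed=1,
        )
        graph = build_linkage_graph(svs, [a, b])
        assert independent_pair_filter(graph, ("A", "B")) == "linked"

    def test_long_hop_chain_stays_independent(self):
        a = Alteration("A", (("11", 90 * MB),))
        b = Alteration("B", (("17", 50 * MB),))
        svs = simulate_svs(
            [
                SvPlanEntry(
                    "chain",
                    boundary_a=("11", 90 * MB),
                    boundary_b=("17", 50 * MB),
                    via_chrom="5",
                    via_pos=40 * MB,
                    spacing=20 * MB,
                )
            ],
            seed=2,
        )
        graph = build_linkage_graph(svs, [a, b])
        assert independent_pair_filter(graph, ("A", "B")) == "independent"

    def test_short_hop_chain_links(self):
        a = Alteration("A", (("11", 90 * MB),))
        b = Alteration("B", (("17", 50 * MB),))
        svs = simulate_svs(
            [
                SvPlanEntry(
                    "chain",
                    boundary_a=("11", 90 * MB),
                    boundary_b=("17", 50 * MB),
                    via_chrom="5",
                    via_pos=40 * MB,
                    spacing=10 * MB,
                )
            ],
            seed=2,
        )
        graph = build_linkage_graph(svs, [a, b])
        assert independent_pair_filter(graph, ("A", "B")) == "linked"

    def test_hotspot_plan_is_t11_17_positive(self):
        (sv,) = simulate_svs([SvPlanEntry("hotspot_t11_17")], seed=3)
        assert classify_t11_17(sv)


class TestCohort:
    def test_identical_seeds_byte_identical_outputs(self, tmp_path):
        cfg = CohortConfig(n_samples=6, seed=7)
        for name in ("run1", "run2"):
            write_cohort(simulate_cohort(cfg), tmp_path / name)
        for fname in ["segments.tsv", "snvs.tsv", "svs.tsv", "metadata.tsv", "truth.json"]:
            assert (tmp_path / "run1" / fname).read_bytes() == (
                tmp_path / "run2" / fname
            ).read_bytes(), fname

    def test_cohort_size_extension_preserves_earlier_samples(self):
        small = simulate_cohort(CohortConfig(n_samples=4, seed=11))
        large = simulate_cohort(CohortConfig(n_samples=8, seed=11))
        pd.testing.assert_frame_equal(
            small.snvs, large.snvs[large.snvs["sample"].isin(small.profiles)].reset_index(drop=True)
        )

    def test_truth_completeness(self):
        cohort = simulate_cohort(CohortConfig(n_samples=8, seed=13))
        # every sample appears once everywhere
        assert set(cohort.truth) == set(cohort.profiles) == set(cohort.metadata.index)
        for sid, entry in cohort.truth.items():
            sample_snvs = cohort.snvs[cohort.snvs["sample"] == sid]
            assert entry["n_snvs"] == len(sample_snvs)
            # per-SNV truth columns present for every emitted SNV
            assert sample_snvs["true_signature"].notna().all()
            sample_svs = cohort.svs[cohort.svs["sample"] == sid]
            assert len(entry["svs"]) == len(sample_svs)
            if "wc_9plus" in entry["events"]:
                assert len(entry["wc_chromosomes"]) >= 9

    def test_high_purity_config_passes_timing_filter(self):
        cohort = simulate_cohort(CohortConfig(n_samples=6, seed=17, purity_range=(0.7, 0.7)))
        assert (cohort.metadata["purity"] >= 0.7).all()

    def test_age_groups_match_ages(self):
        cohort = simulate_cohort(CohortConfig(n_samples=20, seed=19))
        from nbsomatic.association_stats import assign_age_group

        derived = cohort.metadata["age_years"].map(assign_age_group)
        assert (derived == cohort.metadata["age_group"]).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_samples=0)
        with pytest.raises(ValueError):
            CohortConfig(purity_range=(0.0, 1.0))
        with pytest.raises(ValueError):
            CohortConfig(age_distribution={"A": 1.0, "B": 0.0})
        with pytest.raises(ValueError):
            CohortConfig(event_prevalences={"x": 1.5})
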