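"""Compartment statistics: PC1, strength, saddle, homogeneity, regions, switch."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hictempo import SimConfig, TimepointSpec, simulate_contact_map, simulate_signal_track, simulate_timecourse
from hictempo.compartments import (
    CompartmentProfile,
    aa_decile_means,
    classify_strength_change,
    classify_switch,
    compartment_regions,
    compute_pc1,
    homogeneity,
    interactions_by_pc1_range,
    per_bin_strength,
    region_size_stats,
    saddle,
    smooth_by_tads,
)
from hictempo.matrix import ice_balance, merge_replicates, oe_transform
from hictempo.simulate import TIMEPOINT_ORDER, _plant_structure
from hictempo.tads import TADSet


def _profile(labels, pc1=None, bin_size=40_000):
    labels = np.asarray(labels, dtype=object)
    if pc1 is None:
        pc1 = np.where(labels == "A", 0.8, -0.8).astype(float)
        pc1[labels == "filtered"] = np.nan
    return CompartmentProfile("chrS", bin_size, np.asarray(pc1, float), labels)


def _checkerboard_oe(n=20, same=2.0, cross=0.5):
    lab = np.array(["A", "B"] * (n // 2), dtype=object)
    same_mask = np.equal.outer(lab, lab)
    oe = np.where(same_mask, same, cross)
    return oe, _profile(lab)


class TestPC1:
    def test_recovers_planted_profile(self, small_sim, small_oe):
        cfg, _, truth, bal = small_sim
        track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=77)
        prof = compute_pc1(bal, track, oe=small_oe)
        valid = ~np.isnan(prof.pc1)
        r = np.corrcoef(prof.pc1[valid], truth.true_profile[valid])[0, 1]
        assert r >= 0.9

    def test_orientation_flip_negates(self, small_sim, small_oe):
        cfg, _, truth, bal = small_sim
        track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=77)
        anti = simulate_signal_track(-truth.true_profile, 1.0, 0.2, seed=77)
        a = compute_pc1(bal, track, oe=small_oe)
        b = compute_pc1(bal, anti, oe=small_oe)
        valid = ~np.isnan(a.pc1)
        np.testing.assert_allclose(a.pc1[valid], -b.pc1[valid], rtol=1e-9)
        assert set(np.unique(a.labels[valid])) == {"A", "B"}

    def test_null_amplitude_gives_low_eig_fraction(self):
        cfg = SimConfig(n_bins=200, seed=2, compartment_amplitude=0.0)
        reps, truth = simulate_contact_map(cfg)
        bal = ice_balance(merge_replicates(reps))
        track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=5)
        null_prof = compute_pc1(bal, track)
        strong, truth_s = simulate_contact_map(SimConfig(n_bins=200, seed=2, compartment_amplitude=2.0))
        bal_s = ice_balance(merge_replicates(strong))
        strong_prof = compute_pc1(bal_s, simulate_signal_track(truth_s.true_profile, 1.0, 0.2, seed=5))
        assert null_prof.eig_fraction < strong_prof.eig_fraction


class TestSmoothing:
    def test_single_bin_tads_are_identity(self):
        prof = _profile(["A", "B", "A", "B"], pc1=[0.5, -0.2, 0.9, -0.7])
        tads = TADSet("chrS", 40_000, 4, np.array([1, 2, 3]))
        sm = smooth_by_tads(prof, tads)
        np.testing.assert_array_equal(sm.pc1, prof.pc1)

    def test_single_tad_gives_global_mean(self):
        prof = _profile(["A"] * 4, pc1=[0.1, 0.2, 0.3, 0.4])
        tads = TADSet("chrS", 40_000, 4, np.array([], dtype=int))
        sm = smooth_by_tads(prof, tads)
        assert np.allclose(sm.pc1, 0.25)

    def test_denoising_when_profile_constant_in_tads(self, small_sim, small_oe):
        cfg, _, truth, bal = small_sim
        track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=77)
        prof = compute_pc1(bal, track, oe=small_oe)
        tads = TADSet("chrS", cfg.bin_size, cfg.n_bins, truth.true_boundaries)
        sm = smooth_by_tads(prof, tads)
        mse_raw = np.nanmean((prof.pc1 - truth.true_profile) ** 2)
        mse_sm = np.nanmean((sm.pc1 - truth.true_profile) ** 2)
        assert mse_sm < mse_raw


class TestStrength:
    def test_uniform_oe_gives_strength_one(self):
        oe, prof = _checkerboard_oe(same=1.0, cross=1.0)
        st_vals = per_bin_strength(oe, prof)
        assert np.allclose(st_vals, 1.0)
        ch = classify_strength_change(st_vals, st_vals)
        assert ch["unchanged"] == 1.0

    def test_checkerboard_strength_is_four_exactly(self):
        oe, prof = _checkerboard_oe(same=2.0, cross=0.5)
        st_vals = per_bin_strength(oe, prof)
        assert np.allclose(st_vals, 4.0)

    def test_sharpening_strengthens_more_than_weakens(self):
        cfg = SimConfig(n_bins=300, seed=4)
        course = simulate_timecourse(
            cfg, [TimepointSpec("0"), TimepointSpec("2", amplitude_multiplier=3.0)]
        )
        truth = course["0"][1]
        track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=9)
        st_by_tp = {}
        for tp in ("0", "2"):
            bal = ice_balance(merge_replicates(course[tp][0]))
            oe = oe_transform(bal)
            prof = compute_pc1(bal, track, oe=oe)
            st_by_tp[tp] = per_bin_strength(oe, prof)
        ch = classify_strength_change(st_by_tp["2"], st_by_tp["0"])
        assert ch["strengthened"] > ch["weakened"]


class TestSaddle:
    def test_uniform_oe_all_ones_score_one(self):
        rng = np.random.default_rng(0)
        pc1 = rng.uniform(-1, 1, 200)
        res = saddle(np.ones((200, 200)), pc1, n=10)
        assert np.allclose(res.grid, 1.0)
        assert np.isclose(res.score, 1.0)

    def test_grid_symmetric(self, small_sim, small_oe):
        cfg, _, truth, bal = small_sim
        track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=77)
        prof = compute_pc1(bal, track, oe=small_oe)
        res = saddle(small_oe, prof.pc1, n=15)
        np.testing.assert_allclose(res.grid, res.grid.T, rtol=1e-12)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            saddle(np.ones((8, 8)), np.linspace(-1, 1, 8), n=50)

    def test_score_monotone_in_planted_amplitude(self):
        scores = []
        for amp in (0.5, 1.0, 2.0):
            cfg = SimConfig(n_bins=300, seed=6, compartment_amplitude=amp)
            reps, truth = simulate_contact_map(cfg)
            bal = ice_balance(merge_replicates(reps))
            oe = oe_transform(bal)
            track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=8)
            prof = compute_pc1(bal, track, oe=oe)
            scores.append(saddle(oe, prof.pc1, n=20).score)
        assert scores[0] < scores[1] < scores[2]


class TestPC1RangeGrid:
    def test_checkerboard_forced_values(self):
        oe, prof = _checkerboard_oe(same=2.0, cross=0.5)
        grid = interactions_by_pc1_range(oe, prof, [(0.0, 1.0), (-1.0, 0.0)])
        np.testing.assert_allclose(grid, [[2.0, 0.5], [0.5, 2.0]])

    def test_overlapping_ranges_rejected(self):
        oe, prof = _checkerboard_oe()
        with pytest.raises(ValueError):
            interactions_by_pc1_range(oe, prof, [(0.0, 0.5), (0.4, 1.0)])

    def test_empty_range_gives_nan(self):
        oe, prof = _checkerboard_oe()
        grid = interactions_by_pc1_range(oe, prof, [(0.0, 1.0), (5.0, 6.0)])
        assert np.isnan(grid[1, 1])


class TestHomogeneity:
    def test_textbook_example(self):
        assert homogeneity(np.array([1.0, 2.0, 3.0])) == pytest.approx(4.0)

    def test_zero_variance_is_infinite(self):
        assert homogeneity(np.array([2.0, 2.0, 2.0])) == float("inf")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.1, 100), min_size=3, max_size=20),
        st.floats(0.01, 50),
    )
    def test_scale_invariance(self, values, c):
        v = np.asarray(values)
        # exclude (near-)degenerate inputs where variance is pure float noise
        if v.var(ddof=1) < 1e-9 * v.mean() ** 2:
            return
        assert homogeneity(c * v) == pytest.approx(homogeneity(v), rel=1e-9)

    def test_homogenization_schedule_raises_homogeneity(self):
        cfg = SimConfig(n_bins=300, seed=1)
        course = simulate_timecourse(
            cfg, [TimepointSpec("0"), TimepointSpec("2", amplitude_multiplier=0.4)]
        )
        truth = course["0"][1]
        track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=3)
        h = {}
        for tp in ("0", "2"):
            bal = ice_balance(merge_replicates(course[tp][0]))
            oe = oe_transform(bal)
            prof = compute_pc1(bal, track, oe=oe)
            h[tp] = homogeneity(aa_decile_means(oe, prof))
        assert h["2"] > h["0"]


class TestRegions:
    def test_run_length_encoding(self):
        prof = _profile(["A", "A", "B", "B", "A"])
        regions = compartment_regions(prof)
        assert regions.records["name"].tolist() == ["A", "B", "A"]
        assert (regions.records["end"] - regions.records["start"]).tolist() == [
            80_000, 80_000, 40_000,
        ]

    def test_all_a_single_region(self):
        prof = _profile(["A"] * 6)
        regions = compartment_regions(prof)
        mean, total = region_size_stats(regions, "A")
        assert len(regions) == 1 and total == 6 * 40_000

    def test_breakpoints_match_planted_sign_changes(self, small_sim, small_oe):
        cfg, _, truth, bal = small_sim
        track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=77)
        prof = compute_pc1(bal, track, oe=small_oe)
        tads = TADSet("chrS", cfg.bin_size, cfg.n_bins, truth.true_boundaries)
        sm = smooth_by_tads(prof, tads)
        regions = compartment_regions(sm)
        called = set(regions.records["start"] // cfg.bin_size) - {0}
        sign_changes = {
            i for i in range(1, cfg.n_bins)
            if np.sign(truth.true_profile[i]) != np.sign(truth.true_profile[i - 1])
        }
        # every planted sign change is a called region breakpoint
        assert sign_changes <= called


class TestSwitch:
    def _uniform_profiles(self, labels):
        return {tp: _profile(labels) for tp in TIMEPOINT_ORDER}

    def test_identical_profiles_no_switch(self):
        sw = classify_switch(self._uniform_profiles(["A", "A", "B", "B"]))
        assert sw.proportions["switch"] == 0.0
        assert sw.proportions["constant A"] == 0.5

    def test_missing_timepoint_rejected(self):
        profs = self._uniform_profiles(["A", "B"])
        del profs["5"]
        with pytest.raises(ValueError, match="missing timepoint"):
            classify_switch(profs)

    def test_planted_flip_subtypes(self):
        labels0 = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
        profs = {}
        for tp in TIMEPOINT_ORDER:
            lab = labels0.copy()
            if tp in ("2", "5", "10", "30"):
                lab[0:2] = "B"  # early flip, reverts at withdrawal
            if tp in ("30", "withdrawal"):
                lab[4:6] = "A"  # late flip, persists
            profs[tp] = _profile(lab)
        sw = classify_switch(profs)
        early = sw.region_at(0)
        late = sw.region_at(4)
        assert (early.label, early.subtype) == ("switch", "early-affected,recoverable")
        assert (late.label, late.subtype) == ("switch", "late-affected,irrecoverable")

    def test_regions_partition_all_bins(self):
        labels = np.array(["A", "B", "filtered", "B", "A", "A"], dtype=object)
        sw = classify_switch(self._uniform_profiles(labels))
        covered = sorted(
            (b for r in sw.regions for b in range(r.start_bin, r.end_bin))
        )
        assert covered == list(range(6))
        assert sum(sw.proportions.values()) == pytest.approx(1.0)
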