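"""TAD calling, differential boundaries, reorganization events, ATA."""

import numpy as np
import pytest

from hictempo import SimConfig, TimepointSpec, simulate_contact_map, simulate_timecourse
from hictempo.matrix import ContactMatrix, ice_balance, merge_replicates, oe_transform
from hictempo.simulate import _plant_structure
from hictempo.tads import (
    BoundaryChange,
    TADSet,
    ata,
    bin_signal,
    boundary_change_test,
    boundary_f1,
    call_tads,
    classify_reorganization,
    direction_index,
)
from hictempo.tads import test_boundary_change as detect_boundary_changes


def _balanced(counts, bin_size=40_000):
    m = ContactMatrix("chrS", bin_size, counts)
    m.weights = np.ones(counts.shape[0])
    return m


class TestBinSignal:
    def test_constant_matrix_constant_signal(self):
        m = _balanced(np.full((30, 30), 5.0))
        sig = bin_signal(m, window=3)
        interior = sig[3:-4]
        assert np.allclose(interior, 5.0)

    def test_zero_cross_block_contact_gives_zero_at_split(self):
        c = np.zeros((20, 20))
        c[:10, :10] = 4.0
        c[10:, 10:] = 4.0
        m = _balanced(c)
        sig = bin_signal(m, window=3)
        assert sig[9] == 0.0
        assert sig[5] > 0

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            bin_signal(_balanced(np.ones((5, 5))), window=5)

    def test_local_minima_at_planted_boundaries(self, small_sim):
        cfg, _, truth, bal = small_sim
        sig = bin_signal(bal, window=5)
        for b in truth.true_boundaries[2:-2]:
            window = sig[b - 3 : b + 2]
            assert np.nanargmin(window) in (1, 2, 3)  # minimum within +-1 of gap


class TestCallTads:
    def test_planted_boundaries_recovered(self, small_sim):
        cfg, _, truth, bal = small_sim
        tset = call_tads(bal)
        assert boundary_f1(tset.boundaries, truth.true_boundaries, tol=1) >= 0.9

    def test_domains_tile_chromosome(self, small_sim):
        _, _, _, bal = small_sim
        tset = call_tads(bal)
        doms = tset.domains
        assert doms[0][0] == 0 and doms[-1][1] == bal.n_bins
        for (s1, e1), (s2, e2) in zip(doms, doms[1:]):
            assert e1 == s2

    def test_null_simulation_rarely_spurious(self):
        spurious = []
        for seed in range(10):
            cfg = SimConfig(
                n_bins=300, seed=seed, tad_boost=1.0, loop_boost=1.0,
                compartment_amplitude=0.0,
            )
            reps, _ = simulate_contact_map(cfg)
            bal = ice_balance(merge_replicates(reps))
            spurious.append(len(call_tads(bal).boundaries))
        assert np.mean([s <= 2 for s in spurious]) >= 0.9


class TestDirectionIndex:
    def test_symmetric_constant_interior_balanced(self):
        m = ContactMatrix("chrS", 40_000, np.full((30, 30), 3.0))
        up, down = direction_index(m, span=5)
        assert up[15] == down[15]

    def test_bin_left_of_boundary_upstream_dominated(self):
        c = np.zeros((30, 30))
        c[:15, :15] = 10.0
        c[15:, 15:] = 10.0
        m = ContactMatrix("chrS", 40_000, c)
        up, down = direction_index(m, span=5)
        assert up[14] > down[14]
        assert down[15] > up[15]

    def test_chromosome_ends_truncated(self):
        m = ContactMatrix("chrS", 40_000, np.full((10, 10), 2.0))
        up, down = direction_index(m, span=7)
        assert up[0] == 0.0
        assert down[-1] == 0.0


class TestBoundaryChangeTest:
    def test_single_replicate_refused(self):
        di = [(np.ones(10), np.ones(10))]
        with pytest.raises(ValueError):
            boundary_change_test(di, di, np.array([5]))

    def test_null_false_change_rate_controlled(self):
        tested = sig = 0
        for seed in range(25):
            cfg = SimConfig(n_bins=300, seed=seed, n_replicates=4, depth=1e6)
            reps, truth = simulate_contact_map(cfg)
            di = [direction_index(m) for m in reps]
            _, _, q = boundary_change_test(di[:2], di[2:], truth.true_boundaries)
            tested += q.size
            sig += int((q < 0.05).sum())
        rate = sig / tested
        # nominal 0.05 within the binomial 95% CI
        assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / tested)

    def test_planted_deletion_reported_lost(self):
        hits = 0
        seeds = (0, 1, 2, 3)
        for seed in seeds:
            cfg = SimConfig(n_bins=300, seed=seed)
            truth = _plant_structure(cfg, np.random.default_rng(seed))
            delb = int(truth.true_boundaries[len(truth.true_boundaries) // 2])
            sched = [
                TimepointSpec("0"),
                TimepointSpec("2", boundary_deletions=(delb,)),
            ]
            course = simulate_timecourse(cfg, sched)
            reps0, reps2 = course["0"][0], course["2"][0]
            t_ref = call_tads(ice_balance(merge_replicates(reps0)))
            t_alt = call_tads(ice_balance(merge_replicates(reps2)))
            di0 = [direction_index(m) for m in reps0]
            di2 = [direction_index(m) for m in reps2]
            changes = detect_boundary_changes(di2, di0, t_ref, t_alt)
            lost = [c.boundary for c in changes if c.direction == "lost"]
            hits += any(abs(b - delb) <= 2 for b in lost)
        assert hits >= 3

    def test_no_candidates_gives_empty(self):
        t = TADSet("chrS", 40_000, 100, np.array([50]))
        di = [(np.ones(100), np.ones(100))] * 2
        assert detect_boundary_changes(di, di, t, t) == []


class TestClassifyReorganization:
    def test_fusion_forced_case(self):
        ref = TADSet("chrS", 40_000, 200, np.array([50, 100, 150]))
        alt = TADSet("chrS", 40_000, 200, np.array([50, 150]))
        changes = [BoundaryChange(100, "lost", 0.001)]
        events, unchanged = classify_reorganization(ref, alt, changes)
        assert len(events) == 1 and events[0].kind == "fusion"
        assert sorted(events[0].ref_domains) == [(50, 100), (100, 150)]
        assert events[0].alt_domains == [(50, 150)]
        assert unchanged == 2

    def test_shift_within_tolerance(self):
        ref = TADSet("chrS", 40_000, 200, np.array([50, 100, 150]))
        alt = TADSet("chrS", 40_000, 200, np.array([50, 102, 150]))
        changes = [BoundaryChange(100, "lost", 0.01), BoundaryChange(102, "gained", 0.01)]
        events, _ = classify_reorganization(ref, alt, changes, shift_tol_bins=2)
        assert [e.kind for e in events] == ["shifting"]
        assert events[0].boundaries == [100, 102]

    def test_separation_forced_case(self):
        ref = TADSet("chrS", 40_000, 200, np.array([50, 150]))
        alt = TADSet("chrS", 40_000, 200, np.array([50, 100, 150]))
        changes = [BoundaryChange(100, "gained", 0.001)]
        events, _ = classify_reorganization(ref, alt, changes)
        assert [e.kind for e in events] == ["separation"]
        assert events[0].ref_domains == [(50, 150)]

    def test_unknown_change_rejected(self):
        ref = TADSet("chrS", 40_000, 200, np.array([50]))
        alt = TADSet("chrS", 40_000, 200, np.array([50]))
        with pytest.raises(ValueError):
            classify_reorganization(ref, alt, [BoundaryChange(77, "lost", 0.01)])

    def test_every_change_in_exactly_one_event(self):
        ref = TADSet("chrS", 40_000, 300, np.array([50, 100, 150, 200, 250]))
        alt = TADSet("chrS", 40_000, 300, np.array([50, 101, 150, 250, 270]))
        changes = [
            BoundaryChange(100, "lost", 0.01),
            BoundaryChange(101, "gained", 0.01),
            BoundaryChange(200, "lost", 0.01),
            BoundaryChange(270, "gained", 0.01),
        ]
        events, _ = classify_reorganization(ref, alt, changes)
        assigned = [b for e in events for b in e.boundaries]
        assert sorted(assigned) == [100, 101, 200, 270]


class TestATA:
    def test_single_tad_is_its_own_average(self):
        oe = np.ones((60, 60))
        tads = TADSet("chrS", 40_000, 60, np.array([20, 40]))
        mat, intra = ata(oe, tads, target_size=20, domains=[(20, 40)])
        assert np.allclose(mat[~np.isnan(mat)], 1.0)
        assert intra == pytest.approx(1.0)

    def test_planted_boost_enriches_center_over_flanks(self, small_sim, small_oe):
        cfg, _, truth, bal = small_sim
        tads = TADSet("chrS", cfg.bin_size, cfg.n_bins, truth.true_boundaries)
        mat, intra = ata(small_oe, tads, target_size=30)
        f = 15  # flank pixels at flank_frac=0.5
        center = np.nanmean(mat[f:-f, f:-f])
        flank = np.nanmean(mat[:f, f:-f])  # upstream flank vs body columns
        assert center / flank >= 1.5

    def test_no_eligible_tads_rejected(self):
        oe = np.ones((10, 10))
        tads = TADSet("chrS", 40_000, 10, np.array([], dtype=int))
        with pytest.raises(ValueError):
            ata(oe, tads, domains=[(0, 2)])
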