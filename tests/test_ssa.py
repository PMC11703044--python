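"""Single-trajectory SSA semantics: propensities, reaction updates,
invariants, RNG reproducibility, and distributional laws."""

import math

import numpy as np
import pytest
from scipy import stats

from fiberlysis import (
    ABSENT,
    RateSet,
    SimConfig,
    apply_reaction,
    build_cross_section,
    init_state,
    local_propensities,
    simulate_run,
    spawn_seeds,
)
from fiberlysis.ssa import (
    fraction_threshold_counts,
    simulate_run_reference,
    step,
    threshold_count,
)


def fresh_state(cs, loc=None, rng=None):
    rng = rng or np.random.RandomState(0)
    s = init_state(cs, rng)
    if loc is not None:
        # relocate plasmin deterministically for constructed scenarios
        s.n00[s.plasmin_location] += 1
        s.plasmin_location = loc
        s.n00[loc] -= 1
    return s


class TestThresholds:
    def test_two_thirds_of_294_is_196(self):
        assert threshold_count(2 / 3, 294) == 196

    def test_exact_tie_counts_as_reached(self):
        assert threshold_count(0.5, 294) == 147

    def test_fraction_grid_monotone(self):
        counts = fraction_threshold_counts(294)
        assert len(counts) == 100
        assert counts[-1] == 294
        assert np.all(np.diff(counts) >= 0)


class TestInitState:
    def test_single_protofibril(self):
        cs = build_cross_section(1)
        s = init_state(cs, np.random.RandomState(0))
        p = s.protofibril(0)
        assert (p.N00, p.N03, p.phi00, p.phi03, p.N_cryptic) == (0, 1, 0, 0, 5)

    def test_plasmin_on_edge_others_untouched(self, cs7, rng):
        s = init_state(cs7, rng)
        assert s.plasmin_location in set(cs7.edge_indices)
        for i in range(49):
            p = s.protofibril(i)
            if i == s.plasmin_location:
                assert (p.N00, p.N03, p.N_cryptic) == (0, 1, 5)
            else:
                assert (p.N00, p.N03, p.N_cryptic) == (1, 0, 5)

    def test_edge_placement_uniform(self, cs7):
        # empirical distribution over the 24 edge sites vs the uniform law
        zero = RateSet(0, 0, 0, 0)
        locs = [
            simulate_run(cs7, zero, SimConfig(), seed=s).initial_plasmin
            for s in spawn_seeds(42, 8000)
        ]
        counts = np.bincount(locs, minlength=49)[cs7.edge_indices]
        assert counts.sum() == 8000
        _, p = stats.chisquare(counts)
        assert p > 0.001


class TestLocalPropensities:
    def test_fresh_plasmin_protofibril_hand_values(self, cs7, baseline):
        s = fresh_state(cs7, loc=0)
        a = local_propensities(s, baseline)
        expected = [0.05, 0, 5, 0, 25, 0, 0, 0, 0, 57.6, 0]
        assert a == pytest.approx(expected)
        assert a.sum() == pytest.approx(87.65)

    def test_plasmin_absent_all_zero(self, cs7, baseline):
        s = fresh_state(cs7, loc=0)
        apply_reaction(s, 1)  # unbind
        assert s.plasmin_location == ABSENT
        assert np.all(local_propensities(s, baseline) == 0)

    def test_plasmin_on_degraded_with_only_cryptic_left(self, cs7, baseline):
        # state (0,0,0,1,5): only unbind, exposure, and crawl-out possible
        s = fresh_state(cs7, loc=0)
        apply_reaction(s, 3)  # N03 -> phi03
        a = local_propensities(s, baseline)
        expected = [0, 0, 0, 0.05, 25, 0, 0, 0, 0, 0, 57.6]
        assert a == pytest.approx(expected)

    def test_crawl_out_zeroed_without_neighbors(self, baseline):
        cs1 = build_cross_section(1)
        s = init_state(cs1, np.random.RandomState(0))
        a = local_propensities(s, baseline)
        assert a[9] == 0 and a[10] == 0


class TestApplyReaction:
    def test_unbind_restores_doublet_and_removes_plasmin(self, cs7):
        s = fresh_state(cs7, loc=0)
        apply_reaction(s, 1)
        p = s.protofibril(0)
        assert (p.N00, p.N03, p.phi00, p.phi03, p.N_cryptic) == (1, 0, 0, 0, 5)
        assert s.plasmin_location == ABSENT

    def test_degrade_unbound_doublet(self, cs7, rng):
        s = fresh_state(cs7, loc=0)
        apply_reaction(s, 5)  # expose one cryptic -> N00
        apply_reaction(s, 2)  # degrade it
        p = s.protofibril(0)
        assert (p.N00, p.N03, p.phi00, p.phi03, p.N_cryptic) == (0, 1, 1, 0, 4)
        assert s.degraded_count == 1
        assert s.first_degradation == 0

    def test_degrade_bound_doublet_marks_plasmin_on_phi(self, cs7):
        s = fresh_state(cs7, loc=0)
        apply_reaction(s, 3)
        assert s.plasmin_on_degraded
        assert s.protofibril(0).phi03 == 1

    def test_null_swaps_change_nothing(self, cs7):
        s = fresh_state(cs7, loc=0)
        apply_reaction(s, 5)
        before = (s.n00.copy(), s.phi00.copy(), s.cryptic.copy(),
                  s.plasmin_location, s.plasmin_on_degraded)
        apply_reaction(s, 8)
        after = (s.n00, s.phi00, s.cryptic,
                 s.plasmin_location, s.plasmin_on_degraded)
        assert np.array_equal(before[0], after[0])
        assert np.array_equal(before[1], after[1])
        assert before[3:] == after[3:]

    def test_within_protofibril_crawl_to_degraded(self, cs7):
        s = fresh_state(cs7, loc=0)
        apply_reaction(s, 5)
        apply_reaction(s, 2)  # a phi00 now exists alongside bound N03
        apply_reaction(s, 6)  # N03 -> phi00 swap
        p = s.protofibril(0)
        assert (p.N00, p.N03, p.phi00, p.phi03) == (1, 0, 0, 1)
        assert s.plasmin_on_degraded

    def test_zero_propensity_reaction_rejected(self, cs7):
        s = fresh_state(cs7, loc=0)
        with pytest.raises(ValueError):
            apply_reaction(s, 2)  # no unbound exposed doublet yet
        with pytest.raises(ValueError):
            apply_reaction(s, 4)  # plasmin not on a degraded doublet
        with pytest.raises(ValueError):
            apply_reaction(s, 12)

    def test_corner_crawl_destinations_equally_likely(self):
        cs = build_cross_section(2)
        rng = np.random.RandomState(7)
        dests = []
        for _ in range(8000):
            s = fresh_state(cs, loc=0)
            apply_reaction(s, 10, rng)
            dests.append(s.plasmin_location)
        counts = np.bincount(dests, minlength=4)
        assert set(np.flatnonzero(counts)) == {1, 2}  # the two lattice neighbors
        _, p = stats.chisquare(counts[[1, 2]])
        assert p > 0.001

    def test_conservation_and_single_plasmin_along_trajectory(self, cs3, baseline):
        rng = np.random.RandomState(99)
        s = init_state(cs3, rng)
        total = s.total_doublets
        prev_degraded = 0
        for _ in range(600):
            rid = step(s, baseline, rng)
            s.check_invariants()
            bound = sum(
                s.protofibril(i).N03 + s.protofibril(i).phi03
                for i in range(cs3.n_protofibrils)
            )
            if s.plasmin_location == ABSENT:
                assert bound == 0
                break
            assert bound == 1
            assert s.degraded_count >= prev_degraded
            prev_degraded = s.degraded_count
            assert s.total_doublets == total


class TestSimulateRun:
    def test_nothing_degrades_without_deg_or_exp(self, cs7):
        r = simulate_run(cs7, RateSet(0.05, 57.6, 0, 0), SimConfig(), seed=3)
        assert not r.success
        assert r.final_map.sum() == 0

    def test_never_unbinding_always_cleaves(self, cs7):
        rates = RateSet(0, 57.6, 5, 5)
        for seed in spawn_seeds(5, 20):
            assert simulate_run(cs7, rates, SimConfig(), seed=seed).success

    def test_same_seed_same_trajectory(self, cs7, baseline):
        cfg = SimConfig(record_events=True)
        a = simulate_run(cs7, baseline, cfg, seed=11)
        b = simulate_run(cs7, baseline, cfg, seed=11)
        assert a.event_log == b.event_log
        assert a.cleavage_time_s == b.cleavage_time_s
        assert np.array_equal(a.final_map, b.final_map)

    def test_fraction_times_nondecreasing(self, cs7, baseline):
        r = simulate_run(cs7, baseline, SimConfig(stop_at_cleavage=False), seed=21)
        times = [t for t in r.fraction_times_s.values() if t is not None]
        assert times == sorted(times)
        # success flag is equivalent to the threshold fraction being crossed
        assert r.success == (r.cleavage_time_s is not None)

    def test_kernel_matches_pure_python_reference(self, cs3, baseline):
        cfg = SimConfig(record_events=True, max_events=500_000)
        for seed in (1, 123, 9999):
            a = simulate_run(cs3, baseline, cfg, seed=seed)
            b = simulate_run_reference(cs3, baseline, cfg, seed=seed)
            assert a.event_log == b.event_log
            assert a.success == b.success
            assert a.end_time_s == b.end_time_s
            assert np.array_equal(a.final_map, b.final_map)


class TestDistributionalLaws:
    def test_unbinding_times_exponential(self):
        # with degradation, exposure, and crawling off, the only event is
        # unbinding: run end times must follow Exponential(k_unbind)
        cs = build_cross_section(7)
        rates = RateSet(k_unbind=0.05, k_crawl=0, k_deg=0, k_exp=0)
        times = [
            simulate_run(cs, rates, SimConfig(), seed=s).end_time_s
            for s in spawn_seeds(8, 2000)
        ]
        _, p = stats.kstest(times, "expon", args=(0, 1 / 0.05))
        assert p > 0.001


class TestCtmcOracle:
    """Side-1 fiber with crawling off is a small continuous-time Markov
    chain; its success probability and conditional mean cleavage time are
    solved exactly and compared with the SSA."""

    KU, KD, KE = 0.05, 5.0, 5.0
    THRESHOLD = 4  # 2/3 of 6 doublets

    def _solve(self):
        # state: (x1 exposed-unbound, x3 degraded-unbound, x5 cryptic,
        # b: plasmin on degraded doublet?) with x1+x3+x5 = 5
        states = [
            (x1, x3, 5 - x1 - x3, b)
            for x1 in range(6)
            for x3 in range(6 - x1)
            for b in (0, 1)
            if x3 + b < self.THRESHOLD
        ]
        index = {s: i for i, s in enumerate(states)}
        n = len(states)
        Q = np.zeros((n, n))
        to_success = np.zeros(n)
        for s, i in index.items():
            x1, x3, x5, b = s
            rates = []
            rates.append((self.KU, None))  # unbind -> failure
            if x1 > 0:  # degrade an unbound exposed doublet
                rates.append((self.KD * x1, (x1 - 1, x3 + 1, x5, b)))
            if b == 0:  # degrade the bound doublet
                rates.append((self.KD, (x1, x3, x5, 1)))
            if x5 > 0:  # expose a cryptic doublet
                rates.append((self.KE * x5, (x1 + 1, x3, x5 - 1, b)))
            for rate, dest in rates:
                Q[i, i] -= rate
                if dest is None:
                    continue
                if dest[1] + dest[3] >= self.THRESHOLD:
                    to_success[i] += rate
                else:
                    Q[i, index[dest]] += rate
        h = np.linalg.solve(Q, -to_success)  # success probability
        g = np.linalg.solve(Q, -h)  # E[time * 1{success}]
        i0 = index[(0, 0, 5, 0)]
        return h[i0], g[i0] / h[i0]

    def test_ssa_matches_exact_chain(self):
        h, mean_t = self._solve()
        cs = build_cross_section(1)
        rates = RateSet(self.KU, 0.0, self.KD, self.KE)
        n = 40_000
        results = [
            simulate_run(cs, rates, SimConfig(), seed=s)
            for s in spawn_seeds(17, n)
        ]
        succ = np.array([r.success for r in results])
        times = np.array(
            [r.cleavage_time_s for r in results if r.success]
        )
        se = math.sqrt(h * (1 - h) / n)
        assert abs(succ.mean() - h) < 5 * se
        assert abs(times.mean() - mean_t) < 5 * times.std() / math.sqrt(len(times))
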