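"""Injection-protocol algebra: pool designation, perturbation, bands, ramps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from empathynet.protocol import (
    InjectionSchedule,
    RegionRule,
    StimLevels,
    build_protocol_empathy,
    build_protocol_self_attachment,
    designate_targets,
    perturb_targets,
    ramp_count,
    select_fixed_band,
)

LEVELS = StimLevels()


class TestDesignation:
    def test_pool_size_is_floor_of_high_level(self, rng):
        g = designate_targets(1000, LEVELS, rng)
        assert len(g) == 150
        assert len(np.unique(g)) == 150

    def test_empty_region(self, rng):
        assert designate_targets(0, LEVELS, rng).size == 0

    def test_inclusion_is_uniform(self):
        counts = np.zeros(100)
        reps = 10_000
        for seed in range(reps):
            counts[designate_targets(100, LEVELS, np.random.default_rng(seed))] += 1
        freq = counts / reps
        se = math.sqrt(0.15 * 0.85 / reps)
        assert np.all(np.abs(freq - 0.15) < 3 * se + 0.01)


class TestPerturbation:
    def test_exactly_ten_percent_swapped(self, rng):
        g = designate_targets(1000, LEVELS, rng)
        g_t = perturb_targets(g, 1000, 0.1, rng)
        assert len(g_t) == len(g) == 150
        assert len(set(g) - set(g_t)) == 15
        assert len(set(g_t) - set(g)) == 15

    def test_zero_fraction_is_identity(self, rng):
        g = designate_targets(200, LEVELS, rng)
        np.testing.assert_array_equal(perturb_targets(g, 200, 0.0, rng), g)

    def test_error_when_no_room_to_swap(self, rng):
        g = np.arange(95)
        with pytest.raises(ValueError, match="cannot swap"):
            perturb_targets(g, 100, 0.5, rng)

    def test_repeated_perturbation_covers_region(self, rng):
        g = designate_targets(1000, LEVELS, rng)
        seen = np.zeros(1000, dtype=bool)
        seen[g] = True
        for _ in range(10_000):
            g = perturb_targets(g, 1000, 0.1, rng)
            seen[g] = True
        assert seen.mean() > 0.99

    @given(size=st.integers(50, 400), frac=st.floats(0.0, 0.3))
    @settings(max_examples=25, deadline=None)
    def test_cardinality_and_membership_invariants(self, size, frac):
        rng = np.random.default_rng(0)
        g = designate_targets(size, LEVELS, rng)
        g_t = perturb_targets(g, size, frac, rng)
        assert len(g_t) == len(g)
        assert len(np.unique(g_t)) == len(g_t)
        assert g_t.min() >= 0 and g_t.max() < size


class TestFixedBand:
    def test_count_in_band_and_subset_of_pool(self, rng):
        g_t = designate_targets(1000, LEVELS, rng)
        for _ in range(50):
            c = select_fixed_band(g_t, 1000, LEVELS.M, LEVELS.H, rng)
            assert 100 <= len(c) <= 150
            assert set(c) <= set(g_t)

    def test_mean_count_is_band_midpoint(self, rng):
        g_t = designate_targets(1000, LEVELS, rng)
        counts = [len(select_fixed_band(g_t, 1000, LEVELS.M, LEVELS.H, rng))
                  for _ in range(10_000)]
        sd = math.sqrt((51**2 - 1) / 12)
        assert abs(np.mean(counts) - 125) < 3 * sd / math.sqrt(10_000) + 0.5

    def test_degenerate_band_is_deterministic(self, rng):
        g_t = designate_targets(1000, LEVELS, rng)
        counts = {len(select_fixed_band(g_t, 1000, 0.12, 0.12, rng)) for _ in range(20)}
        assert counts == {120}

    def test_band_exceeding_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds injectable pool"):
            select_fixed_band(np.arange(10), 1000, LEVELS.M, LEVELS.H, rng)


class TestRampCount:
    """The three printed linear-ramp count formulas, via their algebraic identity."""

    def test_decreasing_ramp_endpoints_and_midpoint(self):
        # phase 2, |G|(L-H)(t/p) + |G|(2H-L)
        assert ramp_count(1000, 0.15, 0.05, 10_000, 10_000, phase_index=2) == 150
        assert ramp_count(1000, 0.15, 0.05, 20_000, 10_000, phase_index=2) == 50
        assert ramp_count(1000, 0.15, 0.05, 15_000, 10_000, phase_index=2) == 100

    def test_increasing_ramp_endpoints(self):
        # phase 2, |G|(H-L)(t/p) + |G|(2L-H)
        assert ramp_count(1000, 0.05, 0.15, 10_000, 10_000, phase_index=2) == 50
        assert ramp_count(1000, 0.05, 0.15, 20_000, 10_000, phase_index=2) == 150

    def test_third_phase_ramp_endpoints(self):
        # phase 3, |G|(H-L)(t/p) + |G|(3L-2H)
        assert ramp_count(1000, 0.05, 0.15, 20_000, 10_000, phase_index=3) == 50
        assert ramp_count(1000, 0.05, 0.15, 30_000, 10_000, phase_index=3) == 150

    def test_matches_printed_formula_throughout_phase(self):
        size, p = 250, 10_000
        L, H = 0.05, 0.15
        for t in range(10_001, 20_001, 997):
            printed = math.floor(size * (L - H) * (t / p) + size * (2 * H - L) + 1e-9)
            assert ramp_count(size, H, L, t, p) == printed

    def test_final_step_proportion_equals_low_level(self):
        # the injected proportion for a decreasing ramp at t = 2p is exactly L
        assert ramp_count(1000, 0.15, 0.05, 20_000, 10_000, phase_index=2) / 1000 == 0.05

    @given(st.integers(100, 2000), st.integers(1, 2))
    @settings(max_examples=30, deadline=None)
    def test_ramp_monotone_within_phase(self, size, phase):
        p = 9000
        counts = [ramp_count(size, 0.15, 0.05, t, p)
                  for t in range((phase - 1) * p + 1, phase * p + 1, 100)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPackagedSchedules:
    def test_empathy_phase_table(self):
        sched = build_protocol_empathy()
        p1, p2, p3 = sched.phases
        assert p1.rules["AI"] == RegionRule.band("M", "H")
        assert p2.rules["AI"] == RegionRule.band("L", "M")
        assert p1.rules["aMCC"] == RegionRule.band("L", "M")
        assert p2.rules["aMCC"] == RegionRule.band("M", "H")
        for ph in (p1, p2, p3):
            assert ph.rules["BLMA_neg"] == RegionRule.band("M", "H")
        assert (p1.mpfc_target_mode, p2.mpfc_target_mode, p3.mpfc_target_mode) == (
            "close", "distant", "close")
        assert p1.rules["mPFC"].kind == "off"
        assert sched.amplitude == 90.0
        assert sched.perturb_fraction == 0.10

    def test_self_attachment_phase_table(self):
        sched = build_protocol_self_attachment()
        p1, p2, p3 = sched.phases
        assert p2.rules["AI"] == RegionRule.ramp("H", "L")
        assert p2.rules["PI"] == RegionRule.ramp("H", "L")
        assert p2.rules["aMCC"] == RegionRule.ramp("L", "H")
        assert p2.rules["mPFC"] == RegionRule.ramp("L", "H")
        assert p3.rules["mOFC"] == RegionRule.ramp("L", "H")
        assert p1.rules["mOFC"] == RegionRule.band("L", "M")
        # close-other targeting throughout phases 2-3 of this model
        assert p2.mpfc_target_mode == p3.mpfc_target_mode == "close"

    def test_self_phase_one_is_empathy_phase_one_plus_mofc(self):
        emp = build_protocol_empathy().phases[0]
        sa = build_protocol_self_attachment().phases[0]
        rules = dict(sa.rules)
        assert rules.pop("mOFC") == RegionRule.band("L", "M")
        assert rules == dict(emp.rules)

    def test_ramp_endpoints_join_band_levels(self):
        """Phase-2 ramps start at the phase-1 band's upper level and end at
        the phase-3 band's lower level (protocol continuity)."""
        sched = build_protocol_self_attachment()
        size, p = 1000, 10_000
        ai2 = sched.phases[1].rules["AI"]
        lo = sched.levels.value(ai2.lo)
        hi = sched.levels.value(ai2.hi)
        assert ramp_count(size, lo, hi, p + 1, p) in (149, 150)
        assert ramp_count(size, lo, hi, 2 * p, p) == 50

    def test_levels_and_validation(self):
        with pytest.raises(ValueError):
            StimLevels(L=0.2, M=0.1, H=0.15)
        with pytest.raises(ValueError, match="BLMA_neg"):
            InjectionSchedule(
                "x", LEVELS, 90.0,
                build_protocol_empathy().phases[:2] + (
                    build_protocol_empathy().phases[2].__class__(
                        phase_index=3, t_range=(20000, 30000), rules={},
                    ),),
            )
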