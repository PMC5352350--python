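"""Die-casting rules, Hill behavior probabilities, kernel primitives."""

import numpy as np
import pytest

from habm._kernels import (
    nearest_of_kind,
    pick_free_neighbor,
    pick_stiffest_neighbor,
    pick_toward,
)
from habm.agents import (
    AbmParams,
    attempt_lysis,
    cd8_proliferation_prob,
    decide,
    divide_site,
    hill_prob,
    mic_fate,
    mic_step_death_prob,
    mm_death_prob,
    thal_attenuation,
    treg_proliferation_prob,
    treg_suppress,
)


class TestDecide:
    def test_degenerate_probabilities(self, rng):
        assert not any(decide(0.0, rng) for _ in range(100))
        assert all(decide(1.0, rng) for _ in range(100))

    def test_acceptance_frequency(self, rng):
        n = 100_000
        hits = sum(decide(0.3, rng) for _ in range(n))
        assert hits / n == pytest.approx(0.300, abs=0.005)

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            decide(1.2, rng)


class TestHillProb:
    def test_identities(self):
        assert hill_prob(0.0, 0.8, 2.0, 2.0) == 0.0
        assert hill_prob(2.0, 0.8, 2.0, 3.0) == pytest.approx(0.4)

    def test_monotone_and_bounded(self):
        xs = np.linspace(0, 50, 100)
        vals = [hill_prob(x, 0.9, 5.0, 2.0) for x in xs]
        assert np.all(np.diff(vals) >= 0)
        assert max(vals) <= 0.9

    @pytest.mark.parametrize("kw", [dict(x=-1), dict(pmax=1.4), dict(H=0), dict(n=0.5)])
    def test_domain_errors(self, kw):
        args = dict(x=1.0, pmax=0.5, H=1.0, n=1.0)
        args.update(kw)
        with pytest.raises(ValueError):
            hill_prob(**args)


class TestFate:
    def test_deterministic_extremes(self, rng):
        assert mic_fate(1.0, rng) == "self_renew"
        assert mic_fate(0.0, rng) == "differentiate"

    def test_long_run_ratio_matches_probability(self, rng):
        p = 0.62
        n = 10_000
        renew = sum(mic_fate(p, rng) == "self_renew" for _ in range(n))
        assert renew / n == pytest.approx(p, abs=0.02)


class TestDivision:
    def _occ(self, free_sites):
        occ = np.full((5, 5, 5), 0, dtype=np.int32)  # everything occupied
        for s in free_sites:
            occ[s] = -1
        return occ

    def test_crowded_neighborhood_defers(self, rng):
        occ = self._occ([])
        assert divide_site(occ, (2, 2, 2), rng) is None

    def test_single_free_site_is_certain(self, rng):
        occ = self._occ([(1, 2, 3)])
        assert divide_site(occ, (2, 2, 2), rng) == (1, 2, 3)

    def test_uniform_over_free_moore_sites(self, rng):
        occ = np.full((5, 5, 5), -1, dtype=np.int32)
        counts = {}
        n = 13_000
        for _ in range(n):
            site = divide_site(occ, (2, 2, 2), rng)
            counts[site] = counts.get(site, 0) + 1
        assert len(counts) == 26
        observed = np.array(list(counts.values()))
        chi2 = ((observed - n / 26) ** 2 / (n / 26)).sum()
        assert chi2 < 60  # chi2(25) 99.9% quantile ~ 52.6, with margin


class TestLysis:
    def test_certain_kill_of_unattached_target(self, rng):
        assert attempt_lysis(1.0, False, 0.3, rng)

    def test_attachment_protection_factor(self, rng):
        n = 10_000
        free = sum(attempt_lysis(0.5, False, 0.3, rng) for _ in range(n)) / n
        prot = sum(attempt_lysis(0.5, True, 0.3, rng) for _ in range(n)) / n
        assert free == pytest.approx(0.5, abs=0.02)
        assert prot == pytest.approx(0.15, abs=0.02)
        assert prot < free


class TestSuppression:
    def test_zero_probability_never_acts(self, rng):
        assert all(treg_suppress(0.0, 0.5, rng) is None for _ in range(200))

    def test_arrest_apoptosis_split(self, rng):
        n = 20_000
        outcomes = [treg_suppress(1.0, 0.5, rng) for _ in range(n)]
        arrests = outcomes.count("arrest")
        assert arrests / n == pytest.approx(0.5, abs=0.01)
        assert set(outcomes) == {"arrest", "apoptosis"}


class TestBehaviorProbabilities:
    def test_cd8_saturating_tgfb_floor(self):
        p = AbmParams()
        lo = cd8_proliferation_prob(1e9, 0.0, 0.0, p)
        floor = p.prolif_pmax_cd8 * p.tgfb_floor_cd8
        assert lo == pytest.approx(floor, rel=1e-6)

    def test_cd8_len_boost_and_treg_inhibition(self):
        p = AbmParams()
        base = cd8_proliferation_prob(0.3, 5, 0.0, p)
        assert cd8_proliferation_prob(0.3, 5, 10.0, p) > base
        assert cd8_proliferation_prob(0.3, 50, 0.0, p) < base
        assert 0.0 <= base <= 1.0

    def test_treg_tgfb_driven_len_suppressed(self):
        p = AbmParams()
        assert treg_proliferation_prob(0.0, 0.0, p) == 0.0
        assert treg_proliferation_prob(1.0, 0.0, p) > treg_proliferation_prob(
            1.0, 10.0, p
        )

    def test_mm_death_monotone_in_dose(self):
        p = AbmParams()
        doses = np.linspace(0, 5, 11)
        vals = [mm_death_prob(d, p) for d in doses]
        assert vals[0] == pytest.approx(p.death_base_mm)
        assert np.all(np.diff(vals) >= 0)

    def test_mic_hazard_consistent_with_window(self):
        p = AbmParams()
        s = 0.108
        # applying the per-step hazard over the whole window recovers S
        per_step = mic_step_death_prob(s, 2.0, p)
        n_steps = p.survival_window_h / 2.0
        assert (1 - per_step) ** n_steps == pytest.approx(s, rel=1e-9)

    def test_thal_attenuation_limits(self):
        p = AbmParams()
        assert thal_attenuation(0.0, p) == 1.0
        assert thal_attenuation(1e9, p) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(ValueError):
            thal_attenuation(-1.0, p)


class TestKernelPrimitives:
    def test_pick_free_neighbor_is_unbiased(self, rng):
        occ = np.full((7, 7, 7), -1, dtype=np.int32)
        disp = np.zeros(3)
        n = 4000
        for _ in range(n):
            i, j, k = pick_free_neighbor(occ, 3, 3, 3, rng)
            disp += (i - 3, j - 3, k - 3)
        assert np.all(np.abs(disp / n) < 0.05)  # mean displacement ~ 0

    def test_pick_stiffest_prefers_the_gradient(self, rng):
        occ = np.full((5, 5, 5), -1, dtype=np.int32)
        stiff = np.full((5, 5, 5), 100.0)
        stiff[3, 2, 2] = 400.0  # one stiff neighbor
        for _ in range(50):
            assert pick_stiffest_neighbor(occ, stiff, 2, 2, 2, rng) == (3, 2, 2)

    def test_pick_toward_strictly_reduces_distance(self, rng):
        occ = np.full((9, 9, 9), -1, dtype=np.int32)
        for _ in range(50):
            i, j, k = pick_toward(occ, 2, 2, 2, 7, 7, 7, rng)
            assert (i - 7) ** 2 + (j - 7) ** 2 + (k - 7) ** 2 < (2 - 7) ** 2 * 3

    def test_nearest_of_kind_finds_the_closest(self, rng):
        occ = np.full((9, 9, 9), -1, dtype=np.int32)
        kind = np.array([0, 0], dtype=np.int8)
        occ[4, 4, 6] = 0  # distance 2
        occ[4, 4, 1] = 1  # distance 3
        assert nearest_of_kind(occ, kind, 4, 4, 4, 5, 0, 1, rng) == 0
        # out of sensing range
        assert nearest_of_kind(occ, kind, 0, 0, 0, 2, 0, 1, rng) == -1
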