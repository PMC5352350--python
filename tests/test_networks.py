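"""Topology, kinetics and calibrated-readout tests of the two ODE networks."""

import numpy as np
import pytest

from habm.networks import (
    ADHESION_FLOOR,
    OdeParameters,
    StiffnessMap,
    bmsc_stiffness_response,
    build_bmsc_network,
    build_mic_network,
    hill,
    integrate,
    mic_adhesion_rate,
    mic_survival_rate,
)


class TestHill:
    def test_zero_input_gives_zero_production(self):
        assert hill(0.0, 3.0, 0.5) == 0.0

    def test_half_saturation_identity(self):
        assert hill(0.7, 3.0, 0.7) == pytest.approx(1.5)

    def test_saturation_limit(self):
        assert hill(1e9, 3.0, 0.5) == pytest.approx(3.0, rel=1e-6)

    def test_monotone_increasing(self):
        xs = np.linspace(0, 10, 50)
        vals = [hill(x, 2.0, 1.3) for x in xs]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("x,k,H", [(-1, 1, 1), (1, 1, 0), (1, 1, -2), (1, -1, 1)])
    def test_domain_errors(self, x, k, H):
        with pytest.raises(ValueError):
            hill(x, k, H)


class TestTopology:
    def test_bmsc_network_shape(self, bmsc_net):
        assert len(bmsc_net.species) == 7
        assert len(bmsc_net.edges) == 10
        assert bmsc_net.inputs == ("SDF1",)
        assert bmsc_net.outputs == ("stiffness",)

    def test_myl2_has_two_parents(self, bmsc_net):
        parents = [src for src, dst, *_ in bmsc_net.edges if dst == "MYL2"]
        assert sorted(parents) == ["ERK", "RhoA"]

    def test_input_has_no_degradation(self, bmsc_net):
        assert "SDF1" not in bmsc_net.degradations
        assert all(s in bmsc_net.degradations for s in bmsc_net.species)

    def test_rac_has_two_parents(self, mic_net):
        parents = [src for src, dst, *_ in mic_net.edges if dst == "Rac"]
        assert sorted(parents) == ["FAK", "PI3K"]

    def test_survival_carries_the_btz_inhibition(self, mic_net):
        prods = [src for src, dst, *_ in mic_net.edges if dst == "Survival"]
        assert prods == ["NFKB"]
        assert len(mic_net.inhibitions) == 1
        sym, target, _, _ = mic_net.inhibitions[0]
        assert (sym, target) == ("D1", "Survival")

    def test_undeclared_species_rejected(self, bmsc_net):
        from habm.networks import SignalingNetwork

        with pytest.raises(ValueError, match="undeclared"):
            SignalingNetwork(
                name="bad", species=("A",), inputs=(), degradations={"A": "d1"},
                edges=(("ghost", "A", "k1", "H1"),), outputs=("A",),
            )


class TestIntegration:
    def test_decay_limit_reproduces_exponential(self, bmsc_net):
        # with vanishing production every node decays as e^{-d t} from 1
        params = OdeParameters(
            k={f"k{i}": 1e-12 for i in range(1, 11)},
            H={f"H{i}": 1.0 for i in range(1, 11)},
            d={f"d{i}": 0.5 + 0.3 * i for i in range(1, 8)},
        )
        t = np.array([0.0, 0.5, 1.0, 2.0])
        tc = integrate(bmsc_net, params, {"SDF1": 1.0}, t)
        for i, sp in enumerate(bmsc_net.species):
            d = params.d[bmsc_net.degradations[sp]]
            np.testing.assert_allclose(tc.values[i], np.exp(-d * t), rtol=1e-5)

    def test_fixed_point_agreement_with_iteration_oracle(self, bmsc_truth, bmsc_net):
        # brute-force fixed-point iteration: x_s = (sum productions)/d_s
        inputs = {"SDF1": 0.8}
        levels = {s: 1.0 for s in bmsc_net.species}
        levels.update(inputs)
        for _ in range(300):
            new = dict(levels)
            for sp in bmsc_net.species:
                prod = sum(
                    hill(levels[src], bmsc_truth.k[kid], bmsc_truth.H[hid])
                    for src, dst, kid, hid in bmsc_net.edges
                    if dst == sp
                )
                new[sp] = prod / bmsc_truth.d[bmsc_net.degradations[sp]]
            levels = new
        tc = integrate(bmsc_net, bmsc_truth, inputs, [0.0, 400.0])
        for i, sp in enumerate(bmsc_net.species):
            assert tc.values[i, -1] == pytest.approx(levels[sp], rel=1e-4)

    def test_states_bounded_by_production_over_decay(self, mic_truth, mic_net):
        tc = integrate(
            mic_net, mic_truth, {"stiffness": 1.0, "D1": 0.0}, [0.0, 50.0, 200.0]
        )
        assert (tc.values >= 0).all()
        for i, sp in enumerate(mic_net.species):
            k_in = sum(
                mic_truth.k[kid] for _, dst, kid, _ in mic_net.edges if dst == sp
            )
            bound = k_in / mic_truth.d[mic_net.degradations[sp]] + 1.0
            assert tc.values[i].max() <= bound + 1e-9

    def test_missing_input_raises(self, bmsc_truth, bmsc_net):
        with pytest.raises(ValueError, match="SDF1"):
            integrate(bmsc_net, bmsc_truth, {}, [0.0, 1.0])

    def test_zero_dose_inhibition_is_inert(self, mic_truth, mic_net):
        a = integrate(mic_net, mic_truth, {"stiffness": 0.7, "D1": 0.0}, [0, 10.0])
        b = integrate(mic_net, mic_truth, {"stiffness": 0.7}, [0, 10.0])
        np.testing.assert_array_equal(a.values, b.values)

    def test_deterministic(self, bmsc_truth, bmsc_net):
        t = [0.0, 0.3, 1.0]
        a = integrate(bmsc_net, bmsc_truth, {"SDF1": 1.0}, t)
        b = integrate(bmsc_net, bmsc_truth, {"SDF1": 1.0}, t)
        np.testing.assert_array_equal(a.values, b.values)


class TestStiffnessMap:
    def test_anchors_and_clamping(self):
        smap = StiffnessMap(s0=1.5, s_sat=2.0)
        assert smap(1.5) == 400.0
        assert smap(2.0) == 530.0
        assert smap(0.2) == 400.0  # below-baseline states clamp to 400
        assert smap(9.0) == 530.0

    def test_monotone(self):
        smap = StiffnessMap(s0=1.0, s_sat=2.0)
        s = np.linspace(0, 3, 40)
        assert np.all(np.diff(smap(s)) >= 0)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            StiffnessMap(s0=2.0, s_sat=2.0)


class TestCalibratedReadouts:
    def test_baseline_stiffness_at_zero_dose(self, bmsc_payload):
        pa = bmsc_stiffness_response(
            0.0, bmsc_payload["params"], bmsc_payload["stiffness_map"]
        )
        assert pa == pytest.approx(400.0, abs=0.5)

    def test_saturating_dose_reaches_ceiling(self, bmsc_payload):
        pa = bmsc_stiffness_response(
            1.0, bmsc_payload["params"], bmsc_payload["stiffness_map"]
        )
        assert pa == pytest.approx(530.0, abs=0.5)

    def test_stiffness_monotone_in_dose(self, bmsc_payload):
        doses = np.linspace(0, 1.2, 25)
        pa = [
            bmsc_stiffness_response(
                x, bmsc_payload["params"], bmsc_payload["stiffness_map"]
            )
            for x in doses
        ]
        assert np.all(np.diff(pa) >= -1e-9)

    def test_survival_decreasing_in_btz(self, mic_payload):
        doses = np.linspace(0, 5, 11)
        surv = [mic_survival_rate(400.0, b, mic_payload["params"]) for b in doses]
        assert np.all(np.diff(surv) <= 1e-12)

    def test_survival_increasing_in_stiffness(self, mic_payload):
        s_soft = mic_survival_rate(100.0, 0.0, mic_payload["params"])
        s_stiff = mic_survival_rate(400.0, 0.0, mic_payload["params"])
        assert s_stiff >= s_soft

    def test_untreated_survival_dominates_treated(self, mic_payload):
        for btz in (0.5, 2.0, 5.0):
            assert mic_survival_rate(400.0, 0.0, mic_payload["params"]) >= \
                mic_survival_rate(400.0, btz, mic_payload["params"])

    def test_adhesion_monotone_in_stiffness(self, mic_payload):
        a_soft = mic_adhesion_rate(100.0, mic_payload["params"])
        a_stiff = mic_adhesion_rate(400.0, mic_payload["params"])
        assert a_stiff >= a_soft

    def test_zero_stiffness_leaves_only_the_floor(self, mic_payload):
        total = mic_adhesion_rate(0.0, mic_payload["params"], t=96.0)
        assert total == pytest.approx(ADHESION_FLOOR, abs=0.02)

    def test_negative_dose_rejected(self, mic_payload):
        with pytest.raises(ValueError):
            mic_survival_rate(400.0, -1.0, mic_payload["params"])
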