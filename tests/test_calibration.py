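"""GA fitting, L1 objective, sensitivity and uncertainty analyses."""

import numpy as np
import pandas as pd
import pytest

from habm.calibration import (
    GaConfig,
    ObservationTable,
    fit_parameters_ga,
    integrate_batch,
    l1_objective,
    local_sensitivity,
    params_to_vector,
    uncertainty_analysis,
)
from habm.datasets import (
    BMSC_OBSERVED,
    BMSC_TIME_GRID_H,
    bmsc_observation_tables,
    generate_synthetic_proteomics,
)
from habm.networks import integrate


def _table_from_params(net, params, inputs, species, times):
    tc = integrate(net, params, inputs, times)
    rows = [
        {"species": sp, "time_h": t, "fold_change": tc.values[net.index(sp), i]}
        for sp in species
        for i, t in enumerate(times)
    ]
    return ObservationTable(data=pd.DataFrame(rows), inputs=inputs)


class TestObservationTable:
    def test_t0_must_be_one(self):
        df = pd.DataFrame(
            {"species": ["A"], "time_h": [0.0], "fold_change": [1.4]}
        )
        with pytest.raises(ValueError, match="t=0"):
            ObservationTable(data=df, inputs={})

    def test_positive_fold_changes_required(self):
        df = pd.DataFrame(
            {"species": ["A"], "time_h": [1.0], "fold_change": [-0.5]}
        )
        with pytest.raises(ValueError, match="positive"):
            ObservationTable(data=df, inputs={})


class TestL1Objective:
    def test_self_generated_observations_have_zero_loss(self, bmsc_net, bmsc_truth):
        obs = _table_from_params(
            bmsc_net, bmsc_truth, {"SDF1": 1.0}, BMSC_OBSERVED, list(BMSC_TIME_GRID_H)
        )
        assert l1_objective(bmsc_truth, bmsc_net, obs) == pytest.approx(0.0, abs=1e-8)

    def test_single_entry_absolute_difference(self, bmsc_net, bmsc_truth):
        tc = integrate(bmsc_net, bmsc_truth, {"SDF1": 1.0}, [0.0, 0.5])
        simulated = tc.values[bmsc_net.index("MEK"), -1]
        df = pd.DataFrame(
            {"species": ["MEK"], "time_h": [0.5], "fold_change": [simulated + 0.3]}
        )
        obs = ObservationTable(data=df, inputs={"SDF1": 1.0})
        assert l1_objective(bmsc_truth, bmsc_net, obs) == pytest.approx(0.3, abs=1e-6)

    def test_matches_brute_force_double_loop(self, bmsc_net, bmsc_truth, rng):
        obs = generate_synthetic_proteomics(
            bmsc_net, bmsc_truth, {"SDF1": 1.0},
            {sp: BMSC_TIME_GRID_H for sp in BMSC_OBSERVED},
            noise_cv=0.2, seed=5,
        )
        # independent double loop over every (species, time) entry
        times = sorted(obs.data["time_h"].unique())
        tc = integrate(bmsc_net, bmsc_truth, obs.inputs, times)
        expected = 0.0
        for _, row in obs.data.iterrows():
            sim = tc.values[bmsc_net.index(row.species), times.index(row.time_h)]
            expected += abs(row.fold_change - sim)
        assert l1_objective(bmsc_truth, bmsc_net, obs) == pytest.approx(
            expected, rel=1e-9
        )

    def test_unknown_species_listed(self, bmsc_net, bmsc_truth):
        df = pd.DataFrame(
            {"species": ["GHOST"], "time_h": [1.0], "fold_change": [1.2]}
        )
        obs = ObservationTable(data=df, inputs={"SDF1": 1.0})
        with pytest.raises(ValueError, match="GHOST"):
            l1_objective(bmsc_truth, bmsc_net, obs)


class TestBatchIntegrator:
    def test_agrees_with_reference_solver(self, mic_net, mic_truth):
        times = [0.5, 1.0, 24.0, 96.0]
        ref = integrate(mic_net, mic_truth, {"stiffness": 0.75, "D1": 0.0},
                        [0.0] + times)
        batch = integrate_batch(
            mic_net, params_to_vector(mic_net, mic_truth),
            {"stiffness": 0.75, "D1": 0.0}, times,
        )
        np.testing.assert_allclose(batch[0], ref.values[:, 1:], rtol=2e-3)


class TestGaFit:
    def test_same_seed_reproduces_the_fit(self, bmsc_net):
        obs = bmsc_observation_tables(noise_cv=0.05, seed=3)
        cfg = GaConfig(pop_size=16, generations=5, seed=9, polish=False)
        a = fit_parameters_ga(bmsc_net, obs, cfg)
        b = fit_parameters_ga(bmsc_net, obs, cfg)
        np.testing.assert_array_equal(
            params_to_vector(bmsc_net, a.params), params_to_vector(bmsc_net, b.params)
        )
        assert a.loss == b.loss

    def test_best_loss_bounds_final_population(self, bmsc_net):
        obs = bmsc_observation_tables(noise_cv=0.05, seed=3)
        res = fit_parameters_ga(
            bmsc_net, obs, GaConfig(pop_size=20, generations=8, seed=2, polish=False)
        )
        assert res.loss <= res.final_losses.min() + 1e-12
        assert np.all(np.diff(res.history) <= 1e-12)  # elitism: non-increasing

    def test_noiseless_recovery_of_output_trajectories(self, bmsc_net, bmsc_truth):
        """On noiseless synthetic data the fitted model must reproduce the
        generating trajectories within 5% at every observed point."""
        obs = bmsc_observation_tables(noise_cv=0.0, seed=3)
        res = fit_parameters_ga(
            bmsc_net, obs, GaConfig(pop_size=60, generations=60, seed=7)
        )
        for table in obs:
            truth = integrate(bmsc_net, bmsc_truth, table.inputs,
                              list(BMSC_TIME_GRID_H))
            fitted = integrate(bmsc_net, res.params, table.inputs,
                               list(BMSC_TIME_GRID_H))
            for sp in BMSC_OBSERVED:
                t_vals = truth.get(sp)[1:]
                f_vals = fitted.get(sp)[1:]
                rel = np.abs(f_vals - t_vals) / np.maximum(t_vals, 1e-9)
                assert rel.max() < 0.05, f"{sp}: {rel.max():.3f}"

    def test_summary_lists_parameters(self, bmsc_net):
        obs = bmsc_observation_tables(noise_cv=0.05, seed=3)
        res = fit_parameters_ga(
            bmsc_net, obs, GaConfig(pop_size=12, generations=3, seed=0, polish=False)
        )
        text = res.summary()
        assert "k1" in text and "d7" in text and "L1 loss" in text


class TestLocalSensitivity:
    def test_unreachable_parameter_has_zero_sensitivity(self, bmsc_net, bmsc_truth):
        # the stiffness-node constants cannot influence the upstream FAK readout
        table = local_sensitivity(
            bmsc_net, bmsc_truth, ["FAK"], {"SDF1": 1.0}, t_final=1.0
        )
        for pid in ("k9", "k10", "H9", "H10", "d7"):
            assert table.loc[pid, "FAK"] == 0.0

    def test_degradation_sign(self, bmsc_net, bmsc_truth):
        # raising the stiffness decay must lower the stiffness readout
        vec = params_to_vector(bmsc_net, bmsc_truth)
        base = integrate(bmsc_net, bmsc_truth, {"SDF1": 1.0}, [0, 1.0]).get(
            "stiffness")[-1]
        bumped = {**bmsc_truth.d, "d7": bmsc_truth.d["d7"] * 1.2}
        from habm.networks import OdeParameters

        up = OdeParameters(k=dict(bmsc_truth.k), H=dict(bmsc_truth.H), d=bumped)
        high = integrate(bmsc_net, up, {"SDF1": 1.0}, [0, 1.0]).get("stiffness")[-1]
        assert high < base

    def test_first_order_consistency_across_step_sizes(self, bmsc_net, bmsc_truth):
        full = local_sensitivity(
            bmsc_net, bmsc_truth, ["stiffness"], {"SDF1": 1.0}, 1.0,
            perturbation=0.10,
        )["stiffness"]
        half = local_sensitivity(
            bmsc_net, bmsc_truth, ["stiffness"], {"SDF1": 1.0}, 1.0,
            perturbation=0.05,
        )["stiffness"]
        # first-order responses scale with the step for the leading parameters
        lead = full.sort_values(ascending=False).index[:5]
        ratio = (full[lead] / half[lead]).to_numpy()
        assert np.all(ratio > 1.5) and np.all(ratio < 2.6)

    def test_perturbation_bounds(self, bmsc_net, bmsc_truth):
        with pytest.raises(ValueError):
            local_sensitivity(bmsc_net, bmsc_truth, ["stiffness"], {"SDF1": 1.0},
                              1.0, perturbation=0.9)


class TestUncertainty:
    def test_zero_range_collapses_to_baseline(self, bmsc_net, bmsc_truth):
        rep = uncertainty_analysis(
            bmsc_net, bmsc_truth, ["stiffness"], {"SDF1": 1.0}, 1.0,
            range_frac=0.0, sizes=[20], seed=0,
        )
        assert rep["mean_norm"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert rep["sd_norm"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_means_positive_and_sizes_respected(self, mic_net, mic_truth):
        rep = uncertainty_analysis(
            mic_net, mic_truth, ["Adhesion", "Survival"],
            {"stiffness": 0.75, "D1": 0.0}, 96.0, sizes=[30, 100], seed=1,
        )
        assert sorted(rep["size"].unique()) == [30, 100]
        assert (rep["mean_norm"] > 0).all()

    def test_empty_sizes_rejected(self, bmsc_net, bmsc_truth):
        with pytest.raises(ValueError):
            uncertainty_analysis(bmsc_net, bmsc_truth, ["stiffness"],
                                 {"SDF1": 1.0}, 1.0, sizes=[])
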