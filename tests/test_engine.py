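"""Orchestrator: initialization, conservation, reproducibility, replicates."""

import numpy as np
import pytest

from habm._kernels import EV_BIRTH, EV_DEATH, EV_DIFF, EV_LYSIS
from habm.engine import (
    SimulationConfig,
    initialize,
    replicate_seeds,
    run,
    run_replicates,
    step,
)
from habm.fields import Domain


class TestInitialize:
    def test_initial_counts(self, small_cfg):
        state = initialize(small_cfg, 1)
        counts = state.counts_by_kind()
        assert counts.tolist() == [30, 30, 8, 2]

    def test_default_counts_match_study_design(self):
        cfg = SimulationConfig()
        assert (cfg.n_mic, cfg.n_mm, cfg.n_cd8, cfg.n_treg) == (100, 100, 20, 5)

    def test_same_seed_identical_placement(self, small_cfg):
        a = initialize(small_cfg, 3)
        b = initialize(small_cfg, 3)
        np.testing.assert_array_equal(a.pos[: a.n_total], b.pos[: b.n_total])
        np.testing.assert_array_equal(a.kind[: a.n_total], b.kind[: b.n_total])

    def test_agents_inside_cylindrical_mask(self, small_cfg):
        state = initialize(small_cfg, 5)
        pos = state.pos[: state.n_total]
        assert state.mask[pos[:, 0], pos[:, 1], pos[:, 2]].all()

    def test_overfull_sphere_rejected(self):
        cfg = SimulationConfig(domain=Domain(8, 8, 8), n_mic=400, n_mm=400)
        with pytest.raises(ValueError, match="sphere"):
            initialize(cfg, 0)

    def test_horizon_must_align_with_step(self):
        with pytest.raises(ValueError, match="multiple"):
            SimulationConfig(horizon_h=601.0)


class TestStep:
    def test_empty_domain_relaxes_and_stays_empty(self):
        cfg = SimulationConfig(
            domain=Domain(16, 16, 16), n_mic=0, n_mm=0, n_cd8=0, n_treg=0,
            horizon_h=20.0,
        )
        series = run(cfg, 0)
        assert series.counts.sum() == 0
        assert series.events[:, :, EV_BIRTH].sum() == 0

    def test_ledger_conservation_every_step(self, small_cfg):
        """Population deltas must equal births − deaths − lyses − conversions
        recorded in the event ledger, per kind, at every step."""
        series = run(small_cfg, 11)
        for s in range(series.events.shape[0]):
            delta = series.counts[s + 1] - series.counts[s]
            ev = series.events[s]
            expect = (
                ev[:, EV_BIRTH] - ev[:, EV_DEATH] - ev[:, EV_LYSIS] - ev[:, EV_DIFF]
            )
            np.testing.assert_array_equal(delta, expect, err_msg=f"step {s}")

    def test_site_exclusivity_after_stepping(self, small_cfg):
        state = initialize(small_cfg, 7)
        for _ in range(20):
            step(state)
            n = state.n_total
            alive = state.alive[:n]
            pos = state.pos[:n][alive]
            keys = pos[:, 0] * 10_000 + pos[:, 1] * 100 + pos[:, 2]
            assert len(np.unique(keys)) == len(keys)

    def test_untreated_tumor_growth_trend(self, small_cfg):
        cfg = small_cfg.with_overrides(horizon_h=240.0)
        summ = run_replicates(cfg, 6, 5)
        assert summ.myeloma[-1] > 1.5 * summ.myeloma[0]


class TestReproducibility:
    def test_identical_seed_bitwise_identical_output(self, small_cfg):
        a = run(small_cfg, 42)
        b = run(small_cfg, 42)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.events, b.events)
        assert a.to_frame().to_csv() == b.to_frame().to_csv()

    def test_different_seeds_diverge(self, small_cfg):
        a = run(small_cfg, 1)
        b = run(small_cfg, 2)
        assert not np.array_equal(a.counts, b.counts)


class TestReplicates:
    def test_single_replicate_mean_is_the_run(self, small_cfg):
        summ = run_replicates(small_cfg, 1, 9)
        single = run(small_cfg, replicate_seeds(9, 1)[0])
        np.testing.assert_allclose(summ.mean, single.counts)
        np.testing.assert_allclose(summ.sd, 0.0)

    def test_replicate_means_stable_between_batches(self):
        """Two independent replicate batches agree on the untreated baseline."""
        cfg = SimulationConfig(horizon_h=144.0)
        a = run_replicates(cfg, 25, 100)
        b = run_replicates(cfg, 25, 200)
        final_a, final_b = a.myeloma[-1], b.myeloma[-1]
        assert abs(final_a - final_b) / final_a < 0.05

    def test_sem_shrinks_with_replicates(self):
        """The SD of the replicate-mean shrinks roughly like 1/sqrt(n)."""
        cfg = SimulationConfig(
            domain=Domain(24, 24, 24), n_mic=30, n_mm=30, n_cd8=8, n_treg=2,
            horizon_h=96.0,
        )
        finals = np.array(
            [run(cfg, ss).myeloma[-1] for ss in replicate_seeds(77, 48)], float
        )
        sem_small = np.std([finals[i::12].mean() for i in range(12)])
        sem_large = np.std([finals[i::4].mean() for i in range(4)])
        # groups of 4 vs groups of 12: expect ~sqrt(3) reduction, loosely
        assert sem_large < sem_small * 1.2

    def test_requires_at_least_one_replicate(self, small_cfg):
        with pytest.raises(ValueError):
            run_replicates(small_cfg, 0, 1)


class TestImmuneEffect:
    def test_immune_presence_slows_tumor_growth(self):
        """Replicate-mean myeloma with the immune compartment must not exceed
        the immune-free trajectory (within binomial noise allowance)."""
        n = 16
        cfg_p = SimulationConfig(horizon_h=240.0)
        cfg_a = cfg_p.with_overrides(n_cd8=0, n_treg=0)
        sp = run_replicates(cfg_p, n, 31)
        sa = run_replicates(cfg_a, n, 31)
        sem = np.sqrt(
            (sp.sd[:, 0] ** 2 + sp.sd[:, 1] ** 2 + sa.sd[:, 0] ** 2
             + sa.sd[:, 1] ** 2) / n
        )
        assert np.all(sp.myeloma <= sa.myeloma + 2.5 * sem + 1e-9)
        # and the effect is real at the end of the window
        assert sp.myeloma[-1] < sa.myeloma[-1]
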