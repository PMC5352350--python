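"""Multi-scale orchestrator: initialization, the 2-h step loop, replicates.

Each 2-h step advances the three scales in order: (1) cytokine secretion
and explicit diffusion sub-stepping over the step; (2) stromal-cell
stiffness updates from the local SDF-1 level (thalidomide-attenuated)
through the calibrated signaling ODE, cached as a dose→Pa response
curve; (3) the shuffled stochastic agent-behavior phase; (4) event
bookkeeping.  Fields are frozen within a step (quasi-steady separation
of the minutes-scale signaling from the hours-scale cell behavior).

The ODE readouts enter the lattice model through lookup tables built
once per run: the stiffness response curve of the stromal network and
the stiffness→(survival, adhesion) curves of the MIC network at the
run's BTZ dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import CD8, EV_BIRTH, EV_DEATH, EV_DIFF, EV_LYSIS, MIC, MM, TREG
from .agents import (
    KIND_NAMES,
    AbmParams,
    cd8_proliferation_prob,
    mic_step_death_prob,
    mm_death_prob,
    thal_attenuation,
)
from .calibration import integrate_batch, params_to_vector
from .fields import (
    SOFT_ECM_PA,
    ConcentrationField,
    Domain,
    DrugRegimen,
    drug_level,
)
from .networks import (
    STIFFNESS_INPUT_REF_PA,
    OdeParameters,
    StiffnessMap,
    build_bmsc_network,
    build_mic_network,
    load_params,
)

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "PopulationTimeSeries",
    "SummaryTimeSeries",
    "initialize",
    "step",
    "run",
    "run_replicates",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulated bone-marrow experiment."""

    domain: Domain = field(default_factory=Domain)
    n_mic: int = 100
    n_mm: int = 100
    n_cd8: int = 20
    n_treg: int = 5
    bmsc_spacing: int = 4
    regimen: DrugRegimen = field(default_factory=DrugRegimen)
    horizon_h: float = 600.0
    dt_h: float = 2.0
    abm: AbmParams = field(default_factory=AbmParams)

    def __post_init__(self) -> None:
        if min(self.n_mic, self.n_mm, self.n_cd8, self.n_treg) < 0:
            raise ValueError("initial counts must be non-negative")
        n_steps = self.horizon_h / self.dt_h
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("horizon must be a multiple of the step")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_h / self.dt_h))

    def with_overrides(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class PopulationTimeSeries:
    """Per-step population counts of one replicate (plus the event ledger)."""

    times: np.ndarray  # (n_steps+1,)
    counts: np.ndarray  # (n_steps+1, 4) int64, order MIC/MM/CD8/TREG
    events: np.ndarray  # (n_steps, 4 kinds, 4 events) int64
    mean_bmsc_pa: np.ndarray  # (n_steps+1,)

    def count(self, kind_name: str) -> np.ndarray:
        return self.counts[:, KIND_NAMES.index(kind_name)]

    @property
    def myeloma(self) -> np.ndarray:
        return self.counts[:, MIC] + self.counts[:, MM]

    def at(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.counts[idx]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times}
        data.update({n: self.counts[:, i] for i, n in enumerate(KIND_NAMES)})
        data["mean_bmsc_pa"] = self.mean_bmsc_pa
        return pd.DataFrame(data)


@dataclass
class SummaryTimeSeries:
    """Replicate mean and SD of the population counts."""

    times: np.ndarray
    mean: np.ndarray  # (n_steps+1, 4)
    sd: np.ndarray
    n_replicates: int

    def count(self, kind_name: str) -> np.ndarray:
        return self.mean[:, KIND_NAMES.index(kind_name)]

    @property
    def myeloma(self) -> np.ndarray:
        return self.mean[:, MIC] + self.mean[:, MM]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times}
        for i, n in enumerate(KIND_NAMES):
            data[f"{n}_mean"] = self.mean[:, i]
            data[f"{n}_sd"] = self.sd[:, i]
        return pd.DataFrame(data)


class SimulationState:
    """Mutable lattice state: fields, scaffold, agent registry, clock, RNG."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator,
                 ode_bmsc: dict, ode_mic: dict):
        self.cfg = cfg
        self.rng = rng
        self.t = 0.0
        dom = cfg.domain
        self.mask = dom.cylinder_mask()

        # static stromal scaffold: every `spacing`-th site inside the mask
        sp, off = cfg.bmsc_spacing, cfg.bmsc_spacing // 2
        gx, gy, gz = np.meshgrid(
            np.arange(off, dom.nx, sp),
            np.arange(off, dom.ny, sp),
            np.arange(off, dom.nz, sp),
            indexing="ij",
        )
        cand = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        inside = self.mask[cand[:, 0], cand[:, 1], cand[:, 2]]
        self.bmsc_pos = cand[inside].astype(np.int64)
        self.bmsc_stiff = np.full(len(self.bmsc_pos), 400.0)

        # occupancy template: -1 free inside mask, -2 blocked
        self.occ_base = np.where(self.mask, np.int32(-1), np.int32(-2))
        self.occ_base[self.bmsc_pos[:, 0], self.bmsc_pos[:, 1], self.bmsc_pos[:, 2]] = -2
        self.occ = self.occ_base.copy()

        # cytokine fields, uniform at the boundary value initially
        p = cfg.abm
        self.sdf1 = ConcentrationField.uniform(dom, p.boundary, p.diffusion, p.boundary)
        self.tgfb = ConcentrationField.uniform(dom, p.boundary, p.diffusion, p.boundary)

        # agent storage (structure of arrays, capacity grows on demand)
        cap = max(1024, 4 * (cfg.n_mic + cfg.n_mm + cfg.n_cd8 + cfg.n_treg))
        self._alloc(cap)
        self.n_total = 0

        # static site -> nearest-adjacent-BMSC index map (the scaffold never
        # moves); offsets ordered by distance so the closest stromal cell wins
        self._bmsc_site_idx = np.full(dom.shape, -1, dtype=np.int32)
        offsets = sorted(
            ((dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
             for dz in (-1, 0, 1)),
            key=lambda o: o[0] ** 2 + o[1] ** 2 + o[2] ** 2,
        )
        nb = len(self.bmsc_pos)
        for off in offsets:
            ptc = self.bmsc_pos + np.array(off)
            ok = np.all((ptc >= 0) & (ptc < np.array(dom.shape)), axis=1)
            q = ptc[ok]
            cur = self._bmsc_site_idx[q[:, 0], q[:, 1], q[:, 2]]
            write = cur == -1
            self._bmsc_site_idx[q[write, 0], q[write, 1], q[write, 2]] = np.arange(
                nb, dtype=np.int32
            )[ok][write]

        self._build_lookups(ode_bmsc, ode_mic)
        self.stiff_pa = self._stiffness_field()

        self.count_rows: list[np.ndarray] = []
        self.event_rows: list[np.ndarray] = []
        self.mean_pa_rows: list[float] = []

    def _stiffness_field(self) -> np.ndarray:
        """Pa field from the cached nearest-BMSC map (soft-ECM floor elsewhere)."""
        idx = self._bmsc_site_idx
        return np.where(idx >= 0, self.bmsc_stiff[np.maximum(idx, 0)], SOFT_ECM_PA)

    # -- storage ------------------------------------------------------------

    def _alloc(self, cap: int) -> None:
        self.kind = np.zeros(cap, dtype=np.int8)
        self.pos = np.zeros((cap, 3), dtype=np.int64)
        self.alive = np.zeros(cap, dtype=np.bool_)
        self.phase = np.zeros(cap, dtype=np.float64)
        self.m_phase = np.zeros(cap, dtype=np.bool_)
        self.passage = np.zeros(cap, dtype=np.int16)
        self.attached = np.zeros(cap, dtype=np.bool_)
        self.arrest = np.zeros(cap, dtype=np.bool_)

    def _compact_and_grow(self) -> None:
        idx = np.flatnonzero(self.alive[: self.n_total])
        n = len(idx)
        cap = len(self.kind)
        if 2 * n + 64 > cap:
            cap = max(2 * cap, 2 * n + 1024)
        old = (self.kind, self.pos, self.alive, self.phase, self.m_phase,
               self.passage, self.attached, self.arrest)
        self._alloc(cap)
        for new, prev in zip(
            (self.kind, self.pos, self.alive, self.phase, self.m_phase,
             self.passage, self.attached, self.arrest),
            old,
        ):
            new[:n] = prev[idx]
        self.n_total = n
        self.occ = self.occ_base.copy()
        self.occ[self.pos[:n, 0], self.pos[:n, 1], self.pos[:n, 2]] = np.arange(
            n, dtype=np.int32
        )

    # -- ODE lookup tables ----------------------------------------------------

    def _build_lookups(self, ode_bmsc: dict, ode_mic: dict) -> None:
        bnet, mnet = build_bmsc_network(), build_mic_network()
        bp: OdeParameters = ode_bmsc["params"]
        self.smap: StiffnessMap = ode_bmsc["stiffness_map"]
        self.sdf1_rel_5nm = float(ode_bmsc.get("sdf1_rel_5nm", 1.0))

        # stiffness response curve at the 60-min quasi-steady response time
        self.dose_grid = np.linspace(0.0, 1.5, 61)
        vecs = np.tile(params_to_vector(bnet, bp), (len(self.dose_grid), 1))
        out = integrate_batch(bnet, vecs, {"SDF1": self.dose_grid}, [1.0])
        self.pa_curve = np.asarray(
            self.smap(out[:, bnet.index("stiffness"), -1]), dtype=float
        )

        # MIC survival/adhesion vs stiffness, at zero dose and the run dose
        mp: OdeParameters = ode_mic["params"]
        K_btz, H_btz = mp.drug["D1"]
        self.stiff_grid = np.linspace(0.0, STIFFNESS_INPUT_REF_PA, 28)
        level = self.stiff_grid / STIFFNESS_INPUT_REF_PA
        btz = self.cfg.regimen.btz_nm
        mv = params_to_vector(mnet, mp)
        nv = len(self.stiff_grid)
        vecs = np.tile(mv, (2 * nv, 1))
        levels = np.concatenate([level, level])
        drug_terms = np.zeros((2 * nv, mnet.n_states))
        if btz > 0:
            drug_terms[nv:, mnet.index("Survival")] = K_btz * btz / (H_btz + btz)
        out = integrate_batch(
            mnet, vecs, {"stiffness": levels, "D1": 0.0}, [24.0, 144.0],
            drug_terms=drug_terms,
        )
        adh = np.clip(out[:nv, mnet.index("Adhesion"), 0], 0.0, 1.0)
        surv0 = np.clip(out[:nv, mnet.index("Survival"), 1], 0.0, 1.0)
        survd = np.clip(out[nv:, mnet.index("Survival"), 1], 0.0, 1.0)
        self.adhesion_curve = adh
        self.survival_curve_control = surv0
        self.survival_curve_treated = survd

    # -- views ---------------------------------------------------------------

    def counts_by_kind(self) -> np.ndarray:
        alive_kinds = self.kind[: self.n_total][self.alive[: self.n_total]]
        return np.bincount(alive_kinds, minlength=4).astype(np.int64)


def initialize(cfg: SimulationConfig, seed) -> SimulationState:
    """Build the initial state: scaffold, central tumor/immune sphere, fields.

    Stromal cells sit on a regular sub-lattice inside the cylindrical
    mask; the MIC/MM/CD8/Treg mixture is scattered uniformly over a
    central sphere just large enough to hold the initial counts at one
    agent per site.
    """
    rng = np.random.default_rng(seed)
    ode_bmsc = load_params("bmsc")
    ode_mic = load_params("mic")
    state = SimulationState(cfg, rng, ode_bmsc, ode_mic)

    total = cfg.n_mic + cfg.n_mm + cfg.n_cd8 + cfg.n_treg
    dom = cfg.domain
    center = np.array([dom.nx // 2, dom.ny // 2, dom.nz // 2])
    xs = np.arange(dom.nx)[:, None, None]
    ys = np.arange(dom.ny)[None, :, None]
    zs = np.arange(dom.nz)[None, None, :]
    d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2

    radius = None
    for r in range(2, max(dom.nx, dom.ny, dom.nz)):
        free = (d2 <= r * r) & (state.occ_base == -1)
        if free.sum() >= total:
            radius = r
            break
    if radius is None:
        raise ValueError(
            f"central sphere cannot hold {total} agents in this domain"
        )
    sites = np.argwhere((d2 <= radius * radius) & (state.occ_base == -1))
    chosen = sites[rng.choice(len(sites), size=total, replace=False)]

    kinds = np.concatenate(
        [
            np.full(cfg.n_mic, MIC, dtype=np.int8),
            np.full(cfg.n_mm, MM, dtype=np.int8),
            np.full(cfg.n_cd8, CD8, dtype=np.int8),
            np.full(cfg.n_treg, TREG, dtype=np.int8),
        ]
    )
    state.kind[:total] = kinds
    state.pos[:total] = chosen
    state.alive[:total] = True
    # desynchronize the cell cycles at t=0
    cyc = np.array(
        [cfg.abm.cycle_mic_h, cfg.abm.cycle_mm_h, cfg.abm.cycle_cd8_h,
         cfg.abm.cycle_treg_h]
    )[kinds]
    state.phase[:total] = rng.uniform(0.0, cyc)
    state.n_total = total
    state.occ = state.occ_base.copy()
    state.occ[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = np.arange(
        total, dtype=np.int32
    )

    state.count_rows.append(state.counts_by_kind())
    state.mean_pa_rows.append(float(state.bmsc_stiff.mean()))
    return state


def step(state: SimulationState) -> SimulationState:
    """Advance the multi-scale clock by one 2-h step (in place)."""
    cfg = state.cfg
    p = cfg.abm
    dt = cfg.dt_h
    btz = drug_level(cfg.regimen, "BTZ", state.t)
    len_um = drug_level(cfg.regimen, "LEN", state.t)
    thal = drug_level(cfg.regimen, "THAL", state.t)
    thal_f = thal_attenuation(thal, p)

    state._compact_and_grow()
    n = state.n_total
    kind = state.kind[:n]
    posn = state.pos[:n]

    # (1) secretion + diffusion over the step
    mic_pos = posn[kind == MIC]
    if len(mic_pos):
        np.add.at(
            state.sdf1.grid,
            (mic_pos[:, 0], mic_pos[:, 1], mic_pos[:, 2]),
            p.secretion_sdf1 * dt,
        )
    if len(state.bmsc_pos):
        np.add.at(
            state.tgfb.grid,
            (state.bmsc_pos[:, 0], state.bmsc_pos[:, 1], state.bmsc_pos[:, 2]),
            p.secretion_tgfb_bmsc * thal_f * dt,
        )
    mm_pos = posn[kind == MM]
    if len(mm_pos):
        np.add.at(
            state.tgfb.grid,
            (mm_pos[:, 0], mm_pos[:, 1], mm_pos[:, 2]),
            p.secretion_tgfb_mm * dt,
        )
    nsub = max(1, int(np.ceil(6.0 * p.diffusion * dt)))
    for fld in (state.sdf1, state.tgfb):
        _kernels.diffuse_steps(fld.grid, fld.diffusion, dt / nsub, nsub, fld.boundary)

    # (2) stromal stiffness from local SDF-1 (thalidomide-attenuated)
    if len(state.bmsc_pos):
        local = state.sdf1.grid[
            state.bmsc_pos[:, 0], state.bmsc_pos[:, 1], state.bmsc_pos[:, 2]
        ]
        state.bmsc_stiff = np.interp(local * thal_f, state.dose_grid, state.pa_curve)
        state.stiff_pa = state._stiffness_field()

    # (3) per-agent behavior probabilities at step start
    cap = len(state.kind)
    p_death = np.zeros(cap)
    p_divide = np.zeros(cap)
    p_migrate = np.zeros(cap)
    p_selfrenew = np.zeros(cap)
    p_adhesion = np.zeros(cap)
    cycle_len = np.zeros(cap)

    s_ag = state.stiff_pa[posn[:, 0], posn[:, 1], posn[:, 2]]
    tgfb_ag = state.tgfb.grid[posn[:, 0], posn[:, 1], posn[:, 2]]
    treg_count = int((kind == TREG).sum())

    sel = kind == MIC
    if sel.any():
        s = s_ag[sel]
        surv = np.interp(
            s,
            state.stiff_grid,
            state.survival_curve_treated if btz > 0 else state.survival_curve_control,
        )
        p_death[:n][sel] = mic_step_death_prob(surv, dt, p)
        p_divide[:n][sel] = p.div_pmax_mic * s**p.div_n / (
            p.div_H_pa**p.div_n + s**p.div_n
        )
        p_selfrenew[:n][sel] = p.sr_pmax * s**p.sr_n / (p.sr_H_pa**p.sr_n + s**p.sr_n)
        p_adhesion[:n][sel] = np.interp(s, state.stiff_grid, state.adhesion_curve)
        p_migrate[:n][sel] = p.migrate_mic
        cycle_len[:n][sel] = p.cycle_mic_h
    sel = kind == MM
    if sel.any():
        s = s_ag[sel]
        p_death[:n][sel] = mm_death_prob(btz, p)
        p_divide[:n][sel] = p.div_pmax_mm * s / (p.div_H_pa_mm + s)
        p_migrate[:n][sel] = p.migrate_mm
        cycle_len[:n][sel] = p.cycle_mm_h
    sel = kind == CD8
    if sel.any():
        inhib = p.tgfb_floor_cd8 + (1.0 - p.tgfb_floor_cd8) * p.tgfb_H_cd8 / (
            p.tgfb_H_cd8 + tgfb_ag[sel]
        )
        base = p.prolif_pmax_cd8 * inhib * p.treg_K_cd8 / (p.treg_K_cd8 + treg_count)
        boost = p.len_amp_cd8 * len_um / (p.len_H_um + len_um)
        p_divide[:n][sel] = np.clip(base + boost, 0.0, 1.0)
        p_death[:n][sel] = p.death_base_cd8
        p_migrate[:n][sel] = p.migrate_cd8
        cycle_len[:n][sel] = p.cycle_cd8_h
    sel = kind == TREG
    if sel.any():
        val = (
            p.prolif_pmax_treg
            * tgfb_ag[sel] / (p.tgfb_H_treg + tgfb_ag[sel])
            * p.len_H_treg_um / (p.len_H_treg_um + len_um)
        )
        p_divide[:n][sel] = np.clip(val, 0.0, 1.0)
        p_death[:n][sel] = p.death_base_treg
        p_migrate[:n][sel] = p.migrate_treg
        cycle_len[:n][sel] = p.cycle_treg_h

    # (4) shuffled stochastic behavior phase
    order = state.rng.permutation(n).astype(np.int64)
    events = np.zeros((4, 4), dtype=np.int64)
    state.n_total = _kernels.agent_phase(
        state.occ,
        state.kind,
        state.pos,
        state.alive,
        state.phase,
        state.m_phase,
        state.passage,
        state.attached,
        state.arrest,
        order,
        state.n_total,
        state.stiff_pa,
        SOFT_ECM_PA,
        p_death,
        p_divide,
        p_migrate,
        p_selfrenew,
        p_adhesion,
        cycle_len,
        dt,
        p.lgn,
        p.lysis_p,
        p.lysis_protect,
        p.suppress_p,
        p.arrest_frac,
        p.sense_radius,
        events,
        state.rng,
    )

    state.t += dt
    state.count_rows.append(state.counts_by_kind())
    state.event_rows.append(events)
    state.mean_pa_rows.append(float(state.bmsc_stiff.mean()))
    return state


def run(cfg: SimulationConfig, seed) -> PopulationTimeSeries:
    """One full replicate; deterministic for a fixed seed."""
    state = initialize(cfg, seed)
    for _ in range(cfg.n_steps):
        step(state)
    times = np.arange(cfg.n_steps + 1) * cfg.dt_h
    return PopulationTimeSeries(
        times=times,
        counts=np.stack(state.count_rows),
        events=np.stack(state.event_rows) if state.event_rows
        else np.zeros((0, 4, 4), dtype=np.int64),
        mean_bmsc_pa=np.array(state.mean_pa_rows),
    )


def replicate_seeds(master_seed, n: int) -> list[np.random.SeedSequence]:
    """Independent, reproducible per-replicate seed sequences."""
    if isinstance(master_seed, np.random.SeedSequence):
        return master_seed.spawn(n)
    return [np.random.SeedSequence([int(master_seed), i]) for i in range(n)]


def run_replicates(cfg: SimulationConfig, n: int, master_seed: int) -> SummaryTimeSeries:
    """``n`` independent replicates with derived seeds; per-time mean/SD."""
    if n < 1:
        raise ValueError("need at least one replicate")
    all_counts = []
    times = None
    for ss in replicate_seeds(master_seed, n):
        series = run(cfg, ss)
        all_counts.append(series.counts)
        times = series.times
    arr = np.stack(all_counts).astype(float)  # (n, T, 4)
    return SummaryTimeSeries(
        times=times,
        mean=arr.mean(axis=0),
        sd=arr.std(axis=0, ddof=0),
        n_replicates=n,
    )
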