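"""Synthetic calibration data for the two signaling networks.

The calibration inputs of the model are phospho-protein fold-change time
courses (reverse-phase protein-array style): each species normalized to
its t=0 level, 4–5 time points, saturating Hill-shaped kinetics.  This
module ships a generator that emulates that structure from a known
ground-truth parameter set — integrate the network, sample the stated
time grids, apply multiplicative log-normal noise — so the whole fitting
pipeline is exercisable offline.

The generator's defaults define the study conditions: the stromal-cell
network is observed under the saturating SDF-1 reference dose (relative
level 1.0) at 0/5/10/15/60 min for the five phospho-proteins the assay
covers (MEK, FAK, RhoA, ERK, MYL2); the MIC network is observed on a
400 Pa surface at 0/0.5/1 h for its six phospho-proteins, with the slow
Adhesion/Survival readouts sampled at 24 and 96 h.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import ObservationTable
from .networks import (
    STIFFNESS_INPUT_REF_PA,
    OdeParameters,
    SignalingNetwork,
    integrate,
)

__all__ = [
    "bmsc_true_params",
    "mic_true_params",
    "generate_synthetic_proteomics",
    "bmsc_observation_table",
    "mic_observation_table",
    "BMSC_OBSERVED",
    "MIC_OBSERVED_FAST",
    "MIC_OBSERVED_SLOW",
    "BMSC_TIME_GRID_H",
    "MIC_FAST_GRID_H",
    "MIC_SLOW_GRID_H",
]

#: Trajectories the stromal-cell fit is constrained by: the five assayed
#: phospho-proteins (PI3K is not measured) plus the stiffness readout,
#: whose time course is anchored experimentally by the 400→530 Pa ramp.
BMSC_OBSERVED = ("MEK", "FAK", "RhoA", "ERK", "MYL2", "stiffness")
#: Fast (minutes-scale) phospho-proteins of the MIC assay; Rac is not measured.
MIC_OBSERVED_FAST = ("FAK", "PI3K", "AKT", "JNK", "cJUN", "NFKB")
#: Slow population-level readouts of the MIC assay.
MIC_OBSERVED_SLOW = ("Adhesion", "Survival")

BMSC_TIME_GRID_H = (0.0, 5 / 60, 10 / 60, 15 / 60, 1.0)
MIC_FAST_GRID_H = (0.0, 0.5, 1.0)
MIC_SLOW_GRID_H = (24.0, 96.0)


def bmsc_true_params() -> OdeParameters:
    """Ground-truth constants used to synthesize stromal-cell time courses.

    Decay rates of 2.5–5 h⁻¹ give 12–24 min response times, and production
    rates are chosen so steady fold-changes sit between 1.8 and 2.5 —
    the range the minutes-scale phospho-assays typically show.
    """
    return OdeParameters(
        k={
            "k1": 12.0, "k2": 17.5, "k3": 8.1, "k4": 6.0, "k5": 6.7,
            "k6": 14.8, "k7": 5.4, "k8": 5.4, "k9": 4.5, "k10": 4.5,
        },
        H={
            "H1": 0.5, "H2": 0.4, "H3": 1.0, "H4": 1.0, "H5": 1.0,
            "H6": 1.2, "H7": 1.1, "H8": 1.0, "H9": 0.9, "H10": 1.2,
        },
        d={"d1": 4.0, "d2": 5.0, "d3": 3.0, "d4": 4.0, "d5": 5.0, "d6": 3.0, "d7": 2.5},
    )


def mic_true_params() -> OdeParameters:
    """Ground-truth constants used to synthesize MIC time courses.

    Signaling nodes relax within the hour (d of 3–4 h⁻¹); the Adhesion and
    Survival readouts are slow (d of 0.08 and 0.03 h⁻¹) so that their 24-
    and 96-h samples carry the population-level kinetics.  The BTZ pair is
    a placeholder overwritten by anchor calibration.
    """
    return OdeParameters(
        k={
            "k1": 8.4, "k2": 6.0, "k3": 4.7, "k4": 7.8, "k5": 12.4,
            "k6": 11.2, "k7": 8.7, "k8": 7.2, "k9": 7.4, "k10": 0.046,
            "k11": 0.041,
        },
        H={
            "H1": 0.3, "H2": 1.0, "H3": 1.0, "H4": 0.9, "H5": 1.0,
            "H6": 0.8, "H7": 1.0, "H8": 1.0, "H9": 1.2, "H10": 1.0,
            "H11": 1.0,
        },
        d={
            "d1": 3.0, "d2": 4.0, "d3": 3.0, "d4": 4.0, "d5": 3.5,
            "d6": 3.0, "d7": 4.0, "d8": 0.08, "d9": 0.03,
        },
        drug={"D1": (0.03, 1.5)},
    )


def generate_synthetic_proteomics(
    net: SignalingNetwork,
    true_params: OdeParameters,
    inputs: dict,
    species_times: dict,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> ObservationTable:
    """Synthesize an RPPA-style fold-change table from known parameters.

    ``species_times`` maps each observed species to its sampling grid in
    hours.  Trajectories are integrated from the all-ones state, sampled,
    and multiplied by median-1 log-normal noise of coefficient of
    variation ``noise_cv``; t=0 entries are forced to exactly 1.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    all_times = sorted({0.0} | {t for ts in species_times.values() for t in ts})
    tc = integrate(net, true_params, inputs, all_times)
    t_pos = {t: i for i, t in enumerate(all_times)}
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    rows = []
    for sp, ts in species_times.items():
        traj = tc.get(sp)
        for t in ts:
            val = float(traj[t_pos[float(t)]])
            if t > 0 and noise_cv > 0:
                val *= float(np.exp(rng.normal(0.0, sigma)))
            rows.append({"species": sp, "time_h": float(t), "fold_change": 1.0 if t == 0 else val})
    return ObservationTable(data=pd.DataFrame(rows), inputs=dict(inputs))


def bmsc_observation_table(
    noise_cv: float = 0.05, seed: int = 0, sdf1: float = 1.0
) -> ObservationTable:
    """Stromal-cell calibration table at one SDF-1 condition."""
    return generate_synthetic_proteomics(
        net=_bmsc_net(),
        true_params=bmsc_true_params(),
        inputs={"SDF1": sdf1},
        species_times={sp: BMSC_TIME_GRID_H for sp in BMSC_OBSERVED},
        noise_cv=noise_cv,
        seed=seed,
    )


def bmsc_observation_tables(noise_cv: float = 0.05, seed: int = 0) -> list[ObservationTable]:
    """Stimulated (saturating SDF-1) and unstimulated-control table pair.

    The control well pins the decay rates that a single stimulated
    condition leaves unidentified.
    """
    return [
        bmsc_observation_table(noise_cv, seed, sdf1=1.0),
        bmsc_observation_table(noise_cv, seed + 1, sdf1=0.0),
    ]


def mic_observation_table(
    stiffness_pa: float = 400.0, noise_cv: float = 0.05, seed: int = 0
) -> ObservationTable:
    """Default MIC calibration table (400 Pa surface, mixed time grids)."""
    level = stiffness_pa / STIFFNESS_INPUT_REF_PA
    species_times = {sp: MIC_FAST_GRID_H for sp in MIC_OBSERVED_FAST}
    species_times.update({sp: (0.0,) + MIC_SLOW_GRID_H for sp in MIC_OBSERVED_SLOW})
    return generate_synthetic_proteomics(
        net=_mic_net(),
        true_params=mic_true_params(),
        inputs={"stiffness": level, "D1": 0.0},
        species_times=species_times,
        noise_cv=noise_cv,
        seed=seed,
    )


def mic_observation_tables(noise_cv: float = 0.05, seed: int = 0) -> list[ObservationTable]:
    """Soft (100 Pa) and stiff (400 Pa) surface table pair.

    Mirrors the two-stiffness design of the underlying assay and makes
    the stiffness sensitivity of the network identifiable.
    """
    return [
        mic_observation_table(400.0, noise_cv, seed),
        mic_observation_table(100.0, noise_cv, seed + 1),
    ]


def _bmsc_net():
    from .networks import build_bmsc_network

    return build_bmsc_network()


def _mic_net():
    from .networks import build_mic_network

    return build_mic_network()
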