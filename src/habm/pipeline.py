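"""End-to-end calibration pipeline producing the shipped parameter assets.

Each network is calibrated in two stages:

1. **GA fit** to the synthetic phospho-proteomics tables (the observation
   structure of the underlying assays: fold-changes, 4–5 time points).
2. **Anchor solving** against the quantitative in-vitro anchors that the
   trajectory data cannot pin down:

   * stromal network — the stiffness map is anchored so the initial state
     reads 400 Pa and the saturating 60-min response reads 530 Pa, and the
     relative-dose equivalent of 5 nM SDF-1 is solved so the response is
     526 Pa;
   * MIC network — the Adhesion production rate is rescaled so the
     stiffness-driven adhesion component is 47% at the 400 Pa myeloma-
     stroma operating point (24-h assay), and the BTZ inhibition strength
     is solved so 5 nM BTZ over 6 days reduces survival by 89.2%.

The solved constants ride along in the parameter payloads consumed by
:func:`habm.networks.load_params`.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .calibration import GaConfig, fit_parameters_ga
from .datasets import bmsc_observation_tables, mic_observation_tables
from .networks import (
    STIFFNESS_INPUT_REF_PA,
    OdeParameters,
    StiffnessMap,
    build_bmsc_network,
    build_mic_network,
    integrate,
)

__all__ = ["calibrate_bmsc", "calibrate_mic", "write_params"]


def _repin_input_hills(params: OdeParameters, net_name: str,
                       input_levels: dict[str, float],
                       net) -> OdeParameters:
    """Fix input-edge half-saturations at their structural values.

    For every edge leaving an input species, set H to the structural
    constant and rescale its k so the production at the fit's constant
    input level is unchanged (the fitted trajectories are preserved
    bit-for-bit; only the off-condition dose sensitivity changes).
    """
    k = dict(params.k)
    H = dict(params.H)
    targets = INPUT_HALF_SAT[net_name]
    for src, _dst, k_id, H_id in net.edges:
        if src in net.inputs and H_id in targets:
            level = input_levels[src]
            H_new = targets[H_id]
            k[k_id] = k[k_id] * (level / (H[H_id] + level)) / (level / (H_new + level))
            H[H_id] = H_new
    return OdeParameters(k=k, H=H, d=dict(params.d), drug=dict(params.drug))

#: Structural input half-saturations.  A single-condition trajectory fit
#: cannot identify the sensitivity of the input edges (any saturated Hill
#: reproduces the data), so these are fixed constants of the model — the
#: saturating reference dose sits at ~2/3 of input-edge saturation — and
#: after the fit the paired rate constants are rescaled to preserve the
#: fitted operating-point production exactly.
INPUT_HALF_SAT = {"bmsc": {"H1": 0.5, "H2": 0.4}, "mic": {"H1": 0.3}}

ADHESION_STIFF_COMPONENT = 0.47  # at the myeloma-stroma operating point
ADHESION_EVAL_H = 24.0
BTZ_KILL_FRACTION = 0.892  # viability reduction at 5 nM over 6 days
BTZ_ANCHOR_NM = 5.0
BTZ_EVAL_H = 144.0
BTZ_HALF_SAT_NM = 1.5  # dose response turning point of BTZ killing
MYELOMA_BMSC_PA = 400.0
TARGET_5NM_PA = 526.0


def calibrate_bmsc(seed: int = 12345, noise_cv: float = 0.05,
                   ga: GaConfig | None = None) -> dict:
    """Fit the stromal network and anchor its stiffness map and dose scale."""
    net = build_bmsc_network()
    obs = bmsc_observation_tables(noise_cv=noise_cv, seed=seed)
    cfg = ga or GaConfig(pop_size=100, generations=150, seed=seed)
    fit = fit_parameters_ga(net, obs, cfg)
    params = _repin_input_hills(fit.params, "bmsc", {"SDF1": 1.0}, net)

    # Anchor the Pa map at the *responses*: the unstimulated 60-min state
    # reads 400 Pa and the saturating 60-min state reads 530 Pa.  The
    # all-ones initial state maps to 400 Pa as well through the lower clamp.
    s0 = float(integrate(net, params, {"SDF1": 0.0}, [0.0, 1.0]).get("stiffness")[-1])
    s_sat = float(integrate(net, params, {"SDF1": 1.0}, [0.0, 1.0]).get("stiffness")[-1])
    if s_sat <= s0:
        raise RuntimeError("fitted stiffness response does not rise above baseline")
    smap = StiffnessMap(s0=s0, s_sat=s_sat)

    def response(x: float) -> float:
        tc = integrate(net, params, {"SDF1": x}, [0.0, 1.0])
        return float(smap(tc.get("stiffness")[-1]))

    # the relative dose equivalent of 5 nM is the free constant anchored to
    # the 400 -> 526 Pa response
    x5 = brentq(lambda x: response(x) - TARGET_5NM_PA, 1e-6, 1.0, xtol=1e-10)

    return {
        "network": "bmsc",
        "params": params.to_dict(),
        "stiffness_map": {"s0": s0, "s_sat": s_sat},
        "sdf1_rel_5nm": float(x5),
        "calibration": {
            "seed": seed,
            "noise_cv": noise_cv,
            "ga_loss": fit.loss,
            "anchor_response_5nm_pa": response(x5),
        },
    }


def calibrate_mic(seed: int = 54321, noise_cv: float = 0.05,
                  ga: GaConfig | None = None) -> dict:
    """Fit the MIC network and anchor its adhesion and BTZ-kill constants."""
    net = build_mic_network()
    obs = mic_observation_tables(noise_cv=noise_cv, seed=seed)
    cfg = ga or GaConfig(
        pop_size=100,
        generations=150,
        seed=seed,
        # the Adhesion/Survival readouts relax over days, not minutes
        bounds_overrides={"d8": (0.005, 1.0), "d9": (0.005, 1.0)},
    )
    fit = fit_parameters_ga(net, obs, cfg)
    level = MYELOMA_BMSC_PA / STIFFNESS_INPUT_REF_PA

    def adhesion_at(params: OdeParameters) -> float:
        tc = integrate(net, params, {"stiffness": level, "D1": 0.0},
                       [0.0, ADHESION_EVAL_H])
        return float(tc.get("Adhesion")[-1])

    # Adhesion(t; k10) is affine in k10 (its node has a single linear-in-k10
    # production and first-order decay): two evaluations give the rescale.
    p0 = _repin_input_hills(fit.params, "mic", {"stiffness": level}, net)
    a1 = adhesion_at(p0)
    p2 = OdeParameters(
        k={**p0.k, "k10": 2 * p0.k["k10"]}, H=dict(p0.H), d=dict(p0.d)
    )
    a2 = adhesion_at(p2)
    slope = (a2 - a1) / p0.k["k10"]
    intercept = a1 - slope * p0.k["k10"]
    k10_star = (ADHESION_STIFF_COMPONENT - intercept) / slope
    if k10_star <= 0:
        raise RuntimeError("adhesion anchor not reachable with positive k10")
    params = OdeParameters(
        k={**p0.k, "k10": float(k10_star)}, H=dict(p0.H), d=dict(p0.d)
    )

    # solve the BTZ inhibition strength for the 6-day 89.2% kill anchor
    def survival(params_drug: OdeParameters, dose: float) -> float:
        tc = integrate(net, params_drug, {"stiffness": level, "D1": dose},
                       [0.0, BTZ_EVAL_H])
        return float(np.clip(tc.get("Survival")[-1], 0.0, 1.0))

    s_control = survival(params, 0.0)

    def kill_gap(K: float) -> float:
        trial = OdeParameters(
            k=dict(params.k), H=dict(params.H), d=dict(params.d),
            drug={"D1": (K, BTZ_HALF_SAT_NM)},
        )
        return 1.0 - survival(trial, BTZ_ANCHOR_NM) / s_control - BTZ_KILL_FRACTION

    K_star = brentq(kill_gap, 1e-6, 10.0, xtol=1e-12)
    params = OdeParameters(
        k=dict(params.k), H=dict(params.H), d=dict(params.d),
        drug={"D1": (float(K_star), BTZ_HALF_SAT_NM)},
    )

    return {
        "network": "mic",
        "params": params.to_dict(),
        "calibration": {
            "seed": seed,
            "noise_cv": noise_cv,
            "ga_loss": fit.loss,
            "survival_control_144h": s_control,
            "anchor_kill_fraction": 1.0
            - survival(params, BTZ_ANCHOR_NM) / s_control,
            "anchor_adhesion_24h": adhesion_at(params),
        },
    }


def write_params(payload: dict, directory: str | Path) -> Path:
    """Write a calibrated payload as a versioned JSON asset."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{payload['network']}_ode.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path
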