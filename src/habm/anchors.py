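"""Machine-readable validation anchors and their experiment recipes.

Every quantitative validation point of the model is encoded here as a
:class:`CalibrationAnchor` whose ``run`` callable re-executes the full
experiment from the shipped calibrated parameters — nothing is read
from disk beyond the parameter assets.  The same recipes back the
acceptance tests, the acceptance script and the ``habm anchors`` CLI.

Replicate counts are desk-scale defaults chosen so each stochastic
anchor's Monte-Carlo error is well inside its tolerance on one CPU; the
``fast`` flag trades precision for a quick smoke run.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np

from .calibration import uncertainty_analysis
from .engine import SimulationConfig, run, replicate_seeds
from .fields import DrugRegimen
from .networks import (
    STIFFNESS_INPUT_REF_PA,
    bmsc_stiffness_response,
    build_bmsc_network,
    build_mic_network,
    load_params,
    mic_adhesion_rate,
    mic_survival_rate,
)
from .synergy import synergy_index

__all__ = [
    "CalibrationAnchor",
    "anchor_suite",
    "mic_expansion_fold",
    "stiffness_response_5nm",
    "btz_viability_reduction_pct",
    "btz_myeloma_reduction_48h_pct",
    "len_cd8_increase_pct",
    "uncertainty_mean_deviation_pct",
    "independence_synergy_index",
    "total_adhesion_pct",
]


@dataclass(frozen=True)
class CalibrationAnchor:
    """One validation experiment with its expected value and tolerance."""

    name: str
    description: str
    expected: float
    rel_tol: float  # relative tolerance; for bounds, interpreted as the bound
    units: str
    kind: str  # 'eq' two-sided, 'le' upper bound
    run: Callable[..., float]  # run(seed, fast=False) -> value

    def check(self, value: float) -> bool:
        if self.kind == "le":
            return value <= self.expected
        return abs(value - self.expected) <= self.rel_tol * abs(self.expected)


# ---------------------------------------------------------------------------
# Experiment recipes


def mic_expansion_fold(seed: int, replicates: int = 50) -> float:
    """Replicate-mean MIC fold-expansion over 4 weeks, immune disabled."""
    cfg = SimulationConfig(n_cd8=0, n_treg=0, horizon_h=672.0)
    folds = [
        run(cfg, ss).count("MIC")[-1] / cfg.n_mic
        for ss in replicate_seeds(seed, replicates)
    ]
    return float(np.mean(folds))


def stiffness_response_5nm() -> float:
    """Stromal stiffness (Pa) after the 5 nM SDF-1 equivalent input."""
    payload = load_params("bmsc")
    return bmsc_stiffness_response(
        payload["sdf1_rel_5nm"], payload["params"], payload["stiffness_map"]
    )


def btz_viability_reduction_pct() -> float:
    """Percent MIC viability reduction at day 6 of 5 nM BTZ (survival ODE)."""
    params = load_params("mic")["params"]
    treated = mic_survival_rate(400.0, 5.0, params, t=144.0)
    control = mic_survival_rate(400.0, 0.0, params, t=144.0)
    return 100.0 * (1.0 - treated / control)


def btz_myeloma_reduction_48h_pct(seed: int, replicates: int = 60) -> float:
    """Percent myeloma (MIC+MM) reduction after 2 days of 1.5 nM BTZ."""
    seeds = replicate_seeds(seed, replicates)
    cfg_c = SimulationConfig(horizon_h=48.0)
    cfg_t = cfg_c.with_overrides(regimen=DrugRegimen(btz_nm=1.5))
    control = np.mean([run(cfg_c, ss).myeloma[-1] for ss in seeds])
    treated = np.mean([run(cfg_t, ss).myeloma[-1] for ss in seeds])
    return float(100.0 * (1.0 - treated / control))


@lru_cache(maxsize=4)
def len_cd8_increase_pct(seed: int, replicates: int = 250) -> tuple[float, float]:
    """Percent CD8 increases under 5 and 10 µM LEN at the treatment horizon.

    All three arms (control, 5 µM, 10 µM) share matched replicate seeds;
    counts are compared at the end of the 144-h treatment window.  Cached
    so the two dose anchors share one three-arm experiment.
    """
    seeds = replicate_seeds(seed, replicates)
    finals = {}
    for dose in (0.0, 5.0, 10.0):
        cfg = SimulationConfig(horizon_h=144.0, regimen=DrugRegimen(len_um=dose))
        finals[dose] = np.mean([run(cfg, ss).count("CD8")[-1] for ss in seeds])
    inc5 = 100.0 * (finals[5.0] / finals[0.0] - 1.0)
    inc10 = 100.0 * (finals[10.0] / finals[0.0] - 1.0)
    return float(inc5), float(inc10)


def uncertainty_mean_deviation_pct(model: str, seed: int, size: int = 5000) -> float:
    """Worst |mean/baseline − 1| (%) under ±5% parameter perturbation.

    BMSC model: stiffness readout at 60 min under the saturating input.
    MIC model: adhesion and survival readouts at 96 h on a 400 Pa niche;
    the larger deviation of the two is reported.
    """
    if model == "bmsc":
        net = build_bmsc_network()
        params = load_params("bmsc")["params"]
        rep = uncertainty_analysis(
            net, params, ["stiffness"], {"SDF1": 1.0}, t_final=1.0,
            sizes=[size], seed=seed,
        )
    elif model == "mic":
        net = build_mic_network()
        params = load_params("mic")["params"]
        rep = uncertainty_analysis(
            net, params, ["Adhesion", "Survival"],
            {"stiffness": 400.0 / STIFFNESS_INPUT_REF_PA, "D1": 0.0},
            t_final=96.0, sizes=[size], seed=seed,
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    return float((rep["mean_norm"] - 1.0).abs().max() * 100.0)


def independence_synergy_index(seed: int = 0) -> float:
    """Synergy index under multiplicative independence of the ratios."""
    rng = np.random.default_rng(seed)
    Di, Dj, Dk = rng.uniform(0.2, 0.9, size=3)
    return synergy_index(Di, Dj, Dk, Di * Dj, Di * Dk, Dj * Dk, Di * Dj * Dk)


def total_adhesion_pct() -> float:
    """Total MIC adhesion (%) at myeloma-stroma stiffness: ODE + 20% floor."""
    params = load_params("mic")["params"]
    return 100.0 * mic_adhesion_rate(400.0, params, t=24.0)


# ---------------------------------------------------------------------------


def anchor_suite() -> list[CalibrationAnchor]:
    """The full validation-anchor suite, in spec order."""
    return [
        CalibrationAnchor(
            "mic_expansion_4wk",
            "MIC fold-expansion after 4 weeks without immune cells",
            expected=5.98, rel_tol=0.15, units="fold", kind="eq",
            run=lambda seed, fast=False: mic_expansion_fold(
                seed, 12 if fast else 50
            ),
        ),
        CalibrationAnchor(
            "bmsc_stiffness_5nm",
            "Stromal stiffness response to the 5 nM SDF-1 equivalent",
            expected=526.0, rel_tol=0.005, units="Pa", kind="eq",
            run=lambda seed, fast=False: stiffness_response_5nm(),
        ),
        CalibrationAnchor(
            "btz_mic_viability",
            "MIC viability reduction at day 6 of 5 nM BTZ",
            expected=89.2, rel_tol=0.01, units="%", kind="eq",
            run=lambda seed, fast=False: btz_viability_reduction_pct(),
        ),
        CalibrationAnchor(
            "btz_myeloma_48h",
            "Myeloma reduction after 2 days of 1.5 nM BTZ",
            expected=49.5, rel_tol=0.15, units="%", kind="eq",
            run=lambda seed, fast=False: btz_myeloma_reduction_48h_pct(
                seed, 15 if fast else 60
            ),
        ),
        CalibrationAnchor(
            "len_cd8_5um",
            "CD8 increase under 5 µM LEN at the treatment horizon",
            expected=38.4, rel_tol=0.15, units="%", kind="eq",
            run=lambda seed, fast=False: len_cd8_increase_pct(
                seed, 40 if fast else 250
            )[0],
        ),
        CalibrationAnchor(
            "len_cd8_10um",
            "CD8 increase under 10 µM LEN at the treatment horizon",
            expected=46.4, rel_tol=0.15, units="%", kind="eq",
            run=lambda seed, fast=False: len_cd8_increase_pct(
                seed, 40 if fast else 250
            )[1],
        ),
        CalibrationAnchor(
            "bmsc_uncertainty",
            "BMSC mean-output deviation under ±5% parameters, n≥5000",
            expected=4.0, rel_tol=0.0, units="%", kind="le",
            run=lambda seed, fast=False: uncertainty_mean_deviation_pct(
                "bmsc", seed, 1000 if fast else 5000
            ),
        ),
        CalibrationAnchor(
            "mic_uncertainty",
            "MIC mean-output deviation under ±5% parameters, n≥5000",
            expected=5.0, rel_tol=0.0, units="%", kind="le",
            run=lambda seed, fast=False: uncertainty_mean_deviation_pct(
                "mic", seed, 1000 if fast else 5000
            ),
        ),
        CalibrationAnchor(
            "synergy_additive",
            "Synergy index equals 1 under multiplicative independence",
            expected=1.0, rel_tol=1e-12, units="", kind="eq",
            run=lambda seed, fast=False: independence_synergy_index(seed),
        ),
        CalibrationAnchor(
            "mic_adhesion_total",
            "Total MIC adhesion at myeloma-stroma stiffness",
            expected=67.0, rel_tol=0.01, units="%", kind="eq",
            run=lambda seed, fast=False: total_adhesion_pct(),
        ),
    ]
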