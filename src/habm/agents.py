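"""Stochastic behavior rules of the five cell-agent compartments.

Every behavior follows the same die-casting pattern: a probability is
computed from the agent's local microenvironment (via the embedded ODE
readouts or Hill functions), then a uniform draw against that probability
commits the decision.  The compiled engine applies these rules in bulk;
this module exposes them individually, together with the full set of
tunable rule constants (:class:`AbmParams`).

Kind codes follow :mod:`habm._kernels`: 0 MIC, 1 MM, 2 CD8, 3 Treg
(stromal cells are a static scaffold handled by the orchestrator).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from ._kernels import (
    CD8,
    MIC,
    MM,
    TREG,
    adjacent_of_kind,
    nearest_of_kind,
    pick_free_neighbor,
    pick_stiffest_neighbor,
    pick_toward,
)

__all__ = [
    "MIC",
    "MM",
    "CD8",
    "TREG",
    "KIND_NAMES",
    "AbmParams",
    "decide",
    "hill_prob",
    "mic_fate",
    "divide_site",
    "attempt_lysis",
    "treg_suppress",
    "cd8_proliferation_prob",
    "treg_proliferation_prob",
    "mm_death_prob",
    "mic_step_death_prob",
    "thal_attenuation",
]

KIND_NAMES = ("MIC", "MM", "CD8", "TREG")


def decide(p: float, rng: np.random.Generator) -> bool:
    """Commit a behavior by rolling a die against probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    return bool(rng.random() < p)


def hill_prob(x: float, pmax: float, H: float, n: float = 1.0) -> float:
    """Saturating behavior probability ``pmax·xⁿ/(Hⁿ+xⁿ)``."""
    if x < 0:
        raise ValueError(f"signal must be non-negative, got {x}")
    if not 0.0 <= pmax <= 1.0:
        raise ValueError(f"pmax must be in [0, 1], got {pmax}")
    if H <= 0 or n < 1:
        raise ValueError("require H > 0 and n >= 1")
    xn = float(x) ** n
    return pmax * xn / (H**n + xn)


@dataclass(frozen=True)
class AbmParams:
    """Tunable rule constants of the lattice model.

    Probabilities are per decision opportunity; Hill half-saturations for
    stiffness-driven rules are in Pa, for TGFβ in relative concentration
    units, for drug terms in the drug's dose unit (BTZ nM, LEN/Thal µM).
    The defaults are the calibrated values reproducing the validation
    anchors (tumor expansion, BTZ kill, LEN-driven CTL expansion).
    """

    # cell-cycle lengths (h)
    cycle_mic_h: float = 24.0
    cycle_mm_h: float = 24.0
    cycle_cd8_h: float = 12.0
    cycle_treg_h: float = 12.0
    #: maximum passage number of an MM cell (obligatory death beyond it)
    lgn: int = 5

    # stiffness-driven MIC rules
    div_pmax_mic: float = 0.62
    div_H_pa: float = 220.0
    div_n: float = 2.0
    sr_pmax: float = 0.691
    sr_H_pa: float = 110.0
    sr_n: float = 1.0
    #: horizon (h) over which the survival-ODE readout is interpreted as a
    #: cumulative survival fraction when converting it to a per-step hazard
    survival_window_h: float = 144.0

    # MM rules
    div_pmax_mm: float = 0.92
    div_H_pa_mm: float = 150.0
    death_base_mm: float = 0.0015
    btz_pmax_mm: float = 0.076
    btz_H_nm: float = 1.5
    btz_n: float = 1.5

    # CD8 rules
    prolif_pmax_cd8: float = 0.12
    #: TGFβ inhibition floor: at saturating TGFβ the proliferation
    #: probability falls to this fraction of its uninhibited value
    tgfb_floor_cd8: float = 0.18
    tgfb_H_cd8: float = 0.25
    treg_K_cd8: float = 30.0
    len_amp_cd8: float = 0.0378
    len_H_um: float = 2.0
    death_base_cd8: float = 0.0015
    # Treg rules
    prolif_pmax_treg: float = 0.12
    tgfb_H_treg: float = 0.3
    len_H_treg_um: float = 3.0
    death_base_treg: float = 0.010

    # contact interactions
    lysis_p: float = 0.08
    lysis_protect: float = 0.3
    suppress_p: float = 0.015
    arrest_frac: float = 0.8
    sense_radius: int = 5

    # migration probabilities per step
    migrate_mic: float = 0.6
    migrate_mm: float = 0.5
    migrate_cd8: float = 0.8
    migrate_treg: float = 0.8

    # MIC adhesion handled through the adhesion-ODE lookup (no extra knob)

    # tissue scale
    secretion_sdf1: float = 0.15  # per MIC per hour
    secretion_tgfb_bmsc: float = 0.15  # per BMSC per hour
    secretion_tgfb_mm: float = 0.08  # per MM per hour
    diffusion: float = 1.0  # sites^2/h, both cytokines
    boundary: float = 0.0  # Dirichlet (sink-like marrow edge)
    thal_H_um: float = 2.0  # Thal attenuation of SDF-1 signaling / TGFβ output

    def with_overrides(self, **kw) -> "AbmParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Individual rules (thin, testable fronts of the engine kernels)


def mic_fate(p_selfrenew: float, rng: np.random.Generator) -> str:
    """Fate of an MIC committed to division.

    Self-renewal yields two MIC daughters; differentiation consumes the
    parent into two MM daughters.  The probability of self-renewal is the
    stiffness-driven Hill probability computed by the caller.
    """
    return "self_renew" if decide(p_selfrenew, rng) else "differentiate"


def divide_site(occ: np.ndarray, site: tuple[int, int, int],
                rng: np.random.Generator):
    """Daughter placement: uniform over free Moore neighbors, else None.

    ``None`` means the division is deferred — the parent remains in
    M-phase and retries at the next step.
    """
    i, j, k = _kernels.pick_free_neighbor(occ, site[0], site[1], site[2], rng)
    return None if i < 0 else (int(i), int(j), int(k))


def attempt_lysis(p_lysis: float, target_attached: bool, protect: float,
                  rng: np.random.Generator) -> bool:
    """CTL kill roll against an adjacent tumor cell.

    Stroma-attached targets are protected: the kill probability is scaled
    by ``protect`` (< 1).
    """
    p = p_lysis * (protect if target_attached else 1.0)
    return decide(p, rng)


def treg_suppress(p_suppress: float, arrest_frac: float,
                  rng: np.random.Generator) -> str | None:
    """Treg action on an adjacent CTL: arrest, apoptosis, or nothing.

    A first roll decides whether suppression happens at all; a second
    chooses cycle arrest (skip one proliferation opportunity) versus
    direct apoptosis.
    """
    if not decide(p_suppress, rng):
        return None
    return "arrest" if decide(arrest_frac, rng) else "apoptosis"


def cd8_proliferation_prob(
    tgfb: float, treg_count: float, len_um: float, p: AbmParams
) -> float:
    """Per-cycle CTL proliferation probability.

    Baseline probability inhibited by the local TGFβ level and by the
    global Treg load, plus a saturating lenalidomide co-stimulation term.
    """
    if min(tgfb, treg_count, len_um) < 0:
        raise ValueError("inputs must be non-negative")
    inhib = p.tgfb_floor_cd8 + (1.0 - p.tgfb_floor_cd8) * p.tgfb_H_cd8 / (
        p.tgfb_H_cd8 + tgfb
    )
    base = p.prolif_pmax_cd8 * inhib * p.treg_K_cd8 / (p.treg_K_cd8 + treg_count)
    boost = p.len_amp_cd8 * len_um / (p.len_H_um + len_um)
    return float(np.clip(base + boost, 0.0, 1.0))


def treg_proliferation_prob(tgfb: float, len_um: float, p: AbmParams) -> float:
    """Per-cycle Treg proliferation: TGFβ-driven, lenalidomide-suppressed."""
    if min(tgfb, len_um) < 0:
        raise ValueError("inputs must be non-negative")
    val = (
        p.prolif_pmax_treg
        * tgfb / (p.tgfb_H_treg + tgfb)
        * p.len_H_treg_um / (p.len_H_treg_um + len_um)
    )
    return float(np.clip(val, 0.0, 1.0))


def mm_death_prob(btz_nm: float, p: AbmParams) -> float:
    """Per-step MM death probability: baseline plus the BTZ Hill kill term."""
    if btz_nm < 0:
        raise ValueError("dose must be non-negative")
    kill = hill_prob(btz_nm, p.btz_pmax_mm, p.btz_H_nm, p.btz_n)
    return float(np.clip(p.death_base_mm + kill, 0.0, 1.0))


def mic_step_death_prob(survival: float | np.ndarray, dt_h: float,
                        p: AbmParams) -> np.ndarray:
    """Convert the survival-ODE readout into a per-step death probability.

    The readout is the surviving fraction over the acute treatment window,
    so the equivalent constant hazard gives a per-``dt`` death probability
    of ``1 − S^(dt/window)``.
    """
    s = np.clip(np.asarray(survival, dtype=float), 1e-9, 1.0)
    return 1.0 - s ** (dt_h / p.survival_window_h)


def thal_attenuation(thal_um: float, p: AbmParams) -> float:
    """Thalidomide attenuation factor on SDF-1→stiffness signaling and
    stromal TGFβ secretion (1 at no drug, →0 at saturating dose)."""
    if thal_um < 0:
        raise ValueError("dose must be non-negative")
    return p.thal_H_um / (p.thal_H_um + thal_um)
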