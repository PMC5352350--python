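"""Intracellular Hill-activation signaling networks.

Two ODE systems drive the cell agents of the myeloma niche model:

* the **BMSC stiffness network** — SDF-1/CXCR4 signaling (PI3K, MEK, FAK,
  RhoA, ERK, MYL2) converging on a dimensionless ``stiffness`` readout that
  is mapped onto the 400–530 Pa elastic-modulus range of bone-marrow stromal
  cells;
* the **MIC adhesion/survival network** — integrin/FAK signaling (FAK, Rac,
  PI3K, AKT, JNK, cJUN, NFKB) in myeloma-initiating cells, driven by the
  local niche stiffness, with ``Adhesion`` and ``Survival`` probability
  readouts and a bortezomib (BTZ) inhibition term acting on ``Survival``.

Every interaction is a saturating Hill production ``k·x/(H+x)`` and every
state carries first-order decay ``−d·x``.  States are fold-changes relative
to t=0, so integration always starts from the all-ones state unless
overridden.  Time is in hours throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "hill",
    "SignalingNetwork",
    "OdeParameters",
    "TimeCourse",
    "StiffnessMap",
    "IntegrationError",
    "build_bmsc_network",
    "build_mic_network",
    "integrate",
    "bmsc_stiffness_response",
    "mic_survival_rate",
    "mic_adhesion_rate",
    "load_params",
    "STIFFNESS_INPUT_REF_PA",
    "ADHESION_FLOOR",
]

#: Reference used to normalize the Pa-valued stiffness input of the MIC
#: network to a dimensionless level in (0, 1]; 530 Pa is the network's
#: maximal admissible input.
STIFFNESS_INPUT_REF_PA = 530.0

#: Constant non-stiffness contribution to MIC adhesion (all other adhesion
#: factors lumped as ~20 percentage points, identical across conditions).
ADHESION_FLOOR = 0.20


class IntegrationError(RuntimeError):
    """Raised when the stiff ODE solver fails to converge."""


def hill(x: float, k: float, H: float) -> float:
    """Saturating production rate ``k*x/(H+x)``.

    Parameters
    ----------
    x : float
        Non-negative input level (fold-change units).
    k : float
        Maximal production rate (per hour); upper bound of the response.
    H : float
        Half-saturation constant (same units as *x*); must be positive.
    """
    if H <= 0:
        raise ValueError(f"half-saturation H must be positive, got {H}")
    if k < 0:
        raise ValueError(f"rate k must be non-negative, got {k}")
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"input level must be non-negative, got {x}")
    return k * x / (H + x)


@dataclass(frozen=True)
class SignalingNetwork:
    """Directed Hill-activation network with per-node degradation.

    ``edges`` are ``(source, target, k_id, H_id)`` tuples; ``inhibitions``
    are ``(dose_symbol, target, K_id, H_id)`` drug terms subtracted from the
    target's rate.  ``inputs`` are held constant during integration and are
    not part of the state vector.
    """

    name: str
    species: tuple[str, ...]
    inputs: tuple[str, ...]
    edges: tuple[tuple[str, str, str, str], ...]
    degradations: Mapping[str, str]
    outputs: tuple[str, ...]
    inhibitions: tuple[tuple[str, str, str, str], ...] = ()

    def __post_init__(self) -> None:
        declared = set(self.species) | set(self.inputs)
        for src, dst, _, _ in self.edges:
            if src not in declared or dst not in declared:
                raise ValueError(f"edge {src}->{dst} uses undeclared species")
            if dst in self.inputs:
                raise ValueError(f"input species {dst} cannot be a target")
        missing = [s for s in self.species if s not in self.degradations]
        if missing:
            raise ValueError(f"species without degradation term: {missing}")

    @property
    def n_states(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)


@dataclass(frozen=True)
class OdeParameters:
    """Rate constants of one signaling network.

    ``k`` maximal production rates (1/h), ``H`` half-saturations
    (fold-change units), ``d`` first-order decays (1/h), ``drug`` maps a
    dose symbol to its ``(K, H)`` inhibition pair (K in 1/h, H in dose
    units).
    """

    k: Mapping[str, float]
    H: Mapping[str, float]
    d: Mapping[str, float]
    drug: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group in (self.k, self.H, self.d):
            for key, val in group.items():
                if not np.isfinite(val) or val <= 0:
                    raise ValueError(f"parameter {key}={val} must be positive finite")
        for sym, (K, Hd) in self.drug.items():
            if not (np.isfinite(K) and K > 0 and np.isfinite(Hd) and Hd > 0):
                raise ValueError(f"drug pair {sym}=({K}, {Hd}) must be positive finite")

    def to_dict(self) -> dict:
        return {
            "k": dict(self.k),
            "H": dict(self.H),
            "d": dict(self.d),
            "drug": {s: list(pair) for s, pair in self.drug.items()},
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "OdeParameters":
        return cls(
            k=dict(payload["k"]),
            H=dict(payload["H"]),
            d=dict(payload["d"]),
            drug={s: tuple(p) for s, p in payload.get("drug", {}).items()},
        )


@dataclass(frozen=True)
class TimeCourse:
    """Solution of one network on a time grid (fold-change units)."""

    network: str
    times: np.ndarray
    species: tuple[str, ...]
    values: np.ndarray  # shape (n_species, n_times)

    def get(self, name: str) -> np.ndarray:
        return self.values[self.species.index(name)]

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times}
        data.update({s: self.values[i] for i, s in enumerate(self.species)})
        return pd.DataFrame(data)


@dataclass(frozen=True)
class StiffnessMap:
    """Affine, clamped map from the dimensionless stiffness state to Pa.

    Anchored at the unstimulated 60-min response (``s0`` → 400 Pa) and at
    the saturating 60-min response (``s_sat`` → 530 Pa); clamped to
    [400, 530] Pa, so the all-ones initial state also reads the 400 Pa
    baseline.
    """

    s0: float = 1.0
    s_sat: float = 2.0
    baseline_pa: float = 400.0
    max_pa: float = 530.0

    def __post_init__(self) -> None:
        if self.s_sat <= self.s0:
            raise ValueError("saturating state must exceed the initial state")

    def __call__(self, s):
        frac = (np.asarray(s, dtype=float) - self.s0) / (self.s_sat - self.s0)
        pa = self.baseline_pa + (self.max_pa - self.baseline_pa) * frac
        return np.clip(pa, self.baseline_pa, self.max_pa)


def build_bmsc_network() -> SignalingNetwork:
    """SDF-1/CXCR4 → stiffness network of the stromal-cell agent.

    Seven states with ten Hill edges: SDF-1 activates PI3K and MEK; PI3K
    feeds FAK and RhoA; MEK feeds RhoA and ERK; RhoA and ERK converge on
    MYL2; FAK and MYL2 set the stiffness readout.
    """
    return SignalingNetwork(
        name="bmsc",
        species=("PI3K", "MEK", "FAK", "RhoA", "ERK", "MYL2", "stiffness"),
        inputs=("SDF1",),
        edges=(
            ("SDF1", "PI3K", "k1", "H1"),
            ("SDF1", "MEK", "k2", "H2"),
            ("PI3K", "FAK", "k3", "H3"),
            ("PI3K", "RhoA", "k4", "H4"),
            ("MEK", "RhoA", "k5", "H5"),
            ("MEK", "ERK", "k6", "H6"),
            ("RhoA", "MYL2", "k7", "H7"),
            ("ERK", "MYL2", "k8", "H8"),
            ("FAK", "stiffness", "k9", "H9"),
            ("MYL2", "stiffness", "k10", "H10"),
        ),
        degradations={
            "PI3K": "d1",
            "MEK": "d2",
            "FAK": "d3",
            "RhoA": "d4",
            "ERK": "d5",
            "MYL2": "d6",
            "stiffness": "d7",
        },
        outputs=("stiffness",),
    )


def build_mic_network() -> SignalingNetwork:
    """Integrin/FAK → adhesion & survival network of the MIC agent.

    Driven by the (normalized) local stiffness; NFKB integrates Rac and AKT
    branches into the Survival readout, which additionally carries the BTZ
    dose-inhibition term ``−K_BTZ·D1/(H_BTZ+D1)``.
    """
    return SignalingNetwork(
        name="mic",
        species=(
            "FAK",
            "Rac",
            "PI3K",
            "AKT",
            "JNK",
            "cJUN",
            "NFKB",
            "Adhesion",
            "Survival",
        ),
        inputs=("stiffness", "D1"),
        edges=(
            ("stiffness", "FAK", "k1", "H1"),
            ("FAK", "Rac", "k2", "H2"),
            ("PI3K", "Rac", "k3", "H3"),
            ("FAK", "PI3K", "k4", "H4"),
            ("PI3K", "AKT", "k5", "H5"),
            ("Rac", "JNK", "k6", "H6"),
            ("JNK", "cJUN", "k7", "H7"),
            ("Rac", "NFKB", "k8", "H8"),
            ("AKT", "NFKB", "k9", "H9"),
            ("cJUN", "Adhesion", "k10", "H10"),
            ("NFKB", "Survival", "k11", "H11"),
        ),
        degradations={
            "FAK": "d1",
            "Rac": "d2",
            "PI3K": "d3",
            "AKT": "d4",
            "JNK": "d5",
            "cJUN": "d6",
            "NFKB": "d7",
            "Adhesion": "d8",
            "Survival": "d9",
        },
        outputs=("Adhesion", "Survival"),
        inhibitions=(("D1", "Survival", "K_BTZ", "H_BTZ"),),
    )


def _compile_rhs(net: SignalingNetwork, params: OdeParameters, inputs: Mapping[str, float]):
    """Assemble vectorized RHS arrays for the coupled Hill ODEs."""
    missing = [s for s in net.inputs if s not in inputs and not any(
        sym == s for sym, _, _, _ in net.inhibitions)]
    if missing:
        raise ValueError(f"missing input levels for {missing}")

    n = net.n_states
    src_state = []  # (state_idx, target_idx, k, H) edges from states
    const_prod = np.zeros(n)  # contributions from constant inputs / inhibitions
    for src, dst, k_id, H_id in net.edges:
        k, H = params.k[k_id], params.H[H_id]
        j = net.index(dst)
        if src in net.inputs:
            const_prod[j] += hill(float(inputs[src]), k, H)
        else:
            src_state.append((net.index(src), j, k, H))
    # drug inhibition pairs are stored under the dose symbol
    for sym, dst, _, _ in net.inhibitions:
        dose = float(inputs.get(sym, 0.0))
        if dose < 0:
            raise ValueError(f"negative drug dose {sym}={dose}")
        if dose > 0:
            K, Hd = params.drug[sym]
            const_prod[net.index(dst)] -= K * dose / (Hd + dose)

    si = np.array([e[0] for e in src_state], dtype=np.intp)
    ti = np.array([e[1] for e in src_state], dtype=np.intp)
    kk = np.array([e[2] for e in src_state])
    HH = np.array([e[3] for e in src_state])
    dd = np.array([params.d[net.degradations[s]] for s in net.species])

    def rhs(_t, y):
        x = np.maximum(y, 0.0)  # clamp: fold-changes cannot go negative
        dy = const_prod - dd * x
        np.add.at(dy, ti, kk * x[si] / (HH + x[si]))
        return dy

    return rhs


def integrate(
    net: SignalingNetwork,
    params: OdeParameters,
    inputs: Mapping[str, float],
    t_grid: Sequence[float],
    y0: Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> TimeCourse:
    """Integrate a network on ``t_grid`` (hours) from the all-ones state.

    Inputs are held constant; drug dose symbols (e.g. ``D1``) are read from
    ``inputs`` as well and default to 0.  States are clamped at 0 from
    below (only the Survival readout can mathematically go negative through
    its inhibition term).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0")
    rhs = _compile_rhs(net, params, inputs)
    y0 = np.ones(net.n_states) if y0 is None else np.asarray(y0, dtype=float)
    if len(t_grid) == 1:  # degenerate: initial state only
        return TimeCourse(net.name, t_grid, net.species, y0[:, None].copy())
    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        y0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"{net.name}: solver failed: {sol.message}")
    return TimeCourse(net.name, t_grid, net.species, np.maximum(sol.y, 0.0))


# ---------------------------------------------------------------------------
# Calibrated readouts


def bmsc_stiffness_response(
    sdf1: float,
    params: OdeParameters,
    smap: StiffnessMap,
    t: float = 1.0,
) -> float:
    """Stiffness (Pa) of a stromal cell exposed to relative SDF-1 dose ``sdf1``.

    ``sdf1`` is dimensionless with 1.0 ≡ the saturating 100 ng/ml reference;
    the response is read at ``t`` hours (default 60 min, the response time
    at which the 530 Pa ceiling is anchored).
    """
    if sdf1 < 0:
        raise ValueError("SDF-1 dose must be non-negative")
    tc = integrate(build_bmsc_network(), params, {"SDF1": sdf1}, [0.0, t])
    return float(smap(tc.get("stiffness")[-1]))


def mic_survival_rate(
    stiffness_pa: float,
    btz_nm: float,
    params: OdeParameters,
    t: float = 144.0,
) -> float:
    """Survival probability of an MIC over ``t`` hours at the given niche.

    The Survival readout of the integrin/FAK network under normalized
    stiffness input and BTZ dose ``btz_nm`` (nM), clamped to [0, 1].
    """
    if btz_nm < 0:
        raise ValueError("BTZ dose must be non-negative")
    if stiffness_pa < 0:
        raise ValueError("stiffness must be non-negative")
    level = min(stiffness_pa, STIFFNESS_INPUT_REF_PA) / STIFFNESS_INPUT_REF_PA
    tc = integrate(
        build_mic_network(), params, {"stiffness": level, "D1": btz_nm}, [0.0, t]
    )
    return float(np.clip(tc.get("Survival")[-1], 0.0, 1.0))


def mic_adhesion_rate(
    stiffness_pa: float,
    params: OdeParameters,
    t: float = 24.0,
    include_floor: bool = True,
) -> float:
    """Adhesion probability of an MIC on a stromal surface of given stiffness.

    Stiffness-driven Adhesion readout (24-h incubation by default) plus the
    constant 20-percentage-point non-stiffness contribution; clamped to
    [0, 1].
    """
    if stiffness_pa < 0:
        raise ValueError("stiffness must be non-negative")
    level = min(stiffness_pa, STIFFNESS_INPUT_REF_PA) / STIFFNESS_INPUT_REF_PA
    tc = integrate(build_mic_network(), params, {"stiffness": level, "D1": 0.0}, [0.0, t])
    component = float(np.clip(tc.get("Adhesion")[-1], 0.0, 1.0))
    total = component + (ADHESION_FLOOR if include_floor else 0.0)
    return float(np.clip(total, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Shipped calibrated parameters

_PARAM_DIR = Path(__file__).parent / "params"


def load_params(model: str) -> dict:
    """Load the shipped calibrated parameter asset for ``bmsc`` or ``mic``.

    Returns a dict with keys ``params`` (:class:`OdeParameters`) plus the
    calibration constants stored alongside (stiffness map anchors, the
    5 nM ↦ relative-dose mapping, …).
    """
    path = _PARAM_DIR / f"{model}_ode.json"
    payload = json.loads(path.read_text())
    out = dict(payload)
    out["params"] = OdeParameters.from_dict(payload["params"])
    if "stiffness_map" in payload:
        out["stiffness_map"] = StiffnessMap(**payload["stiffness_map"])
    return out
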