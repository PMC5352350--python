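"""Three-drug dose grids and the triple-combination synergy index.

For drug levels i, j, k (BTZ, LEN, Thal) with replicate-mean myeloma
survival ratios D, the synergy index of the triple combination is

    C_ijk = (Di·Djk + Dj·Dik + Dk·Dij − 2·Di·Dj·Dk) / D_ijk

— the numerator is the response expected from the lower-order effects
under multiplicative independence, the denominator the simulated triple
response.  C > 1 is synergistic, C < 1 antagonistic, C = 1 additive; if
all pairwise and triple ratios factorize (D_ab = D_a·D_b,
D_ijk = Di·Dj·Dk) the index collapses to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SimulationConfig, run_replicates
from .fields import DrugRegimen

__all__ = [
    "DoseGrid",
    "SynergyCube",
    "survival_ratio",
    "synergy_index",
    "classify",
    "sweep",
    "ADDITIVE_BAND",
]

#: |C − 1| tolerance inside which a combination is called additive.
ADDITIVE_BAND = 0.02


@dataclass(frozen=True)
class DoseGrid:
    """11-level dose grid per drug: 0, then 0.1× to 1.0× of the maximum."""

    btz_max_nm: float = 5.0
    len_max_um: float = 10.0
    thal_max_um: float = 10.0
    n_levels: int = 11

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least the zero level and one dose level")

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.n_levels)

    def dose(self, drug: str, level: int) -> float:
        """Dose of ``drug`` at integer ``level`` (0 = no drug)."""
        if not 0 <= level < self.n_levels:
            raise ValueError(f"level {level} outside 0..{self.n_levels - 1}")
        top = {"BTZ": self.btz_max_nm, "LEN": self.len_max_um,
               "THAL": self.thal_max_um}[drug]
        return top * level / (self.n_levels - 1)

    def conditions(self) -> list[tuple[int, int, int]]:
        """All level triples — the full factorial (11³ = 1331 by default)."""
        lv = self.levels
        return [(int(i), int(j), int(k)) for i in lv for j in lv for k in lv]


def survival_ratio(treated, control, t_eval: float) -> float:
    """Myeloma (MIC+MM) survival ratio treated/control at ``t_eval`` hours.

    Accepts single-replicate or replicate-summary time series; clamped to
    [0, 1] (a treated arm can stochastically exceed its control).
    """
    it = int(np.argmin(np.abs(treated.times - t_eval)))
    ic = int(np.argmin(np.abs(control.times - t_eval)))
    c = float(control.myeloma[ic])
    if c <= 0:
        raise ValueError("control myeloma count is zero at the evaluation time")
    return float(np.clip(float(treated.myeloma[it]) / c, 0.0, 1.0))


def synergy_index(Di, Dj, Dk, Dij, Dik, Djk, Dijk) -> float:
    """Three-drug synergy index C from the seven survival ratios.

    ``Dijk == 0`` (complete kill by the triple) returns ``inf`` — the
    maximal-synergy sentinel rather than a finite index.
    """
    for name, val in (("Di", Di), ("Dj", Dj), ("Dk", Dk), ("Dij", Dij),
                      ("Dik", Dik), ("Djk", Djk), ("Dijk", Dijk)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [0, 1]")
    expected = Di * Djk + Dj * Dik + Dk * Dij - 2.0 * Di * Dj * Dk
    if Dijk == 0.0:
        return float("inf")
    return float(expected / Dijk)


def classify(C: float, band: float = ADDITIVE_BAND) -> str:
    """SYNERGISTIC / ANTAGONISTIC / ADDITIVE with an |C−1| ≤ band additive zone."""
    if np.isinf(C):
        return "SYNERGISTIC"
    if abs(C - 1.0) <= band:
        return "ADDITIVE"
    return "SYNERGISTIC" if C > 1.0 else "ANTAGONISTIC"


@dataclass
class SynergyCube:
    """Replicate-mean survival ratios and synergy indices on a level grid."""

    grid: DoseGrid
    level_subset: np.ndarray  # actual levels simulated, ascending, 0 first
    D: np.ndarray  # (n, n, n) survival ratios
    D_sd: np.ndarray
    C: np.ndarray  # NaN where any required level is missing / not all >0
    labels: np.ndarray  # object array of classification strings ('' where C NaN)
    t_eval_h: float
    replicates: int

    @property
    def n_conditions(self) -> int:
        return self.D.size

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ls = self.level_subset
        for a, i in enumerate(ls):
            for b, j in enumerate(ls):
                for c, k in enumerate(ls):
                    rows.append(
                        {
                            "i": i,
                            "j": j,
                            "k": k,
                            "dose_btz_nM": self.grid.dose("BTZ", i),
                            "dose_len_uM": self.grid.dose("LEN", j),
                            "dose_thal_uM": self.grid.dose("THAL", k),
                            "D_mean": self.D[a, b, c],
                            "D_sd": self.D_sd[a, b, c],
                            "C": self.C[a, b, c],
                            "label": self.labels[a, b, c],
                        }
                    )
        return pd.DataFrame(rows)


def compute_indices(D: np.ndarray, band: float = ADDITIVE_BAND):
    """Fill C and labels from a cube of survival ratios (level 0 first)."""
    n = D.shape[0]
    C = np.full(D.shape, np.nan)
    labels = np.full(D.shape, "", dtype=object)
    for a in range(1, n):
        for b in range(1, n):
            for c in range(1, n):
                Dijk = D[a, b, c]
                val = synergy_index(
                    D[a, 0, 0], D[0, b, 0], D[0, 0, c],
                    D[a, b, 0], D[a, 0, c], D[0, b, c],
                    Dijk,
                ) if Dijk > 0 else float("inf")
                C[a, b, c] = val
                labels[a, b, c] = classify(val, band)
    return C, labels


def sweep(
    config: SimulationConfig,
    grid: DoseGrid | None = None,
    replicates: int = 20,
    seed: int = 0,
    t_eval_h: float = 144.0,
    level_subset: Sequence[int] | None = None,
) -> SynergyCube:
    """Factorial dose sweep over the three drugs.

    Runs ``replicates`` seeded replicates per condition, takes the
    replicate-mean myeloma count at ``t_eval_h`` relative to the shared
    zero-dose control, and fills the synergy index for every all-treated
    triple.  ``level_subset`` restricts the factorial to a sub-grid
    (it must contain level 0); the default is the full 11³ = 1331
    conditions, which is cluster-scale — desk-scale work uses a 4-level
    sub-grid.
    """
    grid = grid or DoseGrid()
    if replicates < 1:
        raise ValueError("need at least one replicate per condition")
    ls = np.array(sorted(set(level_subset))) if level_subset is not None else grid.levels
    if ls[0] != 0:
        raise ValueError("the level subset must include the zero-dose level")
    n = len(ls)

    means = np.empty((n, n, n))
    sds = np.empty((n, n, n))
    for a, i in enumerate(ls):
        for b, j in enumerate(ls):
            for c, k in enumerate(ls):
                regimen = DrugRegimen(
                    btz_nm=grid.dose("BTZ", i),
                    len_um=grid.dose("LEN", j),
                    thal_um=grid.dose("THAL", k),
                )
                cfg = config.with_overrides(regimen=regimen)
                # condition-specific master seed, derived reproducibly
                cond_seed = [seed, int(i), int(j), int(k)]
                summ = run_replicates(cfg, replicates, np.random.SeedSequence(cond_seed))
                it = int(np.argmin(np.abs(summ.times - t_eval_h)))
                means[a, b, c] = summ.myeloma[it]
                sds[a, b, c] = float(
                    np.sqrt(summ.sd[it, 0] ** 2 + summ.sd[it, 1] ** 2)
                )
    control = means[0, 0, 0]
    if control <= 0:
        raise ValueError("zero-dose control died out; cannot form survival ratios")
    D = np.clip(means / control, 0.0, 1.0)
    D_sd = sds / control
    C, labels = compute_indices(D)
    return SynergyCube(
        grid=grid,
        level_subset=ls,
        D=D,
        D_sd=D_sd,
        C=C,
        labels=labels,
        t_eval_h=t_eval_h,
        replicates=replicates,
    )
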