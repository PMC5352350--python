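"""Tissue-scale 3D microenvironment: cytokine fields, drugs, stiffness.

The bone-marrow domain is a rectangular lattice (one cell diameter per
site) with an inscribed cylindrical mask of valid agent sites.  Two
diffusible cytokine fields live on the lattice — SDF-1 (secreted by
myeloma-initiating cells) and TGFβ (secreted by stromal and mature
myeloma cells) — evolved by an explicit 7-point-stencil diffusion scheme
with Dirichlet boundary.  Drugs are spatially uniform step functions of
time (144-h treatment window).  The biophysical microenvironment is the
stiffness field: the Pa-valued stiffness of the nearest adjacent stromal
cell, or a 100 Pa soft-ECM floor away from the stromal scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._kernels import diffuse_steps

__all__ = [
    "Domain",
    "ConcentrationField",
    "DrugRegimen",
    "SOFT_ECM_PA",
    "TREATMENT_DURATION_H",
    "diffuse",
    "secrete",
    "drug_level",
    "stiffness_field",
    "local_stiffness",
]

#: Elastic modulus of the extracellular matrix away from any stromal cell.
SOFT_ECM_PA = 100.0
#: Default acute-treatment window (6 days).
TREATMENT_DURATION_H = 144.0


@dataclass(frozen=True)
class Domain:
    """Rectangular lattice with an inscribed cylindrical mask (axis z)."""

    nx: int = 50
    ny: int = 50
    nz: int = 50
    spacing: float = 1.0  # one cell diameter per site

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 3:
            raise ValueError("domain must be at least 3 sites in each dimension")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    def cylinder_mask(self) -> np.ndarray:
        """Boolean array of valid agent sites (cylinder inscribed in x-y)."""
        cx, cy = (self.nx - 1) / 2.0, (self.ny - 1) / 2.0
        r = min(self.nx, self.ny) / 2.0 - 0.5
        x, y = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        disk = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        return np.broadcast_to(disk[:, :, None], self.shape).copy()


@dataclass
class ConcentrationField:
    """Scalar cytokine field on the lattice (relative concentration units)."""

    grid: np.ndarray
    diffusion: float = 1.0  # sites^2 per hour
    boundary: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.ascontiguousarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("field grid must be 3D")
        if (self.grid < 0).any():
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def uniform(cls, domain: Domain, value: float, diffusion: float = 1.0,
                boundary: float = 0.0) -> "ConcentrationField":
        return cls(np.full(domain.shape, value), diffusion, boundary)

    def to_frame(self):
        """Long-format snapshot (x, y, z, value) for CSV export."""
        import pandas as pd

        nx, ny, nz = self.grid.shape
        x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                              indexing="ij")
        return pd.DataFrame(
            {"x": x.ravel(), "y": y.ravel(), "z": z.ravel(),
             "value": self.grid.ravel()}
        )


def diffuse(fld: ConcentrationField, dt: float, substeps: int = 1) -> ConcentrationField:
    """Advance the field by ``dt`` hours of explicit diffusion.

    7-point stencil with Dirichlet boundary (the outer lattice shell held
    at the boundary value).  The per-substep time step must satisfy the
    explicit stability bound D·dt/Δx² ≤ 1/6.
    """
    h = dt / substeps
    if fld.diffusion * h > 1.0 / 6.0 + 1e-12:
        need = int(np.ceil(6.0 * fld.diffusion * dt))
        raise ValueError(
            f"explicit diffusion unstable (D*dt={fld.diffusion * h:.3g} > 1/6); "
            f"use substeps>={need}"
        )
    out = fld.grid.copy()
    diffuse_steps(out, fld.diffusion, h, substeps, fld.boundary)
    return ConcentrationField(out, fld.diffusion, fld.boundary)


def secrete(
    fld: ConcentrationField,
    positions: np.ndarray,
    kinds: np.ndarray,
    rate_map: Mapping[int, float],
    dt: float,
) -> ConcentrationField:
    """Add ``rate·dt`` at each secreting agent's site.

    ``rate_map`` maps agent-kind codes to secretion rates (concentration
    per hour); kinds not in the map secrete nothing.
    """
    out = fld.grid.copy()
    for kind, rate in rate_map.items():
        sel = positions[kinds == kind]
        if len(sel):
            np.add.at(out, (sel[:, 0], sel[:, 1], sel[:, 2]), rate * dt)
    return ConcentrationField(out, fld.diffusion, fld.boundary)


@dataclass(frozen=True)
class DrugRegimen:
    """Constant-dose treatment over a fixed window.

    Doses: BTZ in nM, LEN and Thal in µM.  Each drug is present at its
    dose for ``start <= t < start + duration`` and absent otherwise,
    spatially uniform (no pharmacokinetics modeled).
    """

    btz_nm: float = 0.0
    len_um: float = 0.0
    thal_um: float = 0.0
    start_h: float = 0.0
    duration_h: float = TREATMENT_DURATION_H

    def __post_init__(self) -> None:
        if min(self.btz_nm, self.len_um, self.thal_um) < 0:
            raise ValueError("drug doses must be non-negative")
        if self.duration_h < 0:
            raise ValueError("treatment duration must be non-negative")

    def dose(self, drug: str) -> float:
        return {"BTZ": self.btz_nm, "LEN": self.len_um, "THAL": self.thal_um}[drug]


def drug_level(regimen: DrugRegimen, drug: str, t: float) -> float:
    """Dose of ``drug`` at time ``t`` (half-open treatment window)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    inside = regimen.start_h <= t < regimen.start_h + regimen.duration_h
    return regimen.dose(drug) if inside else 0.0


def stiffness_field(
    shape: tuple[int, int, int],
    bmsc_positions: np.ndarray,
    bmsc_stiffness_pa: np.ndarray,
    floor_pa: float = SOFT_ECM_PA,
) -> np.ndarray:
    """Pa-valued stiffness at every site.

    Each site takes the stiffness of the stiffest stromal cell at or
    Moore-adjacent to it; sites away from the scaffold fall back to the
    soft-ECM floor.
    """
    arr = np.full(shape, floor_pa)
    if len(bmsc_positions) == 0:
        return arr
    nx, ny, nz = shape
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                p = bmsc_positions + np.array([dx, dy, dz])
                ok = (
                    (p[:, 0] >= 0) & (p[:, 0] < nx)
                    & (p[:, 1] >= 0) & (p[:, 1] < ny)
                    & (p[:, 2] >= 0) & (p[:, 2] < nz)
                )
                q = p[ok]
                np.maximum.at(arr, (q[:, 0], q[:, 1], q[:, 2]), bmsc_stiffness_pa[ok])
    return arr


def local_stiffness(stiff_pa: np.ndarray, site: tuple[int, int, int]) -> float:
    """Stiffness (Pa) sensed by an agent at ``site``."""
    return float(stiff_pa[site])
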