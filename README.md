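# habm — hybrid multiscale agent-based model of multiple myeloma growth

Multiple myeloma grows inside a bone-marrow niche that actively protects
it: myeloma-initiating cells (MICs) secrete SDF-1, which stiffens the
bone-marrow stromal cells (BMSCs) they attach to; the stiffer niche in
turn boosts MIC adhesion, survival and self-renewal, while
stroma- and tumor-derived TGFβ expands regulatory T cells (Tregs) and
suppresses the cytotoxic CD8⁺ T cells (CTLs) that would otherwise lyse
tumor cells. `habm` is a simulator of this system for computational
biologists studying how cytotoxic and immunomodulatory drugs — alone and
in combination — act on that feedback architecture.

The model couples three scales:

* **Intracellular** — two ODE networks of saturating (Hill)
  interactions, `dx_s/dt = Σ_e k_e·x_src/(H_e + x_src) − d_s·x_s`:
  SDF-1/CXCR4 signaling (PI3K, MEK, FAK, RhoA, ERK, MYL2) sets BMSC
  stiffness on the 400–530 Pa scale, and integrin/FAK signaling (FAK,
  Rac, PI3K, AKT, JNK, cJUN, NFKB) sets MIC adhesion and survival, the
  latter carrying a bortezomib inhibition term −K·D/(H+D).
* **Intercellular** — a stochastic lattice model of five cell kinds
  (BMSC, MIC, MM, CD8⁺, Treg) with die-casting rules for division,
  MIC self-renewal vs differentiation, migration, CTL lysis
  (attachment-protected), and Treg-mediated arrest/apoptosis of CTLs.
* **Tissue** — diffusing SDF-1/TGFβ fields (explicit 7-point stencil,
  Dirichlet boundary) and spatially uniform drug levels over a 144-h
  treatment window.

Network parameters are estimated by a genetic algorithm from
fold-change phospho-proteomics time courses (bundled as a synthetic
generator) and anchored to in-vitro dose–response measurements. For
three-drug treatment (bortezomib BTZ, lenalidomide LEN, thalidomide
Thal) the package computes the triple-combination synergy index

    C_ijk = (Di·Djk + Dj·Dik + Dk·Dij − 2·Di·Dj·Dk) / D_ijk

from myeloma survival ratios D on an 11×11×11 dose grid (C > 1
synergistic, < 1 antagonistic, = 1 additive).

## Worked example

```python
from habm import SimulationConfig, run
from habm.networks import load_params, bmsc_stiffness_response, mic_survival_rate

# calibrated ODE readouts
bp = load_params("bmsc")
bmsc_stiffness_response(bp["sdf1_rel_5nm"], bp["params"], bp["stiffness_map"])
# -> 526.0   (Pa: stromal stiffness after the 5 nM SDF-1 equivalent)

mp = load_params("mic")
mic_survival_rate(400.0, 0.0, mp["params"])   # -> 0.967  untreated, 144 h
mic_survival_rate(400.0, 5.0, mp["params"])   # -> 0.104  5 nM BTZ (89.2% kill)

# one untreated lattice replicate over a 6-day window
series = run(SimulationConfig(horizon_h=144.0), seed=7)
print(series.to_frame().iloc[::24].to_string(index=False))
```

```
 time_h  MIC   MM  CD8  TREG  mean_bmsc_pa
    0.0  100  100   20     5    400.000000
   48.0  102  265   30     5    409.483587
   96.0  105  638   33     6    416.711185
  144.0   99 1266   35     4    420.024504
```

Mature myeloma (MM) expands much faster than the stem-like MIC pool,
which self-renews slowly while seeding MM; the small CTL compartment
grows modestly against rising TGFβ; and mean stromal stiffness creeps up
from its 400 Pa baseline as tumor-derived SDF-1 accumulates — the
niche-stiffening feedback at work. With `regimen=DrugRegimen(btz_nm=1.5)`
the myeloma count at 48 h roughly halves relative to this control.

The command-line interface exposes the same machinery:

```bash
habm simulate --config cfg.yaml --seed 1 --replicates 50 --out runs/
habm sweep --levels 4 --replicates 20 --seed 1 --out cube.csv
habm synergy --cube cube.csv
habm fit --model bmsc --seed 1 --out params.json
habm sensitivity --model mic --out sens.csv
habm uncertainty --model bmsc --seed 1 --out unc.csv
habm anchors --run --fast
```

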