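# Methods

`habm` simulates the growth of multiple myeloma in a 3D bone-marrow niche
as a hybrid of two deterministic intracellular ODE systems and a
stochastic lattice agent-based model, with diffusible SDF-1 and TGFβ
fields coupling the scales and three drugs (bortezomib/BTZ,
lenalidomide/LEN, thalidomide/Thal) acting on distinct arms of the
system. This note records the model, its assumptions, the calibration
procedure, the numerical choices, and what the bundled synthetic data do
and do not establish.

## 1. Intracellular scale: two Hill-activation ODE networks

Both networks are built from one primitive: every directed interaction
contributes a saturating production `k·x/(H+x)` to its target and every
state carries first-order decay `−d·x`. States are fold-changes relative
to t = 0, so integration starts from the all-ones state; time is in
hours.

**Stromal-cell (BMSC) stiffness network.** SDF-1 (a constant input
during each integration; dimensionless relative dose with 1.0 ≡ the
saturating 100 ng/ml reference) activates PI3K and MEK; PI3K feeds FAK
and RhoA, MEK feeds RhoA and ERK, RhoA and ERK converge on MYL2, and FAK
plus MYL2 drive a dimensionless `stiffness` readout (7 states, 10
edges). An affine, clamped map converts the readout to Pascals. The map
is anchored at the *responses*: the unstimulated 60-min state reads
400 Pa and the saturating 60-min state reads 530 Pa, with clamping to
[400, 530] Pa (so the all-ones initial state also reads the 400 Pa
baseline). Anchoring at the zero-dose response rather than the initial
state removes a spurious ~70 Pa offset caused by the unstimulated
network's own t = 0 transient.

**MIC adhesion/survival network.** The local niche stiffness (input,
normalized by the 530 Pa ceiling) activates FAK; FAK feeds Rac and PI3K;
PI3K feeds Rac and AKT; Rac drives JNK→cJUN→`Adhesion` and, with AKT,
NFKB→`Survival` (9 states, 11 edges). `Survival` additionally carries a
BTZ inhibition term `−K_BTZ·D1/(H_BTZ+D1)` with `D1` the BTZ dose in nM.
Both readouts are used as probabilities and are clamped to [0, 1]; the
inhibition term is the only way a state can go negative, and states are
clamped at 0 during integration. Total adhesion is the stiffness-driven
readout plus a constant 0.20 floor — all non-stiffness contributions to
adhesion are lumped into one additive constant assumed equal across
conditions.

The naming of the small GTPase differs between the two diagrams (RhoA in
the stromal network, Rac in the MIC network); both are implemented
exactly as drawn per network.

## 2. Calibration

### 2.1 Synthetic phospho-proteomics

The original calibration tables are not available, so the package ships
a generator that emulates their structure: integrate a network from the
all-ones state under a constant condition, sample the assay's time grid,
multiply by median-1 log-normal noise (default CV 0.05, a typical
technical replicate spread for array-based phospho-assays), and force
t = 0 entries to exactly 1. Default conditions:

* stromal network — MEK, FAK, RhoA, ERK, MYL2 plus the stiffness readout
  at 0/5/10/15/60 min, as a **pair** of tables: saturating SDF-1 and an
  unstimulated control;
* MIC network — FAK, PI3K, AKT, JNK, cJUN, NFKB at 0/0.5/1 h and
  Adhesion/Survival at 24/96 h, as a pair of tables on 400 Pa and 100 Pa
  surfaces (the two-stiffness design of the underlying assay).

The two-condition design is essential, not cosmetic: with a single
condition the fit is blind to input sensitivity and to the decay rates
(deeply saturated Hills and frozen nodes reproduce a lone stimulated
time course equally well), and the fitted network then has no dose
response for the lattice model to use. The ground-truth constants
(`habm.datasets`) put steady fold-changes at 1.8–2.5 and response times
at 10–30 min for signaling nodes, with slow day-scale readout decays
(0.08 and 0.03 h⁻¹) — the ranges the assays' grids were designed to
resolve.

### 2.2 GA fit

Parameters are fitted by minimizing the summed absolute deviation
between measured and simulated fold-changes over all observed
(species, time, condition) points. The optimizer is a seeded genetic
algorithm in log10 parameter space — tournament selection (k = 3),
BLX-0.5 blend crossover, Gaussian mutation annealed from 0.2 to 0.01
log-units, elitism — followed by a projected Levenberg–Marquardt polish
of the best distinct individuals (finite-difference Jacobians evaluated
in one batched integration per iteration). Defaults: population 100,
300 generations for library use; the shipped assets used population 100,
150 generations, seeds 12345 (stromal) and 54321 (MIC).

Search bounds are part of the model: k ∈ [10⁻³, 10²] h⁻¹,
H ∈ [0.2, 10] fold-change units, d ∈ [0.5, 20] h⁻¹ for signaling nodes
and [0.005, 1] h⁻¹ for the slow Adhesion/Survival readouts.
Half-saturations far below the observable fold-change range and decays
far outside the assay's response band are observationally
indistinguishable from saturated/frozen kinetics yet destroy the dose
response, so they are excluded a priori. The networks remain
over-parameterized relative to the data; the contract of the fit is
*output-trajectory* equivalence (≤5% at observed points on noiseless
data), not parameter recovery.

After the fit, the input-edge half-saturations are re-pinned to
structural values (the saturating reference sits at ~2/3 of input-edge
saturation) with the paired rate constants rescaled so the fitted
operating-point production — and hence every fitted trajectory — is
preserved exactly. Input sensitivity is not identifiable from data
measured at fixed input levels, so it is fixed by convention rather than
estimated.

### 2.3 Anchor solving

Three constants are solved exactly against quantitative in-vitro
anchors after the trajectory fit:

* the relative-dose equivalent of 5 nM SDF-1 — 1D root solve so the
  stromal response reads 526 Pa (shipped value 0.679);
* the Adhesion production rate `k10` — `Adhesion(24 h)` is affine in
  `k10`, so two evaluations give the rescale that puts the
  stiffness-driven component at 0.47 on a 400 Pa niche;
* the BTZ inhibition strength `K_BTZ` (with `H_BTZ` = 1.5 nM, the
  observed turning point of BTZ killing) — 1D root solve so 5 nM BTZ
  over 144 h reduces survival by exactly 89.2% relative to the untreated
  control.

The shipped JSON assets (`src/habm/params/*_ode.json`) carry the fitted
constants, the stiffness-map anchors, the dose mapping and calibration
metadata; `scripts/calibrate_params.py` reproduces them bit for bit.

## 3. Tissue scale

The domain is a 50×50×50 lattice (one ~cell diameter per site) with an
inscribed cylindrical mask of valid agent sites — a rectangular frame
with a cylindrical marrow lumen. SDF-1 (secreted by MICs) and TGFβ
(secreted by stromal cells, Thal-attenuated, and by MM cells) diffuse by
an explicit 7-point stencil with Dirichlet value 0 on the outer shell (a
sink-like marrow edge); both fields start uniform at the boundary value.
D = 1.0 site²/h for both cytokines, giving a ~3.5-site diffusion length
per 2-h step — cytokine length scales are calibration-degenerate with
secretion rates here, so D is fixed and the secretion rates (0.15/h per
MIC for SDF-1; 0.15/h per BMSC and 0.08/h per MM for TGFβ) are chosen so
local field levels near an established tumor are O(0.1–1), the range the
Hill constants of the immune rules operate on. Stability requires
D·dt ≤ 1/6, i.e. 12 substeps per 2-h step. Drugs are spatially uniform
step functions: full dose for `start ≤ t < start+144 h`, zero outside
(no pharmacokinetics).

Fields are frozen within each 2-h step and the signaling ODEs read the
step-start values — a quasi-steady separation of the minutes-scale
signaling from the hours-scale cell behavior. Stromal stiffness per
step is the 60-min ODE response to the current local (Thal-attenuated)
SDF-1 level, evaluated through a precomputed dose→Pa curve; the
stiffness sensed at any site is that of the nearest Moore-adjacent
stromal cell, or the 100 Pa soft-ECM floor away from the scaffold.

## 4. Cell agents and stochastic rules

Five compartments: static stromal cells on a spacing-4 sub-lattice
inside the mask, and four mobile kinds — MIC, MM, CD8⁺ CTL, Treg — with
at most one mobile agent per site. Every behavior follows die casting:
a probability from the local environment, then a uniform draw. Each
2-h step processes agents in a freshly shuffled order (removing
grid-scan bias); all randomness flows through one per-replicate
`numpy.random.Generator`, so runs are bit-reproducible.

Per-agent, per-step, in order: (1) stochastic death — MICs convert
their survival-ODE readout S (a 144-h surviving fraction at their local
stiffness and the current BTZ dose) to a per-step hazard
`1 − S^(dt/144)`; MMs use a baseline plus a BTZ Hill kill term; immune
cells use baseline rates. (2) Contact interactions — a CTL picks one
Moore-adjacent tumor cell, preferring stroma-unattached targets, and
kills with probability 0.08, reduced 0.3× for attached targets; a Treg
suppresses an adjacent CTL with probability 0.015, choosing cycle arrest
(80%) or apoptosis (20%) by a second roll. (3) Cell cycle — on
completing its cycle (24 h tumor, 12 h immune) an agent rolls its
division probability; MIC division and self-renewal probabilities are
stiffness-driven Hills, MM division is stiffness-driven with a passage
limit (LGN = 5; an MM at the limit dies at its next division attempt),
CTL proliferation is the baseline Hill reduced by TGFβ (with a floor —
saturating TGFβ leaves 18% of the uninhibited probability) and by the
global Treg count, plus a saturating LEN boost; Treg proliferation is
TGFβ-driven and LEN-suppressed. A committed divider places its daughter
uniformly at random on a free Moore neighbor; with none free it stays in
M-phase and retries (divisions defer, never abort). An MIC fate draw
sends both daughters to MIC (self-renewal) or both to MM
(differentiation). An arrested CTL consumes its proliferation
opportunity instead. (4) Migration — MIC up the stiffness field
(attached MICs stay put), CTL toward the nearest tumor cell within a
5-site radius, Treg toward the nearest CTL, MM random walk; blocked
moves stay. (5) An unattached MIC on a stiff site adheres with its
adhesion-ODE probability.

Initial state: 100 MIC, 100 MM, 20 CTL, 5 Treg scattered uniformly over
the smallest central sphere that holds them at one per site, with
cell-cycle phases desynchronized uniformly.

Bookkeeping is exact: per-step event counts (birth, death, lysis,
differentiation) satisfy `Δcount = births − deaths − lyses −
conversions` for every kind at every step, and the suite asserts this.

## 5. Lattice calibration

The ODE anchors fix the intracellular scale; the free lattice constants
(`habm.agents.AbmParams` defaults) were tuned, in order, against the
population-level anchors, holding everything previously set:

1. **MIC expansion** — self-renewal ceiling `sr_pmax = 0.691` puts the
   replicate-mean 4-week immune-free MIC fold-expansion at ≈5.98.
   The expected per-cycle factor is `1 − p_div + 2·p_div·p_sr`, but
   crowding, adhesion kinetics and the SDF-1→stiffness feedback make the
   realized growth emergent, so the constant is set by simulation.
2. **Immune homeostasis** — CTL rates are set so the untreated CTL pool
   expands modestly and never runs away or goes extinct. Two design
   points matter: the TGFβ inhibition floor prevents the
   tumor-grows→TGFβ-rises→CTL-extinct collapse, and weak per-contact
   lysis (0.08) prevents the mirror-image CTL-wins→tumor-extinct→
   CTL-explosion runaway. Treg suppression is kept mild (0.015/contact,
   80% arrest) because Tregs chase CTLs persistently, so even small
   per-contact kill probabilities are demographically strong.
3. **BTZ kill** — the MM BTZ Hill amplitude (0.076, H = 1.5 nM,
   n = 1.5) puts the 48-h myeloma reduction under 1.5 nM BTZ at ≈49.5%
   (the MIC arm of the kill comes from the survival ODE with no free
   constant).
4. **LEN response** — amplitude 0.0378 and H = 2.0 µM put the CTL
   increases under 5/10 µM LEN at ≈38.4%/46.4%. The CD8 comparison is
   evaluated at the end of the 144-h treatment window: the increase is
   established during treatment and its expectation is preserved
   afterwards, while multiplicative demographic noise keeps compounding,
   so the treatment horizon is where the drug effect is defined and
   measured. Treated and control arms always share matched replicate
   seeds.

Thalidomide needs no separate anchor: it attenuates the SDF-1 input to
the stiffness ODE and stromal TGFβ secretion through one Hill constant
(H = 2 µM), and its effect on tumor growth emerges through the stiffness
feedback.

## 6. Sensitivity, uncertainty, synergy

*Local sensitivity* perturbs one constant at a time by ±10% (both
signs, max-abs relative readout change at the final time); parameters
with no directed path to a readout report exactly zero.

*Uncertainty analysis* scales every (k, H, d) independently by
Uniform(1−r, 1+r) with r = 0.05, integrates from the all-ones state, and
reports final-time readout means/SDs normalized by baseline (stromal:
stiffness at 60 min; MIC: adhesion and survival at 96 h, worst of the
two). At 5000 samples the mean deviations are ≈0.01% (stromal) and
≈0.14% (MIC) — far inside the 4%/5% stability bands, as expected for
smooth responses under ±5% zero-mean perturbations.

*Synergy.* Drug levels are an 11-point grid per drug (0, then 0.1×–1.0×
of 5 nM BTZ / 10 µM LEN / 10 µM Thal; 1331 conditions in full
factorial). For level triple (i, j, k), D is the replicate-mean myeloma
(MIC+MM) count relative to the shared zero-dose control at the end of
treatment (144 h), clamped to [0, 1], and

    C = (Di·Djk + Dj·Dik + Dk·Dij − 2·Di·Dj·Dk) / Dijk,

synergistic above 1, antagonistic below, additive within |C−1| ≤ 0.02;
multiplicative independence gives C = 1 identically, and a complete
triple kill (D = 0) returns the maximal-synergy sentinel `inf` rather
than a number. The full 11³ factorial at 200 replicates is
cluster-scale; desk-scale work uses a 4-level sub-grid at ~20
replicates, on which the suite checks symmetry, monotone single-drug
response and the zero-dose identity.

## 7. Numerical choices

* Single-trajectory ODE integration: LSODA, rtol 10⁻⁶ / atol 10⁻⁹
  (rate constants can spread widely after fitting).
* Population/ensemble integration (GA, sensitivity, uncertainty, lookup
  tables): a second-order exponential predictor–corrector — decay
  handled exactly per node, production frozen then trapezoidally
  averaged — unconditionally stable in d, fine 0.02-h steps through the
  2-h transient and 0.5-h steps after; agrees with LSODA to ~2·10⁻⁴
  relative.
* The lattice engine couples the ODEs through lookup tables built once
  per run (stiffness dose→Pa curve; stiffness→survival at the run's BTZ
  dose; stiffness→adhesion), linearly interpolated.
* Explicit diffusion obeys D·dt ≤ 1/6 with automatic substepping; the
  hot loops (diffusion, agent phase) are numba-compiled, and all
  stochastic kernels consume one seeded Generator, so every run is
  bit-reproducible end to end.
* Replicate seeds derive from `SeedSequence([master, index])`; treated
  and control arms reuse the same list (matched experiments).

## 8. Problem sizes

Defaults are desk-scale on one CPU: the validation suite uses 50
replicates for the 4-week expansion, 60 for the 48-h BTZ response, 250
per arm for the LEN comparison (three matched arms), and 5000 parameter
draws per network for the uncertainty analysis. A full 600-h replicate
on the default 50³ domain takes ~1.3 s after JIT warm-up; the complete
validation suite re-runs in ~5 minutes. The 200-replicate, 1331-
condition synergy factorial from the original study design remains
available through `habm sweep --levels 11 --replicates 200`.

## 9. What the synthetic data do and do not show

The generator reproduces the *structure* of the calibration assays
(fold-change normalization, time grids, multiplicative noise,
two-condition contrasts) from a plausible ground truth — it does not
reproduce their measured values, which are unavailable. Consequently the
pipeline demonstrates that calibration *recovers generating dynamics
from data of this shape* (the noiseless-recovery test) and that the
calibrated system reproduces the published population-level anchors; it
does not validate the parameter values against real myeloma biology.
Other known limitations: drugs have no pharmacokinetics; CTL killing has
no exhaustion or per-cell budget; the stem-cell hierarchy is the
simplified two-stage MIC→MM process; stromal cells neither move nor
die; and the immune repertoire contains no NK cells, macrophages or
dendritic cells.
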