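# Methods

`emphysim` couples an immunological model of smoke-induced inflammation to a
biomechanical model of alveolar tissue, to simulate the onset and progression
of emphysema and its appearance in CT images. This note records the model,
its assumptions, the parameters that matter, and the numerical and design
choices made where the underlying biology leaves the implementation open.

## Kinetic model of inflammation and remodeling (`wm_model`)

The core is a well-mixed system of thirteen coupled nonlinear ODEs plus two
algebraic response curves. State variables: undifferentiated monocytes
`Mun`, pro-inflammatory `M1` and anti-inflammatory `M2` macrophages (cells);
cytokines IL-10, TNF-α, IL-1, TGF-β, IL-8 (pg/ml); fibroblasts `F` (cells);
collagen `C` (µg); MMP and elastase (pg/ml); neutrophils `N` (cells). The
interactions:

- Monocyte recruitment is an empirical cubic in TNF-α,
  `M(Tα) = 0.335·Tα³ − 6.309·Tα² + 32.281·Tα + 57.302` cells/day. At rest
  (`Tα = 0`) recruitment balances emigration `µ = 0.2/day`, so the baseline
  pool is `M(0)/µ = 286.51` cells — used as the default initial condition.
- Activation of `Mun` into `M1` (by IL-1, TNF-α) and `M2` (by IL-10) uses
  cooperative Hill terms `x/(x+c)`; `M1 ↔ M2` interconversion uses first-order
  rates `km12`, `km21`.
- Secretion: `M2` produces IL-10 (self-inhibited with constant `c1 =
  100 pg/ml`), TGF-β and IL-8 (self-inhibited with `c2`); `M1` produces
  TNF-α and IL-1 (both inhibited by IL-10 with constant `c = 25 pg/ml`) and
  MMP. `c` and `c1` are deliberately independent config entries; setting
  `c = c1` recovers the variant in which one constant serves both roles.
- Fibroblasts proliferate with the cubic TGF-β growth factor
  `Fg(Tβ) = 0.05·Tβ³ − 0.98·Tβ² + 6.54·Tβ + 7.11` times `k10 = 0.924/day`,
  and die at `dF = 0.12/day`. Because `k10·Fg(Tβ) > dF` already at `Tβ = 0`,
  fibroblast growth is exponential as written; the model is used in regimes
  where `F` starts at zero (no growth) or runs are short. This instability
  is inherent to the printed growth law and is guarded by an overflow check
  (any component above 1e12 aborts with a diagnostic).
- Matrix turnover: `Ċ = k11·F − dFC·MMP·C`; MMP is produced by `M1`,
  consumed by cleavage and decays at `dM`. Neutrophils are recruited by
  IL-8 up to a carrying capacity `Nmax` and secrete elastase.

Defaults are the literature values of the model's parameter table.
Constants the table leaves blank are estimated and flagged in
`ImmuneParams.ESTIMATED`: neutrophil emigration `muN = 0.2/day` (mirror of
µ), IL-8 decay `dIL8 = 2.5/day` (mirror of IL-10), `c2 = 100 pg/ml`,
`Nmax = 1000` cells, elastase decay `dE = 1/day`, cleavage coefficient
`dFC = 1e-3 ml/pg/day`, and the neutrophil recruitment magnitude
`k14rate = 10 cells/day` (the tabulated 8 pg/ml is the IL-8 half-saturation
`cIL8`). The tabulated 0.12/day labeled as fibroblast apoptosis is used as
`dF`; the MMP·C cleavage coefficient is the separate `dFC`.

Integration uses an adaptive stiff-capable scheme (LSODA) by default — the
TNF-α decay (55/day) and fibroblast growth terms are fast relative to the
rest — with a fixed-step explicit Euler available for lock-step consistency
with the agent layer. Components nudged below zero by discretization are
clamped to zero and the clamp count is reported on the trajectory.

## Agent-based spatial layer (`abm`)

Each cell of a rows × cols grid is a small portion of an alveolar unit
carrying tissue life ∈ [0, 1], normalized elastin `cel` and collagen `ccl`
content, deposited particles, and local concentrations of the seven
diffusible species. Discrete agents (monocytes, M1/M2, neutrophils,
fibroblasts) move and act on cells using the kinetic rates above; each grid
cell is treated as a unit well-mixed volume, so pg/cell/day secretion adds
pg/ml/day per resident agent.

A periodic square-wave smoking signal (default period 10 steps, duty 0.5)
deposits `e_s` particles per active step at uniformly random cells for `T_s`
steps, then the simulation runs `post_steps = 20` more to re-equilibrate.

One step (`dt = 0.1` day) applies, in fixed order: particle TNF-α emission;
agent secretion; 4-neighbor mass-conserving diffusion (coefficient `D`
cell²/step, zero-flux borders, `D ≤ 0.25` for stability); concentration
decay; monocyte influx (expected count `M(mean Tα)·dt·influx_scale·n_alive`,
Poisson-sampled, uniform over alive cells); agent random walk with a one-step
climb up the TNF-α gradient where `Tα > cTα`; differentiation, transition
and emigration as Bernoulli events with `p = rate·dt`; neutrophil
recruitment and fibroblast seeding; phagocytosis (a co-located macrophage
removes one particle with probability `p_clear`); matrix turnover (`ccl =
min(C/C0, 1)` with `C0 = 100 µg`, elastin decay `ċel = −k_eldeg·El·cel`,
`k_eldeg = 0.05 ml/pg/day`, no resynthesis); DAMPS damage; and TGF-β
secretion by damaged tissue at `λ·(1 − life)`. All randomness flows from one
seeded generator and agents iterate in stable order, so runs are
bit-reproducible. A dead cell (life = 0) never recovers.

The DAMPS rule reduces tissue life proportionally to the local
pro-inflammatory level, quantified as the mean of the IL-1 and TNF-α Hill
activations, scaled by `k_damps` (per day).

Numerical choices specific to this layer:

- Decay is applied as the exact factor `exp(−d·dt)`: the TNF-α rate gives
  `d·dt = 5.5`, for which the linear factor `1 − d·dt` would be negative.
- The cubic recruitment curve is only meaningful over roughly 0–10 pg/ml of
  TNF-α and grows without bound beyond; the value fed to it is clamped at
  `ta_influx_cap = 10 pg/ml` (configurable, `inf` disables).
- In `deterministic_mode` all draws are replaced by fractional
  expected-value updates on per-cell population counts, agents do not move,
  and the local kinetics advance by one explicit-Euler step evaluated at the
  start-of-step state. On a 1 × 1 grid with diffusion and DAMPS off this
  reproduces the well-mixed Euler trajectory exactly (a regression oracle in
  the test suite). Deterministic mode is intended for small `dt`, where the
  pure Euler decay is stable.

### Calibration of the free damage constants

The strength of the inflammatory response to a deposited particle is not
fixed by the underlying biology; the package calibrates it once so that the
documented qualitative behavior holds: zero exposure leaves tissue exactly
intact for any horizon, while *every* nonzero exposure of the studied design
grid (5–20 particles, 10–90 smoking steps) destroys at least half of the
tissue. The binding scenario is the weakest corner (5 particles for 10
steps: 25 particles on 130 cells for 30 steps). Because TNF-α decays by
`exp(−5.5)` within one step, a particle must act as a strong local source for
its cell and its diffusion halo to accumulate lethal damage in that window.
The calibrated defaults are `s_p = 1e6` pg/ml per particle per step (a
pre-decay bolus equivalent to a sustained ≈ 4 × 10³ pg/ml at the source,
saturating the Hill response two rings outward), `k_damps = 3.0/day`,
`p_clear = 0.02` and `D = 0.2`. With these, the worst-case residual tissue
life across the design grid is 30–40 % over many seeds, and the
zero-exposure column is exactly 100 %. These four constants form one
calibration set; they were not revisited afterwards.

## Plane-stress mechanics (`mechanics`)

The alveolar grid maps one-to-one onto a structured mesh of square bilinear
quadrilaterals (Q4). Tissue is linear elastic, isotropic, in plane stress
(thin-section assumption) with global Poisson ratio ν = 0.3 (configurable).
The element modulus mixes the phases linearly:

    E_tissue = 0.7·cel·E_el + 0.3·ccl·E_cl,  E_el = 0.1 kPa, E_cl = 20 kPa,

so fully healthy tissue is 6070 Pa and stiffness is collagen-dominated. A
dead cell keeps its elements (fixed topology) at E = 1 Pa; a still-alive
cell whose matrix is fully depleted is floored at the same 1 Pa.

Breathing is displacement-controlled: boundary nodes carry the displacement
field of a uniform strain `eps_app` (default 0.05, tidal-breathing order of
magnitude; biaxial by default, uniaxial variants available). The underlying
study does not report its boundary conditions, ν, or strain measure; all
three are exposed as configuration with these defaults. Because every
element is the same square, the global stiffness is a modulus-weighted
scatter of a single unit element matrix; the reduced system is solved
sparsely with a relative-residual check at 1e-8, and an independently coded
dense isoparametric assembly serves as the test oracle.

Rupture compares the maximum principal strain at the element centroid with
a composition-weighted tensile limit, the normalized linear blend of the
elastin (100 %) and collagen (10 %) endpoints:
`limit = (cel·1.0 + ccl·0.1)/(cel + ccl)`. A cell with no matrix gets the
conservative collagen limit. Healthy tissue (limit 0.55) never ruptures at
5 % breathing strain; rupture requires prior elastin depletion and/or strain
concentration around destroyed regions.

## Coupling (`coupling`)

Every `ab_steps_per_cycle = 10` agent steps (one simulated day) the grid is
frozen. If the damaged fraction has reached `damage_stop_fraction = 0.80`
the mechanical solve is skipped and the run ends; otherwise per-cell content
becomes per-element moduli, the elastic problem is solved, over-strained
cells are killed, and the agent simulation resumes. Exchange is in-memory;
contours of the damaged zone (4-connected components after one binary
closing pass) are extracted for reporting only — the fixed-topology
dead-element treatment makes adaptive remeshing unnecessary. Damaged
fraction is non-decreasing across cycles by construction.

Note that softening an element never decreases *that element's* strain under
displacement control (verified over randomized instances), but it can relieve
the global peak elsewhere; weakest-link reasoning in this model is local.

## Imaging layer (`imaging`)

Parenchyma is segmented from a square HU patch with a fixed −750 HU
threshold (air-rich side). With the stereological mean of 170 alveoli/mm³
and 0.78 × 0.78 × 1.25 mm voxels, one voxel holds ≈ 130 alveoli (rounded to
the nearest ten), simulated as the most-square 13 × 10 grid. Random
parenchyma pixels plus their in-mask 4-neighbors are "affected"; each runs
one coupled job, and its final mean element modulus `Ē` is translated
linearly back to HU anchored at the healthy modulus and at air:
`HU = −1000 + (HU_orig + 1000)·(Ē/6070)`, clipped to `[−1000, HU_orig]`.
The remap is monotone and never brightens a pixel, so simulated progression
can only lower the Mean Lung Density (mean HU over the parenchyma mask —
computed on the baseline mask for before/after comparability).

The synthetic patch generator stands in for clinical CT data: 61 × 61
Gaussian-textured parenchyma (−820 ± 40 HU) with sparse bright vessel
streaks, plus 5 (moderate) or 15 (severe) low-attenuation disk clusters near
−960 HU with radii 2–4 / 3–8 px. It reproduces the qualitative signatures
the pipeline needs — a segmentable parenchyma mask, MLD decreasing with
severity class, seeded reproducibility — but none of the texture statistics,
spatial correlation, scanner noise or anatomy of real HRCT. Tests passing on
these patches therefore demonstrate the mechanics of the pipeline and the
direction of its effects, not clinical accuracy.

## Packaged experiments and problem sizes (`experiments`)

- *Exposure grid*: exposures {0, 5, 10, 15, 20} × smoking times
  {10, 30, 50, 70, 90} (five evenly spaced levels per axis across the
  studied ranges, 25 design points), each run on a 13 × 10 grid with 3
  seeds and 20 equilibration steps. Residual tissue life is reported in %
  of initial; the zero-exposure column is exactly 100 % and all nonzero
  runs fall at or below 50 %.
- *Parameter screen*: the 16-row two-level fractional factorial (2^(6−2))
  over (k8, dIL10, k12, k13, dF, dM), re-running the medium scenario
  (10 particles, 50 steps) with identical seeds so differences isolate the
  constants. The variability statistic is the SD of mean tissue life across
  the 16 runs at each step, averaged over steps. At this scale it is
  essentially zero: damage is dominated by particle-driven TNF-α and DAMPS,
  and the screened secretion/decay constants act on pathways (fibrosis,
  neutrophils, MMP) that are nearly inert with so few agents. The screen
  thus shows the damage trajectory is insensitive to these constants, in
  keeping with the bounded-variability property it is tested against.
- *MLD progression*: 20 synthetic healthy patches, 20 seed pixels per patch
  (≈ 100 affected voxels), one coupled job per affected voxel. The shift is
  a few HU with Welch p far below 0.05; the magnitude scales with the
  affected fraction and is smaller than clinical cohort shifts, which would
  require database-scale seeding (200 seeds/patch over 69 patches).

These problem sizes are the package defaults, chosen to make the full suite
a desk-scale computation; all are parameters of the experiment functions.

## Known limitations

- 2D only; no airway/vessel structures inside a job's grid; no 3D
  connectivity.
- The fibroblast/fibrosis arm is nearly inactive at the default agent
  densities (the TGF-β secretion rate of damaged tissue, 5e-6 pg/cell/day,
  is far below the seeding threshold), so collagen-thickening phenotypes
  are not explored.
- The printed fibroblast growth law is exponential; long runs with `F > 0`
  require care (overflow guard, stiff integrator).
- Rupture cascades are rare under the default 5 % breathing strain; most
  destruction is DAMPS-driven, with mechanics contributing strain
  concentration around already-damaged regions.
- The HU remap anchors and the synthetic-patch parameters are package
  choices, not fitted to clinical data.
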