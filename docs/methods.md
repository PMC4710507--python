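# Methods

## Model

`gliotrial` simulates glioblastoma growth and invasion on a 2-D brain grid
at clinical-MRI resolution (1.5 mm voxels, 2.25 mm² each) with four
concentration fields: proliferative tumour cells `P`, invasive tumour cells
`I`, healthy brain `B`, and necrotic debris `N` (dimensionless, healthy
brain ≡ 1).  The dynamics implement the go-or-grow dichotomy: `P` divides
but does not move; `I` moves but does not divide; hypoxia converts `P → I`
(rate `α H`) and normoxia converts back (rate `β (1 − H)`).

```
∂t P = M P − α H P + β (1 − H) I − γF P
∂t I = δ ∇·(D ∇I) − η ∇·(I ∇B) + α H P − β (1 − H) I − γF I
∂t B = −γF B
∂t N = +γF (P + I + B)
```

with closures

```
C_liv   = P + I + B                      living concentration
C_hyp   = σ ln(1 + P + I) + Ω            hypoxic threshold (angiogenesis)
C_ltm   = C_hyp + Φ                      necrotic threshold
H       = (1 − tanh(k (C_hyp − C_liv)))/2
M       = τ (1 − H) · [P + I ≥ u_min]    mitosis, clonogenic-floor gated
γF      = γ (P+I)(1/100 + 1/(B+0.01)) (1 − tanh(k (C_ltm − C_liv)))/2
```

Defaults: α = 2.02/hr, β = 2.00/hr, τ = 0.35/hr, γ = 0.17/hr, Ω = 1.1,
σ = 1.5 (0 under anti-angiogenic treatment), Φ = 0.10, k = 40,
δ ∈ [8·10⁻⁷, 4·10⁻³] mm²/hr and η ∈ [1.4·10⁻⁴, 1.4·10⁻³] mm/hr spanning the
motility phenotypes, u_min = 0.045.

Invasive motility has two mechanisms.  Concentration-driven motility is
passive diffusion `δ ∇·(D ∇I)`; the diffusion-support field `D` (1.0 in
brain) collapses to ~0 where ≥80 % of the brain is dead, so cells cannot
re-enter the necrotic core.  Hypoxia-driven motility `−η ∇·(I ∇B)` is
active transport up the healthy-brain gradient — away from necrosis,
towards oxygenated tissue — and produces the characteristic sharp
accumulation of invasive cells at the hypoxic rim.  That spike raises the
local living concentration past `C_ltm`, necrosis advances, a new brain
gradient forms, and the invasion–necrosis feedback loop propagates: this
is the engine of the Expanding Necrosis phenotype, and its speed scales
with η.  High diffusion drains the rim spike below the necrotic threshold,
which is why strongly dispersive tumours progress by expanding FLAIR
rather than expanding necrosis.

### Design choices in the closures

Four closure choices were genuinely open, and each was resolved by
requiring the model to be able to display the phenomenology it exists to
study (standing contrast-enhancing masses, phenotype-dependent progression
patterns, month-scale survival).  All four are exposed as `ModelParams`
options so the alternatives can be simulated:

* **Switches read the living concentration** (`switch_concentration`,
  default `"living"`).  Necrotic debris consumes no oxygen, so the hypoxia
  and necrosis switches compare `P + I + B` with the thresholds.  If the
  inert compartment is counted (`"total"`), the reaction-term identity
  `dC/dt = M P ≥ 0` makes total concentration a ratchet: every
  tumour-bearing voxel eventually crosses the necrotic threshold on the
  reaction timescale (~1 day), and the whole brain necroses behind a
  reaction-speed burn wave for every phenotype.

* **Angiogenesis is driven by total tumour burden** (`angiogenic_drive`,
  default `"total"`).  Both compartments are viable tumour secreting
  angiogenic factors.  If only `P` drives the threshold (`"P"`), the
  hypoxic P→I conversion depletes the drive, the threshold collapses from
  under the mass, and no dense focus can persist longer than ~1 day —
  incompatible with contrast-enhancing masses that grow over months.

* **The necrosis rate scales with tumour burden**
  (`necrosis_multiplier`, default `"burden_scaled"`):
  `γF ∝ (P+I)(1/100 + 1/(B+0.01))`.  Dense cores (burden ~1.5) necrose on
  the week scale; sparse infiltration (burden ~0.1) erodes the brain an
  order of magnitude more slowly; tumour-free tissue never necroses; the
  `1/(B+0.01)` factor still extinguishes every population inside the
  necrotic core, and the growth of `γF` with burden caps the total mass.
  The additive alternative `(P+I)/100 + 1/(B+0.01)` is density-independent
  near healthy tissue, which puts hypoxia-stalled FLAIR-density tissue on
  the same necrosis clock as dense cores and turns every treated run into
  whole-brain necrosis.

* **A clonogenic floor gates mitosis** (`growth_floor`, default 0.045
  ≈ 4.5 % of normal cell density).  Below the floor, cells are present
  (they move, convert, and count towards imaging) but too sparse to found
  a growing colony at voxel scale.  Without a floor, exponential growth
  amplifies arbitrarily small diffusive leakage, so invasion fronts travel
  at a nearly δ-independent lattice speed (the continuum front width
  √(δ/τ) ≲ 0.1 mm is unresolvable on any affordable grid) and the
  concentration-driven motility phenotypes collapse onto each other.  With
  the floor, the time to seed the next voxel is ∝ u_min h²/(δ u), restoring
  the δ-scaling of invasion speed.  The value 0.045 was calibrated once so
  that the four progression phenotypes and the treated-arm survival
  ordering are reproduced at the reduced grid scale, and then frozen.

`N` is pure bookkeeping (necrotic mass accumulates; imaging reads brain
death from `B/B0`).  The logarithm in the angiogenic term is natural; with
a decimal log the angiogenic equilibrium caps tumour burden at ~0.27 and
the high-density imaging class (>0.7) would never occur.

## Numerics

Forward Euler with a 5-point Laplacian (harmonic-mean face diffusivity) and
donor-cell upwind advection, both in flux form with fluxes zeroed on faces
leaving the brain mask (impermeable skull), so invasive-cell mass is
conserved exactly and, with τ = 0, total mass is conserved to round-off.
The time step is `safety · min(h²/(4δ max D), h²/(η max B0), 1/(α+β+100γ))`
with safety 0.5 (≈ 0.024 h at the default rates — the reaction bound
dominates).  Negative round-off values are clipped to zero and accounted;
a run aborts if clipped mass exceeds 10⁻⁶ of the total.

The production path is a fused numba kernel with an active-bounding-box
optimisation: voxels the tumour has never touched all share a single
background (B, N) value (they follow an identical pointwise update
sequence), which is integrated as two scalars and stamped back on exit.
The box grows one ring ahead of the invasive front each step, so this is
exact — the test suite asserts agreement with the plain NumPy operator
composition to 10⁻¹² after hundreds of steps.

## Virtual MRI

Per voxel, with precedence top to bottom:

* **necrosis** — `B/B0 < 0.2` (≥80 % brain death);
* **high-density tumour** ("Gad" proxy) — `P + I > 0.7`;
* **FLAIR** — `0.05 ≤ P + I ≤ 0.7` (bounds inclusive).

Areas are percent of brain-mask voxels.  Serial summaries (pre-treatment,
first follow-up two months after treatment, death) are mapped to
progression-pattern labels from the direction of change of FLAIR and
necrosis, judged by relative change against a 25 % band (the same fraction
that defines an initial gadolinium response; the stability band is not
otherwise quantified in the clinical criteria and is configurable).

## Trials

A virtual patient is one simulation.  Heterogeneity comes from titrating
the trigger and death criteria across their design windows (evenly spaced
grids, seed-shuffled pairing).  Treatment (or diagnosis, for controls)
fires at the first 12-hour cadence point where the trigger criterion is
crossed; anti-angiogenesis sets σ = 0; rate- and motility-reducing agents
scale τ (uniformly or per voxel) and η.  Death is the first crossing of
the death criterion; overall survival is (death − treatment)/730 h months.
Runs are censored at the follow-up horizon (12 000 h ≈ 16 months for the
bundled reduced trial; 5 years for open-ended runs) and enter the
Kaplan-Meier analysis as censored.  Patients within an arm share the
pre-trigger course, which is simulated once and resumed per patient
(exactly equivalent, because the kernel is chunking-invariant).

The bundled four-group design: treated highly-dispersive
(δ = 4·10⁻³ mm²/hr; trigger tumour 2.0–2.8 % of brain; death FLAIR
55–88 %), treated moderately-dispersive (8·10⁻⁵; tumour 2.0–2.8 %; death
necrosis 3.5–4.4 %), treated hypoxia-driven (8·10⁻⁷; trigger necrosis
0.09–0.32 %; death necrosis 3.5–4.4 %), and untreated controls pooling all
three phenotypes (death: tumour 10–18 % for the dispersive phenotype,
necrosis ~3.5–4.4 % for the others); η = 1.4·10⁻³ mm/hr everywhere.

## Reduced scale and what it does (not) show

Reference cohorts in the full-scale design use a 112×83 head-slice grid.
The bundled reproductions run a synthetic ~1 000–1 600-voxel brain (48×36
for trials, 60×45 for phenotype curves); the acceptance script runs the
full cohort sizes (30/25/25 treated + 75 pooled controls) on the 48×36
reference anatomy in ~10 minutes on one CPU, while the test suite uses 12
patients per arm.  Shrinking the brain compresses all area-percent criteria
onto fewer voxels while wave speeds stay fixed in mm/hr, so absolute
survival times are compressed and arm separations shrink relative to the
full-scale design; the qualitative structure — treated highly-dispersive
tumours surviving longest by slowly expanding FLAIR, necrosis-led death in
the moderately-dispersive and hypoxia-driven phenotypes, indolence of the
low-motility variant, futility of rate reduction in hypoxia-driven
tumours — is preserved and is what the acceptance suite asserts.

Several full-scale features are not reproduced at desk scale (the
corresponding checks are present in the suite and fail, documenting the
gap): the treated moderately-dispersive FLAIR halo is frozen below the
clonogenic floor at δ = 8·10⁻⁵, so the FLAIR–necrosis gap does not grow;
the treated highly-dispersive site's necrosis ring keeps creeping instead
of plateauing in label terms (FLAIR dominance, ≥4× necrosis, still holds);
near-total FLAIR coverage (≥88 %) is unreachable on a small irregular
mask, so the slowest highly-dispersive patients censor at the follow-up
horizon as long-term survivors (a lethal-necrosis guard — death at ≥50 %
brain necrosis — bounds the pathological corner where the FLAIR criterion
can never fire); and hypoxia-driven survival retains a mitotic-rate
dependence (~70 % across τ ∈ [0.05, 0.35]/hr) because the necrosis-ring
advance is partly rate-limited by growth-driven refill of the eroding rim
at this resolution, whereas at full scale it is transport-limited.

The synthetic brain is a seeded, irregular ellipse: connected, one-voxel
margin to the grid border, ~40–75 % grid occupancy, uniform `B0 = 1` and
`D = 1` (optional smooth white-matter ridges of elevated D).  It emulates
domain shape and impermeable boundaries, not anatomy: no ventricles, no
grey/white contrast, no registered tissue labels, so geometry-specific
quantities (e.g. exact percent-of-brain thresholds crossed by an irregular
front) carry a few-voxel quantisation that the titration windows absorb.

## Tumour-treating fields

Electric-field intensity maps (two transducer orientations) are combined
by voxelwise maximum and converted through a cubic dose-response curve
(curve(0) = 1, clamped to [0, 1]) into a per-voxel factor multiplying τ.
The bundled curve is synthetic — monotone decreasing from 1 at 0 V/cm to
~0.1 at 4 V/cm, mirroring the shape of published in-vitro dose-response
data whose numeric points are not bundled; fitted coefficients can be
supplied as configuration.  A uniform factor f is exactly the uniform
rate-reduction intervention with efficacy 1 − f (asserted in the tests).

## Survival statistics

Kaplan-Meier product-limit estimation and the two-group log-rank test are
delegated to `lifelines` (deaths precede censorings at ties; χ² p-value
with 1 df).  An independent brute-force permutation null (label shuffling
over a hand-rolled log-rank statistic) is implemented for cross-checking,
and the suite verifies the χ² p against it and calibrates the type-I error
on equal-hazard simulations.  The efficacy–survival curve is summarised by
a bi-exponential fit `f(x) = a e^{bx} + c e^{dx}` (nonlinear least squares,
log-linear initialisation, multi-start on failure).

## Known limitations

* 2-D only; no anatomy, registration, or tissue segmentation.
* Explicit Euler with first-order upwinding: fronts are diffused over
  ~1–2 voxels; invasion speeds carry lattice corrections that the
  clonogenic floor regularises but does not remove.
* The α, β ≫ τ reaction rates make the phenotype switch effectively
  instantaneous; no attempt is made to resolve sub-hour transients.
* Progression-pattern labels are sharp at desk scale only for the
  highly-dispersive phenotype; the moderately-dispersive and
  hypoxia-driven patterns coincide in label space on small brains (both
  read as necrosis-led) and are distinguished by their motility
  parameters, not their imaging signature.
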