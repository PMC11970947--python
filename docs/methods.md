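# Methods

This note documents the model, the numerical scheme, the default study
conditions and their rationale, and the known limitations of `tumorperf`.

## Physical model

### Two-segment domain

The tumor microenvironment is reduced to two 2D segments that are solved
separately and coupled one-way:

1. **Vessel segment** — a straight channel (default 30 µm × 30 µm) with a
   semicircular depression (depth 2.6 µm, chord 5.2 µm — these printed
   dimensions describe exactly a half-disc) carved into the tumor-facing
   wall. The depression marks the entry location to the tumor extracellular
   space; its chord stays >10× the largest fenestra diameter and its depth
   >8× the fenestra streamwise length, so the whole fenestra would sit well
   inside it.
2. **Tumor segment** — a rectangle (default 6 µm × 6 µm) reached through an
   explicit fenestra channel (width 0.1/0.3/0.5 µm for Models 1–3, length
   0.3 µm) in its top edge, packed with circular fiber cross-sections at
   packing fraction 0.27 (the marker of stromal density/solid stress in
   dense tumors). The whole bottom edge is the outlet sink.

Segregating the segments algorithmically prevents micron-scale blood cells
(RBC 7 µm, WBC 14 µm) from entering the sub-micron fenestra; the only
coupling is the probe relay described below.

### Phases and closures

The vessel stage solves three phases (plasma primary; RBC, WBC secondary),
the tumor stage two (plasma primary, air secondary). Registered properties:

| phase  | ρ (kg/m³) | η (kg/(m·s))       | d (µm)   | shape factor |
|--------|-----------|--------------------|----------|--------------|
| plasma | 1030      | 1e-3               | —        | —            |
| RBC    | 1100      | shear-thinning     | 7        | dynamic      |
| WBC    | 1080      | 1.1e-2             | 14       | 1            |
| air    | 1.225     | 1.7894e-5          | 4.12e-4  | 1            |

The RBC viscosity comes from the hematocrit- and shear-dependent relative
mixture viscosity (Carreau bracket with polynomial a, b coefficients,
τ = 0.11 s, regime switch at γ̇ = 6 s⁻¹) solved explicitly for η_RBC via the
mixture identity. Two guards apply:

- the low-shear coefficient k = ln(ln γ̇)/ln γ̇ is undefined for γ̇ ≤ 1; the
  shear rate inside k is clamped to 1+1e-6 and b is capped at 1 so viscosity
  stays bounded at vanishing shear;
- inside the solver the result is floored at the **plasma** viscosity: at
  extreme corner shear the correlation can thin below the plasma bound
  (negative η_RBC after rearrangement), and a suspension phase thinner than
  its carrier both lacks physical meaning and destabilises outlet corners.
  The public constitutive function exposes the floor as a parameter and
  logs when it engages.

The branch switches at γ̇ = 6 s⁻¹ (a, b) and γ̇ = 300 s⁻¹ (shape factor) are
implemented as printed — discontinuous, no smoothing.

The scalar shear rate is γ̇ = √(2 S:S) with S the strain-rate tensor of the
volume-fraction-weighted mixture velocity.

Interphase drag uses Schiller–Naumann between the primary phase and each
secondary phase (no secondary–secondary drag; virtual mass and lift are
neglected as small against drag). The exchange coefficient is evaluated in
product form, 18·η_cp·Ψ_cp·Ψ_dp·(1+0.15 Re^0.687)/(d_dp²ξ²), so the Stokes
limit C_d·Re → 24 keeps it finite and nonzero as slip → 0. Inside the
solver the fractions entering α are floored at 1e-3 so a locally vanished
phase stays drag-slaved to the carrier instead of developing an
unconstrained ghost velocity; the public function implements the exact
formula (α = 0 at Ψ_dp = 0).

### Boundary conditions

Vessel: velocity-driven inlet (the pulsatile waveform below) with 3325 Pa
as the reference/initial inlet level, pressure outlet 2128 Pa, no-slip
walls and fiber surfaces. The printed inlet specification names both a
pressure inlet and a pulsatile velocity; both cannot bind one boundary, so
when a waveform is supplied the inlet is velocity-driven and the pressure
value only sets the initial level. Outlet backflow volume fractions are
RBC 1, WBC 0 (imposed only where a face velocity points inward; physically
odd but implemented as published). Inlet fractions default to
plasma/RBC/WBC = 0.54/0.45/0.01 (hematocrit mid-range 30–55%; the initial
composition is not printed and is configuration, not a reference value).

Tumor: the probed plasma speed is applied normal to the fenestra entry
(velocity inlet, fractions plasma 1/air 0), air outlet at 2780 Pa (elevated
interstitial pressure), initial state Ψ_air ≡ 1 (the "vacuum" that lets an
uncontaminated perfusion trend be read off as plasma displaces air).

### Pulsatile waveform

u(t) = U₀·(1 + Σₙ aₙcos(2πnt/T) + bₙsin(2πnt/T)), T = 0.735 s (one cardiac
cycle), five harmonics. The coefficients are a packaged fixture chosen to
mimic a cardiac cycle qualitatively (systolic peak ≈ 1.9·U₀, dicrotic
shoulder, u ≥ 0 throughout); users may supply their own CSV.

**Mean speed U₀ = 0.105 m/s.** No amplitude is printed; the default is the
plane-Poiseuille mean speed at which the viscous drop of the blood mixture
across a vessel-scale segment matches the prescribed 3325−2128 Pa
difference, i.e. the speed the printed boundary pressures themselves imply.
This choice also sets the shear regime: at wall shear rates ~10⁴–10⁵ s⁻¹
the mixture correlation thins the RBC viscosity to near the plasma value,
the drag coupling locks the phases (negligible slip), and the constituent
composition stays near the inlet value throughout the run. Slower regimes
were examined and rejected: below ~10³ s⁻¹ the correlation keeps the RBC
phase 5–15× more viscous than plasma, the resulting 10–30% interphase slip
(verified against a 1D two-fluid channel solution) enriches the domain
hematocrit within a few flow-through transits, and the composition leaves
the reported bands.

### Vessel dimensions

Height and length are not printed. Length 30 µm comfortably hosts the
5.2 µm depression with >2 diameters of clearance on each side. Height
30 µm respects the validity bound of the two-fluid drag closure — the
model assumes particles much smaller than the channel, so the height is
kept at about twice the largest suspended particle (WBC, 14 µm); a channel
narrower than its particles would be internally inconsistent.

### Probe relay

The vessel stage records, every time step, the area-weighted mean plasma
pressure and velocity over a probe band at the depression: width = the
largest fenestra diameter (0.5 µm, widened to at least two grid columns),
height = the lower half of the depression (1.3 µm above the floor). The
floor itself is a closed no-slip wall in the segregated vessel — the
fenestra exists only in the tumor segment — so a floor-only probe would
read the cavity stagnation zone (an order of magnitude below the cavity
recirculation) rather than the flow that would feed the fenestra; the half-depth band samples the recirculating
cavity flow that the fenestra entry would drain. Both extents are
configurable.

The tumor stage interpolates the probe linearly in time and applies the
speed as the fenestra inflow; a clearly-labelled steady surrogate mode
(time-averaged probe) exists for fast tests. Tangential components are
dropped at the narrow channel entry.

## Numerical scheme

Uniform staggered (MAC) Cartesian grid; cell (i,j) covers
[i·h,(i+1)·h)×[j·h,(j+1)·h); a one-cell padding ring carries wall and
inlet/outlet cells. A production unstructured mesh is deliberately out of
scope — the uniform grid is fully specifiable and adequate for a
reduced-order reimplementation.

Velocity inlets impose a parabolic (fully developed) profile whose mean
follows the waveform — a plug profile meeting no-slip corners seeds an
entrance singularity. For velocity-driven runs the outlet-adjacent faces
are convective (zero-gradient) outflows, rescaled each step so the mixture
outflow matches the inflow exactly; the pressure projection is then a
pure-Neumann solve pinned at a reference cell, with the pressure level
re-anchored to the prescribed outlet value. Pressure-driven runs keep
momentum-solved outlet faces against the Dirichlet ghost pressure (this is
the configuration the plane-Poiseuille verification exercises).

Per time step (default dt = 1e-4 s):

1. **Momentum prediction** per phase and component: implicit first-order
   upwind convection + implicit diffusion with the shear-dependent phase
   viscosity (micron-scale flow is strongly viscous; explicit diffusion
   would demand dt ~ 1e-7 s). Sparse direct solves; LU factors are reused
   across steps through residual-guarded iterative refinement, refactoring
   automatically when the operator drifts.
2. **Implicit drag coupling**: per staggered face, the primary/secondary
   drag system is solved exactly (vectorised small matrices). This step
   also yields each phase's velocity response r_i = (M⁻¹Ψ)_i to a pressure
   gradient through the same drag matrix.
3. **SIMPLEC-style projection**: one shared pressure correction enforces
   mixture continuity div(Σᵢ Ψᵢvᵢ) = 0 with face mobilities Σᵢ Ψᵢ·r_i and
   per-phase corrections −r_i∇p′. Using the drag-consistent responses
   (rather than dt/ρᵢ) is essential: a per-density correction would kick
   near-massless air ~840× harder than plasma and un-tie the phases the
   drag step just coupled. Projection and fraction advection are
   re-coupled in CFL-limited mini-steps within dt when the step CFL is
   large.
4. **Fraction advection**: conservative donor-cell upwind of the
   *dispersed* phases, sub-cycled to its own CFL ≤ 0.8 (standard
   phase-fraction sub-cycling), donors at boundaries taken from the ghost
   cells (inlet fractions; outlet backflow fractions when a face points
   inward). The primary (carrier) phase closes ΣΨ = 1 and absorbs the
   mixture-continuity defect — rescaling all phases instead would create
   and destroy dispersed mass systematically wherever the carrier locally
   out- or under-runs it, a bias that accumulates into spurious phase
   enrichment over thousands of steps. Dispersed fractions are clipped to
   [0,1]; clip and closure magnitudes are logged per step, along with the
   per-step mixture mass-balance defect |Δm − boundary flux|/m.

Residuals (continuity defect, normalised velocity change) are logged per
step; `check_convergence` classifies a log tail as converged / marginal /
not converged. A blow-up guard aborts with a diagnostic dump when the
continuity residual outruns its recent history by the configured factor.

### Verification anchors

- Pressure-driven single-phase channel flow recovers the plane-Poiseuille
  profile: centreline/mean = 1.5 within 0.5% at h = 0.5 µm, error
  decreasing monotonically under refinement; per-step mass balance closes
  to machine precision.
- Quiescent equilibrium is an exact fixed point; two identical phases at
  Ψ = 0.5 stay velocity-identical to 1e-8.
- The two-phase tumor configuration conserves mixture mass to ~1e-12 per
  step. The three-phase vessel run at the pulse crest (step CFL ~40)
  shows per-step balance defects up to ~4e-4 of total mass, absorbed by
  the primary-phase closure where the fraction fields are most strongly
  sheared; the residual log exposes this honestly per step.

## Percolation quantification

Plasma maps are thresholded at θ₁ = 1/3 and θ₂ = 2/3 of the fraction range
(the rainbow-colormap reading convention; thresholds configurable):
blue < θ₁ ≤ green < θ₂ ≤ red. Class areas count tumor fluid cells only;
fiber solids never count, and the fenestra channel is excluded by default
(configurable). Areas are conserved exactly for any threshold pair.

The exponent table reports x (0.3/0.1 µm pair) and y (0.5/0.1 µm pair) per
flow time, rounded half-up to 2 d.p. for reporting with full precision
retained. The rate-decay slopes are finite differences of the *reported*
(rounded) x/y column against time — matching how the reference table is
read; the full-precision slopes are also available. The table-reproduction
mode consumes a ratio CSV directly and is therefore independent of solver,
thresholds and resolution.

## Default problem sizes

The packaged defaults are desk-scale: vessel 48×52 cells (h = 0.65 µm),
tumor at h = D/4 per model (Model 3: 50×52 cells), dt = 1e-4 s, 0.30 s of
flow time. These resolve the depression and fenestra but are far below the
reference unstructured meshes; quantitative leakiness ratios from the
solver at this scale are indicative only (the table-reproduction mode
carries the exact reference arithmetic). The miniaturised test domain
(3×3 µm, h = 0.025 µm) exists so all three fenestra models can be compared
on one grid quickly.

## What the synthetic data does and does not emulate

The fiber layout is random non-overlapping discs at the measured packing
fraction with a minimum inter-fiber gap (default ≥ 2 cell sizes) so no
fluid passage pinches off; real tumor stroma has elongated, oriented,
polydisperse fiber bundles and cellular matter between them. The air
"vacuum" initial state isolates the plasma invasion trend; real
interstitium is liquid-filled, so absolute invasion speeds are not
predictive — only the relative trends across fenestra size and time are
meaningful. Passing tests therefore demonstrate internal consistency and
the directional physics (monotone invasion, diameter scaling, rate decay),
not clinical time scales; the computed 0.1–0.3 s horizons would map to
longer real times via scaling factors this package does not estimate.

## Known limitations

- 2D, unit depth; no tortuous walls, no image-derived geometry.
- Isothermal: no energy equation (constant properties make it inert).
- First-order upwind transport: fronts are diffused at coarse resolution.
- The Eulerian drag closure degrades when particle diameter approaches the
  channel height (see the vessel-height rationale); WBC (14 µm) remains
  marginal even at H = 30 µm but carries only 1% volume fraction.
- The printed pure-RBC outlet backflow condition is implemented as printed;
  with strong backflow it injects unphysical pure-RBC mixture.
- No glycocalyx electrohydrodynamics, no hypoxia, no drug transport, no
  whole-spheroid domain.
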