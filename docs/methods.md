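# Methods

This note records the physical model, its assumptions, the numerical
choices, and the known limits of validity, in the order the computation
proceeds: electrolyte chemistry → interface electrostatics → channel
statistics → transport → sensing metrics.

## Model structure and assumptions

The device is an electrolyte–insulator–semiconductor FET: a 2D
semiconductor channel between a back oxide (capacitance C_box = ε_box/t_box)
and a barrier oxide (C_tox = ε_tox/t_tox) whose outer surface faces the
electrolyte. Global charge neutrality couples three sheet densities —
channel (σ₂D), oxide surface (σ₀), and membrane + diffuse layer (σ_md).
Because σ₂D (≲ 10⁻³ C/m² in subthreshold) is orders of magnitude smaller
than σ₀ (q·Ns ≈ 0.64 C/m² at the default site density) and the double-layer
charges, the electrolyte-side balance is solved with σ₂D dropped:

    σ₀(ψ₀) + σ_md(ψ_m) = 0,      ψ_m = ψ₀ − σ₀/C_Stern.

This decoupling makes ψ₀ independent of every terminal voltage, so one
interface solve per chemical condition serves a whole I–V sweep. No
option to re-couple σ₂D is provided: re-coupling changes the model class
and would invalidate the closed-form transport below.

**Potential convention.** All electrolyte-side potentials (ψ₀, ψ_m, ψ_DP)
are measured *local minus bulk*; the bulk electrolyte sits at the
liquid-gate electrode potential Vlg. Three relations pin this convention
simultaneously: the Boltzmann factor for surface protons
(a_s = a_b·e^(−ψ₀/φ_th)), the Stern drop (ψ₀ − ψ_m = σ₀/C_Stern for
positive σ₀), and the sign of the diffuse countercharge. The channel
therefore sees the effective top-gate potential **Vlg + ψ₀**: a surface
made more positive (lower pH below the point of zero charge, or
positively charged macromolecules) lowers the threshold voltage of an
n-type device and raises its current; negative membrane charge raises
the threshold. These are the directions the model must (and does)
reproduce in the pH, fixed-charge, and protein studies.

**Electrolyte.** Symmetric 1:1 salt of molarity i0 (number concentration
n₀ = N_A·i0·10³ m⁻³); point ions (no Bikerman/steric corrections); no
ion-specific adsorption at the inner Helmholtz plane. The Stern layer is
a bias-independent capacitance.

**Membrane.** The receptor–target layer is a uniform volumetric fixed
charge Nm of thickness hm, assumed thick compared with the internal
screening length so a field-free Donnan plateau exists
(ψ_DP = φ_th·asinh(Nm/2n₀)); no finite-thickness correction, no
potential profile inside the membrane is resolved. Salt concentration
inside the membrane equals n₀; its permittivity ε_m defaults to the
water value and can be overridden. Receptor occupancy is equilibrium
Langmuir — no binding kinetics, no crowding or electrostatic feedback on
Kc.

The membrane + diffuse-layer charge is the first integral of the
Poisson–Boltzmann equation from the Donnan plateau (ψ = ψ_DP, dψ/dz = 0)
to the outer Helmholtz plane, with the fixed charge eliminated through
the Donnan condition Nm = 2n₀·sinh(ψ_DP/φ_th):

    σ_md = −sgn(ψ_m−ψ_DP)·√(4·q·n₀·φ_th·ε_m·f),
    f = cosh x − cosh x₀ − (x−x₀)·sinh x₀,   x = ψ_m/φ_th, x₀ = ψ_DP/φ_th.

The 4· prefactor is fixed by requiring the Nm = 0 limit to be *exactly*
the Gouy–Chapman charge −√(8·ε·kT·n₀)·sinh(ψ_m/2φ_th); the test suite
enforces this identity to a relative 10⁻¹⁰.

**Channel statistics.** Effective-mass, two-valley density of states
with the second valley Boltzmann-weighted by its energy separation
(ΔE ≈ 2–3 kT in common TMDs, hence not negligible); further valleys
neglected; non-parabolicity neglected; single carrier type selected by
configuration (no ambipolar conduction). The chemical potential φ_ch is
treated as an unconstrained real.

**Transport.** Diffusive (drift–diffusion) regime with constant
effective mobility: no velocity saturation, contact resistance,
short-channel electrostatics, hysteresis, noise, or AC response. The
drain current closed form is an accurate approximation of
μ·(W/L)·∫|σ₂D|dφ along the channel: changing variables to
u = ln(1+e^(−φ_ch/φ_th)) gives the exact integrand
u·[1/(1−e^(−u)) + C_dq/C_tb], whose first factor the closed form
replaces by u + e^(−u). For the default device (C_dq/C_tb ≈ 58) the
resulting error is below 0.1% deep in subthreshold and in strong
accumulation, and peaks at ≈ 0.7% around threshold (u ≈ 0.1); the test
suite pins this envelope against brute-force integration with the
channel potential re-solved pointwise.

## Parameters that matter

| Parameter | Default | Units | Role |
|---|---|---|---|
| Ns | 4×10¹⁸ (4×10¹⁴ cm⁻²) | m⁻² | hydroxyl site density; sets pH response and how strongly the surface buffers external charge. The functionalized preset uses 1% of it (4×10¹² cm⁻²) |
| pKa, pKb | 7, 7 | — | HfO₂ dissociation constants; pH_pzc = 7 |
| C_Stern | 0.2 (20 µF/cm²) | F/m² | Stern capacitance; divides ψ₀ between surface and OHP |
| i0 | 10⁻³ (1 mM) | mol/L | ionic strength; larger i0 screens the membrane charge and kills sensitivity |
| Nr, Kc, hm | 2.3×10¹⁷ m⁻², 10¹³ M⁻¹, 5 nm | | biotin receptor density, streptavidin binding constant, membrane height |
| kq | user-set (+22.3 at pH 3, −15.2 at pH 9) | e/molecule | net charge per bound target; pH-dependent and supplied externally (per-molecule protonation is out of scope) |
| band | 0.54/0.58 m₀, g = 2/6, ΔE = 70 meV | | MoS₂ conduction valleys → C_dq ≈ 0.44 F/m² |
| Vgo, Vbo | 0.48, 0 | V | gate offset voltages (work functions + fixed charge) |
| μ | 2×10⁻³ (20 cm²/Vs) | m²/Vs | effective electron mobility |
| T | 300 | K | not stated in the source parameter set; room temperature assumed, overridable |

Internally everything is SI (config files accept the common mixed units:
nm, cm⁻², mM, fM, µF/cm², cm²/Vs, multiples of ε₀). Physical constants
are CODATA 2018.

## Numerics

* **Interface solve.** g(ψ₀) = σ₀ + σ_md is strictly decreasing (σ₀
  falls with ψ₀; σ_md falls with ψ_m; ψ_m rises with ψ₀), so the root is
  unique. Bracketed Brent iteration, initial bracket ±2 V expanded
  geometrically to at most ±5 V (beyond which the parameters are
  declared inconsistent); xtol 10⁻¹⁴ V. The charge-neutrality residual
  is checked to ≤ 10⁻¹² C/m² (configurable) at every solution, and a
  plain-bisection path is kept as a cross-check. The radicand f is
  evaluated as cosh(x₀)·2 sinh²(d/2) + sinh(x₀)·(sinh d − d), d = x−x₀
  (with a series for sinh d − d below |d| = 10⁻⁴): the naive form loses
  ~10 digits to cancellation near the Donnan point at large |Nm|, which
  would put a ~10⁻¹⁰ C/m² noise floor under the residual. Negative f
  from rounding is clamped to zero.
* **Channel potential.** The bias equation is strictly increasing in
  φ_ch (σ₂D monotone + linear oxide terms); same bracketed solve,
  residual ≤ 10⁻¹² C/m². log(1+eˣ) is evaluated with a branch at x = 0,
  stable over |x| ≤ 2000, so deep accumulation and deep depletion both
  work.
* **Degenerate inputs.** Ns = 0 and Nm = 0 short-circuits to the exact
  zero solution; n₀ = 0 with Nm ≠ 0 is rejected (the Donnan limit does
  not exist); hm = 0 in Langmuir mode is rejected.
* **Threshold extraction.** Constant-current (default; level
  Ith·W/L with Ith = 10⁻⁷ A) interpolates Vlg linearly in log₁₀(Ids)
  between grid points, exact for an exponential subthreshold branch. A
  max-transconductance extrapolation is provided as an alternative;
  note that on this model's superlinear on-state (no mobility
  degradation) the gm maximum sits at the sweep edge, so that method is
  grid-dependent — reports always name the method used.
* **Default sweeps.** The Vlg grid defaults to Vgo − ψ₀ + [−0.6, +1.0] V
  in 5 mV steps, bracketing the threshold for any chemistry; ψ₀ is
  solved once per sweep. All outputs are deterministic; CSV export uses
  17-significant-digit floats so re-import is bit-exact.
* **Problem sizes.** Test and acceptance runs use 100–400-point bias
  sweeps and ≤ 10⁴-point integration grids; a full sensing report
  (two sweeps + interface solves) completes in well under a second on
  one core.

## Sensing metrics

ΔVth = Vth(analyte) − Vth(reference) on matched grids; since ψ₀ shifts
the curve rigidly, ΔVth = −Δψ₀ independent of extraction method. The
current sensitivity S = |I_after − I_before|/min(I_before, I_after) is
evaluated by default 0.2 V below the reference threshold (the bias is
configurable; the region, not the exact bias, is what the literature
states). In pure subthreshold S saturates at
exp(|ΔVth|·C_tox/(C_tb·φ_th)) − 1, which is the analytic ceiling over
evaluation biases; at the default bias the after-curve is only ~0.1 V
below its own threshold, so the reported S sits below that ceiling.
Operating regions are classified as subthreshold (Vlg < Vth − margin),
saturation (Vds > Vlg − Vth), else linear; representative region biases
for the sensitivity comparison are Vth − 0.2 V and Vth + 0.3 V at the
on-state Vds, and Vth + 0.5 V at Vds = 50 mV.

## Design choices that were genuinely open

* The source equations are ambiguous about the sign with which ψ₀
  enters the channel equation (the printed form conflicts with the
  documented behaviour of every study); the convention above is the one
  consistent with the stated pH/charge response directions and with
  standard ISFET theory. Only signs of shifts, not their magnitudes or
  any sensitivity value, depend on this.
* The printed membrane-charge prefactor (2·q·n₀·φ_th·ε_m) disagrees by
  √2 with the Gouy–Chapman limit; the Poisson–Boltzmann-derived 4·
  prefactor is used so the Nm = 0 limit is exact.
* Thresholds have no canonical definition in the source context;
  constant-current was chosen as default because it is robust in the
  subthreshold-dominated comparisons these sensors live in.
* kq at intermediate pH (e.g. titration studies at pH 4.75) must be
  provided by the user; the package only requires its sign to be
  consistent with the isoelectric point.

## What the model does not capture

Selectivity/cross-binding chemistry, per-molecule charge computation,
binding kinetics and drift, noise and limit-of-detection statistics,
finite ion size, ion-specific effects, spatial structure inside the
membrane, ambipolar transport, and any AC/transient behaviour. Model
studies reproduce the *shape and ordering* of measured BioFET responses;
absolute currents inherit the uncertainty of Vgo, μ and C_Stern, which
are effective, fitted quantities.
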