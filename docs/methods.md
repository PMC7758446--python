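# Methods

This note records the model equations as implemented, the defaults and
their rationale, the numerical choices, and the limits of what the
package's tests can demonstrate.

## Geometry generation

The conducting airways form a rooted binary tree of right circular
cylinders. The trachea is fixed at D = 1.5 cm, L = 12 cm; every other
airway obeys L = α_i·D with α = (8.00, 3.07, 1.75, 1.43, 1.85) for
generations 1–5 and 3.00 from generation 6 on (per-generation parameter
sequences extend by repeating their last entry). Daughter diameters
scale by h_0^min = 2^(−1/3−χ^min) and h_0^maj = 2^(−1/3+χ^maj); the
asymmetry parameters default to the morphometric reference set
(χ^min = 0.10, 0.12, 0.12, 0.05, 0.12, 0.12…; χ^maj = 0.08, 0.01,
0.04, 0.07, 0.08, 0.08…). Anatomical variability adds σ_i·X to the
minor ratio (X ~ N(0,1)), with the major ratio adjusted so that the
summed daughter diameter cubes are conserved exactly; σ_i = 0 for the
first four generations and 0.05 beyond, the midpoint of the plausible
0.02–0.1 range. Draws that would produce a non-positive or
parent-exceeding ratio are rejected and redrawn, preserving the body of
the Gaussian without unphysical airways; redraws are counted on the
tree object. A single seeded PCG64 generator is consumed in
breadth-first order, so a seed reproduces a geometry bit-for-bit and
alterations never shift the stream.

An airway whose minor (or, after a large draw, major) daughter would be
≤ D_lim = 2·d_alv = 400 µm becomes terminal and neither daughter is
created. A guard at 40 generations catches runaway parameter sets.
With the defaults this yields ≈ 21,000 terminal airways with the
terminal-generation mode at 15–17. The generation-mode and
distribution shape match published morphometry; the absolute count is
~40% above the ≈15,000 sometimes quoted for human lungs. We note an
internal tension in the reference description itself: with terminal
aspect ratio α = 3 and a 400 µm cutoff, a 15,000-terminal tree cannot
simultaneously produce the quoted terminal Peclet statistics (see
below); the parameters are implemented as printed rather than tuned to
either statistic.

Two acini attach to every terminal airway. An acinus is seven
generations of identical cylinders (L_a = 1 mm, D_a = 400 µm) with
n_alv = (12, 26, 42, 87, 102, 123, 123) alveoli of diameter 200 µm
budding on the walls of generations 1–7.

## Airflow

The electrical analogy assigns each airway R = Z·128ρνL/(πD⁴) with the
entrance-flow (non-established flow) correction
Z = max(1, (C_P/4√2)·√(Re·D/L)), C_P = 1.85, Re = V·D/ν. The
correction constant and form follow the classical entrance-flow
analysis of branched inspiratory flow; the factor is pluggable
(`z_factor`). Each acinus is a Poiseuille ladder whose seven
generations halve the per-airway flow, giving the exact series
coefficient Σ 128/2^(m−1) = 254; acinar linear shrinkage by φ enters as
R_a/(2φ³) at each terminal airway (two acini in parallel). Expiration
reuses the same resistances with the flow reversed (quasi-static, no
inertance).

Since Z depends on the flow, the solver iterates: resistances from the
current Z, subtree resistances leaf-to-root, flow split at every
bifurcation inversely to the downstream branch resistance (flow
conservation is exact at every iterate), Q at the trachea either
imposed or ΔP/(R + R_sub). Damping 0.5, convergence at max relative
flow change < 1e−8, cap 200 iterations (26 are typical at forced
flows). The 250 Pa ↔ 2.78 l/s forced-expiration anchor validates the
π-inclusive Poiseuille prefactor convention.

## NO exchange

Wall flux. The airway wall is a planar three-layer slab (liquid δ_μ,
epithelium δ_E, muscle/connective δ_M — defaults 10/10/30 µm), one
tissue diffusivity D_t = 3.3e−9 m²/s, volumetric production
P = 25 µmol·m⁻³·s⁻¹ confined to the epithelium, first-order
consumption k_t = 0.2 s⁻¹ in epithelium and muscle, zero-concentration
boundaries at the blood and at the liquid–lumen interface. The closed
form

    J_br = (P δ_E/2)(δ_E + 2δ_M) / (δ_μ + δ_E + δ_M + (δ_μ/2) Ha²)

agrees with a brute-force planar boundary-value solve
(`wall_flux_bvp_oracle`, second-order finite differences with
interface-overlap-weighted coefficients) to well under 5% across the
physiological range (thicknesses up to ×3 the defaults, Ha ≤ 2, and a
severe 205 µm mucus layer); the slab approximation is justified by
layer thicknesses ≤ 50 µm against lumen radii ≥ 200 µm where exchange
matters. Planarity, not annularity, is the one geometric
simplification here.

Alterations are parameterized by the lumen-area reduction
β = 1 − (D'/D)². Liquid accumulation thickens only the liquid layer by
(D − D')/2; muscle contraction conserves each layer's annular
cross-sectional area, thickening all three. Under constant P this
makes J_br rise with β for contraction (longer diffusive residence in
the epithelium raises its concentration) and fall for liquid (a pure
barrier); the delivered amount F = πLD·J_br falls in both cases —
surface loss dominates.

Acinar exchange. Per unit theoretical lateral area πD_aL_a of acinar
generation m,

    J_a,m = −γ·k_alv·(C − C_eq)·n_alv,m d_alv²/(2 D_a L_a)
            + J_wall,a · max(0, 1 − n_alv,m d_alv²/(4 D_a L_a)),

with k_alv = 2e−3 m/s, C_eq = 2 ppb, γ ∈ [0,1] the perfusion
coefficient, and J_wall,a the wall flux evaluated with δ_μ = 0 (healthy
acini carry no liquid lining). With the reference alveolar counts the
producing-wall factor is zero from generation 3 on (n_alv ≥ 40
alveolus areas cover the wall).

Concentrations are SI (mol·m⁻³) internally; ppb conversion uses the
ideal gas law at 37 °C and 1 atm at the configuration and reporting
boundaries only.

## Acinar transport and the linking map

Per airway of acinar generation m (2^(m−1) parallel airways, flow
Q_a/2^(m−1), mean velocity u_m):

    ± u_m dC/dz = D_g d²C/dz² + (4/D_a)·J_a,m(C).

Interfaces impose concentration continuity and diffusive-flux
conservation with the cross-section doubling (trumpet-style
2^(m−1)·πD_a²/4). Because J_a,m is affine in C the full system is
linear: per generation the solution is two exponentials (referenced to
the end where they are largest, so nothing overflows at any Peclet
number) plus a constant/linear/quadratic particular branch (switch at
local dimensionless scale 1e−10, continuity across the switch tested);
a batched, row/column-equilibrated 14×14 solve per acinus with two
right-hand sides yields the affine linking map dC/dz|₀ = a·C(0) + b by
superposition. The batch path computes linking maps for ~20,000
terminals in well under a second.

Distal closure. The distal end of generation 7 abuts the alveolar
sacs. Two closures are implemented; the default pins the sac gas at
the blood-equilibrium concentration C_eq (Dirichlet), the alternative
closes the end (zero diffusive flux). The default matters only when
wall uptake is disabled: with a closed end and γ → 0 nothing pins the
gas concentration in the affected subtree, the steady problem
approaches singularity, and the computed exhaled fraction diverges to
physically meaningless values (the slow mode's time constant also
exceeds the 10 s manoeuvre, so no quasi-steady reading exists). The
sac reservoir — a large, well-perfused surface downstream of the
modelled generations — keeps the perfusion-defect scenarios bounded
while leaving healthy lungs and all other scenarios numerically
unchanged (the healthy acinar end already sits near C_eq). This is the
package's own closure choice for an under-determined corner of the
model class.

## Bronchial transport

Steady (F_E_NO) mode: with ∂/∂t = 0 each airway's equation
D_g C'' ∓ V C' + S = 0 (S = 4J_br/D) has the closed form
A + B·e^(±Vz/D_g) + (S/±V)·z, quadratic below Peclet 1e−8. The
2·n_airw unknowns satisfy: trachea — C(0) = C_in on inspiration, no
axial diffusion C'(0) = 0 on expiration; every bifurcation —
concentration continuity and D²-weighted diffusive-flux conservation;
every terminal airway — D²·C'(L) = 2(φD_a)²·(a·C(L) + b), the linking
map built at Q_a = Q_ij/2 (two acini per terminal). The exponential
basis is end-referenced per airway, which keeps the sparse system
well-scaled at tracheal Peclet numbers in the thousands; SuperLU
solves the 2n system (≈85,000 unknowns for a reference lung) in under
a second, and the steady global NO balance (trachea outflow vs wall
production plus terminal-face supply) closes to machine precision.
F_E_NO is the trachea-top concentration in ppb; per-generation
profiles report distal-end values averaged equally over the airways of
a generation, with the trachea top labelled generation 0.

Unsteady mode: cell-centred finite volumes per airway (default
max(4, ceil(L/(D/2))) cells), first-order upwind convection, central
diffusion, implicit Euler (default dt = 10 ms), junction faces
exchanging with both daughters and terminal faces closed by the same
linking maps. The operator is assembled once per flow state and
factorized (SuperLU), so long manoeuvres cost one triangular solve per
step. The scheme conserves mass up to boundary fluxes, preserves
positivity and equilibria exactly, and converges to the analytic
steady field at first order in the cell size (verified by refinement;
0.5% agreement at 96 cells/airway on the test fixture).

## Scenarios and metrics

Delivery metrics at constant inspiratory flow: cavity time
t_cav = V_cav/Q (V_cav = 106 ml), transit time Σ L/V along the root
path, delivery time t_del = max(0, t_ins − t_cav − t_trans), supply
ratio Ω = Q_ij·t_del / ((Q/n_term)(t_ins − t_cav)).

Bundled exhaled-NO scenarios (50 ml/s expiration, paired against the
same-seed healthy baseline): φ = 0.1 on the nearest/farthest half of
the terminals; 65% diameter reduction (β = 0.8775) on the farthest
half plus their three parent generations, by muscle or by liquid;
γ = 0.7 nearest half; γ = 1e−6 farthest half. "Nearest/farthest" ranks
terminals by generation index with ties broken by the within-generation
index. The COPD experiment narrows a seeded random fraction of the
small airways (D < 2 mm) by β = 0.99 and blocks a random fraction of
acini at φ = 0.01, then compares pressure-driven expiratory flows at
250 Pa.

## Problem sizes and defaults used in the shipped studies

The reference study (`asymlung.study.run_reference_study`, used by
`scripts/acceptance.py` and the end-to-end tests) averages five
independent geometries (~42,000 airways each), solving per seed: two
flow-driven and one pressure-driven network solves, two delivery
computations, and four steady F_E_NO solves. The complete study runs
in ~40 s on one CPU. Unit and property tests use deterministic 2–6
generation fixture trees; the independent oracles are a nodal
linear-circuit solve (airflow), adaptive collocation
(`scipy.integrate.solve_bvp`) for the acinar chain, a finite-difference
layered-wall solve (wall flux), and the finite-volume solver run to its
steady state (bronchial transport).

## What the tests do and do not show

All inputs are synthetic: geometries come from the package's own
generator at the reference parameter set, so end-to-end numbers probe
the implemented model, not any patient. Real lungs differ in ways the
model excludes by design: no turbulence (the entrance-flow factor
captures the dominant non-established-flow resistance), no intra-cycle
airway compliance or volume change, no Taylor dispersion, no 3D acinar
morphology, no nasal NO, lumped upper-airway cavities, and alveolar
uptake reduced to a first-order transfer with an equilibrium
back-pressure. Agreements with published whole-lung statistics are
therefore structural (shapes, signs, orders of magnitude, paired
responses), not clinical validation. Known quantitative deviations —
the terminal-airway count running ~40% above the commonly quoted
15,000 under the printed parameter set, with the terminal Peclet means
and blockage-induced dispersion increases shifted correspondingly, and
the severe-perfusion-defect F_E_NO rise of +5% against a reported
+13.5% under a differently closed acinus — are documented above rather
than patched by parameter adjustment.
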