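# asymlung

Multi-scale simulation of gas transport and exchange in human lungs
with an **asymmetric branching pattern**, applied to exhaled nitric
oxide (F_E_NO).

The package is aimed at respiratory-physiology modellers who need a
whole-lung model in which every airway is represented individually, so
that local, disease-like alterations (smooth-muscle constriction, mucus
accumulation, acinar swelling, perfusion defects) can be imposed on
selected airways and their effect on airflow and on the exhaled-NO
signal computed.

## The model

**Geometry.** The tracheobronchial tree is a binary tree of cylinders.
Airway (i, j) has length L = α_i·D and divides into a minor and a major
daughter with diameter ratios

    h_0^min = 2^(−1/3 − χ_i^min),   h_0^maj = 2^(−1/3 + χ_i^maj),

the Hess–Murray law plus per-generation asymmetry. Anatomical
variability perturbs the minor ratio by σ_i·X (X standard normal) while
(h^min)³ + (h^maj)³ is held fixed (daughter-volume conservation). An
airway becomes terminal when a would-be daughter falls to or below
D_lim = 2·d_alv = 400 µm; two seven-generation acini hang from every
terminal airway.

**Airflow.** Each airway carries a Poiseuille resistance
128ρνL/(πD⁴) multiplied by an entrance-flow correction
Z = max(1, (1.85/4√2)·√(Re·D/L)); each acinus contributes
254·ρνL_a/(πD_a⁴), reduced acini scale as 1/φ³. Because Z depends on
the flow, the network is nonlinear and solved by a damped fixed point.

**NO exchange.** The airway wall is a liquid/epithelium/muscle slab;
with the species pinned to zero at the blood and at the lumen
interface, the wall-to-lumen flux density is

    J_br = (P·δ_E/2)·(δ_E + 2δ_M) / (δ_μ + δ_E + δ_M + (δ_μ/2)·Ha²),

with Hatta number Ha = (δ_E + δ_M)·√(k_t/D_t). In the acini the
alveolar openings absorb NO toward the blood at rate
γ·k_alv·(C − C_eq) per unit alveolar surface and shrink the producing
wall; the net exchange density is affine in the local concentration.

**Lumen transport.** A quasi-steady 1D convection–diffusion equation
per airway, closed at every terminal airway by the acinar *linking
map*: the seven-generation acinar problem is solved in closed form and
reduced to dC/dz|₀ = a·C(0) + b. The steady F_E_NO solve assembles one
sparse linear system of size 2·n_airw; a finite-volume implicit-Euler
solver covers time-dependent manoeuvres.

## Worked example

```bash
asymlung tree --seed 1 --out tree.csv
# tree: 42363 airways, 21182 terminals -> tree.csv

asymlung flow --tree tree.csv --drive-pressure 250 --direction expiration --out flow.csv
# Q_trachea = 2.783 l/s, dP = 250 Pa (26 iterations)

asymlung feno --tree tree.csv --flow 50e-6 --out profile.csv
# F_E_NO = 21.002 ppb

asymlung scenario --tree tree.csv --name preacinar_liquid --out results
# preacinar_liquid: F_E_NO 21.00 -> 15.83 ppb (-24.6%)
```

The first command generates a reference lung (seed 1) and writes its
flat airway table. The second drives a forced expiration with a 250 Pa
alveolar overpressure: the 2.78 l/s tracheal flow corresponds to the
FEV1 of a healthy adult. The third simulates the standard slow
expiration at 50 ml/s; 21 ppb is a typical healthy exhaled-NO
fraction, and `profile.csv` holds the mean ± sd NO concentration per
generation (generation 0 = top of the trachea). The last command
narrows the distal half of the tree by 65% in diameter through mucus
accumulation and reports the paired F_E_NO drop — the signature of a
peripheral obstruction.

The same operations are available as library calls
(`generate_tree`, `solve_flow`, `solve_feno`, `run_no_scenario`, ...);
see the docstrings and `docs/methods.md`.

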