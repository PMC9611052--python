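# Methods

This note records the models implemented in micellekit, their assumptions,
the tunable parameters that matter, and the design choices made where the
underlying procedures were open to interpretation. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Charge bookkeeping (formulation)

The N/P ratio is computed from raw group counts: every lysine ε-amine
counts +1 (10 per mPEG₄₅-PLL₁₀-PLA₂₅ chain; the terminal α-amine is not
counted extra) and every backbone phosphate −1 (n − 1 per n-mer strand,
40 per 21+21-mer duplex). Protonation is assumed complete — no pKa model —
because the characterization this mirrors works with nominal group counts.
The default chain molar mass (5300 g/mol) follows from the stock pairing
0.3 mM copolymer ↔ 1.59 mg/mL; both it and the group counts are
constructor arguments.

## ITC one-site analysis

**Model.** n identical independent sites per macromolecule, mass-action
binding. Per injection the fractional occupancy Θ is the physical root of

Θ² − Θ·[1 + X_t/(n·M_t) + 1/(n·K_a·M_t)] + X_t/(n·M_t) = 0,

with cell heat content Q = n·Θ·M_t·ΔH·V₀ and per-injection heat
ΔQ_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2, divided by the moles of
injectant delivered. The last term is the standard perfusion-cell
displacement correction (constant active volume V₀ = 1.8 mL; each
injection pushes an equal volume out). Concentrations after cumulative
injected volume ΔV use M_t = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀) and
X_t = X₀(ΔV/V₀)/(1 + ΔV/2V₀).

**Basis.** Fitting runs on the charge basis actually loaded — cell 0.05 mM
siRNA phosphate, syringe 3 mM amine nitrogen. The per-siRNA stoichiometry
is then n × (40 phosphates/duplex)/(10 amines/chain) = 4n. ΔH is per mole
of injectant (amine).

**Schedule defaults.** 1.8 mL cell, an initial 2 µL aliquot (guards
against syringe backlash; excluded from fitting), then 10 µL injections
every 180 s. The number of injections is not fixed by the source protocol
("until saturation"); the default is 28, a standard full-syringe VP-ITC
program that carries the amine:phosphate ratio to ≈9, far past the
equivalence at ≈1.43.

**Integration.** Window = [injection start, start + spacing]. The baseline
is the line through the mean of the quiet trailing 20 % of the preceding
window and of the window itself; it removes any linear drift exactly (a
test asserts invariance under added drift). Areas are trapezoidal;
1 µcal = 4.184 µJ exactly.

**Optimizer.** `scipy.optimize.least_squares` (TRF) over (n, log₁₀K_a,
ΔH), started from a deterministic 3×3×3 grid: n seeded from the molar
ratio where |heat| first halves, ΔH from the first plateau heat, log₁₀K_a
from {5, 7, 9}. The best of the 27 solutions wins; there is no random
restart, so fits are reproducible. Parameter uncertainties come from the
residual covariance s²(JᵀJ)⁻¹. An optional constant heat-of-dilution
offset (4th parameter) is off by default, matching the plain three-
parameter analysis. Degenerate inputs fail loudly: fewer than 5 usable
injections or a transition-free (constant) isotherm raise
`NonIdentifiableError`.

**Why K_a is soft.** At c = n·K_a·M_t ≈ 1.9×10³ the isotherm is nearly a
step; the transition injection pins n and the plateau pins ΔH, but K_a is
only bounded below. Recovery tests therefore check n and ΔH tightly and
K_a loosely.

**Derived quantities.** K_d = 1/K_a, ΔG = −RT ln K_a, ΔS = (ΔH − ΔG)/T
with R = 8.314 J K⁻¹ mol⁻¹ and T = 298 K by default; the closure
ΔG = ΔH − TΔS holds by construction.

## Trajectory metrics

All coordinates are nm (PDB Å are scaled ×0.1 on read). Metrics over an
ensemble are reported per frame (`ensemble_metrics`) with mean ± SD left
to the caller, frames weighted uniformly.

* **θ bending angle** — vertex at the center of mass of the central two
  base pairs, arms to the centers of mass of the two terminal nucleotides
  at each duplex end (both strands, antiparallel pairing respected;
  window sizes configurable). 180° is rectilinear. The angle is computed
  from heavy atoms only. Near 180° the arccos is ill-conditioned at the
  √ε level (~10⁻⁶ deg), which the invariance tests tolerate.
* **Hydrogen bonds** — donor–acceptor heavy-atom distance ≤ 0.35 nm and a
  donor–H–acceptor angle ≥ 150°. The source analysis names no criterion;
  this mirrors the convention of the MD package it used. Explicit donor
  hydrogens are required (the generators emit them); atoms without flags
  give a warned zero, not an error.
* **Buried surface** — SASA(siRNA) + Σ SASA(copolymer k) − SASA(complex),
  unhalved (no interface ½ convention), clipped at 0. SASA is an in-house
  Shrake–Rupley kernel: probe 0.14 nm, 960-point Fibonacci sphere per
  atom — deterministic by construction, hydrogens excluded, van der Waals
  radii from a bundled element table unless the frame carries radii. The
  kernel is validated against the one- and two-sphere closed forms (<1 %)
  and cross-checked against an independent SASA implementation in tests.
* **PLL-contact stoichiometry** — a PLL residue is complexed when its
  minimum heavy-atom distance to any siRNA atom is ≤ 0.3 nm; a copolymer
  is complexed when ≥ 1 of its PLL residues is. The source text prints
  "at a distance of at least 0.3 nm", which as written would count
  everything except touching residues; it is read as a contact criterion
  (≤ 0.3 nm) and the cutoff is exposed as a parameter.

## CZE quantification

Peak areas are trapezoidal over a straight-line baseline between window
endpoints, each endpoint anchored on the mean of the outer 5 % of the
window (noise-robust variant of the endpoint baseline). The corrected
ratio is (A260/T260)/(A210/T210) with T the apex migration times; a
missing internal-standard peak is an error because quantification is then
impossible. Calibration is unweighted ordinary least squares (a plain r²
is reported). Percent complexed = 100(1 − free/control), clipped to
[0, 100] with a warning — noise can push free marginally above the
control.

## Saturation extrapolation

Degree fixed at 2: the saturation point is operationalized as the
parabola's stationary point x* = −b/(2a) (a maximum when a < 0; a ≈ 0
within 10⁻¹⁰ of the coefficient scale raises instead of returning a
spurious extremum). Enthalpy series are fitted in kcal/mol and converted
×4.184 on request; the printed −132.2 kJ/mol arises from evaluating the
enthalpy parabola at x = 10 (not at its own stationary point) and
converting — the tool reproduces that arithmetic path via `predict(x,
unit_out="kJ")` rather than guessing a different intent.

## Synthetic worlds — what a green test establishes

The generators state the world the analysis assumes, with the published
operating points as defaults: the ITC schedule above with the Table-row
parameters (n = 5.71/4 on the charge basis, K_a = 2.6×10⁷, ΔH = −16.5);
metric series at copolymer counts {1, 4, 6, 8} from the printed
interpolation coefficients; electropherograms at 2 µM siRNA with 4 µg/mL
internal standard; 21-bp duplexes.

Deliberate idealizations:

* ITC noise is white Gaussian on the power trace (σ = 2 % of the tallest
  pulse by default) on a linear baseline; real baselines wander
  nonlinearly and injection peaks tail.
* Pulses are Gaussians centered 5σ into each injection window, so cut
  tails are negligible against the integration tolerance.
* The duplex is an idealized straight helix (rise 0.34 nm, twist 36°/bp)
  at one pseudo-atom per moiety (phosphate, sugar, base, plus a base
  hydrogen), with the strands placed diametrically opposite so every
  base-pair center lies exactly on the axis — a real B-form groove phase
  would itself bend the three-center angle by a few degrees. Copolymers
  are bead chains with a prescribed fraction of PLL beads placed 0.25 nm
  from distinct phosphates.
* Electropherogram peaks are pure Gaussians with linear response; no
  tailing, drift or matrix effects.

Recovery tests therefore establish correctness of the estimators under
the stated noise model, not robustness to instrument pathologies; the
frame metrics are validated against brute-force oracles and closed forms,
not against force-field trajectories.

## Known limitations

* Single-site binding only; no sequential/cooperative models and no blank
  (buffer-into-buffer) subtraction beyond the optional constant offset.
* No peak deconvolution in CZE; overlapping analyte/IS windows are
  rejected, not resolved.
* PDB is the only structure format; chain ids must fit the PDB column
  (one character).
* SASA cost grows as (atoms × neighbors × 960 points); fine for the
  ≤ ~1000-atom pseudo-atom frames it targets, not for all-atom systems.
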