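# micellekit

Characterization toolkit for the complexation of siRNA by cationic
triblock-copolymer micelles (micelleplexes). It reimplements, as a tested
reusable library, the combined experimental/computational workflow used to
characterize an mPEG₄₅-α-PLL₁₀-PLA₂₅ copolymer binding a 21-mer siRNA
duplex:

* **Formulation arithmetic** — the N/P charge ratio (protonatable amine
  groups N over backbone phosphate groups P) and its inverse, for scripting
  mixing recipes. With 10 lysine amines per chain and 40 phosphates per
  duplex, charge neutrality (N/P = 1) needs 4 chains per duplex.
* **ITC one-site binding analysis** — integration of differential-power
  thermograms into per-injection molar heats, a Wiseman one-site fit
  (n, K_a, ΔH) with perfusion dilution correction, and the derived
  thermodynamics K_d = 1/K_a, ΔG = −RT ln K_a, ΔS = (ΔH − ΔG)/T.
* **Trajectory complexation metrics** — on labeled coordinate frames
  (generated or read from PDB): the duplex bending angle θ (three centers
  of mass; 180° = rectilinear), geometric hydrogen-bond counts between
  segments, the total buried surface (Shrake–Rupley SASA of the isolated
  partners minus the complex), and the PLL-contact stoichiometry (a PLL
  residue counts as complexed within 0.3 nm of the siRNA).
* **CZE free-siRNA quantification** — corrected peak-area ratios
  (A260/T260)/(A210/T210) against a co-injected internal standard, a linear
  calibration, and percent-complexed arithmetic.
* **Saturation extrapolation** — a degree-2 least-squares fit to
  stoichiometry or enthalpy values versus copolymer count; the saturation
  point is the parabola's stationary point x* = −b/(2a).
* **Synthetic data** — seeded generators for every input above
  (thermograms, idealized duplex/copolymer frames, electropherograms,
  quadratic metric series), each emitting machine-readable ground truth.

Who it is for: formulation scientists and modellers who want the
quantitative glue of a micelleplex characterization campaign — not the
instruments (no ITC/CE control) and not the simulations (no MD engine) —
in one scriptable, unit-tested place.

## Worked example

Generate a synthetic titration from the experimental one-site parameters
(n = 5.71 copolymers/siRNA on the charge basis, K_a = 2.6×10⁷ M⁻¹,
ΔH = −16.5 kJ/mol) with 2 % power noise, integrate it and refit:

```python
import micellekit as mk
from micellekit.synthetic import gen_itc_thermogram, GeneratorConfig

tg, truth = gen_itc_thermogram(cfg=GeneratorConfig(seed=7))
heats = mk.integrate_injections(tg)
res = mk.OneSiteBindingModel(heats).fit()
print(res.summary())
```

```
One-site binding fit
==============================================
n injections fitted     27
residual sum of squares 3.242 (kJ/mol)^2
----------------------------------------------
n (charge basis)       1.4178 +/- 0.0120
n (per siRNA)           5.671
Ka (1/M)            2.055e+07 +/- 8.09e+06
dH (kJ/mol)           -16.454 +/- 0.220
----------------------------------------------
Kd (nM)                  48.7
dG (kJ/mol)             -41.7
dS (kJ/(K mol))         0.085
T (K)                   298.0
```

The per-siRNA stoichiometry (5.67 here) recovers the generating 5.71
within noise; K_a is the softest parameter (tight binding makes the
isotherm step-like, so only a lower bound on K_a is sharp — visible in its
large standard error). ΔG and K_d are derived from the fitted K_a.

The computational stoichiometry route fits a parabola to complexed-copolymer
counts per simulated system size and reads off its maximum:

```python
import numpy as np
from micellekit import MetricSeries, fit_quadratic

x = np.array([1, 4, 6, 8], float)
series = MetricSeries(x, -0.05 * x**2 + 1.07 * x + 0.01)
print(fit_quadratic(series).summary())
```

```
Quadratic saturation fit
========================================
value = a x^2 + b x + c
a = -0.05   b = 1.07   c = 0.01
rss = 1.3e-29
stationary point (maximum): x* = 10.7, value = 5.735
```

i.e. the siRNA saturates at ≈10.7 copolymers with an asymptotic
stoichiometry of 5.73 — consistent with the calorimetric 5.71 ± 0.15.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the saturation-extrapolation quantities end to end: it samples
the stoichiometry interpolation polynomial at the simulated copolymer
counts (1, 4, 6, 8), refits the quadratic saturation model and writes the
stationary point's value and location as JSON.
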