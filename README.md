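# bindfe

Restraint-based absolute binding free energies and coupled
folding-and-binding order parameters for peptide–RNA association,
exercised end-to-end on synthetic biased-sampling data with known ground
truth.

## The scientific problem

Short, arginine-rich peptides — such as the phage N-peptide segments
that bind boxB RNA hairpins — are largely disordered free in solution
and fold into an α-helix only upon binding. Quantifying this coupled
folding and binding requires two kinds of machinery:

1. **Free-energy bookkeeping.** The standard-state binding free energy
   from a separation potential of mean force (PMF) with axial,
   orientational and conformational restraints (the Woo–Roux scheme):

   ΔG_b° = −k_BT ln(I\* S\* C°) + ΔG_p^B + ΔG_n^B + ΔG_o^B
           − ΔG_p^S − ΔG_n^S − ΔG_o^S − ΔG_a^S

   where I\* = ∫_site exp(−β[W(r) − W(r\*)]) dr is the separation
   integral of the restrained PMF W(r), S\* = r\*² ∬ sinθ e^{−βu_a} dθ dφ
   the angular surface factor of the axial restraint at the unbound
   reference r\*, C° = 1/1661 Å⁻³ the 1 M standard state, and the
   ΔG terms are restraint-release free energies for the peptide (p),
   the RNA (n), orientation (o) and the axial angles (a) in bulk (B)
   and at the binding site (S).

2. **Order parameters along the separation coordinate.** Per-window
   statistics that localize the onset of orientation and folding:
   the mean closest contact ⟨r_cc⟩ and contact frequency f_cc (4 Å
   cutoff), dipole projections onto the separation axis, native
   contacts Q by the soft-cutoff sigmoid, hydrogen bonds per residue
   (4 Å / 120° criterion), RMSD variants, a dihedral-based helicity,
   and the total variation distance
   D_TV = Σ_ω |P(ω) − P_ref(ω)| ∈ [0, 2]
   between a window's orientation-angle distribution and a bulk
   reference, with onset boundaries Ξ extracted by a
   three-increasing-windows rule and generalized-logistic /
   log-exponential / Debye–Hückel tail fits on top.

The estimators (1-D WHAM, BAR, mBAR, exponential perturbation, block
errors) and the assembly are implemented here and validated against
closed forms, quadrature oracles, and a complete two-route closure of
the thermodynamic cycle on a rigid toy model whose exact reference is
computable on a desk-scale CPU budget. Reference free-energy tables
from explicit-solvent simulations of the P22 N-peptide–boxB system
(two water models × three NaCl concentrations) ship as packaged CSV
fixtures and drive the bookkeeping analyses.

## Worked example

Assemble a binding free energy from the packaged contribution table and
regress its salt dependence:

```python
from bindfe.io import ledger_from_table, salt_series_from_table
from bindfe.restraint_fe import assemble_binding_free_energy
from bindfe.transitions import salt_dependence_regression, interpolate_concentration

ledger = ledger_from_table("TIP3P", 81)
total, err = assemble_binding_free_energy(ledger)
print(f"dG_b = {total:.2f} +- {err:.2f} kcal/mol")

series = salt_series_from_table("TIP4P-D", source="contributions")
slope, stderr = salt_dependence_regression(series, log_base="natural")
conc = interpolate_concentration(series, -12.2)
print(f"salt slope = {slope:.2f} +- {stderr:.2f} kcal/mol per ln[NaCl]")
print(f"dG = -12.2 kcal/mol corresponds to {conc:.0f} mM")
```

prints

```
dG_b = -19.95 +- 0.23 kcal/mol
salt slope = 4.46 +- 0.60 kcal/mol per ln[NaCl]
dG = -12.2 kcal/mol corresponds to 126 mM
```

i.e. the signed sum of the eight TIP3P/81 mM ledger terms (−19.95,
matching the tabulated −20.0 at table precision), the natural-log OLS
slope of the TIP4P-D totals (4.5 kcal/mol per e-fold of salt), and the
salt concentration at which the fitted line crosses the experimentally
measured affinity of the homologous λ-phage complex.

The numbered scripts under `analysis/` run the full set of analyses —
ledger assembly for all six conditions, salt regressions, estimator
validation against analytic landscapes, the two-route toy binding
cycle, and the orientation/transition fits — and write their tables
under `results/`.

A YAML-driven pipeline (`configs/demo.yaml`) chains synthetic data
generation → WHAM → ledger assembly → fits:

```python
from bindfe.io import run_pipeline
run_pipeline("configs/demo.yaml")
```

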