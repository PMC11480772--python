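# Methods

This note documents the models, estimators, numerical choices and
validation strategy of `bindfe`. Units throughout: kcal/mol, Ångström,
radians, Kelvin; k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, default temperature
300 K, standard state C° = 1/1660.6 Å⁻³ (1 M).

## The restraint-release (Woo–Roux) bookkeeping

Separating a bound peptide from its RNA partner along a center-of-mass
distance converges slowly when the peptide may tumble and unfold on the
way out. The remedy is to restrain the separation geometry: six anchor
points (three per partner, each the mass-weighted center of a
non-hydrogen atom group) define a distance r = |P0–Q0|, two axial
angles (θ = ∠P1-P0-Q0, φ = dihedral P2-P1-P0-Q0) that fix the exit
direction, and three orientational angles (Θ = ∠P0-Q0-Q1,
Ψ = dihedral P1-P0-Q0-Q1, Φ = dihedral P0-Q0-Q1-Q2) that fix the
ligand's orientation. Harmonic restraints on the five angles (and on
each partner's internal RMSD) are applied during the PMF calculation
and their free-energy cost is removed at the endpoints:

ΔG_b° = −k_BT ln(I\* S\* C°) + ΔG_p^B + ΔG_n^B + ΔG_o^B
        − ΔG_p^S − ΔG_n^S − ΔG_o^S − ΔG_a^S.

The ledger stores each term as a (value, stderr) magnitude with a
bulk/site label and the assembler applies the signs, which prevents
double-negation errors; errors combine as a root sum of squares
(the terms come from separate simulations). Bulk angular releases are
analytic:

* ΔG_o^B = −k_BT ln[(1/8π²) ∭ sinΘ e^{−βu_o} dΘ dΦ dΨ]
* S\* = r\*² ∬ sinθ e^{−βu_a} dθ dφ

computed by adaptive 1-D quadrature per dimension (the integrand
factorizes; absolute tolerance 1e-10, dihedral deviations wrapped to
(−π, π]). Site releases use single-step exponential perturbation
−k_BT ln⟨e^{−βu}⟩ on unrestrained-target samples (with an
effective-sample-size reliability check) or two-sided BAR when both
endpoint ensembles are available. Conformational releases integrate a
WHAM PMF over an RMSD coordinate:
−k_BT ln(Z[restrained region]/Z[full profile]), which is non-negative
and grows as the region shrinks.

**Force-constant conventions.** Published restraint force constants are
ambiguous between U = kΔ² (the Amber NMR-restraint form, our default,
called `full`) and U = (k/2)Δ² (`half`). The convention is an explicit
field on every bias and restraint — never defaulted silently — and the
bulk orientational release exposes it as a parameter. For the published
anchor equilibria (Θ₀ = 2.53, Φ₀ = 2.7, Ψ₀ = −3.13, θ₀ = 1.49,
φ₀ = −2.88 rad, k = 100 kcal mol⁻¹ rad⁻²) at 300 K an independent
dense-grid oracle gives ΔG_o^B = 6.4932 kcal/mol (`full`) and
5.8743 kcal/mol (`half`). The value tabulated in the reference data
(6.81) is reproduced by neither integrand variant; both oracle values
are frozen as regression constants and the discrepancy is left open
rather than calibrated away. The bookkeeping analyses use the tabulated
6.81 as a printed input, so they are unaffected.

**Known bookkeeping tolerance.** Re-summing the printed contribution
columns reproduces five of the six printed totals within one unit in
the last printed digit; the TIP4P-D/177 mM column re-sums to −9.98
versus the printed −10.1. The worst-case accumulated rounding of the
eight printed components is ±0.13, so the acceptance check compares at
max(one ulp of the total, the propagated component half-ulps).

## Free-energy estimators

* **WHAM (1-D).** Shared global bin edges across windows (default width
  0.1 in coordinate units — required for consistency), self-consistent
  iteration with convergence declared when no window free energy moves
  by more than 1e-7 kcal/mol (max 10⁵ iterations, error carrying the
  last residual otherwise). Adjacent windows with zero histogram
  overlap raise a disconnected-windows error. Per-bin errors repeat
  WHAM on 10 block-split windows (matching the block-averaging error
  protocol); the block profiles are retained on the result for
  downstream propagation.
* **BAR.** Bennett self-consistency solved by bracketed root finding
  (brentq; the bracket grows from both one-sided exponential estimates),
  with the standard asymptotic variance from the Fermi-function moments.
* **mBAR.** The convex multistate objective is minimized by L-BFGS with
  analytic gradient over the sampled states; unsampled states are
  filled in by reweighting against the converged mixture. Covariance by
  the SVD form of the asymptotic estimator. At K = 2, mBAR and BAR agree
  to 1e-6 kcal/mol on identical input (tested).
* **Exponential averaging** uses a max-shift for overflow safety and
  block-averaged (10 blocks, remainder discarded, ddof = 1) errors.
* **I\*** integrates exp(−β[W − W(r_ref)]) over the site range by the
  trapezoid rule on the profile grid with interpolated endpoints.
* **Histogram overlap QC** is the Bhattacharyya coefficient of adjacent
  normalized histograms.

## Order parameters

All statistics operate on plain coordinate frames with an explicit
topology (names, residues, masses, charges, hydrogen flags).
Centers of mass are mass-weighted by default (geometric available);
closest contacts use non-hydrogen selections by default. δ⟨r_cc⟩ is the
population standard deviation of r_cc(t) (standard error of the mean
available as an option). Dipoles of net-charged groups are taken about
the group's center of mass — the same point that steers the separation —
and the projection sign convention makes "positive charge points at the
polyanion" negative. Orientation angles are binned in 5° bins on a
shared [0, π] grid; principal-axis angles are folded to [0, π/2]
(a headless line), dipole and end-to-end angles are not. The total
variation distance keeps the un-halved convention Σ|P − P_ref| with
maximum 2. Native contacts use the soft sigmoid
1/(1+exp[β(r − λr⁰)]) with β = 5 Å⁻¹, λ = 1.8 over inter-partner
heavy-atom pairs within 4.5 Å in the reference (the radius is the
cited soft-cutoff method's convention). Hydrogen bonds require
|D−A| ≤ 4 Å and a D-H⋯A angle ≥ 120°, counted residue-wise and averaged
over the peptide. RMSD uses the quaternion-verified Kabsch fit;
the orientational RMSD superposes each frame on the RNA only and then
measures the peptide without a second fit, so it is bounded below by
the best-fit peptide RMSD. Helicity replaces an external
secondary-structure binary with a dihedral rule — runs of ≥ 3
consecutive residues with φ ∈ [−100°, −30°], ψ ∈ [−67°, −7°] — which is
deliberately not equivalent to STRIDE but needs no dependency.

## Transition fits and boundary extraction

The generalized logistic y = A + (K−A)/(1+e^{−B(x−M)})^{1/ν} is
multimodal in its five parameters; fits use 16 seeded starts with
bounds from the data range. The closest-contact model
f(x) = a + b·log(c·e^{x−d} + e) carries a two-dimensional gauge
degeneracy — (c,d) → (c e^s, d+s) and (a,d,e) → (a−bs, d−s, e e^s)
leave the curve invariant — so the default fit pins the canonical gauge
c = e = 1, in which (a, b, d) are identifiable; the full five-parameter
mode exists for exploration and flags boundary parameters.
The onset boundary Ξ scans from the largest window center toward
smaller r and returns the middle of the first three consecutive windows
that each rise above their larger-r predecessor by more than a noise
floor ε = 0.01 (strict increases; the rule needs three rising *steps*,
which is the reading consistent with the worked example it comes from).
The long-range PMF tail is fitted to A e^{−κr}/r + w₀ for r ≥ 20 Å; when
an ionic strength is supplied the theoretical κ = √I/3.04 Å⁻¹
(1:1 electrolyte near 300 K) is reported alongside. Salt-dependence
slopes are ordinary least squares of ΔG_b against ln[NaCl in M]
(natural log is the default because only it reproduces the tabulated
slope values; the decadic slope is the natural one × ln 10). The
tabulated TIP3P restraint-route slope 2.9 ± 1.1 is not reproduced by
plain OLS in either base (natural-log OLS gives 2.58 ± 0.97, within the
printed error but not at printed precision); the regression variant
behind that number is unknown and no agreement is forced.

## Synthetic data: what it emulates and what it does not

No molecular dynamics is run anywhere. The generators provide exactly
the statistical structure the analyses consume, with ground truth:

* **Metropolis windows on analytic potentials** (harmonic, double-well,
  screened-Coulomb, polynomial) emulate umbrella-sampled reaction
  coordinate series; a replica-exchange variant attempts neighbor bias
  swaps with the Metropolis criterion every `attempt_interval` steps
  (detailed balance verified by KS comparison of marginals against
  no-exchange runs over 20 seeds).
* **The toy complex** is a 19-bead flexible chain (integer bead charges
  patterned on an arginine-rich sequence: 9 basic, 3 acidic, net +6e)
  and a rigid 15-bead scaffold (net −14e) interacting through
  dielectric-scaled screened Coulomb (ε_r = 78, Debye length
  3.04/√I Å) plus a Gaussian-core repulsion, evolved by overdamped
  Euler–Maruyama Langevin steps sized so bonded displacements stay
  below ~0.1 Å (a stability guard rejects steps over 1 Å). It produces
  trajectories on which every order-parameter routine runs; it does not
  reproduce — and is not meant to reproduce — real N-peptide/boxB
  energetics, kinetics, hydrogen-bond chemistry or solvent structure.
  Passing tests therefore certify the *analysis code paths*, not force
  fields.
* **Orientation ensembles** draw a dipolar dumbbell axis from a von
  Mises–Fisher distribution about the separation axis, with the exact
  angle density p(ω) = κ e^{κ(cosω−1)} sinω / (1−e^{−2κ}) attached for
  quadrature truth.
* **The rigid pair** reduces the toy complex to three beads per partner.
  Its six degrees of freedom are exactly the Woo–Roux internals, sampled
  by a vectorized walker-ensemble Metropolis chain in internal
  coordinates with the configurational Jacobian r² sinθ sinΘ in the
  target density.

Every generator records its seed and version; identical seeds give
bit-identical output.

## The two-route cycle validation

Because the rigid pair is conformationally frozen, ΔG_p and ΔG_n vanish
identically and the ledger closure can be tested end-to-end at desk
scale: the restrained route (umbrella windows along r with angular
restraints → WHAM → I\*, analytic S\* and ΔG_o^B, staged two-sided
single-step site releases → signed assembly) must match the direct
route (unrestrained windows → WHAM → −k_BT ln(C°·I\*_free·4πr\*²)).
The default cycle model uses 300 mM salt so that the Debye length
(~5.5 Å) makes the interaction negligible at the unbound reference
r\* = 24 Å; at low salt the monopole tail (~0.4 kcal/mol at 81 mM)
would violate the plateau assumption behind the S\* factorization at
this window range. Problem sizes: 25 windows × 32 walkers × 1200 sweeps
per route, 2000 sweeps for the site ensembles (a few minutes on one
CPU). The bound pose that defines the restraint equilibria is located
by a 60-start Nelder–Mead search with its own fixed seed — it is a
property of the model, not of the sampling replica. I\* errors are
propagated to first order from the per-bin WHAM block errors (re-running
the integral on block profiles is unstable at profile edges). Across
independent seeds the two routes agree within their combined standard
errors (≈ 0.3 kcal/mol at these problem sizes).

## Degenerate inputs and tie-breaks

Coincident anchors and collinear dihedral triples raise geometry errors;
zero-length orientation vectors (e.g. a vanishing dipole) are rejected
rather than silently binned. Dihedrals use the right-handed two-plane
atan2 convention with range (−π, π] (the boundary value maps to +π).
Constant data in the logistic fit short-circuits to a flagged degenerate
result with A ≈ K. WHAM drops empty bins from the returned profile.
PDB round trips are exact to the format's 1e-3 Å coordinate precision;
bead formal charges ride in columns 79–80.

## Known limitations

* 1-D WHAM only; no autocorrelation estimation beyond block averaging
  and no decorrelation subsampling — error bars on heavily correlated
  series lean on the 10-block protocol.
* The helicity rule is a deliberate, documented stand-in for a
  secondary-structure assignment program and will disagree with it near
  helix termini.
* Single-step site releases degrade when the restraint-on/off overlap is
  poor; the ESS warning fires, and the cycle workflow uses staged
  two-sided estimates instead.
* The salt-dependence regression is plain OLS; no error-in-variables or
  weighted variant is provided (the printed slope of one tabulated row
  appears to come from such a variant and is not reproduced).
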