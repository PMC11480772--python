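"""Restraint-release bookkeeping for absolute binding free energies.

The Woo–Roux route to a standard-state binding free energy applies
axial (theta, phi), orientational (Theta, Phi, Psi) and conformational
(RMSD) restraints during the separation PMF and removes their
contributions analytically or by perturbation at the endpoints.  The
assembled quantity is

    dG_b = -kT ln(I* S* C0)
           + dG_p^B + dG_n^B + dG_o^B
           - dG_p^S - dG_n^S - dG_o^S - dG_a^S

where I* is the separation integral over the bound range of the
restrained PMF, S* the angular surface factor of the axial restraint at
the unbound reference distance r*, C0 the 1 M standard-state
concentration (one molecule per 1660.6 A^3), superscript B/S mark bulk
and site terms, and subscripts p/n/o/a mark peptide-conformational,
RNA(nucleic)-conformational, orientational and axial restraints.

Bulk releases of purely angular restraints are analytic (quadrature over
the restraint Boltzmann factor); site releases use single-step
exponential perturbation or BAR; conformational releases integrate an
RMSD-coordinate PMF.  Term errors are treated as independent and
combined in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .constants import STANDARD_VOLUME, kbt
from .core import RestraintScheme, UmbrellaWindowSet, wrap_angle
from .estimators import (FreeEnergyEstimate, PmfProfile, bar,
                         exponential_averaging, wham_1d)

__all__ = [
    "FreeEnergyLedger",
    "LedgerError",
    "LEDGER_TERMS",
    "orientational_release_bulk",
    "axial_surface_term",
    "standard_state_term",
    "conformational_release",
    "single_step_release",
    "assemble_binding_free_energy",
    "bulk_to_site_deltas",
]


class LedgerError(ValueError):
    """A required ledger term is missing or malformed."""


#: Term names (ASCII) and the sign each carries in the assembly.
LEDGER_TERMS = {
    "sep_term": +1,   # -kT ln(I* S* C0), stored with its own sign
    "dG_p_B": +1,
    "dG_n_B": +1,
    "dG_o_B": +1,
    "dG_p_S": -1,
    "dG_n_S": -1,
    "dG_o_S": -1,
    "dG_a_S": -1,
}


@dataclass
class FreeEnergyLedger:
    """Named restraint-release terms, stored as magnitudes with B/S labels.

    ``terms`` maps the names in :data:`LEDGER_TERMS` to (value, stderr)
    pairs in kcal/mol.  The assembler applies the signs, so bulk releases
    and site releases are both stored as the (usually positive) release
    free energies and the separation term is stored as the full signed
    -kT ln(I* S* C0).
    """

    terms: dict[str, tuple[float, float]] = field(default_factory=dict)
    temperature: float = 300.0
    salt_mM: float | None = None
    water_model: str | None = None

    def set_term(self, name: str, value: float, stderr: float = 0.0) -> None:
        if name not in LEDGER_TERMS:
            raise LedgerError(f"unknown ledger term {name!r}")
        if stderr < 0:
            raise LedgerError("stderr must be >= 0")
        self.terms[name] = (float(value), float(stderr))

    def get(self, name: str) -> tuple[float, float]:
        try:
            return self.terms[name]
        except KeyError:
            raise LedgerError(f"ledger term {name!r} is missing") from None


def _angular_partition_1d(
    equilibrium: float,
    force_constant: float,
    beta: float,
    convention: str,
    periodic: bool,
    jacobian_sin: bool,
) -> float:
    """integral of [sin(x)] exp(-beta u(x)) over the angle's domain."""
    pref = force_constant if convention == "full" else 0.5 * force_constant

    if periodic:
        def integrand(x):
            d = wrap_angle(x - equilibrium)
            return math.exp(-beta * pref * d * d)
        lo, hi = -math.pi, math.pi
    else:
        def integrand(x):
            d = x - equilibrium
            val = math.exp(-beta * pref * d * d)
            return math.sin(x) * val if jacobian_sin else val
        lo, hi = 0.0, math.pi
    val, err = quad(integrand, lo, hi, epsabs=1e-10, epsrel=1e-12, limit=400)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise RuntimeError("angular quadrature did not converge")
    return val


def orientational_release_bulk(
    scheme: RestraintScheme,
    temperature: float = 300.0,
    convention: str | None = None,
) -> float:
    """Analytic bulk release of the three orientational restraints.

    Returns -kT ln[(1/8 pi^2) Int sin(Theta) exp(-beta u(Theta,Phi,Psi))
    dTheta dPhi dPsi], positive for a stiff restraint.  The integrand
    convention ("full" U=k d^2 vs "half" U=(k/2) d^2) is exposed because
    published values are sensitive to it.
    """
    conv = convention or scheme.convention
    beta = 1.0 / kbt(temperature)
    k = scheme.force_constant
    if k == 0.0:
        return 0.0
    z_Theta = _angular_partition_1d(scheme.Theta0, k, beta, conv,
                                    periodic=False, jacobian_sin=True)
    z_Phi = _angular_partition_1d(scheme.Phi0, k, beta, conv,
                                  periodic=True, jacobian_sin=False)
    z_Psi = _angular_partition_1d(scheme.Psi0, k, beta, conv,
                                  periodic=True, jacobian_sin=False)
    z = z_Theta * z_Phi * z_Psi / (8.0 * math.pi**2)
    return -kbt(temperature) * math.log(z)


def axial_surface_term(
    scheme: RestraintScheme,
    r_star: float,
    temperature: float = 300.0,
    convention: str | None = None,
) -> float:
    """Angular surface factor S* (A^2) of the axial restraint at r*.

    S* = r*^2 Int sin(theta) exp(-beta u(theta, phi)) dtheta dphi.  For
    k -> 0 this tends to the full sphere 4 pi r*^2.
    """
    if r_star <= 0:
        raise ValueError("r_star must be positive")
    conv = convention or scheme.convention
    beta = 1.0 / kbt(temperature)
    k = scheme.force_constant
    if k == 0.0:
        return 4.0 * math.pi * r_star**2
    z_theta = _angular_partition_1d(scheme.theta0, k, beta, conv,
                                    periodic=False, jacobian_sin=True)
    z_phi = _angular_partition_1d(scheme.phi0, k, beta, conv,
                                  periodic=True, jacobian_sin=False)
    return r_star**2 * z_theta * z_phi


def standard_state_term(i_star: float, s_star: float, temperature: float = 300.0) -> float:
    """Separation term -kT ln(I* S* C0) in kcal/mol (C0 = 1/1660.6 A^-3)."""
    if i_star <= 0 or s_star <= 0:
        raise ValueError("I* and S* must be positive")
    return -kbt(temperature) * math.log(i_star * s_star / STANDARD_VOLUME)


def conformational_release(
    windows_on_rmsd: UmbrellaWindowSet,
    bound_region: tuple[float, float],
    temperature: float | None = None,
    bin_width: float = 0.1,
    **wham_kwargs,
) -> FreeEnergyEstimate:
    """Free energy of confining the conformation to ``bound_region``.

    Builds the RMSD-coordinate PMF by WHAM and returns
    -kT ln( Z[bound_region] / Z[full profile] ), a non-negative release
    cost, with the error propagated from the per-bin profile errors.
    """
    lo, hi = bound_region
    if lo < 0:
        raise ValueError("RMSD coordinate is non-negative")
    pmf = wham_1d(windows_on_rmsd, bin_width=bin_width, **wham_kwargs)
    T = temperature if temperature is not None else windows_on_rmsd.temperature
    beta = 1.0 / kbt(T)
    r = pmf.bin_centers
    boltz = np.exp(-beta * pmf.free_energy)
    z_full = np.trapezoid(boltz, r)
    mask = (r >= lo) & (r <= hi)
    if mask.sum() < 2:
        raise ValueError("bound region covers fewer than two profile bins")
    z_bound = np.trapezoid(boltz[mask], r[mask])
    value = -kbt(T) * math.log(z_bound / z_full)

    # first-order propagation of per-bin errors through both integrals
    w_full = boltz * np.gradient(r) / z_full
    w_bound = np.where(mask, boltz * np.gradient(r), 0.0) / z_bound
    dvdg = w_bound - w_full   # d(value)/dG_j in units of the bin errors
    var = float(np.sum((dvdg * pmf.stderr) ** 2))
    return FreeEnergyEstimate(value=float(value), stderr=math.sqrt(var),
                              method="WHAM", diagnostics={"n_bins": len(r)})


def single_step_release(
    site_samples: np.ndarray,
    temperature: float = 300.0,
    du_reverse: np.ndarray | None = None,
    ess_fraction_threshold: float = 0.01,
    strict: bool = False,
) -> FreeEnergyEstimate:
    """Free energy of switching a restraint on, from unrestrained samples.

    ``site_samples`` holds the restraint energy u evaluated on samples of
    the unrestrained target ensemble; the estimate is the exponential
    average -kT ln <exp(-beta u)> with block-averaged error.  When
    ``du_reverse`` (i.e. -u evaluated on restrained samples) is supplied
    the two-sided BAR estimate is used instead.
    """
    u = np.asarray(site_samples, dtype=float).ravel()
    if len(u) == 0:
        raise ValueError("restraint-energy series must be non-empty")
    if du_reverse is not None:
        return bar(u, np.asarray(du_reverse, dtype=float), temperature)
    est = exponential_averaging(u, temperature)
    ess = est.diagnostics["ess"]
    if ess < ess_fraction_threshold * len(u):
        msg = (f"single-step release unreliable: effective sample size {ess:.1f} "
               f"of {len(u)} samples")
        if strict:
            raise RuntimeError(msg)
        import warnings
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return est


def assemble_binding_free_energy(ledger: FreeEnergyLedger) -> tuple[float, float]:
    """Signed sum of all eight ledger terms and its RSS standard error."""
    total = 0.0
    var = 0.0
    for name, sign in LEDGER_TERMS.items():
        value, stderr = ledger.get(name)
        total += sign * value
        var += stderr * stderr
    return total, math.sqrt(var)


def bulk_to_site_deltas(ledger: FreeEnergyLedger) -> dict[str, tuple[float, float]]:
    """Bulk-minus-site restraint deltas ddG_x^{B->S} = dG_x^B - dG_x^S."""
    out = {}
    for x in ("p", "n", "o"):
        vb, eb = ledger.get(f"dG_{x}_B")
        vs, es = ledger.get(f"dG_{x}_S")
        out[f"ddG_{x}_BS"] = (vb - vs, math.hypot(eb, es))
    return out
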