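"""Fits and change-point extraction over order-parameter profiles.

Covers the generalized logistic transition fit, the log-exp closest
contact fit, the three-increasing-windows boundary rule for the onset
distance Xi, the Debye-Hueckel tail fit of the long-range PMF, and the
salt-dependence regression dG_b vs log[NaCl] with its inverse
interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .constants import DEBYE_PREFACTOR, kbt
from .estimators import PmfProfile
from .order_params import OrderParameterProfile

__all__ = [
    "FitResult",
    "SaltSeries",
    "FitError",
    "fit_generalized_logistic",
    "fit_contact_decay",
    "extract_boundary",
    "debye_huckel_fit",
    "salt_dependence_regression",
    "interpolate_concentration",
]


class FitError(RuntimeError):
    """All fit starts failed to converge."""


@dataclass
class FitResult:
    model: str
    parameters: dict[str, float]
    residual_rms: float
    covariance: np.ndarray | None = None
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual RMS must be >= 0")
        if self.converged and not all(np.isfinite(v) for v in self.parameters.values()):
            raise ValueError("converged fit must have finite parameters")

    def predict(self, x):
        x = np.asarray(x, float)
        p = self.parameters
        if self.model == "generalized_logistic":
            return _glogistic(x, p["A"], p["K"], p["B"], p["M"], p["nu"])
        if self.model == "contact_decay":
            return _contact_decay(x, p["a"], p["b"], p.get("c", 1.0), p["d"], p.get("e", 1.0))
        if self.model == "debye_huckel":
            return p["A"] * np.exp(-p["kappa"] * x) / x + p["offset"]
        raise ValueError(f"no predictor for model {self.model!r}")


@dataclass
class SaltSeries:
    """dG_b values across NaCl concentrations (mM)."""

    concentrations_mM: np.ndarray
    dG: np.ndarray
    stderr: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations_mM = np.asarray(self.concentrations_mM, float)
        self.dG = np.asarray(self.dG, float)
        if len(self.concentrations_mM) < 2:
            raise ValueError("need at least two concentrations")
        if np.any(self.concentrations_mM <= 0):
            raise ValueError("concentrations must be positive")
        if len(set(self.concentrations_mM.tolist())) != len(self.concentrations_mM):
            raise ValueError("concentrations must be distinct")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, float)


def _glogistic(x, A, K, B, M, nu):
    z = np.clip(-B * (x - M), -500, 500)
    # (1+e^z)^(-1/nu) computed in log space to avoid overflow
    return A + (K - A) * np.exp(-np.logaddexp(0.0, z) / nu)


def _contact_decay(x, a, b, c, d, e):
    # a + b*log(c*exp(x-d) + e), computed stably for large x-d
    t = np.asarray(x, float) - d
    inner = np.logaddexp(np.log(max(c, 1e-300)) + t, math.log(max(e, 1e-300)))
    return a + b * inner


def _multistart_fit(residual_fn, starts, bounds, x_scale=None):
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual_fn, p0, bounds=bounds, method="trf",
                                x_scale=x_scale or "jac", max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("no fit start converged")
    return best


def _covariance_from_jac(res, n_points):
    m = len(res.fun)
    n = len(res.x)
    if m <= n:
        return None
    dof = m - n
    s2 = 2 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        return s2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:
        return None


def fit_generalized_logistic(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    n_starts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Fit y = A + (K-A)/(1+exp(-B(x-M)))^(1/nu) by seeded multi-start.

    The five-parameter family is multimodal; ``n_starts`` random
    initializations drawn within the data range are tried and the lowest
    cost solution returned.  nu is kept positive by bounds.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 6:
        raise ValueError("need at least 6 points")
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    span = max(y.max() - y.min(), 1e-12)
    xspan = max(x.max() - x.min(), 1e-12)

    flags = []
    if span < 1e-10 * max(abs(y).max(), 1.0) or np.allclose(y, y[0]):
        flags.append("degenerate: constant data, A ~ K")
        return FitResult("generalized_logistic",
                         {"A": float(y.mean()), "K": float(y.mean()),
                          "B": 0.0, "M": float(x.mean()), "nu": 1.0},
                         residual_rms=float(np.sqrt(np.mean((y - y.mean())**2))),
                         converged=True, flags=flags)

    def residual(p):
        return (_glogistic(x, *p) - y) * w

    rng = np.random.default_rng(seed)
    starts = [[y.min(), y.max(), 4.0 / xspan, x.mean(), 1.0]]
    for _ in range(n_starts - 1):
        starts.append([
            y.min() + span * rng.uniform(-0.2, 0.2),
            y.max() + span * rng.uniform(-0.2, 0.2),
            rng.uniform(0.5, 20.0) / xspan * rng.choice([-1, 1]),
            rng.uniform(x.min(), x.max()),
            rng.uniform(0.3, 3.0),
        ])
    lo = [y.min() - 2 * span, y.min() - 2 * span, -1e3 / xspan, x.min() - xspan, 1e-3]
    hi = [y.max() + 2 * span, y.max() + 2 * span, 1e3 / xspan, x.max() + xspan, 1e3]
    best = _multistart_fit(residual, starts, (lo, hi))
    names = ("A", "K", "B", "M", "nu")
    params = dict(zip(names, (float(v) for v in best.x)))
    rms = float(np.sqrt(np.mean((best.fun / w) ** 2)))
    return FitResult("generalized_logistic", params, rms,
                     covariance=_covariance_from_jac(best, len(x)),
                     converged=True, flags=flags)


def fit_contact_decay(
    x: np.ndarray,
    y: np.ndarray,
    parameters: str = "canonical",
    n_starts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Fit the closest-contact curve f(x) = a + b log(c exp(x-d) + e).

    The 5-parameter family carries a two-dimensional gauge freedom —
    (c, d) -> (c e^s, d + s) and (a, d, e) -> (a - b s, d - s, e e^s)
    leave the curve unchanged — so by default the canonical gauge
    ``c = e = 1`` is fitted (parameters a, b, d; fully identifiable).
    ``parameters="full"`` fits all five with bounds and flags boundary
    parameters.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 6:
        raise ValueError("need at least 6 points")
    slope_guess = (y[-1] - y[0]) / max(x[-1] - x[0], 1e-12)
    rng = np.random.default_rng(seed)
    flags = []
    if parameters == "canonical":
        def residual(p):
            a, b, d = p
            return _contact_decay(x, a, b, 1.0, d, 1.0) - y
        starts = [[y.min(), max(slope_guess, 0.1), x.mean()]]
        for _ in range(n_starts - 1):
            starts.append([y.min() + rng.normal(0, 1),
                           abs(slope_guess) * rng.uniform(0.3, 3.0) + 0.01,
                           rng.uniform(x.min(), x.max())])
        lo = [-np.inf, 1e-8, x.min() - 5 * (x.max() - x.min())]
        hi = [np.inf, np.inf, x.max() + 5 * (x.max() - x.min())]
        best = _multistart_fit(residual, starts, (lo, hi))
        a, b, d = best.x
        params = {"a": float(a), "b": float(b), "c": 1.0, "d": float(d), "e": 1.0}
    elif parameters == "full":
        def residual(p):
            return _contact_decay(x, *p) - y
        starts = [[y.min(), max(slope_guess, 0.1), 1.0, x.mean(), 1.0]]
        for _ in range(n_starts - 1):
            starts.append([y.min() + rng.normal(0, 1),
                           abs(slope_guess) * rng.uniform(0.3, 3.0) + 0.01,
                           rng.uniform(0.2, 5.0), rng.uniform(x.min(), x.max()),
                           rng.uniform(0.05, 5.0)])
        e_floor = 1e-8
        lo = [-np.inf, 1e-8, 1e-8, x.min() - 5 * (x.max() - x.min()), e_floor]
        hi = [np.inf, np.inf, np.inf, x.max() + 5 * (x.max() - x.min()), np.inf]
        best = _multistart_fit(residual, starts, (lo, hi))
        names = ("a", "b", "c", "d", "e")
        params = dict(zip(names, (float(v) for v in best.x)))
        if params["e"] <= 10 * e_floor:
            flags.append("boundary: e at lower bound (left asymptote unidentified)")
        flags.append("gauge: (c,d) and (a,d,e) families are degenerate; "
                     "compare invariants, not raw parameters")
    else:
        raise ValueError("parameters must be 'canonical' or 'full'")
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    return FitResult("contact_decay", params, rms,
                     covariance=_covariance_from_jac(best, len(x)),
                     converged=True, flags=flags)


def extract_boundary(
    profile: OrderParameterProfile,
    epsilon: float = 0.01,
) -> float | None:
    """Onset distance Xi by the three-increasing-windows rule.

    Scanning from the largest window center toward smaller r, find the
    first run of three consecutive windows whose statistic each exceeds
    its larger-r predecessor by more than ``epsilon``; return the middle
    window's center.  Returns ``None`` (not an error) when no such run
    exists.
    """
    if len(profile.centers) < 4:
        raise ValueError("need at least four windows (three increases)")
    # order from largest r to smallest
    r = profile.centers[::-1]
    v = profile.values[::-1]
    increases = v[1:] > v[:-1] + epsilon   # increase at window i+1 vs predecessor
    for i in range(len(increases) - 2):
        if increases[i] and increases[i + 1] and increases[i + 2]:
            # windows i+1, i+2, i+3 are the three increasing columns
            return float(r[i + 2])
    return None


def debye_huckel_fit(
    pmf: PmfProfile,
    r_min: float = 20.0,
    ionic_strength: float | None = None,
    temperature: float | None = None,
) -> FitResult:
    """Fit the PMF tail (r >= r_min) to W(r) = A exp(-kappa r)/r + w0.

    When ``ionic_strength`` (mol/L) is given, the theoretical screening
    constant kappa_DH = sqrt(I)/3.04 1/A for a 1:1 electrolyte near 300 K
    is reported alongside the fitted kappa.
    """
    mask = pmf.bin_centers >= r_min
    x = pmf.bin_centers[mask]
    y = pmf.free_energy[mask]
    if len(x) < 4:
        raise ValueError("too few tail points beyond r_min")
    flags = []
    yspan = y.max() - y.min()
    if yspan < 1e-10:
        flags.append("flat tail: kappa unidentifiable")
        params = {"A": 0.0, "kappa": 0.0, "offset": float(y.mean())}
        return FitResult("debye_huckel", params, residual_rms=0.0,
                         converged=True, flags=flags)

    def residual(p):
        a, kappa, w0 = p
        return a * np.exp(-kappa * x) / x + w0 - y

    a0 = (y[0] - y[-1]) * x[0] * math.exp(0.05 * x[0])
    starts = [[a0, 0.05, y[-1]], [a0, 0.1, y[-1]], [-a0, 0.1, y[-1]],
              [a0 * 10, 0.2, y[-1]], [a0 / 10, 0.02, y[-1]]]
    best = _multistart_fit(residual, starts,
                           ([-np.inf, 1e-6, -np.inf], [np.inf, 2.0, np.inf]))
    params = {"A": float(best.x[0]), "kappa": float(best.x[1]), "offset": float(best.x[2])}
    if ionic_strength is not None:
        params["kappa_DH_theory"] = math.sqrt(ionic_strength) / DEBYE_PREFACTOR
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    if abs(params["A"]) < 1e-6 * max(abs(y).max(), 1.0):
        flags.append("A ~ 0: kappa unidentifiable")
    return FitResult("debye_huckel", params, rms,
                     covariance=_covariance_from_jac(best, len(x)),
                     converged=True, flags=flags)


_LOG_BASES = {"natural": 1.0, "decadic": math.log(10.0)}


def salt_dependence_regression(
    series: SaltSeries,
    log_base: str = "natural",
) -> tuple[float, float]:
    """OLS slope of dG_b against log concentration (in mol/L).

    Returns (slope, stderr) in kcal/mol per log unit of the chosen base.
    The natural base reproduces printed salt-dependence values; decadic
    slope = natural slope * ln 10.
    """
    if log_base not in _LOG_BASES:
        raise ValueError("log_base must be 'natural' or 'decadic'")
    x = np.log(series.concentrations_mM / 1000.0) / _LOG_BASES[log_base]
    fit = linregress(x, series.dG)
    return float(fit.slope), float(fit.stderr)


def interpolate_concentration(
    series: SaltSeries,
    target_dG: float,
    log_base: str = "natural",
) -> float:
    """Invert the fitted salt-dependence line at ``target_dG``; result in mM."""
    if log_base not in _LOG_BASES:
        raise ValueError("log_base must be 'natural' or 'decadic'")
    scale = _LOG_BASES[log_base]
    x = np.log(series.concentrations_mM / 1000.0) / scale
    fit = linregress(x, series.dG)
    if fit.slope == 0:
        raise ZeroDivisionError("zero regression slope: cannot invert")
    x_target = (target_dG - fit.intercept) / fit.slope
    return float(math.exp(x_target * scale) * 1000.0)
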