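"""Free-energy estimators over biased sample sets.

Implements 1-D WHAM over umbrella windows with shared global histogram
edges, the Bennett acceptance ratio (BAR) and its multistate extension
(mBAR), plain exponential averaging, block-averaged standard errors, a
Bhattacharyya histogram-overlap diagnostic, and the separation integral
I* that feeds the standard-state term of the binding free energy.

WHAM solves the usual self-consistent equations

    p_j  propto  H_j / sum_i N_i exp(beta (f_i - u_i(x_j)))
    exp(-beta f_i) = sum_j p_j exp(-beta u_i(x_j))

on a shared bin grid; iteration stops when the largest change in any
window free energy f_i falls below ``tol`` (kcal/mol).  Per-bin standard
errors come from repeating WHAM on block-split windows (block count 10
by default), matching the block-averaging error protocol used for the
window series themselves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

from .constants import kbt
from .core import UmbrellaWindowSet

__all__ = [
    "PmfProfile",
    "FreeEnergyEstimate",
    "ConvergenceError",
    "DisconnectedWindowsError",
    "wham_1d",
    "bar",
    "mbar",
    "exponential_averaging",
    "block_error",
    "histogram_overlap",
    "pmf_to_I_star",
]


class ConvergenceError(RuntimeError):
    """Self-consistent iteration failed to converge within max_iter."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DisconnectedWindowsError(ValueError):
    """Adjacent umbrella windows have zero histogram overlap."""


@dataclass
class PmfProfile:
    """A 1-D free-energy profile, normalized so that min(G) = 0."""

    bin_centers: np.ndarray
    free_energy: np.ndarray       # kcal/mol
    stderr: np.ndarray            # kcal/mol
    temperature: float
    #: optional per-block profiles (same grid) behind the error estimate
    block_profiles: list | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if not (len(self.bin_centers) == len(self.free_energy) == len(self.stderr)):
            raise ValueError("profile arrays must have equal length")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.stderr < 0):
            raise ValueError("per-bin standard errors must be >= 0")
        finite = np.isfinite(self.free_energy)
        if finite.any():
            self.free_energy = self.free_energy - np.nanmin(self.free_energy[finite])

    def interp(self, x: float) -> float:
        """Linear interpolation of the free energy at x (kcal/mol)."""
        if x < self.bin_centers[0] or x > self.bin_centers[-1]:
            raise ValueError(f"x={x} outside profile range")
        return float(np.interp(x, self.bin_centers, self.free_energy))


@dataclass
class FreeEnergyEstimate:
    value: float                 # kcal/mol
    stderr: float                # kcal/mol
    method: str                  # WHAM | BAR | mBAR | EXP
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


def _bias_matrix(windows: UmbrellaWindowSet, bin_centers: np.ndarray) -> np.ndarray:
    """u[i, j] = bias energy of window i at bin center j (kcal/mol)."""
    return np.array([w.bias.energy(bin_centers) for w in windows.windows])


def _wham_solve(
    counts: np.ndarray,       # (n_windows, n_bins) histogram counts
    n_i: np.ndarray,          # (n_windows,) samples per window
    u_ij: np.ndarray,         # (n_windows, n_bins) bias energies
    beta: float,
    tol_energy: float,
    max_iter: int,
) -> np.ndarray:
    """Return -kT ln p_j (unnormalized) for occupied bins; NaN where empty."""
    h_j = counts.sum(axis=0)
    occupied = h_j > 0
    boltz = np.exp(-beta * u_ij[:, occupied])       # (K, B_occ)
    h = h_j[occupied].astype(float)
    f = np.zeros(len(n_i))
    for _ in range(max_iter):
        denom = (n_i * np.exp(beta * f)) @ boltz     # (B_occ,)
        p = h / denom
        z = boltz @ p                                # (K,)
        f_new = -np.log(z) / beta
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol_energy:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations", residual=delta)
    denom = (n_i * np.exp(beta * f)) @ boltz
    p = h / denom
    g = np.full(counts.shape[1], np.nan)
    g[occupied] = -np.log(p) / beta
    return g


def wham_1d(
    windows: UmbrellaWindowSet,
    bin_width: float = 0.1,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    n_error_blocks: int = 10,
    check_overlap: bool = True,
) -> PmfProfile:
    """Unbias umbrella windows into a single PMF by 1-D WHAM.

    Bins share global edges spanning all window samples.  ``tol`` is the
    convergence threshold on window free energies in kcal/mol.  Errors
    come from ``n_error_blocks`` block-split WHAM repeats (0 disables).
    """
    T = windows.temperature
    beta = 1.0 / kbt(T)
    all_samples = np.concatenate([w.samples for w in windows.windows])
    lo, hi = all_samples.min(), all_samples.max()
    n_bins = max(int(math.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # include right-most sample
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows.windows])
    if check_overlap and len(windows.windows) > 1:
        for i in range(len(windows.windows) - 1):
            if not np.any((counts[i] > 0) & (counts[i + 1] > 0)):
                raise DisconnectedWindowsError(
                    f"windows {i} and {i + 1} (centers "
                    f"{windows.windows[i].bias.center}, "
                    f"{windows.windows[i + 1].bias.center}) share no occupied bins")

    n_i = np.array([len(w.samples) for w in windows.windows], dtype=float)
    u_ij = _bias_matrix(windows, centers)
    g = _wham_solve(counts, n_i, u_ij, beta, tol, max_iter)

    stderr = np.zeros_like(g)
    block_g = []
    if n_error_blocks and n_error_blocks > 1:
        for b in range(n_error_blocks):
            bcounts = []
            bn = []
            for w in windows.windows:
                n = len(w.samples)
                size = n // n_error_blocks
                if size == 0:
                    raise ValueError("window too short for requested error blocks")
                chunk = w.samples[b * size:(b + 1) * size]
                bcounts.append(np.histogram(chunk, bins=edges)[0])
                bn.append(size)
            try:
                gb = _wham_solve(np.array(bcounts), np.array(bn, dtype=float),
                                 u_ij, beta, tol * 10, max_iter)
            except ConvergenceError:
                continue
            finite = np.isfinite(gb)
            if finite.any():
                gb = gb - np.nanmin(gb[finite])
            block_g.append(gb)
        if len(block_g) >= 2:
            stack = np.array(block_g)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                stderr = np.nanstd(stack, axis=0, ddof=1) / math.sqrt(len(block_g))
            stderr = np.where(np.isfinite(stderr), stderr, 0.0)

    keep = np.isfinite(g)
    blocks = None
    if block_g:
        blocks = []
        for gb in block_g:
            keep_b = keep & np.isfinite(gb)
            if keep_b.sum() < 2:
                continue
            blocks.append(PmfProfile(centers[keep_b], gb[keep_b],
                                     np.zeros(int(keep_b.sum())), T))
    return PmfProfile(
        bin_centers=centers[keep],
        free_energy=g[keep],
        stderr=stderr[keep],
        temperature=T,
        block_profiles=blocks,
    )


def _fermi(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))


def bar(
    du_forward: np.ndarray,
    du_reverse: np.ndarray,
    temperature: float = 300.0,
    tol: float = 1e-12,
) -> FreeEnergyEstimate:
    """Bennett acceptance ratio free-energy difference between two states.

    ``du_forward`` holds U2-U1 evaluated on samples from state 1 and
    ``du_reverse`` holds U1-U2 evaluated on samples from state 2, both in
    kcal/mol.  Solves the Bennett self-consistency for dF = F2-F1 and
    reports the standard asymptotic variance.
    """
    du_f = np.asarray(du_forward, dtype=float).ravel()
    du_r = np.asarray(du_reverse, dtype=float).ravel()
    if len(du_f) == 0 or len(du_r) == 0:
        raise ValueError("both work-value series must be non-empty")
    kT = kbt(temperature)
    beta = 1.0 / kT
    n_f, n_r = len(du_f), len(du_r)
    log_ratio = math.log(n_f / n_r)

    def residual(df):
        # Bennett: sum_F fermi(ln(nF/nR) + beta(duF - df)) =
        #          sum_R fermi(-ln(nF/nR) + beta(duR + df))
        lhs = _fermi(log_ratio + beta * (du_f - df)).sum()
        rhs = _fermi(-log_ratio + beta * (du_r + df)).sum()
        return lhs - rhs

    # bracket around the EXP estimates from both directions
    with np.errstate(over="ignore"):
        guess_f = -kT * (np.log(np.mean(np.exp(-beta * (du_f - du_f.min())))) - beta * du_f.min())
        guess_r = kT * (np.log(np.mean(np.exp(-beta * (du_r - du_r.min())))) - beta * du_r.min())
    lo = min(guess_f, guess_r, float(du_f.mean()), float(-du_r.mean())) - 1.0
    hi = max(guess_f, guess_r, float(du_f.mean()), float(-du_r.mean())) + 1.0
    for _ in range(60):
        if residual(lo) * residual(hi) <= 0:
            break
        span = hi - lo
        lo -= span
        hi += span
    else:
        raise ConvergenceError("BAR: could not bracket the Bennett root",
                               residual=residual(0.0))
    if residual(lo) == 0.0:
        df = lo
    elif residual(hi) == 0.0:
        df = hi
    else:
        df = brentq(residual, lo, hi, xtol=tol)

    # asymptotic variance (Bennett 1976)
    f_f = _fermi(log_ratio + beta * (du_f - df))
    f_r = _fermi(-log_ratio + beta * (du_r + df))
    var = 0.0
    for f_vals, n in ((f_f, n_f), (f_r, n_r)):
        m = f_vals.mean()
        if m > 0:
            var += (np.mean(f_vals**2) / m**2 - 1.0) / n
    stderr = kT * math.sqrt(max(var, 0.0))
    overlap = float(min(f_f.mean(), f_r.mean()))
    return FreeEnergyEstimate(value=float(df), stderr=stderr, method="BAR",
                              diagnostics={"overlap": overlap})


def exponential_averaging(
    du: np.ndarray,
    temperature: float = 300.0,
) -> FreeEnergyEstimate:
    """One-sided free-energy perturbation: dF = -kT ln <exp(-beta dU)>.

    The standard error is from block averaging (10 blocks) of the
    per-block free-energy estimates.
    """
    du = np.asarray(du, dtype=float).ravel()
    if len(du) == 0:
        raise ValueError("work-value series must be non-empty")
    kT = kbt(temperature)
    beta = 1.0 / kT

    def fep(vals):
        shift = vals.min()
        return shift - kT * math.log(np.mean(np.exp(-beta * (vals - shift))))

    value = fep(du)
    n_blocks = 10
    if len(du) >= n_blocks:
        size = len(du) // n_blocks
        blocks = [fep(du[b * size:(b + 1) * size]) for b in range(n_blocks)]
        stderr = float(np.std(blocks, ddof=1) / math.sqrt(n_blocks))
    else:
        stderr = 0.0
    w = np.exp(-beta * (du - du.min()))
    ess = float(w.sum() ** 2 / np.sum(w**2))
    return FreeEnergyEstimate(value=float(value), stderr=stderr, method="EXP",
                              diagnostics={"ess": ess, "n": len(du)})


def mbar(
    reduced_potentials: np.ndarray,
    counts: np.ndarray,
    tol: float = 1e-12,
    temperature: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multistate Bennett acceptance ratio free energies.

    Parameters
    ----------
    reduced_potentials
        (K, N) matrix: u[k, n] = beta * U_k(x_n) for all N pooled samples
        (dimensionless).  If ``temperature`` is given the matrix is taken
        in kcal/mol instead and reduced internally, and the returned free
        energies/covariance are in kcal/mol.
    counts
        Per-state sample counts, summing to N.

    Returns
    -------
    (f_k, covariance) with the first state pinned to zero.
    """
    u_kn = np.asarray(reduced_potentials, dtype=float)
    n_k = np.asarray(counts, dtype=float)
    if u_kn.ndim != 2:
        raise ValueError("reduced_potentials must be a K x N matrix")
    K, N = u_kn.shape
    if len(n_k) != K or int(n_k.sum()) != N:
        raise ValueError("counts must have length K and sum to N")
    if not np.all(np.isfinite(u_kn)):
        raise ValueError("reduced potential matrix must be finite")
    kT = kbt(temperature) if temperature is not None else 1.0
    if temperature is not None:
        u_kn = u_kn / kT

    sampled = n_k > 0
    u_s = u_kn[sampled]
    n_s = n_k[sampled]
    log_n_s = np.log(n_s)

    def objective(f):
        # Convex MBAR objective (up to constants); gradient is the SCF residual.
        a = f[:, None] + log_n_s[:, None] - u_s         # (K_s, N)
        lse = _logsumexp(a, axis=0)                     # (N,)
        val = lse.sum() - float(n_s @ f)
        w = np.exp(a - lse)
        grad = w.sum(axis=1) - n_s
        return val, grad

    f0 = np.zeros(int(sampled.sum()))
    res = minimize(objective, f0, jac=True, method="L-BFGS-B",
                   options={"ftol": 1e-15, "gtol": tol * max(N, 1), "maxiter": 10_000})
    f_s = res.x
    _, grad = objective(f_s)
    if np.max(np.abs(grad)) > 1e-6 * N:
        raise ConvergenceError("mBAR failed to converge",
                               residual=float(np.max(np.abs(grad))))
    # free energies of all states (incl. unsampled) by reweighting against
    # the converged mixture denominator
    log_denom = _logsumexp(f_s[:, None] + log_n_s[:, None] - u_s, axis=0)
    f = -_logsumexp(-u_kn - log_denom[None, :], axis=1)
    f = f - f[0]

    # asymptotic covariance from the weight matrix (MBAR, Shirts & Chodera)
    log_denom = _logsumexp(f[sampled][:, None] + log_n_s[:, None]
                           - u_kn[sampled], axis=0)
    w = np.exp(-u_kn + f[:, None] - log_denom[None, :])  # W^T rows ~ states
    wt = w.T                                            # (N, K)
    try:
        theta = _mbar_covariance(wt, n_k)
    except np.linalg.LinAlgError:
        theta = np.full((K, K), np.nan)
    # covariance of differences relative to state 0
    cov = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            cov[i, j] = theta[i, j] - theta[i, 0] - theta[0, j] + theta[0, 0]
    return f * kT, cov * kT * kT


def _mbar_covariance(wt: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """Asymptotic MBAR covariance Theta = V S (I - S V^T N V S)^+ S V^T.

    ``wt`` is the N x K weight matrix with columns summing to one.
    """
    u, s, vt = np.linalg.svd(wt, full_matrices=False)
    v = vt.T
    s_mat = np.diag(s)
    inner = np.eye(len(s)) - s_mat @ vt @ np.diag(n_k) @ v @ s_mat
    core = np.linalg.pinv(inner, rcond=1e-10)
    return v @ s_mat @ core @ s_mat @ vt


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    amax = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis=axis)
    return out


def block_error(series: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean from block averaging.

    The series is split into ``n_blocks`` equal blocks (trailing
    remainder discarded); the result is stdev(block means)/sqrt(n_blocks)
    with the sample (ddof=1) standard deviation.
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} shorter than {n_blocks} blocks")
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    size = len(x) // n_blocks
    means = x[: size * n_blocks].reshape(n_blocks, size).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_blocks))


def histogram_overlap(windows: UmbrellaWindowSet, n_bins: int = 50) -> np.ndarray:
    """Bhattacharyya overlap of adjacent window histograms, each in [0, 1]."""
    if len(windows.windows) < 2:
        raise ValueError("need at least two windows")
    all_samples = np.concatenate([w.samples for w in windows.windows])
    edges = np.linspace(all_samples.min(), all_samples.max(), n_bins + 1)
    probs = []
    for w in windows.windows:
        h = np.histogram(w.samples, bins=edges)[0].astype(float)
        probs.append(h / h.sum())
    out = np.empty(len(probs) - 1)
    for i in range(len(probs) - 1):
        out[i] = np.sum(np.sqrt(probs[i] * probs[i + 1]))
    return np.clip(out, 0.0, 1.0)


def pmf_to_I_star(
    pmf: PmfProfile,
    site_range: tuple[float, float],
    r_ref: float,
) -> float:
    """Separation integral I* = int_site exp(-beta [W(r)-W(r_ref)]) dr (A).

    Trapezoid rule on the profile grid restricted to ``site_range``,
    with the endpoints included by interpolation.
    """
    lo, hi = site_range
    if lo >= hi:
        raise ValueError("site_range must be (r_min, r_max) with r_min < r_max")
    r = pmf.bin_centers
    if lo < r[0] or hi > r[-1]:
        raise ValueError("site_range outside profile support")
    if r_ref < r[0] or r_ref > r[-1]:
        raise ValueError("r_ref outside profile support")
    beta = 1.0 / kbt(pmf.temperature)
    w_ref = pmf.interp(r_ref)
    inside = (r > lo) & (r < hi)
    grid = np.concatenate([[lo], r[inside], [hi]])
    w_grid = np.concatenate([
        [pmf.interp(lo)], pmf.free_energy[inside], [pmf.interp(hi)]])
    integrand = np.exp(-beta * (w_grid - w_ref))
    return float(np.trapezoid(integrand, grid))
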