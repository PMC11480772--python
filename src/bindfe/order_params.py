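"""Structural order parameters along the association coordinate.

Per-frame statistics (closest contacts, dipole projections, native
contacts, hydrogen bonds, RMSD variants, helicity) and their
distributional summaries (orientation-angle histograms and the total
variation distance between a window ensemble and a bulk reference) are
computed here and tabulated against the center-of-mass separation as
:class:`OrderParameterProfile` objects.

The total variation statistic follows the un-halved convention
D_TV = sum_bins |P - P_ref|, which ranges from 0 (bulk-like) to 2
(disjoint ensembles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import (AtomSelection, GeometryError, RestraintScheme, Topology,
                   Trajectory, center_of_mass, dihedral_angle)

__all__ = [
    "OrderParameterProfile",
    "AngleDistribution",
    "mean_closest_contact",
    "contact_frequency",
    "closest_contact_series",
    "dipole_moment",
    "dipole_projection_profile",
    "orientation_angles",
    "total_variation_distance",
    "native_contacts_q",
    "hydrogen_bonds_per_residue",
    "rmsd",
    "orientational_rmsd",
    "helicity",
    "profile_over_windows",
]


@dataclass
class OrderParameterProfile:
    """A scalar statistic tabulated against window centers (Angstrom)."""

    centers: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    statistic: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if not (len(self.centers) == len(self.values) == len(self.stderr)):
            raise ValueError("profile arrays must be aligned")
        if len(self.centers) > 1 and np.any(np.diff(self.centers) <= 0):
            raise ValueError("profile centers must be strictly monotone increasing")


@dataclass
class AngleDistribution:
    """Normalized histogram of an angle over shared bin edges."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    count: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ValueError("need len(edges) = len(probabilities) + 1")
        if np.any(self.probabilities < -1e-12):
            raise ValueError("probabilities must be non-negative")
        total = self.probabilities.sum()
        if self.count > 0 and not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError("probabilities must sum to 1")


def closest_contact_series(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
) -> np.ndarray:
    """Per-frame minimum inter-selection atom distance r_cc(t), Angstrom."""
    if traj.n_frames == 0:
        raise ValueError("trajectory is empty")
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("both selections must be non-empty")
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        d = cdist(traj.frames[t][sel_a.indices], traj.frames[t][sel_b.indices])
        out[t] = d.min()
    return out


def mean_closest_contact(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    error_mode: str = "stdev",
) -> tuple[float, float]:
    """Time mean and spread of the closest-contact distance.

    ``error_mode="stdev"`` (default) returns the population standard
    deviation of r_cc(t); ``"sem"`` returns the standard error of the
    mean instead.
    """
    rcc = closest_contact_series(traj, sel_a, sel_b)
    spread = float(np.std(rcc))
    if error_mode == "sem":
        spread /= math.sqrt(len(rcc))
    elif error_mode != "stdev":
        raise ValueError("error_mode must be 'stdev' or 'sem'")
    return float(rcc.mean()), spread


def contact_frequency(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff: float = 4.0,
) -> float:
    """Fraction of frames whose closest contact is within ``cutoff``."""
    rcc = closest_contact_series(traj, sel_a, sel_b)
    return float(np.mean(rcc <= cutoff))


def dipole_moment(
    frame: np.ndarray,
    sel: AtomSelection,
    topology: Topology,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Dipole vector sum q_i (x_i - origin) in e*Angstrom.

    For a net-charged group the dipole depends on the origin; the default
    origin is the selection's center of mass, matching the convention of
    steering the separation by the center of mass.
    """
    if len(sel) == 0:
        raise ValueError("selection must be non-empty")
    q = topology.charge[sel.indices]
    if not np.all(np.isfinite(q)):
        raise ValueError("charges missing or non-finite")
    if origin is None:
        origin = center_of_mass(frame, sel, topology)
    coords = np.asarray(frame, float)[sel.indices]
    return ((coords - np.asarray(origin, float)) * q[:, None]).sum(axis=0)


def dipole_projection_profile(
    traj: Trajectory,
    rna_sel: AtomSelection,
    pep_sel: AtomSelection,
    step: int = 5000,
    window: int = 20000,
    normalized: bool = False,
) -> OrderParameterProfile:
    """Rolling mean of the dipole projection onto the RNA->peptide axis.

    Per frame the projection is d . r_hat (e*A), or d_hat . r_hat when
    ``normalized``; negative values mean the positive end of the peptide
    charge distribution points toward the RNA.  The rolling mean uses a
    sliding window of ``window`` frames advanced by ``step`` frames; the
    profile abscissa is the center frame time of each window.
    """
    if traj.n_frames < window:
        raise ValueError(f"need at least {window} frames, got {traj.n_frames}")
    proj = np.empty(traj.n_frames)
    topo = traj.topology
    for t in range(traj.n_frames):
        frame = traj.frames[t]
        com_r = center_of_mass(frame, rna_sel, topo)
        com_p = center_of_mass(frame, pep_sel, topo)
        axis = com_p - com_r
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise GeometryError("coincident centers of mass")
        axis /= norm
        d = dipole_moment(frame, pep_sel, topo)
        if normalized:
            dn = np.linalg.norm(d)
            if dn == 0:
                raise GeometryError("zero dipole cannot be normalized")
            d = d / dn
        proj[t] = float(d @ axis)
    starts = np.arange(0, traj.n_frames - window + 1, step)
    centers = np.array([traj.frame_times[s:s + window].mean() for s in starts])
    values = np.array([proj[s:s + window].mean() for s in starts])
    stderr = np.array([proj[s:s + window].std(ddof=1) / math.sqrt(window)
                       if window > 1 else 0.0 for s in starts])
    return OrderParameterProfile(centers, values, stderr,
                                 statistic="dipole_projection" + ("_norm" if normalized else ""))


def _peptide_vector(frame, sel, topology, kind):
    coords = np.asarray(frame, float)[sel.indices]
    if kind == "principal_axis":
        com = center_of_mass(frame, sel, topology)
        w = topology.mass[sel.indices]
        x = coords - com
        gyr = (x * w[:, None]).T @ x / w.sum()
        evals, evecs = np.linalg.eigh(gyr)
        return evecs[:, -1]  # long axis = largest gyration eigenvalue
    if kind == "dipole":
        return dipole_moment(frame, sel, topology)
    if kind == "end_to_end":
        return coords[-1] - coords[0]
    raise ValueError(f"unknown vector kind {kind!r}")


def orientation_angles(
    traj: Trajectory,
    sel: AtomSelection,
    vector_kind: str,
    partner_sel: AtomSelection | None = None,
    reference_axis: np.ndarray | None = None,
    n_bins: int = 36,
) -> AngleDistribution:
    """Histogram of the angle between a peptide vector and a reference axis.

    The axis is the peptide->partner center-of-mass vector when
    ``partner_sel`` is given, else the fixed ``reference_axis`` (e.g. the
    lab x axis for a bulk reference ensemble).  Principal-axis angles are
    folded to [0, pi/2] (the axis is headless); dipole and end-to-end
    angles live on [0, pi].  Bin edges always span [0, pi] so that
    measurement and reference share a discretization.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory is empty")
    if (partner_sel is None) == (reference_axis is None):
        raise ValueError("give exactly one of partner_sel or reference_axis")
    topo = traj.topology
    omegas = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.frames[t]
        if partner_sel is not None:
            axis = (center_of_mass(frame, partner_sel, topo)
                    - center_of_mass(frame, sel, topo))
        else:
            axis = np.asarray(reference_axis, float)
        na = np.linalg.norm(axis)
        v = _peptide_vector(frame, sel, topo, vector_kind)
        nv = np.linalg.norm(v)
        if na == 0 or nv == 0:
            raise GeometryError("degenerate (zero-length) vector in orientation angle")
        c = float(np.clip(v @ axis / (na * nv), -1.0, 1.0))
        w = math.acos(c)
        if vector_kind == "principal_axis" and w > math.pi / 2:
            w = math.pi - w
        omegas[t] = w
    edges = np.linspace(0.0, math.pi, n_bins + 1)
    h = np.histogram(omegas, bins=edges)[0].astype(float)
    return AngleDistribution(edges, h / h.sum(), count=traj.n_frames)


def total_variation_distance(p: AngleDistribution, p_ref: AngleDistribution) -> float:
    """D_TV = sum_bins |P - P_ref|, in [0, 2] (un-halved convention)."""
    if len(p.bin_edges) != len(p_ref.bin_edges) or not np.allclose(p.bin_edges, p_ref.bin_edges):
        raise ValueError("distributions must share bin edges")
    return float(np.abs(p.probabilities - p_ref.probabilities).sum())


def _native_pairs(native_frame, sel_a, sel_b, cutoff):
    d0 = cdist(np.asarray(native_frame, float)[sel_a.indices],
               np.asarray(native_frame, float)[sel_b.indices])
    ii, jj = np.nonzero(d0 <= cutoff)
    return ii, jj, d0[ii, jj]


def native_contacts_q(
    frame: np.ndarray,
    native_frame: np.ndarray,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    beta: float = 5.0,
    lam: float = 1.8,
    native_cutoff: float = 4.5,
) -> float:
    """Soft-cutoff fraction of native inter-partner contacts.

    Q = (1/|S|) sum_{(i,j) in S} 1/(1 + exp[beta (r_ij - lam r_ij^0)])
    with S the inter-partner pairs within ``native_cutoff`` in the
    native frame; beta in 1/A sets the sigmoid steepness.
    """
    ii, jj, r0 = _native_pairs(native_frame, sel_a, sel_b, native_cutoff)
    if len(r0) == 0:
        raise ValueError("no native pairs within the cutoff")
    d = cdist(np.asarray(frame, float)[sel_a.indices],
              np.asarray(frame, float)[sel_b.indices])
    r = d[ii, jj]
    return float(np.mean(1.0 / (1.0 + np.exp(np.clip(beta * (r - lam * r0), -500, 500)))))


def hydrogen_bonds_per_residue(
    frame: np.ndarray,
    topology: Topology,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    peptide_sel: AtomSelection,
    d_cut: float = 4.0,
    angle_cut_deg: float = 120.0,
) -> float:
    """Hydrogen bonds per peptide residue in one frame.

    ``donors`` is a list of (donor, hydrogen) atom index pairs and
    ``acceptors`` a list of acceptor indices.  A bond requires
    |D-A| <= d_cut and a D-H...A angle (at the hydrogen) >= angle_cut.
    Each bond is assigned to the peptide residue of its peptide-side
    atom; the count is averaged over all residues in ``peptide_sel``.
    """
    frame = np.asarray(frame, float)
    for d_idx, h_idx in donors:
        if not topology.is_hydrogen[h_idx]:
            raise ValueError(f"donor {d_idx}: attached atom {h_idx} is not a hydrogen")
    pep_atoms = set(int(i) for i in peptide_sel.indices)
    pep_residues = sorted(set(int(topology.residue_index[i]) for i in pep_atoms))
    if not pep_residues:
        raise ValueError("peptide selection is empty")
    counts = dict.fromkeys(pep_residues, 0)
    cos_cut = math.cos(math.radians(angle_cut_deg))
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            da = frame[a_idx] - frame[d_idx]
            if np.linalg.norm(da) > d_cut:
                continue
            hd = frame[d_idx] - frame[h_idx]
            ha = frame[a_idx] - frame[h_idx]
            nh, na_ = np.linalg.norm(hd), np.linalg.norm(ha)
            if nh == 0 or na_ == 0:
                continue
            cosang = float(hd @ ha / (nh * na_))
            if cosang > cos_cut:   # angle smaller than the cutoff
                continue
            pep_atom = d_idx if d_idx in pep_atoms else (a_idx if a_idx in pep_atoms else None)
            if pep_atom is None:
                continue
            counts[int(topology.residue_index[pep_atom])] += 1
    return sum(counts.values()) / len(pep_residues)


def rmsd(
    frame: np.ndarray,
    ref_frame: np.ndarray,
    indices: np.ndarray | None = None,
    fit: bool = True,
    weights: np.ndarray | None = None,
) -> float:
    """Root-mean-square deviation between two coordinate sets, Angstrom.

    With ``fit`` the optimal translation+rotation (Kabsch) is applied
    first; without it the raw coordinate RMSD is returned.
    """
    x = np.asarray(frame, float)
    y = np.asarray(ref_frame, float)
    if indices is not None:
        idx = np.asarray(indices, int)
        x, y = x[idx], y[idx]
    if x.shape != y.shape:
        raise ValueError("atom count mismatch between frame and reference")
    if fit:
        w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
        xc = x - np.average(x, axis=0, weights=w)
        yc = y - np.average(y, axis=0, weights=w)
        rot, _ = Rotation.align_vectors(yc, xc, weights=w)
        x = rot.apply(xc)
        y = yc
    diff = x - y
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def superpose(
    frame: np.ndarray,
    ref_frame: np.ndarray,
    fit_indices: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Rigidly transform ``frame`` so ``fit_indices`` best match the reference."""
    frame = np.asarray(frame, float)
    ref = np.asarray(ref_frame, float)
    idx = np.asarray(fit_indices, int)
    w = np.ones(len(idx)) if weights is None else np.asarray(weights, float)
    mob_c = np.average(frame[idx], axis=0, weights=w)
    ref_c = np.average(ref[idx], axis=0, weights=w)
    rot, _ = Rotation.align_vectors(ref[idx] - ref_c, frame[idx] - mob_c, weights=w)
    return rot.apply(frame - mob_c) + ref_c


def orientational_rmsd(
    traj: Trajectory,
    complex_ref: np.ndarray,
    rna_sel: AtomSelection,
    pep_sel: AtomSelection,
) -> np.ndarray:
    """Per-frame peptide RMSD without rotational alignment of the peptide.

    Each frame is superposed on the reference by fitting the RNA
    selection only; the peptide RMSD is then computed without a second
    fit, so it reports displacement *and* misorientation relative to the
    bound pose.
    """
    if len(rna_sel) == 0 or len(pep_sel) == 0:
        raise ValueError("both selections must be non-empty")
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        moved = superpose(traj.frames[t], complex_ref, rna_sel.indices)
        out[t] = rmsd(moved, complex_ref, indices=pep_sel.indices, fit=False)
    return out


_ALPHA_PHI = (math.radians(-100.0), math.radians(-30.0))
_ALPHA_PSI = (math.radians(-67.0), math.radians(-7.0))


def helicity(traj: Trajectory, min_run: int = 3) -> float:
    """Fraction of residues in alpha-helical runs, averaged over frames.

    A residue is alpha if its backbone (phi, psi) falls in the box
    phi in [-100, -30] deg, psi in [-67, -7] deg, and it belongs to a run
    of at least ``min_run`` consecutive alpha residues.  The fraction is
    over residues with both dihedrals defined (chain interior).
    """
    topo = traj.topology
    residues = sorted(set(int(r) for r in topo.residue_index))
    backbone = {}
    for res in residues:
        entry = {}
        for i in range(topo.n_atoms):
            if int(topo.residue_index[i]) == res:
                nm = str(topo.names[i]).strip()
                if nm in ("N", "CA", "C"):
                    entry[nm] = i
        if not all(k in entry for k in ("N", "CA", "C")):
            raise ValueError(f"residue {res} lacks backbone atoms N/CA/C")
        backbone[res] = entry
    interior = residues[1:-1]
    if not interior:
        raise ValueError("need at least three residues for dihedrals")
    fracs = []
    for t in range(traj.n_frames):
        f = traj.frames[t]
        alpha = []
        for res in interior:
            prev_res, next_res = res - 1, res + 1
            phi = dihedral_angle(f[backbone[prev_res]["C"]], f[backbone[res]["N"]],
                                 f[backbone[res]["CA"]], f[backbone[res]["C"]])
            psi = dihedral_angle(f[backbone[res]["N"]], f[backbone[res]["CA"]],
                                 f[backbone[res]["C"]], f[backbone[next_res]["N"]])
            alpha.append(_ALPHA_PHI[0] <= phi <= _ALPHA_PHI[1]
                         and _ALPHA_PSI[0] <= psi <= _ALPHA_PSI[1])
        helical = np.zeros(len(alpha), dtype=bool)
        run_start = None
        for i, a in enumerate(alpha + [False]):
            if a and run_start is None:
                run_start = i
            elif not a and run_start is not None:
                if i - run_start >= min_run:
                    helical[run_start:i] = True
                run_start = None
        fracs.append(helical.mean())
    return float(np.mean(fracs))


def profile_over_windows(
    window_trajs: list[Trajectory],
    centers: np.ndarray,
    statistic,
    stderr_fn=None,
    name: str = "",
) -> OrderParameterProfile:
    """Apply a per-trajectory statistic across windows to build a profile."""
    centers = np.asarray(centers, float)
    order = np.argsort(centers)
    vals, errs = [], []
    for i in order:
        v = statistic(window_trajs[i])
        vals.append(v)
        errs.append(stderr_fn(window_trajs[i]) if stderr_fn else 0.0)
    return OrderParameterProfile(centers[order], np.array(vals), np.array(errs), name)
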