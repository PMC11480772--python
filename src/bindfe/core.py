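"""Domain types and geometric primitives.

Structures are plain arrays-of-atoms (:class:`Topology`) with coordinate
frames in Angstrom.  Everything downstream — umbrella windows, restraint
schemes, order parameters — consumes the measurement functions defined
here: mass-weighted centers of mass, the peptide–RNA separation distance,
and the six internal coordinates (r, theta, phi, Theta, Phi, Psi) of the
Woo–Roux anchor construction.

Angle conventions
-----------------
Planar angles lie in [0, pi].  Dihedrals are signed with the right-handed
(IUPAC) convention via the standard two-plane atan2 formula and lie in
(-pi, pi].  Harmonic bias/restraint potentials support two force-constant
conventions: ``"full"`` (U = k * d^2, the Amber NMR-restraint form) and
``"half"`` (U = k/2 * d^2); the convention is always explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "AtomSelection",
    "BiasPotential",
    "UmbrellaWindow",
    "UmbrellaWindowSet",
    "RestraintScheme",
    "SelectionError",
    "GeometryError",
    "center_of_mass",
    "separation_distance",
    "measure_virtual_angles",
    "restraint_energy",
    "angle_between",
    "dihedral_angle",
    "wrap_angle",
    "nerf_place",
]


class SelectionError(ValueError):
    """An atom selection resolved to no atoms where atoms are required."""


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear anchor points)."""


_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "X": 12.0,
}


def element_from_name(name: str) -> str:
    """Deduce the element from a PDB-style atom name.

    Strips digits/primes and leading whitespace; a leading H (possibly
    after a digit, as in ``1HB``) means hydrogen.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    first = stripped[0].upper()
    if first == "H":
        return "H"
    two = stripped[:2].capitalize()
    if two in ("Cl", "Na", "Mg", "Fe", "Zn", "Br"):
        return two
    return first


@dataclass
class Topology:
    """Static per-atom metadata for a structure.

    Atom ids are implicit: the arrays are indexed 0..n_atoms-1.
    """

    names: np.ndarray           # str atom names
    residue_index: np.ndarray   # int
    residue_name: np.ndarray    # str
    chain_id: np.ndarray        # str
    mass: np.ndarray            # amu
    charge: np.ndarray          # elementary charges
    is_hydrogen: np.ndarray     # bool

    def __post_init__(self) -> None:
        n = len(self.names)
        arrays = {
            "names": np.asarray(self.names, dtype=object),
            "residue_index": np.asarray(self.residue_index, dtype=int),
            "residue_name": np.asarray(self.residue_name, dtype=object),
            "chain_id": np.asarray(self.chain_id, dtype=object),
            "mass": np.asarray(self.mass, dtype=float),
            "charge": np.asarray(self.charge, dtype=float),
            "is_hydrogen": np.asarray(self.is_hydrogen, dtype=bool),
        }
        for key, arr in arrays.items():
            if len(arr) != n:
                raise ValueError(f"topology field {key!r} has length {len(arr)}, expected {n}")
            setattr(self, key, arr)
        if n and not np.all(self.mass > 0):
            raise ValueError("all atom masses must be positive")
        for i, name in enumerate(self.names):
            deduced = element_from_name(str(name)) == "H"
            if bool(self.is_hydrogen[i]) != deduced:
                raise ValueError(
                    f"atom {i} ({name!r}): is_hydrogen={bool(self.is_hydrogen[i])} "
                    f"inconsistent with element deduced from name"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @classmethod
    def from_atoms(cls, atoms: Sequence[dict]) -> "Topology":
        """Build from an iterable of per-atom dicts (keys as field names)."""
        def col(key, default=None):
            return [a.get(key, default) for a in atoms]
        names = col("name")
        return cls(
            names=np.array(names, dtype=object),
            residue_index=np.array(col("residue_index", 0)),
            residue_name=np.array(col("residue_name", "UNK"), dtype=object),
            chain_id=np.array(col("chain_id", "A"), dtype=object),
            mass=np.array(col("mass", 12.0), dtype=float),
            charge=np.array(col("charge", 0.0), dtype=float),
            is_hydrogen=np.array(
                [a.get("is_hydrogen", element_from_name(str(n)) == "H")
                 for a, n in zip(atoms, names)], dtype=bool),
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology (Angstrom)."""

    topology: Topology
    frames: np.ndarray          # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, :, :]
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, topology has {self.topology.n_atoms}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory coordinates must be finite")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_frames:
                raise ValueError("frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AtomSelection:
    """A resolved set of atom indices, with the predicate that produced it."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)

    @classmethod
    def select(
        cls,
        topology: Topology,
        residue_index: int | Sequence[int] | None = None,
        residue_name: str | None = None,
        name: str | None = None,
        chain_id: str | None = None,
        exclude_hydrogens: bool = False,
        predicate: Callable[[int], bool] | None = None,
        label: str = "",
    ) -> "AtomSelection":
        mask = np.ones(topology.n_atoms, dtype=bool)
        if residue_index is not None:
            wanted = np.atleast_1d(residue_index)
            mask &= np.isin(topology.residue_index, wanted)
        if residue_name is not None:
            mask &= topology.residue_name == residue_name
        if name is not None:
            mask &= np.array([str(n).strip() == name for n in topology.names])
        if chain_id is not None:
            mask &= topology.chain_id == chain_id
        if exclude_hydrogens:
            mask &= ~topology.is_hydrogen
        idx = np.nonzero(mask)[0]
        if predicate is not None:
            idx = np.array([i for i in idx if predicate(int(i))], dtype=int)
        return cls(indices=idx, label=label)


VALID_BIAS_KINDS = ("harmonic_distance", "harmonic_angle", "harmonic_dihedral", "harmonic_rmsd")
VALID_CONVENTIONS = ("half", "full")


@dataclass
class BiasPotential:
    """Harmonic bias on a scalar coordinate.

    ``convention="full"`` means U = k*(x-x0)^2; ``"half"`` means
    U = (k/2)*(x-x0)^2.  Never defaulted: callers must state it.
    """

    kind: str
    center: float
    force_constant: float
    convention: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_BIAS_KINDS:
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.convention not in VALID_CONVENTIONS:
            raise ValueError(f"bias convention must be one of {VALID_CONVENTIONS}")
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")

    @property
    def prefactor(self) -> float:
        return self.force_constant if self.convention == "full" else 0.5 * self.force_constant

    def deviation(self, x):
        d = np.asarray(x, dtype=float) - self.center
        if self.kind == "harmonic_dihedral":
            d = wrap_angle(d)
        return d

    def energy(self, x):
        """Bias energy in kcal/mol at coordinate value(s) x."""
        d = self.deviation(x)
        return self.prefactor * d * d

    def gradient(self, x):
        return 2.0 * self.prefactor * self.deviation(x)


@dataclass
class UmbrellaWindow:
    bias: BiasPotential
    samples: np.ndarray
    temperature: float = 300.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if len(self.samples) < 1:
            raise ValueError("window sample series must have length >= 1")


@dataclass
class UmbrellaWindowSet:
    """Umbrella windows along one reaction coordinate, center-sorted."""

    reaction_coordinate_id: str
    windows: list[UmbrellaWindow]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("window set must contain at least one window")
        centers = [w.bias.center for w in self.windows]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("window centers must be strictly increasing")
        temps = {w.temperature for w in self.windows}
        if len(temps) > 1:
            raise ValueError("all windows must share a temperature")

    @property
    def temperature(self) -> float:
        return self.windows[0].temperature

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.bias.center for w in self.windows])


@dataclass
class RestraintScheme:
    """Anchor selections and restraint parameters of the Woo–Roux scheme.

    The axial angles (theta0, phi0) position the ligand center relative
    to the receptor anchors; the orientational angles (Theta0, Phi0,
    Psi0) fix its orientation.  All five share one angular force
    constant k (kcal mol^-1 rad^-2) and one convention.
    """

    p0: AtomSelection
    p1: AtomSelection
    p2: AtomSelection
    q0: AtomSelection
    q1: AtomSelection
    q2: AtomSelection
    Theta0: float
    Phi0: float
    Psi0: float
    theta0: float
    phi0: float
    force_constant: float
    convention: str
    rmsd_reference: dict | None = None  # partner label -> reference frame array
    com_weighting: str = "mass"

    def __post_init__(self) -> None:
        if self.convention not in VALID_CONVENTIONS:
            raise ValueError(f"restraint convention must be one of {VALID_CONVENTIONS}")
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        for label, val in (("Theta0", self.Theta0), ("theta0", self.theta0)):
            if not (0.0 < val < math.pi):
                raise ValueError(f"{label} must lie in (0, pi)")
        for label, val in (("Phi0", self.Phi0), ("Psi0", self.Psi0), ("phi0", self.phi0)):
            if not (-math.pi < val <= math.pi):
                raise ValueError(f"{label} must lie in (-pi, pi]")

    @property
    def equilibria(self) -> dict[str, float]:
        return {
            "theta": self.theta0, "phi": self.phi0,
            "Theta": self.Theta0, "Phi": self.Phi0, "Psi": self.Psi0,
        }


# ---------------------------------------------------------------------------
# geometry


def wrap_angle(x):
    """Wrap angle(s) to (-pi, pi]."""
    wrapped = np.mod(np.asarray(x, dtype=float) + math.pi, 2.0 * math.pi) - math.pi
    # np.mod maps exact -pi to -pi; move it to +pi for a (-pi, pi] interval
    wrapped = np.where(wrapped == -math.pi, math.pi, wrapped)
    if np.ndim(x) == 0:
        return float(wrapped)
    return wrapped


def center_of_mass(
    frame: np.ndarray,
    sel: AtomSelection,
    topology: Topology,
    weighting: str = "mass",
) -> np.ndarray:
    """Mass-weighted (default) or geometric center of the selected atoms."""
    if len(sel) == 0:
        raise SelectionError(f"selection {sel.label!r} resolved to zero atoms")
    coords = np.asarray(frame, dtype=float)[sel.indices]
    if weighting == "geometric":
        return coords.mean(axis=0)
    if weighting != "mass":
        raise ValueError("weighting must be 'mass' or 'geometric'")
    w = topology.mass[sel.indices]
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def separation_distance(
    frame: np.ndarray,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    topology: Topology,
    weighting: str = "mass",
) -> float:
    """Euclidean distance between the two selection centers of mass."""
    ca = center_of_mass(frame, sel_a, topology, weighting)
    cb = center_of_mass(frame, sel_b, topology, weighting)
    return float(np.linalg.norm(cb - ca))


def angle_between(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Planar angle a-b-c in [0, pi]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("coincident points in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(math.acos(cosang))


def dihedral_angle(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in (-pi, pi], right-handed convention.

    Positive when, looking down b->c, d rotates clockwise... concretely:
    the IUPAC convention where the cis (eclipsed) arrangement is 0 and the
    sign follows atan2((b1 x b2) . b3_hat ... the standard praxeolitic
    formula.
    """
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n2 = np.linalg.norm(b2)
    if n2 == 0.0:
        raise GeometryError("coincident central atoms in dihedral")
    m1 = np.cross(b1, b2)
    m2 = np.cross(b2, b3)
    if np.linalg.norm(m1) < 1e-12 or np.linalg.norm(m2) < 1e-12:
        raise GeometryError("collinear triple makes dihedral undefined")
    x = np.dot(m1, m2)
    y = np.dot(np.cross(m1, m2), b2) / n2
    ang = math.atan2(y, x)
    return math.pi if ang == -math.pi else ang


def measure_virtual_angles(
    frame: np.ndarray,
    scheme: RestraintScheme,
    topology: Topology,
) -> dict[str, float]:
    """Measure the six Woo–Roux internal coordinates of a frame.

    Returns ``{"r", "theta", "phi", "Theta", "Phi", "Psi"}`` where
    r = |P0-Q0|, theta = angle(P1,P0,Q0), phi = dihedral(P2,P1,P0,Q0),
    Theta = angle(P0,Q0,Q1), Psi = dihedral(P1,P0,Q0,Q1),
    Phi = dihedral(P0,Q0,Q1,Q2).
    """
    w = scheme.com_weighting
    pts = {
        label: center_of_mass(frame, getattr(scheme, label), topology, w)
        for label in ("p0", "p1", "p2", "q0", "q1", "q2")
    }
    consecutive = ("p2", "p1", "p0", "q0", "q1", "q2")
    for u, v in zip(consecutive, consecutive[1:]):
        if np.linalg.norm(pts[u] - pts[v]) < 1e-9:
            raise GeometryError(f"anchors {u} and {v} are coincident")
    return {
        "r": float(np.linalg.norm(pts["q0"] - pts["p0"])),
        "theta": angle_between(pts["p1"], pts["p0"], pts["q0"]),
        "phi": dihedral_angle(pts["p2"], pts["p1"], pts["p0"], pts["q0"]),
        "Theta": angle_between(pts["p0"], pts["q0"], pts["q1"]),
        "Psi": dihedral_angle(pts["p1"], pts["p0"], pts["q0"], pts["q1"]),
        "Phi": dihedral_angle(pts["p0"], pts["q0"], pts["q1"], pts["q2"]),
    }


_DIHEDRAL_KEYS = ("phi", "Phi", "Psi")


def restraint_energy(angle_record: dict[str, float], scheme: RestraintScheme) -> float:
    """Total energy of the five angular restraints, kcal/mol.

    Dihedral deviations are wrapped to (-pi, pi] before squaring.
    """
    pref = (scheme.force_constant if scheme.convention == "full"
            else 0.5 * scheme.force_constant)
    total = 0.0
    for key, eq in scheme.equilibria.items():
        dev = angle_record[key] - eq
        if key in _DIHEDRAL_KEYS:
            dev = wrap_angle(dev)
        total += pref * dev * dev
    return total


def nerf_place(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D given three positions and internal coordinates.

    D is at distance ``bond`` from C, with planar angle B-C-D equal to
    ``angle`` and dihedral A-B-C-D equal to ``dihedral`` under the same
    right-handed convention as :func:`dihedral_angle` (natural extension
    reference frame).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise GeometryError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local
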