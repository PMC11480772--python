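import math

import numpy as np
import pytest

from bindfe.core import AtomSelection, RestraintScheme, Topology, Trajectory


@pytest.fixture
def three_atom_water_like():
    """O-H-H fixture: one heavy atom and two hydrogens."""
    topo = Topology.from_atoms([
        dict(name="O", residue_index=0, residue_name="HOH", mass=15.999, charge=-0.8),
        dict(name="H1", residue_index=0, residue_name="HOH", mass=1.008, charge=0.4),
        dict(name="H2", residue_index=0, residue_name="HOH", mass=1.008, charge=0.4),
    ])
    frame = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
    return topo, frame


@pytest.fixture
def published_scheme():
    """Restraint scheme with the published anchor-angle equilibria.

    Theta0=2.53, Phi0=2.7, Psi0=-3.13, theta0=1.49, phi0=-2.88 rad and
    k=100 kcal/mol/rad^2.
    """
    sel = AtomSelection([0])
    return RestraintScheme(
        p0=sel, p1=sel, p2=sel, q0=sel, q1=sel, q2=sel,
        Theta0=2.53, Phi0=2.7, Psi0=-3.13, theta0=1.49, phi0=-2.88,
        force_constant=100.0, convention="full")


def make_bead_topology(n, charges=None, name="CA", chain="A", mass=100.0):
    charges = charges if charges is not None else [0.0] * n
    return Topology.from_atoms([
        dict(name=name, residue_index=i, residue_name="GLY", chain_id=chain,
             mass=mass, charge=float(charges[i]))
        for i in range(n)
    ])


def ideal_helix_frame(n_res, phi=math.radians(-57.0), psi=math.radians(-47.0)):
    """Backbone-only chain with prescribed (phi, psi) at every residue.

    Built by NeRF with standard bond lengths/angles and omega = 180 deg.
    Returns (topology, frame) with atoms N, CA, C per residue.
    """
    from bindfe.core import nerf_place

    b_n_ca, b_ca_c, b_c_n = 1.458, 1.525, 1.329
    ang_n_ca_c = math.radians(111.0)
    ang_ca_c_n = math.radians(116.6)
    ang_c_n_ca = math.radians(121.7)
    omega = math.pi
    coords = [np.array([0.0, 0.0, 0.0]),
              np.array([b_n_ca, 0.0, 0.0])]
    coords.append(coords[1] + np.array(
        [-b_ca_c * math.cos(ang_n_ca_c), b_ca_c * math.sin(ang_n_ca_c), 0.0]))
    seq = []
    for i in range(1, n_res):
        seq += [(b_c_n, ang_ca_c_n, psi), (b_n_ca, ang_c_n_ca, omega),
                (b_ca_c, ang_n_ca_c, phi)]
    for bond, ang, dih in seq:
        coords.append(nerf_place(coords[-3], coords[-2], coords[-1], bond, ang, dih))
    atoms = []
    for i in range(n_res):
        for nm in ("N", "CA", "C"):
            atoms.append(dict(name=nm, residue_index=i, residue_name="ALA",
                              chain_id="A", mass=14.0 if nm == "N" else 12.0,
                              charge=0.0))
    return Topology.from_atoms(atoms), np.array(coords)


@pytest.fixture
def helix_builder():
    return ideal_helix_frame


@pytest.fixture(scope="session")
def woo_roux_cycle_result():
    """One shared run of the two-route toy binding free-energy cycle."""
    from bindfe.cycle import run_woo_roux_cycle
    return run_woo_roux_cycle(seed=1)
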