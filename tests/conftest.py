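import numpy as np
import pytest

from trpm2kit.pore import AtomSet


def make_ring_atoms(n_atoms=8, ring_radius=4.0, vdw=1.5, z=0.0,
                    entry_id="ring") -> AtomSet:
    """Ring of identical atoms around the z axis; analytic pore radius at the
    ring plane is ring_radius - vdw."""
    ang = 2 * np.pi * np.arange(n_atoms) / n_atoms
    xyz = np.column_stack([ring_radius * np.cos(ang),
                           ring_radius * np.sin(ang),
                           np.full(n_atoms, float(z))])
    return AtomSet(
        xyz=xyz,
        radii=np.full(n_atoms, float(vdw)),
        elements=np.array(["X"] * n_atoms),
        chains=np.array(["A"] * n_atoms),
        residue_names=np.array(["RNG"] * n_atoms),
        residue_numbers=np.arange(1, n_atoms + 1),
        het_flags=np.zeros(n_atoms, dtype=bool),
        entry_id=entry_id,
    )


def stack_atomsets(*sets) -> AtomSet:
    return AtomSet(
        xyz=np.vstack([s.xyz for s in sets]),
        radii=np.concatenate([s.radii for s in sets]),
        elements=np.concatenate([s.elements for s in sets]),
        chains=np.concatenate([s.chains for s in sets]),
        residue_names=np.concatenate([s.residue_names for s in sets]),
        residue_numbers=np.concatenate([s.residue_numbers for s in sets]),
        het_flags=np.concatenate([s.het_flags for s in sets]),
        entry_id=sets[0].entry_id,
    )


def grid_clearance(point, tangent, xyz, radii, wander=2.0, grid=0.05):
    """Brute-force oracle for the inscribed-sphere radius: exhaustive 2-D
    grid search over sphere centers in the plane normal to ``tangent``."""
    t = np.asarray(tangent, float)
    t = t / np.linalg.norm(t)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(t @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    offsets = np.arange(-wander, wander + grid / 2, grid)
    a, b = np.meshgrid(offsets, offsets, indexing="ij")
    centers = (point[None, :] + a.reshape(-1, 1) * u[None, :]
               + b.reshape(-1, 1) * v[None, :])
    d = np.linalg.norm(centers[:, None, :] - xyz[None, :, :], axis=2) - radii[None, :]
    return float(d.min(axis=1).max())


@pytest.fixture
def two_ring_atoms():
    """Two stacked, laterally offset rings: an off-axis constriction whose
    profile must match the brute-force grid oracle."""
    r1 = make_ring_atoms(n_atoms=10, ring_radius=4.0, vdw=1.4, z=0.0)
    r2 = make_ring_atoms(n_atoms=10, ring_radius=3.6, vdw=1.4, z=2.5)
    r2.xyz[:, 0] += 1.2  # lateral offset
    atoms = stack_atomsets(r1, r2)
    atoms.residue_numbers = np.arange(1, len(atoms) + 1)
    return atoms
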