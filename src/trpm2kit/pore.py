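"""Pore and tunnel radius profiling of channel structures.

Implements inscribed-sphere radius profiling along a straight axis or a
curved (spline) path, in the spirit of HOLE: at each station along the path
the profiler finds the largest sphere, centered in the plane normal to the
local path tangent, that overlaps no atom,

    R(s) = max over centers c in the plane of  min over atoms a  (|c - x_a| - r_a),

by deterministic multi-start local optimization seeded on the axis point
(fixed start lattice, so results are bit-reproducible).  Van der Waals
radii come from a Bondi-style element table; hydrogens absent from typical
cryo-EM/crystallographic models are simply not present (no united-atom
inflation), which matches common practice.  Absolute agreement of profile
radii with other radius tables is therefore only expected to ~0.2 Å.

Stations are classified against the water molecule radius: too tight for
water (radius < 1.15 Å), just wide enough for single-file water
(1.15-2.30 Å), or wider (> 2.30 Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
from scipy import optimize

__all__ = [
    "VDW_RADII",
    "AtomSet",
    "Axis",
    "PoreProfile",
    "read_structure",
    "pore_axis",
    "radius_profile",
    "tunnel_profile",
    "summarize_profile",
    "catmull_rom_path",
]

# Bondi-style van der Waals radii (Å); elements not listed fall back to DEFAULT_VDW
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 1.63,
    "MN": 1.61, "CU": 1.40,
}
DEFAULT_VDW = 1.70

RADIUS_CLASS_EDGES = (1.15, 2.30)  # Å; single-water-radius boundaries


def _classify(radius: float) -> str:
    if radius < RADIUS_CLASS_EDGES[0]:
        return "red"
    if radius <= RADIUS_CLASS_EDGES[1]:
        return "green"
    return "purple"


@dataclass
class AtomSet:
    """Atoms with coordinates and van der Waals radii.

    ``chains``/``residue_names``/``residue_numbers``/``het_flags`` are
    per-atom annotation arrays aligned with ``xyz``.
    """

    xyz: np.ndarray  # (N, 3) Å
    radii: np.ndarray  # (N,) Å
    elements: np.ndarray
    chains: np.ndarray
    residue_names: np.ndarray
    residue_numbers: np.ndarray
    het_flags: np.ndarray  # True for heteroatoms (ligands, ions, waters)
    entry_id: str = ""

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (N, 3)")
        if not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("vdW radii must be > 0")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def polymer_residue_count(self) -> int:
        """Number of distinct polymer (non-het) residues."""
        mask = ~self.het_flags
        keys = set(zip(self.chains[mask].tolist(),
                       self.residue_numbers[mask].tolist()))
        return len(keys)

    def ligand_counts(self) -> dict[str, int]:
        """Distinct het residues per residue name (ions count individually)."""
        mask = self.het_flags
        keys = set(zip(self.chains[mask].tolist(),
                       self.residue_numbers[mask].tolist(),
                       self.residue_names[mask].tolist()))
        out: dict[str, int] = {}
        for _, _, name in keys:
            out[name] = out.get(name, 0) + 1
        return out

    def select_chains(self, chain_ids: Sequence[str]) -> "AtomSet":
        mask = np.isin(self.chains, list(chain_ids))
        return self._subset(mask)

    def select_residue_range(self, lo: int, hi: int) -> "AtomSet":
        mask = (self.residue_numbers >= lo) & (self.residue_numbers <= hi)
        return self._subset(mask)

    def _subset(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(self.xyz[mask], self.radii[mask], self.elements[mask],
                       self.chains[mask], self.residue_names[mask],
                       self.residue_numbers[mask], self.het_flags[mask],
                       self.entry_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomSet":
        return AtomSet(self.xyz @ np.asarray(rotation).T + translation,
                       self.radii, self.elements, self.chains,
                       self.residue_names, self.residue_numbers,
                       self.het_flags, self.entry_id)


@dataclass(frozen=True)
class Axis:
    """A straight line (anchor + direction) or a spline waypoint path."""

    kind: str  # "line" | "spline"
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    waypoints: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if self.kind == "line":
            if n == 0:
                raise ValueError("direction must be nonzero")
            object.__setattr__(self, "direction", d / n)
        elif self.kind == "spline":
            wp = np.asarray(self.waypoints, dtype=float)
            if wp.ndim != 2 or wp.shape[0] < 2 or wp.shape[1] != 3:
                raise ValueError("spline needs >= 2 waypoints of shape (k, 3)")
            object.__setattr__(self, "waypoints", wp)
        else:
            raise ValueError("kind must be 'line' or 'spline'")


@dataclass
class PoreProfile:
    """Inscribed-sphere radii along the path (stations ordered by arc length)."""

    s: np.ndarray  # Å arc length
    centers: np.ndarray  # (M, 3) Å
    radii: np.ndarray  # Å
    classes: list[str]
    capped: np.ndarray  # True where no nearby atoms bounded the sphere

    def __post_init__(self):
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("stations must be ordered by arc length")
        if np.any(self.radii < 0):
            raise ValueError("radii must be >= 0")


# ---------------------------------------------------------------------------
# structure reading

def read_structure(path: str, fmt: str | None = None) -> AtomSet:
    """Read a PDB or mmCIF file into an :class:`AtomSet` (first model only)."""
    import gemmi

    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ValueError(f"failed to parse structure {path}: {exc}") from exc

    st.setup_entities()
    xyz, radii, elements, chains, resnames, resnums, hets = [], [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            for atom in res:
                el = atom.element.name.upper()
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(VDW_RADII.get(el, DEFAULT_VDW))
                elements.append(el)
                chains.append(chain.name)
                resnames.append(res.name)
                resnums.append(res.seqid.num)
                hets.append(is_het)
    if not xyz:
        raise ValueError(f"no atoms found in {path}")
    return AtomSet(np.array(xyz), np.array(radii), np.array(elements),
                   np.array(chains), np.array(resnames),
                   np.array(resnums, dtype=int), np.array(hets, dtype=bool),
                   entry_id=st.name or "")


# ---------------------------------------------------------------------------
# axis determination

def _rotation_axis_between(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Kabsch rotation mapping centered set a onto b; returns (axis, angle)."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    angle = math.acos(min(1.0, max(-1.0, (np.trace(r) - 1.0) / 2.0)))
    w, v = np.linalg.eig(r)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    # orient by the skew-symmetric part so consecutive pairs agree in sign
    skew = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    if np.dot(axis, skew) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), angle


def pore_axis(atoms: AtomSet, mode: str = "c4_symmetry") -> Axis:
    """Symmetry (or principal-component) axis of the channel.

    ``c4_symmetry``: the rotation axis of the Kabsch superposition of each
    chain onto its neighbor (matched by residue number and element order),
    averaged over the four neighbor pairs; requires four chains with matched
    residue numbering and falls back to ``principal`` with a warning
    otherwise.  ``principal``: largest-inertia eigenvector of the atom cloud.
    """
    centroid = atoms.xyz.mean(axis=0)
    if mode == "c4_symmetry":
        chain_ids = list(dict.fromkeys(atoms.chains.tolist()))
        if len(chain_ids) == 4:
            try:
                return _c4_axis(atoms, chain_ids, centroid)
            except ValueError as exc:
                warnings.warn(f"C4 axis failed ({exc}); falling back to principal")
        else:
            warnings.warn(
                f"need 4 chains for C4 axis, have {len(chain_ids)}; "
                "falling back to principal")
        mode = "principal"
    if mode != "principal":
        raise ValueError(f"unknown axis mode {mode!r}")
    centered = atoms.xyz - centroid
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    direction = v[:, np.argmax(w)]
    return Axis("line", anchor=centroid, direction=direction)


def _c4_axis(atoms: AtomSet, chain_ids: list[str], centroid: np.ndarray) -> Axis:
    keyed: dict[str, dict[tuple, np.ndarray]] = {}
    for cid in chain_ids:
        mask = atoms.chains == cid
        keys = {}
        nums = atoms.residue_numbers[mask]
        els = atoms.elements[mask]
        coords = atoms.xyz[mask]
        counter: dict[tuple, int] = {}
        for num, el, c in zip(nums, els, coords):
            k0 = (int(num), el)
            counter[k0] = counter.get(k0, 0) + 1
            keys[(int(num), el, counter[k0])] = c
        keyed[cid] = keys
    common = set.intersection(*(set(k.keys()) for k in keyed.values()))
    if len(common) < 3:
        raise ValueError("chains share fewer than 3 matched atoms")
    order = sorted(common)
    sets = {cid: np.array([keyed[cid][k] for k in order]) - centroid
            for cid in chain_ids}

    axes = []
    pairs = list(zip(chain_ids, chain_ids[1:] + chain_ids[:1]))
    for a_id, b_id in pairs:
        ax, angle = _rotation_axis_between(sets[a_id], sets[b_id])
        if not (math.radians(60) < angle < math.radians(120)):
            raise ValueError(
                f"chains {a_id}->{b_id} related by {math.degrees(angle):.1f}deg, "
                "not ~90deg; chain order is not rotational")
        axes.append(ax)
    ref = axes[0]
    aligned = [ax if np.dot(ax, ref) >= 0 else -ax for ax in axes]
    direction = np.mean(aligned, axis=0)
    return Axis("line", anchor=centroid, direction=direction)


# ---------------------------------------------------------------------------
# spline path

def catmull_rom_path(waypoints: np.ndarray, samples_per_segment: int = 64) -> np.ndarray:
    """Uniform Catmull-Rom spline through the waypoints (endpoints clamped)."""
    wp = np.asarray(waypoints, dtype=float)
    if len(wp) == 2:
        t = np.linspace(0.0, 1.0, samples_per_segment + 1)[:, None]
        return wp[0] * (1 - t) + wp[1] * t
    ext = np.vstack([2 * wp[0] - wp[1], wp, 2 * wp[-1] - wp[-2]])
    pts = []
    for i in range(len(wp) - 1):
        p0, p1, p2, p3 = ext[i], ext[i + 1], ext[i + 2], ext[i + 3]
        t = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)[:, None]
        t2, t3 = t * t, t * t * t
        seg = (0.5 * ((2 * p1) + (-p0 + p2) * t
                      + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t2
                      + (-p0 + 3 * p1 - 3 * p2 + p3) * t3))
        pts.append(seg)
    pts.append(wp[-1][None, :])
    return np.vstack(pts)


# ---------------------------------------------------------------------------
# inscribed-sphere profiling

def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / np.linalg.norm(tangent)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(t, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(t, helper)
    u = u / np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def _clearance_factory(point, u, v, xyz, radii):
    def clearance(ab):
        c = point + ab[0] * u + ab[1] * v
        d = np.linalg.norm(xyz - c, axis=1) - radii
        return float(d.min())
    return clearance


_START_LATTICE = np.array([
    (0.0, 0.0),
    (1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0),
    (0.7, 0.7), (0.7, -0.7), (-0.7, 0.7), (-0.7, -0.7),
])


def _station_radius(point, tangent, xyz, radii, wander, max_radius):
    """Largest inscribed sphere centered in the plane through ``point``."""
    u, v = _plane_basis(tangent)
    cutoff = wander + max_radius + radii.max(initial=1.0)
    near = np.linalg.norm(xyz - point, axis=1) <= cutoff
    if not near.any():
        return max_radius, point, True
    sub_xyz, sub_r = xyz[near], radii[near]
    clearance = _clearance_factory(point, u, v, sub_xyz, sub_r)

    best_val, best_ab = -np.inf, np.zeros(2)
    for start in _START_LATTICE * (wander / 2.0):
        res = optimize.minimize(
            lambda ab: -clearance(ab), start, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 600},
        )
        ab = res.x
        if np.hypot(*ab) > wander:
            ab = ab * (wander / np.hypot(*ab))
        val = clearance(ab)
        if val > best_val:
            best_val, best_ab = val, ab
    center = point + best_ab[0] * u + best_ab[1] * v
    if best_val >= max_radius:
        return max_radius, center, True
    return max(best_val, 0.0), center, False


def radius_profile(
    atoms: AtomSet,
    axis: Axis,
    s_range: tuple[float, float],
    step: float = 0.25,
    wander: float = 5.0,
    max_radius: float = 10.0,
) -> PoreProfile:
    """Inscribed-sphere radius along a straight axis.

    ``s_range`` is the arc-length interval (Å) relative to the axis anchor;
    the sphere center may wander up to ``wander`` Å in the plane normal to
    the axis.  Stations with no atoms within reach are capped at
    ``max_radius`` and flagged.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if axis.kind != "line":
        raise ValueError("radius_profile needs a line axis; see tunnel_profile")
    s_vals = np.arange(s_range[0], s_range[1] + 0.5 * step, step)
    centers, radii_out, classes, capped = [], [], [], []
    for s in s_vals:
        point = axis.anchor + s * axis.direction
        r, c, was_capped = _station_radius(point, axis.direction, atoms.xyz,
                                           atoms.radii, wander, max_radius)
        centers.append(c)
        radii_out.append(r)
        classes.append(_classify(r))
        capped.append(was_capped)
    return PoreProfile(s_vals, np.array(centers), np.array(radii_out),
                       classes, np.array(capped, dtype=bool))


def tunnel_profile(
    atoms: AtomSet,
    waypoints: Sequence[Sequence[float]],
    step: float = 0.25,
    wander: float = 5.0,
    max_radius: float = 10.0,
) -> PoreProfile:
    """Inscribed-sphere radius along a curved (Catmull-Rom) tunnel path.

    Straight-line waypoints reduce exactly to :func:`radius_profile` along
    the segment.  Raises on tangent reversals (self-intersecting path).
    """
    wp = np.asarray(waypoints, dtype=float)
    path = catmull_rom_path(wp)
    deltas = np.diff(path, axis=0)
    seg_len = np.linalg.norm(deltas, axis=1)
    keep = seg_len > 1e-12
    if keep.sum() < 1:
        raise ValueError("degenerate path")
    tangents = deltas[keep] / seg_len[keep][:, None]
    if np.any(np.einsum("ij,ij->i", tangents[:-1], tangents[1:]) < 0):
        raise ValueError("tangent reversal: self-intersecting tunnel path")
    arc = np.concatenate(([0.0], np.cumsum(seg_len)))

    s_vals = np.arange(0.0, arc[-1] + 1e-9, step)
    centers, radii_out, classes, capped = [], [], [], []
    for s in s_vals:
        idx = min(int(np.searchsorted(arc, s, side="right")) - 1, len(deltas) - 1)
        frac = (s - arc[idx]) / max(seg_len[idx], 1e-12)
        point = path[idx] + frac * deltas[idx]
        tangent = deltas[idx] / max(seg_len[idx], 1e-12)
        r, c, was_capped = _station_radius(point, tangent, atoms.xyz,
                                           atoms.radii, wander, max_radius)
        centers.append(c)
        radii_out.append(r)
        classes.append(_classify(r))
        capped.append(was_capped)
    return PoreProfile(s_vals, np.array(centers), np.array(radii_out),
                       classes, np.array(capped, dtype=bool))


def summarize_profile(
    profile: PoreProfile,
    window: tuple[float, float] | None = None,
    atoms: AtomSet | None = None,
    neighbor_cutoff: float = 5.0,
) -> dict:
    """Minimum diameter in the window, its station, and nearby residues."""
    mask = np.ones(len(profile.s), dtype=bool)
    if window is not None:
        mask = (profile.s >= window[0]) & (profile.s <= window[1])
    if not mask.any():
        raise ValueError("window contains no stations")
    idx_local = int(np.argmin(profile.radii[mask]))
    idx = np.nonzero(mask)[0][idx_local]
    out = {
        "min_diameter": float(2.0 * profile.radii[idx]),
        "min_radius": float(profile.radii[idx]),
        "s": float(profile.s[idx]),
        "center": profile.centers[idx].tolist(),
        "capped": bool(profile.capped[idx]),
    }
    if atoms is not None:
        d = np.linalg.norm(atoms.xyz - profile.centers[idx], axis=1)
        near = d <= neighbor_cutoff
        residues = sorted(set(zip(atoms.chains[near].tolist(),
                                  atoms.residue_names[near].tolist(),
                                  atoms.residue_numbers[near].tolist())))
        out["nearby_residues"] = residues
    return out
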