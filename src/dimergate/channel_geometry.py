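"""Pore geometry of the translocation pathway.

``pore_profile`` re-implements the maximal-inscribed-sphere profiling
idea popularized by HOLE: at each position z along the channel axis the
largest sphere that fits between the van der Waals surfaces of the atoms,
with its center constrained to the slice plane, defines the local pore
radius.  The in-plane center is found by a multi-start derivative-free
pattern search seeded from the previous slice, so the profile follows a
continuous channel.  Layer series, symmetry-pair distances (d_pair), end
state differences (delta d_pair) and minimal inter-residue contact
distances complete the gating metrics; all of the distance metrics are
superposition-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ConsistencyError
from .structure_io import AtomSelection, HomodimerMap, Structure, Trajectory

__all__ = [
    "PoreProfile",
    "LayerDefinition",
    "DpairSeries",
    "pore_profile",
    "layer_radius_series",
    "dpair_series",
    "delta_dpair",
    "min_residue_distance_series",
]

ResidueKey = tuple[str, int, str]


@dataclass
class PoreProfile:
    z: np.ndarray  # strictly increasing slice positions (Å, along axis)
    radius: np.ndarray  # pore radius per slice (Å, >= 0 or capped)
    center: np.ndarray  # (n, 2) in-plane sphere centers
    capped: np.ndarray  # bool: slice hit the escape cap (no wall found)
    lining: list[list[ResidueKey]]  # residues bounding the sphere per slice

    def min_radius(self) -> float:
        return float(np.min(self.radius))


@dataclass
class LayerDefinition:
    """A named z-slab of the channel, e.g. the slab around one residue.

    Either an explicit ``window`` (z interval) or ``anchor_residues``
    whose mean Cα z in a reference frame centers the slab.
    """

    name: str
    window: tuple[float, float] | None = None
    anchor_residues: Sequence[ResidueKey] = field(default_factory=tuple)
    half_width: float = 2.0

    def resolve(
        self, reference: Structure | None = None, selection: AtomSelection | None = None
    ) -> tuple[float, float]:
        if self.window is not None:
            lo, hi = self.window
            if hi <= lo:
                raise ConfigurationError(f"layer {self.name!r}: empty z window")
            return float(lo), float(hi)
        if not self.anchor_residues:
            raise ConfigurationError(
                f"layer {self.name!r}: neither window nor anchor residues given"
            )
        if reference is None or selection is None:
            raise ConfigurationError(
                f"layer {self.name!r}: anchor residues need a reference structure"
            )
        keys = {a.residue_key: i for i, a in enumerate(selection.atoms)}
        zs = []
        for res in self.anchor_residues:
            if res not in keys:
                raise ConfigurationError(
                    f"layer {self.name!r}: anchor residue {res} not in selection"
                )
            zs.append(selection.coords_from(reference)[keys[res], 2])
        center = float(np.mean(zs))
        return center - self.half_width, center + self.half_width


@dataclass
class DpairSeries:
    residue: ResidueKey
    partner: ResidueKey
    labels: np.ndarray
    distances: np.ndarray  # Å, per frame


def _axis_rotation(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ``axis`` to +z."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ConfigurationError("channel axis must be a nonzero vector")
    a = axis / n
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _clearance(center2d: np.ndarray, z: float, coords: np.ndarray, vdw: np.ndarray) -> tuple[float, np.ndarray]:
    """min over atoms of (distance from sphere center to atom) - vdw."""
    delta = coords - np.array([center2d[0], center2d[1], z])
    dist = np.sqrt(np.sum(delta * delta, axis=1)) - vdw
    i = int(np.argmin(dist))
    return float(dist[i]), dist


def _pattern_search(
    start: np.ndarray,
    z: float,
    coords: np.ndarray,
    vdw: np.ndarray,
    initial_step: float,
    resolution: float,
    max_radius: float,
) -> tuple[np.ndarray, float]:
    """Maximize the clearance over the slice plane by compass search.

    Stops as soon as the clearance exceeds ``max_radius`` — outside the
    structure the objective grows without bound, so the cap doubles as
    the escape criterion.
    """
    center = np.asarray(start, dtype=float).copy()
    best, _ = _clearance(center, z, coords, vdw)
    step = initial_step
    moves = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
    while step >= resolution and best < max_radius:
        improved = False
        for m in moves:
            cand = center + step * m
            val, _ = _clearance(cand, z, coords, vdw)
            if val > best + 1e-12:
                center, best = cand, val
                improved = True
        if not improved:
            step *= 0.5
    return center, best


def pore_profile(
    structure: Structure | np.ndarray,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    z_range: tuple[float, float] | None = None,
    step: float = 1.0,
    seed_point: np.ndarray = (0.0, 0.0),
    vdw: np.ndarray | None = None,
    atoms=None,
    max_radius: float = 10.0,
    resolution: float = 0.01,
    jitter: float = 1.0,
    lining_tolerance: float = 0.1,
) -> PoreProfile:
    """Profile the pore radius along the channel axis.

    Parameters
    ----------
    structure:
        A Structure, or a raw (n, 3) coordinate array (then ``vdw`` and
        optionally ``atoms`` metadata must be supplied).
    axis:
        Channel axis; coordinates are rotated so it becomes +z.
    z_range:
        Interval profiled (defaults to the coordinate extent along the
        axis); ``step`` is the slice spacing.
    seed_point:
        In-plane starting guess for the first slice's center.
    max_radius:
        Escape cap: a slice whose optimal sphere exceeds this radius is
        reported capped at it (the pore is open to bulk there).
    resolution:
        Final in-plane search step (Å).
    jitter:
        Offset of the four auxiliary multi-start points around the
        previous slice's center.
    """
    if isinstance(structure, Structure):
        coords = structure.coords
        vdw_arr = structure.vdw
        atom_meta = structure.atoms
    else:
        coords = np.asarray(structure, dtype=float)
        if vdw is None:
            raise ConfigurationError("raw coordinates need a vdw radius array")
        vdw_arr = np.asarray(vdw, dtype=float)
        atom_meta = atoms
    if step <= 0:
        raise ConfigurationError("slice step must be positive")

    rot = _axis_rotation(axis)
    rc = coords @ rot.T
    if z_range is None:
        z_range = (float(rc[:, 2].min()), float(rc[:, 2].max()))
    z_lo, z_hi = map(float, z_range)
    if z_hi < z_lo:
        raise ConfigurationError("z range is empty")
    zs = np.arange(z_lo, z_hi + 0.5 * step, step)
    if not np.any((rc[:, 2] >= z_lo - max_radius) & (rc[:, 2] <= z_hi + max_radius)):
        raise ConfigurationError("no atoms inside the profiled z range")

    radii = np.empty(len(zs))
    centers = np.empty((len(zs), 2))
    capped = np.zeros(len(zs), dtype=bool)
    lining: list[list[ResidueKey]] = []
    prev = np.asarray(seed_point, dtype=float)
    offsets = jitter * np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
    for i, z in enumerate(zs):
        best_center, best_val = None, -np.inf
        for start in [prev, *(prev + offsets)]:
            c, v = _pattern_search(
                start, z, rc, vdw_arr,
                initial_step=1.0, resolution=resolution, max_radius=max_radius,
            )
            if v > best_val:
                best_center, best_val = c, v
        if best_val >= max_radius:
            radii[i] = max_radius
            capped[i] = True
        else:
            radii[i] = max(best_val, 0.0)
        centers[i] = best_center
        _, dist = _clearance(best_center, z, rc, vdw_arr)
        if atom_meta is not None:
            near = np.flatnonzero(dist <= dist.min() + lining_tolerance)
            lining.append(sorted({atom_meta[j].residue_key for j in near}))
        else:
            lining.append([])
        prev = best_center
    return PoreProfile(z=zs, radius=radii, center=centers, capped=capped, lining=lining)


def layer_radius_series(
    traj: Trajectory,
    layer: LayerDefinition,
    reference: Structure | None = None,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    step: float = 0.5,
    vdw: np.ndarray | None = None,
    **pore_kwargs,
) -> np.ndarray:
    """Minimum pore radius inside a layer's z window, per frame."""
    lo, hi = layer.resolve(reference, traj.selection)
    if vdw is None:
        if reference is None:
            raise ConfigurationError("need vdw radii or a reference structure")
        vdw = reference.vdw[traj.selection.indices]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        prof = pore_profile(
            traj.coords[f],
            axis=axis,
            z_range=(lo, hi),
            step=step,
            vdw=vdw,
            atoms=traj.selection.atoms,
            **pore_kwargs,
        )
        out[f] = prof.min_radius()
    return out


def _single_atom_index(traj: Trajectory, residue: ResidueKey) -> int:
    for j, atom in enumerate(traj.selection.atoms):
        if atom.residue_key == residue:
            return j
    raise ConfigurationError(f"residue {residue} not in the trajectory selection")


def dpair_series(traj: Trajectory, residue: ResidueKey, hmap: HomodimerMap) -> DpairSeries:
    """Distance between the two symmetry-equivalent Cα atoms, per frame."""
    if residue not in hmap.partner:
        raise ConfigurationError(f"residue {residue} is not in the homodimer map")
    partner = hmap.partner[residue]
    i = _single_atom_index(traj, residue)
    j = _single_atom_index(traj, partner)
    d = np.linalg.norm(traj.coords[:, i] - traj.coords[:, j], axis=1)
    return DpairSeries(residue=residue, partner=partner, labels=np.asarray(traj.labels), distances=d)


def _dpair_static(
    structure: Structure, selection: AtomSelection, residue: ResidueKey, hmap: HomodimerMap
) -> float:
    keys = {a.residue_key: i for i, a in enumerate(selection.atoms)}
    partner = hmap.partner[residue]
    coords = selection.coords_from(structure)
    return float(np.linalg.norm(coords[keys[residue]] - coords[keys[partner]]))


def delta_dpair(
    structure_a: Structure,
    selection_a: AtomSelection,
    structure_b: Structure,
    selection_b: AtomSelection,
    hmap: HomodimerMap,
    residues: Sequence[ResidueKey],
) -> tuple[dict[ResidueKey, float], list[ResidueKey]]:
    """|d_pair(B) - d_pair(A)| per residue between two end states.

    Residues absent from either structure (or unmapped) are returned in
    the missing list rather than raising.
    """
    keys_a = {a.residue_key for a in selection_a.atoms}
    keys_b = {a.residue_key for a in selection_b.atoms}
    out: dict[ResidueKey, float] = {}
    missing: list[ResidueKey] = []
    for res in residues:
        if res not in hmap.partner:
            missing.append(res)
            continue
        partner = hmap.partner[res]
        if not {res, partner} <= keys_a or not {res, partner} <= keys_b:
            missing.append(res)
            continue
        da = _dpair_static(structure_a, selection_a, res, hmap)
        db = _dpair_static(structure_b, selection_b, res, hmap)
        out[res] = abs(db - da)
    return out, missing


def min_residue_distance_series(
    traj: Trajectory, res_a: ResidueKey, res_b: ResidueKey
) -> np.ndarray:
    """Per frame, the minimum heavy-atom distance between two residues.

    Requires the trajectory selection to carry the residues' heavy atoms
    (hydrogens are ignored); raise otherwise so the caller can supply an
    all-atom trajectory.
    """
    ia = [
        j
        for j, a in enumerate(traj.selection.atoms)
        if a.residue_key == res_a and a.element.upper() != "H"
    ]
    ib = [
        j
        for j, a in enumerate(traj.selection.atoms)
        if a.residue_key == res_b and a.element.upper() != "H"
    ]
    if not ia or not ib:
        raise ConfigurationError(
            f"heavy atoms of {res_a} and {res_b} must be present in the "
            "trajectory selection; provide an all-atom trajectory"
        )
    pa = traj.coords[:, ia]  # (F, na, 3)
    pb = traj.coords[:, ib]  # (F, nb, 3)
    diff = pa[:, :, None, :] - pb[:, None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    return dist.reshape(traj.n_frames, -1).min(axis=1)
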