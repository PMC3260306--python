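"""Spin angle between the TMD dimer and the NBD dimer.

The spin angle measures the relative in-plane orientation of the two
domain dimers of a homodimeric transporter.  The reference structure's
TMD dimer is least-squares overlapped onto the TMD Cα atoms of the frame
under analysis, and likewise the reference NBD dimer onto the frame's NBD
atoms.  The two overlaps place the reference subunit mass centers into
the frame; the angle between the line connecting the two TMD subunit
centers and the line connecting the two NBD subunit centers is the spin
angle.  By default both lines are first projected onto the membrane
plane (the plane normal to the z axis of the pre-oriented input), so the
angle is a rotation about the transporter's quasi-twofold axis; the raw
3D angle is available by disabling the projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .structure_io import AtomSelection, HomodimerMap, Structure, Trajectory
from .superposition import superpose

__all__ = ["SpinAngleResult", "spin_angle", "spin_angle_series"]


@dataclass
class SpinAngleResult:
    angle: float  # degrees in [0, 180)
    signed_angle: float  # degrees in (-180, 180], sign from the normal
    tmd_line: np.ndarray  # (2, 3) transformed reference TMD subunit centers
    nbd_line: np.ndarray  # (2, 3) same for NBD
    normal: np.ndarray  # unit projection-plane normal (or NaNs if unprojected)


def _region_half_indices(
    selection: AtomSelection, hmap: HomodimerMap
) -> dict[tuple[str, int], np.ndarray]:
    """Selection indices grouped by (region, half); raises if a group is empty."""
    groups: dict[tuple[str, int], list[int]] = {
        ("TMD", 1): [], ("TMD", 2): [], ("NBD", 1): [], ("NBD", 2): []
    }
    for j, atom in enumerate(selection.atoms):
        key = atom.residue_key
        if key not in hmap.partner:
            continue
        groups[(hmap.region[key], hmap.half[key])].append(j)
    out = {}
    for (region, half), idx in groups.items():
        if not idx:
            raise ConfigurationError(
                f"homodimer map covers no {region} residues of half {half} "
                "in this selection"
            )
        out[(region, half)] = np.array(idx, dtype=int)
    return out


def _line_angles(v1: np.ndarray, v2: np.ndarray, normal: np.ndarray | None) -> tuple[float, float]:
    if normal is not None:
        n = normal / np.linalg.norm(normal)
        v1 = v1 - np.dot(v1, n) * n
        v2 = v2 - np.dot(v2, n) * n
    cross = np.cross(v1, v2)
    dot = float(np.dot(v1, v2))
    angle = float(np.degrees(np.arctan2(np.linalg.norm(cross), dot)))
    if normal is not None:
        n = normal / np.linalg.norm(normal)
        signed = float(np.degrees(np.arctan2(np.dot(cross, n), dot)))
    else:
        signed = angle
    return angle % 180.0, signed


def spin_angle(
    frame: np.ndarray,
    reference: Structure,
    selection: AtomSelection,
    hmap: HomodimerMap,
    project: bool = True,
    normal: np.ndarray = (0.0, 0.0, 1.0),
) -> SpinAngleResult:
    """Spin angle of one coordinate frame against the reference structure.

    Parameters
    ----------
    frame:
        (n, 3) coordinates over ``selection`` (same atom order as the
        reference's selection).
    reference:
        The structure providing the reference subunit dimers.
    selection:
        Cα selection shared by frame and reference.
    hmap:
        Homodimer map labelling each selected residue with region
        (TMD/NBD) and half (1/2).
    project:
        Project both center-connecting lines onto the membrane plane
        before measuring the angle (default); otherwise report the raw
        3D angle between the lines.
    normal:
        Membrane normal of the pre-oriented input (default z).
    """
    frame = np.asarray(frame, dtype=float)
    ref = selection.coords_from(reference)
    if frame.shape != ref.shape:
        raise ConfigurationError(
            f"frame shape {frame.shape} does not match selection ({ref.shape})"
        )
    groups = _region_half_indices(selection, hmap)
    lines = {}
    rotations = {}
    for region in ("TMD", "NBD"):
        idx = np.concatenate([groups[(region, 1)], groups[(region, 2)]])
        transform, _ = superpose(ref[idx], frame[idx])
        rotations[region] = transform.rotation
        centers = np.stack(
            [
                transform.apply(ref[groups[(region, 1)]].mean(axis=0)[None, :])[0],
                transform.apply(ref[groups[(region, 2)]].mean(axis=0)[None, :])[0],
            ]
        )
        lines[region] = centers
    v_tmd = lines["TMD"][1] - lines["TMD"][0]
    v_nbd = lines["NBD"][1] - lines["NBD"][0]
    if project:
        # the membrane is attached to the TMD: carry the reference normal
        # through the TMD overlap so the angle is invariant under global
        # rigid motions of the frame
        nvec = rotations["TMD"] @ np.asarray(normal, dtype=float)
        nvec = nvec / np.linalg.norm(nvec)
    else:
        nvec = None
    angle, signed = _line_angles(v_tmd, v_nbd, nvec)
    return SpinAngleResult(
        angle=angle,
        signed_angle=signed,
        tmd_line=lines["TMD"],
        nbd_line=lines["NBD"],
        normal=nvec if project else np.full(3, np.nan),
    )


def spin_angle_series(
    traj: Trajectory,
    reference: Structure,
    hmap: HomodimerMap,
    project: bool = True,
    normal: np.ndarray = (0.0, 0.0, 1.0),
    signed: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Spin angle for every frame; returns (labels, degrees).

    With ``signed=True`` the signed variant is reported, which is
    continuous across frames when the dimers rotate through alignment.
    """
    angles = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        res = spin_angle(
            traj.coords[f], reference, traj.selection, hmap, project=project, normal=normal
        )
        angles[f] = res.signed_angle if signed else res.angle
    return np.asarray(traj.labels), angles
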