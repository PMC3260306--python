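"""Pore profiling against analytic and grid oracles; d_pair and contacts."""

import numpy as np
import pytest

from dimergate import (
    Atom,
    AtomSelection,
    ConfigurationError,
    LayerDefinition,
    Structure,
    Trajectory,
    delta_dpair,
    dpair_series,
    layer_radius_series,
    min_residue_distance_series,
    pore_profile,
)

from .conftest import make_two_chain_structure, structure_tools
from .test_superposition import random_rotation

VDW = 1.7


def ring(radius: float, z: float, n: int = 12, phase: float = 0.0) -> np.ndarray:
    theta = phase + np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(n, z)]
    )


def grid_oracle(coords, vdw, z, extent=4.5, step=0.05):
    """Exhaustive in-plane search for the optimal sphere center."""
    xs = np.arange(-extent, extent + step / 2, step)
    cx, cy = np.meshgrid(xs, xs)
    centers = np.column_stack([cx.ravel(), cy.ravel(), np.full(cx.size, z)])
    dist = np.sqrt(
        ((centers[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    ) - vdw[None, :]
    return float(dist.min(axis=1).max())


def test_analytic_ring():
    coords = ring(6.0, 0.0)
    prof = pore_profile(coords, z_range=(0.0, 0.0), step=1.0, vdw=np.full(12, VDW))
    assert prof.radius[0] == pytest.approx(6.0 - VDW, abs=0.05)
    assert np.linalg.norm(prof.center[0]) < 0.05


def test_analytic_cylinder_constant():
    coords = np.vstack([ring(6.0, float(z)) for z in range(0, 11)])
    vdw = np.full(len(coords), VDW)
    prof = pore_profile(coords, z_range=(0.0, 10.0), step=1.0, vdw=vdw)
    np.testing.assert_allclose(prof.radius, 6.0 - VDW, atol=0.05)
    assert not prof.capped.any()


def test_random_cloud_matches_grid_oracle():
    rng = np.random.default_rng(20)
    # dense jittered cylindrical wall guarantees a channel near the axis
    walls = []
    for z in np.arange(-2.0, 3.0, 1.0):
        for radius in (5.0, 6.5):
            base = ring(radius, z, n=24, phase=rng.uniform(0, 0.3))
            walls.append(base + rng.normal(scale=0.3, size=base.shape))
    coords = np.vstack(walls)
    vdw = np.full(len(coords), VDW)
    prof = pore_profile(coords, z_range=(0.0, 2.0), step=1.0, vdw=vdw)
    for i, z in enumerate(prof.z):
        assert prof.radius[i] == pytest.approx(
            grid_oracle(coords, vdw, z), abs=0.05
        )


def test_rotation_invariance_with_axis():
    rng = np.random.default_rng(21)
    coords = np.vstack([ring(5.0, float(z), n=18) for z in range(0, 5)])
    vdw = np.full(len(coords), VDW)
    base = pore_profile(coords, z_range=(0.5, 3.5), step=1.0, vdw=vdw)
    for _ in range(3):
        r = random_rotation(rng)
        prof = pore_profile(
            coords @ r.T, axis=r @ np.array([0.0, 0.0, 1.0]),
            z_range=(0.5, 3.5), step=1.0, vdw=vdw,
        )
        np.testing.assert_allclose(prof.radius, base.radius, atol=0.05)


def test_atom_deletion_never_shrinks_radius():
    rng = np.random.default_rng(22)
    base = ring(5.0, 0.0, n=16) + rng.normal(scale=0.2, size=(16, 3))
    vdw = np.full(16, VDW)
    full = grid_oracle(base, vdw, 0.0)
    for drop in rng.choice(16, size=5, replace=False):
        keep = np.ones(16, dtype=bool)
        keep[drop] = False
        reduced = grid_oracle(base[keep], vdw[keep], 0.0)
        assert reduced >= full - 1e-9
        prof = pore_profile(base[keep], z_range=(0.0, 0.0), step=1.0, vdw=vdw[keep])
        assert prof.radius[0] == pytest.approx(reduced, abs=0.05)


def test_escape_is_capped_not_error():
    coords = ring(3.0, 0.0, n=8)
    prof = pore_profile(
        coords, z_range=(0.0, 12.0), step=12.0, vdw=np.full(8, VDW), max_radius=10.0
    )
    # slice far from any atom is capped, not an error
    assert not prof.capped[0] and prof.capped[-1]
    assert prof.radius[-1] == pytest.approx(10.0)


def _beads_selection(n):
    atoms = [
        Atom(chain="A", resnum=i + 1, icode="", resname="GLY", name="CA", element="C")
        for i in range(n)
    ]
    return AtomSelection(indices=np.arange(n), atoms=atoms, label="beads")


def test_layer_series_static_and_closing_gate():
    n = 12
    sel = _beads_selection(n)
    frames = []
    for f in range(6):
        radius = 6.0 - 0.6 * f  # ring shrinks 6.0 -> 3.0
        frames.append(ring(radius, 0.0, n=n))
    traj = Trajectory(np.array(frames), np.arange(6), sel)
    layer = LayerDefinition(name="gate", window=(-0.5, 0.5))
    series = layer_radius_series(traj, layer, vdw=np.full(n, VDW), step=0.5)
    assert series[0] - series[-1] == pytest.approx(3.0, abs=0.1)

    static = Trajectory(np.repeat(frames[0][None], 4, axis=0), np.arange(4), sel)
    sseries = layer_radius_series(static, layer, vdw=np.full(n, VDW), step=0.5)
    assert np.ptp(sseries) == pytest.approx(0.0, abs=1e-9)


def test_layer_window_validation():
    layer = LayerDefinition(name="bad", window=(2.0, 2.0))
    with pytest.raises(ConfigurationError):
        layer.resolve()
    with pytest.raises(ConfigurationError):
        LayerDefinition(name="nothing").resolve()


def test_dpair_constructed_and_translation():
    half1 = np.array([[10.0, 0.0, 0.0], [10.0, 0.0, 4.0], [10.0, 0.0, 8.0]])
    s = make_two_chain_structure(half1)
    sel, hmap = structure_tools(s)
    base = sel.coords_from(s)
    frames = []
    for f in range(5):
        frame = base.copy()
        frame[3:] += np.array([-(1.0 * f), 0.0, 0.0])  # half 2 drifts along -x
        frames.append(frame)
    traj = Trajectory(np.array(frames), np.arange(5), sel)
    series = dpair_series(traj, ("A", 1, ""), hmap)
    assert series.partner == ("B", 1, "")
    assert series.distances[0] == pytest.approx(20.0)
    np.testing.assert_allclose(np.diff(series.distances), 1.0, atol=1e-9)
    # brute force from raw coordinates
    for f in range(5):
        d = np.linalg.norm(frames[f][0] - frames[f][3])
        assert series.distances[f] == pytest.approx(d, abs=1e-12)
    with pytest.raises(ConfigurationError):
        dpair_series(traj, ("A", 99, ""), hmap)


def test_delta_dpair_end_states():
    half1 = np.array([[10.0, 0.0, 0.0], [10.0, 0.0, 4.0], [12.0, 0.0, 8.0]])
    s_a = make_two_chain_structure(half1)
    moved = half1.copy()
    moved[2, 0] += 6.5  # residue 3 d_pair grows by 13 (both halves move apart)
    s_b = make_two_chain_structure(moved)
    sel_a, hmap = structure_tools(s_a)
    sel_b, _ = structure_tools(s_b)
    residues = [("A", 1, ""), ("A", 2, ""), ("A", 3, ""), ("A", 9, "")]
    deltas, missing = delta_dpair(s_a, sel_a, s_b, sel_b, hmap, residues)
    assert missing == [("A", 9, "")]
    assert deltas[("A", 1, "")] == pytest.approx(0.0, abs=1e-9)
    assert deltas[("A", 3, "")] == pytest.approx(13.0, abs=1e-9)

    same, _ = delta_dpair(s_a, sel_a, s_a, sel_a, hmap, residues[:3])
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in same.values())


def test_delta_dpair_matches_brute_force():
    rng = np.random.default_rng(23)
    half_a = rng.uniform(5, 15, size=(6, 3))
    half_b = half_a + rng.normal(scale=2.0, size=(6, 3))
    s_a = make_two_chain_structure(half_a)
    s_b = make_two_chain_structure(half_b)
    sel_a, hmap = structure_tools(s_a)
    sel_b, _ = structure_tools(s_b)
    residues = [("A", i + 1, "") for i in range(6)]
    deltas, missing = delta_dpair(s_a, sel_a, s_b, sel_b, hmap, residues)
    assert not missing
    for i, res in enumerate(residues):
        da = np.linalg.norm(s_a.coords[i] - s_a.coords[6 + i])
        db = np.linalg.norm(s_b.coords[i] - s_b.coords[6 + i])
        assert deltas[res] == pytest.approx(abs(db - da), abs=1e-12)


def _residue_atoms(chain, resnum, names):
    return [
        Atom(chain=chain, resnum=resnum, icode="", resname="LEU", name=n, element="C")
        for n in names
    ]


def test_min_residue_distance():
    atoms = _residue_atoms("A", 1, ["CA"]) + _residue_atoms("B", 2, ["CA"])
    sel = AtomSelection(indices=np.arange(2), atoms=atoms, label="two")
    frames = []
    for f in range(4):
        frames.append(np.array([[0.0, 0.0, 0.0], [4.2 + f, 0.0, 0.0]]))
    traj = Trajectory(np.array(frames), np.arange(4), sel)
    series = min_residue_distance_series(traj, ("A", 1, ""), ("B", 2, ""))
    assert series[0] == pytest.approx(4.2)
    assert np.all(np.diff(series) > 0)
    with pytest.raises(ConfigurationError):
        min_residue_distance_series(traj, ("A", 1, ""), ("C", 9, ""))


def test_min_residue_distance_multiatom_brute_force():
    rng = np.random.default_rng(24)
    atoms = _residue_atoms("A", 1, ["CA", "CB", "CG"]) + _residue_atoms(
        "B", 2, ["CA", "CB", "CD1", "CD2"]
    )
    sel = AtomSelection(indices=np.arange(7), atoms=atoms, label="pair")
    frames = rng.uniform(0, 10, size=(3, 7, 3))
    traj = Trajectory(frames, np.arange(3), sel)
    series = min_residue_distance_series(traj, ("A", 1, ""), ("B", 2, ""))
    for f in range(3):
        best = min(
            np.linalg.norm(frames[f, i] - frames[f, j])
            for i in range(3)
            for j in range(3, 7)
        )
        assert series[f] == pytest.approx(best, abs=1e-12)
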