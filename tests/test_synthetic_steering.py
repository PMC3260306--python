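"""Toy homodimer construction, steering potential, Langevin runs, injection."""

import numpy as np
import pytest

from dimergate import (
    ConfigurationError,
    InstabilityError,
    SteeringSchedule,
    Trajectory,
    aij,
    build_toy_homodimer,
    casymm,
    casymm_series,
    classify_arps,
    inject_asymmetry,
    pore_profile,
    rmsd_to,
    run_steered,
    select_pairs,
    steering_energy,
)
from dimergate.errors import RangeError
from dimergate.synthetic_steering import _elastic_forces

from .conftest import constant_trajectory


def test_end_states_exactly_symmetric(toy, toy_pairs):
    for state in (toy.state_o, toy.state_i):
        for form in ("mean-absolute", "root-mean-square"):
            assert casymm(state, toy_pairs, form) == pytest.approx(0.0, abs=1e-9)


def test_two_gate_preset_apertures(toy):
    """State O: wide top / narrow bottom aperture; state I the reverse."""
    z_top = toy.gate_z["periplasmic"]
    prof_o = pore_profile(toy.as_structure("O"), z_range=(0.0, z_top), step=z_top)
    prof_i = pore_profile(toy.as_structure("I"), z_range=(0.0, z_top), step=z_top)
    assert prof_o.radius[-1] > prof_i.radius[-1]  # periplasmic: O wider
    assert prof_i.radius[0] > prof_o.radius[0]  # cytoplasmic: I wider


def test_build_determinism_and_validation():
    a = build_toy_homodimer(seed=5)
    b = build_toy_homodimer(seed=5)
    np.testing.assert_array_equal(a.state_o, b.state_o)
    np.testing.assert_array_equal(a.state_i, b.state_i)
    np.testing.assert_array_equal(a.edges, b.edges)
    c = build_toy_homodimer(seed=6)
    assert not np.array_equal(a.state_o, c.state_o)
    with pytest.raises(ConfigurationError):
        build_toy_homodimer(beads_per_chain=5)
    with pytest.raises(ConfigurationError):
        build_toy_homodimer(preset="nope")


def test_steering_energy_closed_form():
    rng = np.random.default_rng(30)
    frame = rng.normal(size=(1100, 3))
    schedule = SteeringSchedule(initial=2.0, final=2.0, steps=10, k=5550.0, n_atoms=1100)
    energy, forces = steering_energy(frame, frame, schedule, 5)
    # rmsd = 0, rmsd* = 2: E = k/(2N) * 4
    assert energy == pytest.approx(5550.0 / (2 * 1100) * 4.0, abs=1e-6)
    np.testing.assert_allclose(forces, 0.0, atol=1e-9)  # direction undefined at rmsd 0


def test_steering_energy_zero_when_schedule_met():
    rng = np.random.default_rng(31)
    target = rng.normal(size=(30, 3)) * 3
    frame = target + rng.normal(scale=0.5, size=target.shape)
    r = rmsd_to(frame, target)
    schedule = SteeringSchedule(initial=r, final=r, steps=4, k=100.0, n_atoms=30)
    energy, forces = steering_energy(frame, target, schedule, 2)
    assert energy == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(forces, 0.0, atol=1e-9)


def test_steering_forces_match_finite_differences():
    rng = np.random.default_rng(32)
    frame = rng.normal(size=(14, 3)) * 2
    target = rng.normal(size=(14, 3)) * 2
    schedule = SteeringSchedule(initial=3.0, final=0.0, steps=10, k=7.5, n_atoms=14)
    energy, forces = steering_energy(frame, target, schedule, 4)
    h = 1e-6
    num = np.zeros_like(forces)
    for i in range(14):
        for c in range(3):
            fp = frame.copy()
            fp[i, c] += h
            fm = frame.copy()
            fm[i, c] -= h
            ep, _ = steering_energy(fp, target, schedule, 4)
            em, _ = steering_energy(fm, target, schedule, 4)
            num[i, c] = -(ep - em) / (2 * h)
    assert np.max(np.abs(num - forces)) / np.max(np.abs(forces)) < 1e-5


def test_steering_net_force_zero():
    rng = np.random.default_rng(33)
    for _ in range(5):
        frame = rng.normal(size=(25, 3)) * 4
        target = rng.normal(size=(25, 3)) * 4
        schedule = SteeringSchedule(initial=2.0, final=0.0, steps=8, k=50.0, n_atoms=25)
        _, forces = steering_energy(frame, target, schedule, 3)
        np.testing.assert_allclose(forces.sum(axis=0), 0.0, atol=1e-9)


def test_schedule_validation():
    with pytest.raises(ConfigurationError):
        SteeringSchedule(initial=1.0, final=2.0, steps=10, k=1.0, n_atoms=10)
    with pytest.raises(ConfigurationError):
        SteeringSchedule(initial=1.0, final=0.0, steps=10, k=1.0, n_atoms=2)
    sch = SteeringSchedule(initial=4.0, final=0.0, steps=4, k=1.0, n_atoms=10)
    assert sch.rmsd_star(0) == 4.0 and sch.rmsd_star(4) == 0.0
    with pytest.raises(RangeError):
        sch.rmsd_star(5)
    with pytest.raises(Exception):
        steering_energy(np.zeros((5, 3)), np.zeros((5, 3)), sch, 1)  # N mismatch


def test_default_run_tracks_schedule(steered_oi):
    err = steered_oi.rmsd - steered_oi.rmsd_star
    assert np.sqrt(np.mean(err**2)) < 0.3
    assert steered_oi.rmsd[-1] <= 0.25
    # rmsd* non-increasing by construction
    assert np.all(np.diff(steered_oi.rmsd_star) <= 1e-12)


def test_run_determinism(toy, steered_oi):
    again = run_steered(toy, "O", seed=2)
    np.testing.assert_array_equal(steered_oi.trajectory.coords, again.trajectory.coords)
    other = run_steered(toy, "O", seed=3)
    assert not np.array_equal(steered_oi.trajectory.coords, other.trajectory.coords)


def test_zero_coupling_equals_unsteered_reference(toy):
    """With k = 0 the steering term contributes exactly zero force, so the
    trajectory must be bitwise identical to an independently integrated
    unsteered Langevin run consuming the same random stream."""
    initial = rmsd_to(toy.state_o, toy.state_i)
    schedule = SteeringSchedule(
        initial=initial, final=0.0, steps=200, k=0.0, n_atoms=toy.n_beads
    )
    steered = run_steered(toy, "O", schedule=schedule, seed=9, save_every=50)

    # reference: same integrator, elastic + noise only (incl. gate stiffening)
    dt, friction, spring_k, kT0 = 0.01, 1.0, 0.02, 0.01
    start = toy.state_o.copy()
    eq_len = np.linalg.norm(start[toy.edges[:, 0]] - start[toy.edges[:, 1]], axis=1)
    springs = np.full(len(toy.edges), spring_k)
    tmd = np.array([a.chain in ("A", "B") for a in toy.atoms])
    in_gate = tmd & (np.abs(start[:, 2] - toy.gate_z["cytoplasmic"]) < 1.2)
    stiff = in_gate[toy.edges[:, 0]] & in_gate[toy.edges[:, 1]]
    springs[stiff] *= 600.0
    rng = np.random.default_rng(9)
    coords = start.copy()
    frames = [coords.copy()]
    for step in range(1, 201):
        if stiff.any():
            length = np.linalg.norm(
                coords[toy.edges[:, 0]] - coords[toy.edges[:, 1]], axis=1
            )
            broke = stiff & (np.abs(length - eq_len) > 0.3)
            if broke.any():
                springs[broke] = spring_k
                stiff &= ~broke
        f_el = _elastic_forces(coords, toy.edges, eq_len, springs)
        noise = np.sqrt(2 * kT0 * dt / friction) * rng.standard_normal(coords.shape)
        coords = coords + (dt / friction) * f_el + noise
        if step % 50 == 0 or step == 200:
            frames.append(coords.copy())
    np.testing.assert_array_equal(steered.trajectory.coords, np.array(frames))


def test_null_steering_fluctuates_about_start(toy):
    """Start = target: the run must only jitter thermally around the state."""
    null = build_toy_homodimer(seed=1)
    null.state_i[:] = null.state_o
    steered = run_steered(null, "O", seed=12)
    assert steered.rmsd.mean() < 0.3


def test_initial_rmsd_star_clamped(toy):
    initial = rmsd_to(toy.state_o, toy.state_i)
    schedule = SteeringSchedule(
        initial=initial + 5.0, final=0.0, steps=100, k=3.0 * toy.n_beads**2,
        n_atoms=toy.n_beads,
    )
    with pytest.warns(UserWarning, match="clamping"):
        steered = run_steered(toy, "O", schedule=schedule, seed=4, save_every=50)
    assert steered.rmsd_star[0] == pytest.approx(initial, abs=1e-9)


def test_instability_detected(toy):
    with pytest.raises(InstabilityError):
        run_steered(toy, "O", seed=5, dt=5.0, save_every=10)


def test_inject_static_recovered_by_arps(toy, toy_selection, toy_pairs, toy_map):
    traj = constant_trajectory(toy.state_o, toy_selection, 5)
    perturbed = inject_asymmetry(traj, residues={10, 11, 12}, half=1, amplitude=2.0, seed=3)
    values = aij(perturbed, toy_pairs)
    table = classify_arps(values, toy_pairs, threshold=0.8)
    assert table.n_arp > 0
    injected = {("A", r, "") for r in (10, 11, 12)} | {("C", r, "") for r in (10, 11, 12)}
    allowed = injected | {toy_map.partner[k] for k in injected}
    for i in np.flatnonzero(table.is_arp):
        assert {toy_pairs.keys_i[i], toy_pairs.keys_j[i]} & allowed
    # maximal A_ij is attained at an injected pair
    top = int(np.argmax(values))
    assert {toy_pairs.keys_i[top], toy_pairs.keys_j[top]} & allowed


def test_inject_amplitude_zero_identity(toy, toy_selection):
    traj = constant_trajectory(toy.state_o, toy_selection, 3)
    out = inject_asymmetry(traj, residues={10}, half=1, amplitude=0.0, seed=3)
    np.testing.assert_array_equal(out.coords, traj.coords)


def test_inject_growing_casymm_non_decreasing(toy, toy_selection, toy_pairs):
    traj = constant_trajectory(toy.state_o, toy_selection, 8)
    grown = inject_asymmetry(
        traj, residues={10, 11}, half=1, amplitude=1.5, mode="growing", seed=5
    )
    series = casymm_series(grown, toy_pairs)
    assert series[0] == pytest.approx(0.0, abs=1e-12)
    assert np.all(np.diff(series) >= -1e-12)
    assert series[-1] > 0


def test_inject_arp_count_monotone_in_amplitude(toy, toy_selection, toy_pairs):
    traj = constant_trajectory(toy.state_o, toy_selection, 4)
    counts = []
    for amplitude in (0.0, 0.5, 1.0, 2.0):
        perturbed = inject_asymmetry(
            traj, residues={10, 11, 12}, half=1, amplitude=amplitude, seed=3
        )
        table = classify_arps(aij(perturbed, toy_pairs), toy_pairs, threshold=0.8)
        counts.append(table.n_arp)
    assert counts[0] == 0
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_inject_validation(toy, toy_selection):
    traj = constant_trajectory(toy.state_o, toy_selection, 2)
    with pytest.raises(ConfigurationError):
        inject_asymmetry(traj, residues={10}, half=1, chains=["B"])  # B is half 2
    with pytest.raises(ConfigurationError):
        inject_asymmetry(traj, residues={999}, half=1)
    with pytest.raises(ConfigurationError):
        inject_asymmetry(traj, residues={10}, half=1, amplitude=-1.0)
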