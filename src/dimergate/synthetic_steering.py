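"""Coarse-grained toy homodimer evolved under a targeted-steering potential.

This module generates synthetic trajectories with known ground truth so
that every analysis in the package (spin angle, C_asymm/A_ij/ARPs, pore
and gate metrics) can be exercised without external data.

The system is a Cα-like bead model of a homodimeric transporter: two
transmembrane-role chains (A/B) forming a channel wall around the z axis
and two cytoplasmic-domain-role chains (C/D) beneath it.  Both end
states (O: wide periplasmic aperture, narrow cytoplasmic aperture; I:
the reverse, with the wall twisted and the cytoplasmic domains rotated)
are exactly twofold symmetric about z by construction.  Beads interact
through a single-cutoff harmonic elastic network whose equilibrium
lengths come from the start state, plus the targeted-steering potential

    U(t) = k / (2N) * (rmsd(t) - rmsd*(t))**2,

where rmsd(t) is the instantaneous best-fit RMSD of the current
coordinates to the target state and rmsd*(t) a preset, monotonically
non-increasing schedule.  Dynamics are overdamped (position) Langevin in
reduced units; the same seed always reproduces a trajectory bitwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .channel_geometry import LayerDefinition
from .errors import (
    ConfigurationError,
    ConnectivityError,
    EmptyInputError,
    InstabilityError,
    RangeError,
    ShapeError,
)
from .structure_io import (
    Atom,
    AtomSelection,
    HomodimerMap,
    Structure,
    Trajectory,
    build_homodimer_map,
)
from .superposition import rmsd_to, superpose

__all__ = [
    "ToyHomodimer",
    "SteeringSchedule",
    "SteeredTrajectory",
    "build_toy_homodimer",
    "steering_energy",
    "run_steered",
    "inject_asymmetry",
]

TMD_CHAINS = ("A", "B")  # halves 1, 2
NBD_CHAINS = ("C", "D")
REGION_BY_CHAIN = {"A": "TMD", "B": "TMD", "C": "NBD", "D": "NBD"}
BEAD_VDW = 1.7  # Å, carbon-like beads

_ROT180 = np.diag([-1.0, -1.0, 1.0])  # twofold axis = z


def _rz(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class ToyHomodimer:
    """Bead coordinates, network topology and the two end states."""

    atoms: list[Atom]
    state_o: np.ndarray  # (n, 3)
    state_i: np.ndarray  # (n, 3)
    edges: np.ndarray  # (E, 2) bead index pairs
    vdw: np.ndarray  # (n,)
    contact_cutoff: float
    preset: str
    seed: int
    gate_z: dict[str, float] = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.atoms)

    def state(self, which: str) -> np.ndarray:
        if which not in ("O", "I"):
            raise ConfigurationError(f"state must be 'O' or 'I', got {which!r}")
        return self.state_o if which == "O" else self.state_i

    def as_structure(self, which: str = "O") -> Structure:
        return Structure(
            atoms=list(self.atoms),
            coords=self.state(which).copy(),
            vdw=self.vdw.copy(),
            name=f"toy-{self.preset}-{which}",
        )

    def selection(self) -> AtomSelection:
        return AtomSelection(
            indices=np.arange(self.n_beads),
            atoms=list(self.atoms),
            label="toy-all-beads",
        )

    def homodimer_map(self) -> HomodimerMap:
        return build_homodimer_map(
            self.as_structure("O"),
            half1_chains=[TMD_CHAINS[0], NBD_CHAINS[0]],
            half2_chains=[TMD_CHAINS[1], NBD_CHAINS[1]],
            region_by_chain=REGION_BY_CHAIN,
        )

    def gate_layers(self, half_width: float = 1.0) -> dict[str, LayerDefinition]:
        """Layer definitions of the two gates (two-gate-channel preset)."""
        if not self.gate_z:
            raise ConfigurationError(f"preset {self.preset!r} defines no gates")
        return {
            name: LayerDefinition(name=name, window=(z - half_width, z + half_width))
            for name, z in self.gate_z.items()
        }


@dataclass
class SteeringSchedule:
    """Monotone target-RMSD schedule with force constant and atom count."""

    initial: float  # Å
    final: float  # Å
    steps: int
    k: float  # kcal/mol/Å² convention, passed through as-is
    n_atoms: int

    def __post_init__(self) -> None:
        if self.final > self.initial:
            raise ConfigurationError("rmsd* schedule must be non-increasing")
        if self.k < 0:
            raise ConfigurationError("force constant must be non-negative")
        if self.n_atoms < 3:
            raise ConfigurationError("need at least 3 targeted atoms")
        if self.steps < 1:
            raise ConfigurationError("schedule needs at least one step")

    def rmsd_star(self, step: int) -> float:
        if not (0 <= step <= self.steps):
            raise RangeError(f"step {step} outside schedule 0..{self.steps}")
        frac = step / self.steps
        return self.initial + (self.final - self.initial) * frac


@dataclass
class SteeredTrajectory:
    """A trajectory plus per-frame steering diagnostics."""

    trajectory: Trajectory
    rmsd: np.ndarray  # instantaneous best-fit rmsd to target, per frame
    rmsd_star: np.ndarray  # scheduled value, per frame
    energy: np.ndarray  # steering energy, per frame
    schedule: SteeringSchedule
    seed: int

    def __post_init__(self) -> None:
        n = self.trajectory.n_frames
        if not (len(self.rmsd) == len(self.rmsd_star) == len(self.energy) == n):
            raise ShapeError("diagnostics length must equal frame count")


def _fibonacci_ball(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform filling of a ball with n points."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5**0.5) * k
    r = radius * (k / n) ** (1.0 / 3.0)
    return np.column_stack(
        [r * np.sin(phi) * np.cos(theta), r * np.sin(phi) * np.sin(theta), r * np.cos(phi)]
    )


def build_toy_homodimer(
    beads_per_chain: int = 40,
    preset: str = "two-gate-channel",
    contact_cutoff: float = 7.0,
    seed: int = 0,
) -> ToyHomodimer:
    """Construct the symmetric toy homodimer and its two end states.

    The two-gate-channel preset stacks partial bead rings around z.  In
    state O the ring radius widens from 4.5 Å at the bottom (cytoplasmic
    gate) to 8.0 Å at the top (periplasmic gate); state I reverses the
    profile and twists the wall azimuthally by 120°, so that a straight
    path between the states closes both apertures at mid-transition.
    The cytoplasmic-domain chains sit below the channel, their center
    axis rotated by 30° (state O) / 38° (state I) from the channel
    dimer axis.  The generic preset is a constant-radius cylinder with
    the same domain layout.  Both end states are exactly C2-symmetric
    about z; the seed only perturbs the cytoplasmic-domain bead packing
    (identically in both halves).
    """
    if beads_per_chain < 10:
        raise ConfigurationError("need at least 10 beads per chain")
    if preset not in ("two-gate-channel", "generic"):
        raise ConfigurationError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)

    # --- TMD wall, half 1: stacked partial rings in the x>0 half-plane
    n_levels = max(3, beads_per_chain // 4)
    base, extra = divmod(beads_per_chain, n_levels)
    counts = [base + (1 if k < extra else 0) for k in range(n_levels)]
    dz = 2.0
    z_top = dz * (n_levels - 1)
    r_narrow, r_wide = 4.5, 8.0

    def wall_half1(state: str) -> np.ndarray:
        pts = []
        for k, m in enumerate(counts):
            z = k * dz
            frac = k / (n_levels - 1)
            if preset == "two-gate-channel":
                r = r_narrow + (r_wide - r_narrow) * (frac if state == "O" else 1 - frac)
            else:
                r = 6.0
            for j in range(m):
                theta = -90.0 + (j + 0.5) * 180.0 / m
                t = np.radians(theta)
                pts.append((r * np.cos(t), r * np.sin(t), z))
        return np.array(pts)

    # --- NBD blob, half 1: quasi-uniform ball below the channel
    blob = _fibonacci_ball(beads_per_chain, radius=3.2)
    blob = blob + rng.normal(scale=0.15, size=blob.shape)  # packing jitter
    d_nbd, z_nbd = 6.5, -6.0

    def nbd_half1(state: str) -> np.ndarray:
        angle = 30.0 if state == "O" else 38.0
        center = np.array([d_nbd, 0.0, z_nbd])
        return (blob + center) @ _rz(angle).T

    def full(state: str) -> np.ndarray:
        t1 = wall_half1(state)
        n1 = nbd_half1(state)
        return np.vstack([t1, t1 @ _ROT180.T, n1, n1 @ _ROT180.T])

    state_o = full("O")
    state_i = full("I")

    atoms: list[Atom] = []
    for chain in (*TMD_CHAINS, *NBD_CHAINS):
        for res in range(1, beads_per_chain + 1):
            atoms.append(
                Atom(chain=chain, resnum=res, icode="", resname="GLY", name="CA", element="C")
            )
    # atom order above is A..., B..., C..., D... — rebuild to match coords
    order = [atoms[i] for i in range(len(atoms))]
    assert len(order) == len(state_o)

    # --- elastic network topology: union of contacts in the two states
    n = len(order)
    pair_set = set()
    for coords in (state_o, state_i):
        tree = cKDTree(coords)
        pair_set.update(map(tuple, tree.query_pairs(contact_cutoff, output_type="ndarray").tolist()))
    edges = np.array(sorted(pair_set), dtype=int)
    if len(edges) == 0:
        raise ConnectivityError("contact cutoff selects no edges")
    adj = csr_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ConnectivityError(
            f"elastic network splits into {n_comp} components at cutoff "
            f"{contact_cutoff} Å; increase the cutoff"
        )

    gate_z = {}
    if preset == "two-gate-channel":
        gate_z = {"cytoplasmic": 0.0, "periplasmic": z_top}
    return ToyHomodimer(
        atoms=order,
        state_o=state_o,
        state_i=state_i,
        edges=edges,
        vdw=np.full(n, BEAD_VDW),
        contact_cutoff=contact_cutoff,
        preset=preset,
        seed=seed,
        gate_z=gate_z,
    )


def steering_energy(
    frame: np.ndarray,
    target: np.ndarray,
    schedule: SteeringSchedule,
    step: int,
) -> tuple[float, np.ndarray]:
    """Steering energy and per-bead forces at one schedule step.

    The target is superposed onto the frame before differentiating, so
    the gradient is taken at the optimal fit; by the envelope argument
    the dependence through the rotation contributes nothing at the
    optimum, and the resulting forces sum exactly to zero (centroids of
    frame and fitted target coincide).  Forces vanish when the schedule
    is satisfied (rmsd = rmsd*).
    """
    frame = np.asarray(frame, dtype=float)
    target = np.asarray(target, dtype=float)
    if frame.shape != target.shape:
        raise ShapeError("frame and target shapes differ")
    n = schedule.n_atoms
    if frame.shape[0] != n:
        raise ShapeError(
            f"schedule expects {n} targeted atoms, frame has {frame.shape[0]}"
        )
    star = schedule.rmsd_star(step)
    transform, rmsd = superpose(target, frame)
    fitted = transform.apply(target)
    delta = rmsd - star
    energy = schedule.k / (2.0 * n) * delta * delta
    if rmsd < 1e-12:
        forces = np.zeros_like(frame)
    else:
        # dE/dx_i = (k/N) * delta * (x_i - y_i) / (N * rmsd)
        forces = -(schedule.k / n) * delta * (frame - fitted) / (n * rmsd)
    return float(energy), forces


def _elastic_forces(
    coords: np.ndarray, edges: np.ndarray, eq_len: np.ndarray, spring_k: np.ndarray
) -> np.ndarray:
    vec = coords[edges[:, 0]] - coords[edges[:, 1]]
    length = np.linalg.norm(vec, axis=1)
    length = np.where(length < 1e-12, 1e-12, length)
    f = (-spring_k * (length - eq_len))[:, None] * vec / length[:, None]
    out = np.zeros_like(coords)
    np.add.at(out, edges[:, 0], f)
    np.add.at(out, edges[:, 1], -f)
    return out


def run_steered(
    dimer: ToyHomodimer,
    from_state: str = "O",
    schedule: SteeringSchedule | None = None,
    temperature_factor: float = 1.0,
    friction: float = 1.0,
    seed: int = 0,
    save_every: int = 30,
    dt: float = 0.01,
    spring_k: float = 0.02,
    gate_stiffen: float = 600.0,
    gate_rupture: float = 0.3,
) -> SteeredTrajectory:
    """Run an overdamped Langevin steered transition between end states.

    ``from_state`` names the start; the other end state is the target.
    The default schedule decreases rmsd* linearly from the best-fit RMSD
    between the end states to 0 over 3000 steps with k = 3N² (the
    kcal/mol/Å² convention is accepted and passed through as-is; at toy
    scale only the ratio to the network spring constant matters).  ``temperature_factor`` scales the thermal
    noise amplitude (0 = deterministic descent); ``friction`` is the
    Langevin drag in reduced units.  The same seed and settings always
    produce a bitwise-identical trajectory.  A run whose rmsd to target
    exceeds twice its initial value aborts with InstabilityError.

    ``gate_stiffen`` multiplies the spring constant of network edges
    inside the start state's occluded gate layer (two-gate-channel
    preset), emulating the constriction's tight packing.  A stiffened
    contact breaks irreversibly once stretched beyond ``gate_rupture``
    Å (its constant drops back to the base value), the way a packed
    constriction ruptures under load: the closed gate therefore resists
    opening until late in the schedule and then snaps open, while the
    open gate closes on schedule — so the run passes through an
    intermediate with both gates occluded, as a steered transition of a
    real two-gate transporter does.  Set gate_stiffen=1 to disable the
    ordering.
    """
    if friction <= 0 or dt <= 0:
        raise ConfigurationError("friction and dt must be positive")
    start = dimer.state(from_state).copy()
    target = dimer.state("I" if from_state == "O" else "O")
    initial_rmsd = rmsd_to(start, target)
    if schedule is None:
        # default k scales with N² so the per-bead restraint stiffness
        # k/N² (≈3 energy/Å²) always dominates the elastic network
        # (spring_k × mean degree ≈ 0.6) and the run tracks its schedule
        schedule = SteeringSchedule(
            initial=initial_rmsd,
            final=0.0,
            steps=3000,
            k=3.0 * dimer.n_beads**2,
            n_atoms=dimer.n_beads,
        )
    if schedule.n_atoms != dimer.n_beads:
        raise ConfigurationError(
            f"schedule targets {schedule.n_atoms} atoms, dimer has {dimer.n_beads}"
        )
    if schedule.initial > initial_rmsd + 1e-9:
        warnings.warn(
            f"initial rmsd* ({schedule.initial:.2f} Å) exceeds the best-fit "
            f"RMSD between the end states ({initial_rmsd:.2f} Å); clamping",
            stacklevel=2,
        )
        schedule = SteeringSchedule(
            initial=initial_rmsd,
            final=min(schedule.final, initial_rmsd),
            steps=schedule.steps,
            k=schedule.k,
            n_atoms=schedule.n_atoms,
        )

    rng = np.random.default_rng(seed)
    kT0 = 0.01  # reduced baseline temperature
    noise_amp = temperature_factor * np.sqrt(2.0 * kT0 * dt / friction)
    eq_len = np.linalg.norm(
        start[dimer.edges[:, 0]] - start[dimer.edges[:, 1]], axis=1
    )
    springs = np.full(len(dimer.edges), float(spring_k))
    stiff = np.zeros(len(dimer.edges), dtype=bool)
    if gate_stiffen != 1.0 and dimer.gate_z:
        narrow = dimer.gate_z["cytoplasmic" if from_state == "O" else "periplasmic"]
        tmd = np.array([a.chain in TMD_CHAINS for a in dimer.atoms])
        in_gate = tmd & (np.abs(start[:, 2] - narrow) < 1.2)
        stiff = in_gate[dimer.edges[:, 0]] & in_gate[dimer.edges[:, 1]]
        springs[stiff] *= gate_stiffen
    divergence_limit = 2.0 * max(initial_rmsd, 1.0)

    coords = start.copy()
    frames, diag_rmsd, diag_star, diag_energy, labels = [], [], [], [], []

    def record(step: int) -> None:
        energy, _ = steering_energy(coords, target, schedule, step)
        frames.append(coords.copy())
        diag_rmsd.append(rmsd_to(coords, target))
        diag_star.append(schedule.rmsd_star(step))
        diag_energy.append(energy)
        labels.append(step)

    record(0)
    for step in range(1, schedule.steps + 1):
        if stiff.any():
            # irreversible rupture of overstretched gate contacts
            length = np.linalg.norm(
                coords[dimer.edges[:, 0]] - coords[dimer.edges[:, 1]], axis=1
            )
            broke = stiff & (np.abs(length - eq_len) > gate_rupture)
            if broke.any():
                springs[broke] = spring_k
                stiff &= ~broke
        f_el = _elastic_forces(coords, dimer.edges, eq_len, springs)
        _, f_st = steering_energy(coords, target, schedule, step)
        noise = noise_amp * rng.standard_normal(coords.shape)
        coords = coords + (dt / friction) * (f_el + f_st) + noise
        if step % save_every == 0 or step == schedule.steps:
            record(step)
            if diag_rmsd[-1] > divergence_limit:
                raise InstabilityError(
                    f"rmsd to target reached {diag_rmsd[-1]:.2f} Å "
                    f"(> {divergence_limit:.2f}); reduce dt or raise friction"
                )

    traj = Trajectory(
        coords=np.array(frames),
        labels=np.array(labels),
        selection=dimer.selection(),
    )
    return SteeredTrajectory(
        trajectory=traj,
        rmsd=np.array(diag_rmsd),
        rmsd_star=np.array(diag_star),
        energy=np.array(diag_energy),
        schedule=schedule,
        seed=seed,
    )


def _half_chains(half: int) -> set[str]:
    return {TMD_CHAINS[half - 1], NBD_CHAINS[half - 1]}


def inject_asymmetry(
    traj: Trajectory,
    residues: Iterable[int],
    half: int = 1,
    amplitude: float = 1.0,
    mode: str = "static",
    seed: int = 0,
    chains: Sequence[str] | None = None,
) -> Trajectory:
    """Displace named residues of one half by a known amount.

    Each targeted residue is moved along a reproducible random unit
    direction by ``amplitude`` Å — identically in every frame (static
    mode) or scaled linearly from 0 to amplitude across frames (growing
    mode).  All other coordinates are untouched.  Ground truth for
    ARP-recovery tests.
    """
    if amplitude < 0:
        raise ConfigurationError("amplitude must be non-negative")
    if mode not in ("static", "growing"):
        raise ConfigurationError(f"mode must be 'static' or 'growing', got {mode!r}")
    if half not in (1, 2):
        raise ConfigurationError("half must be 1 or 2")
    residues = sorted(set(residues))
    if not residues:
        raise EmptyInputError("no residues to perturb")
    allowed = _half_chains(half) if chains is None else set(chains)
    bad = allowed - _half_chains(half)
    if bad:
        raise ConfigurationError(f"chains {sorted(bad)} are not in half {half}")

    targets: dict[tuple[str, int], list[int]] = {}
    for j, atom in enumerate(traj.selection.atoms):
        if atom.chain in allowed and atom.resnum in residues:
            targets.setdefault((atom.chain, atom.resnum), []).append(j)
    found = {r for (_, r) in targets}
    missing = [r for r in residues if r not in found]
    if missing:
        raise ConfigurationError(
            f"residues {missing} not found in half {half} (chains {sorted(allowed)})"
        )

    rng = np.random.default_rng(seed)
    coords = traj.coords.copy()
    nf = traj.n_frames
    for (chain, resnum) in sorted(targets):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        for j in targets[(chain, resnum)]:
            if mode == "static" or nf == 1:
                coords[:, j] += amplitude * u
            else:
                scale = np.linspace(0.0, 1.0, nf)[:, None]
                coords[:, j] += amplitude * scale * u
    return Trajectory(coords=coords, labels=traj.labels.copy(), selection=traj.selection)
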