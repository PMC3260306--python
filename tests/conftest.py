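"""Shared fixtures: toy homodimer, steered runs, small hand-built structures."""

from __future__ import annotations

import numpy as np
import pytest

from dimergate import (
    Atom,
    AtomSelection,
    Structure,
    Trajectory,
    build_homodimer_map,
    build_toy_homodimer,
    run_steered,
    select_calpha,
    select_pairs,
)


@pytest.fixture(scope="session")
def toy():
    return build_toy_homodimer(seed=1)


@pytest.fixture(scope="session")
def toy_selection(toy):
    return toy.selection()


@pytest.fixture(scope="session")
def toy_map(toy):
    return toy.homodimer_map()


@pytest.fixture(scope="session")
def toy_pairs(toy, toy_selection, toy_map):
    return select_pairs(toy.as_structure("O"), toy_selection, toy_map, d0=8.0)


@pytest.fixture(scope="session")
def steered_oi(toy):
    """Default O→I steered run, shared by the schedule/gate tests."""
    return run_steered(toy, "O", seed=2)


@pytest.fixture(scope="session")
def steered_io(toy):
    """Default I→O steered run."""
    return run_steered(toy, "I", seed=7)


def make_two_chain_structure(
    half1: np.ndarray, chain1: str = "A", chain2: str = "B", mirror: bool = True
) -> Structure:
    """Symmetric two-chain Cα structure: chain B is chain A rotated 180° about z."""
    rot180 = np.diag([-1.0, -1.0, 1.0])
    half2 = half1 @ rot180.T if mirror else half1.copy()
    atoms = []
    for chain, block in ((chain1, half1), (chain2, half2)):
        for i in range(len(block)):
            atoms.append(
                Atom(chain=chain, resnum=i + 1, icode="", resname="GLY", name="CA", element="C")
            )
    coords = np.vstack([half1, half2])
    return Structure(atoms=atoms, coords=coords, vdw=np.full(len(atoms), 1.7))


def structure_tools(structure: Structure):
    """(selection, homodimer map) for a two-chain A/B structure."""
    sel = select_calpha(structure, {"A", "B"})
    hmap = build_homodimer_map(structure, ["A"], ["B"], {"A": "TMD", "B": "TMD"})
    return sel, hmap


def constant_trajectory(frame: np.ndarray, selection: AtomSelection, n_frames: int) -> Trajectory:
    coords = np.repeat(frame[None, :, :], n_frames, axis=0)
    return Trajectory(coords=coords, labels=np.arange(n_frames), selection=selection)
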