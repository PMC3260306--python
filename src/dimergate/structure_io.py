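"""Structure and trajectory I/O plus the homodimer partner mapping.

Structures and trajectories are exchanged as (multi-model) PDB text, read
and written through :mod:`gemmi`.  Atoms carry per-element van der Waals
radii assigned from a bundled table (overridable), because pore profiling
needs them and crystallographic files do not store radii.

A residue is identified everywhere by the key ``(chain, resnum, icode)``;
insertion-coded residues are kept as distinct residues and numbering is
never silently changed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    ConfigurationError,
    ConsistencyError,
    FormatError,
    RangeError,
    SelectionError,
)

__all__ = [
    "Atom",
    "Structure",
    "AtomSelection",
    "HomodimerMap",
    "Trajectory",
    "VDW_RADII",
    "read_structure",
    "write_structure",
    "write_trajectory",
    "select_calpha",
    "build_homodimer_map",
    "read_trajectory",
]

#: Per-element van der Waals radii in Å (Bondi-style values commonly used
#: for pore profiling).  Elements not listed fall back to ``VDW_DEFAULT``.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
VDW_DEFAULT = 1.70

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """Identity of one atom; coordinates live in the owning container."""

    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.resnum, self.icode)


@dataclass
class Structure:
    """One coordinate set of a (possibly multi-model) PDB file."""

    atoms: list[Atom]
    coords: np.ndarray  # (n_atoms, 3) Å
    vdw: np.ndarray  # (n_atoms,) Å
    n_models: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.vdw = np.asarray(self.vdw, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ConsistencyError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ConsistencyError("non-finite coordinates in structure")
        if np.any(self.vdw <= 0):
            raise ConsistencyError("van der Waals radii must be positive")

    def __len__(self) -> int:
        return len(self.atoms)

    def atom_index(self) -> dict[tuple[ResidueKey, str], int]:
        """Map (residue key, atom name) -> position in the atom list."""
        return {
            (a.residue_key, a.name): i for i, a in enumerate(self.atoms)
        }


@dataclass
class AtomSelection:
    """An ordered, duplicate-free list of atoms out of a Structure."""

    indices: np.ndarray  # positions in the parent structure's atom list
    atoms: list[Atom]  # same order as indices
    label: str = ""
    skipped: list[ResidueKey] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords_from(self, structure: Structure) -> np.ndarray:
        return structure.coords[self.indices]

    def residue_keys(self) -> list[ResidueKey]:
        return [a.residue_key for a in self.atoms]


@dataclass
class HomodimerMap:
    """Symmetry-partner mapping between the two halves of a homodimer.

    ``partner`` is an involution over residue keys: the partner of a
    residue in half 1 is the same-numbered residue of the paired chain in
    half 2 and vice versa.  ``region`` labels every mapped residue TMD or
    NBD; partners always share the label.
    """

    partner: dict[ResidueKey, ResidueKey]
    region: dict[ResidueKey, str]  # "TMD" | "NBD"
    half: dict[ResidueKey, int]  # 1 | 2
    unmatched: list[ResidueKey] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.partner)

    def residues(self, half: int | None = None, region: str | None = None) -> list[ResidueKey]:
        out = []
        for key in self.partner:
            if half is not None and self.half[key] != half:
                continue
            if region is not None and self.region[key] != region:
                continue
            out.append(key)
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom selection."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    labels: np.ndarray  # (n_frames,), strictly increasing
    selection: AtomSelection

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConsistencyError("trajectory coords must be (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.selection):
            raise ConsistencyError("frame atom count does not match selection")
        if len(self.labels) != self.coords.shape[0]:
            raise ConsistencyError("labels length does not match frame count")
        if len(self.labels) > 1 and not np.all(np.diff(self.labels) > 0):
            raise ConsistencyError("frame labels must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames


def _validate_pdb_text(path: Path) -> None:
    """Reject ATOM/HETATM records with unparseable coordinate fields.

    gemmi is deliberately lenient; this pre-pass gives a precise error
    naming the offending line instead of silently reading garbage.
    """
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        value = float(fieldtxt)
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {lineno}: unparseable coordinate "
                            f"field {fieldtxt!r}"
                        ) from None
                    if not math.isfinite(value):
                        raise FormatError(
                            f"{path}: line {lineno}: non-finite coordinate"
                        )


def _vdw_for(element: str, radii: Mapping[str, float]) -> float:
    return radii.get(element.upper(), VDW_DEFAULT)


def _model_to_structure(
    model: gemmi.Model, n_models: int, radii: Mapping[str, float], name: str
) -> Structure:
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    vdw: list[float] = []
    for chain in model:
        for res in chain:
            for at in res:
                # keep altloc blank or 'A'; drop alternates
                if at.altloc not in ("\0", "", "A"):
                    continue
                element = at.element.name if at.element else ""
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        icode=(res.seqid.icode or " ").strip(),
                        resname=res.name,
                        name=at.name,
                        element=element,
                    )
                )
                coords.append((at.pos.x, at.pos.y, at.pos.z))
                vdw.append(_vdw_for(element, radii))
    return Structure(
        atoms=atoms,
        coords=np.array(coords, dtype=float).reshape(len(atoms), 3),
        vdw=np.array(vdw, dtype=float),
        n_models=n_models,
        name=name,
    )


def read_structure(
    path: str | Path,
    model_index: int = 1,
    vdw_radii: Mapping[str, float] | None = None,
) -> Structure:
    """Read one coordinate set out of a (multi-model) PDB file.

    Parameters
    ----------
    path:
        PDB file with ATOM/HETATM records.
    model_index:
        1-based position of the coordinate set to extract.
    vdw_radii:
        Optional element → radius override table (Å); unlisted elements
        fall back to the bundled defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no coordinate models found")
    if not (1 <= model_index <= len(st)):
        raise RangeError(
            f"{path}: model {model_index} requested but file has {len(st)} model(s)"
        )
    radii = dict(VDW_RADII)
    if vdw_radii:
        radii.update({k.upper(): float(v) for k, v in vdw_radii.items()})
    return _model_to_structure(st[model_index - 1], len(st), radii, path.stem)


def _gemmi_model(num: int, atoms: Sequence[Atom], coords: np.ndarray) -> gemmi.Model:
    model = gemmi.Model(num)
    chain = None
    res = None
    for atom, xyz in zip(atoms, coords):
        if chain is None or chain.name != atom.chain:
            if chain is not None:
                model.add_chain(chain)
            chain = gemmi.Chain(atom.chain)
            res = None
        if (
            res is None
            or res.seqid.num != atom.resnum
            or (res.seqid.icode.strip() or "") != atom.icode
            or res.name != atom.resname
        ):
            res = gemmi.Residue()
            res.name = atom.resname
            res.seqid = gemmi.SeqId(atom.resnum, atom.icode if atom.icode else " ")
            res.het_flag = "A"
            chain.add_residue(res)
            res = chain[-1]
        g = gemmi.Atom()
        g.name = atom.name
        g.element = gemmi.Element(atom.element or "C")
        g.occ = 1.0
        g.pos = gemmi.Position(*map(float, xyz))
        res.add_atom(g)
    if chain is not None:
        model.add_chain(chain)
    return model


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as single-model PDB (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.add_model(_gemmi_model(1, structure.atoms, structure.coords))
    Path(path).write_text(st.make_pdb_string())


def write_trajectory(
    atoms: Sequence[Atom], frames: np.ndarray | Iterable[np.ndarray], path: str | Path
) -> None:
    """Write ordered frames over a fixed atom list as multi-model PDB."""
    st = gemmi.Structure()
    for k, frame in enumerate(frames):
        st.add_model(_gemmi_model(k + 1, atoms, np.asarray(frame, dtype=float)))
    if len(st) == 0:
        raise ConsistencyError("no frames to write")
    Path(path).write_text(st.make_pdb_string())


def select_calpha(structure: Structure, chains: Iterable[str], label: str = "") -> AtomSelection:
    """Select the Cα atoms of the named chains.

    Atoms come out sorted by (chain id, residue number, insertion code),
    one per residue; residues lacking a Cα are skipped and listed in the
    selection's ``skipped`` attribute.  Calcium ions (atom name CA but
    element Ca) are never selected.
    """
    wanted = set(chains)
    if not wanted:
        raise SelectionError("no chains requested")
    hits: dict[ResidueKey, int] = {}
    residues_seen: set[ResidueKey] = set()
    for i, atom in enumerate(structure.atoms):
        if atom.chain not in wanted:
            continue
        residues_seen.add(atom.residue_key)
        if atom.name == "CA" and atom.element.upper() != "CA":
            hits.setdefault(atom.residue_key, i)
    if not hits:
        raise SelectionError(
            f"no C-alpha atoms found in chains {sorted(wanted)}"
        )
    order = sorted(hits, key=lambda k: (k[0], k[1], k[2]))
    indices = np.array([hits[k] for k in order], dtype=int)
    skipped = sorted(residues_seen - set(hits), key=lambda k: (k[0], k[1], k[2]))
    return AtomSelection(
        indices=indices,
        atoms=[structure.atoms[i] for i in indices],
        label=label or f"calpha:{'+'.join(sorted(wanted))}",
        skipped=skipped,
    )


def build_homodimer_map(
    structure: Structure,
    half1_chains: Sequence[str],
    half2_chains: Sequence[str],
    region_by_chain: Mapping[str, str],
) -> HomodimerMap:
    """Pair symmetry-equivalent residues of the two halves of a homodimer.

    Chain ``half1_chains[i]`` is paired with ``half2_chains[i]``; within a
    chain pair, residues with equal (residue number, insertion code) are
    partners.  Residues with no same-numbered counterpart are excluded and
    reported via ``unmatched``.  Each chain must carry a region label in
    ``region_by_chain`` ("TMD" or "NBD"), identical within a chain pair.
    """
    if len(half1_chains) != len(half2_chains):
        raise ConfigurationError(
            f"half chain lists differ in length: {list(half1_chains)} vs "
            f"{list(half2_chains)}"
        )
    for ch in list(half1_chains) + list(half2_chains):
        if ch not in region_by_chain:
            raise ConfigurationError(f"chain {ch!r} has no region label")
        if region_by_chain[ch] not in ("TMD", "NBD"):
            raise ConfigurationError(
                f"chain {ch!r}: region must be TMD or NBD, got {region_by_chain[ch]!r}"
            )
    for c1, c2 in zip(half1_chains, half2_chains):
        if region_by_chain[c1] != region_by_chain[c2]:
            raise ConfigurationError(
                f"paired chains {c1!r}/{c2!r} have different region labels"
            )

    by_chain: dict[str, dict[tuple[int, str], ResidueKey]] = {}
    for atom in structure.atoms:
        by_chain.setdefault(atom.chain, {}).setdefault(
            (atom.resnum, atom.icode), atom.residue_key
        )

    partner: dict[ResidueKey, ResidueKey] = {}
    region: dict[ResidueKey, str] = {}
    half: dict[ResidueKey, int] = {}
    unmatched: list[ResidueKey] = []
    for c1, c2 in zip(half1_chains, half2_chains):
        res1 = by_chain.get(c1, {})
        res2 = by_chain.get(c2, {})
        for num_icode, key1 in res1.items():
            key2 = res2.get(num_icode)
            if key2 is None:
                unmatched.append(key1)
                continue
            partner[key1] = key2
            partner[key2] = key1
            region[key1] = region[key2] = region_by_chain[c1]
            half[key1] = 1
            half[key2] = 2
        for num_icode, key2 in res2.items():
            if num_icode not in res1:
                unmatched.append(key2)
    if not partner:
        raise ConfigurationError("homodimer map is empty: no residues matched")
    return HomodimerMap(partner=partner, region=region, half=half, unmatched=unmatched)


def read_trajectory(
    path: str | Path,
    selection: AtomSelection,
    vdw_radii: Mapping[str, float] | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory over ``selection``.

    Every model must contain every selected atom; frames keep the model
    order of the file and are labelled 0..n-1.
    """
    path = Path(path)
    _validate_pdb_text(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no coordinate models found")
    radii = dict(VDW_RADII)
    if vdw_radii:
        radii.update({k.upper(): float(v) for k, v in vdw_radii.items()})
    frames = np.empty((len(st), len(selection), 3), dtype=float)
    for m, model in enumerate(st):
        frame_struct = _model_to_structure(model, len(st), radii, path.stem)
        index = frame_struct.atom_index()
        for j, atom in enumerate(selection.atoms):
            pos = index.get((atom.residue_key, atom.name))
            if pos is None:
                raise ConsistencyError(
                    f"{path}: model {m + 1} is missing atom "
                    f"{atom.chain}/{atom.resnum}{atom.icode}/{atom.name}"
                )
            frames[m, j] = frame_struct.coords[pos]
    return Trajectory(coords=frames, labels=np.arange(len(st)), selection=selection)
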