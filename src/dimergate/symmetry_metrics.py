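"""Symmetry-breaking statistics for homodimer trajectories.

For a residue pair (i, j) with Cα separation d_ij, the symmetry partner
pair (i', j') lives in the opposite half of the homodimer.  The asymmetry
coefficient C_asymm aggregates |d_ij - d_i'j'| over a fixed pair set; the
per-pair coefficient A_ij is the quadratic mean of |d_ij - d_i'j'| along
a trajectory, and pairs whose A_ij exceeds a threshold are flagged as
asymmetric residue pairs (ARPs).  All quantities are built from internal
distances only, so they are invariant under global rigid motions and
need no superposition.

Pairs are selected once, from a reference structure, with a strict
distance cutoff d0 (default 8 Å), and held fixed along trajectories.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ConsistencyError, EmptyInputError
from .structure_io import AtomSelection, HomodimerMap, Structure, Trajectory

__all__ = [
    "REGION_CLASSES",
    "SymmetryPairSet",
    "ARPTable",
    "select_pairs",
    "casymm",
    "casymm_series",
    "aij",
    "classify_arps",
]

ResidueKey = tuple[str, int, str]

#: Pair taxonomy: within a TMD chain, within an NBD chain, across the
#: TMD-NBD interface, and across the two half-interfaces of the dimer.
REGION_CLASSES = ("TMD", "NBD", "TMD-NBD", "TMD-TMD'", "NBD-NBD'")


@dataclass
class SymmetryPairSet:
    """A fixed set of residue pairs with their symmetry partners.

    The index arrays point into the Cα selection used at selection time;
    any frame over the same selection can be scored against them.
    """

    d0: float
    keys_i: list[ResidueKey]
    keys_j: list[ResidueKey]
    idx_i: np.ndarray
    idx_j: np.ndarray
    idx_ip: np.ndarray  # partner of i
    idx_jp: np.ndarray  # partner of j
    region_class: list[str]
    selection: AtomSelection
    deduplicated: bool = False

    @property
    def n_pair(self) -> int:
        return len(self.keys_i)

    def __len__(self) -> int:
        return self.n_pair

    def region_counts(self) -> Counter:
        return Counter(self.region_class)


@dataclass
class ARPTable:
    """Per-pair A_ij with threshold classification and tier histogram."""

    aij: np.ndarray
    threshold: float
    is_arp: np.ndarray  # bool mask, A_ij > threshold
    region_counts: Counter  # ARPs per region class
    tier_edges: tuple[float, ...]
    tier_counts: np.ndarray  # pairs (all pairs) falling in each tier bin
    pairs: SymmetryPairSet

    @property
    def n_arp(self) -> int:
        return int(self.is_arp.sum())


def _classify(region_i: str, region_j: str, half_i: int, half_j: int) -> str:
    if region_i != region_j:
        return "TMD-NBD"
    if half_i == half_j:
        return region_i
    return f"{region_i}-{region_i}'"


def select_pairs(
    structure: Structure,
    selection: AtomSelection,
    hmap: HomodimerMap,
    d0: float = 8.0,
    deduplicate: bool = False,
) -> SymmetryPairSet:
    """Select all Cα pairs closer than d0 whose partners are both mapped.

    The cutoff is strict (< d0).  Each unordered pair is listed once; a
    pair and its symmetry image are distinct entries when both satisfy
    the cutoff, unless ``deduplicate`` keeps only one representative per
    symmetry-equivalent pair.
    """
    if d0 <= 0:
        raise ConfigurationError("d0 must be positive")
    if not len(hmap):
        raise ConfigurationError("homodimer map is empty")
    coords = selection.coords_from(structure)
    keys = selection.residue_keys()
    pos_of = {k: i for i, k in enumerate(keys)}

    tree = cKDTree(coords)
    candidates = tree.query_pairs(d0, output_type="ndarray")
    # the cutoff is strict (< d0); the KD-tree query includes d == d0
    if len(candidates):
        dist = np.linalg.norm(coords[candidates[:, 0]] - coords[candidates[:, 1]], axis=1)
        candidates = candidates[dist < d0]
    raw = sorted(candidates.tolist())

    keys_i: list[ResidueKey] = []
    keys_j: list[ResidueKey] = []
    idx_i, idx_j, idx_ip, idx_jp = [], [], [], []
    region_class: list[str] = []
    seen: set[tuple] = set()
    for a, b in raw:
        ki, kj = keys[a], keys[b]
        if ki not in hmap.partner or kj not in hmap.partner:
            continue
        kip, kjp = hmap.partner[ki], hmap.partner[kj]
        if kip not in pos_of or kjp not in pos_of:
            continue  # partner residue lacks a Cα in this selection
        if deduplicate:
            canon = min(
                tuple(sorted((ki, kj))),
                tuple(sorted((kip, kjp))),
            )
            if canon in seen:
                continue
            seen.add(canon)
        keys_i.append(ki)
        keys_j.append(kj)
        idx_i.append(a)
        idx_j.append(b)
        idx_ip.append(pos_of[kip])
        idx_jp.append(pos_of[kjp])
        region_class.append(
            _classify(hmap.region[ki], hmap.region[kj], hmap.half[ki], hmap.half[kj])
        )
    return SymmetryPairSet(
        d0=d0,
        keys_i=keys_i,
        keys_j=keys_j,
        idx_i=np.array(idx_i, dtype=int),
        idx_j=np.array(idx_j, dtype=int),
        idx_ip=np.array(idx_ip, dtype=int),
        idx_jp=np.array(idx_jp, dtype=int),
        region_class=region_class,
        selection=selection,
        deduplicated=deduplicate,
    )


def _pair_deltas(frame: np.ndarray, pairs: SymmetryPairSet) -> np.ndarray:
    """|d_ij - d_i'j'| for every pair in one frame."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] != len(pairs.selection):
        raise ConsistencyError(
            f"frame shape {frame.shape} does not cover the pair selection "
            f"({len(pairs.selection)} atoms)"
        )
    if not np.all(np.isfinite(frame)):
        raise ConsistencyError("frame contains non-finite coordinates")
    d = np.linalg.norm(frame[pairs.idx_i] - frame[pairs.idx_j], axis=1)
    dp = np.linalg.norm(frame[pairs.idx_ip] - frame[pairs.idx_jp], axis=1)
    return np.abs(d - dp)


def casymm(frame: np.ndarray, pairs: SymmetryPairSet, form: str = "mean-absolute") -> float:
    """Asymmetry coefficient of one frame (Å).

    ``form`` selects the aggregation over pairs: "mean-absolute"
    (default) or "root-mean-square".  Zero for an exactly symmetric
    structure under either form.
    """
    if pairs.n_pair == 0:
        raise EmptyInputError("pair set is empty")
    deltas = _pair_deltas(frame, pairs)
    if form == "mean-absolute":
        return float(np.mean(deltas))
    if form == "root-mean-square":
        return float(np.sqrt(np.mean(deltas**2)))
    raise ConfigurationError(f"unknown aggregation form {form!r}")


def casymm_series(
    traj: Trajectory, pairs: SymmetryPairSet, form: str = "mean-absolute"
) -> np.ndarray:
    """C_asymm for every frame of a trajectory."""
    return np.array([casymm(traj.coords[f], pairs, form) for f in range(traj.n_frames)])


def aij(traj: Trajectory, pairs: SymmetryPairSet) -> np.ndarray:
    """Per-pair asymmetry coefficient A_ij (Å).

    Quadratic mean of |d_ij - d_i'j'| over the frames of the trajectory;
    a single-frame input reduces to the per-frame |d_ij - d_i'j'|.
    """
    if traj.n_frames == 0:
        raise EmptyInputError("trajectory has no frames")
    sq = np.zeros(pairs.n_pair)
    for f in range(traj.n_frames):
        sq += _pair_deltas(traj.coords[f], pairs) ** 2
    return np.sqrt(sq / traj.n_frames)


def aij_static(frame: np.ndarray, pairs: SymmetryPairSet) -> np.ndarray:
    """A_ij of a single static structure (one-frame special case)."""
    return _pair_deltas(frame, pairs)


def classify_arps(
    aij_values: np.ndarray,
    pairs: SymmetryPairSet,
    threshold: float = 0.8,
    tier_edges: tuple[float, ...] = (0.5, 1.0, 2.0),
) -> ARPTable:
    """Flag asymmetric residue pairs and summarize them by region.

    A pair is an ARP when A_ij > threshold (default 0.8 Å).  The tier
    histogram (default edges 0.5/1.0/2.0 Å) is a display summary over
    all pairs, separate from the ARP selection rule: bins are
    [e0, e1), [e1, e2), ..., [e_last, inf).
    """
    aij_values = np.asarray(aij_values, dtype=float)
    if aij_values.shape != (pairs.n_pair,):
        raise ConsistencyError("A_ij vector does not match the pair set")
    if threshold <= 0:
        raise ConfigurationError("ARP threshold must be positive")
    edges = tuple(float(e) for e in tier_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ConfigurationError("tier edges must be strictly ascending")
    is_arp = aij_values > threshold
    region_counts = Counter(
        rc for rc, flag in zip(pairs.region_class, is_arp) if flag
    )
    bins = np.concatenate([edges, [np.inf]])
    tier_counts = np.array(
        [np.count_nonzero((aij_values >= lo) & (aij_values < hi)) for lo, hi in zip(bins[:-1], bins[1:])]
    )
    return ARPTable(
        aij=aij_values,
        threshold=threshold,
        is_arp=is_arp,
        region_counts=region_counts,
        tier_edges=edges,
        tier_counts=tier_counts,
        pairs=pairs,
    )
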