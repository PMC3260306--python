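"""End-to-end pipeline: simulate and/or analyze on one configuration.

Stages run in dependency order (simulate first, then the analyses over
the resulting — or the configured — structure and trajectory).  Every
output file starts with a comment header recording the package version,
a hash of the driving config and the seed, so results are traceable to
their run.  Outputs are write-once: a stage refuses to overwrite files
from a previous run.  On stage failure the partial outputs are kept and
a FAILED marker names the failing stage.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from . import __version__
from .channel_geometry import dpair_series, layer_radius_series, pore_profile
from .config import RunConfig
from .errors import ConfigurationError, DimergateError
from .spin_angle import spin_angle_series
from .structure_io import (
    Structure,
    Trajectory,
    build_homodimer_map,
    read_structure,
    read_trajectory,
    select_calpha,
    write_structure,
    write_trajectory,
)
from .symmetry_metrics import aij, casymm_series, classify_arps, select_pairs
from .synthetic_steering import SteeringSchedule, build_toy_homodimer, run_steered

__all__ = ["run_pipeline", "table_header", "write_table"]

log = logging.getLogger("dimergate")


def table_header(cfg: RunConfig, stage: str, params: dict) -> list[str]:
    lines = [
        f"# dimergate {__version__}",
        f"# config: {cfg.config_hash or 'builtin'}",
        f"# seed: {cfg.seed}",
        f"# stage: {stage}",
    ]
    lines.extend(f"# {key} = {value}" for key, value in params.items())
    return lines


def write_table(
    path: Path, header: Iterable[str], columns: Sequence[str], rows: Iterable[Sequence]
) -> None:
    if path.exists():
        raise ConfigurationError(
            f"refusing to overwrite existing output {path}; use a fresh run directory"
        )
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


class _Workspace:
    """Lazily loaded shared inputs for the stages."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self._structure: Structure | None = None
        self._trajectory: Trajectory | None = None
        self._selection = None
        self._map = None
        self._pairs = None

    @property
    def structure(self) -> Structure:
        if self._structure is None:
            if self.cfg.structure is None:
                raise ConfigurationError("no input structure configured")
            self._structure = read_structure(self.cfg.structure)
        return self._structure

    @property
    def selection(self):
        if self._selection is None:
            chains = set(self.cfg.half1) | set(self.cfg.half2)
            present = {a.chain for a in self.structure.atoms}
            missing = chains - present
            if missing:
                raise ConfigurationError(
                    f"configured chains {sorted(missing)} not present in the structure"
                )
            self._selection = select_calpha(self.structure, chains)
        return self._selection

    @property
    def hmap(self):
        if self._map is None:
            self._map = build_homodimer_map(
                self.structure, self.cfg.half1, self.cfg.half2, self.cfg.regions
            )
        return self._map

    @property
    def trajectory(self) -> Trajectory:
        if self._trajectory is None:
            if self.cfg.trajectory is None:
                raise ConfigurationError("no trajectory configured for this stage")
            self._trajectory = read_trajectory(self.cfg.trajectory, self.selection)
        return self._trajectory

    @property
    def pairs(self):
        if self._pairs is None:
            self._pairs = select_pairs(
                self.structure,
                self.selection,
                self.hmap,
                d0=self.cfg.d0,
                deduplicate=self.cfg.deduplicate_pairs,
            )
        return self._pairs


def _stage_simulate(ws: _Workspace, out: Path, manifest: list[Path]) -> None:
    cfg = ws.cfg
    dimer = build_toy_homodimer(
        beads_per_chain=cfg.beads_per_chain, preset=cfg.preset, seed=cfg.seed
    )
    from .superposition import rmsd_to

    target_state = "I" if cfg.from_state == "O" else "O"
    initial = rmsd_to(dimer.state(cfg.from_state), dimer.state(target_state))
    k = cfg.force_constant if cfg.force_constant is not None else 3.0 * dimer.n_beads**2
    schedule = SteeringSchedule(
        initial=initial, final=0.0, steps=cfg.steps, k=k, n_atoms=dimer.n_beads
    )
    steered = run_steered(
        dimer,
        from_state=cfg.from_state,
        schedule=schedule,
        seed=cfg.seed,
        save_every=cfg.save_every,
    )

    traj_path = out / "trajectory.pdb"
    if traj_path.exists():
        raise ConfigurationError(f"refusing to overwrite {traj_path}")
    write_trajectory(dimer.atoms, steered.trajectory.coords, traj_path)
    ref_path = out / "reference.pdb"
    write_structure(dimer.as_structure(cfg.from_state), ref_path)
    diag_path = out / "steering.tsv"
    write_table(
        diag_path,
        table_header(
            ws.cfg,
            "simulate",
            {
                "preset": cfg.preset,
                "from_state": cfg.from_state,
                "steps": steered.schedule.steps,
                "k": steered.schedule.k,
                "N": steered.schedule.n_atoms,
            },
        ),
        ["step", "rmsd", "rmsd_star", "energy"],
        zip(
            steered.trajectory.labels,
            np.round(steered.rmsd, 6),
            np.round(steered.rmsd_star, 6),
            np.round(steered.energy, 6),
        ),
    )
    manifest.extend([traj_path, ref_path, diag_path])
    # downstream stages analyze what we just simulated
    ws.cfg.structure = ref_path
    ws.cfg.trajectory = traj_path
    ws._structure = None
    ws._trajectory = None
    ws._selection = None
    ws._map = None
    ws._pairs = None


def _stage_pairs(ws: _Workspace, out: Path, manifest: list[Path]) -> None:
    pairs = ws.pairs
    path = out / "pairs.tsv"
    rows = (
        (
            f"{ki[0]}:{ki[1]}",
            f"{kj[0]}:{kj[1]}",
            rc,
        )
        for ki, kj, rc in zip(pairs.keys_i, pairs.keys_j, pairs.region_class)
    )
    header = table_header(
        ws.cfg,
        "pairs",
        {"d0": pairs.d0, "n_pair": pairs.n_pair, "deduplicated": pairs.deduplicated,
         "region_counts": dict(pairs.region_counts())},
    )
    write_table(path, header, ["residue_i", "residue_j", "region_class"], rows)
    manifest.append(path)


def _stage_casymm(ws: _Workspace, out: Path, manifest: list[Path]) -> None:
    series = casymm_series(ws.trajectory, ws.pairs, form=ws.cfg.aggregation)
    path = out / "casymm.tsv"
    write_table(
        path,
        table_header(ws.cfg, "casymm", {"form": ws.cfg.aggregation, "d0": ws.cfg.d0}),
        ["frame", "casymm"],
        zip(ws.trajectory.labels, np.round(series, 6)),
    )
    manifest.append(path)


def _stage_arps(ws: _Workspace, out: Path, manifest: list[Path]) -> None:
    values = aij(ws.trajectory, ws.pairs)
    table = classify_arps(values, ws.pairs, threshold=ws.cfg.arp_threshold)
    order = np.argsort(-values)
    path = out / "arps.tsv"
    rows = (
        (
            f"{ws.pairs.keys_i[i][0]}:{ws.pairs.keys_i[i][1]}",
            f"{ws.pairs.keys_j[i][0]}:{ws.pairs.keys_j[i][1]}",
            ws.pairs.region_class[i],
            round(float(values[i]), 6),
            int(table.is_arp[i]),
        )
        for i in order
    )
    header = table_header(
        ws.cfg,
        "arps",
        {
            "threshold": table.threshold,
            "n_arp": table.n_arp,
            "region_counts": dict(table.region_counts),
            "tier_edges": table.tier_edges,
            "tier_counts": table.tier_counts.tolist(),
        },
    )
    write_table(path, header, ["residue_i", "residue_j", "region_class", "aij", "is_arp"], rows)
    manifest.append(path)


def _stage_spin(ws: _Workspace, out: Path, manifest: list[Path]) -> None:
    labels, angles = spin_angle_series(
        ws.trajectory,
        ws.structure,
        ws.hmap,
        project=ws.cfg.project_spin,
        normal=np.asarray(ws.cfg.axis, dtype=float),
    )
    path = out / "spin.tsv"
    write_table(
        path,
        table_header(ws.cfg, "spin", {"projected": ws.cfg.project_spin, "axis": ws.cfg.axis}),
        ["frame", "angle_deg"],
        zip(labels, np.round(angles, 4)),
    )
    manifest.append(path)


def _stage_pore(ws: _Workspace, out: Path, manifest: list[Path]) -> None:
    prof = pore_profile(ws.structure, axis=np.asarray(ws.cfg.axis, dtype=float))
    path = out / "pore.tsv"
    write_table(
        path,
        table_header(ws.cfg, "pore", {"axis": ws.cfg.axis}),
        ["z", "radius", "cx", "cy", "capped"],
        (
            (round(z, 3), round(r, 4), round(cx, 4), round(cy, 4), int(c))
            for z, r, (cx, cy), c in zip(prof.z, prof.radius, prof.center, prof.capped)
        ),
    )
    manifest.append(path)


def _stage_layers(ws: _Workspace, out: Path, manifest: list[Path]) -> None:
    if not ws.cfg.layers:
        raise ConfigurationError("layers stage requested but no layers configured")
    path = out / "layers.tsv"
    series = {
        name: layer_radius_series(
            ws.trajectory, layer, reference=ws.structure,
            axis=np.asarray(ws.cfg.axis, dtype=float),
        )
        for name, layer in ws.cfg.layers.items()
    }
    names = list(series)
    rows = (
        (label, *(round(series[n][i], 4) for n in names))
        for i, label in enumerate(ws.trajectory.labels)
    )
    write_table(
        path,
        table_header(ws.cfg, "layers", {"layers": {n: ws.cfg.layers[n].window for n in names}}),
        ["frame", *names],
        rows,
    )
    manifest.append(path)


def _stage_dpair(ws: _Workspace, out: Path, manifest: list[Path]) -> None:
    if not ws.cfg.dpair_residues:
        raise ConfigurationError("dpair stage requested but no dpair_residues configured")
    path = out / "dpair.tsv"
    all_series = []
    names = []
    for chain, resnum in ws.cfg.dpair_residues:
        s = dpair_series(ws.trajectory, (chain, resnum, ""), ws.hmap)
        all_series.append(s.distances)
        names.append(f"{chain}:{resnum}")
    rows = (
        (label, *(round(s[i], 4) for s in all_series))
        for i, label in enumerate(ws.trajectory.labels)
    )
    write_table(
        path,
        table_header(ws.cfg, "dpair", {"residues": names}),
        ["frame", *names],
        rows,
    )
    manifest.append(path)


_STAGES: dict[str, Callable[[_Workspace, Path, list[Path]], None]] = {
    "simulate": _stage_simulate,
    "pairs": _stage_pairs,
    "casymm": _stage_casymm,
    "arps": _stage_arps,
    "spin": _stage_spin,
    "pore": _stage_pore,
    "layers": _stage_layers,
    "dpair": _stage_dpair,
}

# dependency order: simulate first, static analyses, then trajectory ones
_ORDER = ["simulate", "pairs", "pore", "spin", "casymm", "arps", "layers", "dpair"]


def run_pipeline(cfg: RunConfig) -> list[Path]:
    """Execute the configured stages; return the manifest of output files."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ws = _Workspace(cfg)
    # validate inputs before any computation
    if "simulate" not in cfg.stages and cfg.structure is not None:
        ws.selection  # raises on missing chains

    manifest: list[Path] = []
    ordered = [s for s in _ORDER if s in cfg.stages]
    for stage in ordered:
        t0 = time.time()
        try:
            _STAGES[stage](ws, out, manifest)
        except DimergateError as exc:
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            log.error("stage %s failed: %s", stage, exc)
            raise
        log.info("stage %s finished in %.2f s", stage, time.time() - t0)
    manifest_path = out / "MANIFEST"
    with open(manifest_path, "w") as fh:
        for p in manifest:
            fh.write(p.name + "\n")
    manifest.append(manifest_path)
    return manifest
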