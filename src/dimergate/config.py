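"""Run configuration: flat ``key = value`` text with sections.

One config file drives a whole figure-style analysis: it names the input
structure/trajectory, assigns chain roles (which chains form half 1 and
half 2 of the homodimer, which are TMD and which NBD), and sets the
analysis parameters (pair cutoff d0, ARP threshold, aggregation form,
channel axis, layer windows) plus the steering-simulation block and the
random seed.  Parsed with :mod:`configparser`.
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .channel_geometry import LayerDefinition
from .errors import ConfigurationError

__all__ = ["RunConfig", "parse_config"]

_KNOWN_STAGES = ("simulate", "pairs", "casymm", "arps", "spin", "pore", "layers", "dpair")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    structure: Path | None = None
    trajectory: Path | None = None
    half1: list[str] = field(default_factory=lambda: ["A", "C"])
    half2: list[str] = field(default_factory=lambda: ["B", "D"])
    regions: dict[str, str] = field(
        default_factory=lambda: {"A": "TMD", "B": "TMD", "C": "NBD", "D": "NBD"}
    )
    d0: float = 8.0
    arp_threshold: float = 0.8
    aggregation: str = "mean-absolute"
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    deduplicate_pairs: bool = False
    project_spin: bool = True
    layers: dict[str, LayerDefinition] = field(default_factory=dict)
    dpair_residues: list[tuple[str, int]] = field(default_factory=list)
    stages: list[str] = field(default_factory=lambda: ["pairs"])
    # steering-simulation block
    preset: str = "two-gate-channel"
    beads_per_chain: int = 40
    from_state: str = "O"
    steps: int = 3000
    save_every: int = 30
    force_constant: float | None = None  # None -> 3 N² default
    seed: int = 0
    out_dir: Path = Path("dimergate-run")
    config_hash: str = ""

    def validate(self) -> None:
        if len(self.half1) != len(self.half2):
            raise ConfigurationError("half1 and half2 chain lists differ in length")
        for ch in self.half1 + self.half2:
            if ch not in self.regions:
                raise ConfigurationError(f"chain {ch!r} has no region assignment")
        for stage in self.stages:
            if stage not in _KNOWN_STAGES:
                raise ConfigurationError(
                    f"unknown stage {stage!r}; known: {', '.join(_KNOWN_STAGES)}"
                )
        needs_structure = {"pairs", "spin", "pore", "arps", "casymm", "layers", "dpair"}
        if (
            "simulate" not in self.stages
            and needs_structure & set(self.stages)
            and self.structure is None
        ):
            raise ConfigurationError(
                "analysis stages need an input structure (or a simulate stage)"
            )
        if self.aggregation not in ("mean-absolute", "root-mean-square"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        if np.linalg.norm(self.axis) == 0:
            raise ConfigurationError("axis must be a nonzero vector")
        if self.from_state not in ("O", "I"):
            raise ConfigurationError("from_state must be O or I")


def _split_list(text: str) -> list[str]:
    return [t.strip() for t in text.split(",") if t.strip()]


def parse_config(path: str | Path) -> RunConfig:
    """Parse and validate a config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} not found")
    text = path.read_text()
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keep chain ids case-sensitive
    try:
        parser.read_string(text)
    except configparser.Error as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc

    cfg = RunConfig()
    cfg.config_hash = hashlib.sha256(text.encode()).hexdigest()[:16]

    if parser.has_section("input"):
        sec = parser["input"]
        if "structure" in sec:
            cfg.structure = Path(sec["structure"])
        if "trajectory" in sec:
            cfg.trajectory = Path(sec["trajectory"])
    if parser.has_section("chains"):
        sec = parser["chains"]
        if "half1" in sec:
            cfg.half1 = _split_list(sec["half1"])
        if "half2" in sec:
            cfg.half2 = _split_list(sec["half2"])
        if "regions" in sec:
            cfg.regions = {}
            for item in _split_list(sec["regions"]):
                if ":" not in item:
                    raise ConfigurationError(
                        f"regions entries must be CHAIN:REGION, got {item!r}"
                    )
                chain, region = item.split(":", 1)
                cfg.regions[chain.strip()] = region.strip()
    if parser.has_section("analysis"):
        sec = parser["analysis"]
        cfg.d0 = sec.getfloat("d0", cfg.d0)
        cfg.arp_threshold = sec.getfloat("arp_threshold", cfg.arp_threshold)
        cfg.aggregation = sec.get("aggregation", cfg.aggregation)
        cfg.deduplicate_pairs = sec.getboolean("deduplicate_pairs", cfg.deduplicate_pairs)
        cfg.project_spin = sec.getboolean("project_spin", cfg.project_spin)
        if "axis" in sec:
            parts = _split_list(sec["axis"])
            if len(parts) != 3:
                raise ConfigurationError("axis must have three components")
            cfg.axis = tuple(float(p) for p in parts)
        if "stages" in sec:
            cfg.stages = _split_list(sec["stages"])
        if "dpair_residues" in sec:
            cfg.dpair_residues = []
            for item in _split_list(sec["dpair_residues"]):
                chain, num = item.split(":", 1)
                cfg.dpair_residues.append((chain.strip(), int(num)))
    if parser.has_section("layers"):
        for name, window in parser["layers"].items():
            lo, hi = (float(v) for v in _split_list(window))
            cfg.layers[name] = LayerDefinition(name=name, window=(lo, hi))
    if parser.has_section("simulate"):
        sec = parser["simulate"]
        cfg.preset = sec.get("preset", cfg.preset)
        cfg.beads_per_chain = sec.getint("beads_per_chain", cfg.beads_per_chain)
        cfg.from_state = sec.get("from_state", cfg.from_state)
        cfg.steps = sec.getint("steps", cfg.steps)
        cfg.save_every = sec.getint("save_every", cfg.save_every)
        if "force_constant" in sec:
            cfg.force_constant = sec.getfloat("force_constant")
    if parser.has_section("run"):
        sec = parser["run"]
        cfg.seed = sec.getint("seed", cfg.seed)
        if "out" in sec:
            cfg.out_dir = Path(sec["out"])

    cfg.validate()
    return cfg
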