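#!/usr/bin/env python
"""Optional checks against published crystal structures (needs network).

Downloads PDB entries of the BtuCD system from RCSB and recomputes the
structural statistics the package implements:

* 1L7V (outward-facing BtuCD): symmetry-pair counts at d0 = 8 Å, per
  region and total, under both deduplication conventions; the static
  asymmetry coefficient C_asymm under both aggregation forms; and the
  projected TMD-NBD spin angle.
* 2QI9 (BtuCD-F): static ARP counts at the 0.8 Å threshold, per region.

These touch the network and therefore do not run in the default test
suite; invoke directly:

    python scripts/accession_checks.py --out results/accessions.json
"""

from __future__ import annotations

import argparse
import json
import urllib.request
from pathlib import Path

import numpy as np

from dimergate import (
    aij_static,
    build_homodimer_map,
    casymm,
    classify_arps,
    read_structure,
    select_calpha,
    select_pairs,
    spin_angle,
)

RCSB = "https://files.rcsb.org/download/{}.pdb"

# chain roles in the deposited entries: A/B = BtuC (TMD), C/D = BtuD (NBD)
HALF1, HALF2 = ["A", "C"], ["B", "D"]
REGIONS = {"A": "TMD", "B": "TMD", "C": "NBD", "D": "NBD"}


def fetch(code: str, cache: Path) -> Path:
    path = cache / f"{code}.pdb"
    if not path.exists():
        cache.mkdir(parents=True, exist_ok=True)
        print(f"downloading {code} ...")
        urllib.request.urlretrieve(RCSB.format(code), path)
    return path


def analyze(code: str, cache: Path) -> dict:
    s = read_structure(fetch(code, cache))
    sel = select_calpha(s, set(HALF1 + HALF2))
    hmap = build_homodimer_map(s, HALF1, HALF2, REGIONS)
    out: dict = {"n_calpha": len(sel), "n_mapped_residues": len(hmap)}
    for dedup in (False, True):
        pairs = select_pairs(s, sel, hmap, d0=8.0, deduplicate=dedup)
        key = "pairs_deduplicated" if dedup else "pairs_distinct"
        out[key] = {"total": pairs.n_pair, **dict(pairs.region_counts())}
    pairs = select_pairs(s, sel, hmap, d0=8.0)
    frame = sel.coords_from(s)
    out["casymm_mean_absolute"] = round(casymm(frame, pairs, "mean-absolute"), 4)
    out["casymm_rms"] = round(casymm(frame, pairs, "root-mean-square"), 4)
    table = classify_arps(aij_static(frame, pairs), pairs, threshold=0.8)
    out["arps_static"] = {"total": table.n_arp, **dict(table.region_counts)}
    out["spin_angle_deg"] = round(
        spin_angle(frame, s, sel, hmap, project=True).angle, 2
    )
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/accessions.json"))
    parser.add_argument("--cache", type=Path, default=Path("scratch/pdb"))
    args = parser.parse_args()
    results = {}
    for code in ("1l7v", "2qi9"):
        try:
            results[code] = analyze(code, args.cache)
        except Exception as exc:  # network or parsing problems: report, go on
            results[code] = {"error": f"{type(exc).__name__}: {exc}"}
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2) + "\n")
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
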