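#!/usr/bin/env python
"""Benchmark real proteins against gold-standard residue decompositions.

This script REPORTS scores; it asserts nothing.  It needs external inputs
that are not shipped with the package:

  * curated PDB files with hydrogens (or rely on the built-in backbone
    amide-H placement), one per conformation;
  * gold-standard residue decompositions (e.g. RigidFinder output converted
    to the package's cluster-per-line dialect, see prorigid.decomposition).

For every (pdb, gold) pair it runs decomposition methods 3-7, sweeping the
H-bond cutoff over [-7, 0] kcal/mol and (for the Lennard-Jones methods) the
hydrophobic cutoff over [-0.3, 0], and prints the best B-cubed score and
cutoffs per method, next to the all-rigid/all-floppy baselines.

Usage:
    python scripts/reproduce_benchmark.py pairs.tsv
where pairs.tsv has two tab-separated columns: pdb_path, gold_path.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

from prorigid.decomposition import read_decomposition
from prorigid.interactions import (
    detect_hbonds,
    detect_hydrophobics_legacy,
    detect_hydrophobics_lj,
    infer_covalent_bonds,
)
from prorigid.mechanical_model import ModelingOptions
from prorigid.scoring import (
    all_floppy_baseline,
    all_rigid_baseline,
    bcubed,
    sweep_cutoffs,
)
from prorigid.structure_io import place_backbone_amide_hydrogens, read_pdb

HBOND_GRID = list(np.arange(-7.0, 0.01, 0.25))
HPHOB_GRID = list(np.arange(-0.3, 0.001, 0.025))


def run_pair(pdb_path: str, gold_path: str) -> None:
    structure = place_backbone_amide_hydrogens(read_pdb(pdb_path))
    gold = read_decomposition(gold_path)
    bonds = infer_covalent_bonds(structure)
    hbonds = detect_hbonds(structure, bonds)
    legacy = detect_hydrophobics_legacy(structure, bonds)
    lj = detect_hydrophobics_lj(structure, bonds)

    name = Path(pdb_path).stem
    for label, base in (("all_floppy(1)", all_floppy_baseline(gold.items)),
                        ("all_rigid(2)", all_rigid_baseline(gold.items))):
        r = bcubed(gold, base)
        print(f"{name}\t{label}\tF1={r.f1:.2f}")

    for method in (3, 4, 5, 6, 7):
        phobics = lj if method in (6, 7) else legacy
        hgrid = [None] if method in (3, 6) else HBOND_GRID
        pgrid = HPHOB_GRID if method in (6, 7) else [None]
        template = ModelingOptions.for_method(
            method, hbond_cutoff=None if method in (3, 6) else 0.0)
        report = sweep_cutoffs(structure, (bonds, hbonds, phobics), gold,
                               template, hgrid, pgrid)
        hc, pc = report.best_cutoffs
        print(f"{name}\tmethod {method}\tF1={report.best_score:.2f}\t"
              f"hbond_cutoff={hc}\thphob_cutoff={pc}")


def main() -> None:
    if len(sys.argv) != 2:
        print(__doc__)
        raise SystemExit(2)
    for line in Path(sys.argv[1]).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pdb_path, gold_path = line.split("\t")[:2]
        run_pair(pdb_path, gold_path)


if __name__ == "__main__":
    main()
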