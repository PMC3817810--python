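"""B-cubed scoring of cluster decompositions and cutoff sweeps.

For item i with gold cluster GS(i) and predicted cluster M(i):

    Pr(i) = |GS(i) ∩ M(i)| / |M(i)|
    Re(i) = |GS(i) ∩ M(i)| / |GS(i)|

Pr(D) and Re(D) are plain means over the n items and F1(D) their harmonic
mean.  The all-floppy baseline (every item its own cluster) always scores
100% precision; the all-rigid baseline (one cluster) always 100% recall.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from prorigid.decomposition import Decomposition, ResidueItem, to_residue_decomposition
from prorigid.mechanical_model import ModelingOptions, build_model, to_multigraph
from prorigid.pebble_game import clusters_to_atoms, run_pebble_game

__all__ = [
    "BCubedResult",
    "bcubed",
    "all_rigid_baseline",
    "all_floppy_baseline",
    "sweep_cutoffs",
    "SweepReport",
    "paired_comparison",
]


@dataclass
class BCubedResult:
    per_item_precision: dict[ResidueItem, float]
    per_item_recall: dict[ResidueItem, float]
    precision: float
    recall: float
    f1: float
    n: int

    def rounded(self, digits: int = 2) -> tuple[float, float, float]:
        """(Pr, Re, F1) rounded half-away-from-zero to ``digits`` decimals."""
        return tuple(_round_half_away(x, digits)
                     for x in (self.precision, self.recall, self.f1))


def _round_half_away(x: float, digits: int) -> float:
    scale = 10 ** digits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def _harmonize(gold: Decomposition, predicted: Decomposition
               ) -> tuple[Decomposition, Decomposition]:
    gu, pu = set(gold.items), set(predicted.items)
    if gu == pu:
        return gold, predicted
    warnings.warn(
        "gold and predicted universes differ; missing items added as singletons")
    universe = gu | pu
    def pad(dec: Decomposition) -> Decomposition:
        extra = [frozenset([i]) for i in sorted(universe - set(dec.items))]
        return Decomposition(items=sorted(universe),
                             clusters=list(dec.clusters) + extra)
    return pad(gold), pad(predicted)


def bcubed(gold: Decomposition, predicted: Decomposition) -> BCubedResult:
    """B-cubed precision/recall/F1 of ``predicted`` against ``gold``."""
    if not gold.items or not predicted.items:
        raise ValueError("empty universe")
    gold, predicted = _harmonize(gold, predicted)
    gs = gold.cluster_of()
    m = predicted.cluster_of()
    pr: dict[ResidueItem, float] = {}
    re: dict[ResidueItem, float] = {}
    for item in gold.items:
        inter = len(gs[item] & m[item])
        pr[item] = inter / len(m[item])
        re[item] = inter / len(gs[item])
    n = len(gold.items)
    precision = sum(pr.values()) / n
    recall = sum(re.values()) / n
    f1 = (0.0 if precision + recall == 0
          else 2 * precision * recall / (precision + recall))
    return BCubedResult(per_item_precision=pr, per_item_recall=re,
                        precision=precision, recall=recall, f1=f1, n=n)


def all_rigid_baseline(universe: Sequence[ResidueItem]) -> Decomposition:
    """Every item in one cluster: 100% recall against any gold standard."""
    if not universe:
        raise ValueError("empty universe")
    return Decomposition(items=sorted(universe),
                         clusters=[frozenset(universe)])


def all_floppy_baseline(universe: Sequence[ResidueItem]) -> Decomposition:
    """Every item its own singleton: 100% precision against any gold standard."""
    if not universe:
        raise ValueError("empty universe")
    items = sorted(universe)
    return Decomposition(items=items,
                         clusters=[frozenset([i]) for i in items])


class SweepPoint(NamedTuple):
    hbond_cutoff: float | None
    hydrophobic_cutoff: float | None
    result: BCubedResult


@dataclass
class SweepReport:
    points: list[SweepPoint]
    best: SweepPoint

    @property
    def best_score(self) -> float:
        return self.best.result.f1

    @property
    def best_cutoffs(self) -> tuple[float | None, float | None]:
        return (self.best.hbond_cutoff, self.best.hydrophobic_cutoff)


def decompose(structure, covalent_bonds, hbonds, hydrophobics,
              options: ModelingOptions,
              universe: list[ResidueItem] | None = None) -> Decomposition:
    """Full pipeline: model -> pebble game -> residue decomposition."""
    model = build_model(structure, covalent_bonds, hbonds, hydrophobics,
                        options)
    result = run_pebble_game(to_multigraph(model))
    atom_clusters = clusters_to_atoms(result, model)
    if universe is None:
        universe = [ResidueItem(*k) for k in structure.residues()
                    if not any(a.is_hetero for a in
                               structure.atoms_by_residue()[k])]
    return to_residue_decomposition(model, atom_clusters, universe)


def sweep_cutoffs(
    structure,
    interactions: tuple,
    gold: Decomposition,
    options_template: ModelingOptions,
    hbond_grid: Sequence[float | None],
    hydrophobic_grid: Sequence[float | None] = (None,),
) -> SweepReport:
    """Score the pipeline at every (H-bond, hydrophobic) cutoff pair.

    ``interactions`` is (covalent_bonds, hbonds, hydrophobics).  The best
    point maximizes F1; ties go to the most negative H-bond cutoff, then the
    most negative hydrophobic cutoff.
    """
    if not hbond_grid or not hydrophobic_grid:
        raise ValueError("cutoff grids must be non-empty")
    covalent_bonds, hbonds, hydrophobics = interactions
    points: list[SweepPoint] = []
    for hc, pc in itertools.product(hbond_grid, hydrophobic_grid):
        opts = replace(options_template, hbond_cutoff=hc)
        if pc is not None:
            opts = replace(opts, hydrophobic_cutoff=pc)
        dec = decompose(structure, covalent_bonds, hbonds, hydrophobics, opts,
                        universe=list(gold.items))
        points.append(SweepPoint(hc, pc, bcubed(gold, dec)))

    def tie_key(p: SweepPoint):
        hc = p.hbond_cutoff if p.hbond_cutoff is not None else math.inf
        pc = p.hydrophobic_cutoff if p.hydrophobic_cutoff is not None else math.inf
        return (p.result.f1, -hc, -pc)

    best = max(points, key=tie_key)
    return SweepReport(points=points, best=best)


class PairedComparison(NamedTuple):
    mean_of_differences: float
    p_value: float
    degenerate: bool = False


def paired_comparison(scores_a: Sequence[float], scores_b: Sequence[float]
                      ) -> PairedComparison:
    """Mean of (a-b) and two-sided paired t-test p-value.

    With zero variance of the differences the t statistic is undefined: the
    p-value is reported as exactly 1.0 when the mean difference is 0, and
    flagged degenerate otherwise.
    """
    if len(scores_a) != len(scores_b):
        raise ValueError("score lists must be matched by protein")
    if len(scores_a) < 2:
        raise ValueError("need at least 2 paired scores")
    diffs = np.asarray(scores_a, dtype=float) - np.asarray(scores_b, dtype=float)
    mean = float(diffs.mean())
    if np.allclose(diffs, diffs[0]):
        if math.isclose(mean, 0.0, abs_tol=1e-15):
            return PairedComparison(0.0, 1.0)
        return PairedComparison(mean, float("nan"), degenerate=True)
    t = stats.ttest_rel(scores_a, scores_b)
    return PairedComparison(mean, float(t.pvalue))
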