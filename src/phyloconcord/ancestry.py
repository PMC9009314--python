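"""Partitioning a cell phylogeny into genetic ancestries.

A *genetic ancestry* is a group of cells circumscribed on the phylogeny such
that genetic distances within the group are smaller than between groups — a
proxy for a tumor clone. Two strategies are provided, suited to the two
tree-shape regimes:

``balanced_annotation``
    For balanced phylogenies. First selects, over all disjoint clade pairs
    satisfying the size constraints, the pair with the least total
    within-clade dissimilarity; further ancestries are the largest clades
    disjoint from everything already selected. Cells in no selected clade
    are labeled ``unassigned``.

``unbalanced_annotation``
    For ladder-like phylogenies. Iteratively peels off the clade whose size
    is nearest to (remaining cells)/(remaining groups); after the peeled
    clade is removed the search repeats on the pruned tree, and the final
    group is whatever remains. Every cell gets a label.

Genetic dissimilarity of a clade is the mean pairwise patristic distance
among its tips (branch-length path sums; unit branch lengths when the input
tree carried none), zero for a singleton. Normal cells are excluded from
clade candidacy and kept in the output with the label ``normal``. All
tie-breaks are deterministic: size, then least dissimilarity, then smallest
preorder node ID.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    ConstraintInfeasibleError,
    InsufficientDataError,
    ValidationError,
)
from .io import NORMAL_LABEL, UNASSIGNED_LABEL, AncestryAnnotation, PhyloTree
from . import treeshape


@dataclass(frozen=True)
class AnnotationParams:
    """Knobs of the ancestry annotation.

    n_clades: number of ancestries to produce (default 3).
    min_total_frac: minimum fraction of cells the first clade pair must
        jointly cover (balanced mode only; default 0.75).
    min_each_frac: minimum fraction of cells each of the first two clades
        must cover (balanced mode only; default 0.1).
    """

    n_clades: int = 3
    min_total_frac: float = 0.75
    min_each_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n_clades < 1:
            raise ValidationError("n_clades must be >= 1")
        if not (0 < self.min_total_frac <= 1):
            raise ValidationError("min_total_frac must be in (0, 1]")
        if self.n_clades * self.min_each_frac > 1 + 1e-12:
            raise ValidationError("n_clades * min_each_frac must be <= 1")


@dataclass(frozen=True)
class CladeCandidate:
    """A clade considered for selection: its node, tips, size and dissimilarity."""

    node: int
    tips: frozenset[str]
    dissimilarity: float

    @property
    def size(self) -> int:
        return len(self.tips)


def clade_dissimilarity(tree: PhyloTree, tips: Iterable[str]) -> float:
    """Mean pairwise patristic distance among ``tips`` (0 for a singleton)."""
    tips = list(dict.fromkeys(tips))
    unknown = set(tips) - set(tree.tip_labels)
    if unknown:
        raise ValidationError(f"unknown tips: {sorted(unknown)}")
    if not tips:
        raise ValidationError("empty tip set")
    if len(tips) == 1:
        return 0.0
    d = tree.patristic_distances().loc[tips, tips].to_numpy()
    iu = np.triu_indices(len(tips), k=1)
    return float(d[iu].mean())


def _mean_pairwise(dist: pd.DataFrame, tips: frozenset[str]) -> float:
    if len(tips) < 2:
        return 0.0
    t = sorted(tips)
    sub = dist.loc[t, t].to_numpy()
    iu = np.triu_indices(len(t), k=1)
    return float(sub[iu].mean())


def _candidates(
    tree: PhyloTree,
    normal: frozenset[str],
    dist: pd.DataFrame,
    include_leaves: bool = False,
    include_root: bool = False,
) -> list[CladeCandidate]:
    """Clade candidates (tip sets below nodes), normals stripped, deduplicated."""
    tip_sets = tree.tip_sets()
    nodes = list(range(tree.n_nodes)) if include_leaves else tree.internal_nodes()
    out: list[CladeCandidate] = []
    seen: set[frozenset[str]] = set()
    for v in sorted(nodes):
        if v == tree.root and not include_root:
            continue
        tips = frozenset(t for t in tip_sets[v] if t not in normal)
        if not tips or tips in seen:
            continue
        seen.add(tips)
        out.append(CladeCandidate(v, tips, _mean_pairwise(dist, tips)))
    return out


def _finish(
    selected: list[frozenset[str]],
    tumor_tips: list[str],
    normal: frozenset[str],
    all_tips: list[str],
    provenance: str,
) -> AncestryAnnotation:
    labels: dict[str, str] = {}
    for k, clade in enumerate(selected, start=1):
        for t in clade:
            labels[t] = f"ancestry_{k}"
    for t in all_tips:
        if t in normal:
            labels[t] = NORMAL_LABEL
        elif t not in labels:
            labels[t] = UNASSIGNED_LABEL
    # preserve tree tip order in the output
    return AncestryAnnotation({t: labels[t] for t in all_tips}, provenance=provenance)


def balanced_annotation(
    tree: PhyloTree,
    params: AnnotationParams = AnnotationParams(),
    normal_cells: Iterable[str] = (),
    provenance: str = "balanced_annotation",
) -> AncestryAnnotation:
    """Ancestry annotation for balanced phylogenies (clade-pair seeding)."""
    normal = frozenset(normal_cells)
    tumor = [t for t in tree.tip_labels if t not in normal]
    n = len(tumor)
    if params.n_clades < 2:
        raise ValidationError("balanced_annotation requires n_clades >= 2")
    if n < 2 * params.n_clades:
        raise InsufficientDataError(
            f"{n} candidate cells cannot support {params.n_clades} clades"
        )
    dist = tree.patristic_distances()
    cands = _candidates(tree, normal, dist)

    min_each = params.min_each_frac * n
    min_total = params.min_total_frac * n
    best: tuple[float, int, int] | None = None
    best_pair: tuple[CladeCandidate, CladeCandidate] | None = None
    for a, b in itertools.combinations(cands, 2):
        if a.tips & b.tips:
            continue
        if a.size < min_each or b.size < min_each:
            continue
        if a.size + b.size < min_total:
            continue
        key = (a.dissimilarity + b.dissimilarity, a.node, b.node)
        if best is None or key < best:
            best, best_pair = key, (a, b)
    if best_pair is None:
        binding = (
            "min_each_frac"
            if not any(c.size >= min_each for c in cands)
            else "min_total_frac (no disjoint pair covers enough cells)"
        )
        raise ConstraintInfeasibleError(
            f"no clade pair satisfies the constraints; binding constraint: {binding}"
        )

    selected = [best_pair[0].tips, best_pair[1].tips]
    while len(selected) < params.n_clades:
        free = [c for c in cands if all(not (c.tips & s) for s in selected)]
        if not free:
            break  # fewer clades than requested are available
        pick = min(free, key=lambda c: (-c.size, c.dissimilarity, c.node))
        selected.append(pick.tips)
    return _finish(selected, tumor, normal, tree.tip_labels, provenance)


def unbalanced_annotation(
    tree: PhyloTree,
    params: AnnotationParams = AnnotationParams(),
    normal_cells: Iterable[str] = (),
    provenance: str = "unbalanced_annotation",
) -> AncestryAnnotation:
    """Ancestry annotation for ladder-like phylogenies (near-equal peeling)."""
    normal = frozenset(normal_cells)
    tumor = [t for t in tree.tip_labels if t not in normal]
    if params.n_clades > len(tumor):
        raise ValidationError(
            f"n_clades={params.n_clades} exceeds the {len(tumor)} candidate cells"
        )
    dist = tree.patristic_distances()
    selected: list[frozenset[str]] = []
    remaining = tree.prune_to(tumor) if normal else tree
    for g in range(params.n_clades - 1):
        n_left = remaining.n_tips
        target = n_left / (params.n_clades - g)
        cands = _candidates(remaining, frozenset(), dist, include_leaves=True)
        pick = min(
            cands,
            key=lambda c: (abs(c.size - target), c.dissimilarity, c.node),
        )
        selected.append(pick.tips)
        keep = [t for t in remaining.tip_labels if t not in pick.tips]
        remaining = remaining.prune_to(keep)
    selected.append(frozenset(remaining.tip_labels))
    return _finish(selected, tumor, normal, tree.tip_labels, provenance)


def auto_annotation(
    tree: PhyloTree,
    params: AnnotationParams = AnnotationParams(),
    normal_cells: Iterable[str] = (),
    threshold: float = treeshape.DEFAULT_THRESHOLD,
    provenance: str = "auto_annotation",
) -> tuple[AncestryAnnotation, "treeshape.BetaEstimate"]:
    """Classify the tree shape, then run the matching annotation function."""
    est = treeshape.estimate_beta(tree, threshold=threshold)
    fn = (
        unbalanced_annotation
        if est.shape == treeshape.UNBALANCED
        else balanced_annotation
    )
    return fn(tree, params, normal_cells, provenance=provenance), est
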