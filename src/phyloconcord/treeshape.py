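"""Tree-shape classification under Aldous' beta-splitting model.

The beta-splitting family assigns each internal node of an n-tip rooted
binary tree a split (i, n-i) with probability

    q_n(i; b) = w_n(i; b) / sum_j w_n(j; b),
    w_n(i; b) = G(b+1+i) G(b+1+n-i) / (G(i+1) G(n-i+1)),   b > -2,

where G is the gamma function. b = 0 recovers the Yule process, b = -1.5
the proportional-to-distinguishable-arrangements (PDA) model, and b -> -2
maximally imbalanced (caterpillar) trees. The maximum-likelihood estimate
of b over the splits of a phylogeny summarizes its balance; trees with
b-hat below a threshold (default -1.5) are classified *unbalanced* and
should be partitioned with the ladder-oriented annotation function,
balanced trees with the clade-pair one.

All likelihood terms are evaluated in log space via ``scipy.special
.gammaln`` and ``logsumexp``; the splits use an ordered convention with a
canonical left child (the likelihood is symmetric in i <-> n-i, so the MLE
is unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .exceptions import (
    InsufficientDataError,
    UnsupportedTopologyError,
    ValidationError,
)
from .io import PhyloTree

DEFAULT_BOUNDS = (-1.999, 10.0)
DEFAULT_THRESHOLD = -1.5

BALANCED = "balanced"
UNBALANCED = "unbalanced"


@dataclass(frozen=True)
class SplitRecord:
    """One internal node's split: ``n`` tips below it, ``i`` in the left child."""

    n: int
    i: int

    def __post_init__(self) -> None:
        if self.n < 2 or not (1 <= self.i <= self.n - 1):
            raise ValidationError(f"invalid split ({self.n}, {self.i})")


@dataclass(frozen=True)
class BetaEstimate:
    """MLE of the beta-splitting parameter and the resulting shape call."""

    beta_hat: float
    log_likelihood: float
    shape: str
    threshold: float = DEFAULT_THRESHOLD
    at_bound: bool = False

    @property
    def suggested_annotation(self) -> str:
        """Which ancestry-annotation strategy suits this shape."""
        return (
            "unbalanced_annotation" if self.shape == UNBALANCED else "balanced_annotation"
        )


def extract_splits(tree: PhyloTree) -> list[SplitRecord]:
    """Split records of every internal node of a binary rooted tree.

    ``i`` is the tip count of the canonical (smaller) child, so i <= n - i;
    the likelihood is symmetric in i <-> n - i, making the choice harmless.
    Polytomies are rejected so the estimate stays deterministic; resolve
    them upstream.
    """
    tip_sets = tree.tip_sets()
    records = []
    for v in tree.internal_nodes():
        ch = tree.children[v]
        if len(ch) != 2:
            raise UnsupportedTopologyError(
                f"node {v} has {len(ch)} children; resolve polytomies before "
                "estimating tree balance"
            )
        sizes = sorted(len(tip_sets[c]) for c in ch)
        records.append(SplitRecord(n=sum(sizes), i=sizes[0]))
    return records


def _log_weights(n: int, beta: float) -> np.ndarray:
    j = np.arange(1, n)
    return (
        gammaln(beta + 1 + j)
        + gammaln(beta + 1 + n - j)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
    )


def beta_loglik(splits: Iterable[SplitRecord], beta: float) -> float:
    """Log-likelihood of the beta-splitting model at ``beta``.

    Always <= 0; a cherry (n = 2) contributes 0 since its split is forced.
    """
    if beta <= -2:
        raise ValidationError("beta must be > -2")
    total = 0.0
    norms: dict[int, np.ndarray] = {}
    for s in splits:
        if s.n == 2:
            continue
        if s.n not in norms:
            norms[s.n] = _log_weights(s.n, beta)
        lw = norms[s.n]
        total += lw[s.i - 1] - logsumexp(lw)
    return float(total)


def fit_beta(
    splits: Sequence[SplitRecord],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    threshold: float = DEFAULT_THRESHOLD,
    xatol: float = 1e-4,
) -> BetaEstimate:
    """Maximize the split log-likelihood over ``bounds`` (1-D bounded search)."""
    if not splits:
        raise InsufficientDataError("no splits to fit")
    res = minimize_scalar(
        lambda b: -beta_loglik(splits, b),
        bounds=bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    beta_hat = float(res.x)
    at_bound = min(abs(beta_hat - bounds[0]), abs(beta_hat - bounds[1])) < 1e-3
    # ties at the threshold are classified balanced
    shape = UNBALANCED if beta_hat < threshold else BALANCED
    return BetaEstimate(
        beta_hat=beta_hat,
        log_likelihood=float(-res.fun),
        shape=shape,
        threshold=threshold,
        at_bound=at_bound,
    )


def estimate_beta(
    tree: PhyloTree,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    threshold: float = DEFAULT_THRESHOLD,
    xatol: float = 1e-4,
) -> BetaEstimate:
    """Estimate the beta-splitting parameter of a binary rooted phylogeny.

    Requires at least 4 tips — smaller trees have at most one informative
    split and carry no information about balance.
    """
    if tree.n_tips < 4:
        raise InsufficientDataError(
            f"tree has {tree.n_tips} tips; >= 4 required to estimate balance"
        )
    return fit_beta(extract_splits(tree), bounds=bounds, threshold=threshold, xatol=xatol)
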