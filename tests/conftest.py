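import numpy as np
import pytest

from phyloconcord.io import PhyloTree, read_newick


def caterpillar(n: int, prefix: str = "t") -> PhyloTree:
    """Fully pectinate n-tip tree (((t1,t2),t3),...)."""
    s = f"({prefix}1,{prefix}2)"
    for k in range(3, n + 1):
        s = f"({s},{prefix}{k})"
    return read_newick(s + ";")


def balanced_tree(n: int, prefix: str = "t") -> PhyloTree:
    """Recursively even-split n-tip tree."""

    def rec(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{prefix}{lo + 1}"
        mid = (lo + hi) // 2
        return f"({rec(lo, mid)},{rec(mid, hi)})"

    return read_newick(rec(0, n) + ";")


def random_binary_tree(n: int, rng: np.random.Generator) -> PhyloTree:
    """Random topology by repeated joining of uniformly chosen subtrees."""
    parts = [f"t{k + 1}" for k in range(n)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return read_newick(parts[0] + ";")


def clade_newick(labels, tip_len: float = 0.1) -> str:
    """Star subtree string over labels with uniformly short branches."""
    return "(" + ",".join(f"{x}:{tip_len}" for x in labels) + ")"


@pytest.fixture
def three_clade_tree() -> PhyloTree:
    """12 tips in three well-separated clades of 5, 4 and 3 cells."""
    a = clade_newick([f"a{i}" for i in range(5)])
    b = clade_newick([f"b{i}" for i in range(4)])
    c = clade_newick([f"c{i}" for i in range(3)])
    return read_newick(f"(({a}:10,{b}:10):10,{c}:10);")
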