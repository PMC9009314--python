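"""Expression trajectories and ancestry/state concordance indices.

Given a normalized gene-by-cell expression matrix and a genetic-ancestry
annotation, this module

1. ranks genes by how differentially expressed they are between ancestries
   (Kruskal–Wallis H with midrank ties, vectorized over genes);
2. builds a deterministic expression trajectory from the top-*k* genes:
   per-gene z-scoring, projection onto principal components with a fixed
   sign convention, a minimum spanning tree over cell–cell Euclidean
   distances with lexicographic tie-breaks, pseudotime as path length from
   a designated root cell (a normal, non-cancerous cell, pseudotime 0), and
   expression *states* as the maximal root/leaf/branch-delimited paths of
   the MST (small states merged rootward);
3. scores concordance between ancestries and states:

   * SCI (sub-concordance index) of an ancestry: the number of states whose
     cell composition is >u (default 0.8) that ancestry — divergent
     expression evolution shows up as SCI > 1;
   * OCI (overall concordance index): the fraction of all states unique (at
     threshold u) to any single ancestry — convergent expression evolution
     pushes OCI below 1.

The trajectory/state algorithm here is a self-contained deterministic
procedure; its states are analogous to, but not identical with, the states
a model-based trajectory tool (e.g. Monocle) would call. Repeating the
analysis over a sweep of gene scales (200..1000 by default) shows how
concordance dilutes as genes without ancestry-linked signal are added.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2 as _chi2
from scipy.stats import rankdata

from .exceptions import ValidationError
from .io import (
    NORMAL_LABEL,
    SPECIAL_LABELS,
    UNASSIGNED_LABEL,
    AncestryAnnotation,
)

DEFAULT_SCALES = tuple(range(200, 1001, 100))
DEFAULT_UNIQUENESS = 0.8
STATE_COMPOSITION = "state-composition"
ANCESTRY_COVERAGE = "ancestry-coverage"


# ---------------------------------------------------------------------------
# differential-gene ranking
# ---------------------------------------------------------------------------

def kruskal_wallis_h(x: np.ndarray, groups: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Kruskal–Wallis H over column groups.

    ``x`` is (n_features, n_samples); ``groups`` are disjoint column-index
    arrays covering all columns. Returns (H, p) arrays; rows that are
    entirely tied get H = 0, p = 1.
    """
    n = x.shape[1]
    ranks = rankdata(x, axis=1)
    h = np.zeros(x.shape[0])
    for idx in groups:
        rbar = ranks[:, idx].mean(axis=1)
        h += len(idx) * (rbar - (n + 1) / 2) ** 2
    h *= 12.0 / (n * (n + 1))
    # midrank tie correction per row
    xs = np.sort(x, axis=1)
    new = np.ones_like(xs, dtype=bool)
    new[:, 1:] = xs[:, 1:] != xs[:, :-1]
    corr = np.empty(x.shape[0])
    for r in range(x.shape[0]):
        t = np.diff(np.append(np.flatnonzero(new[r]), n))
        corr[r] = 1.0 - ((t**3 - t).sum()) / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(corr > 0, h / corr, 0.0)
    p = _chi2.sf(h, df=len(groups) - 1)
    p = np.where(h == 0, 1.0, p)
    return h, p


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered by decreasing Kruskal–Wallis H (ties by gene ID)."""

    table: pd.DataFrame  # columns: gene, statistic, p_value
    groups: tuple[str, ...]

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def top(self, k: int) -> list[str]:
        return self.genes[:k]


def rank_genes(
    expr: pd.DataFrame,
    ann: AncestryAnnotation,
    min_cells: int = 3,
    min_group_size: int = 3,
) -> GeneRanking:
    """Rank genes by expression difference between genetic ancestries.

    Cells labeled ``normal``/``unassigned`` are excluded from the groups;
    genes expressed (non-zero) in fewer than ``min_cells`` cells are dropped
    before testing.
    """
    keep = (expr.to_numpy() != 0).sum(axis=1) >= min_cells
    expr = expr.loc[keep]
    if expr.empty:
        raise ValidationError("no gene passes the expression filter")

    group_cells: dict[str, list[str]] = {}
    for cell, lab in ann.labels.items():
        if lab in SPECIAL_LABELS or cell not in expr.columns:
            continue
        group_cells.setdefault(lab, []).append(cell)
    small = [g for g, cs in group_cells.items() if len(cs) < min_group_size]
    for g in small:
        warnings.warn(f"ancestry {g!r} has < {min_group_size} cells; skipped", stacklevel=2)
        del group_cells[g]
    if len(group_cells) < 2:
        raise ValidationError("need >= 2 ancestries with enough cells to rank genes")

    labels = sorted(group_cells)
    used_cells = [c for g in labels for c in group_cells[g]]
    x = expr[used_cells].to_numpy(dtype=float)
    offsets = np.cumsum([0] + [len(group_cells[g]) for g in labels])
    groups = [np.arange(offsets[k], offsets[k + 1]) for k in range(len(labels))]
    h, p = kruskal_wallis_h(x, groups)
    table = (
        pd.DataFrame({"gene": expr.index, "statistic": h, "p_value": p})
        .sort_values(["statistic", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return GeneRanking(table=table, groups=tuple(labels))


# ---------------------------------------------------------------------------
# trajectory and state assignment
# ---------------------------------------------------------------------------

@dataclass
class StateAssignment:
    """Per-cell expression state and pseudotime for one gene scale."""

    states: dict[str, int]
    pseudotime: dict[str, float]
    root_cell: str
    gene_scale: int
    mst_parent: dict[str, str | None] = field(default_factory=dict)
    mst_edge_length: dict[str, float] = field(default_factory=dict)
    coords: pd.DataFrame | None = None

    @property
    def n_states(self) -> int:
        return len(set(self.states.values()))

    def state_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for c, s in self.states.items():
            out.setdefault(s, []).append(c)
        return out


def _pca_scores(z: np.ndarray, n_dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores with a fixed sign convention: per
    component, the largest-magnitude gene loading is made positive."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    d = min(n_dims, len(s))
    scores = u[:, :d] * s[:d]
    loadings = vt[:d]
    for j in range(d):
        k = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, k] < 0:
            scores[:, j] *= -1
            loadings[j] *= -1
    return scores, loadings


def _mst_edges(dist: np.ndarray, cells: Sequence[str]) -> list[tuple[int, int, float]]:
    """Kruskal MST with ties broken by the lexicographic cell-ID pair."""
    n = len(cells)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((cells[i], cells[j]))
            edges.append((dist[i, j], a, b, i, j))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    parent = list(range(n))

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    out = []
    for d, _, _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            out.append((i, j, d))
            if len(out) == n - 1:
                break
    return out


def build_trajectory(
    expr: pd.DataFrame,
    genes: Sequence[str],
    root_cell: str,
    n_dims: int = 2,
    min_state_frac: float = 0.05,
    min_state_cells: int = 3,
) -> StateAssignment:
    """Deterministic trajectory: z-score -> PCA -> MST -> path states.

    Pseudotime is the MST path length from ``root_cell``. States are the
    maximal paths of the MST delimited by the root, leaves and branch
    vertices (a branch vertex belongs to the path on its root side); states
    smaller than ``max(min_state_cells, ceil(min_state_frac * n))`` are
    merged into their rootward neighbor. States are numbered 1..K by
    increasing mean pseudotime.
    """
    genes = list(genes)
    if root_cell not in expr.columns:
        raise ValidationError(f"root cell {root_cell!r} absent from expression matrix")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing[:5]}")
    if len(genes) < n_dims:
        raise ValidationError("need at least n_dims genes")
    cells = list(expr.columns)
    if len(cells) < 3:
        raise ValidationError("need at least 3 cells")

    x = expr.loc[genes].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    scores, _ = _pca_scores(z.T, n_dims)

    dist = squareform(pdist(scores))
    edges = _mst_edges(dist, cells)
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(cells))}
    for i, j, d in edges:
        adj[i].append((j, d))
        adj[j].append((i, d))

    root_idx = cells.index(root_cell)
    parent_idx: dict[int, int | None] = {root_idx: None}
    edge_len: dict[int, float] = {root_idx: 0.0}
    ptime = {root_idx: 0.0}
    order = [root_idx]
    stack = [root_idx]
    while stack:
        v = stack.pop()
        for w, d in sorted(adj[v], key=lambda e: cells[e[0]]):
            if w not in parent_idx:
                parent_idx[w] = v
                edge_len[w] = d
                ptime[w] = ptime[v] + d
                order.append(w)
                stack.append(w)

    children: dict[int, list[int]] = {i: [] for i in range(len(cells))}
    for v, p in parent_idx.items():
        if p is not None:
            children[p].append(v)
    for v in children:
        children[v].sort(key=lambda w: cells[w])

    # path decomposition: a child of a branching vertex (>= 2 children, or
    # the root when it branches) starts a new path; otherwise it continues
    # its parent's path
    path_of: dict[int, int] = {root_idx: 0}
    n_paths = 1
    for v in order:
        branching = len(children[v]) >= 2
        for w in children[v]:
            if branching:
                path_of[w] = n_paths
                n_paths += 1
            else:
                path_of[w] = path_of[v]

    n = len(cells)
    min_size = max(min_state_cells, math.ceil(min_state_frac * n))

    def members(pid: int) -> list[int]:
        return [v for v, p in path_of.items() if p == pid]

    def mean_ptime(pid: int) -> float:
        ms = members(pid)
        return sum(ptime[v] for v in ms) / len(ms)

    while True:
        sizes = {}
        for v, p in path_of.items():
            sizes[p] = sizes.get(p, 0) + 1
        if len(sizes) <= 1:
            break
        small = [p for p, s in sizes.items() if s < min_size]
        if not small:
            break
        pid = min(small, key=lambda p: (sizes[p], mean_ptime(p), min(cells[v] for v in members(p))))
        ms = members(pid)
        rootmost = min(ms, key=lambda v: ptime[v])
        if parent_idx[rootmost] is not None:
            target = path_of[parent_idx[rootmost]]
        else:
            # the root's own path: absorb the earliest child path instead
            child_paths = sorted(
                {path_of[w] for v in ms for w in children[v] if path_of[w] != pid},
                key=lambda p: (mean_ptime(p), min(cells[v] for v in members(p))),
            )
            target = child_paths[0]
        for v in ms:
            path_of[v] = target

    final_paths = sorted(set(path_of.values()), key=mean_ptime)
    renumber = {p: k + 1 for k, p in enumerate(final_paths)}
    return StateAssignment(
        states={cells[v]: renumber[p] for v, p in path_of.items()},
        pseudotime={cells[v]: t for v, t in ptime.items()},
        root_cell=root_cell,
        gene_scale=len(genes),
        mst_parent={
            cells[v]: (cells[p] if p is not None else None)
            for v, p in parent_idx.items()
        },
        mst_edge_length={cells[v]: d for v, d in edge_len.items()},
        coords=pd.DataFrame(
            scores, index=cells, columns=[f"PC{k + 1}" for k in range(scores.shape[1])]
        ),
    )


# ---------------------------------------------------------------------------
# concordance indices
# ---------------------------------------------------------------------------

def _state_composition(
    states: StateAssignment,
    ann: AncestryAnnotation,
    include_normal: bool,
) -> dict[int, dict[str, int]]:
    """Per-state label counts; unassigned cells (and, optionally, normal
    cells) are left out."""
    comp: dict[int, dict[str, int]] = {s: {} for s in set(states.states.values())}
    for cell, s in states.states.items():
        lab = ann.labels.get(cell)
        if lab is None or lab == UNASSIGNED_LABEL:
            continue
        if lab == NORMAL_LABEL and not include_normal:
            continue
        comp[s][lab] = comp[s].get(lab, 0) + 1
    return comp


def sci(
    states: StateAssignment,
    ann: AncestryAnnotation,
    ancestry: str,
    u: float = DEFAULT_UNIQUENESS,
    uniqueness_mode: str = STATE_COMPOSITION,
    include_normal: bool = False,
) -> int:
    """Sub-concordance index: states largely unique to one ancestry.

    In the default ``state-composition`` mode a state counts when more than
    a fraction ``u`` of its (non-normal, assigned) cells belong to
    ``ancestry``. The ``ancestry-coverage`` variant instead counts states
    holding more than ``u`` of the ancestry's cells.
    """
    valid = set(ann.ancestries) | ({NORMAL_LABEL} if include_normal else set())
    if ancestry not in valid:
        raise ValidationError(f"unknown ancestry {ancestry!r}")
    comp = _state_composition(states, ann, include_normal=include_normal)
    if uniqueness_mode == STATE_COMPOSITION:
        count = 0
        for counts in comp.values():
            total = sum(counts.values())
            if total and counts.get(ancestry, 0) / total > u:
                count += 1
        return count
    if uniqueness_mode == ANCESTRY_COVERAGE:
        total_anc = sum(counts.get(ancestry, 0) for counts in comp.values())
        if total_anc == 0:
            return 0
        return sum(
            1 for counts in comp.values() if counts.get(ancestry, 0) / total_anc > u
        )
    raise ValidationError(f"unknown uniqueness mode {uniqueness_mode!r}")


def oci(
    states: StateAssignment,
    ann: AncestryAnnotation,
    u: float = DEFAULT_UNIQUENESS,
) -> float:
    """Overall concordance index: fraction of states unique to one ancestry.

    The state holding the normal cells counts in the denominator and may be
    unique to ``normal``; unassigned cells are ignored.
    """
    comp = _state_composition(states, ann, include_normal=True)
    n_states = len(comp)
    unique = 0
    for counts in comp.values():
        total = sum(counts.values())
        if total and max(counts.values()) / total > u:
            unique += 1
    return unique / n_states if n_states else 0.0


# ---------------------------------------------------------------------------
# gene-scale sweep
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """SCI/OCI per annotation source, gene scale and ancestry."""

    table: pd.DataFrame  # columns: source, scale, ancestry, sci, oci, n_states, n_unique_states
    assignments: dict[tuple[str, int], StateAssignment]
    uniqueness: float = DEFAULT_UNIQUENESS

    def oci_series(self, source: str) -> pd.Series:
        sub = self.table[self.table["source"] == source]
        return sub.drop_duplicates("scale").set_index("scale")["oci"]


def phylo_trajectory_sweep(
    expr: pd.DataFrame,
    annotations: Sequence[AncestryAnnotation],
    root_cell: str,
    scales: Sequence[int] = DEFAULT_SCALES,
    u: float = DEFAULT_UNIQUENESS,
    n_dims: int = 2,
    min_cells: int = 3,
    uniqueness_mode: str = STATE_COMPOSITION,
) -> ConcordanceReport:
    """Rank genes, build trajectories and score concordance per annotation
    and gene scale.

    For each annotation the differential ranking is computed once and the
    top-k prefix is taken for each scale k (starting with 200 genes and
    extending in steps of 100 up to 1000 by default). Scales exceeding the
    number of rankable genes are dropped with a warning.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValidationError("need at least one annotation")
    rows = []
    assignments: dict[tuple[str, int], StateAssignment] = {}
    for k, ann in enumerate(annotations):
        source = ann.provenance or f"annotation_{k + 1}"
        ranking = rank_genes(expr, ann, min_cells=min_cells)
        avail = len(ranking.genes)
        used_scales = [s for s in scales if s <= avail]
        if len(used_scales) < len(scales):
            warnings.warn(
                f"{source}: only {avail} rankable genes; scales truncated to "
                f"{used_scales or [avail]}",
                stacklevel=2,
            )
            if not used_scales:
                used_scales = [avail]
        cells = [c for c in expr.columns if c in ann.labels]
        sub = expr[cells]
        for scale in used_scales:
            st = build_trajectory(sub, ranking.top(scale), root_cell, n_dims=n_dims)
            assignments[(source, scale)] = st
            comp = _state_composition(st, ann, include_normal=True)
            n_states = len(comp)
            n_unique = sum(
                1
                for counts in comp.values()
                if sum(counts.values())
                and max(counts.values()) / sum(counts.values()) > u
            )
            the_oci = oci(st, ann, u=u)
            for anc in ann.ancestries:
                rows.append(
                    {
                        "source": source,
                        "scale": scale,
                        "ancestry": anc,
                        "sci": sci(st, ann, anc, u=u, uniqueness_mode=uniqueness_mode),
                        "oci": the_oci,
                        "n_states": n_states,
                        "n_unique_states": n_unique,
                    }
                )
    return ConcordanceReport(
        table=pd.DataFrame(rows), assignments=assignments, uniqueness=u
    )


def plot_report(
    report: ConcordanceReport,
    annotations: Sequence[AncestryAnnotation],
    out_dir,
) -> list[str]:
    """Write per-scale trajectory scatters and SCI/OCI-vs-scale line plots."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def safe(name: str) -> str:
        import re

        return re.sub(r"[^A-Za-z0-9._-]+", "_", Path(name).name) or "annotation"

    for (source, scale), st in report.assignments.items():
        if st.coords is None or st.coords.shape[1] < 2:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        states = np.array([st.states[c] for c in st.coords.index])
        sc = ax.scatter(
            st.coords.iloc[:, 0], st.coords.iloc[:, 1], c=states, cmap="tab10", s=25
        )
        ax.scatter(*st.coords.loc[st.root_cell].iloc[:2], marker="*", s=180, c="black")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title(f"{source}, {scale} genes ({st.n_states} states)")
        fig.colorbar(sc, ax=ax, label="state")
        path = out / f"trajectory_{safe(source)}_{scale}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(str(path))

    for source in report.table["source"].unique():
        sub = report.table[report.table["source"] == source]
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        for anc, grp in sub.groupby("ancestry"):
            ax1.plot(grp["scale"], grp["sci"], marker="o", label=anc)
        ax1.set_xlabel("gene scale")
        ax1.set_ylabel("SCI")
        ax1.legend(fontsize=7)
        osr = sub.drop_duplicates("scale")
        ax2.plot(osr["scale"], osr["oci"], marker="o", color="black")
        ax2.set_xlabel("gene scale")
        ax2.set_ylabel("OCI")
        ax2.set_ylim(-0.05, 1.05)
        fig.suptitle(source)
        fig.tight_layout()
        path = out / f"concordance_{safe(source)}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(str(path))
    return written
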