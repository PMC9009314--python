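"""Input/output and quality control.

Containers for the three data modalities — a rooted cell phylogeny, a
site-by-cell genotype call matrix, and a gene-by-cell normalized expression
matrix — together with the plain-text readers/writers (Newick, TSV,
MatrixMarket) and the SNV/cell quality filters applied before phylogeny-aware
analysis.

Genotype calls are the four symbols ``REF``, ``ALT``, ``HET`` and ``MISSING``
(written as ``NA`` in TSV files). The filters mirror standard scRNA-seq SNV
hygiene: drop sites that are uninformative or suspect in the normal
(non-cancerous) cells, drop sites with too much missing data overall, and
drop cells whose call vectors are mostly missing.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.io as _spio
import scipy.sparse as _sparse

from .exceptions import (
    ConfigurationError,
    EmptyResultError,
    FormatError,
    ValidationError,
)

# genotype call symbols
REF = "REF"
ALT = "ALT"
HET = "HET"
MISSING = "MISSING"
CALLS = (REF, ALT, HET, MISSING)

# reserved annotation labels (everything else is an ancestry label)
NORMAL_LABEL = "normal"
UNASSIGNED_LABEL = "unassigned"
SPECIAL_LABELS = frozenset({NORMAL_LABEL, UNASSIGNED_LABEL})


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

class PhyloTree:
    """A rooted phylogeny whose tips are cell IDs.

    Nodes are integers assigned in preorder (root = 0), which makes node IDs
    deterministic for a given Newick string and usable as tie-breakers.
    Branch lengths are stored per node (length of the edge above the node);
    the root's is 0. If the source tree carried no lengths at all, every
    edge gets unit length so that patristic distances degrade gracefully to
    node-count distances.
    """

    def __init__(
        self,
        parent: Sequence[int],
        children: Sequence[Sequence[int]],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = list(parent)  # parent[root] == -1
        self.children = [list(c) for c in children]
        self.lengths = [float(x) for x in lengths]
        self.labels = list(labels)
        self.root = 0
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if not (n == len(self.children) == len(self.lengths) == len(self.labels)):
            raise ValidationError("inconsistent node arrays")
        if n == 0 or self.parent[0] != -1:
            raise ValidationError("node 0 must be the root (parent -1)")
        if sum(1 for p in self.parent if p == -1) != 1:
            raise ValidationError("tree must have exactly one root")
        tips = [self.labels[v] for v in self.tip_nodes()]
        if any(t is None or t == "" for t in tips):
            raise ValidationError("every tip must carry a non-empty label")
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise ValidationError(f"duplicate tip labels: {dups}")
        if any(x < 0 for x in self.lengths):
            raise ValidationError("branch lengths must be non-negative")

    # -- basic structure -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tip_nodes(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tip_nodes()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_nodes())

    def internal_nodes(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.children[v]]

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return list(reversed(self.preorder()))

    def tip_sets(self) -> dict[int, frozenset[str]]:
        """Tip-label set of the clade below every node."""
        out: dict[int, frozenset[str]] = {}
        for v in self.postorder():
            if not self.children[v]:
                out[v] = frozenset({self.labels[v]})
            else:
                s: set[str] = set()
                for c in self.children[v]:
                    s |= out[c]
                out[v] = frozenset(s)
        return out

    # -- metrics -------------------------------------------------------------

    def patristic_distances(self) -> pd.DataFrame:
        """Tip-to-tip branch-length path distances (symmetric DataFrame)."""
        adj: dict[int, list[tuple[int, float]]] = {v: [] for v in range(self.n_nodes)}
        for v in range(1, self.n_nodes):
            p = self.parent[v]
            adj[v].append((p, self.lengths[v]))
            adj[p].append((v, self.lengths[v]))
        tips = self.tip_nodes()
        labels = [self.labels[v] for v in tips]
        mat = np.zeros((len(tips), len(tips)))
        for k, start in enumerate(tips):
            dist = np.full(self.n_nodes, np.nan)
            dist[start] = 0.0
            stack = [start]
            while stack:
                v = stack.pop()
                for w, ell in adj[v]:
                    if np.isnan(dist[w]):
                        dist[w] = dist[v] + ell
                        stack.append(w)
            mat[k] = dist[tips]
        return pd.DataFrame(mat, index=labels, columns=labels)

    # -- editing -------------------------------------------------------------

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict to a subset of tips, suppressing unifurcations.

        Suppressed edges have their lengths summed, so patristic distances
        among retained tips are preserved.
        """
        keep = set(keep)
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise ValidationError(f"unknown tips: {sorted(unknown)}")
        if not keep:
            raise EmptyResultError("cannot prune to an empty tip set")

        # (subtree) -> nested (label, length, children) or None
        def rec(v: int) -> tuple[str | None, float, list] | None:
            if not self.children[v]:
                if self.labels[v] in keep:
                    return (self.labels[v], self.lengths[v], [])
                return None
            subs = [s for s in (rec(c) for c in self.children[v]) if s is not None]
            if not subs:
                return None
            if len(subs) == 1:
                lab, ell, ch = subs[0]
                return (lab, ell + self.lengths[v], ch)
            return (self.labels[v], self.lengths[v], subs)

        top = rec(self.root)
        assert top is not None
        # the new root keeps zero length above it
        top = (top[0], 0.0, top[2])
        parent, children, lengths, labels = [], [], [], []

        def build(node: tuple, par: int) -> None:
            idx = len(parent)
            parent.append(par)
            children.append([])
            lengths.append(node[1])
            labels.append(node[0])
            if par >= 0:
                children[par].append(idx)
            for ch in node[2]:
                build(ch, idx)

        build(top, -1)
        return PhyloTree(parent, children, lengths, labels)

    # -- serialization -------------------------------------------------------

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                core = self.labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
                if self.labels[v]:
                    core += self.labels[v]
            if v == self.root:
                return core
            return f"{core}:{self.lengths[v]:.12g}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, {self.n_nodes} nodes>"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Trees without any branch lengths get unit lengths on every edge; trees
    with only some lengths are rejected.
    """
    try:
        # leaf labels are kept as plain node labels (not taxa) so that
        # duplicate-label detection is ours and raises a validation error
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse failure: {exc}") from exc
    if dtree.seed_node is None or not dtree.leaf_nodes():
        raise FormatError("Newick string contains no tips")

    edge_lengths = [
        nd.edge.length
        for nd in dtree.preorder_node_iter()
        if nd is not dtree.seed_node
    ]
    present = [x for x in edge_lengths if x is not None]
    if present and len(present) != len(edge_lengths):
        raise ValidationError("branch lengths must be present on all edges or none")
    default = 1.0 if not present else None

    parent: list[int] = []
    children: list[list[int]] = []
    lengths: list[float] = []
    labels: list[str | None] = []

    index: dict[int, int] = {}
    for nd in dtree.preorder_node_iter():
        idx = len(parent)
        index[id(nd)] = idx
        par = -1 if nd.parent_node is None else index[id(nd.parent_node)]
        parent.append(par)
        children.append([])
        if par >= 0:
            children[par].append(idx)
        if par == -1:
            lengths.append(0.0)
        else:
            ell = nd.edge.length if nd.edge.length is not None else default
            lengths.append(float(ell))
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            labels.append(lab)
        else:
            labels.append(None)
    return PhyloTree(parent, children, lengths, labels)


def read_newick_file(path: str | Path) -> PhyloTree:
    return read_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Site-by-cell call matrix with a designated set of normal cells.

    ``calls`` is a DataFrame (rows: site IDs, columns: cell IDs) whose values
    are the symbols in :data:`CALLS`.
    """

    calls: pd.DataFrame
    normal_cells: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.normal_cells = frozenset(self.normal_cells)
        if self.calls.columns.duplicated().any():
            raise ValidationError("duplicate cell IDs in genotype matrix")
        if self.calls.index.duplicated().any():
            raise ValidationError("duplicate site IDs in genotype matrix")
        bad = set(np.unique(self.calls.to_numpy())) - set(CALLS)
        if bad:
            raise ValidationError(f"unknown genotype calls: {sorted(bad)}")
        missing_normals = self.normal_cells - set(self.calls.columns)
        if missing_normals:
            raise ValidationError(
                f"normal cells absent from matrix: {sorted(missing_normals)}"
            )

    @property
    def sites(self) -> list[str]:
        return list(self.calls.index)

    @property
    def cells(self) -> list[str]:
        return list(self.calls.columns)


_TSV_MISSING = "NA"


def read_genotype_tsv(
    path: str | Path, normal_cells: Iterable[str] = ()
) -> GenotypeMatrix:
    """Read a genotype TSV: first column site IDs, header row cell IDs,
    calls as ``REF``/``ALT``/``HET``/``NA``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df = df.replace(_TSV_MISSING, MISSING)
    return GenotypeMatrix(df, frozenset(normal_cells))


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    g.calls.replace(MISSING, _TSV_MISSING).to_csv(path, sep="\t", index_label="site")


def filter_snvs(g: GenotypeMatrix, completeness_cutoff: float = 0.7) -> GenotypeMatrix:
    """Drop uninformative or suspect SNV sites.

    A site is removed when (a) every normal-cell call is missing, (b) the
    non-missing normal calls disagree, (c) the normal consensus is HET or ALT
    (potential germline heterozygosity), or (d) the fraction of non-missing
    calls over *all* cells is below ``completeness_cutoff``. Site order is
    preserved; the operation is idempotent.
    """
    if not (0 < completeness_cutoff <= 1):
        raise ConfigurationError("completeness_cutoff must be in (0, 1]")
    if not g.normal_cells:
        raise ConfigurationError("filter_snvs requires at least one normal cell")
    normals = sorted(g.normal_cells)
    arr = g.calls.to_numpy()
    norm = g.calls[normals].to_numpy()

    keep = np.ones(arr.shape[0], dtype=bool)
    norm_obs = norm != MISSING
    keep &= norm_obs.any(axis=1)  # (a)
    for k in range(arr.shape[0]):
        obs = norm[k][norm_obs[k]]
        if obs.size == 0:
            continue
        vals = set(obs)
        if len(vals) > 1:  # (b)
            keep[k] = False
        elif vals != {REF}:  # (c)
            keep[k] = False
    frac_called = (arr != MISSING).mean(axis=1)
    keep &= frac_called >= completeness_cutoff  # (d)
    return GenotypeMatrix(g.calls.loc[keep], g.normal_cells)


def filter_cells(g: GenotypeMatrix, max_missing_fraction: float = 0.5) -> GenotypeMatrix:
    """Drop low-quality cells whose missing-call fraction exceeds the cutoff.

    The inequality is strict (a cell exactly at the threshold is retained).
    """
    if g.calls.shape[0] == 0:
        raise ValidationError("filter_cells requires at least one site")
    miss = (g.calls.to_numpy() == MISSING).mean(axis=0)
    keep_cols = [c for c, m in zip(g.calls.columns, miss) if m <= max_missing_fraction]
    if not keep_cols:
        raise EmptyResultError("every cell exceeded the missing-data threshold")
    return GenotypeMatrix(
        g.calls[keep_cols], g.normal_cells & set(keep_cols)
    )


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-cell normalized expression TSV (first column gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_expression(df)
    return df


def read_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> pd.DataFrame:
    """Read expression from MatrixMarket with companion gene/cell index files
    (one ID per line; genes are rows of the matrix)."""
    mat = _spio.mmread(str(mtx_path))
    if _sparse.issparse(mat):
        mat = mat.toarray()
    genes = Path(genes_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    _validate_expression(df)
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def _validate_expression(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
    if df.columns.duplicated().any():
        raise ValidationError("duplicate cell IDs in expression matrix")


# ---------------------------------------------------------------------------
# AncestryAnnotation
# ---------------------------------------------------------------------------

@dataclass
class AncestryAnnotation:
    """Cell → ancestry-label map.

    Labels other than ``normal`` and ``unassigned`` are ancestry labels
    (conventionally ``ancestry_1 .. ancestry_k``). ``provenance`` records the
    tree or file the annotation came from.
    """

    labels: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("annotation is empty")
        if not self.ancestries:
            raise ValidationError("annotation has no ancestry label")

    @property
    def cells(self) -> list[str]:
        return list(self.labels)

    @property
    def ancestries(self) -> list[str]:
        """Distinct non-special labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels.values():
            if lab not in SPECIAL_LABELS:
                seen.setdefault(lab, None)
        return list(seen)

    def cells_with(self, label: str) -> list[str]:
        return [c for c, lab in self.labels.items() if lab == label]

    def relabel(self, mapping: Mapping[str, str]) -> "AncestryAnnotation":
        return AncestryAnnotation(
            {c: mapping.get(lab, lab) for c, lab in self.labels.items()},
            provenance=self.provenance,
        )


def read_annotation_tsv(path: str | Path) -> AncestryAnnotation:
    """Read a two-column ``cell<TAB>label`` annotation file (no header)."""
    labels: dict[str, str] = {}
    text = Path(path).read_text()
    for ln, line in enumerate(_stdio.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {ln}: expected 'cell<TAB>label'")
        cell, lab = parts
        if cell in labels:
            raise ValidationError(f"{path}: duplicate cell {cell!r}")
        labels[cell] = lab
    return AncestryAnnotation(labels, provenance=str(path))


def write_annotation_tsv(ann: AncestryAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cell, lab in ann.labels.items():
            fh.write(f"{cell}\t{lab}\n")
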