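"""Synthetic coupled phylogeny / genotype / expression datasets.

The generator emulates the structure of scRNA-seq-derived tumor data used
for concordance analysis: a rooted cell phylogeny with a few well-separated
clones (genetic ancestries) plus a small set of normal cells, a site-by-cell
SNV call matrix with heavy missingness and false-negative dropout of mutant
alleles, and a gene-by-cell expression matrix in which each ancestry shifts
its own block of signal genes (log-normal noise elsewhere). An optional
*convergence* fraction re-generates part of ancestry 2's cells from
ancestry 1's expression program, creating cells whose expression state
disagrees with their genetic ancestry.

Every quantity is drawn from a single seeded generator, so a config maps to
exactly one dataset. Defaults describe a small but realistic study: 60
cells (3 of them normal), 3 ancestries, 200 SNV sites with 40% missing
calls and 20% allelic dropout, 1,200 genes of which 120 carry ancestry
signal with a 3-unit shift in log expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import (
    ALT,
    MISSING,
    NORMAL_LABEL,
    REF,
    AncestryAnnotation,
    GenotypeMatrix,
    PhyloTree,
    read_newick,
    write_annotation_tsv,
    write_expression_tsv,
    write_genotype_tsv,
    write_newick,
)

BALANCED_MODE = "balanced"
UNBALANCED_MODE = "unbalanced"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_cells: int = 60
    n_normal: int = 3
    n_ancestries: int = 3
    tree_mode: str = BALANCED_MODE
    n_sites: int = 200
    fn_rate: float = 0.2
    missing_rate: float = 0.4
    n_genes: int = 1200
    n_signal_genes: int = 120
    effect_size: float = 3.0
    convergence_frac: float = 0.0
    noise_sd: float = 0.5
    intra_branch: float = 0.1
    clade_branch: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fn_rate", "missing_rate", "convergence_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_signal_genes > self.n_genes:
            raise ValidationError("n_signal_genes must be <= n_genes")
        if self.n_normal < 1:
            raise ValidationError("need at least one normal cell")
        if self.tree_mode not in (BALANCED_MODE, UNBALANCED_MODE):
            raise ValidationError(f"unknown tree_mode {self.tree_mode!r}")
        if self.n_cells - self.n_normal < 2 * self.n_ancestries:
            raise ValidationError(
                "need at least 2 tumor cells per ancestry "
                f"({self.n_cells - self.n_normal} tumor cells, "
                f"{self.n_ancestries} ancestries)"
            )


@dataclass
class SimTruth:
    """Ground truth: genetic ancestry and expression program per cell."""

    ancestry: dict[str, str]  # cell -> ancestry_k / normal
    program: dict[str, int]  # cell -> program index (-1 for normal)
    signal_genes: list[str] = field(default_factory=list)
    program_genes: dict[int, list[str]] = field(default_factory=dict)
    tree: PhyloTree | None = None

    @property
    def normal_cells(self) -> frozenset[str]:
        return frozenset(
            c for c, lab in self.ancestry.items() if lab == NORMAL_LABEL
        )

    def annotation(self, provenance: str = "truth") -> AncestryAnnotation:
        return AncestryAnnotation(dict(self.ancestry), provenance=provenance)


def _group_sizes(total: int, k: int) -> list[int]:
    base, extra = divmod(total, k)
    return [base + (1 if g < extra else 0) for g in range(k)]


def _balanced_newick(tips: list[tuple[str, float]], inner: float) -> str:
    """Recursively even-split subtree over (label, tip_length) pairs.

    Returns the subtree string without its own branch length (the caller
    attaches one).
    """
    if len(tips) == 1:
        return tips[0][0]
    mid = len(tips) // 2
    parts = []
    for side in (tips[:mid], tips[mid:]):
        sub = _balanced_newick(side, inner)
        ell = side[0][1] if len(side) == 1 else inner
        parts.append(f"{sub}:{ell:.6g}")
    return "(" + ",".join(parts) + ")"


def simulate_tree(config: SimConfig) -> tuple[PhyloTree, SimTruth]:
    """Generate the cell phylogeny and its ancestry ground truth.

    Balanced mode joins per-ancestry balanced subtrees; unbalanced mode is a
    single caterpillar with long edges at ancestry boundaries. In both
    modes the ancestries are separated from each other (and from the normal
    cells) by branches ``clade_branch``-long, two orders of magnitude above
    the within-ancestry scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_tumor = config.n_cells - config.n_normal
    sizes = _group_sizes(n_tumor, config.n_ancestries)
    cells = [f"cell{k:03d}" for k in range(n_tumor)]
    normals = [f"norm{k:02d}" for k in range(config.n_normal)]

    groups: list[list[str]] = []
    start = 0
    for s in sizes:
        groups.append(cells[start : start + s])
        start += s

    def jitter() -> float:
        return float(config.intra_branch * rng.uniform(0.5, 1.5))

    if config.tree_mode == BALANCED_MODE:
        subtrees = [
            _balanced_newick([(c, jitter()) for c in grp], config.intra_branch)
            for grp in groups
        ]
        tumor = subtrees[0]
        for sub in subtrees[1:]:
            tumor = f"({tumor}:{config.clade_branch:.6g},{sub}:{config.clade_branch:.6g})"
        if config.n_normal == 1:
            norm = f"{normals[0]}:{config.clade_branch:.6g}"
        else:
            norm = (
                _balanced_newick([(c, jitter()) for c in normals], config.intra_branch)
                + f":{config.clade_branch:.6g}"
            )
        newick = f"({tumor}:{config.clade_branch:.6g},{norm});"
    else:
        order = [c for grp in groups for c in grp] + normals
        boundaries = set(np.cumsum(sizes).tolist())  # prefix sizes at group ends
        tree_str = f"{order[0]}:{jitter():.6g}"
        for k in range(1, len(order)):
            spine = config.clade_branch if k in boundaries else config.intra_branch
            tip_len = config.clade_branch if order[k] in normals else jitter()
            tree_str = f"({tree_str}:{spine:.6g},{order[k]}:{tip_len:.6g})"
        newick = tree_str + ";"

    tree = read_newick(newick)
    ancestry = {c: f"ancestry_{g + 1}" for g, grp in enumerate(groups) for c in grp}
    for c in normals:
        ancestry[c] = NORMAL_LABEL
    program = {c: g for g, grp in enumerate(groups) for c in grp}
    program.update({c: -1 for c in normals})
    return tree, SimTruth(ancestry=ancestry, program=program, tree=tree)


def simulate_genotypes(
    tree: PhyloTree, truth: SimTruth, config: SimConfig
) -> GenotypeMatrix:
    """Place mutations on tumor branches and corrupt the resulting calls.

    Each site's mutation falls on one branch, with probability proportional
    to branch length, among branches whose descendants contain no normal
    cell; a cell is ALT iff the mutation lies on its root path. Corruption
    then flips each ALT to REF with probability ``fn_rate`` (allelic
    dropout) and any call to MISSING with probability ``missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tip_sets = tree.tip_sets()
    normal = truth.normal_cells
    branch_nodes = [
        v
        for v in range(tree.n_nodes)
        if v != tree.root and not (tip_sets[v] & normal) and tree.lengths[v] > 0
    ]
    weights = np.array([tree.lengths[v] for v in branch_nodes], dtype=float)
    weights /= weights.sum()

    cells = tree.tip_labels
    cell_idx = {c: k for k, c in enumerate(cells)}
    n_sites, n_cells = config.n_sites, len(cells)
    alt = np.zeros((n_sites, n_cells), dtype=bool)
    chosen = rng.choice(len(branch_nodes), size=n_sites, p=weights)
    for s, b in enumerate(chosen):
        for c in tip_sets[branch_nodes[b]]:
            alt[s, cell_idx[c]] = True

    calls = np.where(alt, ALT, REF).astype(object)
    dropout = (rng.random((n_sites, n_cells)) < config.fn_rate) & alt
    calls[dropout] = REF
    miss = rng.random((n_sites, n_cells)) < config.missing_rate
    calls[miss] = MISSING
    df = pd.DataFrame(
        calls,
        index=[f"site{s + 1:04d}" for s in range(n_sites)],
        columns=cells,
    )
    return GenotypeMatrix(df, frozenset(normal))


def simulate_expression(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Generate the gene-by-cell expression matrix from the cell programs.

    Expression is log-normal: ``exp(N(0, noise_sd) + effect_size * 1[gene in
    the cell's program])``. Signal genes are split evenly among the ancestry
    programs; normal cells carry background only. If ``convergence_frac`` >
    0, that fraction of ancestry 2's cells is re-generated from ancestry 1's
    program and ``truth.program`` is updated to record it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = [f"g{k + 1:05d}" for k in range(config.n_genes)]
    per = config.n_signal_genes // config.n_ancestries
    program_genes = {
        p: genes[p * per : (p + 1) * per] for p in range(config.n_ancestries)
    }
    truth.signal_genes = genes[: per * config.n_ancestries]
    truth.program_genes = program_genes

    if config.convergence_frac > 0:
        anc2 = [c for c, lab in truth.ancestry.items() if lab == "ancestry_2"]
        n_conv = int(np.floor(config.convergence_frac * len(anc2)))
        for c in anc2[:n_conv]:
            truth.program[c] = 0

    cells = list(truth.ancestry)
    log_x = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(cells)))
    gene_idx = {g: k for k, g in enumerate(genes)}
    for j, c in enumerate(cells):
        p = truth.program[c]
        if p >= 0 and config.effect_size != 0:
            rows = [gene_idx[g] for g in program_genes[p]]
            log_x[rows, j] += config.effect_size
    return pd.DataFrame(np.exp(log_x), index=genes, columns=cells)


def simulate_dataset(
    config: SimConfig,
) -> tuple[PhyloTree, SimTruth, GenotypeMatrix, pd.DataFrame]:
    """Run all three generators for one config."""
    tree, truth = simulate_tree(config)
    geno = simulate_genotypes(tree, truth, config)
    expr = simulate_expression(truth, config)
    return tree, truth, geno, expr


PRESETS = {
    "concordant": dict(effect_size=3.0, convergence_frac=0.0),
    "convergent": dict(effect_size=3.0, convergence_frac=0.5),
    "null": dict(effect_size=0.0, convergence_frac=0.0),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study conditions: ``concordant``, ``convergent`` or ``null``."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SimConfig(seed=seed, **{**PRESETS[name], **overrides})


def write_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Materialize a dataset as the plain-text files the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, truth, geno, expr = simulate_dataset(config)
    paths = {
        "tree": str(out / "tree.nwk"),
        "genotypes": str(out / "genotypes.tsv"),
        "expression": str(out / "expression.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_newick(tree, paths["tree"])
    write_genotype_tsv(geno, paths["genotypes"])
    write_expression_tsv(expr, paths["expression"])
    write_annotation_tsv(truth.annotation(), paths["truth"])
    return paths
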