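"""Agreement between ancestry annotations from different phylogenies.

Phylogenies inferred from noisy scRNA-seq variant calls differ, so an
ancestry annotation is only trustworthy if independently built trees imply
the same cell grouping. Agreement between two annotations is measured on
the contingency table of shared cells with Pearson's chi-square (no
continuity correction) and Cramér's V,

    V = sqrt(chi2 / (n * (min(r, c) - 1))),

with the convention that V > 0.2 together with p < 0.01 *supports* the
annotations agreeing. A consensus annotation is produced by aligning every
annotation's labels to the first one (optimal one-to-one matching on the
pairwise contingency table) and majority-voting per cell; voting ties give
``unassigned``.

Cells labeled ``normal`` or ``unassigned`` are not genetic ancestries and
are excluded from contingency tables by default (``include_special``
overrides).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2_contingency

from .exceptions import AlignmentError, DegenerateTableError, ValidationError
from .io import SPECIAL_LABELS, UNASSIGNED_LABEL, AncestryAnnotation


@dataclass(frozen=True)
class AgreementStat:
    """Chi-square test and Cramér's V for one annotation pair."""

    cramers_v: float
    chi2: float
    dof: int
    p_value: float

    @property
    def supported(self) -> bool:
        return self.cramers_v > 0.2 and self.p_value < 0.01


def build_contingency(
    a: AncestryAnnotation,
    b: AncestryAnnotation,
    include_special: bool = False,
) -> pd.DataFrame:
    """Cell-count contingency table (rows: labels of ``a``, columns: of ``b``)
    over the cells shared by both annotations."""
    shared = [c for c in a.labels if c in b.labels]
    if not include_special:
        shared = [
            c
            for c in shared
            if a.labels[c] not in SPECIAL_LABELS and b.labels[c] not in SPECIAL_LABELS
        ]
    if len(shared) < 2:
        raise DegenerateTableError(
            "annotations share fewer than 2 (non-special) cells"
        )
    rows = pd.Series({c: a.labels[c] for c in shared}, name="a")
    cols = pd.Series({c: b.labels[c] for c in shared}, name="b")
    table = pd.crosstab(rows, cols)
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            f"table is {table.shape[0]}x{table.shape[1]}; need >= 2 labels per axis"
        )
    return table


def agreement_stat(table: pd.DataFrame) -> AgreementStat:
    """Pearson chi-square (no Yates correction) and Cramér's V of a table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise DegenerateTableError("need a table with >= 2 rows and >= 2 columns")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has an all-zero margin")
    n = t.sum()
    if n < 2:
        raise DegenerateTableError("table holds fewer than 2 cells")
    chi2, p, dof, expected = chi2_contingency(t, correction=False)
    if (expected < 5).any():
        warnings.warn(
            "some expected counts are < 5; the chi-square approximation is rough",
            stacklevel=2,
        )
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))
    return AgreementStat(cramers_v=v, chi2=float(chi2), dof=int(dof), p_value=float(p))


def _align_labels(
    ref: AncestryAnnotation, other: AncestryAnnotation
) -> dict[str, str]:
    """Map ``other``'s ancestry labels onto ``ref``'s by maximum cell overlap."""
    shared = [
        c
        for c in ref.labels
        if c in other.labels
        and ref.labels[c] not in SPECIAL_LABELS
        and other.labels[c] not in SPECIAL_LABELS
    ]
    if not any(c in other.labels for c in ref.labels):
        raise AlignmentError(
            f"annotation {other.provenance!r} shares no cells with the reference"
        )
    ref_labels = ref.ancestries
    oth_labels = other.ancestries
    counts = np.zeros((len(oth_labels), len(ref_labels)))
    for c in shared:
        counts[oth_labels.index(other.labels[c]), ref_labels.index(ref.labels[c])] += 1
    rows, cols = linear_sum_assignment(-counts)
    mapping = {oth_labels[i]: ref_labels[j] for i, j in zip(rows, cols)}
    # unmatched labels (more labels than the reference has) keep a unique name
    taken = set(ref_labels)
    for lab in oth_labels:
        if lab not in mapping:
            new = lab if lab not in taken else f"{lab}~{other.provenance or 'alt'}"
            mapping[lab] = new
            taken.add(new)
    return mapping


def align_annotations(
    annotations: Sequence[AncestryAnnotation],
) -> list[AncestryAnnotation]:
    """Relabel every annotation onto the first one's label set."""
    if len(annotations) < 2:
        raise ValidationError("need at least two annotations")
    ref = annotations[0]
    out = [ref]
    for other in annotations[1:]:
        out.append(other.relabel(_align_labels(ref, other)))
    return out


def consensus_annotation(
    annotations: Sequence[AncestryAnnotation],
) -> AncestryAnnotation:
    """Per-cell majority vote across label-aligned annotations.

    Cells absent from some annotations are voted on by those that include
    them; ties give ``unassigned``.
    """
    aligned = align_annotations(annotations)
    cells: dict[str, None] = {}
    for ann in aligned:
        for c in ann.labels:
            cells.setdefault(c, None)
    labels: dict[str, str] = {}
    for c in cells:
        votes: dict[str, int] = {}
        for ann in aligned:
            if c in ann.labels:
                votes[ann.labels[c]] = votes.get(ann.labels[c], 0) + 1
        best = max(votes.values())
        winners = sorted(lab for lab, k in votes.items() if k == best)
        labels[c] = winners[0] if len(winners) == 1 else UNASSIGNED_LABEL
    return AncestryAnnotation(labels, provenance="consensus")


def pairwise_agreement(
    annotations: Sequence[AncestryAnnotation],
    include_consensus: bool = True,
) -> pd.DataFrame:
    """Tidy table of V / chi2 / p for every annotation pair (optionally
    including the consensus). Emits a warning when any pair is unsupported,
    since downstream trajectory analysis presumes concordant annotations."""
    anns = list(annotations)
    if include_consensus:
        anns.append(consensus_annotation(annotations))
    rows = []
    any_unsupported = False
    for i in range(len(anns)):
        for j in range(i + 1, len(anns)):
            stat = agreement_stat(build_contingency(anns[i], anns[j]))
            any_unsupported |= not stat.supported
            rows.append(
                {
                    "a": anns[i].provenance or f"annotation_{i + 1}",
                    "b": anns[j].provenance or f"annotation_{j + 1}",
                    "cramers_v": stat.cramers_v,
                    "chi2": stat.chi2,
                    "dof": stat.dof,
                    "p_value": stat.p_value,
                    "supported": stat.supported,
                }
            )
    if any_unsupported:
        warnings.warn(
            "some annotation pairs are not supported (V <= 0.2 or p >= 0.01); "
            "downstream trajectory analysis is best performed on concordant "
            "annotations",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def agreement_heatmap(
    annotations: Sequence[AncestryAnnotation],
    consensus: AncestryAnnotation | None = None,
):
    """Label matrix (one row per annotation plus the consensus; cells ordered
    by consensus label then ID) and a categorical heatmap figure.

    Returns ``(figure, matrix)`` where ``matrix`` is the plotted label
    DataFrame, suitable for writing as the companion TSV.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if len(annotations) < 2:
        raise ValidationError("need at least two annotations")
    if consensus is None:
        consensus = consensus_annotation(annotations)
    aligned = align_annotations(annotations)
    cells = sorted(consensus.labels, key=lambda c: (consensus.labels[c], c))
    names = [
        ann.provenance or f"annotation_{k + 1}" for k, ann in enumerate(aligned)
    ] + ["consensus"]
    matrix = pd.DataFrame(
        [[ann.labels.get(c, "") for c in cells] for ann in [*aligned, consensus]],
        index=names,
        columns=cells,
    )
    labels = sorted({lab for row in matrix.to_numpy() for lab in row})
    code = {lab: k for k, lab in enumerate(labels)}
    coded = np.vectorize(code.__getitem__)(matrix.to_numpy()).astype(float)
    cmap = ListedColormap(plt.get_cmap("tab20").colors[: max(len(labels), 1)])
    fig, ax = plt.subplots(figsize=(max(6, len(cells) * 0.12), 1 + 0.5 * len(names)))
    im = ax.imshow(coded, aspect="auto", cmap=cmap, vmin=-0.5, vmax=len(labels) - 0.5)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("cells (ordered by consensus ancestry)")
    cbar = fig.colorbar(im, ax=ax, ticks=range(len(labels)))
    cbar.ax.set_yticklabels(labels)
    fig.tight_layout()
    return fig, matrix
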