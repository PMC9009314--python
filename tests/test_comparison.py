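import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from phyloconcord.comparison import (
    agreement_heatmap,
    agreement_stat,
    align_annotations,
    build_contingency,
    consensus_annotation,
    pairwise_agreement,
)
from phyloconcord.exceptions import AlignmentError, DegenerateTableError
from phyloconcord.io import AncestryAnnotation


def chi_square_first_principles(table: np.ndarray):
    """Brute-force Pearson chi-square from margins (the oracle)."""
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = ((table - expected) ** 2 / expected).sum()
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = chi2_dist.sf(chi2, dof)
    v = np.sqrt(chi2 / (n * (min(table.shape) - 1)))
    return chi2, dof, p, v


def ann(mapping, name=""):
    return AncestryAnnotation(dict(mapping), provenance=name)


class TestContingency:
    def test_identical_annotations_give_diagonal(self):
        a = ann({f"c{i}": "A1" if i < 10 else "A2" for i in range(20)})
        t = build_contingency(a, a)
        assert t.to_numpy().tolist() == [[10, 0], [0, 10]]

    def test_disjoint_cell_sets_rejected(self):
        a = ann({"c1": "A1", "c2": "A2"})
        b = ann({"d1": "B1", "d2": "B2"})
        with pytest.raises(DegenerateTableError):
            build_contingency(a, b)

    def test_hand_counted_cross_table(self):
        a = ann({**{f"c{i}": "A1" for i in range(1, 9)}, "c9": "A2", "c10": "A2"})
        b = ann({**{f"c{i}": "B1" for i in range(1, 7)}, **{f"c{i}": "B2" for i in range(7, 11)}})
        t = build_contingency(a, b)
        assert t.loc["A1", "B1"] == 6 and t.loc["A1", "B2"] == 2
        assert t.loc["A2", "B1"] == 0 and t.loc["A2", "B2"] == 2

    def test_special_labels_excluded_by_default(self):
        a = ann({"c1": "A1", "c2": "A1", "c3": "A2", "c4": "A2", "n1": "normal"})
        b = ann({"c1": "B1", "c2": "B2", "c3": "B1", "c4": "B2", "n1": "normal"})
        t = build_contingency(a, b)
        assert t.to_numpy().sum() == 4
        t2 = build_contingency(a, b, include_special=True)
        assert t2.to_numpy().sum() == 5


class TestAgreementStat:
    def test_diagonal_table_is_perfect_association(self):
        s = agreement_stat(pd.DataFrame([[10, 0], [0, 10]]))
        assert s.cramers_v == pytest.approx(1.0)
        assert s.supported

    def test_uniform_table_is_independence(self):
        s = agreement_stat(pd.DataFrame([[5, 5], [5, 5]]))
        assert s.chi2 == pytest.approx(0.0)
        assert s.cramers_v == pytest.approx(0.0)
        assert not s.supported

    def test_worked_two_by_two(self):
        # expected counts all 5; chi2 = 4 * (9/5) = 7.2; V = sqrt(7.2/20) = 0.6
        s = agreement_stat(pd.DataFrame([[8, 2], [2, 8]]))
        assert s.chi2 == pytest.approx(7.2)
        assert s.cramers_v == pytest.approx(0.6)
        assert s.dof == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            agreement_stat(pd.DataFrame([[3, 0], [2, 0]]))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_first_principles_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r, c = rng.integers(2, 5, size=2)
        table = rng.integers(1, 30, size=(r, c)).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = agreement_stat(pd.DataFrame(table))
        chi2, dof, p, v = chi_square_first_principles(table)
        assert s.chi2 == pytest.approx(chi2, abs=1e-9)
        assert s.p_value == pytest.approx(p, abs=1e-9)
        assert s.cramers_v == pytest.approx(v, abs=1e-9)
        assert s.dof == dof
        assert 0 <= s.cramers_v <= 1

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(1)
        table = rng.integers(1, 20, size=(3, 4)).astype(float)
        s1 = agreement_stat(pd.DataFrame(table))
        s2 = agreement_stat(pd.DataFrame(table[::-1, ::-1]))
        assert s1.cramers_v == pytest.approx(s2.cramers_v)
        assert s1.chi2 == pytest.approx(s2.chi2)


class TestConsensus:
    def test_copies_reproduce_annotation(self):
        a = ann({f"c{i}": f"A{i % 3 + 1}" for i in range(12)}, "a")
        for k in (2, 3, 5):
            cons = consensus_annotation([a] * k)
            assert cons.labels == a.labels

    def test_label_permutation_absorbed(self):
        a = ann({f"c{i}": "A1" if i < 6 else "A2" for i in range(12)}, "a")
        b = a.relabel({"A1": "Z9", "A2": "Z1"})
        cons = consensus_annotation([a, b])
        assert cons.labels == a.labels

    def test_majority_vote(self):
        base = {f"c{i}": "A1" if i < 6 else "A2" for i in range(12)}
        a1, a2 = ann(base, "a1"), ann(base, "a2")
        flipped = dict(base, c0="A2")
        a3 = ann(flipped, "a3")
        cons = consensus_annotation([a1, a2, a3])
        assert cons.labels["c0"] == "A1"  # 2 of 3 aligned votes

    def test_tie_gives_unassigned(self):
        base = {f"c{i}": "A1" if i < 4 else "A2" for i in range(8)}
        a = ann(base, "a")
        b = ann(dict(base, c0="A2"), "b")  # alignment is unambiguous here
        cons = consensus_annotation([a, b])
        assert cons.labels["c0"] == "unassigned"
        assert all(cons.labels[c] == base[c] for c in base if c != "c0")

    def test_no_overlap_is_alignment_error(self):
        a = ann({"c1": "A1", "c2": "A2"}, "a")
        b = ann({"d1": "B1", "d2": "B2"}, "b")
        with pytest.raises(AlignmentError, match="b"):
            align_annotations([a, b])


class TestHeatmap:
    def test_dimensions_and_companion_matrix(self):
        a = ann({f"c{i}": "A1" if i < 5 else "A2" for i in range(10)}, "a")
        b = ann({f"c{i}": "B1" if i < 4 else "B2" for i in range(10)}, "b")
        fig, matrix = agreement_heatmap([a, b])
        assert matrix.shape == (3, 10)  # two annotations + consensus
        assert list(matrix.index)[-1] == "consensus"

    def test_pairwise_table_includes_consensus(self):
        a = ann({f"c{i}": "A1" if i < 5 else "A2" for i in range(10)}, "a")
        b = ann({f"c{i}": "B1" if i < 5 else "B2" for i in range(10)}, "b")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pairwise_agreement([a, b])
        assert len(table) == 3  # (a,b), (a,consensus), (b,consensus)
        assert set(table.columns) >= {"cramers_v", "chi2", "p_value", "supported"}
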