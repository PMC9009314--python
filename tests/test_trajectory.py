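import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

from phyloconcord.exceptions import ValidationError
from phyloconcord.io import AncestryAnnotation
from phyloconcord.simulate import preset_config, simulate_dataset
from phyloconcord.trajectory import (
    ANCESTRY_COVERAGE,
    DEFAULT_SCALES,
    StateAssignment,
    build_trajectory,
    kruskal_wallis_h,
    oci,
    phylo_trajectory_sweep,
    rank_genes,
    sci,
)


def make_states(assignment: dict[str, int]) -> StateAssignment:
    return StateAssignment(
        states=dict(assignment),
        pseudotime={c: float(k) for k, c in enumerate(assignment)},
        root_cell=next(iter(assignment)),
        gene_scale=200,
    )


class TestGeneRanking:
    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_h_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(15, 24))
        x[rng.random(x.shape) < 0.2] = 0.0  # induce ties
        groups = [np.arange(0, 8), np.arange(8, 16), np.arange(16, 24)]
        h, p = kruskal_wallis_h(x, groups)
        for r in range(x.shape[0]):
            h_ref, p_ref = kruskal(*(x[r, g] for g in groups))
            assert h[r] == pytest.approx(h_ref, abs=1e-10)
            assert p[r] == pytest.approx(p_ref, abs=1e-10)

    def test_two_group_shift_h_value(self):
        # ranks 1..5 vs 6..10: H = 12/(10*11) * 5*((3-5.5)^2 + (8-5.5)^2) = 75/11
        x = np.array([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0]])
        h, _ = kruskal_wallis_h(x, [np.arange(5), np.arange(5, 10)])
        assert h[0] == pytest.approx(75 / 11)

    def test_constant_gene_ranked_last_with_zero_h(self):
        cells = [f"c{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.random((3, 12)) + 1, index=["g_a", "g_b", "g_flat"], columns=cells
        )
        expr.loc["g_flat"] = 2.0
        expr.loc["g_a", cells[:6]] += 5.0
        ann = AncestryAnnotation(
            {c: "ancestry_1" if i < 6 else "ancestry_2" for i, c in enumerate(cells)}
        )
        rk = rank_genes(expr, ann)
        row = rk.table.set_index("gene")
        assert row.loc["g_flat", "statistic"] == 0.0
        assert rk.genes[-1] == "g_flat"
        assert rk.genes[0] == "g_a"

    def test_tied_statistics_ordered_by_gene_id(self):
        cells = [f"c{i}" for i in range(12)]
        vals = np.tile(np.arange(12, dtype=float), (2, 1))
        expr = pd.DataFrame(vals, index=["g_z", "g_a"], columns=cells)
        ann = AncestryAnnotation(
            {c: "ancestry_1" if i < 6 else "ancestry_2" for i, c in enumerate(cells)}
        )
        rk = rank_genes(expr, ann)
        assert rk.genes == ["g_a", "g_z"]

    def test_single_group_rejected(self):
        expr = pd.DataFrame(np.ones((2, 6)) + np.eye(2, 6), columns=[f"c{i}" for i in range(6)])
        ann = AncestryAnnotation({f"c{i}": "ancestry_1" for i in range(6)})
        with pytest.raises(ValidationError):
            rank_genes(expr, ann)


class TestTrajectory:
    def test_collinear_cells_single_state_ordered_pseudotime(self):
        expr = pd.DataFrame(
            {"c1": [0.0, 0.0], "c2": [1.0, 1.0], "c3": [2.0, 2.0]},
            index=["g1", "g2"],
        )
        st = build_trajectory(expr, ["g1", "g2"], "c1", min_state_cells=1)
        assert st.n_states == 1
        assert st.pseudotime["c1"] == 0.0
        assert 0.0 < st.pseudotime["c2"] < st.pseudotime["c3"]

    def test_missing_root_rejected(self):
        expr = pd.DataFrame(np.ones((2, 3)), columns=["a", "b", "c"], index=["g1", "g2"])
        with pytest.raises(ValidationError, match="root"):
            build_trajectory(expr, ["g1", "g2"], "zzz")

    def test_y_shaped_cloud_three_states(self):
        rng = np.random.default_rng(42)
        arms = {
            "stem": np.array([1.0, 0.0]),
            "up": np.array([-1.0, 1.0]),
            "down": np.array([-1.0, -1.0]),
        }
        cells, rows = [], []
        for arm, direction in arms.items():
            for k in range(20):
                pos = direction * (2.0 + k)
                rows.append(pos + rng.normal(0, 0.05, size=2))
                cells.append(f"{arm}{k:02d}")
        coords = np.array(rows).T
        expr = pd.DataFrame(coords + 50.0, index=["g1", "g2"], columns=cells)
        st = build_trajectory(expr, ["g1", "g2"], "stem19")
        assert st.n_states == 3
        labels = {arm: {st.states[f"{arm}{k:02d}"] for k in range(20)} for arm in arms}
        # each arm is dominated by a single state
        for arm in arms:
            members = [st.states[f"{arm}{k:02d}"] for k in range(20)]
            top = max(set(members), key=members.count)
            assert members.count(top) >= 17

    def test_pseudotime_tree_recursion(self):
        _, truth, _, expr = simulate_dataset(preset_config("concordant", seed=2))
        rk = rank_genes(expr, truth.annotation())
        root = sorted(truth.normal_cells)[0]
        st = build_trajectory(expr, rk.top(200), root)
        assert st.pseudotime[root] == 0.0
        for cell, parent in st.mst_parent.items():
            if parent is None:
                continue
            assert st.pseudotime[cell] == pytest.approx(
                st.pseudotime[parent] + st.mst_edge_length[cell]
            )

    def test_deterministic(self):
        _, truth, _, expr = simulate_dataset(preset_config("concordant", seed=3))
        rk = rank_genes(expr, truth.annotation())
        root = sorted(truth.normal_cells)[0]
        a = build_trajectory(expr, rk.top(200), root)
        b = build_trajectory(expr, rk.top(200), root)
        assert a.states == b.states and a.pseudotime == b.pseudotime


class TestConcordanceIndices:
    """Worked example: state 4 nearly pure for ancestry 3, the rest mixed."""

    @staticmethod
    def worked_example():
        assignment, labels = {}, {}
        spec = {
            1: [("ancestry_1", 4), ("ancestry_2", 4), ("ancestry_3", 1)],
            2: [("ancestry_1", 5), ("ancestry_2", 3)],
            3: [("ancestry_2", 4), ("ancestry_1", 3), ("ancestry_3", 1)],
            4: [("ancestry_3", 9), ("ancestry_1", 1)],  # 90% ancestry 3
        }
        k = 0
        for state, comps in spec.items():
            for lab, count in comps:
                for _ in range(count):
                    cell = f"c{k:02d}"
                    assignment[cell] = state
                    labels[cell] = lab
                    k += 1
        return make_states(assignment), AncestryAnnotation(labels)

    def test_sci_of_nearly_pure_state(self):
        st, ann = self.worked_example()
        assert sci(st, ann, "ancestry_3") == 1
        assert sci(st, ann, "ancestry_1") == 0
        assert sci(st, ann, "ancestry_2") == 0

    def test_oci_counts_unique_states(self):
        st, ann = self.worked_example()
        assert oci(st, ann) == pytest.approx(0.25)  # 1 unique of 4 states

    def test_multiple_states_per_ancestry(self):
        st = make_states({"a1": 1, "a2": 1, "a3": 2, "a4": 2, "b1": 3, "b2": 3})
        ann = AncestryAnnotation(
            {c: "ancestry_1" if c.startswith("a") else "ancestry_2" for c in st.states}
        )
        assert sci(st, ann, "ancestry_1") == 2
        assert oci(st, ann) == pytest.approx(1.0)

    def test_all_mixed_is_zero(self):
        st = make_states({"a1": 1, "b1": 1, "a2": 2, "b2": 2})
        ann = AncestryAnnotation(
            {c: "ancestry_1" if c.startswith("a") else "ancestry_2" for c in st.states}
        )
        assert oci(st, ann) == 0.0

    def test_unknown_ancestry_rejected(self):
        st, ann = self.worked_example()
        with pytest.raises(ValidationError):
            sci(st, ann, "ancestry_9")

    def test_normal_cells_excluded_from_sci_but_counted_in_oci(self):
        st = make_states({"n1": 1, "n2": 1, "n3": 1, "a1": 2, "a2": 2, "b1": 3, "b2": 3})
        ann = AncestryAnnotation(
            {
                "n1": "normal", "n2": "normal", "n3": "normal",
                "a1": "ancestry_1", "a2": "ancestry_1",
                "b1": "ancestry_2", "b2": "ancestry_2",
            }
        )
        # SCI ignores the all-normal state entirely
        assert sci(st, ann, "ancestry_1") == 1
        # OCI sees 3 states, all unique (one of them to "normal")
        assert oci(st, ann) == pytest.approx(1.0)

    def test_coverage_mode_detects_dispersal(self):
        # ancestry_1 split across two states -> no state covers >80% of it
        st = make_states({"a1": 1, "a2": 1, "a3": 2, "a4": 2, "b1": 3, "b2": 3})
        ann = AncestryAnnotation(
            {c: "ancestry_1" if c.startswith("a") else "ancestry_2" for c in st.states}
        )
        assert sci(st, ann, "ancestry_1", uniqueness_mode=ANCESTRY_COVERAGE) == 0
        assert sci(st, ann, "ancestry_2", uniqueness_mode=ANCESTRY_COVERAGE) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_raising_u_never_increases_indices(self, seed):
        rng = np.random.default_rng(seed)
        cells = [f"c{i:02d}" for i in range(40)]
        st = make_states({c: int(s) for c, s in zip(cells, rng.integers(1, 6, 40))})
        ann = AncestryAnnotation(
            {c: f"ancestry_{int(a)}" for c, a in zip(cells, rng.integers(1, 4, 40))}
        )
        grid = [0.5, 0.6, 0.7, 0.8, 0.9]
        for anc in ann.ancestries:
            vals = [sci(st, ann, anc, u=u) for u in grid]
            assert all(x >= y for x, y in zip(vals, vals[1:]))
        ovals = [oci(st, ann, u=u) for u in grid]
        assert all(x >= y for x, y in zip(ovals, ovals[1:]))

    def test_indices_invariant_to_relabeling_and_order(self):
        st, ann = self.worked_example()
        shuffled = StateAssignment(
            states={c: st.states[c] + 10 for c in reversed(list(st.states))},
            pseudotime=st.pseudotime,
            root_cell=st.root_cell,
            gene_scale=st.gene_scale,
        )
        assert sci(shuffled, ann, "ancestry_3") == sci(st, ann, "ancestry_3")
        assert oci(shuffled, ann) == oci(st, ann)


class TestSweep:
    def test_default_scales_count(self):
        assert len(DEFAULT_SCALES) == 9  # 200..1000 by 100

    def test_sweep_bookkeeping_and_determinism(self):
        _, truth, _, expr = simulate_dataset(
            preset_config("concordant", seed=4, n_genes=400)
        )
        anns = [truth.annotation("t1"), truth.annotation("t2")]
        root = sorted(truth.normal_cells)[0]
        scales = [200, 300, 400]
        r1 = phylo_trajectory_sweep(expr, anns, root, scales=scales)
        r2 = phylo_trajectory_sweep(expr, anns, root, scales=scales)
        assert len(r1.assignments) == 6  # 2 annotations x 3 scales
        assert sorted(set(r1.table["scale"])) == scales
        pd.testing.assert_frame_equal(r1.table, r2.table)
        for key in r1.assignments:
            assert r1.assignments[key].states == r2.assignments[key].states

    def test_scales_truncated_with_warning(self):
        _, truth, _, expr = simulate_dataset(
            preset_config("concordant", seed=5, n_genes=250)
        )
        root = sorted(truth.normal_cells)[0]
        with pytest.warns(UserWarning, match="truncated"):
            report = phylo_trajectory_sweep(
                expr, [truth.annotation()], root, scales=[200, 500, 900]
            )
        assert sorted(set(report.table["scale"])) == [200]

    def test_empty_annotation_list_rejected(self):
        _, truth, _, expr = simulate_dataset(preset_config("concordant", seed=6))
        with pytest.raises(ValidationError):
            phylo_trajectory_sweep(expr, [], "norm00")
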