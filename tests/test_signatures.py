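"""Compartment rule, marker statistics, signature fractions and transition calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from drivereg import (MarkerConfig, VelocityDataset, annotate_compartments,
                      coexpression_transition, find_markers, signature_scores)


def _dataset(counts, genes):
    counts = np.asarray(counts)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])])
    return VelocityDataset(sp.csr_matrix(counts), sp.csr_matrix(counts),
                           pd.Index(genes), obs)


MARKERS = MarkerConfig(ligand_marker="Lig", myogenic_genes=("MyoA", "MyoB"))


class TestAnnotateCompartments:
    @pytest.mark.parametrize("lig,myoa,myob,expected", [
        (0, 0, 0, "non-myogenic"),
        (0, 0, 3, "myogenic"),      # myogenic gene rescues the label
        (5, 0, 0, "myogenic"),
        (1, 2, 0, "myogenic"),
    ])
    def test_marker_rule(self, lig, myoa, myob, expected):
        ds = _dataset([[lig, myoa, myob, 7]], ["Lig", "MyoA", "MyoB", "other"])
        assert annotate_compartments(ds, MARKERS).iloc[0] == expected

    def test_missing_marker_named(self):
        ds = _dataset([[1]], ["other"])
        with pytest.raises(KeyError, match="Lig"):
            annotate_compartments(ds, MARKERS)


class TestFindMarkers:
    def test_group_exclusive_gene_ranks_first(self, rng):
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=[f"c{i}" for i in range(10)])
        expr = pd.DataFrame(rng.uniform(0, 0.2, (10, 4)),
                            index=labels.index, columns=list("wxyz"))
        expr.loc[labels == "a", "w"] = 5.0
        out = find_markers(expr, labels, "a", n_top=4)
        assert out.index[0] == "w"

    def test_identical_gene_excluded(self):
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"c{i}" for i in range(8)])
        expr = pd.DataFrame({"same": np.ones(8), "up": [2.0] * 4 + [0.0] * 4},
                            index=labels.index)
        out = find_markers(expr, labels, "a", n_top=5)
        assert "same" not in out.index

    def test_pvalues_match_exact_permutation_oracle(self, rng):
        # 8 cells, 4 vs 4: exhaustively enumerate group assignments and
        # compare the rank-sum tail probability with the reported p-value
        x = rng.normal(size=8).round(2)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"c{i}" for i in range(8)])
        expr = pd.DataFrame({"g": x + np.where(labels == "a", 1.5, 0.0)},
                            index=labels.index)
        vals = expr["g"].to_numpy()
        ranks = pd.Series(vals).rank().to_numpy()
        obs = ranks[:4].sum()
        stats = [sum(ranks[list(c)]) for c in itertools.combinations(range(8), 4)]
        mean = np.mean(stats)
        p_exact = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats])
        out = find_markers(expr, labels, "a", n_top=1)
        if len(out):  # positive fold change required for inclusion
            assert out["p_value"].iloc[0] == pytest.approx(p_exact, abs=0.06)

    def test_degenerate_group_sizes_rejected(self):
        labels = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        expr = pd.DataFrame({"g": [1.0, 2, 3, 4]}, index=labels.index)
        with pytest.raises(ValueError):
            find_markers(expr, labels, "a")


class TestSignatureScores:
    def test_exclusive_expression_gives_unit_fraction(self):
        expr = pd.DataFrame({"m1": [2.0], "m2": [1.0], "n1": [0.0]}, index=["c"])
        res = signature_scores(expr, ["m1", "m2"], ["n1"])
        assert res.scores.loc["c", "s_m"] == 1.0
        assert res.scores.loc["c", "s_n"] == 0.0
        assert res.scores.loc["c", "coexpression"] == 0.0

    def test_balanced_expression_gives_half_half(self):
        expr = pd.DataFrame({"m": [3.0], "n": [3.0]}, index=["c"])
        res = signature_scores(expr, ["m"], ["n"])
        assert res.scores.loc["c", "s_m"] == 0.5
        assert res.scores.loc["c", "coexpression"] == 0.25

    def test_four_cell_hand_computation(self):
        expr = pd.DataFrame({"m1": [1.0, 0, 2, 0], "m2": [1.0, 0, 0, 0],
                             "n1": [0.0, 4, 2, 0]},
                            index=["c1", "c2", "c3", "c4"])
        res = signature_scores(expr, ["m1", "m2"], ["n1"])
        np.testing.assert_allclose(res.scores["s_m"].iloc[:3], [1.0, 0.0, 0.5])
        assert np.isnan(res.scores["s_m"].iloc[3])  # silent cell flagged missing

    def test_overlapping_sets_rejected(self, toy_expr):
        with pytest.raises(ValueError, match="overlap"):
            signature_scores(toy_expr, ["gA", "gB"], ["gB"])

    def test_fractions_sum_to_one(self, toy_expr):
        res = signature_scores(toy_expr, ["gA"], ["gB", "gC"])
        sums = (res.scores["s_m"] + res.scores["s_n"]).dropna()
        np.testing.assert_allclose(sums, 1.0)


class TestCoexpressionTransition:
    def _result(self, s_m):
        expr = pd.DataFrame({"m": s_m, "n": 1 - np.asarray(s_m)},
                            index=[f"c{i}" for i in range(len(s_m))])
        return signature_scores(expr, ["m"], ["n"])

    def test_maximal_coexpression_is_transition(self):
        res = coexpression_transition(self._result([0.5]))
        assert res.scores["transition"].iloc[0]
        assert res.scores["coexpression"].iloc[0] == 0.25

    def test_pure_cell_is_not_transition(self):
        res = coexpression_transition(self._result([1.0]))
        assert not res.scores["transition"].iloc[0]

    def test_boundary_exactly_at_threshold_excluded(self):
        # f(1-f) = 0.20 at f = (1 - sqrt(1 - 0.8)) / 2
        f = (1 - np.sqrt(1 - 4 * 0.20)) / 2
        assert f * (1 - f) == pytest.approx(0.20, abs=1e-12)
        res = coexpression_transition(self._result([f]))
        assert res.scores["coexpression"].iloc[0] == pytest.approx(0.20, abs=1e-12)
        assert not res.scores["transition"].iloc[0]  # strict inequality

    def test_ordering_by_nonmyogenic_fraction(self):
        res = coexpression_transition(self._result([0.9, 0.1, 0.5]))
        assert list(res.scores.sort_values("order_rank").index) == ["c0", "c2", "c1"]

    def test_unreachable_threshold_warns(self):
        with pytest.warns(UserWarning):
            coexpression_transition(self._result([0.5]), threshold=0.3)

    @settings(max_examples=60, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 0.25))
    def test_score_bounds_and_threshold_monotonicity(self, f, thr):
        res = coexpression_transition(self._result([f]), threshold=thr)
        c = res.scores["coexpression"].iloc[0]
        assert 0.0 <= c <= 0.25
        # symmetric in (s_m, s_n)
        res_swap = coexpression_transition(self._result([1 - f]), threshold=thr)
        assert res_swap.scores["coexpression"].iloc[0] == pytest.approx(c, abs=1e-12)
        # raising the threshold never adds cells
        stricter = coexpression_transition(self._result([f]), threshold=min(thr + 0.02, 0.25))
        assert not (stricter.scores["transition"].iloc[0]
                    and not res.scores["transition"].iloc[0])


class TestBenchmarkRecovery:
    def test_transition_cells_concentrate_at_switch(self, default_benchmark):
        from drivereg import filter_cells, normalize_log
        ds, truth = default_benchmark
        kept = filter_cells(ds)
        expr = normalize_log(kept)
        res = signature_scores(expr, truth.signature_genes_myo,
                               truth.signature_genes_nonmyo)
        res = coexpression_transition(res)
        flag = res.scores["transition"].astype(bool)
        offset = (truth.t.reindex(expr.index) - truth.t_switch).abs()
        assert offset[flag].median() < offset[~flag].median()
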