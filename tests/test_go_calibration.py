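import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrnet import MRNetError
from mrnet.correlation_core import CorrelationMatrix, MRMatrix
from mrnet.go_calibration import (
    PairLabels,
    PriorGeneSets,
    auc_trapezoid,
    classifier_rates,
    label_gene_pairs,
    select_mr_threshold,
    select_prior_sets,
    single_point_auc,
)
from mrnet.io_formats import GOAnnotationTable


def go_table(rows):
    return GOAnnotationTable(
        records=pd.DataFrame(rows, columns=["gene_id", "go_term", "namespace"])
    )


def make_matrices(genes, pcc, mr):
    c = CorrelationMatrix(values=pd.DataFrame(pcc, index=genes, columns=genes))
    m = MRMatrix(
        values=pd.DataFrame(mr, index=genes, columns=genes), direction="descending_pcc"
    )
    return c, m


class TestPriorSelection:
    def test_size_bounds_inclusive(self):
        rows = [(f"a{i}", "GO:0000001", "BP") for i in range(3)]
        rows += [(f"b{i}", "GO:0000002", "BP") for i in range(4)]
        priors = select_prior_sets(go_table(rows), [r[0] for r in rows])
        assert set(priors.sets) == {"GO:0000002"}  # 3 genes excluded, 4 included

    def test_counting_oracle_over_term_size_sweep(self):
        # terms of sizes 1..50: exactly those of size 4..20 survive -> 17
        rows = []
        for size in range(1, 51):
            term = f"GO:{size:07d}"
            rows += [(f"g{size}_{i}", term, "BP") for i in range(size)]
        universe = [r[0] for r in rows]
        priors = select_prior_sets(go_table(rows), universe)
        assert len(priors) == 17

    def test_universe_intersection_counts(self):
        # term has 5 genes but only 3 inside the expression universe
        rows = [(f"g{i}", "GO:0000001", "BP") for i in range(5)]
        with pytest.raises(MRNetError, match="no GO term"):
            select_prior_sets(go_table(rows), ["g0", "g1", "g2"])

    def test_non_bp_namespaces_ignored_by_default(self):
        rows = [(f"g{i}", "GO:0000001", "MF") for i in range(5)]
        with pytest.raises(MRNetError):
            select_prior_sets(go_table(rows), [r[0] for r in rows])


class TestPairLabels:
    def test_co_annotated_pair_positive(self):
        priors = PriorGeneSets(
            sets={"GO:0000001": frozenset({"a", "b"}) | frozenset({"c", "d"})},
            universe=("a", "b", "c", "d"),
        )
        labels = label_gene_pairs(priors)
        assert labels.n_positive == 6

    def test_disjoint_terms_enumeration_oracle(self):
        sets = {
            "GO:0000001": frozenset(f"a{i}" for i in range(4)),
            "GO:0000002": frozenset(f"b{i}" for i in range(4)),
        }
        universe = tuple(sorted(set().union(*sets.values())))
        labels = label_gene_pairs(PriorGeneSets(sets=sets, universe=universe))
        assert labels.n_positive == 12  # 2 * C(4,2)
        assert labels.n_negative == 16  # C(8,2) - 12

    def test_removing_a_term_never_adds_positives(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        sets = {
            f"GO:{t:07d}": frozenset(rng.choice(genes, size=5, replace=False))
            for t in range(1, 5)
        }
        full = label_gene_pairs(
            PriorGeneSets(sets=sets, universe=tuple(genes))
        ).n_positive
        for t in sets:
            reduced = {k: v for k, v in sets.items() if k != t}
            n = label_gene_pairs(
                PriorGeneSets(sets=reduced, universe=tuple(genes))
            ).n_positive
            assert n <= full

    def test_tiny_universe_rejected(self):
        priors = PriorGeneSets(
            sets={"GO:0000001": frozenset({"a", "b"})}, universe=("a", "b")
        )
        with pytest.raises(MRNetError, match="universe"):
            label_gene_pairs(priors)


class TestClassifierRates:
    def _toy(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        rng = np.random.default_rng(17)
        pcc = rng.uniform(-1, 1, size=(6, 6))
        pcc = (pcc + pcc.T) / 2
        np.fill_diagonal(pcc, 1.0)
        mr = rng.uniform(1, 5, size=(6, 6))
        mr = np.sqrt(mr * mr.T)
        np.fill_diagonal(mr, np.nan)
        co = np.zeros((6, 6), dtype=bool)
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4)]:
            co[i, j] = co[j, i] = True
        labels = PairLabels(genes=tuple(genes), co_annotated=co)
        return (*make_matrices(genes, pcc, mr), labels)

    def test_rates_match_exhaustive_enumeration(self):
        corr, mrm, labels = self._toy()
        pcc_cut, mr_cut = 0.1, 3.0
        tp = fp = pos = neg = 0
        for i, j in itertools.combinations(range(6), 2):
            predicted = (
                corr.values.iloc[i, j] > pcc_cut and mrm.values.iloc[i, j] < mr_cut
            )
            if labels.co_annotated[i, j]:
                pos += 1
                tp += predicted
            else:
                neg += 1
                fp += predicted
        tpr, fpr = classifier_rates(mrm, corr, labels, pcc_cut, mr_cut, "positive")
        assert tpr == pytest.approx(tp / pos)
        assert fpr == pytest.approx(fp / neg)

    def test_empty_prediction_gives_zero_rates(self):
        corr, mrm, labels = self._toy()
        assert classifier_rates(mrm, corr, labels, 0.0, 0.5, "positive") == (0.0, 0.0)

    def test_predict_all_gives_unit_rates(self):
        corr, mrm, labels = self._toy()
        tpr, fpr = classifier_rates(mrm, corr, labels, -1.0, 1e9, "positive")
        assert (tpr, fpr) == (1.0, 1.0)

    def test_rates_monotone_in_mr_cutoff(self):
        corr, mrm, labels = self._toy()
        prev = (0.0, 0.0)
        for cut in np.linspace(0.5, 6, 12):
            tpr, fpr = classifier_rates(mrm, corr, labels, 0.1, cut, "positive")
            assert tpr >= prev[0] and fpr >= prev[1]
            prev = (tpr, fpr)


class TestAuc:
    def test_single_point_formula(self):
        assert single_point_auc(0.8, 0.2) == pytest.approx(0.8)
        assert single_point_auc(1.0, 0.0) == 1.0
        for t in (0.0, 0.3, 1.0):
            assert single_point_auc(t, t) == pytest.approx(0.5)

    def test_single_point_rejects_out_of_range(self):
        with pytest.raises(MRNetError):
            single_point_auc(1.2, 0.0)

    @given(
        st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_single_point_bounds_and_antisymmetry(self, tpr, fpr):
        auc = single_point_auc(tpr, fpr)
        assert 0.0 <= auc <= 1.0
        # swapping the operating point across the diagonal mirrors the area
        assert single_point_auc(fpr, tpr) == pytest.approx(1.0 - auc)

    def test_trapezoid_diagonal_and_hand_sum(self):
        assert auc_trapezoid([(0, 0), (1, 1)]) == pytest.approx(0.5)
        # 0.5*0.2*0.8 + 0.5*(0.8+1)*0.8 = 0.08 + 0.72
        assert auc_trapezoid([(0, 0), (0.2, 0.8), (1, 1)]) == pytest.approx(0.8)

    def test_decreasing_fpr_rejected(self):
        with pytest.raises(MRNetError, match="non-decreasing"):
            auc_trapezoid([(0, 0), (0.5, 0.5), (0.2, 0.9), (1, 1)])

    def test_matches_mann_whitney_pair_counting(self):
        # ROC from all cutoffs of a finite score set (low score = linked)
        rng = np.random.default_rng(31)
        for _ in range(20):
            n_pos, n_neg = rng.integers(3, 30, size=2)
            pos = rng.integers(1, 15, size=n_pos).astype(float)
            neg = rng.integers(1, 15, size=n_neg).astype(float)
            cuts = np.unique(np.concatenate([pos, neg, [np.inf]]))
            points = [
                ((neg < c).mean(), (pos < c).mean()) for c in np.append(cuts, np.inf)
            ]
            auc = auc_trapezoid(points)
            wins = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc == pytest.approx(wins / (n_pos * n_neg), abs=1e-9)


class TestThresholdSelection:
    def test_separable_case_picks_smallest_perfect_cutoff(self):
        genes = [f"g{i}" for i in range(6)]
        pcc = np.full((6, 6), 0.9)
        np.fill_diagonal(pcc, 1.0)
        mr = np.full((6, 6), 60.0)
        co = np.zeros((6, 6), dtype=bool)
        for i, j in [(0, 1), (2, 3)]:
            mr[i, j] = mr[j, i] = 5.0
            co[i, j] = co[j, i] = True
        np.fill_diagonal(mr, np.nan)
        corr, mrm = make_matrices(genes, pcc, mr)
        labels = PairLabels(genes=tuple(genes), co_annotated=co)
        res = select_mr_threshold(
            mrm, corr, labels, 0.7, mr_grid=range(10, 110, 10), sign="positive"
        )
        assert res.selected_mr_cutoff == 10
        assert res.selected_auc == 1.0
        assert res.curve_auc == pytest.approx(1.0)

    def test_calibration_deterministic(self, default_sim, default_matrices):
        from mrnet import label_gene_pairs, select_prior_sets, simulate_go

        cfg, expr, truth = default_sim
        corr, mrm = default_matrices
        labels = label_gene_pairs(
            select_prior_sets(simulate_go(truth, cfg), expr.gene_ids)
        )
        a = select_mr_threshold(mrm, corr, labels)
        b = select_mr_threshold(mrm, corr, labels)
        assert a == b

    def test_shuffled_labels_give_chance_auc(self):
        # permutation null: mean single-point AUC ~ 0.5 at every cutoff
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(40)]
        pcc = rng.uniform(-1, 1, size=(40, 40))
        pcc = (pcc + pcc.T) / 2
        np.fill_diagonal(pcc, 1.0)
        mr = rng.uniform(1, 39, size=(40, 40))
        mr = np.sqrt(mr * mr.T)
        np.fill_diagonal(mr, np.nan)
        corr, mrm = make_matrices(genes, pcc, mr)
        iu = np.triu_indices(40, k=1)
        pred = {}
        grid = range(5, 45, 5)
        P = pcc[iu]
        M = mr[iu]
        for cut in grid:
            pred[cut] = (P > 0.0) & (M < cut)
        y = np.zeros(len(P), dtype=bool)
        y[: len(P) // 4] = True
        n_pos = y.sum()
        n_neg = y.size - n_pos
        sums = {cut: 0.0 for cut in grid}
        n_shuffles = 300
        for _ in range(n_shuffles):
            ys = rng.permutation(y)
            for cut in grid:
                tpr = (pred[cut] & ys).sum() / n_pos
                fpr = (pred[cut] & ~ys).sum() / n_neg
                sums[cut] += (1 + tpr - fpr) / 2
        for cut in grid:
            assert sums[cut] / n_shuffles == pytest.approx(0.5, abs=0.02)
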