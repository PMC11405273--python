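"""Feature-selection stage: split rules, smoothed-bootstrap rebalancing,
subsampled L1 scoring and top-k sparsification."""

import numpy as np
import pandas as pd
import pytest

from protrisk import (
    CohortConfig,
    OutcomeTable,
    SelectionConfig,
    SelectionScoreTable,
    generate_cohort,
    make_splits,
    rank_top_k,
    smoothed_bootstrap_rebalance,
    sparsify_by_weight_product,
    subsampled_selection,
)
from protrisk.selection import _one_selection_iteration, _rose_bandwidth, binary_label_at_horizon


def _outcomes(n_cases: int, n_total: int) -> OutcomeTable:
    table = pd.DataFrame(
        {
            "time_years": [5.0] * n_cases + [10.0] * (n_total - n_cases),
            "event": [1] * n_cases + [0] * (n_total - n_cases),
            "prevalent": [0] * n_total,
        },
        index=pd.Index([f"S{i}" for i in range(n_total)], name="sample_id"),
    )
    return OutcomeTable(table, horizon_years=10.0)


class TestMakeSplits:
    def test_three_way_above_800_cases(self):
        splits = make_splits(_outcomes(900, 10_000), seed=0)
        assert splits.rule == "three_way"
        parts = [splits.selection_ids, splits.optimization_ids, splits.validation_ids]
        all_ids = pd.Index([]).append(parts)
        assert len(all_ids) == 10_000 and not all_ids.has_duplicates
        assert abs(len(parts[0]) - 5000) <= 2
        assert abs(len(parts[1]) - 2500) <= 2
        # case-stratified: each part's case count near its share
        assert abs(sum(i.startswith("S") and int(i[1:]) < 900 for i in parts[0]) - 450) <= 1

    def test_two_way_at_or_below_800_cases(self):
        splits = make_splits(_outcomes(400, 5000), seed=0)
        assert splits.rule == "two_way"
        assert len(splits.optimization_ids) == 0
        assert abs(len(splits.selection_ids) - 3500) <= 2
        assert splits.training_ids.equals(splits.selection_ids)

    def test_same_seed_reproduces_partition(self):
        a = make_splits(_outcomes(900, 3000), seed=5)
        b = make_splits(_outcomes(900, 3000), seed=5)
        assert a.selection_ids.equals(b.selection_ids)
        assert a.validation_ids.equals(b.validation_ids)

    def test_below_case_floor_rejected(self):
        with pytest.raises(ValueError, match="80"):
            make_splits(_outcomes(79, 2000), seed=0)


class TestRebalance:
    def test_degenerate_kernel_copies_input_rows(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4))
        y = (rng.random(50) < 0.2).astype(int)
        Xb, yb = smoothed_bootstrap_rebalance(X, y, p=0.5, n_out=200, kernel_shrink=0.0, seed=1)
        rows = {tuple(r) for r in X}
        assert all(tuple(r) in rows for r in Xb)
        # and each synthetic row carries its seed row's label
        for r, lab in zip(Xb, yb):
            k = np.flatnonzero((X == r).all(axis=1))[0]
            assert y[k] == lab

    def test_output_class_fraction_near_target(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 3))
        y = (rng.random(300) < 0.1).astype(int)
        _, yb = smoothed_bootstrap_rebalance(X, y, p=0.5, n_out=10_000, seed=2)
        se = np.sqrt(0.25 / 10_000)
        assert abs(yb.mean() - 0.5) <= 3 * se

    def test_kernel_inflates_variance_by_bandwidth(self):
        """Convolving the class empirical law with a N(0, h^2) kernel gives
        output variance sigma^2 + h^2."""
        rng = np.random.default_rng(2)
        sigma, n_class, d = 2.0, 100, 1
        X = np.concatenate([rng.normal(0, sigma, n_class), rng.normal(0, sigma, n_class)])[:, None]
        y = np.r_[np.zeros(n_class), np.ones(n_class)].astype(int)
        h = _rose_bandwidth(X[y == 1].std(ddof=1, axis=0), n_class, d, 1.0)[0]
        Xb, yb = smoothed_bootstrap_rebalance(X, y, p=0.5, n_out=200_000, kernel_shrink=1.0, seed=3)
        observed = Xb[yb == 1, 0].var()
        expected = X[y == 1, 0].var() + h**2
        assert abs(observed - expected) / expected < 0.10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            smoothed_bootstrap_rebalance(np.zeros((5, 2)), np.zeros(5, int), seed=0)


@pytest.fixture(scope="module")
def selection_cohort():
    cfg = CohortConfig(n_samples=900, n_assays=60, n_panels=2, block_size=10,
                       block_rho=0.3, causal_assays=(5,), beta_protein=(1.5,),
                       target_case_count=150, seed=13)
    return generate_cohort(cfg)


def _quick_config(n_iterations: int, seed: int, **kw) -> SelectionConfig:
    base = dict(n_iterations=n_iterations, cv_folds=3, cv_repeats=1, n_lambda=10,
                lambda_min_ratio=0.05, rebalance_size=400, seed=seed)
    base.update(kw)
    return SelectionConfig(**base)


class TestSubsampledSelection:
    def test_single_iteration_equals_traced_fit(self, selection_cohort):
        """n_iterations=1 is definitional: the score vector is |beta| of one
        traced subsample-rebalance-CV-refit pass."""
        matrix, _, outcomes, _ = selection_cohort
        cfg = _quick_config(1, 42)
        scores = subsampled_selection(matrix.values, outcomes, cfg)

        labels = binary_label_at_horizon(outcomes)
        ids = labels.index.intersection(matrix.values.index)
        X = matrix.values.loc[ids].to_numpy(float)
        y = labels.loc[ids].to_numpy()
        seed0 = int(np.random.SeedSequence(42).generate_state(1)[0])
        traced = _one_selection_iteration(X, y, cfg, seed0)
        np.testing.assert_allclose(scores.table["score"].to_numpy(), traced, rtol=0, atol=1e-12)
        assert (scores.table["times_selected"] == (traced > 0).astype(int)).all()

    def test_causal_assay_attains_top_score(self, selection_cohort):
        """One strong causal assay among correlated nulls should win the
        selection score in (nearly) every pipeline seed."""
        matrix, _, outcomes, truth = selection_cohort
        wins = 0
        for seed in range(5):
            scores = subsampled_selection(matrix.values, outcomes, _quick_config(8, seed))
            wins += rank_top_k(scores, 1)[0] == truth.causal_assays[0]
        assert wins >= 4

    def test_null_cohort_has_no_stable_winner(self):
        cfg = CohortConfig(n_samples=700, n_assays=50, n_panels=1, block_size=10,
                           block_rho=0.3, target_case_count=120, seed=29)
        matrix, _, outcomes, _ = generate_cohort(cfg)
        winners = set()
        for seed in range(4):
            scores = subsampled_selection(matrix.values, outcomes, _quick_config(3, seed))
            winners.add(rank_top_k(scores, 1)[0])
        assert len(winners) > 1

    def test_scores_invariant_to_column_order(self, selection_cohort):
        """With a degenerate kernel the pipeline's randomness is independent
        of column order, so scores are permutation-equivariant."""
        matrix, _, outcomes, _ = selection_cohort
        cfg = _quick_config(2, 3, kernel_shrink=0.0)
        base = subsampled_selection(matrix.values, outcomes, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.values.shape[1])
        permuted = subsampled_selection(matrix.values.iloc[:, perm], outcomes, cfg)
        merged = base.table.join(permuted.table, lsuffix="_a", rsuffix="_b")
        np.testing.assert_allclose(
            merged["score_a"].to_numpy(), merged["score_b"].to_numpy(), atol=1e-5
        )

    def test_score_monotone_in_true_effect(self):
        """On matched seeds, a larger true |beta| never yields a smaller
        selection score (3-assay toy cohorts)."""
        for seed in (1, 2):
            scores = {}
            for beta in (0.3, 1.2):
                cfg = CohortConfig(n_samples=600, n_assays=3, n_panels=1, block_size=3,
                                   block_rho=0.0, causal_assays=(0,), beta_protein=(beta,),
                                   target_case_count=110, seed=seed)
                matrix, _, outcomes, _ = generate_cohort(cfg)
                tab = subsampled_selection(matrix.values, outcomes, _quick_config(4, seed))
                scores[beta] = tab.table.loc["A0001", "score"]
            assert scores[1.2] >= scores[0.3]


class TestRanking:
    def _scores(self, mapping):
        table = pd.DataFrame(
            {"score": list(mapping.values()), "times_selected": [1] * len(mapping)},
            index=pd.Index(mapping.keys()),
        )
        return SelectionScoreTable(table, n_iterations=10)

    def test_orders_by_score_descending(self):
        assert rank_top_k(self._scores({"A": 10.0, "B": 5.0, "C": 1.0}), 2) == ["A", "B"]

    def test_tie_broken_lexicographically(self):
        assert rank_top_k(self._scores({"B": 3.0, "A": 3.0}), 1) == ["A"]

    def test_requesting_beyond_positive_scores_warns(self):
        table = pd.DataFrame(
            {"score": [2.0, 0.0], "times_selected": [1, 0]}, index=pd.Index(["A", "B"])
        )
        with pytest.warns(UserWarning):
            out = rank_top_k(SelectionScoreTable(table, 10), 5)
        assert out == ["A"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(11)
        mapping = {f"A{i:03d}": float(rng.integers(1, 50)) for i in range(100)}
        got = rank_top_k(self._scores(mapping), 20)
        oracle = sorted(mapping, key=lambda a: (-mapping[a], a))[:20]
        assert got == oracle


class TestSparsifyByProduct:
    class _Model:
        def __init__(self, names, beta, penalized):
            self.feature_names = names
            self.beta = np.asarray(beta, float)
            self.penalized = np.asarray(penalized, bool)

    def _scores(self, mapping):
        table = pd.DataFrame(
            {"score": list(mapping.values()), "times_selected": [1] * len(mapping)},
            index=pd.Index(mapping.keys()),
        )
        return SelectionScoreTable(table, n_iterations=10)

    def test_product_rule_arithmetic(self):
        model = self._Model(["A", "B"], [0.1, 0.4], [True, True])
        out = sparsify_by_weight_product(model, self._scores({"A": 10.0, "B": 5.0}), 1)
        assert out == ["B"]  # products: A 1.0, B 2.0

    def test_zero_weight_never_outranks_positive_product(self):
        model = self._Model(["A", "B"], [0.0, 0.01], [True, True])
        out = sparsify_by_weight_product(model, self._scores({"A": 100.0, "B": 1.0}), 1)
        assert out == ["B"]

    def test_clinical_features_not_ranked(self):
        model = self._Model(["age", "A"], [5.0, 0.2], [False, True])
        out = sparsify_by_weight_product(model, self._scores({"A": 1.0}), 5)
        assert out == ["A"]

    def test_missing_feature_named_in_error(self):
        model = self._Model(["A", "B"], [0.1, 0.2], [True, True])
        with pytest.raises(KeyError, match="B"):
            sparsify_by_weight_product(model, self._scores({"A": 1.0}), 1)

    def test_matches_product_sort_oracle(self):
        rng = np.random.default_rng(12)
        names = [f"A{i:02d}" for i in range(20)]
        beta = rng.uniform(0, 1, 20)
        score = {n: float(rng.integers(1, 30)) for n in names}
        model = self._Model(names, beta, [True] * 20)
        got = sparsify_by_weight_product(model, self._scores(score), 5)
        prod = {n: abs(b) * score[n] for n, b in zip(names, beta)}
        oracle = sorted(names, key=lambda a: (-prod[a], a))[:5]
        assert got == oracle
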