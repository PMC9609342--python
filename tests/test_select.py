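import itertools

import numpy as np
import pytest

from ramanqc.errors import (DataError, EmptySelectionError, ParameterError)
from ramanqc.select import (CarsConfig, SelectionResult, cars_select,
                            compare_selectors, edf_ratio_schedule, sipls_select,
                            spa_select, uve_select)


def sparse_linear(n=80, p=200, informative=(10, 50, 90, 130, 170),
                  noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, p))
    w = np.zeros(p)
    w[list(informative)] = rng.uniform(1.0, 2.0, size=len(informative))
    y = X @ w + noise * rng.standard_normal(n)
    return X, y, list(informative)


class TestEdf:
    def test_endpoints_pinned(self):
        p, runs = 200, 50
        r = edf_ratio_schedule(p, runs)
        assert round(r[0] * p) == p
        assert round(r[-1] * p) == 2

    def test_strictly_decreasing_matches_formula(self):
        import math
        p, runs, end = 311, 40, 2
        r = edf_ratio_schedule(p, runs, end)
        assert np.all(np.diff(r) < 0)
        a = (p / end) ** (1 / (runs - 1))
        k = math.log(p / end) / (runs - 1)
        expected = a * np.exp(-k * np.arange(1, runs + 1))
        np.testing.assert_allclose(r, expected)


class TestCars:
    def test_recovers_informative_channels(self):
        hits = 0
        for seed in range(5):
            X, y, informative = sparse_linear(seed=seed)
            res = cars_select(X, y, CarsConfig(n_runs=30), seed=seed)
            hits += set(informative) <= set(res.selected_indices.tolist())
        assert hits >= 4

    def test_trace_counts_non_increasing(self):
        X, y, _ = sparse_linear(seed=3)
        res = cars_select(X, y, CarsConfig(n_runs=30), seed=3)
        counts = [r["n_variables"] for r in res.trace]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_seeded_determinism(self):
        X, y, _ = sparse_linear(seed=1)
        a = cars_select(X, y, CarsConfig(n_runs=20), seed=5)
        b = cars_select(X, y, CarsConfig(n_runs=20), seed=5)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
        assert [r["rmsecv"] for r in a.trace] == [r["rmsecv"] for r in b.trace]

    def test_null_target_unstable_selection(self, rng):
        X = rng.uniform(size=(60, 120))
        y = rng.standard_normal(60)
        res1 = cars_select(X, y, CarsConfig(n_runs=25), seed=1)
        res2 = cars_select(X, y, CarsConfig(n_runs=25), seed=2)
        assert res1.trace[res1.best_run]["rmsecv"] > 0.5 * y.std()
        s1, s2 = set(res1.selected_indices), set(res2.selected_indices)
        jaccard = len(s1 & s2) / max(1, len(s1 | s2))
        assert jaccard < 0.5

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            CarsConfig(mc_rate=1.5)
        with pytest.raises(ParameterError):
            CarsConfig(n_runs=1)

    def test_best_run_is_minimal_rmsecv(self):
        X, y, _ = sparse_linear(seed=2)
        res = cars_select(X, y, CarsConfig(n_runs=20), seed=2)
        rmse = [r["rmsecv"] for r in res.trace]
        assert res.best_run == int(np.argmin(rmse))
        np.testing.assert_array_equal(
            res.selected_indices,
            np.sort(np.asarray(res.trace[res.best_run]["indices"])))


class TestUve:
    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_informative_kept_junk_removed(self, seed):
        X, y, informative = sparse_linear(n=60, p=80,
                                          informative=(5, 25, 45, 60, 70),
                                          noise=0.02, seed=seed)
        res = uve_select(X, y, seed=seed)
        selected = set(res.selected_indices.tolist())
        assert set(informative) <= selected
        junk = set(range(80)) - set(informative)
        assert len(junk & selected) <= 0.1 * len(junk)

    def test_pure_noise_empty(self, rng):
        X = rng.uniform(size=(40, 30))
        y = rng.standard_normal(40)
        with pytest.raises(EmptySelectionError):
            uve_select(X, y, seed=0)

    def test_n_noise_validation(self, rng):
        X = rng.uniform(size=(20, 10))
        y = X[:, 0]
        with pytest.raises(ParameterError):
            uve_select(X, y, n_noise=5)

    def test_cutoff_definition(self):
        X, y, _ = sparse_linear(n=50, p=40, informative=(3, 20), seed=7)
        res = uve_select(X, y, seed=7)
        cutoff = res.trace[0]["cutoff"]
        stability = res.trace[0]["stability"]
        expected = np.nonzero(np.abs(stability) > cutoff)[0]
        np.testing.assert_array_equal(res.selected_indices, expected)


class TestSpa:
    def test_collinear_channels_never_both(self, rng):
        base = rng.uniform(size=(40, 6))
        X = np.hstack([base, 2.0 * base[:, :1]])  # channel 6 == 2x channel 0
        y = base @ rng.uniform(0.5, 1.5, size=6)
        res = spa_select(X, y, max_vars=5, seed=0)
        assert not {0, 6} <= set(res.selected_indices.tolist())

    def test_zero_variance_excluded_with_warning(self, rng):
        X = rng.uniform(size=(30, 8))
        X[:, 3] = 1.0
        y = X[:, 0] + X[:, 5]
        with pytest.warns(UserWarning, match="zero-variance"):
            res = spa_select(X, y, max_vars=4, seed=0)
        assert 3 not in res.selected_indices

    def test_chain_matches_brute_force_projection(self, rng):
        """Greedy chain = brute-force argmax of projected norms, step by step."""
        from ramanqc.select import _spa_chain
        X = rng.normal(size=(20, 7))
        Xc = X - X.mean(axis=0)
        chain = _spa_chain(Xc, start=2, max_vars=3)
        # brute force with explicit Gram-Schmidt
        sel = [2]
        for _ in range(2):
            best_norm, best_j = -1.0, None
            for j in range(7):
                if j in sel:
                    continue
                v = Xc[:, j].copy()
                basis = np.linalg.qr(Xc[:, sel])[0]
                v = v - basis @ (basis.T @ v)
                if v @ v > best_norm:
                    best_norm, best_j = v @ v, j
            sel.append(best_j)
        assert chain == sel

    def test_selected_beats_full_spectrum(self):
        # near-square design: full-spectrum least squares overfits
        X, y, _ = sparse_linear(n=45, p=40, informative=(5, 25, 35),
                                noise=0.02, seed=9)
        Xv, yv, _ = sparse_linear(n=30, p=40, informative=(5, 25, 35),
                                  noise=0.02, seed=109)
        res = spa_select(X, y, max_vars=10, seed=9)
        idx = res.selected_indices

        def ols_rmse(cols):
            A = np.hstack([np.ones((45, 1)), X[:, cols]])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            pred = np.hstack([np.ones((30, 1)), Xv[:, cols]]) @ coef
            return np.sqrt(np.mean((pred - yv) ** 2))

        assert ols_rmse(idx) <= ols_rmse(np.arange(40)) + 1e-2

    def test_max_vars_validation(self, rng):
        X = rng.uniform(size=(10, 5))
        with pytest.raises(ParameterError):
            spa_select(X, X[:, 0], max_vars=5)


class TestSipls:
    def test_single_interval_returns_everything(self, rng):
        X = rng.uniform(size=(30, 24))
        y = X[:, 3]
        res = sipls_select(X, y, n_intervals=1)
        np.testing.assert_array_equal(res.selected_indices, np.arange(24))

    def test_informative_interval_wins(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(50, 40))
            y = X[:, 12] + X[:, 14] + 0.01 * rng.standard_normal(50)  # interval 3
            res = sipls_select(X, y, n_intervals=10, combo_sizes=(2,),
                               folds=4, seed=seed)
            wins += 3 in res.trace[res.best_run]["combo"]
        assert wins >= 4

    def test_flat_scores_tie_break_lowest_combo(self, rng):
        X = np.full((20, 12), 0.5)
        y = rng.standard_normal(20)
        res = sipls_select(X, y, n_intervals=4, combo_sizes=(2,), folds=4)
        assert res.trace[res.best_run]["combo"] == (0, 1)

    def test_budget_guard(self, rng):
        X = rng.uniform(size=(30, 64))
        y = X[:, 0]
        with pytest.raises(ParameterError, match="budget"):
            sipls_select(X, y, n_intervals=60, combo_sizes=(4,), max_combos=100)


class TestCompareSelectors:
    def test_duplicate_method_identical_rows(self):
        X, y, _ = sparse_linear(n=60, p=50, informative=(4, 24, 44), seed=6)
        Xv, yv, _ = sparse_linear(n=30, p=50, informative=(4, 24, 44), seed=16)
        table = compare_selectors(X, y, Xv, yv, methods=("spa", "spa"), seed=1)
        assert len(table) == 2
        assert table.iloc[0].equals(table.iloc[1])

    def test_requires_two_methods(self, rng):
        X = rng.uniform(size=(30, 20))
        with pytest.raises(ParameterError):
            compare_selectors(X, X[:, 0], X, X[:, 0], methods=("cars",))

    def test_selectors_beat_random_subset(self):
        X, y, informative = sparse_linear(n=80, p=60,
                                          informative=(5, 25, 45), noise=0.02,
                                          seed=2)
        Xv, yv, _ = sparse_linear(n=40, p=60, informative=(5, 25, 45),
                                  noise=0.02, seed=12)
        table = compare_selectors(X, y, Xv, yv,
                                  methods=("cars", "spa", "sipls"), seed=2)
        from ramanqc._pls import pls_fit_predictor
        from ramanqc.evaluate import rmse
        rng = np.random.default_rng(0)
        for _, row in table.iterrows():
            idx = rng.choice(60, size=max(2, int(row.n_selected)), replace=False)
            predict, _ = pls_fit_predictor(X[:, idx], y, min(10, len(idx)))
            random_rmsep = rmse(yv, predict(Xv[:, idx]))
            assert row.rmsep <= random_rmsep + 1e-9


class TestSelectionResult:
    def test_sorted_unique(self):
        res = SelectionResult(np.array([5, 1, 3]), "x")
        np.testing.assert_array_equal(res.selected_indices, [1, 3, 5])

    def test_empty_rejected(self):
        with pytest.raises(EmptySelectionError):
            SelectionResult(np.array([], dtype=int), "x")

    def test_duplicates_rejected(self):
        with pytest.raises(ParameterError):
            SelectionResult(np.array([1, 1, 2]), "x")

    def test_json_round_trip(self):
        import json
        res = SelectionResult(np.array([2, 0]), "cars",
                              trace=[{"run": 1, "n_variables": 2,
                                      "rmsecv": 0.5,
                                      "indices": np.array([0, 2])}],
                              best_run=0)
        payload = json.dumps(res.to_dict())
        assert json.loads(payload)["selected_indices"] == [0, 2]
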