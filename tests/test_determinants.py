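import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circarest import determinants as det


class TestPairwiseCorrelations:
    def test_perfect_monotone_pair(self):
        tab = pd.DataFrame({"io": [1, 2, 3, 4, 5, 6],
                            "x": [2.0, 4.1, 4.2, 9.0, 30.0, 31.0]})
        out = det.pairwise_correlations(tab, "io")
        assert out.loc[out.predictor == "x", "r"].iloc[0] == pytest.approx(1.0)

    def test_constant_predictor_flagged(self):
        tab = pd.DataFrame({"io": [1, 2, 3, 4, 5], "x": [7.0] * 5})
        out = det.pairwise_correlations(tab, "io")
        row = out.loc[out.predictor == "x"].iloc[0]
        assert np.isnan(row.r) and row.flag == "constant predictor"

    def test_matches_rank_then_pearson(self, rng):
        y = rng.normal(0, 1, 30)
        x = rng.normal(0, 1, 30)
        x[rng.integers(0, 30, 4)] = x[0]  # inject ties
        tab = pd.DataFrame({"io": y, "x": x})
        out = det.pairwise_correlations(tab, "io")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.loc[out.predictor == "x", "r"].iloc[0] == \
            pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_deletion(self):
        tab = pd.DataFrame({"io": [1, 2, 3, 4, 5, 6],
                            "x": [1, 2, np.nan, 4, 5, 6],
                            "z": [6, 5, 4, 3, 2, 1]})
        out = det.pairwise_correlations(tab, "io")
        assert out.loc[out.predictor == "x", "n"].iloc[0] == 5
        assert out.loc[out.predictor == "z", "n"].iloc[0] == 6


class TestGroupCompare:
    def test_welch_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = det.group_compare(a, a.copy(), "welch")
        assert out["p"] == pytest.approx(1.0)

    def test_welch_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2, 9)
        out = det.group_compare(a, b, "welch")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert out["statistic"] == pytest.approx(t)
        assert out["p"] == pytest.approx(p)

    def test_fisher_printed_contrasts(self):
        # physiologic temperature rhythm: 9/12 high vs 2/12 low
        _, p = det.fisher_exact_2x2([[9, 3], [2, 10]])
        assert round(p, 4) == 0.0123
        # daily exercise: 10/11 high vs 2/13 low
        _, p = det.fisher_exact_2x2([[10, 1], [2, 11]])
        assert round(p, 3) == 0.001

    def test_fisher_conventions_differ_where_expected(self):
        t = [[13, 12], [4, 29]]
        _, p_mass = det.fisher_exact_2x2(t, two_sided="mass-sum")
        _, p_dbl = det.fisher_exact_2x2(t, two_sided="doubling")
        assert p_mass == pytest.approx(0.001363, abs=5e-7)
        assert p_dbl == pytest.approx(2 * stats.fisher_exact(
            t, alternative="greater")[1])

    def test_fisher_invariant_to_transpose_and_row_swap(self):
        t = np.array([[9, 3], [2, 10]])
        _, p = det.fisher_exact_2x2(t)
        _, pt = det.fisher_exact_2x2(t.T)
        _, pr = det.fisher_exact_2x2(t[::-1])
        assert p == pytest.approx(pt) == pytest.approx(pr)

    def test_fisher_rejects_non_integer_table(self):
        with pytest.raises(det.DeterminantsError):
            det.fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestSelectModel:
    def _table(self, rng, n=60, decoys=8):
        amp = np.maximum(rng.normal(150, 60, n), 10)
        sd = np.abs(rng.normal(1.2, 0.8, n))
        cols = {"amp": amp, "sd": sd}
        for j in range(decoys):
            cols[f"d{j}"] = rng.normal(0, 1, n)
        cols["io"] = 0.1584 * amp - 2.6695 * sd + rng.normal(0, 5.0, n)
        return pd.DataFrame(cols)

    def test_true_predictors_selected(self, rng):
        hits = 0
        for i in range(10):
            tab = self._table(np.random.default_rng(500 + i))
            res = det.select_model(tab, "io", [c for c in tab if c != "io"])
            hits += {"amp", "sd"} <= set(res.predictors)
        assert hits >= 8

    def test_noiseless_intercept_free_fit_recovers_coefficients(self, rng):
        tab = self._table(rng)
        tab["io"] = 0.1584 * tab["amp"] - 2.6695 * tab["sd"]
        res = det.select_model(tab, "io", ["amp", "sd"],
                               include_intercept=False, max_predictors=2)
        assert res.predictors == ("amp", "sd")
        assert res.coefficients["amp"] == pytest.approx(0.1584, abs=1e-8)
        assert res.coefficients["sd"] == pytest.approx(-2.6695, abs=1e-8)

    def test_pure_noise_single_candidate_selects_null_model(self, rng):
        tab = pd.DataFrame({"io": rng.normal(0, 1, 40),
                            "x": rng.normal(0, 1, 40)})
        res = det.select_model(tab, "io", ["x"])
        assert res.predictors == ()

    def test_matches_hand_enumeration_of_all_subsets(self, rng):
        tab = self._table(rng, n=40, decoys=1)
        cands = ["amp", "sd", "d0"]
        res = det.select_model(tab, "io", cands, max_predictors=3)
        # independent enumeration of all 8 subsets
        y = tab["io"].to_numpy()
        n = len(y)
        best = None
        for size in range(4):
            for subset in itertools.combinations(cands, size):
                X = np.column_stack(
                    [np.ones(n)] + [tab[c].to_numpy() for c in subset])
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(((y - X @ coef) ** 2).sum())
                k = X.shape[1] + 1
                ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
                aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
                if best is None or aicc < best[0]:
                    best = (aicc, subset)
        assert res.predictors == best[1]
        assert res.aicc == pytest.approx(best[0])
        assert len(res.ranked) == 8

    def test_listwise_deletion_counts_dropped_rows(self, rng):
        tab = self._table(rng, n=40, decoys=1)
        tab.loc[3, "amp"] = np.nan
        tab.loc[7, "d0"] = np.nan
        res = det.select_model(tab, "io", ["amp", "sd", "d0"])
        assert res.n == 38 and res.n_dropped_rows == 2

    def test_aicc_approaches_aic_for_large_n(self, rng):
        n = 100_000
        k = 5 + 1 + 1  # 5 slopes + intercept + error variance
        correction = 2 * k * (k + 1) / (n - k - 1)
        assert correction < 0.01

    def test_insufficient_rows_rejected(self, rng):
        tab = self._table(rng, n=6, decoys=1)
        with pytest.raises(det.DeterminantsError):
            det.select_model(tab, "io", ["amp", "sd", "d0"],
                             max_predictors=4)
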