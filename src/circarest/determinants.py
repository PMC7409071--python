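"""Group statistics and the determinant analysis of the rest-activity
circadian rhythm (RACR) domain.

Pairwise screening uses Spearman rank correlations against the dichotomy
index; group contrasts use two-tailed Welch t-tests (continuous) and
Fisher's exact test (2x2 tables). The determinant model itself is chosen by
exhaustive all-subsets ordinary least squares ranked by the small-sample
corrected Akaike information criterion

    AICc = AIC + 2k(k+1)/(n-k-1),

with k counting all estimated parameters including the error variance.

Fisher's "two-sided" p has two conventions in circulation; both are exposed:
``"mass-sum"`` (sum of hypergeometric probabilities no larger than the
observed table's — the R/scipy definition, the default) and ``"doubling"``
(twice the smaller one-sided tail, capped at 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import DeterminantsConfig


class DeterminantsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pairwise statistics
# ---------------------------------------------------------------------------

def pairwise_correlations(table: pd.DataFrame, response: str,
                          predictors: list | None = None,
                          config: DeterminantsConfig | None = None) -> pd.DataFrame:
    """Spearman correlation (average-rank ties, pairwise-complete deletion)
    of every predictor with the response; constant predictors flagged."""
    cfg = config or DeterminantsConfig()
    if response not in table.columns:
        raise DeterminantsError(f"response {response!r} not in table")
    if predictors is None:
        predictors = [c for c in table.columns
                      if c != response
                      and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    y = table[response]
    for col in predictors:
        x = pd.to_numeric(table[col], errors="coerce")
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < cfg.min_pairs:
            rows.append({"predictor": col, "r": np.nan, "p": np.nan,
                         "n": n, "flag": "too few complete pairs"})
            continue
        if x[ok].nunique() < 2:
            rows.append({"predictor": col, "r": np.nan, "p": np.nan,
                         "n": n, "flag": "constant predictor"})
            continue
        r, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"predictor": col, "r": float(r), "p": float(p),
                     "n": n, "flag": ""})
    return pd.DataFrame(rows)


def fisher_exact_2x2(table, two_sided: str = "mass-sum") -> tuple:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (odds_ratio, p). ``two_sided`` chooses between the
    probability-mass-summation definition and tail doubling.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if not np.allclose(t, np.rint(t)) or np.any(t < 0):
            raise DeterminantsError("Fisher test needs a 2x2 table of "
                                    "non-negative integers")
        t = np.rint(t).astype(int)
    odds, p_mass = stats.fisher_exact(t, alternative="two-sided")
    if two_sided == "mass-sum":
        return float(odds), float(p_mass)
    if two_sided == "doubling":
        _, pg = stats.fisher_exact(t, alternative="greater")
        _, pl = stats.fisher_exact(t, alternative="less")
        return float(odds), float(min(1.0, 2 * min(pg, pl)))
    raise DeterminantsError(f"unknown two-sided convention {two_sided!r}")


def group_compare(a, b=None, kind: str = "welch",
                  two_sided: str = "mass-sum") -> dict:
    """Welch t-test on two samples, or Fisher exact on a 2x2 table.

    For ``kind="welch"`` pass two samples; for ``kind="fisher"`` pass the
    2x2 table as the single argument.
    """
    if kind == "welch":
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise DeterminantsError("Welch test needs >= 2 values per group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return {"kind": "welch", "statistic": float(t), "p": float(p),
                "n": (int(a.size), int(b.size))}
    if kind == "fisher":
        odds, p = fisher_exact_2x2(a, two_sided=two_sided)
        return {"kind": "fisher", "statistic": odds, "p": p,
                "two_sided": two_sided}
    raise DeterminantsError(f"unknown test kind {kind!r}")


# ---------------------------------------------------------------------------
# AICc all-subsets selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionResult:
    predictors: tuple
    coefficients: dict
    intercept: float | None
    adjusted_r2: float
    aicc: float
    n: int
    n_dropped_rows: int
    ranked: pd.DataFrame                 # all candidate models by AICc
    pvalues: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def _ols_aicc(X: np.ndarray, y: np.ndarray, k_params: int):
    """Gaussian-MLE AICc for an OLS fit; returns (aicc, coef, adj_r2)."""
    n = y.size
    if X.shape[1]:
        cond = np.linalg.cond(X)
        if cond > 1e10:
            return None
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    else:
        coef = np.empty(0)
        resid = y
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    aic = -2 * ll + 2 * k_params
    denom = n - k_params - 1
    aicc = aic + (2 * k_params * (k_params + 1) / denom) if denom > 0 \
        else np.inf
    tss = float(((y - y.mean()) ** 2).sum())
    p_fit = X.shape[1]
    if tss > 0 and n > p_fit:
        r2 = 1 - rss / tss
        adj = 1 - (1 - r2) * (n - 1) / max(n - p_fit, 1)
    else:
        adj = np.nan
    return aicc, coef, adj


def select_model(table: pd.DataFrame, response: str, candidates: list,
                 include_intercept: bool = True,
                 max_predictors: int | None = None,
                 config: DeterminantsConfig | None = None) -> ModelSelectionResult:
    """Exhaustive enumeration of all predictor subsets up to
    ``max_predictors``, ranked by AICc; listwise (complete-case) deletion
    across the response and all candidates."""
    cfg = config or DeterminantsConfig()
    kmax = cfg.max_predictors if max_predictors is None else max_predictors
    cols = [response] + list(candidates)
    sub = table[cols].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    n = len(complete)
    if n <= kmax + 2:
        raise DeterminantsError(
            f"n={n} complete rows cannot support subsets of up to "
            f"{kmax} predictors")
    y = complete[response].to_numpy(float)
    Z = {c: complete[c].to_numpy(float) for c in candidates}

    rows = []
    flags = []
    for size in range(0, kmax + 1):
        for subset in itertools.combinations(candidates, size):
            cols_x = [Z[c] for c in subset]
            if include_intercept:
                X = np.column_stack([np.ones(n)] + cols_x) if cols_x \
                    else np.ones((n, 1))
            else:
                X = np.column_stack(cols_x) if cols_x else np.empty((n, 0))
            k = X.shape[1] + 1          # + error variance
            out = _ols_aicc(X, y, k)
            if out is None:
                flags.append(f"skipped collinear subset {subset}")
                continue
            aicc, coef, adj = out
            rows.append({"predictors": subset, "aicc": aicc,
                         "adjusted_r2": adj, "k": k,
                         "coef": coef})
    if not rows:
        raise DeterminantsError("no estimable candidate model")
    ranked = pd.DataFrame(rows).sort_values("aicc", kind="mergesort") \
        .reset_index(drop=True)
    best = ranked.iloc[0]
    subset = best["predictors"]
    coef = best["coef"]
    if include_intercept:
        intercept = float(coef[0])
        betas = dict(zip(subset, map(float, coef[1:])))
    else:
        intercept = None
        betas = dict(zip(subset, map(float, coef)))

    # inference for the winning model via statsmodels
    pvalues = {}
    if subset:
        Xw = np.column_stack([Z[c] for c in subset])
        Xs = sm.add_constant(Xw) if include_intercept else Xw
        fit = sm.OLS(y, Xs).fit()
        names = (["const"] if include_intercept else []) + list(subset)
        pvalues = {nm: float(p) for nm, p in zip(names, fit.pvalues)}
    view = ranked.drop(columns=["coef"]).copy()
    return ModelSelectionResult(
        predictors=tuple(subset), coefficients=betas, intercept=intercept,
        adjusted_r2=float(best["adjusted_r2"]), aicc=float(best["aicc"]),
        n=n, n_dropped_rows=n_dropped, ranked=view, pvalues=pvalues,
        flags=flags)
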