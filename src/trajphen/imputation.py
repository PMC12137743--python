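"""Missing-data policy for the clinical feature table.

Variables with a missing rate strictly above 20% are dropped; the rest are
completed by a four-method ensemble - mean substitution plus three chained
(variable-by-variable, iterated) single imputations using regression trees,
random forests and L1-regularized linear regression - combined cell-wise by
the arithmetic mean (continuous) or majority vote (categorical).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import IterativeImputer, SimpleImputer
from sklearn.linear_model import Lasso
from sklearn.tree import DecisionTreeRegressor

log = logging.getLogger(__name__)

METHODS = ("mean", "cart", "rf", "lasso_norm")


def missing_report(table: pd.DataFrame, max_rate: float = 0.20) -> pd.DataFrame:
    """Per-variable missing counts/rates; retained iff rate <= 20% (strict '>')."""
    rows = []
    n = len(table)
    for col in table.columns:
        miss = int(table[col].isna().sum())
        rate = miss / n if n else 0.0
        rows.append({"variable": col, "n_missing": miss, "rate": rate,
                     "retained": rate <= max_rate})
    return pd.DataFrame(rows)


def drop_high_missing(table: pd.DataFrame, max_rate: float = 0.20):
    report = missing_report(table, max_rate)
    keep = report.loc[report["retained"], "variable"].tolist()
    return table[keep], report


def _estimator(method: str, seed: int):
    if method == "cart":
        return DecisionTreeRegressor(random_state=seed)
    if method == "rf":
        return RandomForestRegressor(n_estimators=50, random_state=seed, n_jobs=1)
    if method == "lasso_norm":
        return Lasso(alpha=0.01, max_iter=5000)
    raise ValueError(f"unknown method {method!r}")


def _impute_one(numeric: pd.DataFrame, method: str, seed: int,
                max_iter: int) -> pd.DataFrame:
    if numeric.isna().sum().sum() == 0:
        return numeric.copy()
    if method == "mean":
        imp = SimpleImputer(strategy="mean")
    else:
        imp = IterativeImputer(estimator=_estimator(method, seed),
                               max_iter=max_iter, random_state=seed,
                               keep_empty_features=True)
    arr = imp.fit_transform(numeric)
    return pd.DataFrame(arr, index=numeric.index, columns=numeric.columns)


def impute_ensemble(table: pd.DataFrame, methods=METHODS, seed: int = 0,
                    max_iter: int = 5) -> pd.DataFrame:
    """Four-method ensemble imputation; observed cells are never modified.

    Categorical columns are label-encoded for the chained methods, imputed
    values rounded to the nearest observed code, and the ensemble decided by
    majority vote with ties broken by method order.
    """
    for col in table.columns:
        if table[col].isna().all():
            raise ValueError(f"variable {col!r} is entirely missing; "
                             "it should have been dropped")
    cat_cols = [c for c in table.columns
                if table[c].dtype == object or str(table[c].dtype) == "category"
                or table[c].dtype == bool]
    num_cols = [c for c in table.columns if c not in cat_cols]
    codes, cats = {}, {}
    numeric = table[num_cols].astype(float).copy()
    for c in cat_cols:
        cc = table[c].astype("category")
        cats[c] = cc.cat.categories
        codes[c] = cc.cat.codes.replace(-1, np.nan).astype(float)
        numeric[c] = codes[c]

    completions = []
    for m_i, method in enumerate(methods):
        filled = _impute_one(numeric, method, seed + m_i, max_iter)
        for c in cat_cols:  # snap to a valid category code
            filled[c] = filled[c].round().clip(0, len(cats[c]) - 1)
        completions.append(filled)

    out = table.copy()
    for c in num_cols:
        stacked = np.column_stack([f[c].to_numpy() for f in completions])
        ens = stacked.mean(axis=1)
        mask = table[c].isna().to_numpy()
        vals = table[c].astype(float).to_numpy()
        vals[mask] = ens[mask]
        out[c] = vals
    for c in cat_cols:
        stacked = np.column_stack([f[c].to_numpy(dtype=int)
                                   for f in completions])
        mask = table[c].isna().to_numpy()
        if mask.any():
            votes = []
            for row in stacked[mask]:
                vals_r, counts = np.unique(row, return_counts=True)
                best = counts.max()
                winners = set(vals_r[counts == best])
                # tie-break: first method (in listed order) voting for a winner
                pick = next(v for v in row if v in winners)
                votes.append(pick)
            filled_col = out[c].copy()
            filled_col.iloc[np.nonzero(mask)[0]] = [cats[c][v] for v in votes]
            out[c] = filled_col
    return out
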