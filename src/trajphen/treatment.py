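"""Phenotype-specific fluid-resuscitation response.

Per phenotype: a random-forest ICU-death classifier tuned by stratified
5-fold cross-validated AUROC, a brute-force two-predictor partial-dependence
surface over the day-1 x day-2 fluid-intake grid, decile risk stratification
of that surface, extraction of the contiguous lowest-risk fluid range, and
an adjusted Cox contrast for lactated Ringer's receipt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .outcomes import fit_cox

log = logging.getLogger(__name__)

DEFAULT_GRID_ML = np.arange(0.0, 6001.0, 100.0)  # cell left edges, 100-mL cells

DEFAULT_RF_GRID = {
    "n_estimators": [200, 500],
    "max_depth": [None, 6, 10],
    "min_samples_leaf": [1, 5, 20],
}


@dataclass
class PDPSurface:
    grid1: np.ndarray           # day-1 cell left edges (mL)
    grid2: np.ndarray           # day-2 cell left edges (mL)
    pd_values: np.ndarray       # (len(grid1), len(grid2)) death probabilities
    strata: np.ndarray | None = None
    lowest_risk_range: tuple | None = None
    cell_width: float = 100.0


@dataclass
class PhenotypeRF:
    model: RandomForestClassifier
    cv_auc: float
    best_params: dict
    n: int
    n_deaths: int
    reliable: bool = True


def fit_rf_per_phenotype(features: pd.DataFrame, icu_death: pd.Series,
                         labels: pd.Series, cv_folds: int = 5,
                         param_grid: dict | None = None,
                         seed: int = 0) -> dict:
    """One tuned random forest per phenotype; returns {phenotype: PhenotypeRF}.

    ``features`` must contain day1_ml and day2_ml plus the shared clinical
    characteristics; hyperparameters maximize mean stratified-CV AUROC.
    Phenotypes with fewer than 10 deaths are still fit but flagged
    unreliable.
    """
    param_grid = param_grid or DEFAULT_RF_GRID
    out = {}
    for g in sorted(labels.dropna().unique()):
        idx = labels.index[labels == g]
        Xg = features.loc[idx]
        yg = icu_death.loc[idx].astype(int)
        n_deaths = int(yg.sum())
        reliable = n_deaths >= 10
        if not reliable:
            log.warning("phenotype %s has %d deaths (<10); model flagged "
                        "unreliable", g, n_deaths)
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            RandomForestClassifier(random_state=seed, n_jobs=1),
            param_grid, scoring="roc_auc", cv=cv, n_jobs=1)
        search.fit(Xg, yg)
        out[g] = PhenotypeRF(model=search.best_estimator_,
                             cv_auc=float(search.best_score_),
                             best_params=dict(search.best_params_),
                             n=len(idx), n_deaths=n_deaths, reliable=reliable)
    return out


def pdp_2d(classifier, features: pd.DataFrame, grid1=None, grid2=None,
           f1: str = "day1_ml", f2: str = "day2_ml",
           background_sample: int | None = None, seed: int = 0) -> PDPSurface:
    """Brute-force two-feature partial dependence of P(ICU death).

    PD(x1, x2) = mean over cohort rows of predict_proba with f1 := x1 and
    f2 := x2, all other features kept at their observed joint values.
    ``background_sample`` optionally subsamples the averaging cohort for
    speed (the surface is still an unbiased mean over that subsample).
    """
    if len(features) == 0:
        raise ValueError("empty cohort")
    grid1 = DEFAULT_GRID_ML if grid1 is None else np.asarray(grid1, dtype=float)
    grid2 = DEFAULT_GRID_ML if grid2 is None else np.asarray(grid2, dtype=float)
    X = features
    if background_sample is not None and background_sample < len(X):
        rng = np.random.default_rng(seed)
        X = X.iloc[rng.choice(len(X), size=background_sample, replace=False)]
    n = len(X)
    n2 = len(grid2)
    cols = list(X.columns)
    i1, i2 = cols.index(f1), cols.index(f2)
    base = X.to_numpy(dtype=float)
    pdv = np.empty((len(grid1), n2))
    # one predict call per day-1 grid value over (cohort x day-2 grid) rows
    block = np.repeat(base, n2, axis=0)
    block[:, i2] = np.tile(grid2, n)
    for a, x1 in enumerate(grid1):
        block[:, i1] = x1
        proba = classifier.predict_proba(pd.DataFrame(block, columns=cols))[:, 1]
        pdv[a] = proba.reshape(n, n2).mean(axis=0)
    return PDPSurface(grid1=grid1, grid2=grid2, pd_values=pdv,
                      cell_width=float(grid1[1] - grid1[0]) if len(grid1) > 1
                      else 100.0)


def risk_strata(surface: PDPSurface, n_strata: int = 10) -> PDPSurface:
    """Cut PD cells into quantile risk strata; stratum 1 = lowest risk."""
    pdv = surface.pd_values
    flat = pdv.ravel()
    if np.allclose(flat, flat[0]):
        log.warning("constant PD surface; single degenerate stratum")
        surface.strata = np.ones_like(pdv, dtype=int)
        return surface
    qs = np.quantile(flat, np.linspace(0, 1, n_strata + 1)[1:-1])
    strata = np.searchsorted(qs, flat, side="right") + 1
    surface.strata = strata.reshape(pdv.shape)
    return surface


def lowest_risk_range(surface: PDPSurface) -> tuple:
    """Bounding box of the contiguous lowest-risk region, in mL cell edges.

    Takes the 4-connected component of stratum-1 cells containing the global
    PD minimum and reports (day1_lo, day1_hi, day2_lo, day2_hi) using cell
    edges (left edge of the lowest cell, right edge of the highest).
    """
    if surface.strata is None:
        raise ValueError("call risk_strata first")
    if surface.strata.max() == surface.strata.min():
        raise ValueError("no range: degenerate single-stratum surface")
    pdv = surface.pd_values
    in1 = surface.strata == 1
    start = np.unravel_index(np.argmin(pdv), pdv.shape)
    # BFS over the 4-connected stratum-1 component containing the minimum
    stack, seen = [start], {start}
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if (0 <= ni < pdv.shape[0] and 0 <= nj < pdv.shape[1]
                    and in1[ni, nj] and (ni, nj) not in seen):
                seen.add((ni, nj))
                stack.append((ni, nj))
    ii = np.array([p[0] for p in seen])
    jj = np.array([p[1] for p in seen])
    w = surface.cell_width
    rng = (float(surface.grid1[ii.min()]), float(surface.grid1[ii.max()] + w),
           float(surface.grid2[jj.min()]), float(surface.grid2[jj.max()] + w))
    surface.lowest_risk_range = rng
    return rng


def ringer_cox(survival: pd.DataFrame, covariates=("age", "gender", "race"),
               per_phenotype: bool = True) -> pd.DataFrame:
    """Adjusted Cox HR for lactated Ringer's receipt, per phenotype stratum.

    ``survival`` needs time, event, ringer (bool) and phenotype columns plus
    the adjustment covariates.
    """
    rows = []
    strata = sorted(survival["phenotype"].unique()) if per_phenotype else ["all"]
    for g in strata:
        sub = survival if g == "all" else survival[survival["phenotype"] == g]
        df = sub.copy()
        df["phenotype"] = np.where(df["ringer"].astype(bool), "ringer",
                                   "no_ringer")
        try:
            rep = fit_cox(df, covariates=covariates, reference="no_ringer",
                          model_type="adjusted")
        except Exception as exc:  # no events, separation, ...
            log.warning("Ringer Cox failed in stratum %s: %s", g, exc)
            rows.append({"phenotype": g, "HR": np.nan, "ci_lower": np.nan,
                         "ci_upper": np.nan, "p": np.nan, "note": str(exc)})
            continue
        row = rep[rep["contrast"] == "ringer vs no_ringer"].iloc[0]
        rows.append({"phenotype": g, "HR": row["HR"],
                     "ci_lower": row["ci_lower"], "ci_upper": row["ci_upper"],
                     "p": row["p"], "note": ""})
    return pd.DataFrame(rows)
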