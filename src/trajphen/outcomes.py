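"""Clinical characterization and prognosis contrasts across subphenotypes.

Descriptives are median (IQR) / n (%), group differences use
Kruskal-Wallis and Pearson chi-square tests, prognosis uses Cox
proportional-hazards models (Efron ties via lifelines) with phenotype B as
the reference, covariate-adjusted Kaplan-Meier curves via direct (corrected
group prognosis) adjustment, and per-phenotype multivariate Cox models for
comorbidities with cohort prevalence above 5%. Two-sided alpha = 0.05; no
multiplicity correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as sps

log = logging.getLogger(__name__)


def format_count_pct(count: int, n: int) -> str:
    """Render a categorical cell the way clinical tables print it: "46 (12.5)"."""
    pct = 100.0 * count / n if n else float("nan")
    return f"{count} ({pct:.1f})"


def format_median_iqr(values, digits: int = 1) -> str:
    v = pd.Series(values).dropna()
    if v.empty:
        return "NA"
    med, q1, q3 = v.median(), v.quantile(0.25), v.quantile(0.75)
    return f"{med:.{digits}f} ({q1:.{digits}f}, {q3:.{digits}f})"


def describe_by_phenotype(baseline: pd.DataFrame, labels: pd.Series,
                          continuous=(), categorical=()) -> pd.DataFrame:
    """Table-1 style summary: one column per phenotype, median (IQR) or n (%)."""
    df = baseline.set_index("patient_id").join(labels.rename("phenotype"))
    groups = sorted(df["phenotype"].dropna().unique())
    rows = []
    ns = {g: int((df["phenotype"] == g).sum()) for g in groups}
    rows.append({"variable": "N", **{g: str(ns[g]) for g in groups}})
    for var in continuous:
        row = {"variable": var}
        for g in groups:
            vals = df.loc[df["phenotype"] == g, var]
            n_miss = int(vals.isna().sum())
            row[g] = format_median_iqr(vals)
            if vals.notna().sum() == 0:
                row[g] = f"NA (missing {n_miss})"
        rows.append(row)
    for var in categorical:
        levels = sorted(df[var].dropna().unique())
        for lev in levels:
            row = {"variable": f"{var}={lev}"}
            for g in groups:
                sub = df.loc[df["phenotype"] == g, var]
                row[g] = format_count_pct(int((sub == lev).sum()), ns[g])
            rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(baseline: pd.DataFrame, labels: pd.Series,
                   continuous=(), categorical=()) -> pd.DataFrame:
    """Kruskal-Wallis (continuous) and Pearson chi-square (categorical) tests."""
    df = baseline.set_index("patient_id").join(labels.rename("phenotype"))
    groups = sorted(df["phenotype"].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    rows = []
    for var in continuous:
        samples = [df.loc[df["phenotype"] == g, var].dropna() for g in groups]
        if any(len(s) == 0 for s in samples):
            log.warning("variable %s empty in some group; skipped", var)
            rows.append({"variable": var, "test": "kruskal", "statistic": np.nan,
                         "p": np.nan, "note": "empty group"})
            continue
        H, p = sps.kruskal(*samples)
        rows.append({"variable": var, "test": "kruskal", "statistic": H, "p": p,
                     "note": ""})
    for var in categorical:
        tab = pd.crosstab(df[var], df["phenotype"])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            rows.append({"variable": var, "test": "chi2", "statistic": np.nan,
                         "p": np.nan, "note": "degenerate table"})
            continue
        chi2, p, _, expected = sps.chi2_contingency(tab, correction=False)
        note = "low expected counts" if (expected < 5).any() else ""
        if note:
            log.warning("chi-square for %s has expected counts below 5", var)
        rows.append({"variable": var, "test": "chi2", "statistic": chi2, "p": p,
                     "note": note})
    return pd.DataFrame(rows)


def correlation_matrix(baseline: pd.DataFrame, labels: pd.Series,
                       variables=()) -> pd.DataFrame:
    """Pearson correlations among variables and one-hot phenotype indicators."""
    df = baseline.set_index("patient_id").join(labels.rename("phenotype"))
    mat = df[list(variables)].astype(float)
    onehot = pd.get_dummies(df["phenotype"], prefix="phenotype").astype(float)
    mat = pd.concat([mat, onehot], axis=1)
    zero_var = mat.std(ddof=0) == 0
    if zero_var.any():
        log.warning("zero-variance column(s): %s",
                    list(mat.columns[zero_var]))
    corr = mat.corr(method="pearson")
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    return corr


def _prepare_design(survival: pd.DataFrame, covariates, reference: str):
    """Phenotype dummies (reference dropped) + covariates, constants removed."""
    df = survival.copy()
    phen = pd.get_dummies(df["phenotype"], prefix="phenotype").astype(float)
    ref_col = f"phenotype_{reference}"
    contrast_cols = [c for c in phen.columns if c != ref_col]
    X = phen[contrast_cols]
    dropped = []
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or col.dtype.name in ("category", "bool"):
            dm = pd.get_dummies(col, prefix=cov, drop_first=True).astype(float)
            X = pd.concat([X, dm], axis=1)
        else:
            X = pd.concat([X, col.astype(float)], axis=1)
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            dropped.append(c)
            X = X.drop(columns=c)
    if dropped:
        log.info("dropped constant covariate column(s): %s", dropped)
    design = pd.concat([df[["time", "event"]].reset_index(drop=True),
                        X.reset_index(drop=True)], axis=1)
    design["event"] = design["event"].astype(bool)
    return design, [c for c in contrast_cols if c in X.columns]


def fit_cox(survival: pd.DataFrame, covariates=(), reference: str = "B",
            model_type: str | None = None) -> pd.DataFrame:
    """Cox PH fit of 30-day mortality on phenotype (+ covariates).

    Returns one row per phenotype contrast vs the reference: HR, Wald 95%
    CI and p. ``model_type`` defaults to 'crude' without covariates and
    'adjusted' with them.
    """
    if survival["event"].sum() == 0:
        raise ValueError("no events; Cox model cannot be fit")
    design, contrast_cols = _prepare_design(survival, covariates, reference)
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    summ = cph.summary
    if model_type is None:
        model_type = "adjusted" if covariates else "crude"
    rows = [{"contrast": f"{reference} (reference)", "HR": 1.0,
             "ci_lower": 1.0, "ci_upper": 1.0, "p": np.nan,
             "model": model_type}]
    for c in summ.index:
        name = c.replace("phenotype_", "") + " vs " + reference \
            if c in contrast_cols else c
        rows.append({"contrast": name,
                     "HR": float(np.exp(summ.loc[c, "coef"])),
                     "ci_lower": float(np.exp(summ.loc[c, "coef lower 95%"])),
                     "ci_upper": float(np.exp(summ.loc[c, "coef upper 95%"])),
                     "p": float(summ.loc[c, "p"]),
                     "model": model_type})
    return pd.DataFrame(rows)


def adjusted_km(survival: pd.DataFrame, covariates=("age", "gender", "race"),
                reference: str = "B") -> pd.DataFrame:
    """Direct-adjusted (corrected group prognosis) survival curves.

    Fits Cox on phenotype + covariates, then for each phenotype averages the
    predicted survival curves over the pooled covariate distribution.
    Returns a step-function table indexed by event time with one column per
    phenotype.
    """
    design, contrast_cols = _prepare_design(survival, covariates, reference)
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    X = design.drop(columns=["time", "event"])
    phenos = sorted(survival["phenotype"].unique())
    curves = {}
    for g in phenos:
        Xg = X.copy()
        for c in contrast_cols:
            Xg[c] = 1.0 if c == f"phenotype_{g}" else 0.0
        sf = cph.predict_survival_function(Xg)
        curves[g] = sf.mean(axis=1)
    out = pd.DataFrame(curves)
    out.index.name = "time"
    # survival at t=0 is 1 by construction
    if 0.0 not in out.index:
        out.loc[0.0] = 1.0
        out = out.sort_index()
    return out


def comorbidity_cox(survival: pd.DataFrame, comorbidity_cols,
                    prevalence_min: float = 0.05) -> pd.DataFrame:
    """Per-phenotype multivariate Cox over prevalent (> 5%) comorbidities."""
    prevalence = {c: float(survival[c].mean()) for c in comorbidity_cols}
    included = [c for c in comorbidity_cols if prevalence[c] > prevalence_min]
    if not included:
        raise ValueError("no comorbidity exceeds the prevalence threshold")
    rows = []
    for g in sorted(survival["phenotype"].unique()):
        sub = survival.loc[survival["phenotype"] == g]
        if sub["event"].sum() == 0:
            log.warning("phenotype %s has no events; stratum skipped", g)
            continue
        cols = [c for c in included if sub[c].nunique() > 1]
        if not cols:
            continue
        design = sub[["time", "event"] + cols].copy()
        design[cols] = design[cols].astype(float)
        design["event"] = design["event"].astype(bool)
        cph = CoxPHFitter()
        cph.fit(design, duration_col="time", event_col="event")
        for c in cols:
            s = cph.summary.loc[c]
            rows.append({"phenotype": g, "comorbidity": c,
                         "prevalence": prevalence[c],
                         "HR": float(np.exp(s["coef"])),
                         "ci_lower": float(np.exp(s["coef lower 95%"])),
                         "ci_upper": float(np.exp(s["coef upper 95%"])),
                         "p": float(s["p"])})
    return pd.DataFrame(rows)
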