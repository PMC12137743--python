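"""Descriptives, group tests, correlations, Cox models, adjusted KM."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

import trajphen as tp
from trajphen import synthetic
from trajphen.outcomes import (adjusted_km, comorbidity_cox, compare_groups,
                               correlation_matrix, describe_by_phenotype,
                               fit_cox, format_count_pct)
from trajphen.synthetic import GeneratorConfig


def test_count_percent_formatting_matches_clinical_tables():
    assert format_count_pct(46, 369) == "46 (12.5)"
    assert format_count_pct(27, 1076) == "27 (2.5)"
    assert format_count_pct(0, 10) == "0 (0.0)"


def test_describe_constant_variable_iqr():
    base = pd.DataFrame({"patient_id": list("abcd"), "x": [5.0] * 4,
                         "sex": ["M", "F", "M", "F"]})
    labels = pd.Series(["A", "A", "B", "B"], index=list("abcd"),
                       name="phenotype")
    tab = describe_by_phenotype(base, labels, continuous=("x",),
                                categorical=("sex",))
    xrow = tab.loc[tab["variable"] == "x"].iloc[0]
    assert xrow["A"] == "5.0 (5.0, 5.0)"
    mrow = tab.loc[tab["variable"] == "sex=M"].iloc[0]
    assert mrow["A"] == "1 (50.0)"


def test_describe_percentages_sum_to_100(small_cohort):
    labels = small_cohort.truth_labels
    tab = describe_by_phenotype(small_cohort.baseline, labels,
                                categorical=("gender",))
    rows = tab[tab["variable"].str.startswith("gender=")]
    for g in "ABCD":
        pcts = rows[g].str.extract(r"\(([\d.]+)\)")[0].astype(float)
        assert pcts.sum() == pytest.approx(100.0, abs=0.11)  # rounding only


def test_kruskal_null_and_chi2_hand_value():
    vals = list(range(10))
    base = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(40)],
        "x": vals * 4,
    })
    labels = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10 + ["D"] * 10,
                       index=base["patient_id"], name="phenotype")
    out = compare_groups(base, labels, continuous=("x",))
    assert out.iloc[0]["statistic"] == pytest.approx(0.0, abs=1e-9)
    # hand 2x2 chi-square: table (10,20 / 20,10), n=60
    two = pd.DataFrame({
        "patient_id": [f"q{i}" for i in range(60)],
        "cat": ["u"] * 10 + ["v"] * 20 + ["u"] * 20 + ["v"] * 10,
    })
    lab2 = pd.Series(["A"] * 30 + ["B"] * 30, index=two["patient_id"],
                     name="phenotype")
    res = compare_groups(two, lab2, categorical=("cat",))
    # chi2 = n (ad - bc)^2 / (r1 r2 c1 c2) = 60 * (100-400)^2 / 30^4
    assert res.iloc[0]["statistic"] == pytest.approx(60 * 300 ** 2 / 30 ** 4)


def test_monotone_p_value_in_group_shift():
    rng = np.random.default_rng(0)
    base_x = rng.normal(size=60)
    ps = []
    for shift in (0.0, 0.8, 2.0):
        df = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(120)],
            "x": np.concatenate([base_x, base_x + shift]),
        })
        lab = pd.Series(["A"] * 60 + ["B"] * 60, index=df["patient_id"],
                        name="phenotype")
        ps.append(compare_groups(df, lab, continuous=("x",)).iloc[0]["p"])
    assert ps[0] > ps[1] > ps[2]


def test_correlation_matrix_hand_values():
    base = pd.DataFrame({
        "patient_id": list("abcde"),
        "x": [1.0, 2, 3, 4, 5],
        "y": [2.0, 1, 4, 3, 5],
        "z": [5.0, 4, 3, 2, 1],
    })
    labels = pd.Series(["A", "A", "A", "B", "B"], index=list("abcde"),
                       name="phenotype")
    corr = correlation_matrix(base, labels, variables=("x", "y", "z"))
    assert corr.loc["x", "x"] == pytest.approx(1.0)
    assert corr.loc["x", "z"] == pytest.approx(-1.0)
    # hand Pearson for x vs y: cov = 2.0, sd_x = sd_y = sqrt(2) -> r = 0.8...
    x, y = base["x"], base["y"]
    hand = (((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    assert corr.loc["x", "y"] == pytest.approx(hand)


def test_correlation_zero_variance_is_na():
    base = pd.DataFrame({"patient_id": list("abcd"), "x": [1.0, 2, 3, 4],
                         "const": [7.0] * 4})
    labels = pd.Series(["A", "A", "B", "B"], index=list("abcd"),
                       name="phenotype")
    corr = correlation_matrix(base, labels, variables=("x", "const"))
    assert np.isnan(corr.loc["const", "x"])


def test_cox_reference_row_and_constant_covariate_drop():
    cfg = GeneratorConfig(seed=21, age_loghr=0.0, male_loghr=0.0)
    rng = np.random.default_rng(21)
    labels = np.array(["A"] * 2000 + ["B"] * 2000)
    cov = synthetic.generate_covariates(labels, cfg, rng)
    surv = synthetic.generate_survival(labels, cfg, rng, baseline=cov)
    rep = fit_cox(surv, covariates=("age", "gender", "race"))  # race constant
    assert rep.iloc[0]["contrast"] == "B (reference)"
    assert rep.iloc[0]["HR"] == 1.0
    assert not rep["contrast"].str.contains("race").any()
    row = rep[rep["contrast"] == "A vs B"].iloc[0]
    assert row["ci_lower"] < row["HR"] < row["ci_upper"]


def test_cox_no_events_raises():
    surv = pd.DataFrame({"time": [30.0] * 10, "event": [False] * 10,
                         "phenotype": ["A", "B"] * 5})
    with pytest.raises(ValueError):
        fit_cox(surv)


def test_adjusted_km_shape_and_null_adjustment():
    cfg = GeneratorConfig(seed=22, age_loghr=0.0, male_loghr=0.0)
    rng = np.random.default_rng(22)
    labels = np.array(["A"] * 1500 + ["B"] * 1500)
    cov = synthetic.generate_covariates(labels, cfg, rng)
    surv = synthetic.generate_survival(labels, cfg, rng, baseline=cov)
    km = adjusted_km(surv, covariates=("age", "gender"))
    assert km.loc[0.0].tolist() == [1.0, 1.0]
    assert ((km.values >= 0) & (km.values <= 1.0 + 1e-12)).all()
    assert (np.diff(km["A"].to_numpy()) <= 1e-12).all()  # non-increasing
    # with no covariate effect, adjusted ~ plain KM
    kmf = KaplanMeierFitter().fit(surv.loc[surv["phenotype"] == "A", "time"],
                                  surv.loc[surv["phenotype"] == "A", "event"])
    plain = float(kmf.survival_function_at_times(29.9).iloc[0])
    adj = float(km["A"].iloc[-1])
    assert adj == pytest.approx(plain, abs=0.02)


def test_adjusted_survival_ordering_on_generator_defaults():
    co = tp.generate_cohort(GeneratorConfig(n_patients=6000, seed=23))
    km = adjusted_km(co.survival)
    final = km.iloc[-1]
    assert final["A"] < final["C"] < final["B"]
    assert abs(final["B"] - final["D"]) < 0.03  # B ~ D (HR 0.77 vs 1)


def test_comorbidity_prevalence_threshold_and_recovery():
    rng = np.random.default_rng(32)
    n = 5000
    rare = np.zeros(n, dtype=bool)
    rare[:245] = True            # prevalence 4.9% exactly
    common = rng.random(n) < 0.30
    lam = 0.004 * np.where(common, 2.0, 1.0)  # true HR 2.0
    t = rng.exponential(1.0 / lam)
    surv = pd.DataFrame({
        "time": np.minimum(t, 30.0), "event": t <= 30.0,
        "phenotype": "A", "rare_dx": rare, "common_dx": common,
    })
    rep = comorbidity_cox(surv, ["rare_dx", "common_dx"])
    assert not (rep["comorbidity"] == "rare_dx").any()  # 4.9% excluded
    row = rep[rep["comorbidity"] == "common_dx"].iloc[0]
    assert row["ci_lower"] < 2.0 < row["ci_upper"]
    # boundary: 5.1% prevalence enters the model
    edge = np.zeros(n, dtype=bool)
    edge[:255] = True            # prevalence 5.1% exactly
    surv["edge_dx"] = edge
    rep2 = comorbidity_cox(surv, ["edge_dx", "common_dx"])
    assert (rep2["comorbidity"] == "edge_dx").any()
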