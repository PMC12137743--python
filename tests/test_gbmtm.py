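"""EM mixture fitting: degenerate cases, closed-form oracles, recovery."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

import trajphen as tp
from trajphen import gbmtm
from trajphen.gbmtm import (GBMTMModel, assign_modal, class_mean_curve, e_step,
                            information_criteria, m_step, time_basis)
from trajphen.prep import zscore
from trajphen.synthetic import GeneratorConfig

from conftest import panel_from_values


def _model(coeffs, var, mixing, order=None):
    coeffs = np.asarray(coeffs, dtype=float)
    return GBMTMModel(K=coeffs.shape[0], order=coeffs.shape[2] - 1,
                      coeffs=coeffs, resid_var=np.asarray(var, dtype=float),
                      mixing=np.asarray(mixing, dtype=float), loglik=0.0)


def test_k1_equals_pooled_least_squares(small_panel):
    model, tau = tp.fit_gbmtm(small_panel, K=1, order=2, n_restarts=1, seed=0)
    assert np.allclose(tau, 1.0)
    assert model.mixing.tolist() == [1.0]
    X = time_basis(2)
    for c in range(5):
        rows, cols = [], []
        for i in range(small_panel.n_patients):
            for h in range(12):
                if small_panel.mask[i, h]:
                    rows.append(X[h])
                    cols.append(small_panel.values[i, h, c])
        beta, *_ = np.linalg.lstsq(np.array(rows), np.array(cols), rcond=None)
        np.testing.assert_allclose(model.coeffs[0, c], beta, atol=1e-8)


def test_zero_noise_recovery_exact(generator_stats):
    cfg = GeneratorConfig(n_patients=120, seed=5, noise_sd=(0,) * 5)
    co = tp.generate_cohort(cfg)
    panel = tp.filter_complete_hours(tp.hourly_aggregate(co.raw_vitals))
    panel, _ = zscore(panel, generator_stats)  # template scale exactly
    model, tau = tp.fit_gbmtm(panel, K=4, order=2, n_restarts=3, seed=5)
    lab = assign_modal(tau)
    truth = co.truth_labels.loc[panel.patients].to_numpy()
    assert adjusted_rand_score(truth, lab) == 1.0
    # recovered coefficients match the generating templates class-by-class
    tmpl = np.asarray(cfg.class_templates)
    for k in range(4):
        klass = "ABCD".index(truth[lab == k][0])
        np.testing.assert_allclose(model.coeffs[k], tmpl[klass], atol=1e-6)


def test_loglik_trace_nondecreasing(small_fit):
    trace = np.array(small_fit[0].loglik_trace)
    assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))


def test_parameter_recovery_moderate_noise():
    cfg = GeneratorConfig(n_patients=2000, seed=11)  # default noise SD 0.5
    co = tp.generate_cohort(cfg)
    panel, _, _ = tp.prepare(co.raw_vitals, co.baseline)
    model, tau = tp.fit_gbmtm(panel, K=4, order=3, n_restarts=10, seed=11)
    lab = assign_modal(tau)
    truth = co.truth_labels.loc[panel.patients].to_numpy()
    assert adjusted_rand_score(truth, lab) >= 0.95
    want = np.sort(np.asarray(cfg.class_proportions))
    got = np.sort(model.mixing)
    assert np.max(np.abs(want - got)) <= 0.03


def test_e_step_degenerate_mixture(small_panel):
    model, _ = tp.fit_gbmtm(small_panel, K=1, order=1, n_restarts=1, seed=0)
    # duplicate the class; posteriors must split 0.5/0.5 by symmetry
    twin = _model(np.repeat(model.coeffs, 2, axis=0),
                  np.repeat(model.resid_var, 2, axis=0), [0.5, 0.5])
    tau = e_step(twin, small_panel)
    np.testing.assert_allclose(tau, 0.5, atol=1e-12)
    # all prior mass on one class forces tau = 1 there
    spike = _model(np.repeat(model.coeffs, 2, axis=0),
                   np.repeat(model.resid_var, 2, axis=0), [1.0 - 1e-300, 1e-300])
    tau = e_step(spike, small_panel)
    np.testing.assert_allclose(tau[:, 0], 1.0)


def test_e_step_matches_bayes_rule_by_hand():
    # one patient, two constant-curve classes differing in channel 0 only
    vals = np.full((1, 12, 5), 0.0)
    vals[0, :, 0] = 1.0
    vals[0, 2:, :] = np.nan  # two observed hours
    panel = panel_from_values(vals)
    coeffs = np.zeros((2, 5, 1))
    coeffs[1, 0, 0] = 2.0  # class 1 expects channel0 = 2
    model = _model(coeffs, np.ones((2, 5)), [0.3, 0.7])
    tau = e_step(model, panel)
    # density ratio over the 2 observed hours of channel 0 (others cancel)
    l0 = norm.pdf(1.0, 0.0, 1.0) ** 2
    l1 = norm.pdf(1.0, 2.0, 1.0) ** 2
    expect = 0.3 * l0 / (0.3 * l0 + 0.7 * l1)
    assert tau[0, 0] == pytest.approx(expect, rel=1e-12)


def test_m_step_uniform_tau_gives_identical_classes(small_panel):
    n = small_panel.n_patients
    tau = np.full((n, 2), 0.5)
    coeffs, var, mixing = m_step(small_panel, tau, order=2)
    np.testing.assert_allclose(coeffs[0], coeffs[1], atol=1e-10)
    np.testing.assert_allclose(var[0], var[1], atol=1e-10)
    np.testing.assert_allclose(mixing, [0.5, 0.5])


def test_m_step_exact_line_closed_form():
    # 3 observed hours lying exactly on value = 1 + 2 * h_s per channel
    hs = np.arange(12) / 11.0
    vals = np.full((1, 12, 5), np.nan)
    for h in (0, 5, 11):
        vals[0, h, :] = 1.0 + 2.0 * hs[h]
    panel = panel_from_values(vals)
    coeffs, var, _ = m_step(panel, np.ones((1, 1)), order=1)
    np.testing.assert_allclose(coeffs[0, :, 0], 1.0, atol=1e-10)
    np.testing.assert_allclose(coeffs[0, :, 1], 2.0, atol=1e-10)
    assert np.all(var <= 1e-6 + 1e-12)  # floored at the variance floor


def test_information_criteria_arithmetic(small_panel, small_fit):
    model, tau = small_fit
    N = small_panel.n_patients
    hard = np.zeros_like(tau)
    hard[np.arange(len(tau)), np.argmax(tau, axis=1)] = 1.0
    ic = information_criteria(model, small_panel, hard)
    assert ic["ICL"] == pytest.approx(ic["BIC"])
    assert ic["entropy"] == pytest.approx(1.0)
    uni = np.full_like(tau, 1.0 / model.K)
    ic_u = information_criteria(model, small_panel, uni)
    assert ic_u["entropy"] == pytest.approx(0.0, abs=1e-12)
    ic2 = information_criteria(model, small_panel, tau)
    assert ic2["BIC"] == pytest.approx(-2 * model.loglik
                                       + model.n_params * np.log(N))
    assert ic2["AIC"] == pytest.approx(-2 * model.loglik + 2 * model.n_params)


def test_assign_modal_and_label_permutation(small_fit):
    tau = np.array([[0.7, 0.1, 0.1, 0.1], [0.5, 0.5, 0.0, 0.0]])
    lab = assign_modal(tau)
    assert lab.tolist() == [0, 0]  # tie in row 2 goes to the lower index
    _, tau_fit = small_fit
    perm = np.array([2, 0, 3, 1])
    lab_a = assign_modal(tau_fit)
    lab_b = assign_modal(tau_fit[:, perm])
    assert adjusted_rand_score(lab_a, lab_b) == 1.0


def test_class_mean_curve_evaluation():
    rng = np.random.default_rng(0)
    coeffs = rng.normal(size=(2, 5, 4))
    model = _model(coeffs, np.ones((2, 5)), [0.5, 0.5])
    hours = np.array([0.0, 3.0, 11.0])
    hs = hours / 11.0
    naive = sum(coeffs[1, 2, j] * hs ** j for j in range(4))
    np.testing.assert_allclose(class_mean_curve(model, 1, 2, hours), naive,
                               atol=1e-12)
    const = _model(np.full((1, 5, 1), 2.5), np.ones((1, 5)), [1.0])
    np.testing.assert_allclose(class_mean_curve(const, 0, 0, np.arange(12)), 2.5)


def test_missing_hours_equal_complete_subset_fit():
    # masking hours out of the likelihood == fitting on the kept subset
    cfg = GeneratorConfig(n_patients=80, seed=13)
    co = tp.generate_cohort(cfg)
    panel, _, _ = tp.prepare(co.raw_vitals, co.baseline)
    masked = panel.copy()
    masked.mask[:, 8:] = False
    masked.values[:, 8:, :] = np.nan
    m1, t1 = tp.fit_gbmtm(masked, K=2, order=1, n_restarts=1, seed=3)
    ll_masked = gbmtm.class_log_density(masked, m1.coeffs, m1.resid_var)
    # recompute on a physically truncated panel: only the first 8 hours exist
    short = masked.copy()
    short.values = short.values[:, :12, :]  # same grid, cells beyond 8 are NaN
    ll_short = gbmtm.class_log_density(short, m1.coeffs, m1.resid_var)
    np.testing.assert_allclose(ll_masked, ll_short, atol=1e-10)
    # and the per-patient log-density equals the brute-force cell sum
    X = time_basis(1)
    mu = np.einsum("hp,kcp->khc", X, m1.coeffs)
    i = 0
    brute = np.zeros(2)
    for k in range(2):
        for h in range(12):
            if masked.mask[i, h]:
                for c in range(5):
                    brute[k] += norm.logpdf(masked.values[i, h, c],
                                            mu[k, h, c],
                                            np.sqrt(m1.resid_var[k, c]))
    np.testing.assert_allclose(ll_masked[i], brute, atol=1e-8)
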