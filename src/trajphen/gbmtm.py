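"""Group-based multi-trajectory model (GBMTM) fitted by EM.

The model is a finite mixture over patients: each latent class k defines,
for every vital-sign channel c, a polynomial mean curve in scaled time
h_s = hour/11 with class/channel-specific Gaussian residual variance.
Conditional on class, observations are independent across observed hours
and channels, so the class log-density of a patient is the sum of normal
log-pdfs over their observed cells. Estimation alternates the usual E-step
(posterior class probabilities) and M-step (weighted least squares per
class and channel, weighted residual variances, mean posterior mixing
weights), with k-means and random restarts to escape local optima.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .prep import TrajectoryPanel
from .synthetic import N_HOURS

log = logging.getLogger(__name__)

VAR_FLOOR = 1e-6
_LOG2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    pass


@dataclass
class GBMTMModel:
    K: int
    order: int
    coeffs: np.ndarray        # (K, C, order+1), scaled-time basis
    resid_var: np.ndarray     # (K, C)
    mixing: np.ndarray        # (K,)
    loglik: float
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    seed: int | None = None
    channels: tuple = ()

    @property
    def n_params(self) -> int:
        C = self.coeffs.shape[1]
        return (self.K - 1) + self.K * C * (self.order + 1) + self.K * C

    def to_json(self, path=None) -> str:
        doc = {
            "K": self.K, "order": self.order,
            "mixing": self.mixing.tolist(),
            "coeffs": self.coeffs.tolist(),
            "resid_var": self.resid_var.tolist(),
            "loglik": self.loglik, "converged": self.converged,
            "n_iter": self.n_iter, "seed": self.seed,
            "channels": list(self.channels),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GBMTMModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(K=doc["K"], order=doc["order"],
                   coeffs=np.asarray(doc["coeffs"], dtype=float),
                   resid_var=np.asarray(doc["resid_var"], dtype=float),
                   mixing=np.asarray(doc["mixing"], dtype=float),
                   loglik=doc["loglik"], converged=doc["converged"],
                   n_iter=doc["n_iter"], seed=doc.get("seed"),
                   channels=tuple(doc.get("channels", ())))


def time_basis(order: int, hours=None) -> np.ndarray:
    """Polynomial design in scaled time h_s = h/11, shape (H, order+1)."""
    if hours is None:
        hours = np.arange(N_HOURS)
    hs = np.asarray(hours, dtype=float) / (N_HOURS - 1)
    return np.vander(hs, N=order + 1, increasing=True)


def _panel_arrays(panel: TrajectoryPanel):
    Y = np.nan_to_num(panel.values, nan=0.0)
    W = panel.mask.astype(float)  # (n, H)
    return Y, W


def class_log_density(panel: TrajectoryPanel, coeffs: np.ndarray,
                      resid_var: np.ndarray) -> np.ndarray:
    """Per-patient per-class log-density matrix, shape (n, K)."""
    Y, W = _panel_arrays(panel)
    X = time_basis(coeffs.shape[2] - 1)                     # (H, p+1)
    mu = np.einsum("hp,kcp->khc", X, coeffs)                # (K, H, C)
    var = np.maximum(resid_var, VAR_FLOOR)                  # (K, C)
    # sum over observed (h, c): -0.5*log(2*pi*var) - r^2/(2*var)
    n_obs_h = W.sum(axis=1)                                 # (n,)
    const = -0.5 * (_LOG2PI + np.log(var)).sum(axis=1)      # (K,) per observed hour
    ll = np.outer(n_obs_h, const)                           # (n, K)
    for k in range(coeffs.shape[0]):
        r2 = (panel.values - mu[k]) ** 2                    # (n, H, C) with NaN
        r2 = np.nan_to_num(r2, nan=0.0) * W[:, :, None]
        ll[:, k] -= 0.5 * np.einsum("nhc,c->n", r2, 1.0 / var[k])
    return ll


def e_step(model: GBMTMModel, panel: TrajectoryPanel) -> np.ndarray:
    """Posterior class probabilities tau (n, K), log-sum-exp stabilized."""
    ll = class_log_density(panel, model.coeffs, model.resid_var)
    return _posterior(ll, model.mixing)[0]


def _posterior(ll: np.ndarray, mixing: np.ndarray):
    logw = ll + np.log(mixing)[None, :]
    norm = logsumexp(logw, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = np.nonzero(~np.isfinite(norm))[0]
        raise FitError(f"zero total density for patient row(s) {bad[:5].tolist()}")
    tau = np.exp(logw - norm[:, None])
    return tau, float(norm.sum())


def m_step(panel: TrajectoryPanel, tau: np.ndarray, order: int):
    """Weighted-least-squares M-step; returns (coeffs, resid_var, mixing)."""
    Y, W = _panel_arrays(panel)
    n, H, C = panel.values.shape
    K = tau.shape[1]
    X = time_basis(order)                                   # (H, p+1)
    P = order + 1
    coeffs = np.zeros((K, C, P))
    resid_var = np.full((K, C), VAR_FLOOR)
    mixing = tau.mean(axis=0)
    for k in range(K):
        wh = tau[:, k] @ W                                  # (H,) hour weights
        G = (X * wh[:, None]).T @ X                         # (P, P)
        wy = np.einsum("n,nhc->hc", tau[:, k], Y * W[:, :, None])  # (H, C)
        b = X.T @ wy                                        # (P, C)
        beta = _solve_wls(G, b, X, wh)
        coeffs[k] = beta.T
        mu = X @ beta                                       # (H, C)
        r2 = np.nan_to_num((panel.values - mu) ** 2, nan=0.0) * W[:, :, None]
        num = np.einsum("n,nhc->c", tau[:, k], r2)
        den = tau[:, k] @ W.sum(axis=1)
        resid_var[k] = np.maximum(num / np.maximum(den, 1e-12), VAR_FLOOR)
    return coeffs, resid_var, mixing


def _solve_wls(G, b, X, wh):
    """Solve G beta = b, reducing the polynomial order on singular designs."""
    P = G.shape[0]
    for p_use in range(P, 0, -1):
        Gs, bs = G[:p_use, :p_use], b[:p_use]
        try:
            # rank check via condition number on the weighted Gram matrix
            if np.linalg.cond(Gs) > 1e12:
                raise np.linalg.LinAlgError
            beta_s = np.linalg.solve(Gs, bs)
        except np.linalg.LinAlgError:
            if p_use > 1:
                log.warning("singular design; reducing polynomial order to %d",
                            p_use - 2)
            continue
        beta = np.zeros((P, b.shape[1]))
        beta[:p_use] = beta_s
        return beta
    return np.zeros((P, b.shape[1]))


def _em(panel, tau0, K, order, tol, max_iter):
    """Run EM from an initial posterior; returns (model fields, tau) or None."""
    trace = []
    tau = tau0
    prev = -np.inf
    converged = False
    coeffs = resid_var = mixing = None
    for it in range(1, max_iter + 1):
        if np.any(tau.sum(axis=0) < order + 2):
            return None  # class collapse
        coeffs, resid_var, mixing = m_step(panel, tau, order)
        if np.any(mixing <= 0):
            return None
        ll_mat = class_log_density(panel, coeffs, resid_var)
        tau, loglik = _posterior(ll_mat, mixing)
        trace.append(loglik)
        if prev > -np.inf and abs(loglik - prev) <= tol * max(1.0, abs(prev)):
            converged = True
            prev = loglik
            break
        prev = loglik
    return coeffs, resid_var, mixing, prev, trace, converged, tau


def _kmeans_tau(panel: TrajectoryPanel, K: int, seed: int) -> np.ndarray:
    """Initial posterior from k-means on per-patient channel means."""
    with np.errstate(invalid="ignore"):
        feats = np.nanmean(panel.values, axis=1)            # (n, C)
    feats = np.nan_to_num(feats, nan=0.0)
    km = KMeans(n_clusters=K, n_init=3, random_state=seed % (2 ** 31))
    lab = km.fit_predict(feats)
    tau = np.full((len(lab), K), 0.05 / max(K - 1, 1))
    tau[np.arange(len(lab)), lab] = 0.95
    if K == 1:
        tau[:] = 1.0
    return tau / tau.sum(axis=1, keepdims=True)


def fit_gbmtm(panel: TrajectoryPanel, K: int, order: int = 3,
              n_restarts: int = 10, tol: float = 1e-6, max_iter: int = 500,
              seed: int = 0):
    """Fit the mixture by EM with restarts; returns (GBMTMModel, tau).

    Restart 0 initializes from k-means on per-patient channel means; the
    remaining restarts use random Dirichlet posteriors. The restart with
    the best final log-likelihood wins. Restarts where a class collapses
    (effective weight below order+2) are discarded.
    """
    if K < 1 or order < 0:
        raise ValueError("K >= 1 and order >= 0 required")
    if np.any(panel.observed_hours() < 2):
        raise ValueError("every patient needs >= 2 observed hours")
    rng = np.random.default_rng(seed)
    n = panel.n_patients
    best = None
    for r in range(max(n_restarts, 1)):
        if r == 0:
            tau0 = _kmeans_tau(panel, K, seed)
        else:
            tau0 = rng.dirichlet(np.ones(K), size=n)
        out = _em(panel, tau0, K, order, tol, max_iter)
        if out is None:
            log.info("restart %d collapsed; skipping", r)
            continue
        if best is None or out[3] > best[3]:
            best = out
    if best is None:
        raise FitError("all restarts collapsed")
    coeffs, resid_var, mixing, loglik, trace, converged, tau = best
    model = GBMTMModel(K=K, order=order, coeffs=coeffs, resid_var=resid_var,
                       mixing=mixing, loglik=loglik, loglik_trace=trace,
                       converged=converged, n_iter=len(trace), seed=seed,
                       channels=tuple(panel.channels))
    return model, tau


def assign_modal(tau: np.ndarray) -> np.ndarray:
    """Modal class per patient; ties broken toward the lowest class index."""
    labels = np.argmax(tau, axis=1)  # argmax takes the first maximum
    ties = (tau == tau.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.info("%d posterior tie(s) broken toward the lowest class index",
                 int(ties.sum()))
    return labels


def class_mean_curve(model: GBMTMModel, k: int, c: int, hours) -> np.ndarray:
    """Evaluate class k's mean curve for channel c at the given hours."""
    hours = np.asarray(hours, dtype=float)
    if np.any((hours < 0) | (hours > N_HOURS - 1)):
        log.warning("evaluating mean curve outside the fitted 0-11 h window")
    X = time_basis(model.order, hours)
    return X @ model.coeffs[k, c]


def information_criteria(model: GBMTMModel, panel: TrajectoryPanel,
                         tau: np.ndarray) -> dict:
    """AIC, BIC, ICL and normalized classification entropy.

    ICL = BIC + 2 * E with E the total posterior entropy; normalized
    entropy is 1 - E/(N ln K) (1 when classification is hard; reported as
    1 for K=1 where it is undefined).
    """
    N = panel.n_patients
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(tau > 0, tau * np.log(tau), 0.0)
    E = -float(plogp.sum())
    aic = -2.0 * model.loglik + 2.0 * model.n_params
    bic = -2.0 * model.loglik + model.n_params * np.log(N)
    icl = bic + 2.0 * E
    norm_entropy = 1.0 if model.K == 1 else 1.0 - E / (N * np.log(model.K))
    return {"AIC": aic, "BIC": bic, "ICL": icl, "entropy": norm_entropy}
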