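"""Choosing the number of subphenotypes K by consensus clustering.

For each candidate K the cohort is repeatedly subsampled, the mixture model
refit, and pairwise modal co-assignment recorded. Stability is summarized
by the empirical CDF of consensus values, the area under that CDF, the
relative delta-area gain across K, and the per-cluster mean consensus of a
hierarchical clustering of the consensus matrix. Information criteria on
full-data fits are carried as sensitivity evidence only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import gbmtm
from .prep import TrajectoryPanel

log = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    K_range: tuple
    matrices: dict              # K -> (n, n) consensus matrix (NaN undefined)
    co_sample_counts: dict      # K -> (n, n) number of co-samplings
    areas: dict                 # K -> A(K)
    deltas: dict                # K -> delta area
    cluster_consensus: dict     # K -> per-cluster mean consensus array
    consensus_labels: dict      # K -> labels from clustering M_K
    n_resamples: int = 0
    subsample_frac: float = 0.8


@dataclass
class SelectionReport:
    chosen_K: int | None
    criteria: pd.DataFrame
    admissible: list = field(default_factory=list)
    message: str = ""


def consensus_cluster(panel: TrajectoryPanel, K_range=range(2, 7),
                      n_resamples: int = 100, subsample_frac: float = 0.8,
                      fit_opts: dict | None = None, seed: int = 0,
                      retry_cap: int = 3) -> ConsensusResult:
    """Subsample-refit consensus clustering over a range of K."""
    if n_resamples < 2 or not (0.0 < subsample_frac < 1.0):
        raise ValueError("need n_resamples >= 2 and 0 < subsample_frac < 1")
    fit_opts = dict(fit_opts or {})
    fit_opts.setdefault("order", 3)
    fit_opts.setdefault("n_restarts", 3)
    n = panel.n_patients
    m = max(2, int(round(subsample_frac * n)))
    rng = np.random.default_rng(seed)
    K_range = tuple(K_range)

    matrices, counts, areas, deltas, ccons, clabels = {}, {}, {}, {}, {}, {}
    for K in K_range:
        co_assign = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        done = 0
        failures = 0
        while done < n_resamples:
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = TrajectoryPanel(values=panel.values[idx], mask=panel.mask[idx],
                                  patients=panel.patients[idx], stats=panel.stats)
            fit_seed = int(rng.integers(0, 2 ** 31 - 1))
            try:
                model, tau = gbmtm.fit_gbmtm(sub, K=K, seed=fit_seed, **fit_opts)
            except gbmtm.FitError:
                failures += 1
                if failures > retry_cap * n_resamples:
                    raise
                log.warning("resample fit failed (K=%d); redrawing", K)
                continue
            lab = gbmtm.assign_modal(tau)
            co_sample[np.ix_(idx, idx)] += 1.0
            for k in range(K):
                sel = idx[lab == k]
                co_assign[np.ix_(sel, sel)] += 1.0
            done += 1
        with np.errstate(invalid="ignore"):
            M = co_assign / co_sample
        np.fill_diagonal(M, 1.0)
        matrices[K] = M
        counts[K] = co_sample
        areas[K] = consensus_cdf_area(M)
        labels_K = cluster_consensus_matrix(M, K)
        clabels[K] = labels_K
        ccons[K] = per_cluster_mean_consensus(M, labels_K)

    for i, K in enumerate(K_range):
        if i == 0:
            deltas[K] = areas[K]
        else:
            prev = K_range[i - 1]
            deltas[K] = (areas[K] - areas[prev]) / areas[prev] if areas[prev] > 0 \
                else np.inf
    return ConsensusResult(K_range=K_range, matrices=matrices,
                           co_sample_counts=counts, areas=areas, deltas=deltas,
                           cluster_consensus=ccons, consensus_labels=clabels,
                           n_resamples=n_resamples, subsample_frac=subsample_frac)


def consensus_cdf_area(M: np.ndarray, n_bins: int = 100) -> float:
    """Area under the empirical CDF of defined off-diagonal consensus values.

    Standard 100-bin histogram rule on [0, 1]: A = sum over bins of the CDF
    at the bin's upper edge times the bin width.
    """
    iu = np.triu_indices_from(M, k=1)
    vals = M[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined off-diagonal consensus entries")
    hist, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist) / vals.size
    return float(cdf.sum() / n_bins)


def cluster_consensus_matrix(M: np.ndarray, K: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of 1 - M into K clusters."""
    D = 1.0 - np.nan_to_num(M, nan=0.5)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=K, criterion="maxclust") - 1


def per_cluster_mean_consensus(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean of defined within-cluster off-diagonal consensus per cluster."""
    out = []
    for k in np.unique(labels):
        idx = np.nonzero(labels == k)[0]
        if len(idx) < 2:
            out.append(1.0)
            continue
        sub = M[np.ix_(idx, idx)]
        iu = np.triu_indices_from(sub, k=1)
        vals = sub[iu]
        vals = vals[~np.isnan(vals)]
        out.append(float(vals.mean()) if vals.size else 1.0)
    return np.asarray(out)


def select_k(result: ConsensusResult, ic_table: pd.DataFrame | None = None,
             min_share: float = 0.10, elbow_threshold: float = 0.1,
             consensus_threshold: float = 0.8,
             class_share_mode: str = "minimum") -> SelectionReport:
    """Pick K from consensus stability, class-size and delta-area criteria.

    Admissible K require every per-cluster mean consensus above
    ``consensus_threshold`` and the smallest consensus-cluster share at
    least ``min_share`` (``class_share_mode='literal'`` instead requires
    every share at most ``min_share``, the published sentence read
    literally). Among admissible K the delta-area elbow wins: the largest
    K whose relative delta-area gain is at least ``elbow_threshold``; if
    none clears the threshold, the admissible K with the largest gain.
    """
    rows = []
    admissible = []
    n = next(iter(result.matrices.values())).shape[0]
    for K in result.K_range:
        shares = np.bincount(result.consensus_labels[K], minlength=K) / n
        min_cons = float(result.cluster_consensus[K].min())
        if class_share_mode == "literal":
            share_ok = bool(shares.max() <= min_share)
        else:
            share_ok = bool(shares.min() >= min_share)
        ok = (min_cons > consensus_threshold) and share_ok
        if ok:
            admissible.append(K)
        rows.append({"K": K, "area": result.areas[K], "delta": result.deltas[K],
                     "min_cluster_consensus": min_cons,
                     "min_class_share": float(shares.min()),
                     "admissible": ok})
    criteria = pd.DataFrame(rows)
    if ic_table is not None:
        criteria = criteria.merge(ic_table, on="K", how="left",
                                  suffixes=("", "_full_fit"))
    if not admissible:
        return SelectionReport(chosen_K=None, criteria=criteria, admissible=[],
                               message="no admissible K")
    above = [K for K in admissible if result.deltas[K] >= elbow_threshold]
    if above:
        chosen = max(above)
    else:
        chosen = max(admissible, key=lambda K: result.deltas[K])
    return SelectionReport(chosen_K=int(chosen), criteria=criteria,
                           admissible=admissible, message="ok")


def sensitivity_table(panel: TrajectoryPanel, K_range=range(1, 7),
                      fit_opts: dict | None = None, seed: int = 0,
                      return_models: bool = False):
    """Full-data fits per K tabulating AIC/BIC/ICL/entropy and min class share."""
    fit_opts = dict(fit_opts or {})
    fit_opts.setdefault("order", 3)
    fit_opts.setdefault("n_restarts", 3)
    rows, models = [], {}
    for K in K_range:
        try:
            model, tau = gbmtm.fit_gbmtm(panel, K=K, seed=seed, **fit_opts)
        except gbmtm.FitError as exc:
            rows.append({"K": K, "error": str(exc)})
            continue
        ic = gbmtm.information_criteria(model, panel, tau)
        shares = np.bincount(gbmtm.assign_modal(tau), minlength=K) / panel.n_patients
        rows.append({"K": K, "loglik": model.loglik, **ic,
                     "min_class_share": float(shares.min()),
                     "converged": model.converged})
        models[K] = (model, tau)
    table = pd.DataFrame(rows)
    return (table, models) if return_models else table
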