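"""MSE-based subphenotype assignment and early (truncated-window) prediction.

External or truncated-window patients are labeled by the mixture component
whose class mean curves minimize the mean squared error over the patient's
observed cells; early-prediction accuracy is the percent agreement between
assignments from the first H hours and from the full 12-hour window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gbmtm import GBMTMModel, time_basis
from .prep import TrajectoryPanel
from .synthetic import CHANNELS as CHANNELS_ORDER
from .synthetic import N_HOURS

log = logging.getLogger(__name__)


@dataclass
class MSETable:
    mse: pd.DataFrame           # index patient_id, one column per class
    assigned: pd.Series         # class index per patient
    margin: pd.Series           # second-best minus best MSE
    excluded: list              # patient ids with zero observed hours


def assign_by_mse(model: GBMTMModel, panel: TrajectoryPanel) -> MSETable:
    """Assign each patient to the class with the lowest trajectory MSE.

    MSE[i][k] averages (y_ihc - mu_kc(h))^2 over the patient's observed
    cells only; the panel must be standardized on the model's scale. Ties
    go to the lower class index. Patients with no observed hours are
    excluded and reported.
    """
    X = time_basis(model.order)
    mu = np.einsum("hp,kcp->khc", X, model.coeffs)          # (K, H, C)
    W = panel.mask.astype(float)
    n_cells = W.sum(axis=1) * panel.values.shape[2]
    K = model.K
    mse = np.full((panel.n_patients, K), np.nan)
    for k in range(K):
        r2 = np.nan_to_num((panel.values - mu[k]) ** 2, nan=0.0) * W[:, :, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            mse[:, k] = r2.sum(axis=(1, 2)) / n_cells
    ok = n_cells > 0
    excluded = list(panel.patients[~ok])
    if excluded:
        log.warning("%d patient(s) with no observed hours excluded", len(excluded))
    mse_df = pd.DataFrame(mse[ok], index=pd.Index(panel.patients[ok],
                                                  name="patient_id"),
                          columns=[f"class_{k}" for k in range(K)])
    arr = mse_df.to_numpy()
    assigned = pd.Series(np.argmin(arr, axis=1), index=mse_df.index,
                         name="assigned")
    ties = (arr == arr.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.info("%d MSE tie(s) broken toward the lowest class index",
                 int(ties.sum()))
    srt = np.sort(arr, axis=1)
    margin = pd.Series(srt[:, 1] - srt[:, 0] if K > 1 else np.zeros(len(arr)),
                       index=mse_df.index, name="margin")
    return MSETable(mse=mse_df, assigned=assigned, margin=margin,
                    excluded=excluded)


def truncate_hours(panel: TrajectoryPanel, H: int):
    """Mask hours >= H; returns (panel, flagged ids with < 2 remaining hours)."""
    if not (1 <= H <= N_HOURS):
        raise ValueError("H must lie in 1..12")
    out = panel.copy()
    out.mask[:, H:] = False
    out.values[:, H:, :] = np.nan
    flagged = list(out.patients[out.observed_hours() < 2])
    return out, flagged


def early_agreement(model: GBMTMModel, panel: TrajectoryPanel, H: int):
    """Fraction of patients whose H-hour MSE label equals their 12-hour label.

    Patients flagged at truncation (fewer than 2 remaining observed hours)
    are excluded from the denominator; their count is returned.
    """
    if not (6 <= H <= N_HOURS):
        raise ValueError("H must lie in 6..12")
    full = assign_by_mse(model, panel)
    trunc_panel, flagged = truncate_hours(panel, H)
    keep = ~np.isin(panel.patients, flagged)
    sub = TrajectoryPanel(values=trunc_panel.values[keep],
                          mask=trunc_panel.mask[keep],
                          patients=trunc_panel.patients[keep],
                          stats=panel.stats)
    early = assign_by_mse(model, sub)
    common = early.assigned.index.intersection(full.assigned.index)
    if len(common) == 0:
        raise ValueError("no patients left after truncation")
    agree = float((early.assigned.loc[common] == full.assigned.loc[common]).mean())
    return agree, len(flagged)


def match_classes_to_templates(model: GBMTMModel, stats, templates) -> dict:
    """Map fitted class index -> generator class letter by mean-curve distance.

    Template curves are mapped from the generator's standardized scale to
    the panel's pooled z-score scale (via the z-scoring ``stats``) before
    comparison; the match minimizes total squared curve distance over all
    class pairings. Only meaningful for synthetic cohorts, where the
    generating templates are known.
    """
    from scipy.optimize import linear_sum_assignment

    from .synthetic import CHANNEL_STATS, template_curves

    X = time_basis(model.order)
    fitted = np.einsum("hp,kcp->khc", X, model.coeffs)
    tmpl_std = template_curves(np.asarray(templates))
    nat_mean = np.array([CHANNEL_STATS[c][0] for c in CHANNELS_ORDER])
    nat_sd = np.array([CHANNEL_STATS[c][1] for c in CHANNELS_ORDER])
    tmpl_panel = (nat_mean + nat_sd * tmpl_std
                  - stats["mean"].to_numpy(dtype=float)) \
        / stats["sd"].to_numpy(dtype=float)
    cost = ((fitted[:, None] - tmpl_panel[None, :]) ** 2).sum(axis=(2, 3))
    rows, cols = linear_sum_assignment(cost)
    return {int(r): "ABCD"[c] for r, c in zip(rows, cols)}


def agreement_by_hours(model: GBMTMModel, panel: TrajectoryPanel,
                       hours=range(6, 13)) -> pd.DataFrame:
    rows = [{"H": H, **dict(zip(("agreement", "n_flagged"),
                                early_agreement(model, panel, H)))}
            for H in hours]
    return pd.DataFrame(rows)
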