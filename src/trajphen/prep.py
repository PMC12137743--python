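"""Raw vital-sign observations -> standardized 12-hour trajectory panel.

Fixed pipeline order: hourly aggregation, complete-hour filtering,
cohort inclusion rules, pooled per-channel z-scoring. No imputation is
performed here: any hour missing one of the five vitals is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CHANNELS, N_HOURS

log = logging.getLogger(__name__)


class InputError(ValueError):
    pass


@dataclass
class TrajectoryPanel:
    """Per-patient hour x channel matrices with an observed-hour mask.

    values has shape (n_patients, 12, 5); unobserved cells are NaN. An hour
    counts as observed only once the complete-hour filter has required all
    five channels. ``stats`` holds the per-channel mean/SD used for
    z-scoring (None while unstandardized).
    """

    values: np.ndarray
    mask: np.ndarray            # (n, 12) bool
    patients: np.ndarray        # patient ids, aligned with axis 0
    stats: pd.DataFrame | None = None
    channels: tuple = field(default=CHANNELS)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def observed_hours(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    def copy(self) -> "TrajectoryPanel":
        return TrajectoryPanel(self.values.copy(), self.mask.copy(),
                               self.patients.copy(),
                               None if self.stats is None else self.stats.copy(),
                               self.channels)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (patient, hour, channel, value) table of observed cells."""
        i, h = np.nonzero(self.mask)
        n = len(i)
        return pd.DataFrame({
            "patient_id": np.repeat(self.patients[i], 5),
            "hour": np.repeat(h, 5),
            "channel": np.tile(list(self.channels), n),
            "value": self.values[i, h, :].reshape(-1),
        })


def fahrenheit_to_celsius(values):
    return (np.asarray(values, dtype=float) - 32.0) * 5.0 / 9.0


def hourly_aggregate(records: pd.DataFrame,
                     temp_in_fahrenheit: bool = False) -> TrajectoryPanel:
    """Bin observations into half-open hours [h, h+1) and average within bins.

    Accepts a long table with columns patient_id, channel, value and a time
    column named either ``time_from_admission`` (hours since ICU admission)
    or ``hour``. Times at or beyond 12 h are ignored.
    """
    df = records.copy()
    tcol = "time_from_admission" if "time_from_admission" in df.columns else "hour"
    if tcol not in df.columns:
        raise InputError("need a time_from_admission or hour column")
    unknown = set(df["channel"].unique()) - set(CHANNELS)
    if unknown:
        raise InputError(f"unknown channel(s): {sorted(unknown)}")
    if temp_in_fahrenheit:
        is_t = df["channel"] == "TEMP"
        df.loc[is_t, "value"] = fahrenheit_to_celsius(df.loc[is_t, "value"])
    df["hour_bin"] = np.floor(df[tcol].to_numpy(dtype=float)).astype(int)
    df = df[(df["hour_bin"] >= 0) & (df["hour_bin"] < N_HOURS)]

    agg = df.groupby(["patient_id", "hour_bin", "channel"], sort=True)[
        "value"].mean().reset_index()
    patients = np.asarray(sorted(df["patient_id"].unique()))
    pcode = pd.Categorical(agg["patient_id"], categories=patients).codes
    ccode = pd.Categorical(agg["channel"], categories=list(CHANNELS)).codes
    values = np.full((len(patients), N_HOURS, 5), np.nan)
    values[pcode, agg["hour_bin"].to_numpy(), ccode] = agg["value"].to_numpy()
    mask = ~np.isnan(values).any(axis=2)  # provisional; finalized by the filter
    return TrajectoryPanel(values=values, mask=mask, patients=patients)


def filter_complete_hours(panel: TrajectoryPanel) -> TrajectoryPanel:
    """Keep only hours where all five channels are present; blank the rest."""
    out = panel.copy()
    complete = ~np.isnan(out.values).any(axis=2)
    out.values[~complete] = np.nan
    out.mask = complete
    return out


def apply_inclusion(panel: TrajectoryPanel, baseline: pd.DataFrame,
                    min_age: float = 18.0, min_los_hours: float = 24.0,
                    min_hours: int = 2):
    """Apply cohort eligibility in fixed order; returns (panel, report).

    Order: first ICU stay only, age >= 18, ICU LOS >= 24 h, >= 2 observed
    hours. Patients missing age or LOS are excluded with their own reason.
    The report counts exclusions per reason in application order.
    """
    base = baseline.set_index("patient_id")
    keep = pd.Series(True, index=pd.Index(panel.patients))
    counts = {}

    def drop(mask_bad: pd.Series, reason: str):
        bad = keep & mask_bad
        counts[reason] = int(bad.sum())
        keep[bad] = False

    in_base = keep.index.isin(base.index)
    drop(pd.Series(~in_base, index=keep.index), "not in baseline table")

    def col(name):
        s = base.reindex(keep.index)[name]
        return s

    if "admission_ordinal" in base.columns:
        ordv = col("admission_ordinal")
        drop(ordv.notna() & (ordv > 1), "not first ICU stay")
    age = col("age")
    los = col("icu_los_hours")
    drop(pd.Series(in_base, index=keep.index) & (age.isna() | los.isna()),
         "missing eligibility field")
    drop(age < min_age, "age under 18")
    drop(los < min_los_hours, "ICU LOS under 24 h")
    nhours = pd.Series(panel.observed_hours(), index=keep.index)
    drop(nhours < min_hours, "fewer than 2 observed hours")

    sel = keep.to_numpy()
    out = TrajectoryPanel(values=panel.values[sel], mask=panel.mask[sel],
                          patients=panel.patients[sel], stats=panel.stats)
    report = pd.DataFrame({"reason": list(counts), "n_excluded": list(counts.values())})
    report.loc[len(report)] = ["retained", int(sel.sum())]
    return out, report


def zscore(panel: TrajectoryPanel, stats: pd.DataFrame | None = None):
    """Z-score each channel pooling all patients and hours; returns (panel, stats).

    When ``stats`` is given (e.g. development-cohort statistics applied to a
    validation cohort) it is used unchanged.
    """
    out = panel.copy()
    if stats is None:
        means, sds = [], []
        for c in range(5):
            col = panel.values[:, :, c][panel.mask]
            if col.size < 2:
                raise InputError("need >= 2 observed cells per channel")
            means.append(float(np.mean(col)))
            sds.append(float(np.std(col, ddof=0)))
        stats = pd.DataFrame({"channel": list(panel.channels),
                              "mean": means, "sd": sds})
    sd = stats["sd"].to_numpy(dtype=float)
    if np.any(sd == 0):
        ch = stats.loc[sd == 0, "channel"].tolist()
        raise InputError(f"degenerate channel (zero SD): {ch}")
    mean = stats["mean"].to_numpy(dtype=float)
    out.values = (panel.values - mean) / sd
    out.values[~np.isfinite(out.values)] = np.nan
    out.values[~out.mask] = np.nan
    out.stats = stats
    return out, stats


def inverse_zscore(panel: TrajectoryPanel) -> TrajectoryPanel:
    """Undo z-scoring using the stats stored on the panel."""
    if panel.stats is None:
        raise InputError("panel carries no standardization stats")
    out = panel.copy()
    mean = panel.stats["mean"].to_numpy(dtype=float)
    sd = panel.stats["sd"].to_numpy(dtype=float)
    out.values = panel.values * sd + mean
    out.stats = None
    return out


def prepare(records: pd.DataFrame, baseline: pd.DataFrame,
            stats: pd.DataFrame | None = None):
    """Full preparation pipeline; returns (panel, stats, exclusion_report)."""
    panel = hourly_aggregate(records)
    panel = filter_complete_hours(panel)
    panel, report = apply_inclusion(panel, baseline)
    panel, stats = zscore(panel, stats)
    return panel, stats, report
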