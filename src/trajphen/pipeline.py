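"""End-to-end study orchestration with a reproducibility manifest.

Stage order: simulate -> prep -> select-k -> fit -> assign -> outcomes ->
treatment. Each stage reads only prior-stage outputs from the artifact
directory; a single global seed is expanded deterministically into
per-stage seeds; the manifest records the config hash, per-stage seeds and
SHA-256 checksums of every written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment, gbmtm, outcomes, selection, treatment
from .prep import prepare
from .synthetic import GeneratorConfig, generate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "select_k", "fit", "assign", "outcomes",
          "treatment")

DEFAULT_CONFIG = {
    "n_patients": 800,
    "seed": 1,
    "missing_rate": 0.0,
    "k_min": 2,
    "k_max": 5,
    "n_resamples": 30,
    "subsample_frac": 0.8,
    "order": 3,
    "n_restarts": 5,
    "resample_restarts": 2,
    "pdp_background_sample": 400,
    "rf_param_grid": {"n_estimators": [200], "max_depth": [6, 10],
                      "min_samples_leaf": [5, 20]},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_seeds(global_seed: int) -> dict:
    """Expand one global seed into stable per-stage integers below 2**31."""
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


def run_pipeline(config: dict | None = None, out_dir="results/run") -> dict:
    """Run the full study on a synthetic cohort; returns the manifest dict."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(int(cfg["seed"]))
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seeds": seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "files": {},
    }

    def record(stage, *paths):
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
        _write_manifest(out, manifest)

    try:
        # --- simulate ------------------------------------------------------
        gen = GeneratorConfig(n_patients=int(cfg["n_patients"]),
                              missing_rate=float(cfg["missing_rate"]),
                              seed=seeds["simulate"])
        cohort = generate_cohort(gen)
        paths = []
        for name, df in [("vitals", cohort.raw_vitals),
                         ("baseline", cohort.baseline),
                         ("survival", cohort.survival),
                         ("fluids", cohort.fluids),
                         ("truth", cohort.truth_labels.reset_index())]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        record("simulate", *paths)

        # --- prep ----------------------------------------------------------
        panel, stats, excl = prepare(cohort.raw_vitals, cohort.baseline)
        p_panel, p_stats, p_excl = (out / "panel.csv", out / "zscore_stats.csv",
                                    out / "exclusions.csv")
        panel.to_frame().to_csv(p_panel, index=False)
        stats.to_csv(p_stats, index=False)
        excl.to_csv(p_excl, index=False)
        record("prep", p_panel, p_stats, p_excl)

        # --- select K ------------------------------------------------------
        k_range = range(int(cfg["k_min"]), int(cfg["k_max"]) + 1)
        cons = selection.consensus_cluster(
            panel, K_range=k_range, n_resamples=int(cfg["n_resamples"]),
            subsample_frac=float(cfg["subsample_frac"]),
            fit_opts={"order": int(cfg["order"]),
                      "n_restarts": int(cfg["resample_restarts"])},
            seed=seeds["select_k"])
        ic = selection.sensitivity_table(
            panel, K_range=k_range,
            fit_opts={"order": int(cfg["order"]), "n_restarts": 2},
            seed=seeds["select_k"])
        report = selection.select_k(cons, ic_table=ic)
        p_crit = out / "selection_criteria.csv"
        report.criteria.to_csv(p_crit, index=False)
        mats = []
        for K in cons.K_range:
            p_m = out / f"consensus_K{K}.csv"
            pd.DataFrame(cons.matrices[K]).to_csv(p_m, index=False)
            mats.append(p_m)
        if report.chosen_K is None:
            raise RuntimeError("no admissible K")
        manifest["chosen_K"] = report.chosen_K
        record("select_k", p_crit, *mats)

        # --- fit final model -------------------------------------------------
        model, tau = gbmtm.fit_gbmtm(panel, K=report.chosen_K,
                                     order=int(cfg["order"]),
                                     n_restarts=int(cfg["n_restarts"]),
                                     seed=seeds["fit"])
        p_model = out / "model.json"
        model.to_json(p_model)
        p_tau = out / "posteriors.csv"
        pd.DataFrame(tau, index=panel.patients).to_csv(p_tau)
        record("fit", p_model, p_tau)

        # --- assign + early agreement ---------------------------------------
        mse = assignment.assign_by_mse(model, panel)
        p_mse = out / "mse_assignment.csv"
        mse.mse.assign(assigned=mse.assigned, margin=mse.margin).to_csv(p_mse)
        agree = assignment.agreement_by_hours(model, panel)
        p_agree = out / "early_agreement.csv"
        agree.to_csv(p_agree, index=False)
        record("assign", p_mse, p_agree)

        # --- outcomes --------------------------------------------------------
        # map fitted class indices to template letters so that phenotype
        # labels in downstream tables carry their clinical meaning
        mapping = assignment.match_classes_to_templates(
            model, stats, gen.class_templates)
        labels = pd.Series(
            np.array([mapping[v] for v in mse.assigned]),
            index=mse.assigned.index, name="phenotype")
        surv = cohort.survival.set_index("patient_id")
        surv = surv.drop(columns=["phenotype"]).join(labels, how="inner")
        surv = surv.reset_index()
        table1 = outcomes.describe_by_phenotype(
            cohort.baseline, labels, continuous=("age", "icu_los_hours"),
            categorical=("gender",))
        pvals = outcomes.compare_groups(
            cohort.baseline, labels, continuous=("age",),
            categorical=("gender",))
        crude = outcomes.fit_cox(surv, covariates=())
        adjusted = outcomes.fit_cox(surv, covariates=("age", "gender", "race"))
        km = outcomes.adjusted_km(surv)
        paths = []
        for name, df in [("table1", table1), ("group_tests", pvals),
                         ("cox_crude", crude), ("cox_adjusted", adjusted),
                         ("adjusted_km", km)]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=(name == "adjusted_km"))
            paths.append(p)
        record("outcomes", *paths)

        # --- treatment -------------------------------------------------------
        treat = cohort.fluids.set_index("patient_id").join(
            cohort.baseline.set_index("patient_id")[["age", "gender"]]).join(
            labels, how="inner")
        feats = treat[["day1_ml", "day2_ml", "age"]].copy()
        feats["male"] = (treat["gender"] == "Male").astype(float)
        rfs = treatment.fit_rf_per_phenotype(
            feats, treat["icu_death"], treat["phenotype"],
            param_grid=cfg["rf_param_grid"], seed=seeds["treatment"])
        rows, pd_paths = [], []
        for g, fitres in rfs.items():
            surf = treatment.pdp_2d(
                fitres.model, feats.loc[treat["phenotype"] == g],
                background_sample=int(cfg["pdp_background_sample"]),
                seed=seeds["treatment"])
            surf = treatment.risk_strata(surf)
            try:
                rng_box = treatment.lowest_risk_range(surf)
            except ValueError:
                rng_box = (np.nan,) * 4
            p_s = out / f"pdp_{g}.csv"
            pd.DataFrame(surf.pd_values, index=surf.grid1,
                         columns=surf.grid2).to_csv(p_s)
            pd_paths.append(p_s)
            rows.append({"phenotype": g, "cv_auc": fitres.cv_auc,
                         "n": fitres.n, "n_deaths": fitres.n_deaths,
                         "day1_lo": rng_box[0], "day1_hi": rng_box[1],
                         "day2_lo": rng_box[2], "day2_hi": rng_box[3]})
        ringer = treatment.ringer_cox(surv)  # survival table carries ringer
        p_tr = out / "treatment_summary.csv"
        pd.DataFrame(rows).to_csv(p_tr, index=False)
        p_ring = out / "ringer_cox.csv"
        ringer.to_csv(p_ring, index=False)
        record("treatment", p_tr, p_ring, *pd_paths)
    except Exception as exc:
        manifest["error"] = str(exc)
        _write_manifest(out, manifest)
        raise
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
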