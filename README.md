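# trajphen

Data-driven subphenotyping of ICU patients with acute pancreatitis (AP)
from the first 12 hours of routine vital signs, with downstream prognosis
contrasts and phenotype-specific fluid-resuscitation response surfaces.

Severe AP is biologically heterogeneous: some patients present
hyperinflammatory (febrile, tachycardic, tachypneic), others hypertensive,
hypotensive, or hypoinflammatory — and these groups differ sharply in
30-day mortality and in how they respond to early fluid therapy. This
package is for biostatisticians and critical-care researchers who want to
(a) derive such trajectory-based subphenotypes from long-format vital-sign
tables, (b) validate the number of classes, (c) assign new or
early-window patients, and (d) quantify outcome and treatment-response
differences — or to study all of the above on a fully synthetic,
truth-known cohort.

## The model

Patient trajectories are modeled by a **group-based multi-trajectory
model** (GBMTM): a finite mixture over patients in which latent class
*k* defines one polynomial mean curve per vital-sign channel
(SBP, DBP, heart rate, respiratory rate, temperature),

    y_ihc | class k  ~  N( Σ_j β_kcj (h/11)^j ,  σ²_kc ),     π_k = P(class k),

fitted by EM on z-scored hourly data (hours missing any channel are
dropped, never imputed). The number of classes K is chosen by
**longitudinal consensus clustering** — subsample, refit, record pairwise
co-assignment — requiring per-cluster mean consensus > 0.8 and a minimum
class share of 10%, with the delta-area elbow of the consensus-CDF area
picking K among admissible values; AIC/BIC/ICL/entropy accompany the
choice as sensitivity evidence. New patients are assigned by lowest
**mean squared error** against class mean curves, which also yields
early-prediction agreement for 6–12-hour windows. Prognosis uses crude
and demographics-adjusted **Cox** models plus direct-adjusted
Kaplan–Meier curves; treatment response uses per-phenotype **random
forests** with two-predictor **partial-dependence** surfaces over day-1 ×
day-2 fluid intake, decile risk strata, lowest-risk fluid ranges, and an
adjusted Cox contrast for lactated Ringer's. See `docs/methods.md` for
the full specification.

A calibrated synthetic-cohort generator (`trajphen.synthetic`) reproduces
the published study conditions — class shares (14.1, 17.6, 27.0, 41.2)%,
adjusted hazard ratios 3.38 / 1.87 / 0.77 vs the hypertensive class,
a protective Ringer's hazard ratio of 0.48 in the hypotensive class, and
class-specific fluid-risk bowls centered on the published lowest-risk
ranges — so every stage can be tested against known truth.

## Worked example

Run the whole study end to end on the default synthetic demo cohort
(n = 800, K scanned over 2–5 with 30 consensus resamples; ~2 min on one
core):

```bash
trajphen run --out results/demo
```

which logs each stage and prints

```
{"chosen_K": 4, "stages": {"simulate": "ok", "prep": "ok", "select_k": "ok",
 "fit": "ok", "assign": "ok", "outcomes": "ok", "treatment": "ok"}}
```

Consensus clustering picks **K = 4** (delta-area 0.125 at K = 4 with
per-cluster mean consensus 1.0; at K = 5 the gain drops to 0.077 and the
weakest cluster's consensus to 0.75). `results/demo/cox_adjusted.csv`
holds the demographics-adjusted 30-day mortality contrasts against the
hypertensive phenotype B — on this run

```
A vs B   HR 13.95 (95% CI 3.30–59.06)
C vs B   HR  4.41 (95% CI 0.99–19.56)
D vs B   HR  3.56 (95% CI 0.81–15.62)
```

i.e. the hyperinflammatory class carries by far the highest risk (the
wide intervals reflect the demo cohort's 50-odd deaths; the recovery
tests at n = 20 000 reproduce the generating ratios to a few percent).
`early_agreement.csv` shows that 6-hour windows already agree perfectly
with the 12-hour assignment on this well-separated cohort, and
`treatment_summary.csv` lists per-phenotype cross-validated AUROC
(0.66–0.71 here) with each phenotype's recovered lowest-risk fluid box —
e.g. day-1 3000–5100 mL for the hyperinflammatory class, whose generating
optimum is 4200 mL.

Every artifact is a plain delimited table; `manifest.json` records
per-stage seeds and SHA-256 checksums, and rerunning the same
configuration reproduces identical files.

The same pieces are available as a library:

```python
import trajphen as tp

cohort = tp.generate_cohort(tp.GeneratorConfig(n_patients=2000, seed=7))
panel, stats, report = tp.prepare(cohort.raw_vitals, cohort.baseline)
model, tau = tp.fit_gbmtm(panel, K=4, order=3, n_restarts=10, seed=7)
labels = tp.assign_modal(tau)
```

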