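# gdrecon

Analysis toolkit for **γδ T-cell immune reconstitution after pediatric
allogeneic hematopoietic stem-cell transplantation (HSCT)**.

After a transplant the T-cell compartment rebuilds over months. Absolute
counts of CD3/CD4/CD8, TCRαβ and TCRγδ cells — and the γδ subsets Vδ1,
Vδ2 and non-Vδ1-non-Vδ2 — are measured by flow cytometry on a fixed
schedule (days +15, +30, +60, +100, +180, +240). Clinicians want to know
whether patients who rebuild certain subsets quickly ("high recoverers")
fare better with respect to acute Graft-versus-Host disease (aGvHD) and
viral infections (EBV, CMV, ADV). `gdrecon` implements that analysis as a
reusable, tested pipeline, together with a synthetic-cohort generator so
every stage is exercised without patient data.

## The statistic at the core

Per patient and subset *s*, the **time-averaged relative abundance**

&nbsp;&nbsp;&nbsp;&nbsp;R = (1 / (t_last − t_first)) ∫ s(t) / αβ(t) dt

is the trapezoidal integral of the subset/TCRαβ count ratio over the
post-transplant sampling days, skipping aplastic timepoints (αβ < 1
cell/µl). Patients are ranked by R and dichotomized at the cut that
maximizes a distance-based **ω² effect size**: each patient becomes a
pair (min–max scaled R, min–max scaled rank), pairwise weighted (Ružička)
Jaccard distances d = 1 − Σmin/Σmax are computed, and every admissible
split of the ranked sequence is scored with a PERMANOVA-style

&nbsp;&nbsp;&nbsp;&nbsp;ω² = max(0, (SS_between − MS_within) / (SS_total + MS_within)).

The split is outcome-blind. Downstream, the pipeline runs Wilcoxon
rank-sum / Kruskal–Wallis / Spearman screens with Cliff's δ effect sizes,
Benjamini–Hochberg correction (q < 0.1), a Gaussian likelihood-ratio
confounder screen (`response ~ focal` vs `+ candidate + interaction`),
Aalen–Johansen cumulative incidence with death as a competing risk, Cox
regression (Breslow ties, Newton–Raphson), and log-rank tests.

## Worked example

```sh
gdrecon simulate --seed 3 --out cohort/
gdrecon stratify --patients cohort/patients.csv --panels cohort/panels.csv \
    --outcomes cohort/outcomes.csv --out strat/
gdrecon outcomes --patients cohort/patients.csv --panels cohort/panels.csv \
    --outcomes cohort/outcomes.csv --split-file strat/splits.json \
    --subset vd2 --outcome ebv --out out/
```

prints

```
wrote 49-patient cohort to cohort/
wrote splits to strat
log-rank p = 0.01422; wrote results to out
```

i.e. in this synthetic replicate the patients stratified as high-Vδ2
recoverers have a significantly lower cumulative incidence of EBV
infection than the low-Vδ2 stratum (log-rank p ≈ 0.02) — the protective
direction the generator plants. `out/cif_vd2_ebv_{low,high}.csv` holds
the two incidence step functions and `out/outcome_vd2_ebv.json` the Cox
hazard ratio with its confidence interval. The same library calls are
available in Python:

```python
from gdrecon import GeneratorConfig, generate_cohort, stratify_cohort, outcome_by_stratum
cohort = generate_cohort(GeneratorConfig(), seed=3)
split = stratify_cohort(cohort, subsets=("vd2",))["vd2"]
res = outcome_by_stratum(cohort, split, "ebv")
print(res.logrank_p, res.cox.hr)
```

`gdrecon run-all --seed 1 --out bundle/` runs every stage (validation,
summaries, abundance, stratification, association matrices per scope,
five outcome analyses per subset) and writes a deterministic CSV/JSON
bundle with a provenance record.

## Layout

| module | contents |
|---|---|
| `gdrecon.cohort` | data model, CSV readers/writers, structural validation |
| `gdrecon.simulate` | synthetic cohort generator (study conditions as defaults) |
| `gdrecon.reconstitution` | summaries, time-averaged abundance R, log Vδ2/Vδ1 |
| `gdrecon.stratify` | weighted Jaccard, distance-based ω², cut-off search |
| `gdrecon.association` | rank tests, Cliff's δ, BH, confounder LRT, matrices |
| `gdrecon.outcomes` | Aalen–Johansen CIF, Cox fit, log-rank, per-stratum bundles |
| `gdrecon.pipeline` / `gdrecon.cli` | orchestration and the `gdrecon` command |

See `docs/methods.md` for the statistical model, generator assumptions
and design choices.
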