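# hfrtrends

Temporal and spatial trend analysis of halogenated flame retardants (HFRs)
in wildlife-egg biomonitoring data.

Long-running egg-monitoring programs — here modelled on the Canadian
herring gull (*Larus argentatus/smithsonianus*) programs, 17 colonies in
four regions, 2008–2023 — measure pooled-egg concentrations of PBDE
congeners, HBCDD and Dechlorane Plus to ask whether regulatory action
(nomination and listing under Annex A of the Stockholm Convention) is
followed by declining concentrations. `hfrtrends` implements that analysis
as a tested, reusable library for ecotoxicologists and monitoring
programs:

* **Censored-data handling** — below-detection-limit values imputed by
  left-censored log-normal maximum likelihood with plotting-position
  quantile replacements ranked by a co-detected reference analyte, with
  the 50%-detection zero rule.
* **Aggregation** — congener sums with a data-driven 3% detection rule
  (Σ₁₁PBDE; BDE-209 kept separate), annual arithmetic means, ln
  transform, Ryder egg volume (v = 0.489·l·d²), Pearson/Spearman
  covariate screening.
* **Segmented trends** — per colony × class, ln mean vs year with one
  estimated breakpoint ψ:

      y_t = β₀ + β₁·t + δ·(t − ψ)₊ + ε_t

  fitted by iterative linearisation plus an exact per-interval profile
  (global least squares), with a calibrated supremum (Davies-bound) test
  gating breakpoint retention and a linear fallback.
* **Milestone classification** — each fit labelled IT / LI / NI / EI /
  CT / NS against the class's nomination and listing years; ln slopes
  reported as percent annual change, (e^β − 1)×100.
* **Regional mixed model** — y_ijk = β₀ + β_region(i) + u_ij + v_k + ε_ijk
  with sum-to-zero region contrasts, colony-within-region and crossed
  year random intercepts, REML variance components, Satterthwaite-df
  region F test, ML likelihood-ratio test, and back-transformed regional
  marginal means.
* **Synthetic data** — a first-class generator reproducing the sampling
  design (alternate-year chemistry, 1–5 pools per colony-year, 2–15 eggs
  per pool, year-varying detection limits) with known ground truth, so
  every stage is testable without access to the raw monitoring data.

See `docs/methods.md` for the full model descriptions, defaults and
numerical choices.

## Worked example

Fit and label a single colony series (from `examples/03_segmented_trends.py`):

```python
import numpy as np
from hfrtrends.segmented import select_trend_fit

rng = np.random.default_rng(3)
years = np.arange(2008, 2022)
truth = np.where(years <= 2015, 2.0 + 0.30 * (years - 2008),
                 2.0 + 0.30 * 7 - 0.20 * (years - 2015))
fit = select_trend_fit(years, truth + rng.normal(0, 0.10, years.size))
```

prints

```
fit type:        segmented   (segmented: improves AIC and slope-change test significant)
breakpoint year: 2015.5 +- 0.34
slope before:    +0.282 +- 0.025 ln-units/yr  (~33%/yr)
slope after:     -0.230 +- 0.038 ln-units/yr  (~21%/yr)
t (first slope): 11.37, p = 0.0000
```

i.e. the fit recovers the generating breakpoint (2015) to within a year
and both slopes within sampling error; on the concentration scale the
series rose ≈33%/yr and then fell ≈21%/yr. Classifying the 68 published
colony × class fits bundled with the package
(`examples/04_milestone_classification.py`):

```
comparisons:                 68
labels reproduced:           100%
stable (no significant fit): 51 (75%)
consistent declines:         9
declines by class:           {'HBCDD': 2, 'Sum11PBDE': 3, 'BDE209': 2, 'SumDP': 2}
```

Each example in `examples/` is a short narrative script for one
capability: simulation, imputation, trend fitting, classification, and
the regional mixed model.

## Command line

The same stages are available as a thin CLI:

```sh
hfrtrends all --seed 5 --out-dir out/            # synthetic end-to-end
hfrtrends classify --mode user-data --config my.yaml
```

writing `measurements.csv`, `class_series.csv`, `trends.csv`,
`trend_labels.csv`, `lmm_summary.csv` and `tallies.json`, byte-identical
under a fixed seed. Exit codes: 0 ok, 1 stage failure, 2 config error.

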