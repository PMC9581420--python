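# urbanbirds

Statistical machinery for asking how a point feature of the urban
landscape — here, restaurants, as a proxy for predictable anthropogenic
food — shapes bird communities surveyed by repeated point counts, while
controlling for land cover and general urbanisation. The package provides
the full inference chain as reusable, tested components:

* **Ingestion**: detection filtering (flyovers out; heard-only out of
  abundance), 1-km buffer counts of businesses/restaurants around survey
  points, data-driven merging of collinear land-cover categories
  (Spearman rho > 0.7), z-scoring, and the four season responses —
  richness, total abundance, per-species presence and mean abundance —
  under an "observed on two or more visits" inclusion rule.
* **Random-intercept GLMMs** (`MixedGLM`): gaussian, binomial and Poisson
  families with a site random intercept, fit by maximum likelihood
  (Laplace approximation for the non-gaussian families), statsmodels-style
  `fit()` -> results object with coefficients, SEs, log-likelihood, AIC.
* **All-subsets model selection** (`AllSubsetsGLMM`): every fixed-effect
  subset of a global model, AIC ranking and Akaike weights, conditional
  model averaging over the ΔAIC ≤ 2 top set, per-term relative importance
  (RI), and a Monte-Carlo **null calibration** of RI — the response is
  replaced by i.i.d. draws 100 times and the mean of the per-iteration
  maximum RI becomes the threshold below which a term is treated as
  uninformative.
* **Community statistics**: Sørensen/Jaccard presence-absence
  dissimilarity, MRPP with per-site-year turnover scores, PERMANOVA,
  multivariate dispersion, non-metric MDS (stress-1, Shepard fit), and
  none/low/high restaurant strata.
* **A synthetic-study generator** that emulates the survey design
  (57 sites × 3 years × 2 seasons, ~24 species, restaurants as a noisy
  thinning of businesses with rank correlation ≈ 0.59) with known ground
  truth, so every stage is testable end to end.

The model behind the species-level analyses is, per species and season,

    g(E[y_ij]) = β0 + β_R·z(Restaurants_ij) + β_B·z(Businesses_ij)
                 + Σ_c β_c·z(LULC_c,ij) + β_Y·z(Year_j) + u_i,
    u_i ~ N(0, σ_u²),

with a logit link for presence and a log link for abundance, and the same
structure (identity link) for site-level community turnover.

## Worked example

```python
import numpy as np
from urbanbirds import (SyntheticConfig, generate_landscape,
                        generate_community, AllSubsetsGLMM, calibrate_null,
                        decide_meaningful)
from urbanbirds import ingest

cfg = SyntheticConfig(seed=7)                      # 57 sites, 3 years
cov = generate_landscape(cfg)
records, visits, truth = generate_community(cfg, cov)

filtered = ingest.filter_detections(records, purpose="presence")
responses = ingest.build_responses(filtered, visits=visits)
frame, _ = ingest.build_modeling_frame(
    responses[responses.season == "spring"], cov.drop(columns=["x", "y"]))

terms = ["restaurant_count", "business_count", "residential",
         "highly_developed", "natural_vegetation", "year_num"]
frame["abund_rock_pigeon"] = np.round(frame["abund_rock_pigeon"])
sel = AllSubsetsGLMM(frame, "abund_rock_pigeon", terms, "site_id", "poisson")
results = sel.fit()                                 # 64 subset fits
averaged = results.average(delta_cutoff=2.0)
print(averaged.summary())
cal = calibrate_null(sel, "species_abundance", n_iter=100, seed=1)
print(decide_meaningful(averaged, cal)[["display", "threshold"]])
```

prints:

```
Conditional model averaging over 6 models (delta AIC <= 2)
term                         beta       se     RI  models
restaurant_count            0.248    0.057   1.00       6
highly_developed            0.344    0.073   1.00       6
business_count              0.141    0.086   0.56       4
residential                 0.099    0.081   0.43       2
year_num                    0.020    0.067   0.28       1
natural_vegetation         -0.009    0.082   0.27       1
                     display  threshold
term
restaurant_count    0.25 (1)   0.570111
highly_developed    0.34 (1)   0.570111
business_count             -   0.570111
residential                -   0.570111
year_num                   -   0.570111
natural_vegetation         -   0.570111
```

The two terms the generator actually wired into this species
(restaurants +0.31, highly-developed cover +0.30 on the z scale) are the
two flagged as meaningful: their averaged coefficients (+0.25 ± 0.06 and
+0.34 ± 0.07) carry relative importance 1.0, above the null-calibrated
threshold of 0.57, while the four spurious candidates fall below it and
print as dashes. A coefficient is read as the change in log expected
count per SD of the predictor.

The same objects drive the community-level analyses; see
`urbanbirds.pipeline.run_h1/run_h2/run_h3` and the CLI
(`urbanbirds simulate | ingest | h1 | h2 | h3`).

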