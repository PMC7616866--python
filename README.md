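# ecgpheno

Prognostic phenogrouping of 12-lead ECGs from neural-network-derived
embeddings — a complete, desk-scale, fully synthetic re-creation of a
transfer-learning risk-stratification pipeline, for methodologists and
biostatisticians who want every stage testable against known generating
truth.

## The method

A residual 1-D convolutional network is trained to detect six common
rhythm/conduction diagnoses (first-degree AV block, RBBB, LBBB, sinus
bradycardia, AF, sinus tachycardia) from a preprocessed 12 × 4096 signal at
400 Hz.  Removing the final classification layer exposes the flattened
penultimate activations — under the full-size configuration a vector
**e ∈ ℝ⁵¹²⁰** per ECG.  The pipeline then:

1. **Phenogroups.** K-means on the raw embeddings (no dimensionality
   reduction), with K chosen by the elbow of the inertia curve
   (operationalized as maximum discrete curvature over k = 2..9; the
   synthetic three-group cohorts select k = 3).  Fitted centroids are
   frozen; external cohorts are labelled by nearest centroid only.
   Letters follow observed mortality: B = highest event rate, C = lowest.
2. **Prognosis.** Kaplan–Meier curves, the multi-group log-rank test, and
   Cox proportional-hazards regression of the hazard
   λ(t | x) = λ₀(t)·exp(βᵀx) on phenogroup indicators plus covariates, via
   Newton maximization of the Efron partial likelihood; HR = exp(β) with
   95% Wald intervals.
3. **PheWAS.** With phenogroups encoded 0 (A) / 1 (B): logistic-regression
   odds ratios against binary incident diseases, univariate (point-biserial)
   correlations against broad phenotype tables, both under Bonferroni
   control at α/m over the testable comparisons m.
4. **Explainability.** Cluster-adapted class-activation maps: the gradient
   of a soft-assignment log-probability over centroid distances, taken with
   respect to the last convolutional feature maps, weights those maps into
   a nonnegative per-sample saliency over the signal, averaged across the
   records nearest each centroid.

Everything runs on a seeded synthetic cohort generator (sum-of-Gaussians
beats, rule-based diagnoses, three latent risk groups expressed only
through terminal-QRS/terminal-T morphology, exponential survival with
group-dependent hazards, phenotypes with group-dependent odds), so every
stage has a known ground truth.  See `docs/methods.md` for models,
defaults, and limitations.

## Worked example

```python
import numpy as np
from ecgpheno import (cox_fit, select_k_elbow, simulate_feature_clusters,
                      simulate_survival)

rng = np.random.default_rng(0)
groups = rng.choice(["A", "B", "C"], size=5000, p=[0.5, 0.35, 0.15])
surv = simulate_survival(groups, baseline_hazard=0.02, censor_time=5.0, rng=rng)
X = np.column_stack([(groups == "B").astype(float),
                     (groups == "C").astype(float)])
fit = cox_fit(surv["time_years"], surv["event"], X,
              names=["phenogroup_B", "phenogroup_C"])
print(fit.summary().round(3))

E, _ = simulate_feature_clusters(3000, rng=rng)
res = select_k_elbow(E, range(2, 10), seed=0)
print(f"elbow-selected k = {res.k} (knee strength {res.knee_strength:.2f})")
```

prints

```
               coef     se     HR  HR 95% lower  HR 95% upper      p
phenogroup_B  1.000  0.083  2.717         2.308         3.199  0.000
phenogroup_C -0.023  0.141  0.977         0.741         1.287  0.869
elbow-selected k = 3 (knee strength 0.48)
```

The survival generator drew event times with hazard multipliers 2.57 (B)
and 0.85 (C) against group A; the Cox fit recovers them within sampling
error (log 2.717 vs log 2.57 is 0.4 standard errors away), and the elbow
criterion recovers the three generating clusters with a pronounced knee.

Full pipeline runs go through one config:

```bash
ecgpheno run-all --out runs/derivation --seed 1     # simulate → … → saliency
ecgpheno validate --model runs/derivation/model.npz \
    --clusters runs/derivation/phenogroups.npz --out runs/external --seed 2
```

`run-all` writes the cohort bundle (HDF5 signals + CSV tables), the trained
model, embeddings, centroids, assignments, KM/log-rank/Cox outputs, PheWAS
tables, saliency maps, and a manifest with per-stage timings and results.

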