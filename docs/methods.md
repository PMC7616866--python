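# Methods

`ecgpheno` re-creates, at desk scale and on fully synthetic data, a
transfer-learning pipeline for ECG risk stratification: a residual 1-D CNN
trained on six rhythm/conduction diagnoses supplies penultimate-layer
embeddings; K-means on those embeddings defines *phenogroups*; the fitted
centroids transfer unchanged to external cohorts; survival, phenome-wide
association, and class-activation saliency analyses characterize the
groups.  This note records the models, the choices behind them, and what
the synthetic experiments do and do not establish.

## Synthetic cohort generator

**Beat model.** A beat is a sum of five Gaussians (P, Q, R, S, T) with
amplitudes in mV, centers in ms relative to the R fiducial, and widths
(Gaussian sigma) in ms, projected onto 12 leads by a fixed per-lead scaling
vector.  The model is linear in the wave amplitudes, so peak values, beat
energy and the effect of every rule below have closed forms that tests
check directly.  It is deliberately not a biophysical simulator: leads are
(up to noise) proportional, morphology within a rhythm class is fixed, and
there is no respiratory or autonomic modulation.

**Diagnosis rules.** Sinus rhythm draws a rate in 60–100 bpm with 2%
beat-to-beat jitter; sinus bradycardia draws 40–49 bpm and sinus
tachycardia 105–140 bpm.  Atrial fibrillation sets the P amplitude to zero
and draws i.i.d. lognormal RR intervals with coefficient of variation 0.30.
First-degree AV block sets PR = 240 ms.  Bundle-branch blocks widen the QRS
to 140 ms; RBBB additionally adds a terminal R′ deflection (+0.5 mV notch)
and flips the V1/V2-analog projection, LBBB inverts the T wave (×−0.8) and
flips the V5/V6-analog projection.  The conduction signatures are
physiologically motivated and serve a second purpose: they force the
classifier to learn terminal-QRS-shape and T-shape detectors, which is
precisely the premise of reusing its embeddings for risk morphology.
Every label is re-derivable from measurable properties of the generated
signal (rate, RR variability, PR, QRS width); a test enumerates all rule
combinations and checks this.

**Latent risk groups.** Three groups A/B/C act on the signal *only* through
two terminal-beat parameters: a terminal-QRS notch (narrow Gaussian at
QRS/3 with sigma QRS/12) and a terminal-T flattening factor that scales the
trailing half of the T wave.  Confining group differences to these windows
makes saliency localization falsifiable.  Cohort defaults are modest
(B: notch 0.30 mV, flatten 0.60; C: flatten 0.30).  A named strong-contrast
profile (`STRONG_GROUP_MORPHOLOGY`: B notch 3.0 mV; C notch −2.0 mV,
flatten 0.9) exists for method-property experiments that require the
generating groups to be well separated in embedding space; the development
experiments below explain why.

**Survival and phenotypes.** Event times are exponential with hazard
`baseline × multiplier(group) × exp(age_log_hr · (age − 55))`, censored
administratively (defaults: baseline 0.02/yr, censoring at 5 yr).  The
generating multipliers default to 1 (A), 2.57 (B) and 0.85 (C), and binary
phenotypes are drawn with log-odds `logit(base) + log(OR)·1[group=B]` with
default ORs of 2.89 (incident AF), 1.44 (IHD), 4.88 (AV block), 2.04
(cardiomyopathy), 2.00 (VT) and 6.68 (cardiac arrest); these are external
prognosis estimates for a high-risk ECG phenogroup, used here as generating
ground truth for parameter-recovery tests, not as claims.  Continuous
phenotypes are Normal with a group-B mean shift (chamber-volume-like
increases, ejection-fraction-like decreases).  Noise is additive Gaussian
(σ = 0.02 mV) plus per-lead sinusoidal baseline drift below 0.5 Hz
(~0.1 mV).  All randomness flows from one `numpy` Generator, so identical
(config, seed) pairs give byte-identical bundles.

## Preprocessing

Records are high-pass filtered, resampled to 400 Hz, and symmetrically
zero-padded to 4096 samples per lead (48 + 48 zeros for a 10 s record).
No amplitude normalization is applied at any point; scaling the input
scales the output.

Numerical choices: drift removal is an order-4 Butterworth high-pass at
0.5 Hz applied forward–backward (zero phase) with symmetric edge extension
and a 1.5 s pad — a 0.3 Hz drift is attenuated to under 2% while beat
content above 1 Hz passes essentially unchanged; the long even pad keeps
the startup transient small when a recording ends mid-complex.  Resampling
is polyphase FIR interpolation at the rational rate 400/fs.  Recordings
longer than 10.24 s are rejected rather than silently truncated.

## Embedding network

A residual 1-D CNN in pure numpy (the package has no deep-learning
framework dependency): a convolutional stem (conv–BN–ReLU) followed by
residual blocks (conv–BN–ReLU–conv–BN with a strided 1×1 projection skip),
a flatten, and a single linear head with one sigmoid per diagnosis.  The
embedding is the flattened penultimate activation map, so its dimension is
`final filters × final temporal length` and removing the head changes
nothing upstream (a test asserts head-equivalence to < 1e−5).  Training is
Adam on per-label binary cross-entropy; label columns that are single-class
in the training split are masked out of the loss and reported as NaN AUROC.
Backpropagation is verified against central finite differences.

Presets:

| preset    | stem | blocks (filters × stride)    | final maps | embedding |
|-----------|------|------------------------------|-----------|-----------|
| `default` | 64×k17 | 128,196,256,320 × s4, k17  | 16 × 320  | 5120      |
| `desk`    | 16×k9  | 32,32,48,64 × s4, k9       | 16 × 64   | 1024      |
| `tiny`    | 6×k9   | 8,8,8,8 × s4, k9           | 16 × 8    | 128       |
| `sharp`   | 8×k3   | 12,16 × s2, k3             | 1024 × 16 | 16384     |

`default` reproduces the published sizing (5120 features, 6 outputs) and is
used for shape introspection and single-record inference only; training it
at scale is out of scope.  `tiny` trains in about a minute on 1200 records
and reaches validation AUROC ≥ 0.99 on all six diagnoses after 12 epochs.
`sharp` is the pipeline default: two kernel-3 blocks give a ~50 ms
receptive field and 10 ms final-map bins, which Section "Saliency" explains.

## Phenogrouping

K-means (k-means++ with 10 restarts, best inertia kept) on the raw
embedding coordinates — no dimensionality reduction, no standardization by
default (a `standardize` flag exists).  The elbow criterion is made
reproducible as *maximum discrete curvature*: inertia is computed for k = 1
(total sum of squares) through the scanned maximum, min–max normalized, and
the second difference taken at each interior k; the selected k maximizes
it.  The curvature at the selected k is reported as a knee strength;
below 0.1 the curve is flagged as having no pronounced knee (a single
isotropic cloud gives values near zero, three well-separated clusters about
0.5).  External cohorts are labelled by nearest centroid only (ties to the
lowest index); centroids are never refit, and the external-validation
driver hashes weights and centroids before and after to prove it.
Phenogroup letters follow observed mortality: B is the highest-event-rate
cluster, C the lowest, A the remainder.  The 2-D view is PCA to 50
components followed by t-SNE, used for figures only.

### Why strong contrasts are needed at desk scale

Flattened convolutional embeddings of beat trains are dominated by
*phase and rate* variance: 2% RR jitter accumulates to ~50 ms of beat-
position wander within 10 s, and heart rate varies continuously between
subjects, so the within-group spread of embeddings is large along many
directions.  With the default (modest) morphology contrasts the
between-group separation is ~1% of total variance — linearly decodable
(a probe reaches AUROC ≈ 0.97) but invisible to variance-driven K-means,
which instead splits by rate and rhythm.  Under the strong-contrast
profile the group axes dominate, K-means isolates the high-risk group
almost perfectly, and survival separation follows.  Passing results under
strong contrasts therefore demonstrate that the *machinery* (embedding →
fixed-centroid clustering → prognosis) behaves as designed; they do not
show that K-means would recover subtle morphology differences in real
cohorts, where cluster structure plausibly tracks the dominant axes of ECG
variation instead.

## Survival analysis

Hand-implemented and oracle-tested: the Kaplan–Meier product-limit
estimator with Greenwood variance; the multi-group log-rank test with
hypergeometric covariance (df = groups − 1); and Cox proportional-hazards
regression maximizing the partial likelihood by Newton iterations with
step-halving (convergence at gradient max-norm < 1e−8, at most 100
iterations), Efron tie correction by default with Breslow available, Wald
standard errors from the inverse observed information, and 95% intervals.
The likelihood evaluation is fully vectorized (reversed cumulative
risk-set sums; tied death sets by segment sums).  Monotone likelihood
(perfect separation) is flagged as non-convergence — including the subtle
case where the gradient vanishes numerically on the plateau — rather than
returned silently.  Subjects with non-positive times are rejected, not
clamped.  Step-halving accepts a new point when the log-likelihood does not
fall by more than 1e−10 relative, which keeps the line search robust to
float noise at cohort scale.  Cross-checks against an independent
implementation (lifelines) agree to ≤ 1e−5 on coefficients and standard
errors.

## PheWAS

Phenogroup membership is encoded 0 (A) / 1 (B); subjects in C must be
excluded upstream and the encoder enforces it.  The disease scan fits a
logistic regression per binary incident-disease column (odds ratio =
exp(slope); on a single binary predictor this equals the 2×2 closed form,
asserted to 1e−6).  The biobank scan computes the Pearson correlation per
numeric phenotype (point-biserial for continuous columns) on
pairwise-complete observations.  No covariate adjustment is applied by
default; optional covariate columns are accepted in the disease scan.
Bonferroni control uses alpha divided by the number of *testable*
comparisons; zero-case, constant, or failed columns are reported but
excluded from the denominator.  A simulation test confirms the family-wise
error of full 100-phenotype null scans stays within alpha plus Monte-Carlo
error.

## Saliency

Phenogroups have no class score, so attribution uses a *soft-assignment
log-probability*: score_j(e) = −‖e − c_j‖²/τ − log Σ_k exp(−‖e − c_k‖²/τ).
It is differentiable, bounded above by zero, equals log(1/2) at an
equidistant pair, and reduces to a one-hot assignment when clusters are far
apart.  That reduction is also its failure mode: at realistic embedding
scales the softmax saturates and the gradient vanishes, so `gradcam` uses
the temperature τ = mean squared centroid distance ("auto"), which keeps
the assignment soft; τ = 1 reproduces the plain form.  Channel weights are
the temporal mean of the score gradient with respect to the final feature
maps (which is the reshaped embedding gradient, since the embedding is
their flattening); the map is the rectified weighted sum of feature maps,
linearly upsampled to the 4096-sample grid, broadcast across the 12 leads
(the flattened embedding mixes leads, so one temporal map is the honest
resolution), and normalized to sum 1.  Cluster averages use the n records
nearest the centroid (n = 1000 by default, all members when fewer).

Two resolution facts shape the experiments.  First, a saliency map cannot
localize more finely than the network's receptive field, so the `sharp`
preset (~50 ms receptive field) is used wherever localization is measured;
the kernel-17 presets have second-scale receptive fields and produce
beat-level, not within-beat, attributions.  Second, averaging maps across
records at unaligned beat phases is uniform by construction, so
localization is measured per record — each record's saliency share inside
its own terminal-QRS/terminal-T windows (defined from the generator's
fiducials) — and then averaged.  Grad-CAM highlights *presence*, not
absence: a group defined by a missing wave cannot attract saliency in that
wave's window, which is why the strong-contrast profile gives group B the
notch (a presence) and group C the flattening.

## Pipeline and problem sizes

`run_derivation` executes simulate → preprocess → train → embed → cluster →
survival → PheWAS → saliency from one config; every stage seed is derived
as SHA-256(global seed, stage name) mod 2³¹, so stages rerun independently
and whole runs are byte-reproducible.  A stage failure aborts with the
stage's name and keeps prior artifacts.  `run_external_validation` consumes
frozen weights and centroids and produces assignment and survival outputs
only.

The shipped experiment sizes are chosen so a complete run is comfortable on
a single CPU: derivation cohorts of n = 3000 (strong contrasts, `sharp`
network, 4 epochs, ~3 minutes end-to-end), external cohorts of n = 800
with shifted group proportions and an age–group confound, training
demonstrations at n = 1200 with the `tiny` network, and parameter-recovery
cohorts of n = 5000 (hazards) and n = 20000 (odds ratios).

## Known limitations

- The generator's lead structure is rank-1 plus noise; no real lead
  physiology, pediatric/sex morphology, or disease-specific (e.g. Chagas)
  abnormalities.
- The elbow criterion, saliency score, selection of "center" records, and
  padding sidedness are explicit operationalizations of steps that admit
  several definitions; each is config-exposed or documented above.
- Clustering recovers latent groups only under strong morphology
  contrasts (see above); the realistic-contrast regime is linearly
  decodable but not K-means-separable at these sample sizes.
- Cox assumes proportional hazards and right-censoring; no time-varying
  covariates, competing risks, or proportionality diagnostics.
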