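# Methods

## Model

For a chosen *target* cell type B and *source* types A₁..A_K, each
image's target pattern is treated as an inhomogeneous Poisson process
conditional on the observed source patterns. The log conditional
intensity is linear in distance-basis interaction features:

    log λ(v) = β₀_m + z(v)ᵀβ + Σ_k q_{A_k}(v)ᵀ δ_{A_k}(m),
    [q_{A_k}(v)]_p = Σ_{x ∈ X_{A_k}} φ_p(dist(v, x)).

The spatial interaction curve SIC(s) = Σ_p c_p φ_p(s) is the additive
log-density contribution of one source cell at distance s; exp(SIC) is a
local density fold-change. Positive and negative values encode attraction
and repulsion; the relation is directional by construction (the model
conditions on the sources and models only the target).

Modeling assumptions worth keeping in mind:

* targets are conditionally Poisson given sources — no target–target
  interaction beyond what the sources induce;
* contributions of multiple source cells add on the log scale;
* the window is a closed axis-aligned rectangle and no edge correction is
  applied to the features: near the boundary, unobserved out-of-window
  source cells attenuate the features, which is expected behavior of a
  model that conditions on *observed* cells only.

### Hierarchy

Interaction coefficients are pooled across three levels, per basis index:
cohort ψ ~ N(0, σ²_cohort), patient γ ~ N(ψ, σ²_patient), image
δ ~ N(γ, σ²_image). Intercepts β₀ are per image and *not* pooled:
baseline density varies across sections and the SIC is defined relative
to it. Covariate coefficients β are shared across images; continuous
covariate columns are standardized study-wide (binary columns left 0/1).

With a singleton hierarchy (one cohort = one patient = one image) the
variance components are unidentified and the posterior splits the
image-level signal roughly evenly across levels, so cohort- and
patient-level curves sit between zero and the image-level curve rather
than collapsing onto it. This is the correct Bayesian answer under the
hyperpriors below, and the test suite asserts exactly this ordered
shrinkage.

### Likelihood approximation

The Poisson likelihood is fit through the dummy-point logistic
construction: dummy locations are drawn from a homogeneous Poisson
process with intensity λ_dummy, and data-vs-dummy labels are modeled with
logit P(y=1|v) = log λ(v) − log λ_dummy. Default λ_dummy is 4× the
observed per-image target density, a standard quadrature density.
A Berman–Turner-style grid quadrature is deliberately *not* the primary
path; it serves as an oracle in tests. An image with zero target cells
still contributes dummy rows, so its coefficient posterior is weakly
pulled negative rather than exactly equal to the prior.

## Priors and defaults

| parameter | default | why |
|---|---|---|
| basis family | cubic B-splines (clamped, uniform knots) | partition of unity; coefficients on the log-intensity scale |
| P | 6 | resolves the biologically interpretive 25–75 µm range without overfitting |
| r_max | 150 µm | associations beyond ~75–100 µm are typically weak; support to 150 leaves headroom |
| r_min | 25 µm | below ~1.5–2 cell diameters crowding/segmentation dominates; fitting uses all distances, reporting masks s < r_min |
| σ_cohort, σ_patient, σ_image | half-Normal(0, 1) | weakly informative on a scale where \|SIC\| rarely exceeds ~2 |
| β₀, β | Normal(0, 5²) | weakly informative for log densities and covariate effects |
| flat-model δ | Normal(0, 2²) | matches the hierarchical prior's marginal scale on δ, so the flat model is a pure no-pooling ablation |
| λ_dummy | 4 × target density | quadrature default |
| bands | 95%, simultaneous | joint coverage over the reported distance range |

Gaussian basis kernels (unnormalized, peak 1, bandwidth = center spacing)
are available as an alternative family; they are truncated to zero beyond
r_max so every SIC has compact support.

## Inference

Sampling uses an in-package adaptive Hamiltonian Monte Carlo sampler
(`shade.hmc`) on the unconstrained parameter vector with analytic
gradients: leapfrog integration, dual-averaging step-size adaptation to a
0.8 target acceptance rate, a diagonal mass matrix estimated from the
warmup second half, jittered trajectory lengths (target path length 1.5
for the hierarchical model), and log-transformed standard deviations.
γ and δ use non-centered parameterizations to avoid funnel geometry.
Defaults are 4 chains × 1000 warmup + 1000 draws; the examples and the
benchmark use 2 chains and a few hundred draws, which the diagnostics
(split-R̂, bulk ESS via arviz; divergence counts) show is adequate for
band-level summaries at these problem sizes. Fits with R̂ > 1.05 on any
SIC coefficient are flagged, not fatal. Likelihood and gradient
correctness are pinned by tests against an independent dense
implementation and finite differences.

## Simultaneous bands and summaries

Bands use the max-standardized-deviation construction: with curve draws
f₁..f_S on a grid, c* is the empirical 95% quantile over draws of
max_s |f(s) − m(s)|/sd(s) and the band is m ± c*·sd. Grid points with
zero posterior sd get zero-width band. Detection on an interval [a, b]
means the band excludes zero at some grid point in [a, b]; detection at
99% is a subset of detection at 95% by construction. Prioritization
summaries are computed from the *mean* curve (the draw-wise variant would
average the same quantity over draws; the mean-curve convention is
simpler and stabler): peak location/magnitude of |mean SIC|, persistence
(fraction of the interval where the band excludes zero), and strength
(trapezoidal integral of |mean| over the excluded-zero region).

Heterogeneity is decomposed by median absolute deviations of
posterior-*mean* curves: between-patient MAD = median over patients and
grid points of |patient SIC − cohort SIC|, within-patient MAD likewise
for images around their patient. Using posterior means keeps the measure
stable at modest draw counts; a draw-wise version would add posterior
spread to the same location summaries.

## Synthetic studies

The generator mirrors the model's assumptions — it emulates segmented,
classified centroids in rectangular 1500×1500 µm² windows with
homogeneous Poisson sources and conditionally Poisson targets — and adds
known ground truth: a fixed cohort curve ψ* (default: a single positive
bump peaking near 40 µm with maximum 0.8, detectable but not trivial),
patient and image curves drawn with σ_patient = σ_image = 0.1, and
benchmark densities of 150 source and 15 target cells per image (50
targets in the recovery study). Baselines β₀ are calibrated per image so
the *expected* target count equals the configured density under the
drawn curves. Targets are realized by exact rejection (thinning)
sampling against λ_max taken from a 256×256 evaluation grid with a 1.2
safety factor; a run aborts if any accepted point's intensity exceeds
the bound. Optional compartment confounding overlays Voronoi cells with
symmetric log-intensity offsets (weak 0.3 / moderate 0.7 / strong 1.2).
Per-image seeds derive deterministically from the study seed and image
index, so single images and replicates are reproducible in isolation and
order-independent.

What the generator does *not* emulate: cell-shaped exclusion zones
(centroids may fall arbitrarily close), segmentation and classification
errors, irregular tissue masks, and target–target dependence. Passing
tests therefore certify the estimator under its own assumptions plus the
studied misspecifications (compartments), not robustness to all real
imaging artifacts.

## Baselines and benchmark

G-cross uses the reduced-sample (border) correction; K-cross the
translation correction, reported as L(r) = √(K/π). CSR envelope tests
redraw the *to*-type points uniformly at their observed count with
from-points fixed (the standard conditional CSR null for cross-type
tests) and use a studentized max-deviation global envelope: curves reduce
to D = max_r |f − m|/s against the simulation mean and sd, the exact
Monte-Carlo rule rejects when the observed D is among the top 5% of all
n_sim + 1, and the reported envelope m ± c*·s makes "exits anywhere" the
rejection event. The naive pointwise min/max-of-simulations envelope was
measured at 11–17% type-I over 200 CSR replicates (multiplicity across
the grid) and the plain extreme-rank envelope at ≈0% (rank ties at
n_sim = 99), so the studentized construction is the one that actually
delivers a calibrated global 95% test; measured type-I is 5.5% (G-cross)
and 8% (K-cross) on 200 null replicates.

The benchmark harness scores *image-level* detection on 0–75 µm: power on
studies generated with the bump curve, type-I error on null studies
(all interaction coefficients zero), and — for the Bayesian models —
simultaneous coverage of the true image-level curve. Reported rates are
medians (tables) or pooled means (calibration checks) over replicates;
all seeds derive from a master seed per (condition, replicate, arm), so
results are independent of execution order.

Problem sizes: the test suite and `scripts/acceptance.py` run the
benchmark at 10 patients × 2 images with 6–10 replicates per condition
and a few hundred HMC draws per fit, and the recovery study at
4 patients × {1, 3} images with 3–5 replicates — reduced from the
40-patient × 50-replicate full grid, which the same harness reproduces
by changing `n_patients`, `replicates`, and the condition list. At
reduced scale the *directions* (hierarchical power ≈ 100% at high source
density, envelope tests materially lower at low target density, flat
ablation less well calibrated than the hierarchical model, type-I rates
in their expected bands) are the reproducible quantities; exact
full-scale percentages are not, and the true curve magnitudes behind the
original per-condition rates are themselves a design choice here (the
bump above). The flat-vs-hierarchical calibration comparison is
evaluated on data-rich null studies (150/150): at low densities both
models' bands are wide enough that neither makes spurious image-level
detections, so the comparison only discriminates where overfitting
without pooling is possible.

## Known limitations

* One target type per fit; cross-target dependence is out of scope.
* No feature edge correction (see above); windows are rectangles.
* SICs are predictive associations, not causal effects; unmeasured
  tissue architecture can masquerade as interaction (the compartment
  simulations quantify this), and the compartment covariate of
  `shade.quadrature` is the built-in adjustment route.
* The sampler is a general-purpose HMC without per-model tuning beyond
  the defaults above; pathological posteriors (e.g., massive studies
  with near-zero variance components) may need more warmup.
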