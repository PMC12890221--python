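# shade-spatial

Hierarchical Bayesian estimation of **directional spatial interaction
curves (SICs)** between cell types in multiplexed tissue imaging.

Multiplexed imaging pipelines yield, per tissue image, a list of cell
centroids with cell-type labels. A recurring question is whether one cell
type shapes the local density of another — do cytotoxic T cells
accumulate near tumor cells, do granulocytes avoid fibroblast-rich
regions — and at which distances. Such associations are often
*asymmetric* (A→B need not equal B→A), and single-image summary
statistics cannot share information across the sections, patients, and
cohorts that make up a study. This package is for computational
pathologists and spatial statisticians who want direction-specific,
distance-resolved estimates with full posterior uncertainty, pooled
across a study's hierarchy.

## Model

The target type's points in each image are modeled as an inhomogeneous
Poisson process conditional on the source-type patterns, with log
conditional intensity

    log λ(v) = β₀_m + z(v)ᵀβ + Σ_k q_{A_k}(v)ᵀ δ_{A_k}(m),
    [q_{A_k}(v)]_p = Σ_{x ∈ X_{A_k}} φ_p(‖v − x‖),

where φ₁..φ_P is a distance basis (cubic B-splines by default) on
[0, r_max]. The **spatial interaction curve** of source type A on the
target is SIC(s) = Σ_p ψ_p φ_p(s): the additive contribution to the log
target density of one type-A cell at distance s, so exp(SIC(s)) is a
density fold-change (SIC = 0.2 → ×1.22, SIC = −0.3 → ×0.74). The
coefficients carry a three-level hierarchy

    ψ(g,p) ~ N(0, σ²_cohort),   γ(n,p) ~ N(ψ(g(n),p), σ²_patient),
    δ(m,p) ~ N(γ(n(m),p), σ²_image),

giving partial pooling of image-level curves toward patient and cohort
means. The Poisson likelihood is fit through the standard logistic
approximation (observed cells vs homogeneous dummy points with offset
−log λ_dummy) by adaptive Hamiltonian Monte Carlo. Uncertainty is
reported through *simultaneous* 95% credible bands with joint coverage
across distances; an interaction is "detected" when the band excludes
zero anywhere on a distance interval. G-cross / K-cross CSR global
envelope tests and a no-pooling ("flat") per-image model are included as
baselines, plus a generator of synthetic hierarchical studies with known
curves.

## Worked example

```python
import numpy as np
from shade import SHADEModel
from shade.simulate import SimulationConfig, simulate_study

cfg = SimulationConfig(n_patients=4, images_per_patient=2,
                       expected_source=150, expected_target=50, seed=3)
patterns, hierarchy, truth = simulate_study(cfg)

model = SHADEModel.from_patterns(patterns, hierarchy,
                                 target="T", sources=("tumor",), seed=1)
results = model.fit(draws=400, warmup=600, chains=2, seed=7)
print(results.diagnostics())
print(results.summary()[["source", "peak_distance_um", "peak_sic",
                         "peak_fold_change", "detected", "sign"]])
```

Output from this exact run:

```
{'max_rhat_sic': 1.024..., 'min_ess_sic': 161.4..., 'divergences': 0, ...}
  source  peak_distance_um  peak_sic  peak_fold_change  detected      sign
0  tumor              37.0  0.870028          2.386979      True  positive
```

The cohort-level SIC of the simulated tumor→T interaction peaks near
37 µm at ≈ 0.87 on the log-intensity scale — a ≈ 2.4-fold elevation of
local T-cell density — and the simultaneous 95% band excludes zero
(`detected`), recovering the generating bump (true peak ≈ 40 µm, height
0.8). `results.credible_band(...)`, `.heterogeneity()` and `.save(...)`
expose bands, patient/image-level variability (MAD decomposition), and
the posterior draws. The same workflow is available from the shell:

```bash
shade simulate --config sim.yaml --out study/
shade fit --cells study/cells.csv --windows study/windows.csv \
          --target T --sources tumor --out fit/
shade summarize --fit fit/ --level cohort
shade baseline --cells study/cells.csv --windows study/windows.csv \
               --stat gcross --from-type tumor --to-type T
shade benchmark --config bench.yaml --replicates 10 --seed 1 --out bench/
```

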