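# poolsi — pooled scale invariance in primate V1

`poolsi` analyzes the joint statistics of spatial tuning in a densely
sampled V1 population — preferred spatial frequency (f_o), receptive-field
width, SF bandwidth, orientation bandwidth and phase selectivity (F1/F0) —
and asks whether they follow **scale invariance** or **pooled scale
invariance**. It is aimed at visual neuroscientists working with two-photon
calcium imaging of cortical populations, and ships a complete synthetic-data
generator so every stage of the analysis is testable without recorded data.

## The model

A scale-invariant Gabor family ties every tuning parameter to f_o (cyc/°):

    σ_x,si(f_o)   = 1/(α f_o)                   RF width (°)
    σ_f,si(f_o)   = α f_o / 2π                  linear SF bandwidth (cyc/°)
    σ_log(f),si   = log₂(1 + α/2π)              log SF bandwidth (octaves)
    σ_θ,si        = atan(α / 2πA)               orientation bandwidth (°)

with α = π (2–3 ON/OFF subfields) and aspect ratio A = 2 by default. Under
scale invariance σ_θ and the octave bandwidth are constant and, at α = π,
σ_θ ≈ 14°.

Pooled scale invariance adds a single Gaussian integration stage over a
population of scale-invariant inputs. Pooling over retinotopy (window
σ_h(x), degrees) and over the 2D spectral plane (window σ_h(f), cyc/°)
yields

    σ_x,p²  = σ_x,si²(f_o) + σ_h(x)²
    F1/F0   = π · exp[−(σ_h(x) · 2π f_o · D)² / 2]
    σ_f,p²  = σ_f,si²(f_o) + σ_h(f)²
    σ_θ,p   = atan( sqrt(σ_f,si²/A² + σ_h(f)²) / f_o )

where D ∈ [0, 1] sets how fast absolute spatial phase advances with
retinotopy inside the pooling window (D = 0: constant absolute phase;
D = 1: constant relative phase). The package estimates σ_h(x) and σ_h(f) by
root-median estimators (median of the signed squared excess over the
scale-invariant prediction), fits D by least squares with σ_h(x) held
fixed, compares the pooled model against fixed- and fitted-α scale
invariance by leave-one-out cross-validation in log₂ space, estimates the
cortical magnification factor from pairwise cortical vs. RF separations,
and quantifies functional clustering in 75-µm distance bins with
shuffle-test significance.

## Worked example

Run the full synthetic pipeline (ground-truth cortical sheet → neuron
population → grating/bar response kernels → tuning fits → model fit →
clustering), here with 150 cells:

```python
from poolsi.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=0, n_cells=150, out_dir="demo_run")
run_dir = run_pipeline(cfg)
print((run_dir / "model_summary.txt").read_text())
```

```
Pooled scale invariance fit
============================================
cells included (grating)     150
sigma_h(x)  [deg]            0.2669
sigma_h(f)  [cyc/deg]        0.7995
D           [-]              0.4833
alpha_flex (rf_width)       1.567
alpha_flex (sf_bandwidth)       4.31
magnification [mm/deg]       1.913
cortical extent 1s/2s [mm]   0.511 / 1.02
LOOCV rf_width pooled_vs_si: dMSE=+1.16 p=2.9e-30 CI95=(1, 1.32)
LOOCV rf_width pooled_vs_si_flex: dMSE=+0.153 p=3.9e-12 CI95=(0.113, 0.193)
LOOCV sf_bandwidth pooled_vs_si: dMSE=+0.255 p=1.4e-22 CI95=(0.211, 0.298)
LOOCV sf_bandwidth pooled_vs_si_flex: dMSE=+0.0479 p=1e-09 CI95=(0.0334, 0.0624)
```

The generator embedded σ_h(x) = 0.24°, σ_h(f) = 0.85 cyc/°, D = 0.54 and a
2.0 mm/° magnification; the pipeline recovers them through the full
measurement chain (kernel noise and tuning-fit error account for the
residual deviation). The positive dMSE rows say the pooled model predicts
held-out RF widths and SF bandwidths better than scale invariance — even
when the scale-invariance coefficient is refit — with paired-t p-values and
95% CIs of the per-cell squared-log₂-error difference. Multiplying
σ_h(x) by the magnification factor converts the pooling window to cortical
distance (~0.5 mm at 1σ).

The same stages are available as a CLI (`poolsi demo`, `poolsi simulate`,
`poolsi extract`, `poolsi fit`, `poolsi fitmodel`, `poolsi cluster`,
`poolsi report`), and as library calls: `PooledScaleInvarianceModel(table).fit()`
returns a results object with `.summary()`, estimates and LOOCV diagnostics.

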