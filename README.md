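# mcginv — magnetocardiographic source localization

`mcginv` reconstructs epicardial potential distributions from
magnetocardiographic (MCG) measurements — the heart's magnetic field sampled
by an array of magnetometers over the chest. It is aimed at researchers in
bioelectromagnetic inverse modelling who want a self-contained, fully
synthetic test bed: the geometry, the sources, the forward fields and the
noise are all generated by code, so every experiment is reproducible from a
seed.

## The model

Epicardial sources are unit current dipoles at the `Q` nodes of a
triangulated ventricular surface, oriented along the outward normals
`â_q` and weighted by the local potential `s_q(t)` (mV). The Biot–Savart
lead field maps them to the field at detector `m`:

```
L(r_m, ⟨r'_q, â_q⟩) = (μ₀/4π) · (r_m − r'_q)/‖r_m − r'_q‖³ × â_q
B = L s + n,        n ~ N(0, β⁻¹I)
```

with `B` sampled on a 9 × 9 planar grid (M = 81, 3 cm spacing) in
picotesla. Because `M < Q` in the full protocol the inversion is ill-posed;
three solvers are provided, all exposed as scikit-learn style estimators
(`fit(A, B)`, `coef_`, `get_params`):

* **`TikhonovRegression`** — zero-order Tikhonov,
  `min ‖B − Ls‖² + λ‖s‖²`, with λ chosen at the maximum-curvature corner of
  the L-curve (log–log plot of `‖s‖` against the residual norm over 100
  linearly spaced λ from 1e-10 to 10).
* **`EvidenceRegression`** — hierarchical Bayes with Gaussian prior
  `N(0, α⁻¹I)` and noise precision β, the hyperparameters re-estimated by
  the evidence approximation: `γ = Σ λᵢ/(λᵢ+α)` over eigenvalues of
  `βLᵀL`, then `α ← γ/(2‖s‖²)`, `β ← (M−γ)/(2‖res‖²)` until
  `max(|Δα|,|Δβ|) < 10⁻³`. The posterior mean equals the Tikhonov solution
  at λ = α/β — an identity the test suite asserts.
* **`VBLinearRegression`** — variational Bayes with a conjugate
  normal-inverse-gamma prior `N(s|0,(βα)⁻¹I)·Gam(β|a₀,b₀)` and a Gamma
  hyperprior on α, fitted by mean-field coordinate ascent on the ELBO with a
  0.001 % relative stopping rule. The ELBO is non-decreasing by
  construction, and with E[α] pinned the estimate reduces to ridge
  regression.

Two infarction morphologies can be simulated over a circular epicardial
patch (default 1.5 cm): **ST elevation** (waveform amplitude reduced by
48 %) and **increased T** (repolarization shortened). The study protocol
avoids the *inverse crime* by simulating the forward data on one mesh
("model 1") and inverting through the lead field of an independently
remeshed variant ("model 2"); estimates are scored by spatial/temporal RMSE
and Pearson correlation against the truth transported through a
nearest-node map.

## Worked example

```python
import numpy as np
from mcginv import (
    make_ellipsoid_mesh, remesh_perturb, make_sensor_grid, nearest_node_map,
    compute_lead_field, forward_field, add_noise, simulate_sources,
    WaveformParams, MIScenario, SourceTimeSeries, evaluate,
    TikhonovRegression, EvidenceRegression, VBLinearRegression,
)

model1 = make_ellipsoid_mesh((4.0, 3.5, 5.0), 60, seed=11, label="model1")
model2 = remesh_perturb(model1, 100, seed=23, label="model2")
sensors = make_sensor_grid(9, 9, spacing=3.0, center=(0, 0, 10.0))

params = WaveformParams(dt=5.0)
lesion = int(np.argmax(model1.node_positions[:, 2]))   # wall facing the array
scenario = MIScenario("st_elevated", lesion_center_node=lesion, lesion_radius=2.5)
truth = simulate_sources(model1, params, scenario)

clean = forward_field(compute_lead_field(model1, sensors), truth)
noisy, record = add_noise(clean, snr_db=6.0, seed=2024)
print(f"realized SNR: {record.realized_snr_db:.2f} dB")

A = compute_lead_field(model2, sensors).design_matrix("all")
node_map = nearest_node_map(model2, model1)
focus = int(np.argmin(np.linalg.norm(
    model2.node_positions - model1.node_positions[lesion], axis=1)))

for name, solver in [
    ("Tikhonov (L-curve)", TikhonovRegression()),
    ("evidence approximation", EvidenceRegression()),
    ("variational Bayes", VBLinearRegression()),
]:
    solver.fit(A, noisy.stacked())
    estimate = SourceTimeSeries(solver.coef_.T, truth.times, "model2")
    report = evaluate(truth, estimate, node_map, instants=[85.0], focus_node=focus)
    print(f"{name:24s} sRMSE(85 ms) = {report.srmse_per_instant[85.0]:.3f} mV, "
          f"spatial CC = {report.cc_spatial[85.0]:.3f}")
```

Output:

```
realized SNR: 6.10 dB
Tikhonov (L-curve)       sRMSE(85 ms) = 2.216 mV, spatial CC = 0.878
evidence approximation   sRMSE(85 ms) = 2.202 mV, spatial CC = 0.769
variational Bayes        sRMSE(85 ms) = 2.192 mV, spatial CC = 0.778
```

The spatial RMSE at the mid-ST instant (t = 85 ms) compares the estimate on
model 2 against the transported truth; at this heavy noise level (6 dB) the
Bayesian solvers edge out the L-curve-tuned Tikhonov solution, and over
replicated noise draws the mean ordering is VBLR ≤ evidence ≤ Tikhonov.

A command-line interface mirrors the library (`mcginv geom make-heart`,
`mcginv simulate-sources`, `mcginv forward`, `mcginv invert`, `mcginv
evaluate`, `mcginv run --config experiment.json`).

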