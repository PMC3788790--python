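# dcewall

Pharmacokinetic analysis of dynamic contrast-enhanced (DCE) MRI of the
abdominal-aortic-aneurysm (AAA) vessel wall.

Increased microvascularization of the AAA wall is linked to aneurysm growth
and rupture. DCE-MRI quantifies it through the volume transfer constant
K^trans (min⁻¹), estimated by fitting tracer-kinetic models to the
gadolinium concentration–time course of the wall, driven by the blood
plasma concentration C_p(t) (the arterial input function, AIF). `dcewall`
implements the full analysis chain and, because no public vessel-wall
DCE-MRI data exist at this scale, a seeded synthetic-phantom generator with
known ground truth so every stage is testable end to end.

## Models

All three models solve the two-compartment (plasma / extravascular
extracellular space) exchange problem under different assumptions:

| Model | Tissue concentration C_t(t) | Parameters |
|---|---|---|
| Patlak | K^trans ∫₀ᵗ C_p dτ + v_p C_p(t) | K^trans, v_p |
| Tofts | K^trans ∫₀ᵗ C_p(τ) e^(−k_ep(t−τ)) dτ | K^trans, v_e |
| Extended Tofts | Tofts + v_p C_p(t) | K^trans, v_p, v_e |

with k_ep = K^trans/v_e, v_p the plasma volume fraction and v_e the
extravascular-extracellular volume fraction. The AIF is the Parker
functional form (two Gaussians plus a sigmoid-modulated exponential
washout); the shipped population parameter set reproduces a slow
(0.5 mL/s) injection with a weak first-pass peak. Signal ↔ concentration
conversion uses the steady-state spoiled-gradient-echo (Ernst) equation
with r1/r2 relaxivities and fixed pre-contrast T1/T2 of 900/30 ms.

Fitting is bounded least squares with analytic Jacobians (Patlak is linear
and solved in closed form). Each fit reports the relative fit error
100·RMS(C_t − C_tfit)/max|C_t| and the covariance-based relative parameter
uncertainty 100·√Cov_ii/|θ̂_i|, both voxel-wise (parameter maps, averaged
over the wall) and ROI-based (wall-mean curve, one fit). Scan-rescan
repeatability is summarized by the one-way intraclass correlation ICC(1,1)
and the within-subject coefficient of variation.

## Worked example

```python
import dcewall as dw

protocol = dw.AcquisitionProtocol()          # TR/TE 13/1.5 ms, 35 deg, 25 x 18 s
phantom = dw.PhantomSpec(seed=0)             # annular wall, Ktrans 0.043/min
series, truth = dw.render_dynamic_series(phantom, protocol)

result = dw.fit_roibased(series, truth["wall_mask"], truth["aif"], "patlak")
print(f"Ktrans = {result.params.ktrans:.4f} min^-1  (true 0.0430)")
print(f"vp     = {result.params.vp:.4f}        (true 0.0100)")
print(f"relative fit error  = {result.rel_fit_error:.1f} %")
print(f"Ktrans uncertainty  = {result.rel_uncertainty['ktrans']:.1f} %")
```

prints

```
Ktrans = 0.0442 min^-1  (true 0.0430)
vp     = 0.0132        (true 0.0100)
relative fit error  = 1.3 %
Ktrans uncertainty  = 0.7 %
```

The small deviations from truth come from the phantom's default signal
noise; the ROI-mean curve averages it down, so the ROI-based fit error
(1.3%) is much smaller than the ~16% seen on single voxels.

The same analysis runs from the shell on a study directory of NIfTI series
with JSON sidecars:

```bash
dcewall simulate --config sim.json --out demo --seed 7   # synthetic cohort
dcewall fit --config demo/study.json                     # fits + report
dcewall report --results demo/results --study demo/study.json
```

`dcewall fit` prints one line per model and fitting mode, e.g.

```
         patlak   roi: Ktrans 0.0311±0.0036 min^-1, fit error 2.8%
         patlak voxel: Ktrans 0.0302±0.0037 min^-1, fit error 20.4%
```

and writes `fits.csv`, per-scan K^trans/v_p/v_e maps (NIfTI) and
`report.json` (per-model summaries, pairwise Wilcoxon tests and win
fractions, Spearman correlation of K^trans with maximal aneurysm diameter,
and the ICC/CV reproducibility table).

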