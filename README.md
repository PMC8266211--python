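# valvemech

Desk-scale computational toolkit for aortic-valve (AV) leaflet biomechanics
and transvalvular hemodynamics. It implements the analysis chain used to
compare candidate leaflet material models and collagen fiber architectures:

* **Anisotropic hyperelastic constitutive laws.** Three incompressible,
  fiber-reinforced strain-energy functions of the invariants
  `I1 = tr(C)` and `I4 = f0 . (C f0)`:

  * `W1 = C10 (e^{C01(I1-3)} - 1) + k1/(2 k2) [e^{k2 (I4-1)^2} - 1]`
  * `W2 = mu (I1-3) + c0 [e^{c1 (I1-3)^2 + c2 (I4-1)^4} - 1]`
  * `W3 = C1 (I1-3) + a/(2b) [e^{b (I4-1)^2} - 1]`

  with Cauchy stress `sigma = -p I + 2 W_{I1} B + 2 W_{I4} f (x) f`, the
  plane-stress planar-biaxial response (pressure `p` eliminated
  analytically), Cauchy/first-Piola conversion, and the fiber strain
  `f0.(E f0)` and fiber stress `f.(sigma f)` measures.
* **Biaxial calibration.** Bound-constrained (all parameters >= 0)
  multi-start least squares on the summed squared stress residuals in both
  test directions, with R^2 = 1 - SSE/SST and per-sample RMSE reporting,
  plus across-sample aggregation.
* **Rule-based fiber architectures.** Harmonic scalar fields on a
  triangulated leaflet surface (cotangent-Laplacian FEM): FD1 (body-fitted,
  point constraints at the two commissures) and FD2 (circumferential,
  attachment-edge constraints); fibers are the normalized surface gradient.
* **Three-element Windkessel afterload** (`Rc`, `Rp`, `C`), integrated with
  the exact exponential update for sampled flow.
* **Hemodynamic indices.** Regurgitant fraction RF, mean systolic
  transvalvular pressure gradient TPG, effective orifice area
  `EOA = Q_rms / (51.6 sqrt(dP/rho))`, and LV energy loss
  `E_L = 0.1333 * integral (P_ao - P_lv) Q dt` (mJ).
* **Multi-criteria case ranking.** Min-max scoring of twelve criteria
  (best case 1, worst 0) across the six law x architecture cases, with the
  published comparative-study metrics bundled as structured input.
* **Synthetic-data generators** for stress-controlled biaxial protocols,
  lumped valve-afterload cycle waveforms, and labeled leaflet meshes.

The package is aimed at cardiovascular-biomechanics researchers who need a
tested, scriptable reference for these building blocks without running a
3-D fluid-structure interaction solver; FSI-derived field quantities enter
only as printed metric tables consumed by the scoring stage.

## Worked example

Rank the six modeled cases (three laws x two fiber architectures) from the
bundled study metrics:

```python
from valvemech.casedata import study_score_table

tbl = study_score_table(reproduce_published=True)
print(tbl.totals.to_dict())
print(tbl.rank)
```

```
{'W1FD1': 9.16, 'W2FD1': 6.54, 'W3FD1': 5.32, 'W1FD2': 8.7, 'W2FD2': 8.54, 'W3FD2': 4.43}
['W1FD1', 'W1FD2', 'W2FD2', 'W2FD1', 'W3FD1', 'W3FD2']
```

Each total sums twelve per-criterion scores in [0, 1]; the exponential
fiber + cross-fiber law with the body-fitted architecture (W1FD1) ranks
best. Calibrating the laws to a synthetic stress-controlled biaxial sample
generated from the W1 parameters with 2% noise
(`python examples/calibrate_biaxial.py`) prints

```
W1: R^2 = 0.9986, RMSE = 4.363 kPa | C10=1.12, C01=8.16, k1=26.8, k2=54.2
W2: R^2 = 0.9983, RMSE = 4.764 kPa | mu=0.049, c0=13.5, c1=6.76, c2=47.6
W3: R^2 = 0.6901, RMSE = 64.125 kPa | C1=109, a=0.929, b=144
```

— the generating law fits best and W3, whose cross-fiber response is
linear, fits worst. The `examples/` directory holds one short script per
capability (scoring, calibration, fiber fields, Windkessel pressures,
hemodynamic indices).

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
decisions and the limits of what the synthetic generators emulate.
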