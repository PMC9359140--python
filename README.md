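# qtransport

Q-system calculator for **A1/A2 radioactive-transport activity limits**, with
analytic and Monte Carlo monoenergetic dose-rate kernels.

## The problem

Shipping a radionuclide in a type A package is only allowed up to a per-nuclide
activity limit: **A1** for special form sources (certified sealed capsules,
indispersible solids) and **A2** for everything else.  For many radionuclides of
growing medical interest — Tb-149, Tb-161, Bi-213, and other theranostic
isotopes — no tabulated limit exists, and very conservative generic values
apply (e.g. 9×10⁻⁵ TBq for untabulated alpha emitters), which can make a single
preclinical study logistically impossible.

The limits derive from the IAEA **Q-system**: five accidental-exposure
scenarios around a damaged package, each yielding an activity `Q` (TBq) that
would deliver a reference dose:

| Q  | scenario | formula |
|----|----------|---------|
| Q_A | external photon dose, 1 m, 30 min, 0.05 Sv | `Q_A = 1e-13 / ė_pt` |
| Q_B | external beta skin dose, 1 m, residual shield SF | `Q_B = 1e-12 / ė_β` |
| Q_C | inhalation of 1e-6 of contents, 0.05 Sv | `Q_C = 5e-8 / ė_inh` |
| Q_D | skin contamination, 5 h, 0.5 Sv, capped at 1e3 TBq | `Q_D = 2.8e-2 / ḣ_skin` |
| Q_E | submersion in released gas | lower of effective/skin branches |

with `ė_pt, ė_β` in Sv Bq⁻¹ h⁻¹, `ė_inh` in Sv/Bq, `ḣ_skin` in
Sv m² TBq⁻¹ s⁻¹.  Then **A1 = min(Q_A, Q_B)** (a sealed source cannot be
inhaled or dispersed) and **A2 = min over all defined Q values**.  Short-lived
progeny (< 10 d half-life and shorter than the parent) are folded in at secular
equilibrium; long-lived progeny form a mixture with the harmonic rule
`X_m = 1 / Σ f(i)/X(i)`.  The beta shielding factor is `SF = exp(0.017
E_β,max^-1.14 · 150)`, capped at 3 for endpoints ≥ 2 MeV or mono-energetic-only
electron emitters.

The dose-rate coefficients themselves come from **monoenergetic kernel
curves** — dose rate per decay vs source energy in each accident geometry —
convolved with each nuclide's emission spectrum (yield-weighted sums for lines,
trapezoidal integration for beta continua, annihilation photons attached to the
photon spectrum at 2× the β⁺ yield).  The package provides an analytic
point-kernel route (buildup-corrected exposure kernel for photons, scaled
point-kernels for betas) and an independent analog Monte Carlo photon transport
(Klein–Nishina sampling, photoelectric, pair production) that cross-validates
it.

## Worked example

Limits for Tb-161 from the shipped illustrative decay library:

```
$ qtransport compute-limits src/qtransport/data/medical_radionuclides.yaml -n Tb-161
nuclide,kernel_source,q_a_tbq,q_b_tbq,q_c_tbq,q_d_tbq,...,a1_tbq,a2_tbq,a1_rounded_tbq,a2_rounded_tbq,a1_limiting,a2_limiting
Tb-161,analytic,123.56,50.48,41.67,0.5965,...,50.48,0.5965,50.0,0.6,Tb-161:QB,Tb-161:QD
```

Reading: with its soft photon lines Tb-161's photon limit Q_A is large
(~124 TBq); the skin-contamination pathway Q_D ≈ 0.6 TBq is limiting for A2.
Both are orders of magnitude above the generic untabulated-beta-emitter limits
(A1 = 0.1, A2 = 0.02 TBq) — the same conclusion the published recalculation
reaches (its A2, from evaluated decay data and full MC, is 0.758 TBq).

The same pipeline in Python:

```python
from qtransport import nuclide_data as nd, compute_transport_limits
lib = nd.read_library("src/qtransport/data/medical_radionuclides.yaml")
report = compute_transport_limits(lib["Tb-161"], lib)
print(report["a1_tbq"], report["a2_tbq"])   # 50.48... 0.5964...
```

`qtransport validate-control-group` recomputes the Q → A chain from the
published coefficients for all 22 fixture nuclides and reports the deviation
(≤ 0.4% for every internally consistent printed row).

## Layout

- `qtransport.nuclide_data` — decay-data model, YAML library I/O, fixture
  generator, annihilation photons, progeny resolution
- `qtransport.physics_tables` — embedded attenuation/energy-absorption,
  exposure→effective-dose, buildup, CSDA-range tables; the partial attenuation
  model shared by the Monte Carlo and its deterministic benchmark
- `qtransport.analytic_kernels` — point kernels for the three geometries
- `qtransport.mc_transport` — analog photon Monte Carlo (kerma and
  energy-deposition tallies), Klein–Nishina sampler, CSDA electron mode
- `qtransport.spectrum_engine` — spectrum × kernel convolution
- `qtransport.qsystem` — Q values, caps, minima, progeny/mixture rules,
  regulatory rounding
- `qtransport.validation` — published-value fixture and comparison sweeps

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
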