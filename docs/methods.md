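# Methods

This note records the models behind `qtransport`, the parameters that matter,
the numerical choices, and what the shipped tests do and do not demonstrate.

## The Q-system chain

The package computes, per radionuclide,

1. monoenergetic **kernel curves** `Ḋ(E)` — dose rate per decay vs source
   energy — for three accident geometries: whole-body photon dose at 1 m
   (water shell, inner radius 1 m, thickness 0.30 m, in air), beta dose to the
   dermal layer (0.04 mm thick at 0.07 mm depth) at 1 m, and the same dermal
   layer under surface contamination at contact;
2. **pathway coefficients** by convolving each nuclide's spectrum with the
   curves: `ė_pt = Σ I(E_i) Ḋ(E_i)` over photon lines,
   `ė_β = (ė_mono + ė_cont)/SF` over electron/positron emissions, and
   `ḣ_skin = ḣ_mono + ḣ_cont` at contact.  Continua are integrated with the
   trapezoid rule on the spectrum's own grid, the kernel being linearly
   interpolated onto the spectrum abscissae (never the reverse).  Conversion
   electrons enter as monoenergetic lines weighted by yield; each positron
   contributes two 0.511 MeV photons to the *photon* spectrum (and its charged
   dose to the beta pathways);
3. the five **Q values**, the **Q_D cap** at 10³ TBq, and
   `A1 = min(Q_A, Q_B)`, `A2 = min(all defined Q)`.  A pathway with zero
   coefficient is *absent* (excluded from the minima), not infinite.

Reference parameters (all overridable via `ReferenceParameters`): effective
reference dose 0.05 Sv; skin reference dose 0.5 Sv; exposure time 0.5 h;
inhaled fraction 1e-6; skin deposit 1e-3 m⁻²; skin exposure 1.8e4 s; unit
constant 1e-12 TBq/Bq.  `q_d` uses the regulatory two-digit constant
2.8×10⁻² TBq (the exact parameter product is 2.778×10⁻²); the tabulated Q_D
values derive from the rounded form, so the package adopts it as the default.

### Shielding factor

`SF = exp(μd)` with `μ = 0.017 E_β,max^(-1.14)` cm²/mg and `d = 150` mg/cm²,
capped at 3 for `E_β,max ≥ 2` MeV, and set a priori to 3 for emitters with
only monoenergetic electrons.  The unshielded dose rate is **divided** by SF:
SF ≥ 1 models absorption by residual package debris, so dividing is the only
orientation that reduces the dose (formulations that write the coefficient as
`SF × (…)` are interpreted as defining the *shielded-source* coefficient; the
division form is algebraically identical when SF is moved across the Q
quotient, and the arithmetic-chain validation confirms the printed tables are
consistent with division).

### Progeny and mixtures

A daughter with half-life < 10 d *and* shorter than its parent is taken in
secular equilibrium (motivated by the 50-day maximum transport window):
coefficients and Q values are computed for parent and daughter (daughter
weighted by the chain activity fraction, i.e. the branching product), and the
elementwise **minimum** of the limits is used.  Any other daughter forms a
mixture with the parent, combined with the harmonic rule
`X_m = 1/Σ f(i)/X(i)`.  Chains recurse at most 5 deep; deeper chains raise
rather than silently truncating.  No Bateman time evolution is performed —
the transport window enters only through the classification rule.

### Rounding

Q values quote to 2 significant digits, limits to 1; both round
half-to-even ("rounded up or down to the nearest significant figure" is
ambiguous between directions; nearest-with-banker's-ties is adopted and
rounding never shifts a value by more than half a decade).  Raw values are the
default output; rounding is explicit.

## Photon kernel (analytic)

Point-kernel at distance d in air:

    ė(E) = (e/X)_E · E · (μ_en/ρ)_E · exp(−μd) · B(E, μd) / (4πd²) · C

with the exposure-to-effective-dose conversion (e/X) interpolated log-log on
an embedded 5 keV–10 MeV table, air attenuation and energy-absorption
coefficients from embedded NIST-style tables, and a Berger-form air buildup
model `B = 1 + a(E)·x·e^{b(E)x}`.  C converts MeV/g per decay to Sv/h per Bq.
At 1 m in air the optical depth is only ~0.005–0.02 mfp, so B ≤ 1.06 and the
buildup model's coarseness is immaterial to the coefficient.  The kernel grid
spans 0.01–10 MeV, denser below 0.2 MeV.

The kernel reports the dose *at the detector entrance point* (1 m), not the
mass-average over the 0.30 m body shell: the point form is what the Q_A
formula consumes, it satisfies exact inverse-square scaling in vacuum mode,
and it reproduces the published photon coefficients (e.g. the pure-EC
control nuclide Be-7 to 0.4% with its single 0.478 MeV line).  The
shell-averaged observable remains available as the Monte Carlo deposit tally;
it is intrinsically 0.4–0.7× the point dose (inverse-square falloff and
self-shielding across 30 cm of water), a geometric fact the test suite pins
with a sanity band rather than hiding.

The embedded (e/X) curve is a smooth synthetic approximation of published
effective-dose-per-exposure data with an isotropic-irradiation-like response
(≈0.70 Sv/Gy·8.76 mGy/R at 0.5 MeV rising slowly with energy); its provenance
header marks it approximate.  With it, the analytic pipeline lands within
about ±25% of the published Monte-Carlo ė_pt for the photon-dominated control
nuclides when fed illustrative decay lines (Be-7 −0.4%, Co-58 −7%, Cs-137
−14%, Na-22 +11%, Na-24 +22%; Co-60 +42% against a published value that
itself sits 24% below the tabulated regulatory coefficient).  This comparison is reported by
`validation.compare_e_pt`, not gated.

## Beta kernels (scaled point-kernel)

Monoenergetic electron dose at areal distance z (g/cm²) from a point source:

    D(E, r) = E · j(z/r_E, E) / (4π r² ρ r_E)

where `r_E` is the CSDA range and `j` a dimensionless deposition profile with
`∫ j dx = 1` (energy conservation, asserted within 2%).  For the 1 m geometry
z is the air column (0.1205 g/cm²) plus the dermal overburden; a mean
tissue/air stopping-power ratio of 1.11 converts to tissue dose.  For contact,
the per-unit-area coefficient integrates the point kernel over the
contaminated plane, `D_plane(z) = E/(2 r_E) ∫_{z/r_E} j(x)/x dx`, averaged
over the dermal layer (0.007–0.011 g/cm²) and normalized to 1 TBq/m² =
10⁸ Bq/cm², giving ḣ_skin in Sv m² TBq⁻¹ s⁻¹.  Positron kernels equal
electron kernels (the density-effect difference in stopping power is
neglected).

**The shipped `j` profile is synthetic**: `j(x) ∝ x² exp(−(x/0.7)³)`,
normalized, energy-independent, constructed — in the absence of
publicly shippable evaluated kernel tables — to reproduce the qualitative
morphology the full Monte-Carlo curves show: zero below the range cutoff
(0.36 MeV at 1 m, 0.06 MeV at the dermal depth), a single peak (0.3–0.7 MeV
at 1 m; at the energy whose range matches the dermal depth scale at contact),
monotone decay at high energy.  Consequences: `ḣ_skin` magnitudes come out
within ~10% of published values (e.g. an allowed 1.39 MeV endpoint spectrum
gives 4.2×10⁻² vs 3.99×10⁻² published), but `ė_β` at 1 m is biased low by a
factor ~2–3 (detour/backscatter physics near end-of-range is not captured by
the parametric shape).  The table object is swappable
(`BetaDoseTables`); replacing it with a digitized evaluated kernel set
upgrades the beta coefficients without touching any other code.  None of the
acceptance checks depend on the absolute beta-kernel scale.

A straight-ahead CSDA electron mode (`run_electron_kernel_csda`) provides an
independent order-of-magnitude check and reproduces both range cutoffs
exactly from the range tables; it is not a kernel source for coefficients.

## Monte Carlo photon transport

Analog (unweighted) transport of isotropic point-source photons through
concentric spherical regions; interactions are sampled from a
self-consistent **partial attenuation model**: Klein–Nishina incoherent
scattering on Z/A free electrons per gram, a photoelectric power law
`A·(E/10 keV)^−n` anchored to the standard totals at 10 and 50 keV, and a pair
term `p·(E−1.022)^q` anchored at 2 and 10 MeV.  Coherent scattering and
fluorescence are omitted (few-percent bias above 50 keV, documented); the
model total therefore deliberately differs from the tabulated
(coherent-inclusive) attenuation table used by the analytic exposure kernel.
Compton scattering uses Kahn's rejection sampling (validated against angular
quadrature to 3σ at 10⁵ samples and against the kinematic bounds); electron
energy deposits locally — i.e. every tally is a collision-kerma estimator,
appropriate for centimetre-scale detectors where secondary-electron ranges
are small; pair production deposits `E − 1.022` locally and tracks both
annihilation photons; photons below 10 keV deposit locally.

Tallies:

* **deposit** — energy deposited in the detector shell per history over the
  shell mass (the pulse-height-tally analogue);
* **kerma** — track-length collision-kerma in a thin (2.5 cm) air probe shell
  at the detector distance, the estimator of the *point* dose at 1 m.

The cross-validation compares the kerma tally against the deterministic
point-kernel built on the *same* partial model (`photon_kerma_point`), so the
comparison isolates transport correctness from cross-section choice; measured
agreement is 2.5–4% across 0.1–5 MeV at 2×10⁵ histories (tolerance
10% + 3σ), the residual being the approximate buildup model vs true
multiple scattering and world truncation at 20 m.  In vacuum mode with an
absorbing detector the closed shell captures every history's full energy
exactly (geometry-closure identity).  Everything is reproducible bit-for-bit
from the seed; the per-energy standard error scales as n^(−1/2) (asserted
within a factor 1.5 over 10³–10⁵ histories).  Production history count
defaults to 10⁷; tests and the cross-validation use 2×10⁵, which already
drives the tally standard error below 0.1%.

## Synthetic data and fixtures

* `make_fixture_nuclide` generates the five emitter archetypes (pure gamma
  line, allowed-shape beta continuum, mixed, positron, parent+daughter chain),
  deterministic per seed; allowed shapes use `p·W·(Q−E)²` without the Fermi
  function.
* The shipped YAML libraries (`control_group.yaml`,
  `medical_radionuclides.yaml`) carry *illustrative, approximate* line and
  endpoint parameters for real nuclides — sufficient to exercise the full
  pipeline and to place coefficients at the right order of magnitude, but not
  evaluated nuclear data; their headers say so.
* The published coefficients/Q/A table for all 22 study nuclides ships as
  `reference_limits.csv` with a per-row flag marking the handful of printed
  rows whose own arithmetic chain is internally inconsistent (ragged cells);
  strict 1% comparisons use only consistent rows.  The fixture records the
  printed daughter strings verbatim (including the At-211 "Po-212" entry).

What passing tests show: the Q→A arithmetic, aggregation, progeny/mixture and
rounding rules reproduce the published tables; the transport and convolution
operators satisfy their conservation, scaling and oracle properties.  What
they do not show: agreement of absolute beta coefficients with evaluated-data
Monte Carlo (see the j-profile limitation), or inhalation/submersion dosimetry
(tabulated inputs by design).

## Numerical choices and degenerate inputs

* Interpolation: log-log for cross-section-like tables, linear for kernel
  curves; exact at grid points; out-of-range energies raise (no
  extrapolation).  Below-cutoff energies return identically 0.
* Beta spectra are stored pre-binned; their trapezoidal integral must match
  the stated yield to 1e-6 relative, and the endpoint must match the grid.
* Zero-coefficient pathways are absent, never 0 or ∞ limits; an emitter with
  no emissions at all has no defined Q and `limits` raises.
* Air's printed composition sums to 100.002%; it is kept verbatim and
  normalized on use.
* All energies are MeV and activities Bq internally; TBq appears only in
  `qsystem`.

## Known limitations

* Synthetic beta deposition profile (factor-level bias in `ė_β`, above).
* No bremsstrahlung generation from beta slowing-down in the analytic
  kernels; no coherent scattering or fluorescence in the MC.
* Effective-dose conversion and buildup coefficients are approximate
  digitizations with provenance headers, not certified compilations.
* Inhalation (`ė_inh`) and submersion coefficients are tabulated inputs;
  alpha hazard enters only through `ė_inh`.
* The electron mode is straight-ahead CSDA — cutoffs and magnitudes only.
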