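"""Convolution engine: interpolation, trapezoid oracle, linearity, SF."""

import numpy as np
import pytest

from qtransport.analytic_kernels import KernelCurve
from qtransport.nuclide_data import (
    BetaSpectrum,
    EmissionLine,
    Nuclide,
    Particle,
    ProgenyLink,
    NuclideLibrary,
    allowed_beta_density,
    make_fixture_nuclide,
)
from qtransport.spectrum_engine import (
    compute_dose_coefficients,
    continuum_integral,
    discrete_sum,
    kernel_at,
    pathway_coefficient,
)


def _curve(energies, values, particle=Particle.PHOTON, geometry="QA_1m_body",
           units="Sv/(Bq h)"):
    e = np.asarray(energies, dtype=float)
    v = np.asarray(values, dtype=float)
    return KernelCurve(particle, geometry, e, v, np.zeros_like(v), units=units)


def _beta_curve(energies, values, geometry="QB_1m_skin"):
    return _curve(energies, values, Particle.ELECTRON, geometry)


# ---------------------------------------------------------------------------
# kernel_at
# ---------------------------------------------------------------------------

def test_kernel_at_contract():
    curve = _curve([1.0, 2.0, 3.0], [4.0, 10.0, 6.0])
    assert kernel_at(curve, 2.0) == 10.0                      # grid identity
    assert kernel_at(curve, 1.5) == pytest.approx((4 + 10) / 2)  # midpoint
    assert kernel_at(curve, 0.5) == 0.0                       # below cutoff
    with pytest.raises(ValueError):
        kernel_at(curve, 3.5)                                 # above grid


# ---------------------------------------------------------------------------
# discrete_sum
# ---------------------------------------------------------------------------

def test_discrete_sum_hand_oracle():
    curve = _curve([1.0, 2.0], [3.0, 7.0])
    lines = [EmissionLine(Particle.PHOTON, 1.0, 0.4),
             EmissionLine(Particle.PHOTON, 2.0, 0.6)]
    assert discrete_sum(lines, curve) == pytest.approx(0.4 * 3.0 + 0.6 * 7.0)
    assert discrete_sum([], curve) == 0.0
    single = [EmissionLine(Particle.PHOTON, 2.0, 1.0)]
    assert discrete_sum(single, curve) == 7.0
    zero_yield = [EmissionLine(Particle.PHOTON, 1.0, 0.0)]
    assert discrete_sum(zero_yield, curve) == 0.0


def test_discrete_sum_particle_mismatch():
    curve = _curve([1.0, 2.0], [3.0, 7.0])
    with pytest.raises(ValueError, match="does not match"):
        discrete_sum([EmissionLine(Particle.ELECTRON, 1.0, 1.0)], curve)
    bcurve = _beta_curve([0.36, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="does not match"):
        discrete_sum([EmissionLine(Particle.PHOTON, 1.0, 1.0)], bcurve)
    # positrons ride the electron kernels
    assert discrete_sum([EmissionLine(Particle.POSITRON, 2.0, 1.0)], bcurve) == 2.0


# ---------------------------------------------------------------------------
# continuum_integral
# ---------------------------------------------------------------------------

def test_constant_density_times_constant_kernel_is_rectangle():
    grid = np.linspace(1.0, 2.0, 11)
    c = 0.8
    dens = np.full_like(grid, c)
    spec = BetaSpectrum(grid, dens, float(np.trapezoid(dens, grid)), 2.0)
    curve = _beta_curve([0.5, 3.0], [5.0, 5.0])
    assert continuum_integral(spec, curve) == pytest.approx(c * 5.0 * 1.0)


def test_three_point_hand_trapezoid():
    grid = np.array([1.0, 1.5, 2.0])
    dens = np.array([0.2, 0.6, 0.1])
    spec = BetaSpectrum(grid, dens, float(np.trapezoid(dens, grid)), 2.0)
    curve = _beta_curve([1.0, 2.0], [2.0, 4.0])  # kernel linear: 2 + 2(E-1)
    prod = dens * np.array([2.0, 3.0, 4.0])
    expected = (prod[0] + prod[1]) / 2 * 0.5 + (prod[1] + prod[2]) / 2 * 0.5
    assert continuum_integral(spec, curve) == pytest.approx(expected)


def test_spectrum_below_cutoff_integrates_to_zero_with_warning():
    grid, dens = allowed_beta_density(0.2, 1.0)
    spec = BetaSpectrum(grid, dens, 1.0, 0.2)
    curve = _beta_curve([0.36, 4.0], [1.0, 2.0])
    with pytest.warns(UserWarning, match="below"):
        assert continuum_integral(spec, curve) == 0.0


def test_trapezoid_against_fine_grid_quadrature():
    """The engine's binned trapezoid tracks a 100x-refined quadrature
    within 1% on smooth synthetic spectra (the residual is the binning
    error of the method itself)."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        e_max = rng.uniform(0.8, 3.0)
        grid, dens = allowed_beta_density(e_max, 1.0, n_bins=60)
        spec = BetaSpectrum(grid, dens, 1.0, e_max)
        kgrid = np.linspace(0.05, 4.0, 25)
        kvals = np.exp(-((kgrid - 0.9) ** 2))  # smooth synthetic kernel
        curve = _beta_curve(kgrid, kvals)
        coarse = continuum_integral(spec, curve)

        fine = np.linspace(grid[0], grid[-1], grid.size * 100)
        dens_f = np.interp(fine, grid, dens)
        kern_f = np.interp(fine, kgrid, kvals)
        kern_f[fine < kgrid[0]] = 0.0
        refined = np.trapezoid(dens_f * kern_f, fine)
        assert coarse == pytest.approx(refined, rel=0.01)


# ---------------------------------------------------------------------------
# pathway_coefficient
# ---------------------------------------------------------------------------

def test_pure_gamma_line_on_grid_returns_kernel_value(curveset):
    curve = curveset["photon_1m"]
    e = float(curve.energies[40])
    nuc = make_fixture_nuclide("gamma_line", energy=e, yield_=1.0)
    res = pathway_coefficient(nuc, curveset, "photon_1m")
    assert res.value == pytest.approx(float(curve.values[40]), rel=1e-12)


def test_high_endpoint_beta_gets_capped_shielding_factor(curveset):
    nuc = make_fixture_nuclide("beta_continuum", e_max=2.5)
    res = pathway_coefficient(nuc, curveset, "beta_1m")
    assert res.shielding_factor == 3.0
    assert res.value == pytest.approx(res.unshielded / 3.0)


def test_mono_only_emitter_gets_a_priori_sf(curveset):
    nuc = Nuclide("CE", 1.0, lines=(EmissionLine(Particle.ELECTRON, 1.0, 0.8),))
    res = pathway_coefficient(nuc, curveset, "beta_1m")
    assert res.shielding_factor == 3.0
    assert res.continuum == 0.0


def test_alpha_only_nuclide_flagged_zero(curveset):
    nuc = Nuclide("A", 1.0, lines=(EmissionLine(Particle.ALPHA, 5.0, 1.0),))
    for pathway in ("photon_1m", "beta_1m", "skin_contact"):
        res = pathway_coefficient(nuc, curveset, pathway)
        assert res.value == 0.0
        assert res.no_emissions


def test_breakdown_sums_to_pre_sf_total(curveset):
    nuc = make_fixture_nuclide("mixed", e_max=1.5)
    nuc = Nuclide(nuc.id, nuc.half_life_days,
                  lines=nuc.lines + (EmissionLine(Particle.ELECTRON, 0.6, 0.3),),
                  beta_spectra=nuc.beta_spectra)
    res = pathway_coefficient(nuc, curveset, "beta_1m")
    assert res.mono + res.continuum == pytest.approx(res.unshielded, rel=1e-9)
    assert res.value == pytest.approx(res.unshielded / res.shielding_factor)


def test_linearity_and_additivity_on_random_fixtures(curveset):
    """Coefficients are additive over lines and linear in the yields."""
    rng = np.random.default_rng(11)
    curve = curveset["photon_1m"]
    for _ in range(100):
        e1, e2 = rng.uniform(0.05, 5.0, 2)
        y1, y2 = rng.uniform(0.05, 1.5, 2)
        scale = rng.uniform(0.1, 5.0)
        n1 = Nuclide("L1", 1.0, lines=(EmissionLine(Particle.PHOTON, e1, y1),))
        n2 = Nuclide("L2", 1.0, lines=(EmissionLine(Particle.PHOTON, e2, y2),))
        both = Nuclide("L12", 1.0, lines=n1.lines + n2.lines)
        scaled = Nuclide("LS", 1.0, lines=(
            EmissionLine(Particle.PHOTON, e1, y1 * scale),))
        v1 = pathway_coefficient(n1, curveset, "photon_1m").value
        v2 = pathway_coefficient(n2, curveset, "photon_1m").value
        v12 = pathway_coefficient(both, curveset, "photon_1m").value
        vs = pathway_coefficient(scaled, curveset, "photon_1m").value
        assert v12 == pytest.approx(v1 + v2, rel=1e-12)
        assert vs == pytest.approx(scale * v1, rel=1e-12)


def test_equilibrium_chain_coefficient_additivity(curveset):
    """Parent + equilibrium daughter: summed coefficient equals
    parent-alone plus branching-weighted daughter-alone."""
    from qtransport.nuclide_data import resolve_progeny

    lib = NuclideLibrary()
    parent = Nuclide("P", 30.0,
                     lines=(EmissionLine(Particle.PHOTON, 0.8, 0.7),),
                     progeny=(ProgenyLink("D", 0.6, 0.01),))
    daughter = Nuclide("D", 0.01, lines=(EmissionLine(Particle.PHOTON, 0.3, 0.9),))
    lib.add(parent), lib.add(daughter)
    vp = pathway_coefficient(parent, curveset, "photon_1m").value
    vd = pathway_coefficient(daughter, curveset, "photon_1m").value
    total = 0.0
    for nuc, treatment, fraction in resolve_progeny(parent, lib):
        w = fraction if treatment == "equilibrium" else 1.0
        total += w * pathway_coefficient(nuc, curveset, "photon_1m").value
    assert total == pytest.approx(vp + 0.6 * vd, rel=1e-12)


def test_compute_dose_coefficients_passthrough(curveset):
    nuc = Nuclide("X", 1.0, lines=(EmissionLine(Particle.PHOTON, 1.0, 1.0),),
                  e_inh=3.3e-9)
    coeffs = compute_dose_coefficients(nuc, curveset)
    assert coeffs.e_inh == 3.3e-9
    assert coeffs.e_pt > 0
    assert coeffs.kernel_source == "analytic"
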