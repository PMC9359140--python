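"""Nuclide data model: I/O round-trips, fixtures, annihilation, progeny."""

import numpy as np
import pytest

from qtransport import nuclide_data as nd
from qtransport.nuclide_data import (
    BetaSpectrum,
    EmissionLine,
    Nuclide,
    NuclideLibrary,
    Particle,
    ProgenyLink,
    SchemaError,
    allowed_beta_density,
    attach_annihilation_photons,
    classify_progeny,
    make_fixture_nuclide,
    read_library,
    resolve_progeny,
    write_library,
)


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kinds", [
    ["gamma_line", "beta_continuum"],
    ["mixed", "positron", "chain"],
])
def test_round_trip_identity(tmp_path, kinds):
    lib = NuclideLibrary(source="test", version="x")
    for i, kind in enumerate(kinds):
        lib.add(make_fixture_nuclide(kind, seed=i, nuclide_id=f"T-{i}"))
    path = tmp_path / "lib.yaml"
    write_library(lib, path)
    back = read_library(path)
    assert back.source == "test" and back.version == "x"
    assert set(back.nuclides) == set(lib.nuclides)
    for nid in lib.nuclides:
        a, b = lib[nid], back[nid]
        assert a.lines == b.lines
        assert a.half_life_days == b.half_life_days
        assert len(a.beta_spectra) == len(b.beta_spectra)
        for sa, sb in zip(a.beta_spectra, b.beta_spectra):
            np.testing.assert_allclose(sa.density, sb.density)
            np.testing.assert_allclose(sa.energy_grid, sb.energy_grid)
        assert a.progeny == b.progeny
        assert a.e_inh == b.e_inh


def test_packaged_round_trip(tmp_path, control_library, medical_library):
    for lib in (control_library, medical_library):
        p = tmp_path / "x.yaml"
        write_library(lib, p)
        back = read_library(p)
        assert set(back.nuclides) == set(lib.nuclides)


def test_inconsistent_beta_yield_is_schema_violation(tmp_path):
    grid, dens = allowed_beta_density(1.0, 0.93)
    lib = NuclideLibrary()
    lib.add(make_fixture_nuclide("gamma_line", nuclide_id="OK-1"))
    path = tmp_path / "bad.yaml"
    write_library(lib, path)
    # corrupt the file: density integrates to 0.93 but total_yield says 1.0
    import yaml

    doc = yaml.safe_load(path.read_text())
    doc["nuclides"]["BAD-1"] = {
        "half_life_days": 1.0,
        "beta_spectra": [{
            "particle": "electron",
            "energy_grid": [float(x) for x in grid],
            "density": [float(x) for x in dens],
            "total_yield": 1.0,
            "e_max": 1.0,
        }],
    }
    path.write_text(yaml.safe_dump(doc))
    with pytest.raises(SchemaError, match="BAD-1.*total_yield"):
        read_library(path)


def test_missing_file_and_duplicate_id(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_library(tmp_path / "nope.yaml")
    lib = NuclideLibrary()
    lib.add(make_fixture_nuclide("gamma_line", nuclide_id="A"))
    with pytest.raises(SchemaError, match="duplicate"):
        lib.add(make_fixture_nuclide("gamma_line", nuclide_id="A"))


def test_twelve_medical_radionuclides_load(medical_library):
    expected = {"Cu-61", "As-71", "Se-72", "Nd-140", "Tb-152", "Tb-155",
                "Tb-156", "Tb-161", "Tm-166", "Yb-166", "Tb-149", "Bi-213"}
    assert set(medical_library.nuclides) == expected
    assert len(medical_library) == 12


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------

def test_gamma_line_fixture_is_single_line():
    nuc = make_fixture_nuclide("gamma_line", energy=0.662, yield_=0.851)
    assert len(nuc.lines) == 1
    line = nuc.lines[0]
    assert line.particle is Particle.PHOTON
    assert line.energy_mev == 0.662 and line.yield_per_decay == 0.851


def test_beta_continuum_normalization():
    nuc = make_fixture_nuclide("beta_continuum", e_max=1.0, total_yield=1.0)
    s = nuc.beta_spectra[0]
    integral = np.trapezoid(s.density, s.energy_grid)
    assert integral == pytest.approx(1.0, rel=1e-6)
    assert s.e_max == pytest.approx(1.0)


def test_fixture_determinism():
    for kind in ("gamma_line", "beta_continuum", "mixed", "positron", "chain"):
        a = make_fixture_nuclide(kind, seed=123)
        b = make_fixture_nuclide(kind, seed=123)
        assert a.lines == b.lines and a.progeny == b.progeny
        for sa, sb in zip(a.beta_spectra, b.beta_spectra):
            np.testing.assert_array_equal(sa.density, sb.density)
    with pytest.raises(ValueError):
        make_fixture_nuclide("nope")


# ---------------------------------------------------------------------------
# Annihilation photons
# ---------------------------------------------------------------------------

def test_annihilation_yield_is_twice_positron_yield():
    nuc = Nuclide("B+", 1.0, beta_spectra=(
        nd.BetaSpectrum(*allowed_beta_density(1.6, 0.071), 0.071, 1.6,
                        Particle.POSITRON),))
    out = attach_annihilation_photons(nuc)
    (line,) = out.lines_of(Particle.PHOTON)
    assert line.energy_mev == 0.511
    assert line.yield_per_decay == pytest.approx(2 * 0.071)
    # energy bookkeeping: added photon energy per decay = 2 * 0.511 * yield
    assert line.energy_mev * line.yield_per_decay == pytest.approx(
        2 * 0.511 * 0.071)
    # positron emissions retained for the beta pathways
    assert out.beta_spectra == nuc.beta_spectra


def test_annihilation_noop_and_idempotence():
    plain = make_fixture_nuclide("gamma_line")
    assert attach_annihilation_photons(plain) == plain
    pos = make_fixture_nuclide("positron")
    once = attach_annihilation_photons(pos)
    assert attach_annihilation_photons(once) == once


# ---------------------------------------------------------------------------
# Progeny
# ---------------------------------------------------------------------------

def test_cs137_chain_resolves_to_equilibrium(control_library):
    chain = resolve_progeny(control_library["Cs-137"], control_library)
    assert chain[0][0].id == "Cs-137" and chain[0][1] is None
    (dau, treatment, fraction) = chain[1]
    assert dau.id == "Ba-137m"
    assert treatment == "equilibrium"
    assert fraction == pytest.approx(0.944)


def test_long_lived_daughter_is_mixture_component():
    lib = NuclideLibrary()
    parent = Nuclide("P", 40.0, lines=(EmissionLine(Particle.PHOTON, 1.0, 1.0),),
                     progeny=(ProgenyLink("D", 0.4, 30.0),))
    lib.add(parent)
    lib.add(Nuclide("D", 30.0, lines=(EmissionLine(Particle.PHOTON, 0.5, 1.0),)))
    chain = resolve_progeny(parent, lib)
    assert chain[1][1] == "mixture_component"
    assert chain[1][2] == pytest.approx(0.4)


def test_no_progeny_gives_singleton(control_library):
    chain = resolve_progeny(control_library["Be-7"], control_library)
    assert len(chain) == 1


def test_unresolvable_daughter_and_depth_cap():
    lib = NuclideLibrary()
    lib.add(Nuclide("P", 40.0, lines=(EmissionLine(Particle.PHOTON, 1.0, 1.0),),
                    progeny=(ProgenyLink("missing", 1.0, 1.0),)))
    with pytest.raises(KeyError, match="missing"):
        resolve_progeny(lib["P"], lib)

    deep = NuclideLibrary()
    for i in range(8):
        deep.add(Nuclide(
            f"C{i}", 40.0 - i, lines=(EmissionLine(Particle.PHOTON, 1.0, 1.0),),
            progeny=(ProgenyLink(f"C{i+1}", 1.0, 1.0),) if i < 7 else (),
        ))
    deep.add(Nuclide("C8", 0.5, lines=(EmissionLine(Particle.PHOTON, 1.0, 1.0),)))
    with pytest.raises(RecursionError):
        resolve_progeny(deep["C0"], deep)


def test_progeny_classification_matches_brute_force():
    """Classification is a pure function of the two half-lives."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        parent_hl = float(rng.uniform(0.001, 100.0))
        daughter_hl = float(rng.uniform(0.001, 100.0))
        expected = ("equilibrium"
                    if daughter_hl < 10.0 and daughter_hl < parent_hl
                    else "mixture_component")
        assert classify_progeny(daughter_hl, parent_hl) == expected
        # cross-check through the full resolver
        lib = NuclideLibrary()
        lib.add(Nuclide("P", parent_hl,
                        lines=(EmissionLine(Particle.PHOTON, 1.0, 1.0),),
                        progeny=(ProgenyLink("D", 0.5, daughter_hl),)))
        lib.add(Nuclide("D", daughter_hl,
                        lines=(EmissionLine(Particle.PHOTON, 1.0, 1.0),)))
        assert resolve_progeny(lib["P"], lib)[1][1] == expected
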