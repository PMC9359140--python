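"""Embedded physical-constant tables with interpolation contracts.

All constant tables ship inside the package as small structured text
files with provenance headers (no runtime download).  Coverage is
deliberately narrow: air, water and skin, photons 5 keV-10 MeV,
electrons 10 keV-5 MeV.  Interpolation never extrapolates: energies
outside a table raise :class:`OutOfRangeError`.

Two distinct cross-section surfaces exist on purpose:

* the *tabulated* attenuation/energy-absorption coefficients (with
  coherent scattering), used by the analytic point-kernel formula; and
* :class:`PartialAttenuationModel`, a self-consistent analytic
  decomposition (Klein-Nishina incoherent + parametric photoelectric
  and pair terms, coherent scattering excluded) shared by the Monte
  Carlo transport and its deterministic cross-check so that the two
  routes sample and integrate exactly the same physics.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .units import ELECTRON_MASS_MEV, N_AVOGADRO, R_E_CM

__all__ = [
    "OutOfRangeError",
    "Material",
    "Table1D",
    "AttenuationTable",
    "ExposureConversionTable",
    "BuildupModel",
    "ElectronRangeTable",
    "PartialAttenuationModel",
    "interp",
    "buildup",
    "standard_materials",
    "attenuation",
    "exposure_conversion",
    "buildup_model",
    "electron_ranges",
    "partial_model",
    "klein_nishina_total_cross_section",
    "klein_nishina_mean_scatter_fraction",
]


class OutOfRangeError(ValueError):
    """Requested energy lies outside the tabulated range (no extrapolation)."""


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Elemental weight fractions (percent) and density of a medium."""

    name: str
    weight_fractions: dict[str, float]
    density_g_cm3: float

    def __post_init__(self) -> None:
        total = sum(self.weight_fractions.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(
                f"{self.name}: weight fractions sum to {total}, expected 100 +- 0.1"
            )
        if self.density_g_cm3 <= 0:
            raise ValueError(f"{self.name}: density must be > 0")

    def normalized_fractions(self) -> dict[str, float]:
        """Fractions rescaled to sum exactly 100 (tables are kept verbatim)."""
        total = sum(self.weight_fractions.values())
        return {k: 100.0 * v / total for k, v in self.weight_fractions.items()}


def standard_materials() -> dict[str, Material]:
    """The three media used by the accident geometries.

    Air and water compositions/densities follow the simulation material
    table of the reference scenarios (air fractions sum to 100.002 as
    printed; they are normalized on use, kept verbatim here).  Skin is
    the ICRU 4-component soft-tissue-like composition.
    """
    return {
        "air": Material(
            "air",
            {"Ar": 1.28, "O": 23.18, "C": 0.012, "N": 75.53},
            0.001205,
        ),
        "water": Material("water", {"H": 11.2, "O": 88.8}, 1.0),
        "skin": Material(
            "skin",
            {"H": 10.0, "C": 20.4, "N": 4.2, "O": 64.5, "misc": 0.9},
            1.09,
        ),
    }


# ---------------------------------------------------------------------------
# Generic 1-D table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1D:
    """Positive-valued quantity on a strictly ascending energy grid."""

    energy_mev: np.ndarray
    values: np.ndarray
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_mev, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "energy_mev", e)
        object.__setattr__(self, "values", v)
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{self.name}: energy grid must be strictly ascending")
        if np.any(v <= 0):
            raise ValueError(f"{self.name}: table values must be > 0")

    @property
    def e_min(self) -> float:
        return float(self.energy_mev[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_mev[-1])

    def __call__(self, energy, mode: str = "loglog"):
        return interp(self, energy, mode)


def interp(table: Table1D, energy, mode: str = "loglog"):
    """Interpolate a table at ``energy`` (scalar or array).

    ``linear`` or ``loglog``; exact at grid points; energies outside the
    grid raise :class:`OutOfRangeError` rather than extrapolating.
    """
    e = np.asarray(energy, dtype=float)
    if np.any(e < table.e_min - 1e-12) or np.any(e > table.e_max + 1e-12):
        raise OutOfRangeError(
            f"{table.name or 'table'}: energy {energy} outside "
            f"[{table.e_min}, {table.e_max}] MeV"
        )
    e = np.clip(e, table.e_min, table.e_max)
    if mode == "linear":
        out = np.interp(e, table.energy_mev, table.values)
    elif mode == "loglog":
        out = np.exp(
            np.interp(np.log(e), np.log(table.energy_mev), np.log(table.values))
        )
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return float(out) if np.isscalar(energy) else out


# ---------------------------------------------------------------------------
# Packaged CSV loading
# ---------------------------------------------------------------------------

def _load_csv(name: str) -> tuple[dict[str, np.ndarray], str]:
    """Read a packaged table; returns columns and the '#' provenance header."""
    text = (resources.files("qtransport.data") / name).read_text()
    header_lines, rows = [], []
    columns: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            header_lines.append(line.lstrip("# "))
            continue
        if columns is None:
            columns = [c.strip() for c in line.split(",")]
            continue
        rows.append([p.strip() for p in line.split(",")])
    assert columns is not None, name
    data = {
        c: np.array(
            [float(r[i]) if r[i] else np.nan for r in rows], dtype=float
        )
        for i, c in enumerate(columns)
    }
    return data, "\n".join(header_lines)


# ---------------------------------------------------------------------------
# Concrete tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttenuationTable:
    """mu/rho and mu_en/rho for one material (cm^2/g), loglog interpolated."""

    material: str
    mu_rho: Table1D
    mu_en_rho: Table1D
    provenance: str = ""

    def mu(self, energy, density_g_cm3: float):
        """Linear attenuation coefficient (1/cm)."""
        return self.mu_rho(energy) * density_g_cm3


@functools.lru_cache(maxsize=None)
def attenuation(material: str) -> AttenuationTable:
    data, prov = _load_csv(f"attenuation_{material}.csv")
    return AttenuationTable(
        material,
        Table1D(data["energy_mev"], data["mu_rho"], f"mu_rho[{material}]", prov),
        Table1D(data["energy_mev"], data["mu_en_rho"], f"mu_en_rho[{material}]", prov),
        prov,
    )


@dataclass(frozen=True)
class ExposureConversionTable:
    """(e/X): effective dose per unit exposure, Sv/R, 5 keV-10 MeV."""

    table: Table1D

    def __post_init__(self) -> None:
        if self.table.e_min < 0.005 - 1e-12 or self.table.e_max > 10.0 + 1e-9:
            raise ValueError("(e/X) grid must lie within [0.005, 10] MeV")

    def __call__(self, energy):
        return self.table(energy, mode="loglog")


@functools.lru_cache(maxsize=None)
def exposure_conversion() -> ExposureConversionTable:
    data, prov = _load_csv("exposure_to_effective.csv")
    return ExposureConversionTable(
        Table1D(data["energy_mev"], data["sv_per_r"], "e_over_X", prov)
    )


@dataclass(frozen=True)
class BuildupModel:
    """Berger-form buildup factors B(E, x) = 1 + a(E) * x * exp(b(E) * x).

    ``x`` is the optical depth in mean free paths; coefficients are
    interpolated linearly in log energy.  B(E, 0) = 1 and B is
    nondecreasing in depth for the embedded (a > 0, b >= 0) rows.
    """

    model_id: str
    energy_mev: np.ndarray
    a: np.ndarray
    b: np.ndarray
    provenance: str = ""

    @property
    def e_min(self) -> float:
        return float(self.energy_mev[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_mev[-1])

    def coefficients(self, energy):
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.e_min - 1e-12) or np.any(e > self.e_max + 1e-9):
            raise OutOfRangeError(
                f"buildup[{self.model_id}]: energy {energy} outside "
                f"[{self.e_min}, {self.e_max}] MeV"
            )
        loge = np.log(np.clip(e, self.e_min, self.e_max))
        a = np.interp(loge, np.log(self.energy_mev), self.a)
        b = np.interp(loge, np.log(self.energy_mev), self.b)
        return a, b

    def __call__(self, energy, mfp):
        x = np.asarray(mfp, dtype=float)
        if np.any(x < 0):
            raise ValueError("optical depth must be >= 0")
        a, b = self.coefficients(energy)
        out = 1.0 + a * x * np.exp(b * x)
        if np.isscalar(mfp) and np.isscalar(energy):
            return float(out)
        return out


@functools.lru_cache(maxsize=None)
def buildup_model(model_id: str = "berger") -> BuildupModel:
    if model_id != "berger":
        raise ValueError(f"unknown buildup model {model_id!r}")
    data, prov = _load_csv("buildup_berger_air.csv")
    return BuildupModel("berger", data["energy_mev"], data["a"], data["b"], prov)


def buildup(energy, mfp, model_id: str = "berger"):
    """Air buildup factor at optical depth ``mfp`` (dimensionless)."""
    return buildup_model(model_id)(energy, mfp)


@dataclass(frozen=True)
class ElectronRangeTable:
    """CSDA ranges (g/cm^2) in air and water; strictly increasing in energy."""

    energy_mev: np.ndarray
    range_air: np.ndarray
    range_water: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("range_air", "range_water"):
            r = getattr(self, name)
            if np.any(np.diff(r) <= 0):
                raise ValueError(f"{name} must be strictly increasing with energy")

    def _table(self, material: str) -> Table1D:
        r = self.range_air if material == "air" else self.range_water
        return Table1D(self.energy_mev, r, f"csda[{material}]", self.provenance)

    def range_of(self, energy, material: str):
        """CSDA range (g/cm^2), loglog interpolation."""
        return self._table(material)(energy, mode="loglog")

    def energy_from_range(self, areal_g_cm2, material: str):
        """Inverse lookup: energy whose CSDA range equals ``areal_g_cm2``.

        Inputs below the table floor return 0 (electron already stopped
        at tabulation threshold); above the ceiling raise.
        """
        r = self.range_air if material == "air" else self.range_water
        x = np.asarray(areal_g_cm2, dtype=float)
        if np.any(x > r[-1] * (1 + 1e-9)):
            raise OutOfRangeError("residual range beyond table ceiling")
        out = np.where(
            x < r[0] * (1 - 1e-9),
            0.0,
            np.exp(np.interp(np.log(np.maximum(x, r[0])), np.log(r),
                             np.log(self.energy_mev))),
        )
        return float(out) if np.isscalar(areal_g_cm2) else out


@functools.lru_cache(maxsize=None)
def electron_ranges() -> ElectronRangeTable:
    data, prov = _load_csv("electron_csda_range.csv")
    return ElectronRangeTable(
        data["energy_mev"], data["range_air"], data["range_water"], prov
    )


# ---------------------------------------------------------------------------
# Klein-Nishina and the partial attenuation model
# ---------------------------------------------------------------------------

def klein_nishina_total_cross_section(energy_mev):
    """Total Klein-Nishina cross-section per electron (cm^2)."""
    k = np.asarray(energy_mev, dtype=float) / ELECTRON_MASS_MEV
    t = 1.0 + 2.0 * k
    sigma = (
        2.0 * np.pi * R_E_CM**2
        * (
            (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - np.log(t) / k)
            + np.log(t) / (2.0 * k)
            - (1.0 + 3.0 * k) / t**2
        )
    )
    return float(sigma) if np.isscalar(energy_mev) else sigma


def _kn_mean_fraction_grid(k_grid: np.ndarray) -> np.ndarray:
    """Mean scattered-photon energy fraction <E'/E> by quadrature over angle."""
    mu = np.linspace(-1.0, 1.0, 4001)
    out = np.empty_like(k_grid)
    for i, k in enumerate(k_grid):
        eps = 1.0 / (1.0 + k * (1.0 - mu))
        w = eps**2 * (eps + 1.0 / eps - 1.0 + mu**2)  # dsigma/dmu (unnormalized)
        out[i] = np.trapezoid(eps * w, mu) / np.trapezoid(w, mu)
    return out


@functools.lru_cache(maxsize=1)
def _kn_fraction_interpolant() -> tuple[np.ndarray, np.ndarray]:
    e = np.geomspace(0.001, 20.0, 240)
    return e, _kn_mean_fraction_grid(e / ELECTRON_MASS_MEV)


def klein_nishina_mean_scatter_fraction(energy_mev):
    """<E'/E> for Compton scattering (tabulated quadrature, interpolated)."""
    e_grid, frac = _kn_fraction_interpolant()
    e = np.asarray(energy_mev, dtype=float)
    out = np.interp(np.log(e), np.log(e_grid), frac)
    return float(out) if np.isscalar(energy_mev) else out


@dataclass(frozen=True)
class PartialAttenuationModel:
    """Analytic photon interaction model for one material (cm^2/g).

    incoherent = Klein-Nishina (free electrons, Z/A electrons per gram);
    photoelectric = A * (E/0.01 MeV)^-n anchored to the standard totals;
    pair = p * (E - 1.022)^q above threshold.  Coherent scattering is
    excluded by construction (a documented few-percent bias above
    50 keV), so attenuation here is slightly weaker than the tabulated
    totals.  The Monte Carlo transport and its deterministic benchmark
    both consume this model, keeping the comparison free of
    cross-section mismatch.
    """

    material: str
    electrons_per_gram: float
    pe_amplitude: float
    pe_exponent: float
    pair_amplitude: float
    pair_exponent: float
    valid_range: tuple[float, float] = (0.005, 10.0)

    def _check(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        lo, hi = self.valid_range
        if np.any(e < lo - 1e-12) or np.any(e > hi + 1e-9):
            raise OutOfRangeError(
                f"partial model[{self.material}]: {energy} outside {self.valid_range}"
            )
        return e

    def mu_incoherent(self, energy):
        e = self._check(energy)
        out = klein_nishina_total_cross_section(e) * self.electrons_per_gram
        return float(out) if np.isscalar(energy) else out

    def mu_photoelectric(self, energy):
        e = self._check(energy)
        out = self.pe_amplitude * (e / 0.01) ** (-self.pe_exponent)
        return float(out) if np.isscalar(energy) else out

    def mu_pair(self, energy):
        e = self._check(energy)
        excess = np.maximum(e - 2.0 * ELECTRON_MASS_MEV, 0.0)
        out = self.pair_amplitude * excess**self.pair_exponent
        return float(out) if np.isscalar(energy) else out

    def mu_total(self, energy):
        return (
            self.mu_incoherent(energy)
            + self.mu_photoelectric(energy)
            + self.mu_pair(energy)
        )

    def mu_transfer(self, energy):
        """Energy-transfer coefficient mu_tr/rho (cm^2/g).

        Photoelectric transfers the full photon energy, Compton the mean
        electron fraction 1 - <E'/E>, pair everything above 1.022 MeV.
        """
        e = self._check(energy)
        f_electron = 1.0 - klein_nishina_mean_scatter_fraction(e)
        out = (
            self.mu_photoelectric(e)
            + self.mu_incoherent(e) * f_electron
            + self.mu_pair(e) * np.maximum(e - 2.0 * ELECTRON_MASS_MEV, 0.0) / e
        )
        return float(out) if np.isscalar(energy) else out

    def interaction_probabilities(self, energy):
        """(p_photoelectric, p_incoherent, p_pair) at ``energy``."""
        parts = np.array(
            [
                self.mu_photoelectric(energy),
                self.mu_incoherent(energy),
                self.mu_pair(energy),
            ]
        )
        return parts / parts.sum(axis=0)


_MODEL_PARAMS = {
    # electrons/g = (Z/A) * N_A; photoelectric anchored at 10 and 50 keV,
    # pair at 2 and 5 MeV, against the standard total coefficients.
    "air": dict(pe_amplitude=4.88, pe_exponent=3.277,
                pair_amplitude=4.00e-4, pair_exponent=1.15, z_over_a=0.49919),
    "water": dict(pe_amplitude=5.07, pe_exponent=3.231,
                  pair_amplitude=4.05e-4, pair_exponent=1.15, z_over_a=0.55509),
}


@functools.lru_cache(maxsize=None)
def partial_model(material: str) -> PartialAttenuationModel:
    try:
        p = _MODEL_PARAMS[material]
    except KeyError:
        raise ValueError(f"no partial attenuation model for {material!r}") from None
    return PartialAttenuationModel(
        material,
        electrons_per_gram=p["z_over_a"] * N_AVOGADRO,
        pe_amplitude=p["pe_amplitude"],
        pe_exponent=p["pe_exponent"],
        pair_amplitude=p["pair_amplitude"],
        pair_exponent=p["pair_exponent"],
    )
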