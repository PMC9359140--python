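"""Closed-form monoenergetic dose-rate kernels for the accident geometries.

Three scenarios drive the external-dose Q values:

* ``QA_1m_body``   -- whole-body photon dose at 1 m in air (the "body" is
  a 0.30 m water shell with inner radius 1 m);
* ``QB_1m_skin``   -- beta dose to the dermal layer (0.04 mm thick at
  0.07 mm depth) of a person at 1 m in air;
* ``QD_contact_skin`` -- beta dose to the same dermal layer from surface
  contamination in contact with the skin.

The photon kernel is the classical point-kernel: effective dose rate at
distance d from an isotropic point source,

    e(E) = (e/X)_E * E * (mu_en/rho)_E * exp(-mu d) * B(E, d) / (4 pi d^2) * C,

with C fixed so that a 1 Bq source of unit photon yield gives Sv/h.
The beta kernels use a scaled point-kernel: a dimensionless energy
deposition profile j(r/r_E, E) over the CSDA range r_E, energy-conserving
by construction (integral of j over scaled distance = 1).  The shipped j
table is a synthetic parametric stand-in (see
:func:`synthetic_scaled_dose_table`).

Kernel curves produced here and by :mod:`qtransport.mc_transport` share
the :class:`KernelCurve` contract and are interchangeable inputs to the
spectrum engine.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from . import physics_tables as pt
from .nuclide_data import Particle
from .units import GY_AIR_PER_R, MEV_PER_G_TO_GY, S_PER_H

__all__ = [
    "GeometrySpec",
    "GEOMETRIES",
    "KernelCurve",
    "BetaDoseTables",
    "synthetic_scaled_dose_table",
    "photon_kernel_point",
    "photon_kerma_point",
    "build_photon_curve",
    "beta_jair",
    "beta_skin_contact",
    "build_beta_curve",
    "electron_cutoff",
    "default_photon_grid",
    "default_beta_grid",
]

#: dose conversion: MeV/g -> Gy, then per-hour
_MEVG_TO_GY_PER_H = MEV_PER_G_TO_GY * S_PER_H

#: mean mass-stopping-power ratio tissue/air applied to the 1 m beta kernel
TISSUE_TO_AIR_STOPPING_RATIO = 1.11

#: areal depth (g/cm^2) of the dermal detector layer: 0.07 mm depth and
#: 0.04 mm thickness in unit-density tissue
SKIN_DEPTH_G_CM2 = 0.007
SKIN_THICKNESS_G_CM2 = 0.004


@dataclass(frozen=True)
class GeometrySpec:
    """One accident geometry: point source, spherical-shell detector."""

    id: str
    distance_m: float            # source -> detector inner surface
    detector_inner_m: float
    detector_thickness_m: float
    detector_depth_m: float      # tissue depth of the sensitive layer
    detector_material: str
    medium_material: str
    particle: Particle

    @property
    def distance_cm(self) -> float:
        return self.distance_m * 100.0

    @property
    def is_beta(self) -> bool:
        return self.particle is not Particle.PHOTON


GEOMETRIES: dict[str, GeometrySpec] = {
    "QA_1m_body": GeometrySpec(
        "QA_1m_body", 1.0, 1.0, 0.30, 0.0, "water", "air", Particle.PHOTON
    ),
    "QB_1m_skin": GeometrySpec(
        "QB_1m_skin", 1.0, 1.0, 0.04e-3, 0.07e-3, "skin", "air", Particle.ELECTRON
    ),
    "QD_contact_skin": GeometrySpec(
        "QD_contact_skin", 0.0, 0.0, 0.04e-3, 0.07e-3, "skin", "skin",
        Particle.ELECTRON,
    ),
}

#: electron kernels vanish below these energies: at 1 m the CSDA range in
#: air falls short of the source-skin distance below 0.36 MeV; at contact
#: the range falls short of the dermal depth below 0.06 MeV
ELECTRON_CUTOFFS_MEV = {"QB_1m_skin": 0.36, "QD_contact_skin": 0.06}


def electron_cutoff(geom: GeometrySpec) -> float:
    """Lower energy limit of the beta kernel for ``geom`` (MeV)."""
    if not geom.is_beta:
        raise ValueError(f"{geom.id} is not a beta geometry")
    return ELECTRON_CUTOFFS_MEV[geom.id]


# ---------------------------------------------------------------------------
# Kernel curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelCurve:
    """Dose rate per decay vs monoenergetic source energy, one geometry.

    Units: Sv/(Bq h) for the 1 m geometries; Sv m^2/(TBq s) for skin
    contact (matching the h_skin convention).  ``stderr`` is zero for
    analytic provenance.  Energies below the first grid point are
    treated as below-cutoff (the spectrum engine returns 0 there).
    """

    particle: Particle
    geometry_id: str
    energies: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    provenance: str = "analytic"
    units: str = "Sv/(Bq h)"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.stderr, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "stderr", s)
        if np.any(np.diff(e) <= 0):
            raise ValueError("kernel grid must be strictly ascending")
        if v.shape != e.shape or s.shape != e.shape:
            raise ValueError("values/stderr shape mismatch")
        if np.any(v < 0):
            raise ValueError("kernel values must be >= 0")

    def to_csv(self, path_or_buf) -> None:
        buf = io.StringIO()
        buf.write(f"# particle: {self.particle.value}\n")
        buf.write(f"# geometry: {self.geometry_id}\n")
        buf.write(f"# provenance: {self.provenance}\n")
        buf.write(f"# units: {self.units}\n")
        buf.write("energy_mev,value,stderr\n")
        for e, v, s in zip(self.energies, self.values, self.stderr):
            buf.write(f"{e:.8g},{v:.8g},{s:.8g}\n")
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(buf.getvalue())
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "KernelCurve":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition(":")
                    meta[key.strip()] = val.strip()
                elif not line.startswith("energy"):
                    rows.append([float(x) for x in line.split(",")])
        arr = np.array(rows)
        return cls(
            Particle(meta.get("particle", "photon")),
            meta.get("geometry", ""),
            arr[:, 0], arr[:, 1], arr[:, 2],
            meta.get("provenance", "analytic"),
            meta.get("units", "Sv/(Bq h)"),
        )


def default_photon_grid() -> np.ndarray:
    """0.01-10 MeV, denser below 0.2 MeV where the kernel varies fastest."""
    low = np.geomspace(0.01, 0.2, 41)
    high = np.geomspace(0.2, 10.0, 41)[1:]
    return np.concatenate([low, high])


def default_beta_grid(geom: GeometrySpec) -> np.ndarray:
    """Cutoff-4 MeV, denser around the dose-rate peak."""
    lo = electron_cutoff(geom)
    if geom.id == "QB_1m_skin":
        dense = np.linspace(lo, 1.2, 36)
        tail = np.linspace(1.2, 4.0, 15)[1:]
    else:
        dense = np.geomspace(lo, 1.0, 36)
        tail = np.linspace(1.0, 4.0, 13)[1:]
    return np.concatenate([dense, tail])


# ---------------------------------------------------------------------------
# Photon kernels
# ---------------------------------------------------------------------------

def photon_kernel_point(energy_mev: float, geom: GeometrySpec, *,
                        vacuum: bool = False,
                        buildup_model_id: str = "berger") -> float:
    """Effective dose rate per decay (Sv/h per Bq) for a unit-yield line.

    The point-kernel of the geometry's source-detector distance: air
    kerma from the attenuated fluence with buildup, converted to
    effective dose through the (e/X) table.  ``vacuum`` disables
    attenuation and buildup (inverse-square only), for verification.
    """
    if geom.is_beta:
        raise ValueError(f"{geom.id} is not a photon geometry")
    e = float(energy_mev)
    conv = pt.exposure_conversion()
    att = pt.attenuation("air")
    if not (conv.table.e_min <= e <= conv.table.e_max):
        raise pt.OutOfRangeError(f"photon energy {e} MeV outside [0.005, 10]")
    d_cm = geom.distance_cm
    mu_en = att.mu_en_rho(e)
    if vacuum:
        transmission, b = 1.0, 1.0
    else:
        mu = att.mu(e, pt.standard_materials()["air"].density_g_cm3)
        mfp = mu * d_cm
        transmission = float(np.exp(-mfp))
        b = pt.buildup(e, mfp, buildup_model_id)
    kerma_air = e * mu_en * transmission * b / (4.0 * np.pi * d_cm**2)  # MeV/g
    exposure_r_per_h = kerma_air * _MEVG_TO_GY_PER_H / GY_AIR_PER_R
    return conv(e) * exposure_r_per_h


def photon_kerma_point(energy_mev: float, distance_m: float = 1.0, *,
                       vacuum: bool = False,
                       buildup_model_id: str = "berger") -> float:
    """Air collision kerma rate at ``distance_m`` (Gy/h per Bq, unit yield).

    Deterministic benchmark for the Monte Carlo kerma tally: uses the
    same :class:`~qtransport.physics_tables.PartialAttenuationModel`
    (attenuation and energy-transfer coefficients) the transport samples
    from, plus the pinned air buildup model for the scattered component.
    """
    model = pt.partial_model("air")
    rho = pt.standard_materials()["air"].density_g_cm3
    d_cm = distance_m * 100.0
    e = float(energy_mev)
    mu_tr = model.mu_transfer(e)
    if vacuum:
        transmission, b = 1.0, 1.0
    else:
        mfp = model.mu_total(e) * rho * d_cm
        transmission = float(np.exp(-mfp))
        b = pt.buildup(e, mfp, buildup_model_id)
    kerma = e * mu_tr * transmission * b / (4.0 * np.pi * d_cm**2)
    return kerma * _MEVG_TO_GY_PER_H


def build_photon_curve(geom: GeometrySpec, grid: np.ndarray | None = None,
                       **kwargs) -> KernelCurve:
    grid = default_photon_grid() if grid is None else np.asarray(grid, dtype=float)
    vals = np.array([photon_kernel_point(e, geom, **kwargs) for e in grid])
    return KernelCurve(Particle.PHOTON, geom.id, grid, vals, np.zeros_like(vals),
                       provenance="analytic")


# ---------------------------------------------------------------------------
# Beta scaled point-kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaDoseTables:
    """Dimensionless dose distribution j(x, E), x = scaled distance r/r_E.

    Each row (fixed E) integrates to 1 over x (energy conservation of
    the scaled point-kernel) within 2%.
    """

    x_grid: np.ndarray
    e_grid: np.ndarray
    j: np.ndarray  # shape (len(e_grid), len(x_grid))
    source: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x_grid, dtype=float)
        e = np.asarray(self.e_grid, dtype=float)
        jj = np.asarray(self.j, dtype=float)
        object.__setattr__(self, "x_grid", x)
        object.__setattr__(self, "e_grid", e)
        object.__setattr__(self, "j", jj)
        if jj.shape != (e.size, x.size):
            raise ValueError("j shape must be (n_energy, n_x)")
        if np.any(jj < 0):
            raise ValueError("j must be >= 0")
        integrals = np.trapezoid(jj, x, axis=1)
        if np.any(np.abs(integrals - 1.0) > 0.02):
            raise ValueError(
                "each j(. , E) must integrate to 1 within 2%, got "
                f"{integrals.min():.4f}..{integrals.max():.4f}"
            )

    def j_at(self, energy_mev: float, x) -> np.ndarray:
        """Bilinear interpolation; 0 beyond the x table (all energy spent)."""
        e = float(np.clip(energy_mev, self.e_grid[0], self.e_grid[-1]))
        i = int(np.searchsorted(self.e_grid, e) - 1)
        i = max(0, min(i, self.e_grid.size - 2))
        w = (e - self.e_grid[i]) / (self.e_grid[i + 1] - self.e_grid[i])
        row = (1 - w) * self.j[i] + w * self.j[i + 1]
        out = np.interp(np.asarray(x, dtype=float), self.x_grid, row,
                        left=row[0], right=0.0)
        return float(out) if np.isscalar(x) else out

    def tail_integral(self, energy_mev: float, x_lo: float) -> float:
        """integral_{x_lo}^{inf} j(x, E) / x dx (plane-source weight)."""
        x = self.x_grid
        mask = x > 0
        xm = x[mask]
        row = self.j_at(energy_mev, xm) / xm
        if x_lo >= xm[-1]:
            return 0.0
        grid = np.concatenate([[max(x_lo, xm[0])], xm[xm > x_lo]])
        vals = np.concatenate([[self.j_at(energy_mev, grid[0]) / grid[0]],
                               row[xm > x_lo]])
        return float(np.trapezoid(vals, grid))


def synthetic_scaled_dose_table(x_max: float = 1.5, n_x: int = 301,
                                ) -> BetaDoseTables:
    """Synthetic stand-in for published electron scaled point-kernels.

    Parametric single-peak profile j(x) = N x^2 exp(-(x/0.7)^3),
    normalized to unit integral, identical for all energies.  It
    reproduces the qualitative morphology of monoenergetic electron
    dose-rate curves in the two skin geometries -- zero below the range
    cutoff, a single peak, monotone decay at high energy -- but is not a
    digitization of evaluated kernels, so absolute beta coefficients
    carry a model uncertainty of a few fold (see the methods note).
    """
    x = np.linspace(0.0, x_max, n_x)
    prof = x**2 * np.exp(-((x / 0.7) ** 3))
    prof /= np.trapezoid(prof, x)
    e_grid = np.geomspace(0.05, 5.0, 12)
    j = np.tile(prof, (e_grid.size, 1))
    return BetaDoseTables(x, e_grid, j, source="synthetic parametric profile")


_DEFAULT_BETA_TABLE: list[BetaDoseTables] = []


def _beta_table(tables: BetaDoseTables | None) -> BetaDoseTables:
    if tables is not None:
        return tables
    if not _DEFAULT_BETA_TABLE:
        _DEFAULT_BETA_TABLE.append(synthetic_scaled_dose_table())
    return _DEFAULT_BETA_TABLE[0]


def beta_jair(energy_mev: float, geom: GeometrySpec,
              tables: BetaDoseTables | None = None) -> float:
    """Monoenergetic electron kernel at 1 m (Sv/h per Bq per electron).

    Scaled point-kernel evaluated at the areal distance through air plus
    the tissue overburden of the dermal layer; zero below the geometry
    cutoff.  The dose is scored in tissue (stopping-power ratio applied).
    """
    if geom.id != "QB_1m_skin":
        raise ValueError("beta_jair applies to the 1 m skin geometry")
    e = float(energy_mev)
    if e < electron_cutoff(geom):
        return 0.0
    tab = _beta_table(tables)
    rho_air = pt.standard_materials()["air"].density_g_cm3
    r_e = pt.electron_ranges().range_of(e, "air")  # g/cm^2
    areal = rho_air * geom.distance_cm + SKIN_DEPTH_G_CM2 + SKIN_THICKNESS_G_CM2 / 2
    x = areal / r_e
    jj = tab.j_at(e, x)
    d_cm = geom.distance_cm
    dose_mev_g = e * jj / (4.0 * np.pi * d_cm**2 * r_e)
    return dose_mev_g * TISSUE_TO_AIR_STOPPING_RATIO * _MEVG_TO_GY_PER_H


def beta_skin_contact(energy_mev: float,
                      tables: BetaDoseTables | None = None) -> float:
    """Contact skin-dose kernel (Sv m^2 / (TBq s) per electron).

    Uniform surface contamination: plane-source integral of the scaled
    point-kernel in tissue, averaged over the dermal layer
    0.007-0.011 g/cm^2.  Normalized per unit activity surface density
    (1 TBq/m^2 = 1e8 Bq/cm^2), giving the h_skin unit convention.
    """
    e = float(energy_mev)
    geom = GEOMETRIES["QD_contact_skin"]
    if e < electron_cutoff(geom):
        return 0.0
    tab = _beta_table(tables)
    r_e = pt.electron_ranges().range_of(e, "water")  # g/cm^2; tissue ~ water
    depths = np.linspace(SKIN_DEPTH_G_CM2,
                         SKIN_DEPTH_G_CM2 + SKIN_THICKNESS_G_CM2, 5)
    vals = [tab.tail_integral(e, z / r_e) for z in depths]
    dose_mev_g_per_decay_cm2 = e / (2.0 * r_e) * float(np.mean(vals))
    # MeV/g per (decay/cm^2)  ->  Sv/s per (TBq/m^2)
    return dose_mev_g_per_decay_cm2 * MEV_PER_G_TO_GY * 1e8


def build_beta_curve(geom: GeometrySpec, grid: np.ndarray | None = None,
                     tables: BetaDoseTables | None = None) -> KernelCurve:
    if not geom.is_beta:
        raise ValueError(f"{geom.id} is not a beta geometry")
    grid = default_beta_grid(geom) if grid is None else np.asarray(grid, dtype=float)
    if geom.id == "QB_1m_skin":
        vals = np.array([beta_jair(e, geom, tables) for e in grid])
        units = "Sv/(Bq h)"
    else:
        vals = np.array([beta_skin_contact(e, tables) for e in grid])
        units = "Sv m^2/(TBq s)"
    return KernelCurve(Particle.ELECTRON, geom.id, grid, vals,
                       np.zeros_like(vals), provenance="analytic", units=units)
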