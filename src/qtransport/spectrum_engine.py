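"""Convolution of nuclide emission spectra with monoenergetic kernels.

The pathway dose-rate coefficients are built from kernel curves by

* weighting each discrete line by its yield (branching ratio) and
  summing, and
* trapezoidal integration of continuous beta spectra against the
  kernel, interpolated linearly onto the spectrum abscissae (the kernel
  is always interpolated onto the spectrum grid, never the reverse).

Energies below a curve's first grid point are below the geometry's
physical cutoff and contribute zero.  The beta coefficient at 1 m is
divided by the residual shielding factor SF(E_beta,max) (see
:func:`qtransport.qsystem.shielding_factor`); the skin-contact
coefficient carries no shielding.  Conversion electrons are treated as
monoenergetic beta particles weighted by their yields; positrons ride
the electron kernels (their annihilation photons are attached to the
photon lines upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import analytic_kernels as ak
from .analytic_kernels import GEOMETRIES, KernelCurve
from .nuclide_data import (
    BetaSpectrum,
    EmissionLine,
    Nuclide,
    Particle,
    attach_annihilation_photons,
)

__all__ = [
    "DoseCoefficients",
    "PathwayResult",
    "kernel_at",
    "discrete_sum",
    "continuum_integral",
    "pathway_coefficient",
    "compute_dose_coefficients",
    "analytic_curveset",
    "PATHWAY_GEOMETRY",
]

PATHWAY_GEOMETRY = {
    "photon_1m": "QA_1m_body",
    "beta_1m": "QB_1m_skin",
    "skin_contact": "QD_contact_skin",
}

_BETA_PARTICLES = (Particle.ELECTRON, Particle.POSITRON)


def kernel_at(curve: KernelCurve, energy_mev: float) -> float:
    """Linear interpolation on the kernel grid; 0 below the cutoff.

    Energies above the grid maximum raise: the curve must cover the
    spectrum, extrapolation is never performed.
    """
    e = float(energy_mev)
    grid = curve.energies
    if e > grid[-1] * (1 + 1e-12):
        raise ValueError(
            f"energy {e} MeV above kernel grid maximum {grid[-1]} MeV"
        )
    if e < grid[0]:
        return 0.0
    return float(np.interp(e, grid, curve.values))


def _kernel_values(curve: KernelCurve, energies: np.ndarray) -> np.ndarray:
    out = np.interp(energies, curve.energies, curve.values)
    out[energies < curve.energies[0]] = 0.0
    if np.any(energies > curve.energies[-1] * (1 + 1e-12)):
        raise ValueError("spectrum extends above the kernel grid")
    return out


def discrete_sum(lines, curve: KernelCurve) -> float:
    """Sum of yield-weighted kernel values over discrete lines.

    All lines must carry a particle type the curve applies to (photon
    curves take photon lines; beta curves take electron/positron
    lines).  Empty input gives 0.
    """
    total = 0.0
    for line in lines:
        if curve.particle is Particle.PHOTON:
            ok = line.particle is Particle.PHOTON
        else:
            ok = line.particle in _BETA_PARTICLES
        if not ok:
            raise ValueError(
                f"line particle {line.particle.value} does not match "
                f"{curve.particle.value} curve"
            )
        total += line.yield_per_decay * kernel_at(curve, line.energy_mev)
    return total


def continuum_integral(spectrum: BetaSpectrum, curve: KernelCurve) -> float:
    """Trapezoid rule of density(E) * kernel(E) over the spectrum grid.

    The kernel is evaluated by linear interpolation at every spectrum
    abscissa; grid regions below the kernel cutoff contribute zero.  A
    spectrum entirely below the cutoff integrates to 0 (with a warning).
    """
    grid = spectrum.energy_grid
    kern = _kernel_values(curve, grid)
    if not np.any(kern > 0):
        warnings.warn(
            f"spectrum (e_max={spectrum.e_max} MeV) lies entirely below the "
            f"{curve.geometry_id} kernel cutoff",
            stacklevel=2,
        )
        return 0.0
    return float(np.trapezoid(spectrum.density * kern, grid))


@dataclass(frozen=True)
class PathwayResult:
    """One pathway coefficient with its mono/continuum breakdown."""

    value: float
    mono: float
    continuum: float
    shielding_factor: float | None = None
    no_emissions: bool = False

    @property
    def unshielded(self) -> float:
        return self.mono + self.continuum


def pathway_coefficient(nuclide: Nuclide, curveset: dict[str, KernelCurve],
                        pathway: str) -> PathwayResult:
    """Pathway dose-rate coefficient of one (progeny-flattened) emitter.

    ``photon_1m``: yield-weighted sum over photon lines, annihilation
    photons included (attached here if not already).  ``beta_1m``:
    (mono + continuum) / SF with SF from the beta endpoint energy, or
    the a-priori SF = 3 for emitters with only monoenergetic electrons.
    ``skin_contact``: mono + continuum, no shielding.  A nuclide with no
    relevant emissions yields a flagged zero.
    """
    from .qsystem import shielding_factor  # single SF definition site

    if pathway not in PATHWAY_GEOMETRY:
        raise ValueError(f"unknown pathway {pathway!r}")
    curve = curveset[pathway]
    if curve.geometry_id != PATHWAY_GEOMETRY[pathway]:
        raise ValueError(
            f"curve geometry {curve.geometry_id} does not serve {pathway}"
        )

    if pathway == "photon_1m":
        nuc = attach_annihilation_photons(nuclide)
        lines = nuc.lines_of(Particle.PHOTON)
        if not lines:
            return PathwayResult(0.0, 0.0, 0.0, no_emissions=True)
        return PathwayResult(discrete_sum(lines, curve), discrete_sum(lines, curve), 0.0)

    lines = [l for l in nuclide.lines if l.particle in _BETA_PARTICLES]
    spectra = [s for s in nuclide.beta_spectra if s.particle in _BETA_PARTICLES]
    if not lines and not spectra:
        return PathwayResult(0.0, 0.0, 0.0, no_emissions=True)
    mono = discrete_sum(lines, curve) if lines else 0.0
    cont = sum(continuum_integral(s, curve) for s in spectra)

    if pathway == "skin_contact":
        return PathwayResult(mono + cont, mono, cont)

    mono_only = bool(lines) and not spectra
    e_max = max((s.e_max for s in spectra), default=0.0)
    sf = shielding_factor(e_max if not mono_only else None, mono_only=mono_only)
    return PathwayResult((mono + cont) / sf, mono, cont, shielding_factor=sf)


@dataclass(frozen=True)
class DoseCoefficients:
    """The pathway coefficients of one emitter (or flattened chain).

    e_pt, e_b in Sv/(Bq h); h_skin in Sv m^2/(TBq s); e_inh in Sv/Bq
    (tabulated pass-through, None when not available).  ``breakdown``
    maps pathway -> :class:`PathwayResult`; per-progeny contributions
    are recorded under ``members`` when a chain was flattened.
    """

    nuclide_id: str
    e_pt: float
    e_b: float
    h_skin: float
    e_inh: float | None
    h_sub_eff: float | None = None
    h_sub_skin: float | None = None
    is_gaseous: bool = False
    breakdown: dict = field(default_factory=dict)
    members: tuple = ()
    kernel_source: str = "analytic"


def compute_dose_coefficients(nuclide: Nuclide,
                              curveset: dict[str, KernelCurve],
                              ) -> DoseCoefficients:
    """All pathway coefficients for a single emitter (no chain logic)."""
    res = {p: pathway_coefficient(nuclide, curveset, p) for p in PATHWAY_GEOMETRY}
    source = curveset["photon_1m"].provenance
    return DoseCoefficients(
        nuclide_id=nuclide.id,
        e_pt=res["photon_1m"].value,
        e_b=res["beta_1m"].value,
        h_skin=res["skin_contact"].value,
        e_inh=nuclide.e_inh,
        h_sub_eff=nuclide.h_sub_eff,
        h_sub_skin=nuclide.h_sub_skin,
        is_gaseous=nuclide.is_gaseous,
        breakdown=res,
        kernel_source=source,
    )


_CURVESET_CACHE: dict = {}


def analytic_curveset(refresh: bool = False) -> dict[str, KernelCurve]:
    """Default analytic kernel curves for the three pathways (cached)."""
    if refresh or not _CURVESET_CACHE:
        _CURVESET_CACHE.clear()
        _CURVESET_CACHE.update(
            {
                "photon_1m": ak.build_photon_curve(GEOMETRIES["QA_1m_body"]),
                "beta_1m": ak.build_beta_curve(GEOMETRIES["QB_1m_skin"]),
                "skin_contact": ak.build_beta_curve(GEOMETRIES["QD_contact_skin"]),
            }
        )
    return dict(_CURVESET_CACHE)
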