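"""Analog Monte Carlo photon transport in the spherical accident geometries.

An isotropic, monoenergetic point source sits at the origin; photons are
tracked through concentric spherical regions (air medium, detector
shell) with the shared :class:`~qtransport.physics_tables.PartialAttenuationModel`
cross-sections: photoelectric absorption (full local deposit), Compton
scattering (Klein-Nishina sampling, electron energy deposited locally),
and pair production above 1.022 MeV (electron/positron energy deposited
locally, both annihilation photons tracked).  No variance reduction; no
coherent scattering or fluorescence; electron secondaries are not
transported -- local deposition makes the energy-deposition tally a
collision-kerma estimator, which is the regime of the centimetre-scale
detectors used here.

Two tallies are provided:

* ``deposit`` -- energy deposited in the detector shell per history
  divided by the shell mass (the F8-style pulse-height analogue);
* ``kerma``   -- track-length collision-kerma estimate in a thin probe
  shell at the source-detector distance, the observable that matches
  the analytic point-kernel at 1 m and therefore drives the
  cross-validation against :mod:`qtransport.analytic_kernels`.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import physics_tables as pt
from .analytic_kernels import GeometrySpec
from .nuclide_data import Particle
from .units import ELECTRON_MASS_MEV, MEV_PER_G_TO_GY, S_PER_H

__all__ = [
    "RngStream",
    "TallyResult",
    "run_photon_kernel",
    "run_electron_kernel_csda",
    "sample_klein_nishina",
    "build_mc_photon_curve",
]

_MEVG_TO_GY_PER_H = MEV_PER_G_TO_GY * S_PER_H

PHOTON_CUTOFF_MEV = 0.01
PAIR_THRESHOLD_MEV = 2.0 * ELECTRON_MASS_MEV

#: production history count of the source study; tests use far fewer
DEFAULT_HISTORIES = 10_000_000


@dataclass(frozen=True)
class RngStream:
    """Seeded random stream; identical seed -> identical history sequence."""

    seed: int

    def generator(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def child(self, index: int) -> "RngStream":
        return RngStream(int(np.random.SeedSequence([self.seed, index])
                             .generate_state(1)[0] % (2**31)))


@dataclass(frozen=True)
class TallyResult:
    """Mean dose per decay with its Monte Carlo standard error."""

    dose_per_decay: float  # Sv/h per Bq (photon/QB) or Sv m^2/(TBq s) (QD)
    stderr: float
    n_histories: int
    geometry_id: str
    energy_mev: float
    tally: str
    provenance: str = "mc"


# ---------------------------------------------------------------------------
# Klein-Nishina sampling (Kahn's rejection method)
# ---------------------------------------------------------------------------

def sample_klein_nishina(energy_mev, rng: np.random.Generator,
                         size: int | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Sample scattered energy and scattering cosine for Compton events.

    ``energy_mev`` may be a scalar (with ``size`` samples drawn) or an
    array (one sample per element).  Returns ``(e_scattered,
    cos_theta)`` distributed per the Klein-Nishina differential
    cross-section (Kahn's rejection method); scattered energies respect
    the Compton kinematic bounds ``[E/(1+2E/m_e c^2), E]``.
    """
    energies = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    if size is not None:
        if energies.size != 1:
            raise ValueError("size only applies to scalar energy")
        energies = np.full(size, energies[0])
    if np.any(energies <= 0):
        raise ValueError("energy must be > 0")
    k = energies / ELECTRON_MASS_MEV
    x = np.empty(k.size)  # x = E / E'
    todo = np.arange(k.size)
    while todo.size:
        kt = k[todo]
        r1, r2, r3 = rng.random((3, todo.size))
        branch1 = r1 <= (1.0 + 2.0 * kt) / (9.0 + 2.0 * kt)
        cand = np.where(branch1,
                        1.0 + 2.0 * kt * r2,
                        (1.0 + 2.0 * kt) / (1.0 + 2.0 * kt * r2))
        mu = 1.0 + (1.0 - cand) / kt
        accept1 = r3 <= 4.0 * (1.0 / cand - 1.0 / cand**2)
        accept2 = r3 <= 0.5 * (mu**2 + 1.0 / cand)
        ok = np.where(branch1, accept1, accept2)
        x[todo[ok]] = cand[ok]
        todo = todo[~ok]
    e_out = energies / x
    cos_theta = 1.0 + (1.0 - x) / k
    return e_out, cos_theta


def _rotate(dirs: np.ndarray, cos_theta: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors by theta about themselves with random azimuth."""
    n = dirs.shape[0]
    phi = rng.random(n) * 2.0 * np.pi
    sin_theta = np.sqrt(np.maximum(1.0 - cos_theta**2, 0.0))
    # orthonormal frame: pick helper axis least aligned with dir
    helper = np.zeros_like(dirs)
    idx = np.argmin(np.abs(dirs), axis=1)
    helper[np.arange(n), idx] = 1.0
    v1 = np.cross(dirs, helper)
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    v2 = np.cross(dirs, v1)
    return (cos_theta[:, None] * dirs
            + sin_theta[:, None] * (np.cos(phi)[:, None] * v1
                                    + np.sin(phi)[:, None] * v2))


def _isotropic(n: int, rng: np.random.Generator) -> np.ndarray:
    mu = rng.random(n) * 2.0 - 1.0
    phi = rng.random(n) * 2.0 * np.pi
    s = np.sqrt(1.0 - mu**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _inside_length(pos, dirs, step, radius):
    """Length of the segment [0, step] along ``dirs`` inside sphere ``radius``."""
    b = np.einsum("ij,ij->i", pos, dirs)
    c = np.einsum("ij,ij->i", pos, pos) - radius**2
    disc = b * b - c
    root = np.sqrt(np.maximum(disc, 0.0))
    t_in = np.where(c < 0.0, 0.0, -b - root)
    t_out = -b + root
    lo = np.clip(t_in, 0.0, step)
    hi = np.clip(t_out, 0.0, step)
    return np.where(disc > 0.0, np.maximum(hi - lo, 0.0), 0.0)


def _boundary_distance(pos, dirs, radii):
    """Distance to the nearest spherical boundary along the flight line."""
    b = np.einsum("ij,ij->i", pos, dirs)
    r2 = np.einsum("ij,ij->i", pos, pos)
    t_min = np.full(pos.shape[0], np.inf)
    for radius in radii:
        c = r2 - radius**2
        disc = b * b - c
        ok = disc > 0.0
        root = np.sqrt(np.maximum(disc, 0.0))
        for t in (-b - root, -b + root):
            cand = np.where(ok & (t > 1e-9), t, np.inf)
            t_min = np.minimum(t_min, cand)
    return t_min


# ---------------------------------------------------------------------------
# Photon transport
# ---------------------------------------------------------------------------

def run_photon_kernel(energy_mev: float, geom: GeometrySpec, n_histories: int,
                      seed: int, *, tally: str = "kerma",
                      vacuum: bool = False, absorbing_detector: bool = False,
                      probe_thickness_cm: float = 2.5,
                      world_radius_cm: float = 2000.0,
                      batch_size: int = 200_000,
                      max_steps: int = 10_000) -> TallyResult:
    """Monoenergetic photon kernel for a 1 m photon geometry.

    ``tally='deposit'`` scores energy deposited in the full detector
    shell per history divided by the shell mass; ``tally='kerma'``
    scores track-length collision kerma in a thin air probe shell at
    the detector distance (the point-kernel observable).  ``vacuum``
    switches off all interactions; with ``absorbing_detector`` every
    photon entering the detector shell deposits its full energy, which
    closes the energy balance exactly (geometry closure check).
    """
    if geom.is_beta:
        raise ValueError(f"{geom.id} is not a photon geometry")
    if not PHOTON_CUTOFF_MEV <= energy_mev <= 10.0:
        raise ValueError(f"photon energy {energy_mev} MeV outside [0.01, 10]")
    if n_histories < 100:
        raise ValueError("need at least 100 histories")
    if tally not in ("deposit", "kerma"):
        raise ValueError(f"unknown tally {tally!r}")

    mats = pt.standard_materials()
    rho_med = mats[geom.medium_material].density_g_cm3
    det_mat = "water" if geom.detector_material in ("water", "skin") else "air"
    rho_det = mats["water"].density_g_cm3 if det_mat == "water" else rho_med
    model_med = pt.partial_model(geom.medium_material if geom.medium_material
                                 in ("air", "water") else "air")
    model_det = pt.partial_model(det_mat)

    r1 = geom.detector_inner_m * 100.0
    r2 = r1 + geom.detector_thickness_m * 100.0
    if tally == "kerma":
        # probe shell in the undisturbed medium at the detector distance
        probe_lo, probe_hi = r1, r1 + probe_thickness_cm
        region_radii = [world_radius_cm]
        region_models = [model_med]
        region_rho = [rho_med]
        det_region = None
        probe_volume = 4.0 / 3.0 * np.pi * (probe_hi**3 - probe_lo**3)
        mu_tr_probe_rho = None  # computed per photon energy below
        norm_mass = None
    else:
        region_radii = [r1, r2, world_radius_cm]
        region_models = [model_med, model_det, model_med]
        region_rho = [rho_med, rho_det, rho_med]
        det_region = 1
        probe_lo = probe_hi = probe_volume = None
        norm_mass = 4.0 / 3.0 * np.pi * (r2**3 - r1**3) * rho_det

    rng = RngStream(seed).generator()
    deposits = np.zeros(n_histories)
    boundaries = np.array(region_radii[:-1]) if det_region is not None else \
        np.array([])

    for start in range(0, n_histories, batch_size):
        n_batch = min(batch_size, n_histories - start)
        pos = np.zeros((n_batch, 3))
        dirs = _isotropic(n_batch, rng)
        eng = np.full(n_batch, float(energy_mev))
        hist = np.arange(start, start + n_batch)

        for _ in range(max_steps):
            if eng.size == 0:
                break
            r = np.linalg.norm(pos, axis=1)
            if det_region is not None:
                region = np.searchsorted(boundaries, r)
            else:
                region = np.zeros(eng.size, dtype=int)
            # linear attenuation per particle
            mu_lin = np.zeros(eng.size)
            if not vacuum:
                for ridx, (model, rho) in enumerate(zip(region_models,
                                                        region_rho)):
                    m = region == ridx
                    if m.any():
                        mu_lin[m] = model.mu_total(eng[m]) * rho
            t_bound = _boundary_distance(pos, dirs, region_radii)
            with np.errstate(divide="ignore"):
                s_int = np.where(mu_lin > 0,
                                 -np.log(rng.random(eng.size)) / mu_lin, np.inf)
            step = np.minimum(s_int, t_bound + 1e-4)
            interact = s_int < t_bound

            if tally == "kerma":
                seg = _inside_length(pos, dirs, step, probe_hi) - \
                    _inside_length(pos, dirs, step, probe_lo)
                scored = seg > 0
                if scored.any():
                    contrib = (seg[scored] * eng[scored]
                               * model_med.mu_transfer(eng[scored]))
                    np.add.at(deposits, hist[scored], contrib)

            pos = pos + dirs * step[:, None]
            r_new = np.linalg.norm(pos, axis=1)

            alive = np.ones(eng.size, dtype=bool)
            # escape through the world boundary
            alive &= r_new < world_radius_cm * (1 - 1e-9)

            if absorbing_detector and det_region is not None:
                entered = alive & (r_new >= r1) & (r_new <= r2)
                if entered.any():
                    np.add.at(deposits, hist[entered], eng[entered])
                    alive &= ~entered

            # interactions
            act = interact & alive
            if act.any() and not vacuum:
                if det_region is not None:
                    in_det = (r_new >= r1) & (r_new <= r2)
                else:
                    in_det = np.zeros(eng.size, dtype=bool)
                idx = np.flatnonzero(act)
                # material model at the interaction point
                reg_act = np.searchsorted(boundaries, r_new[idx]) \
                    if det_region is not None else np.zeros(idx.size, dtype=int)
                kind = np.empty(idx.size, dtype=int)  # 0 pe, 1 compton, 2 pair
                u = rng.random(idx.size)
                for ridx, model in enumerate(region_models):
                    m = reg_act == ridx
                    if not m.any():
                        continue
                    probs = model.interaction_probabilities(eng[idx[m]])
                    cum = np.cumsum(probs, axis=0)
                    kind[m] = (u[m][None, :] > cum).sum(axis=0)

                new_pos, new_dirs, new_eng, new_hist = [], [], [], []

                # photoelectric: full local absorption
                pe = idx[kind == 0]
                if pe.size:
                    dep = pe[in_det[pe]] if det_region is not None else \
                        np.empty(0, dtype=int)
                    if dep.size:
                        np.add.at(deposits, hist[dep], eng[dep])
                    alive[pe] = False

                # Compton
                co = idx[kind == 1]
                if co.size:
                    e_new, mu_s = sample_klein_nishina(eng[co], rng)
                    transfer = eng[co] - e_new
                    dep = in_det[co] if det_region is not None else \
                        np.zeros(co.size, dtype=bool)
                    if dep.any():
                        np.add.at(deposits, hist[co[dep]], transfer[dep])
                    dirs[co] = _rotate(dirs[co], mu_s, rng)
                    eng[co] = e_new
                    low = co[eng[co] < PHOTON_CUTOFF_MEV]
                    if low.size:
                        dep = low[in_det[low]] if det_region is not None else \
                            np.empty(0, dtype=int)
                        if dep.size:
                            np.add.at(deposits, hist[dep], eng[dep])
                        alive[low] = False

                # pair production: charged energy local, photon pair tracked
                pp = idx[kind == 2]
                if pp.size:
                    transfer = eng[pp] - PAIR_THRESHOLD_MEV
                    dep = in_det[pp] if det_region is not None else \
                        np.zeros(pp.size, dtype=bool)
                    if dep.any():
                        np.add.at(deposits, hist[pp[dep]], transfer[dep])
                    gamma_dirs = _isotropic(pp.size, rng)
                    eng[pp] = ELECTRON_MASS_MEV
                    dirs[pp] = gamma_dirs
                    new_pos.append(pos[pp].copy())
                    new_dirs.append(-gamma_dirs)
                    new_eng.append(np.full(pp.size, ELECTRON_MASS_MEV))
                    new_hist.append(hist[pp].copy())

                if new_eng:
                    pos = np.concatenate([pos, *new_pos])
                    dirs = np.concatenate([dirs, *new_dirs])
                    eng = np.concatenate([eng, *new_eng])
                    hist = np.concatenate([hist, *new_hist])
                    alive = np.concatenate(
                        [alive, np.ones(sum(a.size for a in new_eng),
                                        dtype=bool)]
                    )

            pos, dirs, eng, hist = (pos[alive], dirs[alive], eng[alive],
                                    hist[alive])
        else:
            raise RuntimeError("photon transport failed to terminate")

    if tally == "kerma":
        per_hist = deposits / probe_volume  # MeV/g per history
    else:
        per_hist = deposits / norm_mass
    mean = float(per_hist.mean())
    sem = float(per_hist.std(ddof=1) / np.sqrt(n_histories))
    return TallyResult(
        dose_per_decay=mean * _MEVG_TO_GY_PER_H,
        stderr=sem * _MEVG_TO_GY_PER_H,
        n_histories=n_histories,
        geometry_id=geom.id,
        energy_mev=float(energy_mev),
        tally=tally if not vacuum else f"{tally}(vacuum)",
    )


def run_photon_deposit_raw(energy_mev: float, geom: GeometrySpec,
                           n_histories: int, seed: int, **kwargs
                           ) -> tuple[float, float]:
    """Mean deposited energy per history (MeV) and its sem, deposit tally."""
    res = run_photon_kernel(energy_mev, geom, n_histories, seed,
                            tally="deposit", **kwargs)
    r1 = geom.detector_inner_m * 100.0
    r2 = r1 + geom.detector_thickness_m * 100.0
    rho = pt.standard_materials()["water"].density_g_cm3 \
        if geom.detector_material in ("water", "skin") else \
        pt.standard_materials()[geom.medium_material].density_g_cm3
    mass = 4.0 / 3.0 * np.pi * (r2**3 - r1**3) * rho
    scale = mass / _MEVG_TO_GY_PER_H
    return res.dose_per_decay * scale, res.stderr * scale


def build_mc_photon_curve(geom: GeometrySpec, energies, n_histories: int,
                          seed: int, **kwargs):
    """Kernel curve from the Monte Carlo kerma tally (provenance ``mc``)."""
    from .analytic_kernels import KernelCurve  # local to avoid cycle

    energies = np.asarray(energies, dtype=float)
    vals, errs = [], []
    for i, e in enumerate(energies):
        res = run_photon_kernel(float(e), geom, n_histories,
                                RngStream(seed).child(i).seed, **kwargs)
        vals.append(res.dose_per_decay)
        errs.append(res.stderr)
    return KernelCurve(Particle.PHOTON, geom.id, energies, np.array(vals),
                       np.array(errs), provenance="mc")


# ---------------------------------------------------------------------------
# Simplified electron mode (continuous slowing down, straight ahead)
# ---------------------------------------------------------------------------

def run_electron_kernel_csda(energy_mev: float, geom: GeometrySpec,
                             n_histories: int = 1, seed: int = 0
                             ) -> TallyResult:
    """Straight-ahead CSDA electron transport (order-of-magnitude mode).

    Electrons travel radially, losing energy per the CSDA range tables;
    the tally is the energy lost while crossing the dermal detector
    layer.  No multiple scattering or detour -- this mode exists to
    reproduce the range cutoffs and magnitudes, not evaluated kernels;
    the analytic scaled point-kernel remains the default beta source.
    Deterministic (stderr 0).
    """
    if not geom.is_beta:
        raise ValueError(f"{geom.id} is not a beta geometry")
    ranges = pt.electron_ranges()
    mats = pt.standard_materials()
    rho_skin = mats["skin"].density_g_cm3
    depth = 0.007e-1 * rho_skin * 10.0  # 0.07 mm in skin -> g/cm^2
    thick = 0.004e-1 * rho_skin * 10.0  # 0.04 mm -> g/cm^2

    e = float(energy_mev)
    if e <= 0:
        raise ValueError("energy must be > 0")
    e_cap = min(e, float(ranges.energy_mev[-1]))

    if geom.id == "QB_1m_skin":
        air_areal = mats["air"].density_g_cm3 * geom.distance_cm
        resid = ranges.range_of(e_cap, "air") - air_areal
        if resid <= 0:
            de = 0.0
        else:
            e_at_skin = ranges.energy_from_range(resid, "air")
            r_w = ranges.range_of(e_at_skin, "water") if e_at_skin > 0 else 0.0
            e_top = ranges.energy_from_range(max(r_w - depth, 0.0), "water") \
                if r_w > depth else 0.0
            e_bot = ranges.energy_from_range(max(r_w - depth - thick, 0.0),
                                             "water") if r_w > depth + thick \
                else 0.0
            de = max(e_top - e_bot, 0.0)
        r_mid = geom.distance_cm + (geom.detector_depth_m
                                    + geom.detector_thickness_m / 2) * 100.0
        mass = 4.0 * np.pi * r_mid**2 * geom.detector_thickness_m * 100.0 \
            * rho_skin
        dose = de / mass * _MEVG_TO_GY_PER_H
    else:  # QD contact: 1-d slab, half the emissions enter the skin
        r_w = ranges.range_of(e_cap, "water")
        if r_w <= depth:
            de = 0.0
        else:
            e_top = ranges.energy_from_range(r_w - depth, "water")
            e_bot = ranges.energy_from_range(max(r_w - depth - thick, 0.0),
                                             "water") if r_w > depth + thick \
                else 0.0
            de = max(e_top - e_bot, 0.0)
        # Sv/s per TBq/m^2: 0.5 * de / detector areal mass * 1e8 decays/cm^2
        dose = 0.5 * de / thick * MEV_PER_G_TO_GY * 1e8
    return TallyResult(dose_per_decay=float(dose), stderr=0.0,
                       n_histories=n_histories, geometry_id=geom.id,
                       energy_mev=e, tally="csda")
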