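"""Nuclide decay-data model, library I/O, fixtures and progeny resolution.

A :class:`Nuclide` carries everything the Q-system needs about one
radionuclide: discrete emission lines (photons, conversion/Auger
electrons, positrons, alphas), binned continuous beta spectra, progeny
links, and the externally tabulated inhalation and submersion dose
coefficients.  Libraries are stored in a small versioned YAML schema
(see :data:`LIBRARY_FORMAT_VERSION` and :func:`write_library`); no
external decay-data download is ever required.

Beta continua are stored pre-binned on an ascending energy grid; the
trapezoid rule fixes the integration semantics throughout the package,
so the stored density must integrate (trapezoidally) to the stated
total yield.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Particle",
    "EmissionLine",
    "BetaSpectrum",
    "ProgenyLink",
    "Nuclide",
    "NuclideLibrary",
    "SchemaError",
    "read_library",
    "write_library",
    "make_fixture_nuclide",
    "attach_annihilation_photons",
    "resolve_progeny",
    "allowed_beta_density",
    "EQUILIBRIUM_HALF_LIFE_DAYS",
]

LIBRARY_FORMAT_VERSION = "1.0"

#: Daughters with half-lives below this (and below the parent's) are folded
#: into the parent as secular-equilibrium progeny; the classification stems
#: from the 50-day maximum transport window assumed by the Q-system.
EQUILIBRIUM_HALF_LIFE_DAYS = 10.0

ANNIHILATION_MEV = 0.511


class SchemaError(ValueError):
    """A library file or nuclide record violates the published schema."""


class Particle(str, enum.Enum):
    PHOTON = "photon"
    ELECTRON = "electron"
    POSITRON = "positron"
    ALPHA = "alpha"


@dataclass(frozen=True)
class EmissionLine:
    """One discrete emission: particle type, energy (MeV), yield per decay.

    Photon yields summed over lines may exceed 1 (cascades); a yield of
    zero is allowed and contributes nothing downstream.
    """

    particle: Particle
    energy_mev: float
    yield_per_decay: float

    def __post_init__(self) -> None:
        if self.energy_mev <= 0:
            raise SchemaError(f"line energy must be > 0, got {self.energy_mev}")
        if self.yield_per_decay < 0:
            raise SchemaError(f"line yield must be >= 0, got {self.yield_per_decay}")


@dataclass(frozen=True)
class BetaSpectrum:
    """Binned continuous beta spectrum.

    ``density`` holds emissions per decay per MeV on the strictly
    ascending ``energy_grid``; its trapezoidal integral must equal
    ``total_yield`` to 1e-6 relative, and ``e_max`` is the endpoint
    (last grid energy with nonzero density).
    """

    energy_grid: np.ndarray
    density: np.ndarray
    total_yield: float
    e_max: float
    particle: Particle = Particle.ELECTRON

    def __post_init__(self) -> None:
        grid = np.asarray(self.energy_grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "energy_grid", grid)
        object.__setattr__(self, "density", dens)
        if grid.ndim != 1 or grid.size < 2:
            raise SchemaError("beta spectrum needs a 1-d grid of >= 2 energies")
        if dens.shape != grid.shape:
            raise SchemaError("beta density and grid shapes differ")
        if np.any(np.diff(grid) <= 0):
            raise SchemaError("beta energy grid must be strictly ascending")
        if np.any(dens < 0):
            raise SchemaError("beta density must be >= 0 everywhere")
        integral = float(np.trapezoid(dens, grid))
        if self.total_yield <= 0:
            raise SchemaError("beta total_yield must be > 0")
        if abs(integral - self.total_yield) > 1e-6 * self.total_yield:
            raise SchemaError(
                "beta density integrates to "
                f"{integral:.6g} but total_yield is {self.total_yield:.6g}"
            )
        nonzero = np.flatnonzero(dens > 0)
        if nonzero.size == 0:
            raise SchemaError("beta density vanishes everywhere")
        # the spectral endpoint: first grid energy at/after which the density
        # has fallen to zero (the density may vanish exactly at e_max)
        end_idx = min(nonzero[-1] + 1, grid.size - 1)
        expected_emax = float(grid[end_idx])
        if not np.isclose(self.e_max, expected_emax, rtol=1e-6, atol=1e-9):
            raise SchemaError(
                f"e_max={self.e_max:.6g} does not match the spectral endpoint "
                f"{expected_emax:.6g} implied by the density grid"
            )


@dataclass(frozen=True)
class ProgenyLink:
    daughter_id: str
    branching: float
    daughter_half_life_days: float

    def __post_init__(self) -> None:
        if not 0 < self.branching <= 1:
            raise SchemaError(f"branching must be in (0, 1], got {self.branching}")
        if self.daughter_half_life_days <= 0:
            raise SchemaError("daughter half-life must be > 0")


@dataclass(frozen=True)
class Nuclide:
    """Decay data and tabulated pathway coefficients for one radionuclide."""

    id: str
    half_life_days: float
    lines: tuple[EmissionLine, ...] = ()
    beta_spectra: tuple[BetaSpectrum, ...] = ()
    progeny: tuple[ProgenyLink, ...] = ()
    #: inhalation effective dose coefficient (Sv/Bq), tabulated input
    e_inh: float | None = None
    #: submersion dose coefficients (Sv Bq^-1 s^-1 m^3), tabulated inputs
    h_sub_eff: float | None = None
    h_sub_skin: float | None = None
    is_gaseous: bool = False
    #: set by :func:`attach_annihilation_photons`; guards idempotence
    annihilation_attached: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("nuclide id must be nonempty")
        if self.half_life_days <= 0:
            raise SchemaError(f"{self.id}: half-life must be > 0")
        object.__setattr__(self, "lines", tuple(self.lines))
        object.__setattr__(self, "beta_spectra", tuple(self.beta_spectra))
        object.__setattr__(self, "progeny", tuple(self.progeny))

    # -- convenience selectors -------------------------------------------
    def lines_of(self, particle: Particle) -> tuple[EmissionLine, ...]:
        return tuple(l for l in self.lines if l.particle is particle)

    @property
    def positron_yield(self) -> float:
        """Total positron emissions per decay (lines plus beta+ continua)."""
        y = sum(l.yield_per_decay for l in self.lines_of(Particle.POSITRON))
        y += sum(
            s.total_yield for s in self.beta_spectra if s.particle is Particle.POSITRON
        )
        return y

    @property
    def computable(self) -> bool:
        return bool(self.lines) or bool(self.beta_spectra)


@dataclass
class NuclideLibrary:
    """Mapping id -> :class:`Nuclide` with provenance metadata."""

    nuclides: dict[str, Nuclide] = field(default_factory=dict)
    source: str = "unspecified"
    version: str = "0"

    def __post_init__(self) -> None:
        for nid, nuc in self.nuclides.items():
            if nid != nuc.id:
                raise SchemaError(f"library key {nid!r} != nuclide id {nuc.id!r}")

    def __getitem__(self, nuclide_id: str) -> Nuclide:
        return self.nuclides[nuclide_id]

    def __contains__(self, nuclide_id: str) -> bool:
        return nuclide_id in self.nuclides

    def __len__(self) -> int:
        return len(self.nuclides)

    def add(self, nuclide: Nuclide) -> None:
        if nuclide.id in self.nuclides:
            raise SchemaError(f"duplicate nuclide id {nuclide.id!r}")
        self.nuclides[nuclide.id] = nuclide

    def unresolved_progeny(self) -> list[tuple[str, str]]:
        """(parent, daughter) pairs whose daughter is absent from the library."""
        missing = []
        for nuc in self.nuclides.values():
            for link in nuc.progeny:
                if link.daughter_id not in self.nuclides:
                    missing.append((nuc.id, link.daughter_id))
        return missing


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

def _line_to_dict(line: EmissionLine) -> dict:
    return {
        "particle": line.particle.value,
        "energy": float(line.energy_mev),
        "yield": float(line.yield_per_decay),
    }


def _spectrum_to_dict(spec: BetaSpectrum) -> dict:
    return {
        "particle": spec.particle.value,
        "energy_grid": [float(x) for x in spec.energy_grid],
        "density": [float(x) for x in spec.density],
        "total_yield": float(spec.total_yield),
        "e_max": float(spec.e_max),
    }


def _nuclide_to_dict(nuc: Nuclide) -> dict:
    out: dict = {"half_life_days": float(nuc.half_life_days)}
    if nuc.lines:
        out["lines"] = [_line_to_dict(l) for l in nuc.lines]
    if nuc.beta_spectra:
        out["beta_spectra"] = [_spectrum_to_dict(s) for s in nuc.beta_spectra]
    if nuc.progeny:
        out["progeny"] = [
            {
                "daughter": p.daughter_id,
                "branching": float(p.branching),
                "half_life_days": float(p.daughter_half_life_days),
            }
            for p in nuc.progeny
        ]
    for key in ("e_inh", "h_sub_eff", "h_sub_skin"):
        val = getattr(nuc, key)
        if val is not None:
            out[key] = float(val)
    if nuc.is_gaseous:
        out["is_gaseous"] = True
    if nuc.annihilation_attached:
        out["annihilation_attached"] = True
    return out


def _nuclide_from_dict(nid: str, d: dict) -> Nuclide:
    try:
        lines = tuple(
            EmissionLine(Particle(l["particle"]), l["energy"], l["yield"])
            for l in d.get("lines", [])
        )
        spectra = tuple(
            BetaSpectrum(
                np.asarray(s["energy_grid"], dtype=float),
                np.asarray(s["density"], dtype=float),
                s["total_yield"],
                s["e_max"],
                Particle(s.get("particle", "electron")),
            )
            for s in d.get("beta_spectra", [])
        )
        progeny = tuple(
            ProgenyLink(p["daughter"], p["branching"], p["half_life_days"])
            for p in d.get("progeny", [])
        )
        return Nuclide(
            id=nid,
            half_life_days=d["half_life_days"],
            lines=lines,
            beta_spectra=spectra,
            progeny=progeny,
            e_inh=d.get("e_inh"),
            h_sub_eff=d.get("h_sub_eff"),
            h_sub_skin=d.get("h_sub_skin"),
            is_gaseous=bool(d.get("is_gaseous", False)),
            annihilation_attached=bool(d.get("annihilation_attached", False)),
        )
    except KeyError as exc:
        raise SchemaError(f"{nid}: missing required field {exc}") from exc
    except SchemaError as exc:
        raise SchemaError(f"{nid}: {exc}") from exc


def write_library(library: NuclideLibrary, path) -> None:
    doc = {
        "format": "qtransport-nuclide-library",
        "format_version": LIBRARY_FORMAT_VERSION,
        "source": library.source,
        "version": library.version,
        "nuclides": {nid: _nuclide_to_dict(n) for nid, n in library.nuclides.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_library(path, dialect: str = "native") -> NuclideLibrary:
    """Read a nuclide library; every type invariant is enforced on load.

    Violations raise :class:`SchemaError` naming the nuclide and field.
    Only the ``native`` YAML dialect is supported; other decay-data
    formats are converted externally.
    """
    if dialect != "native":
        raise ValueError(f"unsupported dialect {dialect!r}")
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError:
        raise
    if not isinstance(doc, dict) or doc.get("format") != "qtransport-nuclide-library":
        raise SchemaError(f"{path}: not a qtransport nuclide library")
    lib = NuclideLibrary(
        source=str(doc.get("source", "unspecified")),
        version=str(doc.get("version", "0")),
    )
    for nid, d in (doc.get("nuclides") or {}).items():
        lib.add(_nuclide_from_dict(str(nid), d))
    return lib


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def allowed_beta_density(e_max: float, total_yield: float, n_bins: int = 60,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Allowed-shape beta density N(E) on a grid reaching ``e_max``.

    Classical allowed shape p*W*(Q-E)^2 without the Fermi function --
    adequate for synthetic test emitters.  Returned density integrates
    trapezoidally to ``total_yield`` exactly (numeric normalization).
    """
    me = 0.51099895
    grid = np.linspace(0.0, e_max, n_bins + 1)
    w = grid + me
    p = np.sqrt(np.maximum(w**2 - me**2, 0.0))
    dens = p * w * (e_max - grid) ** 2
    norm = np.trapezoid(dens, grid)
    dens = dens * (total_yield / norm)
    return grid, dens


def make_fixture_nuclide(kind: str, *, energy: float = 0.662, yield_: float = 1.0,
                         e_max: float = 1.0, total_yield: float = 1.0,
                         half_life_days: float = 30.0, seed: int | None = None,
                         nuclide_id: str | None = None) -> Nuclide:
    """Deterministic synthetic nuclides for tests.

    Kinds: ``gamma_line`` (one photon line), ``beta_continuum``
    (allowed-shape spectrum), ``mixed`` (line + continuum), ``positron``
    (beta+ continuum, annihilation not yet attached), ``chain`` (parent
    with one short-lived gamma daughter).  With a ``seed`` the energies
    and yields are jittered reproducibly.
    """
    rng = np.random.default_rng(seed)
    if seed is not None:
        energy = float(energy * rng.uniform(0.8, 1.2))
        yield_ = float(yield_ * rng.uniform(0.5, 1.0))
        e_max = float(e_max * rng.uniform(0.8, 1.2))
    nid = nuclide_id or f"FX-{kind}"

    def continuum(particle: Particle) -> BetaSpectrum:
        grid, dens = allowed_beta_density(e_max, total_yield)
        return BetaSpectrum(grid, dens, total_yield, e_max, particle)

    if kind == "gamma_line":
        return Nuclide(nid, half_life_days,
                       lines=(EmissionLine(Particle.PHOTON, energy, yield_),))
    if kind == "beta_continuum":
        return Nuclide(nid, half_life_days, beta_spectra=(continuum(Particle.ELECTRON),))
    if kind == "mixed":
        return Nuclide(
            nid, half_life_days,
            lines=(EmissionLine(Particle.PHOTON, energy, yield_),),
            beta_spectra=(continuum(Particle.ELECTRON),),
        )
    if kind == "positron":
        return Nuclide(nid, half_life_days, beta_spectra=(continuum(Particle.POSITRON),))
    if kind == "chain":
        daughter_hl = 0.01 if seed is None else float(rng.uniform(1e-3, 5.0))
        return Nuclide(
            nid, half_life_days,
            lines=(EmissionLine(Particle.PHOTON, energy, yield_),),
            progeny=(ProgenyLink(f"{nid}-d", 1.0, daughter_hl),),
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Annihilation photons
# ---------------------------------------------------------------------------

def attach_annihilation_photons(nuclide: Nuclide) -> Nuclide:
    """Append the 0.511 MeV annihilation pair to the photon lines.

    Each positron annihilates into two 0.511 MeV photons, so the added
    line has yield 2x the total positron yield.  Positron emissions are
    retained for the beta pathways.  Idempotent: a marker prevents
    double-adding.
    """
    if nuclide.annihilation_attached:
        return nuclide
    beta_plus = nuclide.positron_yield
    if beta_plus <= 0:
        return nuclide
    line = EmissionLine(Particle.PHOTON, ANNIHILATION_MEV, 2.0 * beta_plus)
    return replace(
        nuclide, lines=nuclide.lines + (line,), annihilation_attached=True
    )


# ---------------------------------------------------------------------------
# Progeny resolution
# ---------------------------------------------------------------------------

def classify_progeny(daughter_half_life_days: float,
                     parent_half_life_days: float) -> str:
    """``equilibrium`` or ``mixture_component`` per the two chain rules.

    A daughter is folded into the parent (secular equilibrium) only if
    its half-life is below :data:`EQUILIBRIUM_HALF_LIFE_DAYS` *and*
    below the parent's; otherwise parent and daughter form a mixture.
    """
    if (daughter_half_life_days < EQUILIBRIUM_HALF_LIFE_DAYS
            and daughter_half_life_days < parent_half_life_days):
        return "equilibrium"
    return "mixture_component"


def resolve_progeny(nuclide: Nuclide, library: NuclideLibrary,
                    max_depth: int = 5,
                    ) -> list[tuple[Nuclide, str | None, float]]:
    """Flatten a decay chain into (nuclide, treatment, activity fraction).

    The parent is always first with treatment ``None`` and fraction 1.
    Equilibrium daughters are recursed into (their own short-lived
    progeny fold in too); fractions multiply down the chain by the
    branching ratios.  Exceeding ``max_depth`` raises rather than
    silently truncating.
    """
    out: list[tuple[Nuclide, str | None, float]] = [(nuclide, None, 1.0)]

    def walk(parent: Nuclide, fraction: float, depth: int) -> None:
        if depth > max_depth:
            raise RecursionError(
                f"progeny chain below {nuclide.id} exceeds depth {max_depth}"
            )
        for link in parent.progeny:
            if link.daughter_id not in library:
                raise KeyError(
                    f"{parent.id}: progeny {link.daughter_id!r} not in library"
                )
            daughter = library[link.daughter_id]
            treatment = classify_progeny(
                link.daughter_half_life_days, parent.half_life_days
            )
            frac = fraction * link.branching
            out.append((daughter, treatment, frac))
            if treatment == "equilibrium":
                walk(daughter, frac, depth + 1)

    walk(nuclide, 1.0, 1)
    return out
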