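"""Q values, caps, minima, progeny and mixture rules, regulatory rounding.

The Q-system turns the pathway dose-rate coefficients into five
activity limits (TBq):

* ``QA = 1e-13 / e_pt``   -- external photon dose, 0.05 Sv in 0.5 h at 1 m;
* ``QB = 1e-12 / e_b``    -- external beta skin dose, 0.5 Sv in 0.5 h,
  behind the residual shielding factor SF;
* ``QC = 5e-8  / e_inh``  -- inhalation of 1e-6 of the contents, 0.05 Sv;
* ``QD = 2.8e-2 / h_skin`` -- skin contamination (1e-3 of contents per
  m^2 on the hands, 5 h exposure, 0.5 Sv), capped at 1e3 TBq;
* ``QE``                  -- submersion for gaseous nuclides, the lower
  of the effective and skin branches.

A1 (special form) is min(QA, QB): a sealed capsule cannot be inhaled,
ingested or dispersed.  A2 is the minimum over all defined Q values.
All Bq -> TBq conversion happens here and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .nuclide_data import Nuclide, NuclideLibrary, resolve_progeny

__all__ = [
    "ReferenceParameters",
    "DEFAULT_PARAMETERS",
    "QValues",
    "TransportLimits",
    "MixtureComponent",
    "shielding_factor",
    "q_a",
    "q_b",
    "q_c",
    "q_d",
    "q_e",
    "q_values_from_coefficients",
    "limits",
    "progeny_limit",
    "mixture_limit",
    "generic_fallback",
    "round_regulatory",
    "compute_transport_limits",
]


@dataclass(frozen=True)
class ReferenceParameters:
    """Reference doses, times and release fractions of the Q-system.

    Immutable defaults; override only through an explicit instance.
    """

    d_eff_sv: float = 0.05            # whole-body reference dose
    d_skin_sv: float = 0.5            # skin reference dose
    t_exposure_h: float = 0.5         # external exposure time
    inhaled_fraction: float = 1e-6    # fraction of contents inhaled
    skin_deposit_per_m2: float = 1e-3  # fraction of contents per m^2 of skin
    t_skin_s: float = 1.8e4           # 5 h hand-contamination exposure
    unit_constant: float = 1e-12      # TBq per Bq (C = 1 for QD)
    shield_areal_mg_cm2: float = 150.0
    sf_mu_coefficient: float = 0.017  # cm^2/mg
    sf_mu_exponent: float = -1.14
    sf_cap_energy_mev: float = 2.0
    sf_cap_value: float = 3.0
    #: regulatory rounded value of d_skin * C / (deposit * t) = 0.5/1.8e4/1e-3
    #: * 1e12 Bq/TBq; the tabulated Q_D values derive from this 2-digit form
    qd_constant_tbq: float = 2.8e-2
    qd_cap_tbq: float = 1e3
    tiac_bq_s_m3: float = 2.6         # time-integrated air concentration
    dl_eff_sv: float = 0.05
    dl_skin_sv: float = 0.5

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if name == "sf_mu_exponent":
                continue  # the empirical exponent is negative by definition
            if not val > 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_PARAMETERS = ReferenceParameters()


# ---------------------------------------------------------------------------
# Shielding factor
# ---------------------------------------------------------------------------

def shielding_factor(e_beta_max_mev: float | None, mono_only: bool = False,
                     params: ReferenceParameters = DEFAULT_PARAMETERS) -> float:
    """Residual beta shielding factor SF = exp(mu d), capped at 3.

    ``mu = 0.017 * E_beta,max^-1.14`` (cm^2/mg) through d = 150 mg/cm^2
    of package debris.  Endpoints >= 2 MeV take the conservative cap
    SF = 3, as do emitters with only monoenergetic electrons
    (``mono_only``), where no spectral endpoint is defined.
    """
    if mono_only:
        return params.sf_cap_value
    if e_beta_max_mev is None or e_beta_max_mev <= 0:
        raise ValueError("e_beta_max must be > 0 unless mono_only")
    if e_beta_max_mev >= params.sf_cap_energy_mev:
        return params.sf_cap_value
    mu = params.sf_mu_coefficient * e_beta_max_mev**params.sf_mu_exponent
    return math.exp(mu * params.shield_areal_mg_cm2)


# ---------------------------------------------------------------------------
# The five Q values
# ---------------------------------------------------------------------------

def _positive(coefficient: float | None, name: str) -> float:
    if coefficient is None or coefficient == 0:
        raise ValueError(f"{name}: zero/absent coefficient, pathway undefined")
    if coefficient < 0:
        raise ValueError(f"{name}: coefficient must be > 0")
    return float(coefficient)


def q_a(e_pt: float, params: ReferenceParameters = DEFAULT_PARAMETERS) -> float:
    """External-photon limit: (D_eff / t) * C / e_pt = 1e-13 / e_pt TBq."""
    c = _positive(e_pt, "q_a")
    return params.d_eff_sv / params.t_exposure_h * params.unit_constant / c


def q_b(e_b: float, params: ReferenceParameters = DEFAULT_PARAMETERS) -> float:
    """External-beta limit: (D_skin / t) * C / e_b = 1e-12 / e_b TBq."""
    c = _positive(e_b, "q_b")
    return params.d_skin_sv / params.t_exposure_h * params.unit_constant / c


def q_c(e_inh: float, params: ReferenceParameters = DEFAULT_PARAMETERS) -> float:
    """Inhalation limit: D_eff / (1e-6 * e_inh) * C = 5e-8 / e_inh TBq."""
    c = _positive(e_inh, "q_c")
    return (params.d_eff_sv / (params.inhaled_fraction * c)
            * params.unit_constant)


def q_d(h_skin: float, params: ReferenceParameters = DEFAULT_PARAMETERS
        ) -> tuple[float, bool]:
    """Skin-contamination limit, capped at 1e3 TBq.

    ``D_skin / (1e-3 * h_skin * t) = 2.8e-2 / h_skin`` TBq (h_skin in
    Sv m^2/(TBq s), so C = 1).  Returns ``(value, capped)``.
    """
    c = _positive(h_skin, "q_d")
    raw = params.qd_constant_tbq / c
    return min(raw, params.qd_cap_tbq), raw > params.qd_cap_tbq


def q_e(h_sub_eff: float, h_sub_skin: float,
        params: ReferenceParameters = DEFAULT_PARAMETERS) -> float:
    """Submersion limit: the lower of the effective and skin branches."""
    eff = _positive(h_sub_eff, "q_e")
    skin = _positive(h_sub_skin, "q_e")
    branch_eff = params.dl_eff_sv / (params.tiac_bq_s_m3 * eff) \
        * params.unit_constant
    branch_skin = params.dl_skin_sv / (params.tiac_bq_s_m3 * skin) \
        * params.unit_constant
    return min(branch_eff, branch_skin)


@dataclass(frozen=True)
class QValues:
    """The five Q values (TBq); None marks an absent pathway."""

    nuclide_id: str
    qa: float | None = None
    qb: float | None = None
    qc: float | None = None
    qd: float | None = None
    qe: float | None = None
    qd_capped: bool = False
    inputs: dict = field(default_factory=dict)

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in
                (("QA", self.qa), ("QB", self.qb), ("QC", self.qc),
                 ("QD", self.qd), ("QE", self.qe)) if v is not None}

    def __post_init__(self) -> None:
        for name, v in self.defined().items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0")


def q_values_from_coefficients(nuclide_id: str, e_pt: float | None,
                               e_b: float | None, e_inh: float | None,
                               h_skin: float | None,
                               h_sub_eff: float | None = None,
                               h_sub_skin: float | None = None,
                               is_gaseous: bool = False,
                               params: ReferenceParameters = DEFAULT_PARAMETERS,
                               ) -> QValues:
    """Q values from pathway coefficients; zero/absent pathways are skipped.

    A pathway with a vanishing coefficient is treated as absent (no
    hazard by that route), not as an infinite or zero limit.
    """
    def given(x):
        return x is not None and x > 0

    qd_val, capped = q_d(h_skin, params) if given(h_skin) else (None, False)
    return QValues(
        nuclide_id=nuclide_id,
        qa=q_a(e_pt, params) if given(e_pt) else None,
        qb=q_b(e_b, params) if given(e_b) else None,
        qc=q_c(e_inh, params) if given(e_inh) else None,
        qd=qd_val,
        qe=q_e(h_sub_eff, h_sub_skin, params)
        if is_gaseous and given(h_sub_eff) and given(h_sub_skin) else None,
        qd_capped=capped,
        inputs={"e_pt": e_pt, "e_b": e_b, "e_inh": e_inh, "h_skin": h_skin,
                "h_sub_eff": h_sub_eff, "h_sub_skin": h_sub_skin},
    )


# ---------------------------------------------------------------------------
# A1 / A2 aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportLimits:
    """A1/A2 in TBq, raw and regulatory-rounded, with limiting pathways."""

    nuclide_id: str
    a1: float
    a2: float
    a1_limiting: str
    a2_limiting: str
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.a1 < self.a2 * (1 - 1e-12):
            raise ValueError("A1 must be >= A2")

    @property
    def a1_rounded(self) -> float:
        return round_regulatory(self.a1, "limit_1sig")

    @property
    def a2_rounded(self) -> float:
        return round_regulatory(self.a2, "limit_1sig")


def limits(q: QValues) -> TransportLimits:
    """A1 = min(QA, QB); A2 = min over all defined Q values (QD capped).

    Special form retains its contents in an accident, so the QC/QD/QE
    scenarios are not relevant to A1.
    """
    defined = q.defined()
    if not defined:
        raise ValueError(f"{q.nuclide_id}: no Q value defined")
    special = {k: v for k, v in defined.items() if k in ("QA", "QB")}
    a1_pathway, a1 = min((special or defined).items(), key=lambda kv: kv[1])
    a2_pathway, a2 = min(defined.items(), key=lambda kv: kv[1])
    return TransportLimits(q.nuclide_id, a1, a2, a1_pathway, a2_pathway)


def progeny_limit(parent: TransportLimits,
                  daughters: list[tuple[TransportLimits, str, float]],
                  ) -> TransportLimits:
    """Combine parent limits with progeny per the chain rules.

    Secular-equilibrium daughters impose the elementwise minimum of the
    limits (limiting member of the chain); long-lived daughters form a
    mixture with the stated activity fractions (harmonic rule).
    """
    a1, a2 = parent.a1, parent.a2
    a1_lim = f"{parent.nuclide_id}:{parent.a1_limiting}"
    a2_lim = f"{parent.nuclide_id}:{parent.a2_limiting}"
    mixture: list[tuple[str, float, TransportLimits]] = []
    for lim, treatment, fraction in daughters:
        if treatment == "equilibrium":
            if lim.a1 < a1:
                a1, a1_lim = lim.a1, f"{lim.nuclide_id}:{lim.a1_limiting}"
            if lim.a2 < a2:
                a2, a2_lim = lim.a2, f"{lim.nuclide_id}:{lim.a2_limiting}"
        elif treatment == "mixture_component":
            mixture.append((lim.nuclide_id, fraction, lim))
        else:
            raise ValueError(f"unknown progeny treatment {treatment!r}")
    if mixture:
        parent_fraction = 1.0 - sum(f for _, f, _ in mixture)
        if parent_fraction <= 0:
            raise ValueError("mixture fractions exceed 1")
        a1 = mixture_limit(
            [MixtureComponent(parent.nuclide_id, parent_fraction, a1)]
            + [MixtureComponent(nid, f, lim.a1) for nid, f, lim in mixture]
        )
        a2 = mixture_limit(
            [MixtureComponent(parent.nuclide_id, parent_fraction, a2)]
            + [MixtureComponent(nid, f, lim.a2) for nid, f, lim in mixture]
        )
        a1_lim = a2_lim = "mixture"
    return TransportLimits(parent.nuclide_id, a1, a2, a1_lim, a2_lim)


@dataclass(frozen=True)
class MixtureComponent:
    nuclide_id: str
    fraction: float
    x_tbq: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.x_tbq <= 0:
            raise ValueError("X must be > 0")


def mixture_limit(components: list[MixtureComponent]) -> float:
    """Harmonic mixture rule X_m = 1 / sum_i f(i) / X(i)."""
    total = sum(c.fraction for c in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions sum to {total}, expected 1")
    return 1.0 / sum(c.fraction / c.x_tbq for c in components)


GENERIC_FALLBACKS = {
    "beta_gamma": (0.1, 0.02),
    "alpha_no_neutron": (0.2, 9e-5),
    "neutron_or_unknown": (0.001, 9e-5),
}


def generic_fallback(content_class: str) -> TransportLimits:
    """Conservative generic limits for contents without tabulated values."""
    try:
        a1, a2 = GENERIC_FALLBACKS[content_class]
    except KeyError:
        raise ValueError(f"unknown content class {content_class!r}") from None
    return TransportLimits(content_class, a1, a2, "generic", "generic",
                           fallback=True)


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------

def round_regulatory(x: float, style: str = "raw") -> float:
    """Regulatory rounding: Q to 2 significant digits, limits to 1.

    ``q_2sig`` rounds half-to-even on the second significant digit;
    ``limit_1sig`` to the nearest single significant figure (ties to
    even); ``raw`` returns the input.
    """
    if x <= 0:
        raise ValueError("can only round positive quantities")
    if style == "raw":
        return x
    digits = {"q_2sig": 2, "limit_1sig": 1}.get(style)
    if digits is None:
        raise ValueError(f"unknown rounding style {style!r}")
    exponent = math.floor(math.log10(x))
    scale = 10.0 ** (exponent - digits + 1)
    mantissa = x / scale
    # round-half-even at the last kept digit
    rounded = float(round(mantissa)) * scale
    return rounded


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def compute_transport_limits(nuclide: Nuclide, library: NuclideLibrary,
                             curveset: dict | None = None,
                             params: ReferenceParameters = DEFAULT_PARAMETERS,
                             ) -> dict:
    """End-to-end: decay data -> coefficients -> Q values -> A1/A2.

    Resolves the progeny chain, computes pathway coefficients and Q
    values for the parent and every secular-equilibrium daughter
    (daughter coefficients weighted by the chain activity fraction),
    takes the limiting member, and folds long-lived daughters in with
    the mixture rule.  Returns a report dict with all intermediates.
    """
    from .spectrum_engine import analytic_curveset, compute_dose_coefficients

    curves = curveset if curveset is not None else analytic_curveset()
    chain = resolve_progeny(nuclide, library)
    members = []
    mixture_fraction_used = []
    for nuc, treatment, fraction in chain:
        coeffs = compute_dose_coefficients(nuc, curves)
        weight = fraction if treatment == "equilibrium" else 1.0
        q = q_values_from_coefficients(
            nuc.id,
            coeffs.e_pt * weight if coeffs.e_pt else None,
            coeffs.e_b * weight if coeffs.e_b else None,
            (nuc.e_inh * weight) if nuc.e_inh else None,
            coeffs.h_skin * weight if coeffs.h_skin else None,
            nuc.h_sub_eff, nuc.h_sub_skin, nuc.is_gaseous, params,
        )
        members.append((nuc, treatment, fraction, coeffs, q, limits(q)))
        if treatment == "mixture_component":
            mixture_fraction_used.append(fraction)
    parent_limits = members[0][5]
    daughters = [(m[5], m[1], m[2]) for m in members[1:]]
    combined = progeny_limit(parent_limits, daughters)
    return {
        "nuclide": nuclide.id,
        "members": members,
        "q_values": members[0][4],
        "limits": combined,
        "a1_tbq": combined.a1,
        "a2_tbq": combined.a2,
        "a1_rounded_tbq": combined.a1_rounded,
        "a2_rounded_tbq": combined.a2_rounded,
    }
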