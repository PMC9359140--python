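"""Q formulas, caps, aggregation, mixtures, fallbacks, rounding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qtransport import qsystem as qs
from qtransport.qsystem import (
    MixtureComponent,
    QValues,
    TransportLimits,
    generic_fallback,
    limits,
    mixture_limit,
    progeny_limit,
    q_a,
    q_b,
    q_c,
    q_d,
    q_e,
    round_regulatory,
    shielding_factor,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Shielding factor
# ---------------------------------------------------------------------------

def test_shielding_factor_values():
    assert shielding_factor(2.0) == 3.0
    assert shielding_factor(3.5) == 3.0
    assert shielding_factor(None, mono_only=True) == 3.0
    assert shielding_factor(1.0) == pytest.approx(math.exp(0.017 * 150), rel=1e-12)
    with pytest.raises(ValueError):
        shielding_factor(-1.0)
    with pytest.raises(ValueError):
        shielding_factor(None)


# ---------------------------------------------------------------------------
# Q formulas (published coefficient -> Q pairs)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("func,coeff,expected", [
    (q_a, 4.78e-15, 2.09e1),   # photon pathway, gamma-weak emitter
    (q_a, 1.89e-13, 5.29e-1),  # strong annihilation/gamma emitter
    (q_a, 1e-13, 1.0),         # unit normalization
    (q_b, 5.48e-19, 1.82e6),
    (q_b, 2.20e-12, 4.54e-1),
    (q_b, 1e-12, 1.0),
    (q_c, 5.20e-11, 9.62e2),
    (q_c, 3.10e-9, 1.61e1),
    (q_c, 5e-8, 1.0),
])
def test_q_formulas_reproduce_published_pairs(func, coeff, expected):
    assert func(coeff) == pytest.approx(expected, rel=0.005)


def test_q_d_values_and_cap():
    assert q_d(9.64e-3) == (pytest.approx(2.90, rel=0.005), False)
    assert q_d(1.20e-4) == (pytest.approx(2.33e2, rel=0.005), False)
    val, capped = q_d(1e-6)
    assert val == 1e3 and capped  # raw 2.8e4 exceeds the cap


def test_q_zero_coefficient_is_undefined():
    for fn in (q_a, q_b, q_c):
        with pytest.raises(ValueError):
            fn(0.0)
    with pytest.raises(ValueError):
        q_d(0.0)


def test_q_e_branches():
    # arrange the effective branch to produce exactly X TBq
    x = 7.5
    h_eff = 0.05 / (2.6 * 1e-12 * x) * 1e-24  # solve DL/(TIAC*h)*C = x
    h_eff = 0.05 * 1e-12 / (2.6 * x)
    assert q_e(h_eff, h_eff / 100.0) == pytest.approx(x, rel=1e-9)
    # min semantics: a 10x larger skin coefficient can make skin limiting
    assert q_e(h_eff, h_eff * 100.0) == pytest.approx(
        0.5 * 1e-12 / (2.6 * h_eff * 100.0), rel=1e-9)
    # equal branches after the 10x dose-criterion ratio
    assert q_e(h_eff, 10 * h_eff) == pytest.approx(x, rel=1e-9)


@given(st.floats(1e-20, 1e-5), st.floats(1.01, 100.0))
def test_q_values_strictly_decreasing_in_coefficient(coeff, factor):
    assert q_a(coeff * factor) < q_a(coeff)
    assert q_b(coeff * factor) < q_b(coeff)
    assert q_c(coeff * factor) < q_c(coeff)
    v1, _ = q_d(coeff)
    v2, _ = q_d(coeff * factor)
    assert v2 <= v1  # equality only when both hit the cap


# ---------------------------------------------------------------------------
# Limits aggregation
# ---------------------------------------------------------------------------

def test_limits_for_gamma_weak_emitter_qd_limited():
    q = QValues("Be-7", qa=2.09e1, qb=1.82e6, qc=9.62e2, qd=2.90)
    lim = limits(q)
    assert lim.a1 == pytest.approx(2.09e1)
    assert lim.a2 == pytest.approx(2.90)
    assert lim.a2_limiting == "QD"


def test_limits_a1_is_min_of_qa_qb():
    q = QValues("Na-22", qa=5.29e-1, qb=2.71, qc=25.0, qd=0.696)
    lim = limits(q)
    assert lim.a1 == pytest.approx(5.29e-1)
    assert lim.a1_limiting == "QA"


def test_limits_all_equal_and_empty():
    q = QValues("X", qa=2.0, qb=2.0, qc=2.0, qd=2.0)
    lim = limits(q)
    assert lim.a1 == lim.a2 == 2.0
    with pytest.raises(ValueError):
        limits(QValues("none"))


def test_transport_limits_invariant():
    with pytest.raises(ValueError):
        TransportLimits("bad", a1=1.0, a2=2.0, a1_limiting="QA",
                        a2_limiting="QC")


# ---------------------------------------------------------------------------
# Progeny and mixtures
# ---------------------------------------------------------------------------

def _lim(nid, a1, a2):
    return TransportLimits(nid, a1, a2, "QA", "QA")


def test_progeny_limit_equilibrium_minimum():
    parent = _lim("P", 5.0, 5.0)
    daughter = _lim("D", 2.0, 1.5)
    out = progeny_limit(parent, [(daughter, "equilibrium", 0.9)])
    assert out.a1 == 2.0 and out.a2 == 1.5
    assert out.a2_limiting == "D:QA"


def test_progeny_limit_no_daughters():
    parent = _lim("P", 5.0, 4.0)
    out = progeny_limit(parent, [])
    assert (out.a1, out.a2) == (5.0, 4.0)


def test_progeny_limit_mixture_equal_components():
    parent = _lim("P", 1.0, 1.0)
    daughter = _lim("D", 1.0, 1.0)
    out = progeny_limit(parent, [(daughter, "mixture_component", 0.4)])
    assert out.a1 == pytest.approx(1.0)


def test_mixture_limit_hand_values():
    assert mixture_limit([MixtureComponent("a", 1.0, 4.2)]) == pytest.approx(4.2)
    assert mixture_limit([MixtureComponent("a", 0.5, 1.0),
                          MixtureComponent("b", 0.5, 1.0)]) == pytest.approx(1.0)
    out = mixture_limit([MixtureComponent("a", 0.5, 0.1),
                         MixtureComponent("b", 0.5, 0.9)])
    assert out == pytest.approx(1.0 / (0.5 / 0.1 + 0.5 / 0.9), rel=1e-12)
    assert out == pytest.approx(0.18, abs=0.005)
    with pytest.raises(ValueError):
        mixture_limit([MixtureComponent("a", 0.5, 1.0)])


@given(st.lists(st.tuples(st.floats(0.01, 1.0), st.floats(1e-4, 1e4)),
                min_size=1, max_size=6))
def test_mixture_bounded_and_order_invariant(raw):
    total = sum(f for f, _ in raw)
    comps = [MixtureComponent(f"n{i}", f / total, x)
             for i, (f, x) in enumerate(raw)]
    out = mixture_limit(comps)
    xs = [c.x_tbq for c in comps]
    assert min(xs) * (1 - 1e-9) <= out <= max(xs) * (1 + 1e-9)
    assert mixture_limit(list(reversed(comps))) == pytest.approx(out, rel=1e-12)


def test_generic_fallback_triplets():
    bg = generic_fallback("beta_gamma")
    assert (bg.a1, bg.a2) == (0.1, 0.02) and bg.fallback
    an = generic_fallback("alpha_no_neutron")
    assert (an.a1, an.a2) == (0.2, 9e-5)
    nu = generic_fallback("neutron_or_unknown")
    assert (nu.a1, nu.a2) == (0.001, 9e-5)
    with pytest.raises(ValueError):
        generic_fallback("gthings")


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------

def test_round_regulatory_examples():
    assert round_regulatory(961.5, "q_2sig") == pytest.approx(9.6e2)
    assert round_regulatory(20.92, "limit_1sig") == pytest.approx(2e1)
    for style in ("raw", "q_2sig", "limit_1sig"):
        assert round_regulatory(1.0, style) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        round_regulatory(-1.0, "q_2sig")
    with pytest.raises(ValueError):
        round_regulatory(1.0, "nearest_pi")


@given(st.floats(1e-6, 1e6))
def test_rounding_preserves_order_of_magnitude(x):
    for style in ("q_2sig", "limit_1sig"):
        r = round_regulatory(x, style)
        assert r > 0
        assert abs(math.log10(r / x)) < math.log10(10.0) / 2 + 1e-9
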