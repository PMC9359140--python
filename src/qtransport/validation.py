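"""Published-value fixture: control-group coefficients, Q values, limits.

The package ships the published Monte-Carlo dose-rate coefficients and
the derived Q/A values for 22 radionuclides (10 tabulated control
nuclides, 12 medical nuclides without tabulated limits) as a validation
fixture.  :func:`sweep_reference` re-derives every Q value and both
limits from the printed coefficients through :mod:`qtransport.qsystem`
-- the closed-form arithmetic chain -- and reports the relative
deviation from the printed values.  Rows whose printed arithmetic is
internally inconsistent (a handful of ragged table cells) are flagged
in the fixture and excluded from strict comparisons.
"""

from __future__ import annotations

import io
from importlib import resources

import numpy as np
import pandas as pd

from . import qsystem as qs

__all__ = [
    "load_reference_values",
    "recompute_row",
    "sweep_reference",
    "compare_e_pt",
]


def load_reference_values() -> pd.DataFrame:
    """The shipped published-values fixture as a DataFrame."""
    text = (resources.files("qtransport.data") / "reference_limits.csv").read_text()
    df = pd.read_csv(io.StringIO(text), comment="#")
    df["consistent"] = df["consistent"].astype(bool)
    return df.set_index("nuclide", drop=False)


def recompute_row(row: pd.Series,
                  params: qs.ReferenceParameters = qs.DEFAULT_PARAMETERS) -> dict:
    """Coefficients -> Q -> A for one fixture row, via the Q-system ops."""
    def get(col):
        v = row[col]
        return None if pd.isna(v) else float(v)

    q = qs.q_values_from_coefficients(
        row["nuclide"], get("e_pt"), get("e_b"), get("e_inh"), get("h_skin"),
        params=params,
    )
    lim = qs.limits(q)
    return {
        "nuclide": row["nuclide"],
        "q_a": q.qa, "q_b": q.qb, "q_c": q.qc, "q_d": q.qd,
        "qd_capped": q.qd_capped,
        "a1": lim.a1, "a2": lim.a2,
        "a1_limiting": lim.a1_limiting, "a2_limiting": lim.a2_limiting,
    }


def sweep_reference(params: qs.ReferenceParameters = qs.DEFAULT_PARAMETERS
                    ) -> pd.DataFrame:
    """Recompute all 22 nuclides; add rel. deviation columns vs printed."""
    ref = load_reference_values()
    rows = [recompute_row(r, params) for _, r in ref.iterrows()]
    out = pd.DataFrame(rows).set_index("nuclide", drop=False)
    for col in ("q_a", "q_b", "q_c", "q_d", "a1", "a2"):
        printed = ref[col].astype(float)
        out[f"dev_{col}"] = (out[col] - printed) / printed
    out["consistent"] = ref["consistent"]
    return out


def compare_e_pt(library, curveset=None) -> pd.DataFrame:
    """Analytic-pipeline e_pt vs the published coefficients.

    For every library nuclide present in the fixture, convolve its
    photon lines with the analytic 1 m kernel and report the ratio to
    the printed e_pt.  Reported, not gated: the decay data shipped with
    the package are illustrative and the analytic kernel carries its
    own documented approximations.
    """
    from .nuclide_data import resolve_progeny
    from .spectrum_engine import analytic_curveset, pathway_coefficient

    curves = curveset if curveset is not None else analytic_curveset()
    ref = load_reference_values()
    rows = []
    for nid, nuc in library.nuclides.items():
        if nid not in ref.index or not np.isfinite(ref.loc[nid, "e_pt"]):
            continue
        e_pt = 0.0
        for member, treatment, fraction in resolve_progeny(nuc, library):
            if treatment in (None, "equilibrium"):
                weight = fraction if treatment == "equilibrium" else 1.0
                e_pt += weight * pathway_coefficient(
                    member, curves, "photon_1m").value
        printed = float(ref.loc[nid, "e_pt"])
        rows.append({"nuclide": nid, "e_pt_computed": e_pt,
                     "e_pt_published": printed,
                     "ratio": e_pt / printed if printed else np.nan})
    return pd.DataFrame(rows)
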