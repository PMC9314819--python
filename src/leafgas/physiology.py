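"""Leaflet hydraulics, stomatal anatomy, FvCB A-Ci fitting and pairwise tests.

Hydraulic conductance follows the in-situ evaporative flux method: the
water-potential difference between a bagged (non-transpiring) and an
unbagged (transpiring) leaflet on the same leaf is the driving gradient
for the measured transpiration flux.  Stomatal anatomy yields the
anatomical maximum stomatal conductance from pore dimensions and density.
A-Ci curves are fit with the Farquhar-von Caemmerer-Berry model with
Rubisco- and RuBP-regeneration-limited segments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "k_leaflet",
    "StomatalGeometry",
    "stomatal_metrics",
    "michaelis_km",
    "fvcb_assimilation",
    "FvCBFit",
    "fit_aci",
    "adjusted_alpha",
    "AdjustedAlpha",
    "pairwise_compare",
    "percent_change",
]


def k_leaflet(e_trans: float, psi_bagged: float, psi_unbagged: float) -> float:
    """Leaflet hydraulic conductance, mmol m-2 s-1 MPa-1.

    ``K = E / (psi_bagged - psi_unbagged)`` with ``E`` in mmol m-2 s-1 and
    water potentials in MPa.  The bagged leaflet equilibrates with the
    xylem and is the less negative of the pair for a transpiring leaf; a
    negative driving gradient is physically suspect and triggers a
    warning while still returning the value.
    """
    dpsi = psi_bagged - psi_unbagged
    if dpsi == 0:
        raise ValueError("zero water-potential difference: K_leaflet undefined")
    if dpsi < 0:
        warnings.warn(
            "bagged leaflet more negative than unbagged: negative driving "
            "gradient, K_leaflet flagged",
            stacklevel=2,
        )
    return e_trans / dpsi


@dataclass(frozen=True)
class StomatalGeometry:
    """Derived stomatal anatomy metrics (lengths um, density mm-2)."""

    pore_length: float
    pore_width: float
    guard_cell_length: float
    guard_cell_pair_width: float
    density_mm2: float
    aperture_ratio: float
    stomate_size_um2: float
    g_smax: float  # mol m-2 s-1


def stomatal_metrics(
    pore_length: float,
    pore_width: float,
    guard_cell_length: float,
    guard_cell_pair_width: float,
    density_mm2: float,
    d_w: float = 2.49e-5,
    molar_volume: float = 0.0224,
) -> StomatalGeometry:
    """Aperture ratio, stomate size and anatomical maximum conductance.

    Aperture ratio = inner pore width / inner pore length; stomate size =
    guard-cell length x guard-cell-pair total width.  The anatomical
    maximum stomatal conductance uses the standard diffusion-through-
    a-perforated-plate form

        g_smax = (d_w / v) * SD * a_max / (l + (pi/2) sqrt(a_max / pi))

    with ``a_max`` the elliptical maximal pore area from the pore length
    and width, pore depth ``l`` taken as a single guard-cell width
    (a common anatomical proxy), ``d_w`` water-vapour diffusivity
    (m2 s-1) and ``v`` the molar volume of air (m3 mol-1).
    """
    for name, v in (
        ("pore_length", pore_length),
        ("pore_width", pore_width),
        ("guard_cell_length", guard_cell_length),
        ("guard_cell_pair_width", guard_cell_pair_width),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if density_mm2 <= 0:
        raise ValueError("stomatal density must be positive")

    aperture_ratio = pore_width / pore_length
    size = guard_cell_length * guard_cell_pair_width
    a_max = np.pi * (pore_length * 1e-6 / 2.0) * (pore_width * 1e-6 / 2.0)  # m2
    depth = (guard_cell_pair_width / 2.0) * 1e-6  # single guard cell width, m
    sd = density_mm2 * 1e6  # m-2
    g_smax = (d_w / molar_volume) * sd * a_max / (depth + (np.pi / 2.0) * np.sqrt(a_max / np.pi))
    return StomatalGeometry(
        pore_length=pore_length,
        pore_width=pore_width,
        guard_cell_length=guard_cell_length,
        guard_cell_pair_width=guard_cell_pair_width,
        density_mm2=density_mm2,
        aperture_ratio=aperture_ratio,
        stomate_size_um2=size,
        g_smax=float(g_smax),
    )


# ---------------------------------------------------------------------------
# FvCB A-Ci model


def michaelis_km(kc: float = 404.9, ko: float = 278.4, o: float = 210.0) -> float:
    """Effective Michaelis constant ``Km = Kc (1 + O/Ko)`` at 25 C.

    ``kc`` in umol mol-1, ``ko`` and ``o`` in mmol mol-1; returns
    umol mol-1 (default 710.3 with the standard tobacco kinetics).
    """
    return kc * (1.0 + o / ko)


def fvcb_assimilation(ci, vcmax, j, rd, gamma_star, km):
    """Net assimilation, ``min(Wc, Wj) - Rd`` (umol m-2 s-1).

    Rubisco-limited carboxylation ``Wc = Vcmax (Ci - G*) / (Ci + Km)``;
    RuBP-regeneration-limited ``Wj = J (Ci - G*) / (4 Ci + 8 G*)`` with
    ``J`` the electron transport rate at the measurement irradiance
    (equal to Jmax under saturating light).
    """
    ci = np.asarray(ci, dtype=float)
    wc = vcmax * (ci - gamma_star) / (ci + km)
    wj = j * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)
    return np.minimum(wc, wj) - rd


@dataclass
class FvCBFit:
    """Fitted FvCB parameters and per-point limitation states."""

    v_cmax: float
    j_max: float
    r_d: float
    gamma_star: float
    km: float
    a_max: float  # fitted A at Ci = 1500 umol mol-1
    limitation: np.ndarray  # "Rubisco" | "RuBP" per point
    flags: list[str]

    def predict(self, ci):
        return fvcb_assimilation(ci, self.v_cmax, self.j_max, self.r_d, self.gamma_star, self.km)


def fit_aci(
    ci,
    an,
    gamma_star: float,
    km: float | None = None,
) -> FvCBFit:
    """Least-squares fit of the two-limitation FvCB model to an A-Ci curve.

    The minimum of the two limitations is fit jointly (no pre-assignment
    of points to regimes); each point is then labelled by whichever
    limitation is smaller at the optimum.  If every point falls in a
    single regime the unconstrained parameter is flagged
    (``jmax_unidentified`` / ``vcmax_unidentified``).
    """
    import lmfit

    ci = np.asarray(ci, dtype=float)
    an = np.asarray(an, dtype=float)
    if ci.size < 6:
        raise ValueError("need at least 6 A-Ci points spanning both regimes")
    if km is None:
        km = michaelis_km()

    rd0 = max(0.5, -float(np.min(an)) if np.min(an) < 0 else 1.0)
    # invert each limitation at an anchor point for initial guesses: Vcmax
    # from the point nearest Ci = 150 (reliably Rubisco-limited), J from
    # the highest-Ci point (reliably RuBP-limited)
    lo = int(np.argmin(np.abs(ci - 150.0)))
    hi = int(np.argmax(ci))
    vc0 = max((an[lo] + rd0) * (ci[lo] + km) / max(ci[lo] - gamma_star, 1.0), 5.0)
    j0 = max((an[hi] + rd0) * (4.0 * ci[hi] + 8.0 * gamma_star) / max(ci[hi] - gamma_star, 1.0), 5.0)

    def residual(p):
        return fvcb_assimilation(ci, p["vcmax"].value, p["j"].value, p["rd"].value, gamma_star, km) - an

    best = None
    for vc_start, j_start in ((vc0, j0), (vc0 * 2.0, j0), (vc0, j0 * 2.0), (50.0, 100.0)):
        params = lmfit.Parameters()
        params.add("vcmax", value=vc_start, min=1e-3)
        params.add("j", value=j_start, min=1e-3)
        params.add("rd", value=rd0, min=0.0)
        out = lmfit.minimize(residual, params, method="least_squares")
        if best is None or out.chisqr < best.chisqr:
            best = out
    vcmax = float(best.params["vcmax"].value)
    j = float(best.params["j"].value)
    rd = float(best.params["rd"].value)

    wc = vcmax * (ci - gamma_star) / (ci + km)
    wj = j * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)
    limitation = np.where(wc <= wj, "Rubisco", "RuBP")
    flags: list[str] = []
    if np.all(limitation == "Rubisco"):
        flags.append("jmax_unidentified")
    if np.all(limitation == "RuBP"):
        flags.append("vcmax_unidentified")
    a_max = float(fvcb_assimilation(1500.0, vcmax, j, rd, gamma_star, km))
    return FvCBFit(
        v_cmax=vcmax, j_max=j, r_d=rd, gamma_star=gamma_star, km=km,
        a_max=a_max, limitation=limitation, flags=flags,
    )


# ---------------------------------------------------------------------------
# pairwise testing convention


@dataclass(frozen=True)
class AdjustedAlpha:
    raw: float
    reported: float  # rounded to 4 decimals for reporting


def adjusted_alpha(alpha: float, n_pairs: int) -> AdjustedAlpha:
    """Bonferroni-style threshold ``alpha / n_pairs``.

    The raw value is retained; the reported value is rounded to four
    decimals (0.05 over 6 pairs reports as 0.0083).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    raw = alpha / n_pairs
    return AdjustedAlpha(raw=raw, reported=round(raw, 4))


def pairwise_compare(
    df: pd.DataFrame, value: str, group: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch two-sample t-tests between all pairs of groups.

    Significance is judged against the adjusted threshold
    ``alpha / n_pairs``.  Groups with fewer than two observations are
    skipped with a warning.
    """
    groups = {k: v[value].to_numpy(dtype=float) for k, v in df.groupby(group)}
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    adj = adjusted_alpha(alpha, max(len(pairs), 1))
    rows = []
    for g1, g2 in pairs:
        x, y = groups[g1], groups[g2]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"singleton group in pair ({g1}, {g2}); skipped", stacklevel=2)
            continue
        t, p = sstats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                "group1": g1, "group2": g2,
                "mean1": float(np.mean(x)), "mean2": float(np.mean(y)),
                "t": float(t), "p": float(p),
                "alpha_adjusted": adj.raw,
                "significant": bool(p < adj.raw),
            }
        )
    return pd.DataFrame(rows)


def percent_change(
    df: pd.DataFrame,
    value: str,
    species: str,
    treatment: str,
    reference: str = "well-watered",
) -> pd.DataFrame:
    """Per-species percent change of group means relative to a reference treatment."""
    rows = []
    for sp, sub in df.groupby(species):
        ref_vals = sub.loc[sub[treatment] == reference, value]
        if ref_vals.empty:
            warnings.warn(f"species {sp!r} has no {reference!r} group; skipped", stacklevel=2)
            continue
        ref_mean = float(ref_vals.mean())
        for tr, tsub in sub.groupby(treatment):
            rows.append(
                {
                    species: sp,
                    treatment: tr,
                    "mean": float(tsub[value].mean()),
                    "pct_change": 100.0 * (float(tsub[value].mean()) - ref_mean) / ref_mean,
                }
            )
    return pd.DataFrame(rows)
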