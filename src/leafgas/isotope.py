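"""Mesophyll conductance from combined gas exchange and 13C discrimination.

The core idea: Rubisco strongly discriminates against 13CO2, so the
discrimination a leaf would express if the chloroplast saw the
substomatal CO2 concentration directly (the *predicted* discrimination,
``delta_i``) exceeds the *observed* discrimination (``delta_o``) whenever a
finite mesophyll conductance ``g_m`` draws chloroplast CO2 (``C_c``) below
``C_i``.  After removing the small respiratory (``delta_e``) and
photorespiratory (``delta_f``) components, the residual

    delta_gm = delta_i - delta_o - delta_e - delta_f

is proportional to the CO2 drawdown across the mesophyll and inverts to
``g_m``.  All discriminations are in per mil; conductances in
mol CO2 m-2 s-1; CO2 mole fractions in umol mol-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeConstants",
    "GasExchangeIsotopeRecord",
    "DiscriminationResult",
    "zeta",
    "observed_discrimination",
    "combined_fractionation",
    "ternary_t",
    "predicted_discrimination",
    "nonrubisco_discriminations",
    "estimate_gm",
    "chloroplast_co2",
    "estimate_gm_table",
    "bracket_reference_d13c",
    "read_records_csv",
]


@dataclass(frozen=True)
class IsotopeConstants:
    """Fractionation factors, stored as positive per-mil magnitudes.

    ``a`` diffusion through stomata (4.4), ``a_b`` boundary layer (2.9),
    ``a_i`` dissolution plus diffusion in water at 25 C (1.8), ``b``
    Rubisco carboxylation (29), ``f`` photorespiration (11.6).  The
    respiratory fractionation ``e`` is not a constant: it is computed per
    record as d13C_e - d13C_atm (source-air offset of previously fixed
    carbon).
    """

    a: float = 4.4
    a_b: float = 2.9
    a_i: float = 1.8
    b: float = 29.0
    f: float = 11.6

    def __post_init__(self) -> None:
        for name in ("a", "a_b", "a_i", "b", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"fractionation magnitude {name!r} must be positive")


DEFAULT_CONSTANTS = IsotopeConstants()


@dataclass(frozen=True)
class GasExchangeIsotopeRecord:
    """One cuvette observation with its paired air-sample isotope ratios.

    Units: ``an`` (net assimilation) and ``rd`` (day respiration)
    umol m-2 s-1; ``e_trans`` (transpiration) mol m-2 s-1; ``g_act``
    (combined boundary-layer + stomatal conductance to CO2) mol m-2 s-1;
    ``ca, cs, ci, ce`` and ``gamma_star`` umol mol-1; delta values per mil.
    ``ce`` is the reference (empty-cuvette) CO2, so ``ce > ca`` for an
    assimilating leaf.
    """

    an: float
    e_trans: float
    g_act: float
    ca: float
    cs: float
    ci: float
    ce: float
    rd: float
    gamma_star: float
    d13c_a: float
    d13c_e: float
    d13c_atm: float = -8.0

    def __post_init__(self) -> None:
        if not self.ce > self.ca:
            raise ValueError("ce must exceed ca (leaf draws down cuvette CO2)")
        if not (self.ca >= self.cs >= self.ci > 0):
            raise ValueError("require ca >= cs >= ci > 0")
        if self.an + self.rd <= 0:
            raise ValueError("an + rd must be positive")


@dataclass
class DiscriminationResult:
    """All intermediate and final quantities for one record."""

    zeta: float
    a_prime: float
    t: float
    delta_o: float
    delta_i: float
    delta_e: float
    delta_f: float
    delta_gm: float
    e_resp: float
    gm: float
    cc: float
    flags: list[str] = field(default_factory=list)


def zeta(ce: float, ca: float) -> float:
    """Reference-to-drawdown CO2 ratio, ``ce / (ce - ca)``."""
    if ce == ca:
        raise ValueError("ce equals ca: no net CO2 drawdown, zeta undefined")
    return ce / (ce - ca)


def observed_discrimination(d13c_a: float, d13c_e: float, zeta_val: float) -> float:
    """Observed 13C discrimination (per mil) from the paired air samples."""
    num = 1000.0 * zeta_val * (d13c_a - d13c_e)
    den = 1000.0 + d13c_a - zeta_val * (d13c_a - d13c_e)
    if den <= 0:
        raise ValueError("implausible isotope pair: nonpositive denominator in delta_o")
    return num / den


def combined_fractionation(
    ca: float, cs: float, ci: float, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> float:
    """Weighted boundary-layer + stomatal diffusional fractionation a' (per mil)."""
    if ca == ci:
        raise ValueError("ca equals ci: no diffusion gradient, a' undefined")
    return (constants.a_b * (ca - cs) + constants.a * (cs - ci)) / (ca - ci)


def ternary_t(a_prime: float, e_trans: float, g_act: float) -> float:
    """Ternary correction factor t (dimensionless).

    ``a_prime`` is per mil and enters as the fractional (1 + a'/1000);
    ``e_trans`` in mol m-2 s-1.
    """
    if g_act <= 0:
        raise ValueError("g_act must be positive")
    if e_trans < 0:
        raise ValueError("transpiration must be nonnegative")
    return (1.0 + a_prime / 1000.0) * e_trans / (2.0 * g_act)


def predicted_discrimination(
    t: float,
    a_prime: float,
    ci: float,
    ca: float,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> float:
    """Discrimination predicted from C_i alone (infinite g_m), per mil."""
    if t >= 1:
        raise ValueError("ternary factor t must be < 1")
    return (a_prime + ((1.0 + t) * constants.b - a_prime) * (ci / ca)) / (1.0 - t)


def nonrubisco_discriminations(
    t: float,
    record: GasExchangeIsotopeRecord,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """Respiratory and photorespiratory discriminations.

    Returns ``(delta_e, delta_f, e_resp)`` where ``e_resp = d13c_e -
    d13c_atm`` is the per-record respiratory fractionation.
    """
    if record.an + record.rd == 0:
        raise ValueError("an + rd is zero")
    e_resp = record.d13c_e - record.d13c_atm
    ternary = (1.0 + t) / (1.0 - t)
    delta_e = ternary * (
        e_resp * record.rd / ((record.an + record.rd) * record.ca)
    ) * (record.ci - record.gamma_star)
    delta_f = ternary * constants.f * record.gamma_star / record.ca
    return delta_e, delta_f, e_resp


def chloroplast_co2(ci: float, an: float, gm: float) -> float:
    """Chloroplast CO2, ``C_c = C_i - A_n / g_m`` (umol mol-1)."""
    if gm <= 0:
        raise ValueError("gm must be positive")
    return ci - an / gm


def estimate_gm(
    record: GasExchangeIsotopeRecord,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> DiscriminationResult:
    """Estimate mesophyll conductance and chloroplast CO2 for one record.

    If the residual drawdown ``delta_i - delta_o - delta_e - delta_f`` is
    not positive the record cannot resolve a finite positive conductance
    and the result is flagged ``gm_unresolvable`` (gm and cc are NaN)
    rather than reporting a negative conductance.
    """
    z = zeta(record.ce, record.ca)
    delta_o = observed_discrimination(record.d13c_a, record.d13c_e, z)
    a_prime = combined_fractionation(record.ca, record.cs, record.ci, constants)
    t = ternary_t(a_prime, record.e_trans, record.g_act)
    delta_i = predicted_discrimination(t, a_prime, record.ci, record.ca, constants)
    delta_e, delta_f, e_resp = nonrubisco_discriminations(t, record, constants)
    delta_gm = delta_i - delta_o - delta_e - delta_f

    flags: list[str] = []
    if delta_gm <= 0:
        flags.append("gm_unresolvable")
        gm = math.nan
        cc = math.nan
    else:
        ternary = (1.0 + t) / (1.0 - t)
        carbox = constants.b - constants.a_i - e_resp * record.rd / (record.an + record.rd)
        gm = ternary * carbox * (record.an / record.ca) / delta_gm
        cc = chloroplast_co2(record.ci, record.an, gm)
        if cc < 0:
            flags.append("cc_negative")
    return DiscriminationResult(
        zeta=z,
        a_prime=a_prime,
        t=t,
        delta_o=delta_o,
        delta_i=delta_i,
        delta_e=delta_e,
        delta_f=delta_f,
        delta_gm=delta_gm,
        e_resp=e_resp,
        gm=gm,
        cc=cc,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# batch helpers

CSV_COLUMNS = [
    "An", "E_mmol", "gact", "Ca", "Cs", "Ci", "Ce", "Rd", "GammaStar",
    "d13Ca", "d13Ce",
]


def read_records_csv(path) -> pd.DataFrame:
    """Read a gas-exchange/isotope record table.

    Expected columns: ``An,E_mmol,gact,Ca,Cs,Ci,Ce,Rd,GammaStar,d13Ca,
    d13Ce[,d13Catm]``.  Transpiration is carried in the CSV in
    mmol m-2 s-1 (the unit instruments report) and converted internally.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table is missing columns {missing}")
    return df


def _record_from_row(row: pd.Series) -> GasExchangeIsotopeRecord:
    return GasExchangeIsotopeRecord(
        an=row["An"],
        e_trans=row["E_mmol"] * 1e-3,
        g_act=row["gact"],
        ca=row["Ca"],
        cs=row["Cs"],
        ci=row["Ci"],
        ce=row["Ce"],
        rd=row["Rd"],
        gamma_star=row["GammaStar"],
        d13c_a=row["d13Ca"],
        d13c_e=row["d13Ce"],
        d13c_atm=row.get("d13Catm", -8.0),
    )


def estimate_gm_table(
    df: pd.DataFrame, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Apply :func:`estimate_gm` row-wise; returns input plus result columns."""
    out = df.copy()
    cols = {k: [] for k in (
        "zeta", "a_prime", "t", "delta_o", "delta_i", "delta_e", "delta_f",
        "delta_gm", "gm", "Cc", "flags",
    )}
    for _, row in df.iterrows():
        res = estimate_gm(_record_from_row(row), constants)
        cols["zeta"].append(res.zeta)
        cols["a_prime"].append(res.a_prime)
        cols["t"].append(res.t)
        cols["delta_o"].append(res.delta_o)
        cols["delta_i"].append(res.delta_i)
        cols["delta_e"].append(res.delta_e)
        cols["delta_f"].append(res.delta_f)
        cols["delta_gm"].append(res.delta_gm)
        cols["gm"].append(res.gm)
        cols["Cc"].append(res.cc)
        cols["flags"].append(";".join(res.flags))
    for k, v in cols.items():
        out[k] = v
    return out


def bracket_reference_d13c(kinds, d13c) -> pd.Series:
    """Pair each plant air sample with the mean of its bracketing references.

    The sampling protocol alternates reference (empty cuvette, kind
    ``"R"``) and plant (kind ``"P"``) vials; each plant sample's effective
    reference d13C is the mean of the nearest reference before and after
    it, falling back to the single available neighbour at sequence ends.
    Returns a series indexed like the input with values only at plant
    samples.
    """
    kinds = pd.Series(kinds).reset_index(drop=True)
    vals = pd.Series(d13c).reset_index(drop=True).astype(float)
    ref_idx = kinds[kinds == "R"].index.to_numpy()
    if ref_idx.size == 0:
        raise ValueError("no reference samples in sequence")
    out = pd.Series(np.nan, index=kinds.index)
    for i in kinds[kinds == "P"].index:
        before = ref_idx[ref_idx < i]
        after = ref_idx[ref_idx > i]
        neighbours = []
        if before.size:
            neighbours.append(vals[before[-1]])
        if after.size:
            neighbours.append(vals[after[0]])
        out[i] = float(np.mean(neighbours))
    return out
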