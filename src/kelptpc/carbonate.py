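"""Seawater CO2-system solver for treatment verification.

Given total alkalinity (AT), pH on the total scale, temperature and
salinity, the full inorganic carbon speciation is solved in closed form:
the borate, water and proton terms are removed from AT to leave carbonate
alkalinity, from which HCO3-, CO3--, dissolved CO2* and hence DIC and
pCO2 follow.  Dissociation constants: K1/K2 from the Mehrbach measurements
as refit by Lueker et al. (2000, total scale), KB from Dickson (1990), KW
from Millero (1995), CO2 solubility K0 from Weiss (1974), and total borate
proportional to salinity (Uppstrom 1974).  The alkalinity model excludes
phosphate, silicate and ammonia terms; pressure is surface; pCO2 is
reported without fugacity correction, in uatm.

A bracketed inverse solve (pH from AT + DIC) is provided for round-trip
verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InfeasibleInputError


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants at a given temperature and salinity.

    k0: CO2 solubility, mol kg^-1 atm^-1 (Weiss 1974)
    k1, k2: carbonic acid dissociation, total scale (Lueker et al. 2000)
    kb: boric acid (Dickson 1990), kw: water (Millero 1995)
    bt: total borate, mol kg^-1 (Uppstrom 1974; linear in salinity)
    """

    k0: float
    k1: float
    k2: float
    kb: float
    kw: float
    bt: float
    temp_c: float
    salinity: float
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class CarbonateState:
    """Full speciation solved from AT + pH (+T, S); concentrations umol kg^-1."""

    at: float
    ph_total: float
    temp_c: float
    salinity: float
    dic: float
    pco2: float
    co2_star: float
    hco3: float
    co3: float
    boh4: float
    oh: float
    h: float
    warnings: tuple[str, ...] = ()


def constants(temp_c: float, salinity: float) -> ConstantSet:
    """Equilibrium constants; warns (in the result) outside the fit range
    of the Lueker constants (T 0-35 C, S 19-43) but still computes."""
    warns = []
    if not 0.0 <= temp_c <= 35.0:
        warns.append(f"temperature {temp_c} C outside Lueker fit range [0, 35]")
    if not 19.0 <= salinity <= 43.0:
        warns.append(f"salinity {salinity} outside Lueker fit range [19, 43]")
    tk = temp_c + 273.15
    s = salinity
    pk1 = 3633.86 / tk - 61.2172 + 9.6777 * math.log(tk) - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / tk + 25.929 - 3.16967 * math.log(tk) - 0.01781 * s + 0.0001122 * s * s
    lnkb = (
        (-8966.90 - 2890.53 * s**0.5 - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s * s) / tk
        + 148.0248 + 137.1942 * s**0.5 + 1.62142 * s
        + (-24.4344 - 25.085 * s**0.5 - 0.2474 * s) * math.log(tk)
        + 0.053105 * s**0.5 * tk
    )
    lnkw = (
        148.9652 - 13847.26 / tk - 23.6521 * math.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * math.log(tk)) * s**0.5 - 0.01615 * s
    )
    lnk0 = (
        -60.2409 + 93.4517 * (100.0 / tk) + 23.3585 * math.log(tk / 100.0)
        + s * (0.023517 - 0.023656 * (tk / 100.0) + 0.0047036 * (tk / 100.0) ** 2)
    )
    return ConstantSet(
        k0=math.exp(lnk0), k1=10.0**-pk1, k2=10.0**-pk2,
        kb=math.exp(lnkb), kw=math.exp(lnkw), bt=0.0004157 * s / 35.0,
        temp_c=temp_c, salinity=salinity, warnings=tuple(warns),
    )


def solve_from_ph_alk(
    at_umol_kg: float, ph_total: float, temp_c: float, salinity: float
) -> CarbonateState:
    """Closed-form speciation from AT and total-scale pH.

    Carbonate alkalinity CA = AT - borate - OH + H; then
    HCO3 = CA / (1 + 2 K2/H), CO3 = K2 HCO3 / H, CO2* = H HCO3 / K1,
    DIC = CO2* + HCO3 + CO3 and pCO2 = CO2*/K0.
    """
    if at_umol_kg <= 0:
        raise InfeasibleInputError(f"AT must be > 0, got {at_umol_kg}")
    if not 6.0 <= ph_total <= 9.0:
        raise InfeasibleInputError(f"pH {ph_total} outside supported range [6, 9]")
    k = constants(temp_c, salinity)
    h = 10.0 ** (-ph_total)              # mol/kg
    at = at_umol_kg * 1e-6
    boh4 = k.bt * k.kb / (k.kb + h)
    oh = k.kw / h
    ca = at - boh4 - oh + h
    if ca <= 0:
        raise InfeasibleInputError(
            "carbonate alkalinity non-positive for these inputs"
        )
    hco3 = ca / (1.0 + 2.0 * k.k2 / h)
    co3 = k.k2 * hco3 / h
    co2_star = h * hco3 / k.k1
    dic = co2_star + hco3 + co3
    pco2 = co2_star / k.k0 * 1e6         # uatm
    return CarbonateState(
        at=at_umol_kg, ph_total=ph_total, temp_c=temp_c, salinity=salinity,
        dic=dic * 1e6, pco2=pco2,
        co2_star=co2_star * 1e6, hco3=hco3 * 1e6, co3=co3 * 1e6,
        boh4=boh4 * 1e6, oh=oh * 1e6, h=h * 1e6,
        warnings=k.warnings,
    )


def ph_from_dic_alk(
    at_umol_kg: float, dic_umol_kg: float, temp_c: float, salinity: float,
    bracket: tuple[float, float] = (6.0, 9.0),
) -> float:
    """Total-scale pH from AT and DIC by bracketed root finding.

    Roots the residual DIC(AT, pH) - DIC in pH with Brent's method to
    1e-8; raises if the bracket does not contain a sign change.
    """
    def residual(ph: float) -> float:
        return solve_from_ph_alk(at_umol_kg, ph, temp_c, salinity).dic - dic_umol_kg

    lo, hi = bracket
    try:
        flo, fhi = residual(lo), residual(hi)
    except InfeasibleInputError as exc:
        raise InfeasibleInputError(f"bracket endpoint infeasible: {exc}") from exc
    if flo * fhi > 0:
        raise InfeasibleInputError(
            f"no pH in [{lo}, {hi}] matches AT={at_umol_kg}, DIC={dic_umol_kg}"
        )
    return float(brentq(residual, lo, hi, xtol=1e-8))


def check_state(state: CarbonateState, rtol: float = 1e-6) -> None:
    """Assert the internal consistency identities of a solved state."""
    dic_sum = state.co2_star + state.hco3 + state.co3
    if abs(dic_sum - state.dic) > rtol * state.dic:
        raise AssertionError("speciation does not sum to DIC")
    alk = state.hco3 + 2 * state.co3 + state.boh4 + state.oh - state.h
    if abs(alk - state.at) > rtol * state.at:
        raise AssertionError("alkalinity reconstruction identity violated")


def solve_table(obs: pd.DataFrame) -> pd.DataFrame:
    """Solve each row of a carbonate-observation table.

    Input columns: at_umol_kg, ph_total, temp_c, salinity; appends
    dic_umol_kg, pco2_uatm and the speciation columns.
    """
    need = {"at_umol_kg", "ph_total", "temp_c", "salinity"}
    if not need.issubset(obs.columns):
        raise ValueError(f"carbonate table needs columns {sorted(need)}")
    rows = []
    for _, r in obs.iterrows():
        st = solve_from_ph_alk(
            float(r["at_umol_kg"]), float(r["ph_total"]),
            float(r["temp_c"]), float(r["salinity"]),
        )
        rows.append({
            **{c: r[c] for c in obs.columns},
            "dic_umol_kg": st.dic, "pco2_uatm": st.pco2,
            "co2_star_umol_kg": st.co2_star, "hco3_umol_kg": st.hco3,
            "co3_umol_kg": st.co3, "boh4_umol_kg": st.boh4,
            "oh_umol_kg": st.oh, "h_umol_kg": st.h,
        })
    return pd.DataFrame(rows)
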