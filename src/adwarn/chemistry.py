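"""Acid-base speciation and alkalinity arithmetic for anaerobic digesters.

Two worlds meet here.  On the laboratory side, alkalinity is measured by
three-point titration with HCl (pH end points 5.75, 4.3 and 3.8): partial
alkalinity (PA) is the acid consumed down to pH 5.75, total alkalinity (TA)
down to pH 4.3, intermediate alkalinity IA = TA - PA, and bicarbonate
alkalinity is estimated as BA = 1.25 * PA (Anderson & Yang three-point
method).  On the simulation side, a model cannot titrate, so BA is computed
from the carbonate speciation ([HCO3-] + 2[CO3--]) and IA is represented by
the molar sum of acetic, propionic and butyric acids in acetic-acid
equivalents.

All alkalinities are expressed in mg CaCO3/L; 50.05 mg CaCO3 corresponds to
1 mEq (half the 100.09 g/mol formula weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "MW_ACETIC",
    "MW_PROPIONIC",
    "MW_BUTYRIC",
    "CACO3_MEQ",
    "TitrationRecord",
    "AlkalinityProfile",
    "titration_alkalinity",
    "profile_from_titration",
    "solve_ph",
    "Speciation",
    "simulated_BA",
    "simulated_IA",
]

MW_ACETIC = 60.05  # g/mol
MW_PROPIONIC = 74.08
MW_BUTYRIC = 88.11
CACO3_MEQ = 50.05  # mg CaCO3 per mEq
N_MOLAR_MASS = 14.007  # g N / mol

R_GAS = 8.314  # J/(mol K)
T_REF = 298.15  # K, reference for the pKa table
LN10 = math.log(10.0)

# pKa at 25 degC and van 't Hoff reaction enthalpies (J/mol) used for the
# temperature correction pK(T) = pK(25) + dH/(R ln10) * (1/T - 1/298.15).
_PKA_25 = {
    "acetic": (4.76, 400.0),
    "propionic": (4.87, -700.0),
    "butyric": (4.82, -300.0),
    "carbonate_1": (6.35, 7640.0),
    "carbonate_2": (10.33, 14900.0),
    "ammonium": (9.25, 51900.0),
    "water": (14.00, 55840.0),
}


def pka(name: str, temp_c: float = 35.0) -> float:
    """Temperature-corrected pKa via van 't Hoff (default 35 degC)."""
    pk25, dh = _PKA_25[name]
    t = temp_c + 273.15
    return pk25 + dh / (R_GAS * LN10) * (1.0 / t - 1.0 / T_REF)


@dataclass(frozen=True)
class TitrationRecord:
    """Cumulative HCl consumption of one three-point titration."""

    hcl_conc: float  # mol/L
    vol_to_ph575: float  # mL, cumulative at pH 5.75
    vol_to_ph43: float  # mL, cumulative at pH 4.3
    vol_to_ph38: float  # mL, cumulative at pH 3.8
    sample_vol: float  # mL

    def __post_init__(self) -> None:
        if self.sample_vol <= 0:
            raise ValueError("sample_vol must be positive")
        if self.hcl_conc < 0:
            raise ValueError("hcl_conc must be >= 0")
        vols = (self.vol_to_ph575, self.vol_to_ph43, self.vol_to_ph38)
        if any(v < 0 for v in vols):
            raise ValueError("titrant volumes must be >= 0")
        if not (self.vol_to_ph575 <= self.vol_to_ph43 <= self.vol_to_ph38):
            raise ValueError(
                "cumulative titrant volumes must be nondecreasing in the "
                "order pH 5.75 -> 4.3 -> 3.8"
            )


@dataclass(frozen=True)
class AlkalinityProfile:
    """TA/PA/IA/BA in mg CaCO3/L, as derived from one titration."""

    ta: float
    pa: float
    ia: float
    ba: float


def titration_alkalinity(hcl_conc: float, hcl_vol: float, sample_vol: float) -> float:
    """Alkalinity (mg CaCO3/L) from HCl consumption.

    alkalinity = hcl_conc [mol/L] * hcl_vol [mL] * 50.05 / sample_vol [mL]
                 * 1000
    """
    if sample_vol <= 0:
        raise ValueError("sample_vol must be positive")
    if hcl_vol < 0:
        raise ValueError("hcl_vol must be >= 0")
    return hcl_conc * hcl_vol * CACO3_MEQ / sample_vol * 1000.0


def profile_from_titration(rec: TitrationRecord, use_ph38_correction: bool = False) -> AlkalinityProfile:
    """Three-point alkalinity profile from a titration record.

    PA is titrated to pH 5.75 and TA to pH 4.3; IA = TA - PA and
    BA = 1.25 * PA.  The pH 3.8 reading is retained in the record for the
    method's optional correction term but by default does not enter TA
    (``use_ph38_correction=False``).
    """
    pa = titration_alkalinity(rec.hcl_conc, rec.vol_to_ph575, rec.sample_vol)
    vol_ta = rec.vol_to_ph38 if use_ph38_correction else rec.vol_to_ph43
    ta = titration_alkalinity(rec.hcl_conc, vol_ta, rec.sample_vol)
    return AlkalinityProfile(ta=ta, pa=pa, ia=ta - pa, ba=1.25 * pa)


@dataclass(frozen=True)
class Speciation:
    """Charge-balance pH solution with the ion concentrations (mol/L)."""

    ph: float
    co2_aq: float
    hco3: float
    co3: float
    nh4: float
    nh3: float
    acetate_ion: float
    propionate_ion: float
    butyrate_ion: float


def _charge_residual(
    h: float,
    tic: float,
    tan_mol: float,
    ac_mol: float,
    pro_mol: float,
    bu_mol: float,
    z: float,
    ka: dict,
) -> float:
    # cations + H+ - anions; all in eq/L
    oh = ka["kw"] / h
    denom_c = h * h + ka["k1"] * h + ka["k1"] * ka["k2"]
    hco3 = tic * ka["k1"] * h / denom_c
    co3 = tic * ka["k1"] * ka["k2"] / denom_c
    nh4 = tan_mol * h / (h + ka["kn"])
    a_ac = ac_mol * ka["ka_ac"] / (ka["ka_ac"] + h)
    a_pro = pro_mol * ka["ka_pro"] / (ka["ka_pro"] + h)
    a_bu = bu_mol * ka["ka_bu"] / (ka["ka_bu"] + h)
    return z + nh4 + h - hco3 - 2.0 * co3 - a_ac - a_pro - a_bu - oh


def _ka_set(temp_c: float) -> dict:
    return {
        "k1": 10.0 ** -pka("carbonate_1", temp_c),
        "k2": 10.0 ** -pka("carbonate_2", temp_c),
        "kn": 10.0 ** -pka("ammonium", temp_c),
        "kw": 10.0 ** -pka("water", temp_c),
        "ka_ac": 10.0 ** -pka("acetic", temp_c),
        "ka_pro": 10.0 ** -pka("propionic", temp_c),
        "ka_bu": 10.0 ** -pka("butyric", temp_c),
    }


def solve_ph(
    tic: float,
    tan: float,
    s_ac: float,
    s_pro: float,
    s_bu: float,
    z: float,
    temp_c: float = 35.0,
) -> Speciation:
    """Solve the charge balance for pH and return the full speciation.

    Parameters
    ----------
    tic : total inorganic carbon, mol/L
    tan : total ammonia nitrogen, g N/L
    s_ac, s_pro, s_bu : total (dissociated + undissociated) acid, g/L
    z : net strong-ion charge (strong cations minus strong anions), eq/L
    temp_c : temperature in Celsius (pKa values are corrected to it)

    The root is bracketed on pH in [1, 13] and polished until the charge
    residual is below 1e-10 eq/L.
    """
    if min(tic, tan, s_ac, s_pro, s_bu) < 0:
        raise ValueError("totals must be >= 0")
    ka = _ka_set(temp_c)
    tan_mol = tan / N_MOLAR_MASS
    ac_mol = s_ac / MW_ACETIC
    pro_mol = s_pro / MW_PROPIONIC
    bu_mol = s_bu / MW_BUTYRIC
    args = (tic, tan_mol, ac_mol, pro_mol, bu_mol, z, ka)

    def f(ph: float) -> float:
        return _charge_residual(10.0 ** -ph, *args)

    lo, hi = 1.0, 13.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ArithmeticError(
            f"charge balance has no root in pH [1, 13] "
            f"(residuals {flo:.3e}, {fhi:.3e}); state: TIC={tic:.4g}, "
            f"TAN={tan:.4g}, VFA=({s_ac:.4g},{s_pro:.4g},{s_bu:.4g}), Z={z:.4g}"
        )
    ph = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    if abs(f(ph)) > 1e-10:
        raise ArithmeticError(f"pH residual {f(ph):.3e} eq/L exceeds 1e-10")

    h = 10.0 ** -ph
    denom_c = h * h + ka["k1"] * h + ka["k1"] * ka["k2"]
    return Speciation(
        ph=ph,
        co2_aq=tic * h * h / denom_c,
        hco3=tic * ka["k1"] * h / denom_c,
        co3=tic * ka["k1"] * ka["k2"] / denom_c,
        nh4=tan_mol * h / (h + ka["kn"]),
        nh3=tan_mol * ka["kn"] / (h + ka["kn"]),
        acetate_ion=ac_mol * ka["ka_ac"] / (ka["ka_ac"] + h),
        propionate_ion=pro_mol * ka["ka_pro"] / (ka["ka_pro"] + h),
        butyrate_ion=bu_mol * ka["ka_bu"] / (ka["ka_bu"] + h),
    )


def simulated_BA(spec: Speciation) -> float:
    """Bicarbonate-alkalinity proxy from model speciation, mg CaCO3/L.

    BA_sim = ([HCO3-] + 2 [CO3--]) in mEq/L times 50.05.
    """
    meq_per_l = (spec.hco3 + 2.0 * spec.co3) * 1000.0
    return meq_per_l * CACO3_MEQ


def simulated_IA(s_ac: float, s_pro: float, s_bu: float) -> tuple[float, float]:
    """Intermediate-alkalinity proxy from VFA totals.

    Returns ``(acetic_equivalent_g_per_L, mg_CaCO3_per_L)`` where the molar
    sum S_ac/60.05 + S_pro/74.08 + S_bu/88.11 is expressed once in acetic
    acid equivalents (g/L) and once in CaCO3 units (mEq/L * 50.05, taking
    each acid as monoprotic).
    """
    if min(s_ac, s_pro, s_bu) < 0:
        raise ValueError("VFA concentrations must be >= 0")
    molar = s_ac / MW_ACETIC + s_pro / MW_PROPIONIC + s_bu / MW_BUTYRIC
    return molar * MW_ACETIC, molar * 1000.0 * CACO3_MEQ
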