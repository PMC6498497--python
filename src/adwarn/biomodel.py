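"""Kinetic CSTR model of corn-stalk anaerobic digestion.

The model follows the structure of the classical staged bioconversion
models of anaerobic digestion: first-order hydrolysis of degradable
particulate organics, five Monod microbial groups (glucose-level
acidogens, propionate and butyrate degraders, acetoclastic and
hydrogenotrophic methanogens), two-sided pH inhibition, charge-balance pH,
and gas-liquid transfer to a well-mixed headspace.  Two departures from
the older model family are built in deliberately:

* ammonia never appears as a Monod growth substrate - it acts only through
  the charge balance and as a free-ammonia inhibitor of acetoclastic
  methanogens (corn stalk is a negligible ammonia source);
* acetoclastic methanogens are inhibited noncompetitively by the *total*
  VFA pool (acetate + propionate + butyrate, mg/L) rather than by acetate
  alone, with an inhibition constant Ki of a few hundred mg/L.

Stoichiometry is kept consistent in COD units: every uptake splits into a
biomass yield and catabolic product fractions that sum to one, so chemical
oxygen demand is conserved exactly by construction and carbon imbalances
of each reaction are routed to the inorganic-carbon pool (CO2).  The
elemental composition of the degradable organic matter is derived from the
substrate characterization (C, H, N mass fractions of TS), which is what
makes the simulated CH4/CO2 ratio a property of the feedstock rather than
a tuning knob.

Units: concentrations g/L, inorganic carbon mol/L, ammonia g N/L, gas
amounts mol, time days.  Gas volumes are reported at 1 atm and the
operating temperature (35 degC by default) unless configured otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import chemistry
from .chemistry import MW_ACETIC, MW_BUTYRIC, MW_PROPIONIC
from .schedules import OperationPhase, OperationSchedule

__all__ = [
    "SubstrateSpec",
    "GroupKinetics",
    "KineticParams",
    "ReactorState",
    "SimulationResult",
    "CORN_STALK",
    "INOCULUM",
    "monod",
    "inhibition_noncompetitive",
    "ph_inhibition",
    "characterize_substrate",
    "default_initial_state",
    "ode_rhs",
    "simulate",
    "derive_outputs",
    "total_cod",
]

log = logging.getLogger(__name__)

R_L_ATM = 0.082057  # L atm / (mol K)

MW_CH4 = 16.043
MW_H2 = 2.016
MW_N = 14.007

COD_CH4 = 64.0 / MW_CH4  # g COD / g
COD_H2 = 16.0 / MW_H2
COD_AC = 64.0 / MW_ACETIC
COD_PRO = 112.0 / MW_PROPIONIC
COD_BU = 160.0 / MW_BUTYRIC
# biomass as C5H7NO2
MW_BIO = 113.115
COD_BIO = 160.0 / MW_BIO
C_BIO = 60.055 / MW_BIO  # g C / g biomass
N_BIO = MW_N / MW_BIO  # g N / g biomass

C_AC = 24.022 / MW_ACETIC
C_PRO = 36.033 / MW_PROPIONIC
C_BU = 48.044 / MW_BUTYRIC
C_CH4 = 12.011 / MW_CH4

GROUPS = (
    "acidogens",
    "propionate_degraders",
    "butyrate_degraders",
    "acetoclastic_methanogens",
    "hydrogenotrophic_methanogens",
)


# ---------------------------------------------------------------------------
# substrate characterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstrateSpec:
    """Proximate/elemental characterization of a feedstock (fractions)."""

    ts_frac_of_fresh: float
    vs_frac_of_ts: float
    crude_fiber_frac_of_ts: float
    crude_protein_frac_of_ts: float
    c_frac_of_ts: float
    n_frac_of_ts: float
    h_frac_of_ts: float
    s_frac_of_ts: float
    degradable_frac_of_vs: float  # calibration parameter

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.n_frac_of_ts > 0 and self.c_frac_of_ts <= 0:
            raise ValueError("carbon fraction must be positive when N is present")

    @property
    def c_over_n(self) -> float:
        if self.n_frac_of_ts <= 0:
            raise ZeroDivisionError("substrate has no nitrogen")
        return self.c_frac_of_ts / self.n_frac_of_ts

    # --- composition of the volatile (organic) matter, per g VS ----------
    @property
    def w_c(self) -> float:
        return self.c_frac_of_ts / self.vs_frac_of_ts

    @property
    def w_h(self) -> float:
        return self.h_frac_of_ts / self.vs_frac_of_ts

    @property
    def w_n(self) -> float:
        return self.n_frac_of_ts / self.vs_frac_of_ts

    @property
    def w_o(self) -> float:
        """Oxygen by difference within the organic matter."""
        w_s = self.s_frac_of_ts / self.vs_frac_of_ts
        return max(1.0 - self.w_c - self.w_h - self.w_n - w_s, 0.0)

    @property
    def cod_per_g_vs(self) -> float:
        """Theoretical oxygen demand of 1 g VS (organic N ends as NH3)."""
        return 2.6667 * self.w_c + 8.0 * self.w_h - self.w_o - 1.7143 * self.w_n

    @property
    def organic_frac_of_vs(self) -> float:
        """CHO mass per g VS once organic N is split off to ammonia."""
        return 1.0 - self.w_n

    @property
    def cod_per_g_organic(self) -> float:
        return self.cod_per_g_vs / self.organic_frac_of_vs

    @property
    def c_per_g_organic(self) -> float:
        return self.w_c / self.organic_frac_of_vs


# Table-derived defaults for the corn-stalk study; degradable_frac_of_vs is
# the calibrated effective anaerobic degradability of the lignocellulosic VS.
CORN_STALK = SubstrateSpec(
    ts_frac_of_fresh=0.9014,
    vs_frac_of_ts=0.8481,
    crude_fiber_frac_of_ts=0.3725,
    crude_protein_frac_of_ts=0.0049,
    c_frac_of_ts=0.3964,
    n_frac_of_ts=0.0070,
    h_frac_of_ts=0.0638,
    s_frac_of_ts=0.0016,
    degradable_frac_of_vs=0.51,
)

INOCULUM = SubstrateSpec(
    ts_frac_of_fresh=0.0410,
    vs_frac_of_ts=0.0220,
    crude_fiber_frac_of_ts=0.0,
    crude_protein_frac_of_ts=0.0,
    c_frac_of_ts=0.40,
    n_frac_of_ts=0.03,
    h_frac_of_ts=0.05,
    s_frac_of_ts=0.005,
    degradable_frac_of_vs=0.2,
)


@dataclass(frozen=True)
class InfluentComposition:
    """Feed pools in g/L of influent liquid."""

    vs_g_per_l: float
    x_carb_deg: float  # degradable CHO particulate, g/L
    x_inert: float  # nondegradable VS, g/L
    tan_g_n_per_l: float  # nitrogen of the degradable fraction, mineralized


def characterize_substrate(spec: SubstrateSpec, feed_ts_percent: float) -> InfluentComposition:
    """Influent pool concentrations for a feed prepared at the given TS%.

    A feed of x % TS (fresh mass, density ~1 kg/L) carries 10*x g TS/L and
    10 * x * vs_frac_of_ts g VS/L.  The degradable share of the VS becomes
    hydrolysable particulate (its nitrogen mineralizing to TAN); the rest
    is inert particulate.
    """
    if not 0.0 < feed_ts_percent <= 20.0:
        raise ValueError("feed_ts_percent must be in (0, 20]")
    vs = 10.0 * feed_ts_percent * spec.vs_frac_of_ts
    deg_vs = spec.degradable_frac_of_vs * vs
    return InfluentComposition(
        vs_g_per_l=vs,
        x_carb_deg=deg_vs * spec.organic_frac_of_vs,
        x_inert=vs - deg_vs,
        tan_g_n_per_l=deg_vs * spec.w_n,
    )


def influent_from_olr(spec: SubstrateSpec, olr: float, hrt_days: float) -> InfluentComposition:
    """Influent pools when feeding by a stated OLR (g VS/(L day)) at an HRT."""
    vs = olr * hrt_days
    deg_vs = spec.degradable_frac_of_vs * vs
    return InfluentComposition(
        vs_g_per_l=vs,
        x_carb_deg=deg_vs * spec.organic_frac_of_vs,
        x_inert=vs - deg_vs,
        tan_g_n_per_l=deg_vs * spec.w_n,
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def monod(mu_max: float, s: float, ks: float) -> float:
    """Specific growth rate mu_max * S / (Ks + S), 1/day."""
    if mu_max <= 0 or ks <= 0:
        raise ValueError("mu_max and Ks must be positive")
    if s < 0:
        raise ValueError("substrate concentration must be >= 0")
    return mu_max * s / (ks + s)


def inhibition_noncompetitive(i: float, ki: float) -> float:
    """Noncompetitive inhibition factor 1 / (1 + I/Ki), in (0, 1]."""
    if ki <= 0:
        raise ValueError("Ki must be positive")
    if i < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    return 1.0 / (1.0 + i / ki)


def ph_inhibition(ph: float, pk_low: float, pk_high: float) -> float:
    """Two-sided pH inhibition factor.

    F(pH) = (1 + 2*10^(0.5(pKl-pKh))) / (1 + 10^(pH-pKh) + 10^(pKl-pH)),
    the customary bell-shaped form of this model family: ~1 around the
    midpoint of (pK_low, pK_high), symmetric about it, -> 0 outside.
    """
    if pk_low >= pk_high:
        raise ValueError("pK_low must be below pK_high")
    num = 1.0 + 2.0 * 10.0 ** (0.5 * (pk_low - pk_high))
    return num / (1.0 + 10.0 ** (ph - pk_high) + 10.0 ** (pk_low - ph))


@dataclass(frozen=True)
class GroupKinetics:
    mu_max: float  # 1/day
    ks: float  # g/L of the consumed substrate
    yield_cod: float  # g COD biomass / g COD substrate
    decay: float  # 1/day
    pk_low: float
    pk_high: float

    def __post_init__(self) -> None:
        if min(self.mu_max, self.ks, self.yield_cod, self.decay) <= 0:
            raise ValueError("rate/affinity/yield constants must be positive")
        if not self.yield_cod < 1.0:
            raise ValueError("yield_cod must be < 1")
        if self.pk_low >= self.pk_high:
            raise ValueError("pK_low must be below pK_high")


@dataclass(frozen=True)
class KineticParams:
    """All constants of the bioconversion model (see data/default_params.txt)."""

    groups: dict[str, GroupKinetics]
    k_hyd: float = 0.20  # 1/day, first-order hydrolysis
    ki_vfa: float = 315.0  # mg total VFA / L, acts on acetoclastic methanogens
    ki_nh3: float = 250.0  # mg free NH3-N / L, acts on acetoclastic methanogens
    vfa_inhibitor_free_acid_only: bool = False
    # catabolic COD fractions (sum to 1 within each reaction)
    f_mono_ac: float = 0.50
    f_mono_pro: float = 0.15
    f_mono_bu: float = 0.25
    f_mono_h2: float = 0.10
    f_pro_ac: float = 0.57
    f_pro_h2: float = 0.43
    f_bu_ac: float = 0.80
    f_bu_h2: float = 0.20
    # gas-liquid transfer and equilibria at operating temperature
    kla: float = 200.0  # 1/day
    kh_co2: float = 0.0246  # mol/(L atm) at 35 degC
    kh_h2: float = 7.2e-4
    temp_c: float = 35.0
    # reactor geometry and feed medium
    v_liq: float = 17.0  # L
    v_gas: float = 3.0  # L
    feed_z: float = 0.036  # eq/L net strong cations in the feed medium
    feed_tic: float = 0.0  # mol/L
    reinoculation_biomass: float = 0.05  # g/L added to each group at recovery start
    gas_reference: str = "operating"  # "operating" (1 atm, temp_c) or "stp"

    def __post_init__(self) -> None:
        missing = set(GROUPS) - set(self.groups)
        if missing:
            raise ValueError(f"missing kinetic groups: {sorted(missing)}")
        if self.ki_vfa <= 0 or self.ki_nh3 <= 0:
            raise ValueError("inhibition constants must be positive")
        fsum = self.f_mono_ac + self.f_mono_pro + self.f_mono_bu + self.f_mono_h2
        if abs(fsum - 1.0) > 1e-9:
            raise ValueError("monomer catabolic fractions must sum to 1")
        if abs(self.f_pro_ac + self.f_pro_h2 - 1.0) > 1e-9:
            raise ValueError("propionate catabolic fractions must sum to 1")
        if abs(self.f_bu_ac + self.f_bu_h2 - 1.0) > 1e-9:
            raise ValueError("butyrate catabolic fractions must sum to 1")

    @classmethod
    def default(cls, ki_vfa: float = 315.0, **overrides) -> "KineticParams":
        from .io import load_kinetic_params, default_params_path

        params = load_kinetic_params(default_params_path())
        return replace(params, ki_vfa=ki_vfa, **overrides)

    @property
    def gas_molar_volume(self) -> float:
        """L/mol at the declared gas reference condition."""
        if self.gas_reference == "stp":
            return R_L_ATM * 273.15
        return R_L_ATM * (self.temp_c + 273.15)


# ---------------------------------------------------------------------------
# state vector
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "x_carb",
    "x_inert",
    "x_acidogens",
    "x_propionate_degraders",
    "x_butyrate_degraders",
    "x_acetoclastic_methanogens",
    "x_hydrogenotrophic_methanogens",
    "s_mono",
    "s_ac",
    "s_pro",
    "s_bu",
    "s_h2",
    "tic",
    "tan",
    "z",
    "n_ch4",
    "n_co2",
    "n_h2",
    "cum_ch4",
    "cum_co2",
    "cum_h2",
)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATE = len(STATE_NAMES)


@dataclass
class ReactorState:
    """Reactor contents at one instant (concentrations g/L unless noted).

    ``n_*`` are headspace gas amounts in mol, ``cum_*`` cumulative gas
    exported in mol; ``tic`` mol C/L, ``tan`` g N/L, ``z`` eq/L.
    """

    x_carb: float = 0.5
    x_inert: float = 10.0
    x_acidogens: float = 1.0
    x_propionate_degraders: float = 0.07
    x_butyrate_degraders: float = 0.13
    x_acetoclastic_methanogens: float = 0.5
    x_hydrogenotrophic_methanogens: float = 0.09
    s_mono: float = 0.05
    s_ac: float = 0.1
    s_pro: float = 0.02
    s_bu: float = 0.02
    s_h2: float = 1e-7
    tic: float = 0.13
    tan: float = 0.30
    z: float = 0.12
    n_ch4: float = 0.07
    n_co2: float = 0.05
    n_h2: float = 0.0
    cum_ch4: float = 0.0
    cum_co2: float = 0.0
    cum_h2: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ReactorState":
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def validate(self) -> None:
        for n in STATE_NAMES:
            if getattr(self, n) < 0:
                raise ValueError(f"state field {n} is negative")


def default_initial_state(reactor: str = "R1") -> ReactorState:
    """Inoculum-derived starting state for the packaged reactor setups.

    The seed sludge comes from a full-scale digester: active biomass of all
    five groups, high residual alkalinity (~6000 mg CaCO3/L as net strong
    cations) and little residual degradable substrate.
    """
    state = ReactorState()
    if reactor.upper() == "R2":
        state.z = 0.12
    return state


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


class _FeedTerms:
    """Per-phase dilution and influent concentrations."""

    def __init__(self, phase: OperationPhase, substrate: SubstrateSpec, params: KineticParams):
        self.recovery = phase.mode == "recovery" or phase.olr_stated == 0.0
        if self.recovery:
            # no feed; effluent recycled -> no dilution of any pool
            self.d = 0.0
            self.x_carb_in = self.x_inert_in = self.tan_in = 0.0
            self.z_in = self.tic_in = 0.0
            self.olr = 0.0
        else:
            self.d = 1.0 / phase.hrt_days
            inf = influent_from_olr(substrate, phase.olr_stated, phase.hrt_days)
            self.x_carb_in = inf.x_carb_deg
            self.x_inert_in = inf.x_inert
            self.tan_in = inf.tan_g_n_per_l
            self.z_in = params.feed_z
            self.tic_in = params.feed_tic
            self.olr = phase.olr_stated


def _solve_ph_fast(tic, tan, s_ac, s_pro, s_bu, z, ka):
    """Charge-balance pH; returns (ph, co2_aq mol/L, nh3 g N/L)."""
    tan_mol = tan / MW_N
    ac = s_ac / MW_ACETIC
    pro = s_pro / MW_PROPIONIC
    bu = s_bu / MW_BUTYRIC

    def f(ph):
        return chemistry._charge_residual(10.0 ** -ph, tic, tan_mol, ac, pro, bu, z, ka)

    ph = brentq(f, 1.0, 13.0, xtol=1e-12, rtol=8.9e-16)
    h = 10.0 ** -ph
    denom_c = h * h + ka["k1"] * h + ka["k1"] * ka["k2"]
    co2_aq = tic * h * h / denom_c if denom_c > 0 else 0.0
    nh3 = tan * ka["kn"] / (h + ka["kn"])
    return ph, co2_aq, nh3


def _reaction_terms(y, params: KineticParams, substrate: SubstrateSpec, ka):
    """Biological + transfer rates evaluated at (clipped) state ``y``.

    Returns (dy_react, gas_transfer_mol_per_L_day[ch4, co2, h2], ph).
    """
    yc = np.maximum(y, 0.0)
    dy = np.zeros(N_STATE)

    s_mono, s_ac, s_pro, s_bu, s_h2 = (
        yc[_IDX["s_mono"]],
        yc[_IDX["s_ac"]],
        yc[_IDX["s_pro"]],
        yc[_IDX["s_bu"]],
        yc[_IDX["s_h2"]],
    )
    tic, tan, z = yc[_IDX["tic"]], yc[_IDX["tan"]], yc[_IDX["z"]]

    ph, co2_aq, nh3 = _solve_ph_fast(tic, tan, s_ac, s_pro, s_bu, z, ka)

    cod_org = substrate.cod_per_g_organic
    c_org = substrate.c_per_g_organic
    c_org_cod = c_org / cod_org

    # inhibitors acting on acetoclastic methanogens
    if params.vfa_inhibitor_free_acid_only:
        spec = chemistry.solve_ph(tic, tan, s_ac, s_pro, s_bu, z, params.temp_c)
        free = (
            s_ac - spec.acetate_ion * MW_ACETIC
            + s_pro - spec.propionate_ion * MW_PROPIONIC
            + s_bu - spec.butyrate_ion * MW_BUTYRIC
        )
        i_vfa = max(free, 0.0) * 1000.0
    else:
        i_vfa = (s_ac + s_pro + s_bu) * 1000.0  # mg/L
    f_vfa = 1.0 / (1.0 + i_vfa / params.ki_vfa)
    f_nh3 = 1.0 / (1.0 + nh3 * 1000.0 / params.ki_nh3)

    # --- hydrolysis: degradable particulate -> soluble monomers ---------
    r_hyd = params.k_hyd * yc[_IDX["x_carb"]]  # g/L/d
    dy[_IDX["x_carb"]] -= r_hyd
    dy[_IDX["s_mono"]] += r_hyd

    prod_ch4 = 0.0  # g/L/d
    prod_h2_gas = 0.0

    def uptake_for(group, s, ks):
        g = params.groups[group]
        mu = g.mu_max * s / (ks + s) * ph_inhibition(ph, g.pk_low, g.pk_high)
        return g, mu

    # substrate species per group: (state index, cod factor, carbon g/gCOD)
    # --- acidogens: monomers -> ac/pro/bu/h2 -----------------------------
    g, mu = uptake_for("acidogens", s_mono, params.groups["acidogens"].ks)
    _grow(dy, params, "acidogens", "s_mono", mu, yc, cod_org,
          c_sub_cod=c_org_cod,
          products=((_IDX["s_ac"], params.f_mono_ac, COD_AC, C_AC / COD_AC),
                    (_IDX["s_pro"], params.f_mono_pro, COD_PRO, C_PRO / COD_PRO),
                    (_IDX["s_bu"], params.f_mono_bu, COD_BU, C_BU / COD_BU),
                    (_IDX["s_h2"], params.f_mono_h2, COD_H2, 0.0)))

    # --- propionate degraders -------------------------------------------
    g, mu = uptake_for("propionate_degraders", s_pro, params.groups["propionate_degraders"].ks)
    _grow(dy, params, "propionate_degraders", "s_pro", mu, yc, COD_PRO,
          c_sub_cod=C_PRO / COD_PRO,
          products=((_IDX["s_ac"], params.f_pro_ac, COD_AC, C_AC / COD_AC),
                    (_IDX["s_h2"], params.f_pro_h2, COD_H2, 0.0)))

    # --- butyrate degraders ---------------------------------------------
    g, mu = uptake_for("butyrate_degraders", s_bu, params.groups["butyrate_degraders"].ks)
    _grow(dy, params, "butyrate_degraders", "s_bu", mu, yc, COD_BU,
          c_sub_cod=C_BU / COD_BU,
          products=((_IDX["s_ac"], params.f_bu_ac, COD_AC, C_AC / COD_AC),
                    (_IDX["s_h2"], params.f_bu_h2, COD_H2, 0.0)))

    # --- acetoclastic methanogens (VFA + free-NH3 inhibited) ------------
    g, mu = uptake_for("acetoclastic_methanogens", s_ac, params.groups["acetoclastic_methanogens"].ks)
    mu *= f_vfa * f_nh3
    prod_ch4 += _grow(dy, params, "acetoclastic_methanogens", "s_ac", mu, yc, COD_AC,
                      c_sub_cod=C_AC / COD_AC, products=(), ch4_cod_frac=1.0)

    # --- hydrogenotrophic methanogens -----------------------------------
    g, mu = uptake_for("hydrogenotrophic_methanogens", s_h2, params.groups["hydrogenotrophic_methanogens"].ks)
    prod_ch4 += _grow(dy, params, "hydrogenotrophic_methanogens", "s_h2", mu, yc, COD_H2,
                      c_sub_cod=0.0, products=(), ch4_cod_frac=1.0)

    # --- decay: biomass -> soluble monomers + TAN + CO2 ------------------
    for group in GROUPS:
        b = params.groups[group].decay
        xg = yc[_IDX["x_" + group]]
        r_dec = b * xg  # g biomass /L/d
        dy[_IDX["x_" + group]] -= r_dec
        mono = r_dec * COD_BIO / cod_org
        dy[_IDX["s_mono"]] += mono
        dy[_IDX["tan"]] += r_dec * N_BIO
        dy[_IDX["tic"]] += (r_dec * C_BIO - mono * c_org) / 12.011

    # --- gas transfer ----------------------------------------------------
    n_tot = max(yc[_IDX["n_ch4"]] + yc[_IDX["n_co2"]] + yc[_IDX["n_h2"]], 1e-12)
    p_co2 = yc[_IDX["n_co2"]] / n_tot  # atm, total pressure 1 atm
    p_h2 = yc[_IDX["n_h2"]] / n_tot
    t_ch4 = prod_ch4 / MW_CH4  # produced CH4 strips straight to headspace
    t_co2 = params.kla * (co2_aq - params.kh_co2 * p_co2)
    t_h2 = params.kla * (s_h2 / MW_H2 - params.kh_h2 * p_h2)
    dy[_IDX["tic"]] -= t_co2
    dy[_IDX["s_h2"]] -= t_h2 * MW_H2

    return dy, (t_ch4, t_co2, t_h2), ph


def _grow(dy, params, group, s_name, mu, yc, cod_sub, c_sub_cod, products, ch4_cod_frac=0.0):
    """Apply growth of one group at specific rate mu; returns CH4 g/L/d."""
    g = params.groups[group]
    xg = yc[_IDX["x_" + group]]
    growth = mu * xg  # g biomass /L/d
    uptake_cod = growth * COD_BIO / g.yield_cod  # g COD substrate /L/d
    dy[_IDX["x_" + group]] += growth
    dy[_IDX[s_name]] -= uptake_cod / cod_sub
    catabolic = uptake_cod * (1.0 - g.yield_cod)
    c_out = growth * C_BIO
    ch4 = 0.0
    for idx, frac, cod_p, c_p_cod in products:
        rate_cod = catabolic * frac
        dy[idx] += rate_cod / cod_p
        c_out += rate_cod * c_p_cod
    if ch4_cod_frac:
        ch4 = catabolic * ch4_cod_frac / COD_CH4  # g CH4 /L/d
        c_out += catabolic * ch4_cod_frac * (C_CH4 / COD_CH4)
    dy[_IDX["tan"]] -= growth * N_BIO
    dy[_IDX["tic"]] += (uptake_cod * c_sub_cod - c_out) / 12.011
    return ch4


def ode_rhs(
    y: np.ndarray,
    t: float,
    params: KineticParams,
    schedule: OperationSchedule,
    substrate: SubstrateSpec = CORN_STALK,
    _feed: _FeedTerms | None = None,
    _ka: dict | None = None,
) -> np.ndarray:
    """Time derivative of the full state vector at time ``t`` (days).

    CSTR balances dC/dt = D * (C_in - C) + reaction terms for liquid pools;
    headspace moles gain transfer and lose a vented stream that keeps total
    pressure at 1 atm; ``cum_*`` integrate the vented stream.
    """
    feed = _feed if _feed is not None else _FeedTerms(schedule.phase_at(t), substrate, params)
    ka = _ka if _ka is not None else chemistry._ka_set(params.temp_c)

    dy, (t_ch4, t_co2, t_h2), _ph = _reaction_terms(y, params, substrate, ka)

    d = feed.d
    if d > 0.0:
        for name, cin in (
            ("x_carb", feed.x_carb_in),
            ("x_inert", feed.x_inert_in),
            ("tan", feed.tan_in),
            ("z", feed.z_in),
            ("tic", feed.tic_in),
        ):
            dy[_IDX[name]] += d * (cin - y[_IDX[name]])
        for name in ("x_acidogens", "x_propionate_degraders", "x_butyrate_degraders",
                     "x_acetoclastic_methanogens", "x_hydrogenotrophic_methanogens",
                     "s_mono", "s_ac", "s_pro", "s_bu", "s_h2"):
            dy[_IDX[name]] += d * (0.0 - y[_IDX[name]])

    # headspace (mol); vent keeps the gas inventory constant
    v_l = params.v_liq
    transfer = np.array([t_ch4, t_co2, t_h2]) * v_l  # mol/d
    q_out = max(transfer.sum(), 0.0)
    n = np.maximum(y[[_IDX["n_ch4"], _IDX["n_co2"], _IDX["n_h2"]]], 0.0)
    n_tot = max(n.sum(), 1e-12)
    vent = q_out * n / n_tot
    dy[_IDX["n_ch4"]] += transfer[0] - vent[0]
    dy[_IDX["n_co2"]] += transfer[1] - vent[1]
    dy[_IDX["n_h2"]] += transfer[2] - vent[2]
    dy[_IDX["cum_ch4"]] += vent[0]
    dy[_IDX["cum_co2"]] += vent[1]
    dy[_IDX["cum_h2"]] += vent[2]
    return dy


def total_cod(y: np.ndarray, params: KineticParams, substrate: SubstrateSpec = CORN_STALK) -> float:
    """COD inventory (g) of liquid + headspace + cumulative vented gas.

    Constant on zero-feed intervals; the bookkeeping oracle for the model's
    COD-conserving stoichiometry.
    """
    cod_org = substrate.cod_per_g_organic
    liq = (
        y[_IDX["x_carb"]] * cod_org
        + y[_IDX["s_mono"]] * cod_org
        + sum(y[_IDX["x_" + g]] for g in GROUPS) * COD_BIO
        + y[_IDX["s_ac"]] * COD_AC
        + y[_IDX["s_pro"]] * COD_PRO
        + y[_IDX["s_bu"]] * COD_BU
        + y[_IDX["s_h2"]] * COD_H2
    ) * params.v_liq
    gas = (y[_IDX["n_ch4"]] + y[_IDX["cum_ch4"]]) * 64.0 + (y[_IDX["n_h2"]] + y[_IDX["cum_h2"]]) * 16.0
    return liq + gas


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Daily outputs of one reactor simulation."""

    daily: "object"  # pandas.DataFrame
    schedule: OperationSchedule
    params: KineticParams
    substrate: SubstrateSpec
    final_state: ReactorState
    clip_events: int = 0
    gas_reference: str = "1 atm, operating temperature"


def simulate(
    schedule: OperationSchedule,
    params: KineticParams,
    init: ReactorState | None = None,
    substrate: SubstrateSpec = CORN_STALK,
    t_end: float | None = None,
    output_step: float = 1.0,
    rtol: float = 1e-8,
) -> SimulationResult:
    """Integrate the reactor over its schedule and return daily outputs.

    The ODE system is integrated phase by phase (feed composition is
    piecewise constant) with the stiff BDF method.  ``output_step`` only
    controls the sampling grid of the dense solution, not the solver steps.
    """
    import pandas as pd

    if init is None:
        init = default_initial_state(schedule.name)
    init.validate()
    if t_end is None:
        t_end = float(schedule.end_day + 1)

    ka = chemistry._ka_set(params.temp_c)
    y = init.to_vector()
    times: list[float] = []
    states: list[np.ndarray] = []
    clip_events = 0

    t0 = float(schedule.start_day)
    times.append(t0)
    states.append(y.copy())

    for phase in schedule:
        a = max(float(phase.start_day), t0)
        b = min(float(phase.end_day + 1), t_end)
        if b <= a:
            continue
        feed = _FeedTerms(phase, substrate, params)
        if phase.mode == "recovery" and params.reinoculation_biomass > 0:
            for g in GROUPS:
                y[_IDX["x_" + g]] += params.reinoculation_biomass

        def rhs(t, yv, _feed=feed):
            return ode_rhs(yv, t, params, schedule, substrate, _feed=_feed, _ka=ka)

        t_eval = np.arange(
            math.floor(a / output_step + 1e-9) * output_step + output_step, b + 1e-9, output_step
        )
        t_eval = t_eval[t_eval > a + 1e-12]
        sol = solve_ivp(
            rhs, (a, b), y, method="BDF", rtol=rtol, atol=1e-10,
            t_eval=np.append(t_eval, b) if (len(t_eval) == 0 or t_eval[-1] < b - 1e-9) else t_eval,
            max_step=5.0,
        )
        if not sol.success:
            state_now = ReactorState.from_vector(np.maximum(y, 0.0))
            raise ArithmeticError(
                f"integrator failed in phase {phase.label!r} near day "
                f"{sol.t[-1]:.2f}: {sol.message}; state: {state_now}"
            )
        neg = sol.y < -1e-9
        if neg.any():
            clip_events += int(neg.any(axis=0).sum())
            log.warning("clipped %d negative state samples in phase %r",
                        int(neg.sum()), phase.label)
        for tt, yy in zip(sol.t, sol.y.T):
            if tt > times[-1] + 1e-9:
                times.append(float(tt))
                states.append(np.maximum(yy, 0.0))
        y = np.maximum(sol.y[:, -1], 0.0)
        if b >= t_end:
            break

    arr = np.vstack(states)
    tgrid = np.array(times)
    frame = _daily_frame(tgrid, arr, schedule, params, substrate, ka)
    return SimulationResult(
        daily=frame,
        schedule=schedule,
        params=params,
        substrate=substrate,
        final_state=ReactorState.from_vector(arr[-1]),
        clip_events=clip_events,
        gas_reference=("STP" if params.gas_reference == "stp" else f"1 atm, {params.temp_c:g} degC"),
    )


def _daily_frame(tgrid, arr, schedule, params, substrate, ka):
    import pandas as pd

    vm = params.gas_molar_volume
    rows = []
    # samples at integer-ish times only (output_step may be < 1; report each
    # sample, ch4_yield referenced to VS fed over the preceding interval)
    for k in range(1, len(tgrid)):
        t = tgrid[k]
        y = arr[k]
        prev = arr[k - 1]
        dt = tgrid[k] - tgrid[k - 1]
        d_ch4 = max(y[_IDX["cum_ch4"]] - prev[_IDX["cum_ch4"]], 0.0)
        d_co2 = max(y[_IDX["cum_co2"]] - prev[_IDX["cum_co2"]], 0.0)
        d_h2 = max(y[_IDX["cum_h2"]] - prev[_IDX["cum_h2"]], 0.0)
        tot = d_ch4 + d_co2 + d_h2
        biogas_l = tot * vm / dt  # L/day at reference condition
        ch4_l = d_ch4 * vm / dt
        phase = schedule.phase_at(min(t - dt / 2.0, schedule.end_day))
        olr = 0.0 if phase.mode == "recovery" else phase.olr_stated
        vs_fed = olr * params.v_liq  # g VS/day
        yield_ch4 = ch4_l / vs_fed if vs_fed > 0 else np.nan
        s_ac, s_pro, s_bu = y[_IDX["s_ac"]], y[_IDX["s_pro"]], y[_IDX["s_bu"]]
        spec = chemistry.solve_ph(
            y[_IDX["tic"]], y[_IDX["tan"]], s_ac, s_pro, s_bu, y[_IDX["z"]], params.temp_c
        )
        ba = chemistry.simulated_BA(spec)
        _, ia = chemistry.simulated_IA(s_ac, s_pro, s_bu)
        rows.append({
            "day": t,
            "biogas_L": biogas_l,
            "ch4_frac": d_ch4 / tot if tot > 0 else np.nan,
            "co2_frac": d_co2 / tot if tot > 0 else np.nan,
            "h2_frac": d_h2 / tot if tot > 0 else np.nan,
            "ch4_yield_L_per_gVS": yield_ch4,
            "ac_gL": s_ac,
            "pro_gL": s_pro,
            "bu_gL": s_bu,
            "vfa_gL": s_ac + s_pro + s_bu,
            "ph": spec.ph,
            "ia_mgCaCO3L": ia,
            "ba_mgCaCO3L": ba,
            "ta_mgCaCO3L": ia + ba,
        })
    return pd.DataFrame(rows)


def derive_outputs(result: SimulationResult):
    """Indicator-ready daily table from a simulation result.

    Adds the coupled indicators (CH4/CO2 ratio, IA/BA, BA/TA, VFA/BA) to the
    base daily columns.  Days without CO2 production get a missing CH4/CO2
    ratio rather than an infinite one.
    """
    df = result.daily.copy()
    if df.empty:
        raise ValueError("simulation result holds no daily records")
    with np.errstate(divide="ignore", invalid="ignore"):
        co2 = df["co2_frac"].to_numpy()
        ratio = np.where(co2 > 0, df["ch4_frac"].to_numpy() / co2, np.nan)
        df["ch4_co2"] = ratio
        ba = df["ba_mgCaCO3L"].to_numpy()
        ta = df["ta_mgCaCO3L"].to_numpy()
        df["ia_ba"] = np.where(ba > 0, df["ia_mgCaCO3L"].to_numpy() / ba, np.nan)
        df["ba_ta"] = np.where(ta > 0, ba / ta, np.nan)
        df["vfa_ba"] = np.where(ba > 0, df["vfa_gL"].to_numpy() / (ba / 1000.0), np.nan)
    return df
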