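"""Kinetic CSTR model: substrate arithmetic, kinetics, conservation laws."""

import numpy as np
import pandas as pd
import pytest

from adwarn import biomodel
from adwarn.biomodel import (
    CORN_STALK,
    GROUPS,
    KineticParams,
    ReactorState,
    SubstrateSpec,
    characterize_substrate,
    derive_outputs,
    inhibition_noncompetitive,
    monod,
    ode_rhs,
    ph_inhibition,
    simulate,
    total_cod,
)
from adwarn.schedules import OperationPhase, OperationSchedule


def _batch_schedule(days=30):
    """Zero-feed single-phase schedule (sealed batch, no re-inoculation)."""
    return OperationSchedule(
        "batch", (OperationPhase("batch", 0, days, 0, 25, 0.0, "full_load"),)
    )


def _constant_schedule(olr, hrt, days=60):
    return OperationSchedule(
        "const", (OperationPhase("feed", 0, days, 6, hrt, olr, "full_load"),)
    )


class TestSubstrate:
    def test_feed_vs_concentration(self):
        inf = characterize_substrate(CORN_STALK, 6.0)
        assert inf.vs_g_per_l == pytest.approx(60 * 0.8481, rel=1e-12)

    def test_vanishing_feed_vanishing_pools(self):
        inf = characterize_substrate(CORN_STALK, 1e-4)
        assert inf.x_carb_deg == pytest.approx(0.0, abs=1e-3)
        assert inf.x_inert == pytest.approx(0.0, abs=1e-3)

    def test_fully_degradable_leaves_no_inert(self):
        spec = SubstrateSpec(0.9, 0.85, 0.3, 0.01, 0.4, 0.01, 0.06, 0.001, 1.0)
        assert characterize_substrate(spec, 5.0).x_inert == 0.0

    def test_corn_stalk_c_to_n(self):
        assert CORN_STALK.c_over_n == pytest.approx(56.62, abs=0.05)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SubstrateSpec(1.2, 0.85, 0.3, 0.01, 0.4, 0.01, 0.06, 0.001, 0.5)

    def test_cod_of_organic_matter_is_plausible(self):
        # lignocellulose runs ~1.2-1.5 g COD per g VS
        assert 1.2 < CORN_STALK.cod_per_g_vs < 1.5


class TestKineticPrimitives:
    @pytest.mark.parametrize(
        "s, expected_frac", [(0.0, 0.0), (0.5, 0.5), (5e4, 1.0)]
    )
    def test_monod_limits(self, s, expected_frac):
        # Ks = S gives mu_max/2; S >> Ks saturates at mu_max
        assert monod(0.4, s, 0.5) == pytest.approx(0.4 * expected_frac, rel=1e-4)

    def test_monod_monotone_and_validating(self):
        vals = [monod(1.0, s, 0.3) for s in np.linspace(0, 5, 50)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            monod(1.0, -0.1, 0.3)

    @pytest.mark.parametrize(
        "i, ki, expected", [(0.0, 315.0, 1.0), (315.0, 315.0, 0.5), (630.0, 315.0, 1 / 3)]
    )
    def test_noncompetitive_inhibition(self, i, ki, expected):
        assert inhibition_noncompetitive(i, ki) == pytest.approx(expected, rel=1e-12)

    def test_inhibition_validates_ki(self):
        with pytest.raises(ValueError):
            inhibition_noncompetitive(10.0, 0.0)

    def test_ph_factor_peaks_at_midpoint(self):
        pkl, pkh = 6.0, 8.5
        mid = (pkl + pkh) / 2
        # analytic maximum of the two-sided form is at the pK midpoint
        num = 1 + 2 * 10 ** (0.5 * (pkl - pkh))
        peak = num / (1 + 2 * 10 ** (0.5 * (pkl - pkh)))
        assert ph_inhibition(mid, pkl, pkh) == pytest.approx(peak, abs=1e-6)
        grid = np.linspace(2, 12, 401)
        vals = [ph_inhibition(p, pkl, pkh) for p in grid]
        assert abs(grid[int(np.argmax(vals))] - mid) < 0.05

    def test_ph_factor_vanishes_far_from_band(self):
        assert ph_inhibition(6.0 - 3.0, 6.0, 8.5) < 0.01

    def test_ph_factor_symmetric_about_midpoint(self):
        mid = (6.0 + 8.5) / 2
        for d in (0.3, 1.0, 2.2):
            assert ph_inhibition(mid + d, 6.0, 8.5) == pytest.approx(
                ph_inhibition(mid - d, 6.0, 8.5), rel=1e-12
            )


class TestOdeRhs:
    def test_no_biomass_no_feed_is_inert_for_acetate(self, r1_params):
        state = ReactorState()
        for g in GROUPS:
            setattr(state, "x_" + g, 0.0)
        state.x_carb = 0.0
        state.s_mono = 0.0
        y = state.to_vector()
        dy = ode_rhs(y, 5.0, r1_params, _batch_schedule())
        names = biomodel.STATE_NAMES
        assert dy[names.index("s_ac")] == pytest.approx(0.0, abs=1e-12)

    def test_lone_biomass_decays_exponentially(self, r1_params):
        state = ReactorState()
        for g in GROUPS:
            setattr(state, "x_" + g, 0.0)
        state.x_acidogens = 1.0
        state.x_carb = state.s_mono = state.s_ac = state.s_pro = state.s_bu = 0.0
        dy = ode_rhs(state.to_vector(), 5.0, r1_params, _batch_schedule())
        b = r1_params.groups["acidogens"].decay
        assert dy[biomodel.STATE_NAMES.index("x_acidogens")] == pytest.approx(-b * 1.0, rel=1e-9)

    def test_cod_rate_balance_without_feed(self, r1_params):
        """d(liquid COD)/dt + d(gas COD)/dt = 0: the stoichiometry conserves
        chemical oxygen demand exactly, reaction by reaction."""
        y = ReactorState().to_vector()
        dy = ode_rhs(y, 5.0, r1_params, _batch_schedule())
        scale = total_cod(y, r1_params)
        # directional derivative of the COD inventory along dy
        eps = 1e-7
        drift = (total_cod(y + eps * dy, r1_params) - total_cod(y - eps * dy, r1_params)) / (2 * eps)
        assert abs(drift) / scale < 1e-8


class TestSimulate:
    def test_cod_conserved_in_sealed_batch(self, r1_params):
        init = ReactorState()
        res = simulate(_batch_schedule(20), r1_params, init=init, t_end=20.0)
        y0 = init.to_vector()
        # reconstruct the final raw state vector from the result
        yT = res.final_state.to_vector()
        c0 = total_cod(y0, r1_params)
        cT = total_cod(yT, r1_params)
        assert abs(cT - c0) / c0 < 1e-3

    def test_determinism_bitwise(self, schedules, r1_params):
        a = simulate(schedules["R1"], r1_params, t_end=40.0).daily
        b = simulate(schedules["R1"], r1_params, t_end=40.0).daily
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_washout_at_short_hrt(self, r1_params):
        # HRT below 1/mu_max of every group: dilution outruns growth
        res = simulate(_constant_schedule(olr=1.5, hrt=0.15, days=40), r1_params, t_end=40.0)
        final = res.final_state
        assert all(getattr(final, "x_" + g) < 1e-3 for g in GROUPS)
        last5 = res.daily.tail(5)
        assert (last5["ch4_yield_L_per_gVS"].fillna(0.0) < 0.01).all()

    def test_output_step_refinement(self, schedules, r1_params):
        coarse = simulate(schedules["R1"], r1_params, t_end=30.0, output_step=1.0).daily
        fine = simulate(schedules["R1"], r1_params, t_end=30.0, output_step=0.5).daily
        sub = fine[fine["day"].isin(coarse["day"])].reset_index(drop=True)
        for col in ("vfa_gL", "ph", "ba_mgCaCO3L"):
            rel = np.abs(sub[col].to_numpy() - coarse[col].to_numpy()) / np.abs(coarse[col].to_numpy())
            assert np.nanmax(rel) < 1e-3

    def test_ch4_yield_nonincreasing_in_inverse_ki(self, schedules):
        """Stronger VFA inhibition (smaller Ki) cannot raise the steady yield."""
        yields = []
        for ki in (150.0, 315.0, 630.0):
            params = KineticParams.default(ki_vfa=ki)
            df = simulate(schedules["R1"], params, t_end=60.0).daily
            m = (df.day >= 40) & (df.day <= 60)
            yields.append(df.loc[m, "ch4_yield_L_per_gVS"].mean())
        assert yields[0] <= yields[1] * (1 + 1e-6) <= yields[2] * (1 + 2e-6)

    def test_no_feed_bounded_methane(self, r1_params):
        res = simulate(_batch_schedule(25), r1_params, t_end=25.0)
        ch4_l = (res.daily["biogas_L"] * res.daily["ch4_frac"]).sum()
        # bounded by the initial COD inventory converted wholly to CH4
        max_l = total_cod(ReactorState().to_vector(), r1_params) * 0.3951
        assert 0 < ch4_l < max_l

    def test_invalid_initial_state_rejected(self, schedules, r1_params):
        bad = ReactorState(s_ac=-1.0)
        with pytest.raises(ValueError):
            simulate(schedules["R1"], r1_params, init=bad, t_end=5.0)


class TestDerivedOutputs:
    def test_ratio_and_lengths(self, r1_fullload_result):
        df = derive_outputs(r1_fullload_result)
        assert len(df) == len(r1_fullload_result.daily)
        m = df["co2_frac"] > 0
        assert np.allclose(
            df.loc[m, "ch4_co2"], df.loc[m, "ch4_frac"] / df.loc[m, "co2_frac"]
        )
        assert np.allclose(df["vfa_gL"], df[["ac_gL", "pro_gL", "bu_gL"]].sum(axis=1))

    def test_zero_co2_flagged_missing(self, r1_fullload_result):
        res = r1_fullload_result
        daily = res.daily.copy()
        daily.loc[daily.index[0], "co2_frac"] = 0.0
        patched = biomodel.SimulationResult(
            daily=daily, schedule=res.schedule, params=res.params,
            substrate=res.substrate, final_state=res.final_state,
        )
        df = derive_outputs(patched)
        assert np.isnan(df["ch4_co2"].iloc[0])
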