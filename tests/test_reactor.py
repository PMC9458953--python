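"""Simulator physics: temperature factor, steady states, conservation, events."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lfcr
from lfcr.constants import MW_SULPHUR, R_GAS
from lfcr.reactor import ConfigError, IntegratorStepError, _step


def kinetics(**kw):
    return lfcr.KineticParams(**kw)


class TestTemperatureFactor:
    def test_identity_at_reference(self):
        p = kinetics()
        assert lfcr.temperature_factor(p.t_ref, p) == pytest.approx(1.0)

    def test_warm_range_value(self):
        # direct evaluation of exp(-(Ea/R)(1/T - 1/T_ref)) for Ea = 19 kJ/mol
        p = kinetics(ea_above=19_000.0, t_ref=303.15, t_crit=283.15, ea_below=19_000.0)
        assert lfcr.temperature_factor(288.15, p) == pytest.approx(0.6754, abs=1e-4)

    def test_continuous_at_critical_temperature(self):
        p = kinetics()
        below = lfcr.temperature_factor(p.t_crit - 1e-9, p)
        above = lfcr.temperature_factor(p.t_crit, p)
        assert below == pytest.approx(above, rel=1e-6)

    def test_steeper_below_critical(self):
        p = kinetics()
        drop_warm = lfcr.temperature_factor(p.t_crit + 5, p) / lfcr.temperature_factor(p.t_crit + 10, p)
        drop_cold = lfcr.temperature_factor(p.t_crit - 10, p) / lfcr.temperature_factor(p.t_crit - 5, p)
        assert drop_cold < drop_warm < 1.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            lfcr.temperature_factor(0.0, kinetics())

    @given(st.floats(min_value=275.0, max_value=310.0),
           st.floats(min_value=275.0, max_value=310.0))
    def test_monotone_in_temperature(self, t1, t2):
        p = kinetics()
        f1, f2 = lfcr.temperature_factor(t1, p), lfcr.temperature_factor(t2, p)
        assert (t1 <= t2) == (f1 <= f2) or math.isclose(f1, f2)


class TestStep:
    def test_equilibrium_state_unchanged(self):
        feed = lfcr.FeedSpec(yeast_extract_acetate_rate=0.0)
        p = kinetics(k_max=0.0, k_ox_max=0.0, biofilm_regrowth=0.0)
        state = lfcr.ReactorState(sulphate=feed.sulphate_molar, lactate=feed.carbon_molar)
        new = lfcr.step(state, 30.0, feed, p, hrt=48.0, dt=0.4)
        for name in ("sulphate", "sulphide", "lactate", "acetate", "propionate"):
            assert getattr(new, name) == pytest.approx(getattr(state, name), abs=1e-12)

    def test_zero_order_steady_state_conversion(self):
        # with S >> K_S and unlimited donor, X = k/(D*C_in) = 0.144*48/10.41
        feed = lfcr.FeedSpec(yeast_extract_acetate_rate=0.0)
        p = kinetics(k_max=0.144, k_s=0.0, aux_donor_frac=1.0, t_crit=250.0,
                     ea_above=0.0, ea_below=0.0)
        state = lfcr.ReactorState(sulphate=feed.sulphate_molar, lactate=feed.carbon_molar)
        for _ in range(7500):  # 3000 h at 0.4 h steps
            state = lfcr.step(state, 30.0, feed, p, hrt=48.0, dt=0.4)
        conversion = 1.0 - state.sulphate / feed.sulphate_molar
        assert conversion == pytest.approx(0.664, abs=5e-4)

    def test_monod_steady_state_matches_quadratic_root(self):
        # D(C_in - C) = k C/(K + C) has one positive root; the explicit
        # map's fixed point must land on it.
        feed = lfcr.FeedSpec(yeast_extract_acetate_rate=0.0)
        k, big_k = 0.2, 2.0
        p = kinetics(k_max=k, k_s=big_k, aux_donor_frac=1.0, t_crit=250.0,
                     ea_above=0.0, ea_below=0.0)
        d, c_in = 1.0 / 48.0, feed.sulphate_molar
        roots = np.roots([d, d * big_k + k - d * c_in, -d * big_k * c_in])
        expected = max(r.real for r in roots if abs(r.imag) < 1e-12 and r.real > 0)
        state = lfcr.ReactorState(sulphate=c_in, lactate=feed.carbon_molar)
        for _ in range(10_000):  # 4000 h
            state = lfcr.step(state, 30.0, feed, p, hrt=48.0, dt=0.4)
        assert state.sulphate == pytest.approx(expected, rel=1e-6)

    def test_overshoot_names_species(self):
        feed = lfcr.FeedSpec()
        p = kinetics(k_max=2.0, k_s=0.0, aux_donor_frac=1.0)
        state = lfcr.ReactorState(sulphate=0.01, lactate=5.0)
        with pytest.raises(IntegratorStepError, match="sulphate"):
            lfcr.step(state, 30.0, feed, p, hrt=48.0, dt=0.4)

    def test_step_size_guard(self):
        state = lfcr.ReactorState(sulphate=10.0)
        with pytest.raises(ConfigError, match="hrt/100"):
            lfcr.step(state, 30.0, lfcr.FeedSpec(), kinetics(), hrt=48.0, dt=1.0)


class TestSimulate:
    def test_noiseless_samples_equal_truth(self, short_schedule):
        res = lfcr.simulate(lfcr.FeedSpec(), kinetics(), short_schedule,
                            noise_cv=0.0, seed=1, dt=0.4)
        merged = res.samples.merge(res.truth, on="time_h", suffixes=("", "_truth"))
        for analyte in ("sulphate", "sulphide", "lactate", "acetate", "propionate"):
            col = f"{analyte}_mmol_L"
            assert np.allclose(merged[col], merged[f"{col}_truth"])

    def test_same_seed_identical_output(self, short_schedule):
        runs = [lfcr.simulate(lfcr.FeedSpec(), kinetics(), short_schedule,
                              noise_cv=0.05, seed=42, dt=0.4) for _ in range(2)]
        pd.testing.assert_frame_equal(runs[0].samples, runs[1].samples)
        pd.testing.assert_frame_equal(runs[0].harvests, runs[1].harvests)

    def test_sulphur_atoms_conserved(self, noiseless_run):
        assert lfcr.sulphur_closure_error(noiseless_run) < 1e-6

    def test_conversion_non_increasing_with_cooling(self, noiseless_summaries):
        conv = noiseless_summaries["conversion"].to_numpy()
        assert (np.diff(conv) < 0).all()

    def test_state_bounds_hold_throughout(self, noiseless_run):
        truth = noiseless_run.truth
        assert truth["coverage"].between(0.0, 1.0).all()
        for analyte in ("sulphate", "sulphide", "lactate", "acetate", "propionate"):
            assert (truth[f"{analyte}_mmol_L"] >= 0).all()

    def test_one_harvest_per_stage_and_film_reset(self, noiseless_run):
        assert len(noiseless_run.harvests) == len(noiseless_run.schedule.stages)
        assert noiseless_run.totals["residual_film_s_g"] == pytest.approx(0.0, abs=1e-12)
        # noiseless harvest sulphur is exactly the captured film sulphur
        fsb = (noiseless_run.harvests["dry_mass_g"] * noiseless_run.harvests["frac_S"]).sum()
        assert fsb == pytest.approx(noiseless_run.totals["film_s_g"], rel=1e-9)

    def test_noise_clipping_keeps_concentrations_nonnegative(self, short_schedule):
        res = lfcr.simulate(lfcr.FeedSpec(), kinetics(), short_schedule,
                            noise_cv=0.8, seed=5, dt=0.4)
        conc_cols = [c for c in res.samples.columns if c.endswith("_mmol_L")]
        assert (res.samples[conc_cols] >= 0).all().all()

    def test_empty_schedule_rejected(self):
        with pytest.raises(ConfigError):
            lfcr.Schedule(stages=())

    def test_harvest_must_be_multiple_of_disruption(self):
        with pytest.raises(ConfigError):
            lfcr.Schedule(disruption_interval=3.0, harvest_interval=7.0)


class TestSpecs:
    def test_feed_molarity_conversion(self):
        feed = lfcr.FeedSpec(sulphate_conc=1.0)
        assert feed.sulphate_molar == pytest.approx(1000.0 / 96.06, rel=1e-9)

    def test_lactate_supply_rate_matches_design(self):
        # 10.94 mmol/L over a 48 h residence time supplies 0.228 mmol/L.h
        feed = lfcr.FeedSpec()
        assert feed.carbon_molar / 48.0 == pytest.approx(0.228, abs=5e-4)

    def test_stress_regime_must_be_steeper(self):
        with pytest.raises(ConfigError):
            kinetics(ea_above=60_000.0, ea_below=19_000.0)

    def test_state_validation(self):
        with pytest.raises(ConfigError):
            lfcr.ReactorState(sulphate=-1.0)
        with pytest.raises(ConfigError):
            lfcr.ReactorState(coverage=1.5)
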