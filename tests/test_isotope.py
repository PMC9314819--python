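"""Discrimination components and mesophyll-conductance estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafgas as lg
from leafgas.isotope import DEFAULT_CONSTANTS


def make_record(**overrides) -> lg.GasExchangeIsotopeRecord:
    kwargs = dict(
        an=14.0, e_trans=0.002, g_act=0.25, ca=400.0, cs=390.0, ci=280.0,
        ce=460.0, rd=1.5, gamma_star=40.0, d13c_a=-4.5, d13c_e=-35.0,
    )
    kwargs.update(overrides)
    return lg.GasExchangeIsotopeRecord(**kwargs)


class TestComponents:
    @pytest.mark.parametrize(
        "ce,ca,expected", [(420.0, 400.0, 21.0), (500.0, 450.0, 10.0)]
    )
    def test_zeta_arithmetic(self, ce, ca, expected):
        assert lg.zeta(ce, ca) == pytest.approx(expected)

    def test_zeta_total_drawdown_limit(self):
        assert lg.zeta(500.0, 0.0) == pytest.approx(1.0)

    def test_zeta_degenerate_pair_rejected(self):
        with pytest.raises(ValueError, match="zeta"):
            lg.zeta(400.0, 400.0)

    def test_observed_discrimination_zero_for_identical_ratios(self):
        assert lg.observed_discrimination(-8.0, -8.0, 10.0) == 0.0

    def test_observed_discrimination_worked_value(self):
        # 1000*10*2 / (1000 - 6 - 10*2) = 20000/974
        assert lg.observed_discrimination(-6.0, -8.0, 10.0) == pytest.approx(
            20.534, abs=0.001
        )

    def test_combined_fractionation_limits(self):
        k = DEFAULT_CONSTANTS
        assert lg.combined_fractionation(400.0, 400.0, 280.0, k) == pytest.approx(4.4)
        assert lg.combined_fractionation(400.0, 280.0, 280.0, k) == pytest.approx(2.9)
        assert lg.combined_fractionation(400.0, 380.0, 280.0, k) == pytest.approx(
            (2.9 * 20 + 4.4 * 100) / 120.0
        )

    def test_ternary_worked_value(self):
        assert lg.ternary_t(4.4, 0.002, 0.25) == pytest.approx(0.0040176, abs=1e-6)
        assert lg.ternary_t(4.4, 0.0, 0.25) == 0.0

    def test_ternary_linear_in_transpiration(self):
        assert lg.ternary_t(4.4, 0.004, 0.25) == pytest.approx(
            2 * lg.ternary_t(4.4, 0.002, 0.25)
        )

    def test_predicted_discrimination_limits(self):
        k = DEFAULT_CONSTANTS
        # full carboxylation limitation: Ci = Ca, t = 0 -> b
        assert lg.predicted_discrimination(0.0, 4.15, 400.0, 400.0, k) == pytest.approx(29.0)
        # pure diffusion limitation: Ci = 0 -> a'
        assert lg.predicted_discrimination(0.0, 4.15, 0.0, 400.0, k) == pytest.approx(4.15)

    def test_predicted_discrimination_worked_value(self):
        k = DEFAULT_CONSTANTS
        val = lg.predicted_discrimination(0.004, 4.15, 280.0, 400.0, k)
        assert val == pytest.approx(21.71, abs=0.01)

    def test_nonrubisco_zero_cases(self):
        rec = make_record(d13c_e=-8.0)  # e = d13Ce - d13Catm = 0
        de, df, e = lg.nonrubisco_discriminations(0.004, rec)
        assert e == 0.0 and de == 0.0
        rec2 = make_record(ci=40.0, cs=40.0, ca=40.1, ce=460.0)  # Ci = Gamma*
        de2, _, _ = lg.nonrubisco_discriminations(0.0, rec2)
        assert de2 == pytest.approx(0.0, abs=1e-12)

    def test_photorespiratory_worked_value(self):
        rec = make_record()
        _, df, _ = lg.nonrubisco_discriminations(0.0, rec)
        assert df == pytest.approx(11.6 * 40.0 / 400.0, rel=1e-12)  # 1.16

    def test_chloroplast_co2(self):
        assert lg.chloroplast_co2(280.0, 14.0, 0.14) == pytest.approx(180.0)
        assert lg.chloroplast_co2(280.0, 0.0, 0.14) == pytest.approx(280.0)
        assert lg.chloroplast_co2(280.0, 14.0, 1e12) == pytest.approx(280.0)
        with pytest.raises(ValueError):
            lg.chloroplast_co2(280.0, 14.0, 0.0)


class TestEstimateGm:
    def test_forward_inverse_closure(self):
        records = lg.generate_isotope_records(
            lg.IsotopeSimParams(true_gm=0.12, noise_sd_d13ca=0.0, n=1)
        )
        res = lg.estimate_gm_table(records)
        assert abs(res["gm"].iloc[0] / 0.12 - 1) < 1e-10

    def test_eq1_identity_holds(self):
        res = lg.estimate_gm(make_record())
        assert res.delta_gm == pytest.approx(
            res.delta_i - res.delta_o - res.delta_e - res.delta_f, abs=1e-14
        )

    def test_unresolvable_flag_not_negative_gm(self):
        """When observed discrimination exhausts the predicted value the
        result is flagged instead of returning a negative conductance."""
        base = lg.estimate_gm(make_record())
        # choose d13c_a so delta_o ~= delta_i - delta_e - delta_f
        target = base.delta_i - base.delta_e - base.delta_f
        z = base.zeta
        d13c_e = -35.0
        d13c_a = -(1000 * z * d13c_e + 1000 * target + target * z * d13c_e) / (
            target * (1 - z) - 1000 * z
        )
        res = lg.estimate_gm(make_record(d13c_a=d13c_a + 0.01))
        assert "gm_unresolvable" in res.flags
        assert math.isnan(res.gm)

    def test_monotone_in_observed_discrimination(self):
        """Holding all else fixed, observed discrimination closer to the
        predicted value implies a larger g_m."""
        clean = lg.generate_isotope_records(
            lg.IsotopeSimParams(true_gm=0.15, noise_sd_d13ca=0.0, n=1)
        ).iloc[0]
        gms = []
        for offset in (-0.3, 0.0, 0.3):
            res = lg.estimate_gm(
                make_record(
                    d13c_a=clean["d13Ca"] + offset, ce=clean["Ce"], ca=clean["Ca"],
                    cs=clean["Cs"], ci=clean["Ci"],
                )
            )
            assert not math.isnan(res.gm)
            gms.append((res.delta_o, res.gm))
        gms.sort()
        assert all(g1 < g2 for (_, g1), (_, g2) in zip(gms, gms[1:]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        gm=st.floats(0.02, 0.5),
        ci=st.floats(150.0, 350.0),
        an=st.floats(2.0, 25.0),
        d13c_e=st.floats(-37.0, -32.0),
    )
    def test_closure_property(self, gm, ci, an, d13c_e):
        """Zero-noise forward/inverse closure across the physiological range."""
        params = lg.IsotopeSimParams(
            true_gm=gm, ci=ci, cs=min(390.0, max(ci, 300.0)), an=an,
            d13c_e=d13c_e, noise_sd_d13ca=0.0, n=1,
        )
        out = lg.estimate_gm_table(lg.generate_isotope_records(params))
        assert abs(out["gm"].iloc[0] / gm - 1) < 1e-9

    def test_predicted_between_diffusion_and_carboxylation(self):
        """a' <= delta_i <= (1+t) b / (1-t) for Ci/Ca in [0, 1]."""
        k = DEFAULT_CONSTANTS
        for frac in np.linspace(0.0, 1.0, 7):
            di = lg.predicted_discrimination(0.004, 4.15, 400.0 * frac, 400.0, k)
            assert 4.15 - 1e-9 <= di <= (1.004 / 0.996) * 29.0 + 1e-9


class TestBatch:
    def test_csv_round_trip(self, tmp_path):
        records = lg.generate_isotope_records(
            lg.IsotopeSimParams(noise_sd_d13ca=0.05, n=4, seed=1)
        )
        path = tmp_path / "records.csv"
        records.to_csv(path, index=False)
        df = lg.read_records_csv(path)
        out = lg.estimate_gm_table(df)
        assert {"gm", "Cc", "delta_o", "flags"} <= set(out.columns)
        assert np.isfinite(out["gm"]).all()

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("An,Ca\n1,400\n")
        with pytest.raises(ValueError, match="missing"):
            lg.read_records_csv(path)

    def test_bracketing_reference_means(self):
        kinds = ["R", "P", "R", "P", "R"]
        vals = [-33.0, 0.0, -35.0, 0.0, -36.0]
        out = lg.bracket_reference_d13c(kinds, vals)
        assert out[1] == pytest.approx((-33.0 - 35.0) / 2)
        assert out[3] == pytest.approx((-35.0 - 36.0) / 2)

    def test_bracketing_single_neighbour_fallback(self):
        out = lg.bracket_reference_d13c(["P", "R"], [0.0, -34.0])
        assert out[0] == pytest.approx(-34.0)
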