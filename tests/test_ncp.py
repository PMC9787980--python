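"""NCP from drawdown: worked survey values, conversions, CaCO3 convention."""

import numpy as np
import pytest

from chukchi_carbon.ncp import (DrawdownInput, caco3_correction,
                                integrate_profile, n2_fixation_adjustment,
                                ncp_dic, ncp_from_drawdown, ncp_nutrient,
                                redfield_convert, uptake_ratios)
from _reference import ncp_brute_force


class TestNcpNutrient:
    @pytest.mark.parametrize("d_n,mld,dt,expected", [
        (10.24, 25.0, 73.0, 3.51),   # southern nitrate drawdown
        (9.92, 25.0, 49.0, 5.06),    # northern nitrate drawdown
        (1.19, 25.0, 73.0, 0.41),    # southern phosphate drawdown
        (0.94, 25.0, 49.0, 0.48),    # northern phosphate drawdown
    ])
    def test_surveyed_drawdowns(self, d_n, mld, dt, expected):
        assert round(ncp_nutrient(d_n, mld, dt), 2) == expected

    def test_zero_drawdown(self):
        assert ncp_nutrient(0.0, 25.0, 73.0) == 0.0

    def test_matches_brute_force_bookkeeping(self):
        assert ncp_nutrient(10.24, 25.0, 73.0) == pytest.approx(
            ncp_brute_force(10.24, 25.0, 73.0))

    def test_linearity(self):
        base = ncp_nutrient(5.0, 25.0, 50.0)
        assert ncp_nutrient(10.0, 25.0, 50.0) == pytest.approx(2 * base)
        assert ncp_nutrient(5.0, 50.0, 50.0) == pytest.approx(2 * base)
        assert ncp_nutrient(5.0, 25.0, 100.0) == pytest.approx(base / 2)

    def test_invalid_frame_rejected(self):
        with pytest.raises(ValueError):
            ncp_nutrient(1.0, 25.0, 0.0)
        with pytest.raises(ValueError):
            ncp_nutrient(1.0, -1.0, 10.0)


class TestRedfieldConvert:
    def test_nitrogen_conversion(self):
        assert redfield_convert(3.51, "N") == pytest.approx(23.2, rel=0.02)
        assert redfield_convert(5.06, "N") == pytest.approx(33.4, rel=0.02)

    def test_phosphorus_conversion(self):
        assert redfield_convert(0.41, "P") == pytest.approx(43.3, rel=0.005)
        assert redfield_convert(0.48, "P") == pytest.approx(50.9, rel=0.005)

    def test_zero(self):
        assert redfield_convert(0.0, "N") == 0.0

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            redfield_convert(1.0, "Si")


class TestCaco3Correction:
    def test_zero_changes_zero_term(self):
        assert caco3_correction(0.0, 0.0, 1025.0) == 0.0

    def test_dissolution_dominated_example(self):
        # surveyed southern deltas: TA rose by 34 umol/kg, nitrate fell 10.24 uM
        term = caco3_correction(-34.0, 10.24, 1025.0)
        assert term == pytest.approx(0.5 * (-34.0 * 1.025 + 10.24))
        assert term == pytest.approx(-12.3, abs=0.1)
        assert term < 0  # dissolution added DIC

    def test_pure_biological_ta_change_cancels(self):
        # nitrate uptake alone raises TA one-for-one (in volumetric units)
        rho = 1025.0
        d_nno3 = 10.0
        d_nta = -d_nno3 / (rho / 1000.0)
        assert caco3_correction(d_nta, d_nno3, rho) == pytest.approx(0.0, abs=1e-12)


class TestNcpDic:
    def test_all_zero(self):
        inp = DrawdownInput(d_ndic=0, d_nno3=0, d_npo4=0, d_nta=0, dt=10.0,
                            mean_co2_flux=0.0)
        rate, caco3, corrected = ncp_dic(inp)
        assert rate == 0.0 and caco3 == 0.0 and corrected

    def test_regression_with_flux(self):
        """Pinned arithmetic: 79 umol/kg drawdown over 73 d and 25 m at
        rho=1025 with a -10 mmol m-2 d-1 mean uptake flux, no CaCO3."""
        inp = DrawdownInput(d_ndic=79.0, d_nno3=0.0, d_npo4=0.0, d_nta=0.0,
                            dt=73.0, mld=25.0, rho1=1025.0, rho2=1025.0,
                            mean_co2_flux=-10.0)
        rate, _, corrected = ncp_dic(inp, apply_caco3=False)
        assert corrected
        assert rate == pytest.approx(79.0 * 1.025 * 25.0 / 73.0 + 10.0)
        assert rate == pytest.approx(37.73, abs=0.01)

    def test_missing_flux_flagged(self):
        inp = DrawdownInput(d_ndic=79.0, d_nno3=0, d_npo4=0, d_nta=0, dt=73.0)
        rate, _, corrected = ncp_dic(inp, apply_caco3=False)
        assert not corrected
        assert rate == pytest.approx(79.0 * 1.025 * 25.0 / 73.0)


class TestUptakeRatios:
    def test_surveyed_ratios(self):
        cn, _ = uptake_ratios(38.4, 3.51, 0.41)
        assert cn == pytest.approx(10.9, abs=0.05)
        cn, _ = uptake_ratios(61.4, 5.06, 0.48)
        assert cn == pytest.approx(12.1, abs=0.05)

    def test_redfield_limit(self):
        cn, cp = uptake_ratios(6.625 * 3.0, 3.0, 6.625 * 3.0 / 106.0)
        assert cn == pytest.approx(6.625)
        assert cp == pytest.approx(106.0)

    def test_zero_denominator_undefined(self):
        cn, cp = uptake_ratios(10.0, 0.0, 0.0)
        assert np.isnan(cn) and np.isnan(cp)


class TestN2Fixation:
    def test_depth_integration(self):
        assert n2_fixation_adjustment(0.0, 3.60, 25.0) == pytest.approx(0.09)

    def test_adjusted_southern_ncp(self):
        assert n2_fixation_adjustment(3.51, 3.60, 25.0) == pytest.approx(3.60)

    def test_zero_rate_identity(self):
        assert n2_fixation_adjustment(3.51, 0.0) == 3.51

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            n2_fixation_adjustment(3.51, -1.0)


class TestDepthIntegration:
    def test_trapezoid_inventory(self):
        # uniform 10 uM over 0-40 m: inventory 400 mmol m-2
        assert integrate_profile([0, 20, 40], [10.0, 10.0, 10.0]) == pytest.approx(400.0)
        # order independence
        assert integrate_profile([40, 0, 20], [5.0, 10.0, 7.5]) == pytest.approx(
            integrate_profile([0, 20, 40], [10.0, 7.5, 5.0]))


def test_full_bundle_consistency():
    inp = DrawdownInput(d_ndic=79.0, d_nno3=10.24, d_npo4=1.19, d_nta=-34.0,
                        dt=73.0, mean_co2_flux=-9.2)
    res = ncp_from_drawdown(inp)
    assert res.cn_uptake == pytest.approx(res.ncp_dic / res.ncp_n)
    assert res.cp_uptake == pytest.approx(res.ncp_dic / res.ncp_p)
    assert res.ncp_n_as_c == pytest.approx(res.ncp_n * 6.625)
    assert res.flux_corrected
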