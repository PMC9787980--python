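"""Air-sea CO2 flux: transfer velocity, ice cap, composition, group stats."""

import numpy as np
import pandas as pd
import pytest

from chukchi_carbon import constants as cst
from chukchi_carbon.flux import (ForcingDay, co2_flux, flux_for_cells,
                                 gas_transfer_velocity, pco2_air,
                                 regional_flux_table, schmidt_number)


def _forcing(ice=0.0, u2=49.0, xco2=400.0, psl=1.0, day=150):
    return ForcingDay(day=day, u10_sq=u2, ice_pct=ice, psl=psl, xco2=xco2)


class TestGasTransferVelocity:
    def test_zero_wind_zero_k(self):
        assert gas_transfer_velocity(0.0, 0.0, 32.0, 0.0) == 0.0

    def test_pinned_open_water_value(self):
        # 0.251 * 49 * (Sc(0)/660)^-0.5 with Sc(0 degC) = 2116.8
        expected = 0.251 * 49.0 * (2116.8 / 660.0) ** -0.5
        assert gas_transfer_velocity(49.0, 0.0, 32.0, 0.0) == pytest.approx(expected)
        assert schmidt_number(0.0) == pytest.approx(2116.8)

    def test_full_ice_keeps_ten_percent_open_water(self):
        k_open = gas_transfer_velocity(49.0, 0.0, 32.0, 0.0)
        assert gas_transfer_velocity(49.0, 0.0, 32.0, 100.0) == pytest.approx(0.1 * k_open)
        assert gas_transfer_velocity(49.0, 0.0, 32.0, 95.0) == pytest.approx(0.1 * k_open)

    def test_linear_in_open_water_below_cap(self):
        k0 = gas_transfer_velocity(49.0, 0.0, 32.0, 0.0)
        assert gas_transfer_velocity(49.0, 0.0, 32.0, 40.0) == pytest.approx(0.6 * k0)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            gas_transfer_velocity(-1.0, 0.0)


class TestPco2Air:
    def test_moist_air_below_dry_air(self):
        fd = _forcing(xco2=400.0, psl=1.0)
        assert 390.0 < pco2_air(fd, 0.0, 32.0) < 400.0

    def test_moist_correction_value(self):
        from chukchi_carbon.carbonate import vapor_pressure
        fd = _forcing()
        expected = 400.0 * (1.0 - vapor_pressure(0.0, 1.0, 32.0))
        assert pco2_air(fd, 0.0, 32.0) == pytest.approx(expected)

    def test_zero_xco2(self):
        assert pco2_air(_forcing(xco2=0.0), 0.0, 32.0) == 0.0


class TestCo2Flux:
    def test_equilibrium_is_zero_flux(self):
        fd = _forcing()
        p_air = pco2_air(fd, 0.0, 32.0)
        assert co2_flux(p_air, 0.0, 32.0, fd).flux == pytest.approx(0.0)

    def test_undersaturation_is_a_sink(self):
        res = co2_flux(300.0, 0.0, 32.0, _forcing())
        assert res.dpco2 < 0 and res.flux < 0

    def test_full_composition_pinned(self):
        """Frozen composition of the pinned formulas: u2=49, T=0, S=32,
        ice=50%, pCO2sea=250, xCO2=400, Psl=1 atm."""
        res = co2_flux(250.0, 0.0, 32.0, _forcing(ice=50.0))
        assert res.k == pytest.approx(3.43378, abs=1e-4)
        assert res.ks == pytest.approx(0.0656656, abs=1e-6)
        assert res.pco2_air == pytest.approx(397.629, abs=1e-2)
        assert res.flux == pytest.approx(-7.98898, abs=1e-4)

    def test_linear_in_dpco2(self):
        fd = _forcing()
        p_air = pco2_air(fd, 0.0, 32.0)
        f1 = co2_flux(p_air - 50.0, 0.0, 32.0, fd).flux
        f2 = co2_flux(p_air - 100.0, 0.0, 32.0, fd).flux
        assert f2 == pytest.approx(2.0 * f1)

    def test_ice_cap_invariant(self):
        f0 = co2_flux(300.0, 0.0, 32.0, _forcing(ice=0.0)).flux
        f95 = co2_flux(300.0, 0.0, 32.0, _forcing(ice=95.0)).flux
        f100 = co2_flux(300.0, 0.0, 32.0, _forcing(ice=100.0)).flux
        assert f95 == pytest.approx(f100) == pytest.approx(0.1 * f0)

    def test_unit_factor_dimensional_analysis(self):
        # (cm/hr -> m/d) * (mol/L -> mol/m3) * (uatm -> atm) * (mol -> mmol)
        assert cst.FLUX_UNIT_FACTOR == pytest.approx(0.01 * 24 * 1e3 * 1e-6 * 1e3)

    def test_nonfinite_cell_rejected(self):
        with pytest.raises(ValueError):
            co2_flux(float("nan"), 0.0, 32.0, _forcing())


class TestFluxForCells:
    def test_join_and_missing_forcing(self):
        cells = pd.DataFrame({"day": [150, 151], "mean_pco2": [300.0, 300.0],
                              "mean_sst": [0.0, 0.0], "mean_sss": [32.0, 32.0]})
        forcing = pd.DataFrame({"day": [150, 151], "u10_sq": [49.0, 49.0],
                                "ice_pct": [0.0, 0.0], "psl": [1.0, 1.0],
                                "xco2": [400.0, 400.0]})
        out = flux_for_cells(cells, forcing)
        assert np.isfinite(out["flux"]).all()
        with pytest.raises(ValueError, match="151"):
            flux_for_cells(cells, forcing.iloc[:1])


class TestRegionalFluxTable:
    def _cohort(self, rng, acw_mean, non_mean, sd=2.0, n=20):
        return pd.DataFrame({
            "region": "southern", "period": "early_summer",
            "group": ["ACW"] * n + ["nonACW"] * n,
            "flux": np.concatenate([rng.normal(acw_mean, sd, n),
                                    rng.normal(non_mean, sd, n)]),
        })

    def test_known_separation_flags_significant(self):
        rng = np.random.default_rng(11)
        table = regional_flux_table(self._cohort(rng, -14.0, -22.0))
        row = table.iloc[0]
        assert row["p_value"] < 0.001
        assert row["significance"] == "***"
        assert row["acw_mean"] == pytest.approx(-14.0, abs=2.0)
        assert row["nonacw_n"] == 20

    def test_null_rarely_flags(self):
        flagged = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            table = regional_flux_table(self._cohort(rng, -15.0, -15.0))
            if table.iloc[0]["significance"] != "ns":
                flagged += 1
        assert flagged <= 10  # alpha = 0.05, 100 draws

    def test_single_member_group_skips_test(self):
        df = pd.DataFrame({"region": "southern", "period": "fall",
                           "group": ["ACW", "nonACW", "nonACW"],
                           "flux": [-10.0, -20.0, -21.0]})
        row = regional_flux_table(df).iloc[0]
        assert row["significance"] == "skipped"
        assert np.isnan(row["p_value"])
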