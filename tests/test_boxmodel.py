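"""Mixed-layer DIC box model: budget closure, scenario ordering, limits."""

import numpy as np
import pandas as pd
import pytest

from chukchi_carbon import constants as cst
from chukchi_carbon import boxmodel as bx
from chukchi_carbon.carbonate import CarbParams, density, pco2_from_ta_dic
from chukchi_carbon.synthetic import ScenarioSpec, make_forcing


def _flat_forcing(days=range(136, 160), sst=0.0, sss=32.0, ta=2200.0,
                  u2=0.0, ice=0.0, ncp=0.0):
    days = list(days)
    return pd.DataFrame({
        "day": days, "sst": sst, "sss": sss, "ta_interp": ta,
        "u10_sq": u2, "ice_pct": ice, "psl": 1.0, "xco2": 400.0,
        "ncp_n_daily": ncp,
    })


@pytest.fixture(scope="module")
def forcing_pair():
    spec = ScenarioSpec(seed=3, noise=0.0)
    return {region: make_forcing(spec, region) for region in ("southern", "northern")}


class TestStepArithmetic:
    def test_no_forcing_keeps_dic_constant(self):
        fc = _flat_forcing()
        fc["sst"] = np.linspace(0.0, 4.0, len(fc))  # warming only
        scen = bx.ScenarioConfig(region="southern", t_start=136, t_end=159)
        traj = bx.run(scen, fc, init=(2200.0, 2000.0))
        assert traj["dic"].std() == pytest.approx(0.0, abs=1e-12)
        assert traj["pco2"].iloc[-1] > traj["pco2"].iloc[0]  # thermal rise only

    def test_biological_term_arithmetic(self):
        fc = _flat_forcing(ncp=1.0)
        scen = bx.ScenarioConfig(cn_ratio=6.6, region="southern",
                                 t_start=136, t_end=137)
        traj = bx.run(scen, fc, init=(2200.0, 2000.0))
        rho = density(0.0, 32.0)
        expected = -6.6 / (25.0 * rho / 1000.0)
        assert traj["d_ncp"].iloc[1] == pytest.approx(expected)
        assert expected == pytest.approx(-0.2576, abs=0.001)

    def test_dilution_proportionality(self):
        fc = _flat_forcing()
        days = fc["day"].to_numpy()
        fc["ta_interp"] = np.where(days <= 136, 2200.0, 2200.0 * 0.99)
        scen = bx.ScenarioConfig(region="southern", t_start=136, t_end=137)
        traj = bx.run(scen, fc, init=(2200.0, 2000.0))
        assert traj["d_dilution"].iloc[1] == pytest.approx(-20.0)


class TestRunProperties:
    def test_budget_closure(self, forcing_pair):
        scen = bx.ScenarioConfig(cn_ratio=10.9, region="southern")
        traj = bx.run(scen, forcing_pair["southern"])
        b = traj.attrs["budget"]
        closure = (traj["dic"].iloc[-1] - traj["dic"].iloc[0]
                   - sum(b.values()))
        assert abs(closure) <= 1e-9

    def test_cumulative_uptake_is_flux_integral(self, forcing_pair):
        scen = bx.ScenarioConfig(cn_ratio=10.9, region="southern")
        traj = bx.run(scen, forcing_pair["southern"])
        assert traj.attrs["cum_uptake"] == pytest.approx(
            -traj["flux"].iloc[1:].sum(), abs=1e-9)

    def test_nonredfield_exceeds_redfield(self, forcing_pair):
        for region, cn in (("southern", 10.9), ("northern", 12.1)):
            runs = [bx.run(bx.ScenarioConfig(cn_ratio=c, region=region),
                           forcing_pair[region])
                    for c in (cst.REDFIELD_CN, cn)]
            assert runs[1].attrs["cum_uptake"] > runs[0].attrs["cum_uptake"]
            assert runs[1]["dic"].iloc[-1] < runs[0]["dic"].iloc[-1]

    def test_uptake_monotone_in_cn(self, forcing_pair):
        uptakes = [bx.run(bx.ScenarioConfig(cn_ratio=cn, region="northern"),
                          forcing_pair["northern"]).attrs["cum_uptake"]
                   for cn in (6.6, 9.0, 12.1)]
        assert uptakes[0] < uptakes[1] < uptakes[2]

    def test_redfield_limit_equals_fixed_stoichiometry(self, forcing_pair):
        a = bx.run(bx.ScenarioConfig(cn_ratio=cst.REDFIELD_CN, region="southern",
                                     caco3_correction=False),
                   forcing_pair["southern"])
        b = bx.run(bx.ScenarioConfig(cn_ratio=cst.REDFIELD_CN, region="southern",
                                     caco3_correction=True, caco3_daily=0.0),
                   forcing_pair["southern"])
        assert np.allclose(a["dic"], b["dic"])

    def test_operator_order_effect_below_half_umol(self, forcing_pair):
        """Applying the daily terms sequentially (each on the updated DIC)
        instead of simultaneously changes the final DIC by < 0.5 umol/kg."""
        from chukchi_carbon.flux import ForcingDay, co2_flux
        scen = bx.ScenarioConfig(cn_ratio=10.9, region="southern")
        fc = forcing_pair["southern"].set_index("day")
        traj = bx.run(scen, forcing_pair["southern"])
        ta, dic = traj["ta"].iloc[0], traj["dic"].iloc[0]
        for day in range(scen.t_start, scen.t_end):
            row = fc.loc[day]
            rho = density(row.sst, row.sss)
            per_kg = scen.mld * rho / 1000.0
            pco2 = pco2_from_ta_dic(ta, dic, CarbParams(row.sst, row.sss))
            fd = ForcingDay(day=day, u10_sq=row.u10_sq, ice_pct=row.ice_pct,
                            psl=row.psl, xco2=row.xco2)
            dic = dic - co2_flux(pco2, row.sst, row.sss, fd).flux / per_kg
            dic = dic - row.ncp_n_daily * scen.cn_ratio / per_kg
            ta_next = fc.loc[day + 1, "ta_interp"]
            dic = dic + (ta_next - ta) / ta * dic   # dilution on updated DIC
            ta = ta_next
        assert abs(dic - traj["dic"].iloc[-1]) < 0.5

    def test_forcing_gap_reported(self, forcing_pair):
        fc = forcing_pair["southern"]
        broken = fc[fc["day"] != 150]
        with pytest.raises(ValueError, match="150"):
            bx.run(bx.ScenarioConfig(region="southern"), broken)


class TestScenarioCompare:
    def test_reported_totals_arithmetic(self, forcing_pair):
        """Enhancement/share arithmetic reproduces the published derived
        percentages from the published uptake totals."""
        traj = bx.run(bx.ScenarioConfig(region="southern"), forcing_pair["southern"])
        a, b = traj.copy(), traj.copy()
        a.attrs["cum_uptake"], b.attrs["cum_uptake"] = 751.0, 528.0
        comp = bx.scenario_compare(a, b)
        assert comp["enhancement_pct"] == pytest.approx(42.2, abs=0.1)
        assert comp["share_pct"] == pytest.approx(29.7, abs=0.1)
        a.attrs["cum_uptake"], b.attrs["cum_uptake"] = 343.0, 185.0
        comp = bx.scenario_compare(a, b)
        assert comp["enhancement_pct"] == pytest.approx(85.4, abs=0.1)
        assert comp["share_pct"] == pytest.approx(46.1, abs=0.1)

    def test_equal_runs_zero(self, forcing_pair):
        traj = bx.run(bx.ScenarioConfig(region="southern"), forcing_pair["southern"])
        comp = bx.scenario_compare(traj, traj)
        assert comp["enhancement_pct"] == 0.0 and comp["share_pct"] == 0.0

    def test_mismatched_windows_rejected(self, forcing_pair):
        s = bx.run(bx.ScenarioConfig(region="southern"), forcing_pair["southern"])
        n = bx.run(bx.ScenarioConfig(region="northern"), forcing_pair["northern"])
        with pytest.raises(ValueError):
            bx.scenario_compare(s, n)


def test_invalid_scenarios_rejected():
    with pytest.raises(ValueError):
        bx.ScenarioConfig(region="southern", t_start=200, t_end=150)
    with pytest.raises(ValueError):
        bx.ScenarioConfig(region="atlantis")
    with pytest.raises(ValueError):
        bx.ScenarioConfig(region="southern", tau=0.5)
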