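"""Percent-of-control normalization, ratio curves, and format-comparison flags."""

import numpy as np
import pandas as pd
import pytest

from cycleplate.doseresponse import LogisticFit, fit_4pl_robust
from cycleplate.platecompare import (
    Censored,
    compare_formats,
    mito_fold_change,
    normalize_readout,
    normalize_wells,
    ratio_curve,
    total_mito_mass,
)
from cycleplate.simulate import NoiseModel, builtin_scenarios, simulate_dose_plate


def _fit(log_ec50, emax, valid=True):
    return LogisticFit(bottom=100.0 - emax, top=100.0, log_ec50=log_ec50, hill=1.0,
                       span=emax, rmse_robust=5.0, se_log_ec50=0.1, loss=0.0,
                       converged=True, valid=valid)


class TestNormalizeReadout:
    def test_control_value_maps_to_100(self):
        pct, bg = normalize_readout([8.0], [8.0, 8.0])
        assert pct[0] == 100.0 and bg == 0.0

    def test_blank_subtraction_arithmetic(self):
        # raw 0.5, blank 0.1, control-minus-blank mean 0.8 -> 50 %
        pct, bg = normalize_readout([0.5], [0.9, 0.9], blank_raw=[0.1],
                                    subtract_background=True)
        assert bg == pytest.approx(0.1)
        assert pct[0] == pytest.approx(50.0)

    def test_missing_blanks_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            normalize_readout([1.0], [1.0, 1.0], subtract_background=True)

    def test_control_below_background_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_readout([1.0], [0.05, 0.05], blank_raw=[0.1],
                              subtract_background=True)

    def test_control_centering_exact(self):
        rng = np.random.default_rng(0)
        ctrl = rng.uniform(5, 15, 8)
        pct, _ = normalize_readout(ctrl, ctrl)
        assert pct.mean() == pytest.approx(100.0, abs=1e-12)


class TestNormalizeWells:
    def test_simulator_plate_controls_center_at_100(self, default_noise):
        sc = builtin_scenarios()["mitotic_arrest"]
        plate = simulate_dose_plate(sc.compound, sc.growth, sc.concentrations[:8],
                                    2, default_noise)
        norm = normalize_wells(plate.wells)
        ctrl = norm[norm["is_control"]]
        for col in ("atp_pct", "mts_pct", "cyquant_pct", "count_pct"):
            assert ctrl[col].mean() == pytest.approx(100.0, abs=1e-9)
        assert not norm["is_blank"].any()


class TestRatioCurve:
    def test_identity_ratio_is_one(self):
        df = pd.DataFrame({"conc_molar": [1e-8, 1e-7, 1e-6], "pct": [90.0, 60.0, 30.0]})
        rc = ratio_curve(df, df)
        assert np.allclose(rc["fold_change"], 1.0)

    def test_disjoint_concentrations_rejected(self):
        a = pd.DataFrame({"conc_molar": [1e-8], "pct": [90.0]})
        b = pd.DataFrame({"conc_molar": [1e-7], "pct": [90.0]})
        with pytest.raises(ValueError, match="no concentrations"):
            ratio_curve(a, b)

    def test_near_total_kill_doses_excluded(self):
        sig = pd.DataFrame({"conc_molar": [1e-8, 1e-7], "pct": [50.0, 10.0]})
        cnt = pd.DataFrame({"conc_molar": [1e-8, 1e-7], "pct": [50.0, 0.5]})
        rc = ratio_curve(sig, cnt)
        assert len(rc) == 1 and rc["conc_molar"][0] == 1e-8

    def test_size_doubling_arrest_plateaus_near_two(self, default_noise):
        """G2/M arrest with 2x enlargement: ATP/count ratio plateaus near 2."""
        sc = builtin_scenarios()["mitotic_arrest"]
        plate = simulate_dose_plate(sc.compound, sc.growth, sc.concentrations,
                                    sc.wells_per_conc, default_noise)
        norm = normalize_wells(plate.wells)
        treated = norm[norm["conc_molar"] > 0]
        rc = ratio_curve(
            treated[["conc_molar", "atp_pct"]].rename(columns={"atp_pct": "pct"}),
            treated[["conc_molar", "count_pct"]].rename(columns={"count_pct": "pct"}),
        )
        plateau = rc["fold_change"].iloc[-3:].mean()
        assert plateau == pytest.approx(2.0, abs=0.35)
        assert rc["fold_change"].iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_arrest_then_apoptosis_gives_bell_shape(self, default_noise):
        """Biphasic arrest -> sub-G1 switch: ratio rises then collapses."""
        sc = builtin_scenarios()["dna_damage_biphasic"]
        plate = simulate_dose_plate(sc.compound, sc.growth, sc.concentrations,
                                    sc.wells_per_conc, default_noise)
        norm = normalize_wells(plate.wells)
        treated = norm[norm["conc_molar"] > 0]
        rc = ratio_curve(
            treated[["conc_molar", "atp_pct"]].rename(columns={"atp_pct": "pct"}),
            treated[["conc_molar", "count_pct"]].rename(columns={"count_pct": "pct"}),
        )
        f = rc["fold_change"].to_numpy()
        assert f[0] == pytest.approx(1.0, abs=0.15)
        assert f.max() > 1.8
        assert f[-1] < 0.85 * f.max()


class TestTotalMitoMass:
    def test_unit_fold_reproduces_count_series(self):
        cp = pd.Series({"A01": 100.0, "A02": 100.0, "B01": 50.0})
        mf = pd.Series({"A01": 1.0, "A02": 1.0, "B01": 1.0})
        tm = total_mito_mass(cp, mf, ["A01", "A02"])
        assert tm["B01"] == pytest.approx(50.0)

    def test_product_arithmetic(self):
        cp = pd.Series({"A01": 100.0, "A02": 100.0, "B01": 50.0})
        mf = pd.Series({"A01": 1.0, "A02": 1.0, "B01": 2.0})
        tm = total_mito_mass(cp, mf, ["A01", "A02"])
        assert tm["B01"] == pytest.approx(100.0)

    def test_tracks_atp_curve_under_coupled_generation(self, default_noise):
        """Size-coupled mito and ATP generation: curves correlate > 0.99."""
        sc = builtin_scenarios()["mitotic_arrest"]
        plate = simulate_dose_plate(sc.compound, sc.growth, sc.concentrations,
                                    sc.wells_per_conc, default_noise)
        norm = normalize_wells(plate.wells).set_index("well")
        ctrl_wells = plate.wells.loc[plate.wells["is_control"], "well"].tolist()
        mf = mito_fold_change(plate.cells, ctrl_wells)
        tm = total_mito_mass(norm["count_pct"], mf, ctrl_wells)
        joined = pd.DataFrame(
            {"tm": tm, "atp": norm["atp_pct"], "conc": norm["conc_molar"]}
        ).dropna()
        curves = joined.groupby("conc").mean()
        assert np.corrcoef(curves["tm"], curves["atp"])[0, 1] > 0.99


class TestCompareFormats:
    def test_large_ec50_shift_flagged(self):
        res = compare_formats(_fit(-6.8, 79.0), _fit(-4.5, 80.0))
        assert res.delta_log_ec50 == pytest.approx(2.3)
        assert res.ec50_flag and not res.emax_flag

    def test_censored_emax_flagged_conservatively(self):
        # count Emax 74 vs proxy "<20": gap at least 54 points
        res = compare_formats(_fit(-8.7, 74.0), (None, Censored(20.0, "<")))
        assert res.emax_flag

    def test_censored_ec50_bound_guarantees_flag(self):
        res = compare_formats(-8.7, ">-4.6")
        assert res.ec50_flag

    def test_identical_fits_unflagged(self):
        res = compare_formats(_fit(-6.8, 79.0), _fit(-6.8, 79.0))
        assert not res.ec50_flag and not res.emax_flag
        assert res.delta_log_ec50 == 0.0 and res.delta_emax == 0.0

    def test_invalid_proxy_fit_raises_both_flags(self):
        res = compare_formats(_fit(-6.8, 79.0), _fit(-5.0, 50.0, valid=False))
        assert res.ec50_flag and res.emax_flag and res.reason == "no valid fit"

    def test_invalid_count_fit_yields_no_flags(self):
        res = compare_formats(_fit(-6.8, 79.0, valid=False), _fit(-5.0, 50.0))
        assert not res.ec50_flag and not res.emax_flag
        assert "count" in res.reason

    @pytest.mark.parametrize(
        "c_ec,c_em,p_ec,p_em,exp_ec_flag,exp_em_flag",
        [
            # count vs ATP rows shaped like a published comparison table
            (-6.8, 79.0, -4.5, 80.0, True, False),    # 2.3-log right shift, same Emax
            (-8.7, 74.0, ">-4.6", "<20", True, True),  # censored: gaps >=4.1 / >=54
            (-8.3, 73.0, -8.1, 47.0, False, True),    # 26-point Emax gap only
            (-6.0, 50.0, -6.2, 52.0, False, False),   # concordant pair
        ],
    )
    def test_flags_recomputed_from_table_shaped_fixture(
        self, c_ec, c_em, p_ec, p_em, exp_ec_flag, exp_em_flag
    ):
        """Threshold flags agree with direct recomputation on a published-style
        comparison table (count vs ATP log EC50 / Emax, censored entries)."""
        proxy = (
            _fit(p_ec, p_em)
            if isinstance(p_ec, float)
            else (Censored.parse(p_ec), Censored.parse(p_em))
        )
        res = compare_formats(_fit(c_ec, c_em), proxy)
        assert res.ec50_flag == exp_ec_flag
        assert res.emax_flag == exp_em_flag


class TestCensored:
    def test_parse_forms(self):
        assert Censored.parse(">-4.6") == Censored(-4.6, ">")
        assert Censored.parse("< 20") == Censored(20.0, "<")
        with pytest.raises(ValueError):
            Censored.parse("about 5")
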