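import math

import numpy as np
import pandas as pd
import pytest

from hmrisk import core, synth
from hmrisk.sediment import (
    background_ratio_table,
    contamination_factor,
    ecological_risk,
    er_by_site,
    igeo,
    igeo_table,
    potential_risk,
    risk_index,
    sqg_screen,
)


class TestContaminationFactor:
    def test_at_background_is_one(self):
        assert contamination_factor(11.1, 11.1) == 1.0

    def test_cd_enrichment(self):
        assert contamination_factor(0.512, 0.113) == pytest.approx(4.53, abs=0.005)

    def test_pb_enrichment(self):
        assert contamination_factor(32.99, 20.0) == pytest.approx(1.65, abs=0.005)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(core.ValidationError):
            contamination_factor(1.0, 0.0)


class TestPotentialRisk:
    def test_zero_cf(self):
        assert potential_risk(0.0, 30.0) == 0.0

    def test_cd_worked_value(self):
        assert potential_risk(0.512 / 0.113, 30.0) == pytest.approx(135.93, abs=0.005)

    def test_ni_worked_value(self):
        assert potential_risk(42.07 / 28.0, 5.0) == pytest.approx(7.51, abs=0.005)

    def test_negative_tr_rejected(self):
        with pytest.raises(core.ValidationError):
            potential_risk(1.0, -1.0)


class TestRiskIndex:
    def test_single_metal_identity(self):
        assert risk_index({"Cd": 135.93}) == 135.93

    def test_permutation_invariant(self, sediment_means, standards):
        eco = ecological_risk(sediment_means, standards)
        shuffled = eco.er.sample(frac=1.0, random_state=0)
        assert risk_index(shuffled) == pytest.approx(eco.ri, rel=1e-12)

    def test_subset_never_exceeds_superset(self, sediment_means, standards):
        eco = ecological_risk(sediment_means, standards)
        assert risk_index(eco.er.drop("Cd")) <= eco.ri

    def test_empty_set_rejected(self):
        with pytest.raises(core.ValidationError):
            risk_index({})

    def test_survey_means_ri(self, sediment_means, standards):
        """RI from the published means; 175.7966 frozen from the independent
        per-metal Tr*C/Bn sum (printed value 175.82 is the sum of the
        survey's own rounded Er values)."""
        eco = ecological_risk(sediment_means, standards)
        assert eco.ri == pytest.approx(175.7966, abs=1e-3)
        assert eco.ri_label == "moderate"


class TestIgeo:
    def test_zero_at_corrected_background(self):
        assert igeo(1.5 * 20.0, 20.0) == 0.0

    def test_one_at_twice_corrected_background(self):
        assert igeo(3.0 * 20.0, 20.0) == 1.0

    def test_cd_means_match_log_oracle(self):
        assert igeo(0.512, 0.113) == pytest.approx(math.log2(0.512 / 0.1695), abs=1e-12)

    def test_v_means(self):
        assert igeo(95.65, 75.0) == pytest.approx(-0.234088, abs=1e-6)

    def test_strictly_increasing_in_concentration(self):
        c = np.linspace(0.01, 10.0, 50)
        vals = igeo(c, 1.0)
        assert (np.diff(vals) > 0).all()

    def test_nondetect_maps_to_flagged_sentinel(self, standards):
        df = pd.DataFrame({"Cd": [0.0, 0.5]}, index=["A", "B"])
        res = igeo_table(core.ConcentrationTable(df, core.Medium.SEDIMENT), standards)
        assert np.isneginf(res.values.loc["A", "Cd"])
        assert ("A", "Cd") in res.provenance["nondetect_sentinels"]

    def test_invalid_background_rejected(self):
        with pytest.raises(core.ValidationError):
            igeo(1.0, 0.0)


class TestLinearityOracle:
    def test_mean_site_er_equals_er_of_means(self, gen_spec, standards):
        """Er is linear in concentration, so per-site averaging commutes with
        the index; the moment-calibrated table therefore reproduces the
        published lake-level Er values exactly."""
        t = synth.generate_concentrations(gen_spec, "sediment", seed=2)
        res = er_by_site(t, standards)
        eco = ecological_risk(t.mean(), standards)
        assert np.allclose(res.values.mean(axis=0), eco.er[res.values.columns])
        assert res.summary["Er_means"]["Cd"] == pytest.approx(135.93, abs=0.01)


class TestSqgScreen:
    def _table(self, values, metal="Ni"):
        df = pd.DataFrame({metal: values}, index=[f"S{i}" for i in range(len(values))])
        return core.ConcentrationTable(df, core.Medium.SEDIMENT)

    def test_all_below_tel(self, standards):
        res = sqg_screen(self._table([1.0, 2.0]), standards)
        assert res.values.loc["Ni", "frac_above_tel"] == 0.0
        assert res.values.loc["Ni", "frac_above_pel"] == 0.0

    def test_counting_oracle(self):
        std = core.ReferenceStandards(tel={"Ni": 2.5}, pel={"Ni": 10.0})
        res = sqg_screen(self._table([1.0, 2.0, 3.0, 4.0]), std)
        assert res.values.loc["Ni", "frac_above_tel"] == 0.5
        assert res.values.loc["Ni", "frac_above_pel"] == 0.0

    def test_fractions_weakly_decrease_when_thresholds_rise(self):
        vals = [1.0, 2.0, 3.0, 4.0, 8.0, 12.0]
        lo = core.ReferenceStandards(tel={"Ni": 2.5}, pel={"Ni": 5.0})
        hi = core.ReferenceStandards(tel={"Ni": 3.5}, pel={"Ni": 9.0})
        res_lo = sqg_screen(self._table(vals), lo).values
        res_hi = sqg_screen(self._table(vals), hi).values
        assert res_hi.loc["Ni", "frac_above_tel"] <= res_lo.loc["Ni", "frac_above_tel"]
        assert res_hi.loc["Ni", "frac_above_pel"] <= res_lo.loc["Ni", "frac_above_pel"]

    def test_metal_without_thresholds_skipped_with_warning(self, standards):
        with pytest.warns(UserWarning, match="Co"):
            res = sqg_screen(self._table([1.0, 2.0], metal="Co"), standards)
        assert "Co" in res.summary["skipped"]

    def test_synthetic_survey_screening_is_qualitatively_reproduced(
        self, gen_spec, standards
    ):
        """Most Ni sites and roughly half the Zn sites exceed TEL; nothing
        exceeds PEL (the survey's screening finding)."""
        t = synth.generate_concentrations(gen_spec, "sediment", seed=0)
        res = sqg_screen(t, standards)
        assert res.values.loc["Ni", "frac_above_tel"] > 0.8
        assert 0.2 < res.values.loc["Zn", "frac_above_tel"] < 0.8
        assert (res.values["frac_above_pel"].dropna() == 0.0).all()


class TestBackgroundRatios:
    def test_survey_ratio_list(self, sediment_means, standards):
        ratios = background_ratio_table(sediment_means, standards)
        expected = {
            "Cd": 4.53, "Co": 1.67, "Pb": 1.65, "Cu": 1.58, "Ni": 1.50,
            "Zn": 1.34, "Mn": 1.33, "Cr": 1.31, "V": 1.28,
        }
        for metal, val in expected.items():
            assert ratios[metal] == pytest.approx(val, abs=0.005), metal
        assert list(ratios.index) == list(expected)  # descending order

    def test_metal_at_background_has_ratio_one(self, standards):
        ratios = background_ratio_table({"Cd": 0.113}, standards)
        assert ratios["Cd"] == pytest.approx(1.0)
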