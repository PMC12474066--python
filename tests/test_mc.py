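import numpy as np
import pytest

from hmrisk import core
from hmrisk.health import assess
from hmrisk.mc import ParameterDistribution, convergence_check, run_mc, sensitivity


@pytest.fixture()
def point_dists(sediment_means):
    return {
        f"C:{m}": ParameterDistribution(f"C:{m}", "point", (float(v),))
        for m, v in sediment_means.items()
    }


class TestRunMc:
    def test_point_masses_reproduce_deterministic_result(
        self, point_dists, sediment_means, standards, receptors
    ):
        run = run_mc(standards, receptors["child"], point_dists, n=50, seed=0)
        det = assess(sediment_means, standards, receptors["child"])
        tehi = run.results["TEHI:child"]
        tcri = run.results["TCRI:child"]
        assert np.ptp(tehi.samples) == 0.0
        assert tehi.mean == pytest.approx(det.tehi, rel=1e-12)
        assert tcri.mean == pytest.approx(det.tcri, rel=1e-12)

    def test_point_mass_below_threshold_has_zero_exceedance(
        self, point_dists, standards, receptors
    ):
        run = run_mc(standards, receptors["child"], point_dists, n=20, seed=0)
        assert run.results["TEHI:child"].exceedance[1.0] == 0.0
        assert run.results["TCRI:child"].exceedance[1e-4] == 0.0

    def test_same_seed_reproduces_samples_exactly(self, standards, receptors):
        dists = {"C:Cd": ParameterDistribution("C:Cd", "lognormal", (0.512, 0.23))}
        a = run_mc(standards, receptors["child"], dists, n=500, seed=42)
        b = run_mc(standards, receptors["child"], dists, n=500, seed=42)
        assert np.array_equal(
            a.results["TCRI:child"].samples, b.results["TCRI:child"].samples
        )

    def test_linear_output_mean_within_3se_of_closed_form(self, standards, receptors):
        """TCRI is linear in C, so E[TCRI] equals the deterministic TCRI at
        the distribution mean; the MC mean must sit within 3 standard errors."""
        dists = {"C:Cd": ParameterDistribution("C:Cd", "lognormal", (0.512, 0.23))}
        run = run_mc(standards, receptors["child"], dists, n=10_000, seed=1)
        res = run.results["TCRI:child"]
        analytic = assess(
            {"Cd": 0.512}, standards, receptors["child"], carcinogens=["Cd"]
        ).tcri
        se = res.samples.std(ddof=1) / np.sqrt(res.n)
        assert abs(res.mean - analytic) < 3 * se

    def test_seed_to_seed_means_agree_within_mc_error(self, standards, receptors):
        dists = {"C:Cd": ParameterDistribution("C:Cd", "lognormal", (0.512, 0.23))}
        a = run_mc(standards, receptors["child"], dists, n=10_000, seed=2)
        b = run_mc(standards, receptors["child"], dists, n=10_000, seed=3)
        ra, rb = a.results["TCRI:child"], b.results["TCRI:child"]
        se = np.hypot(ra.samples.std(ddof=1), rb.samples.std(ddof=1)) / np.sqrt(ra.n)
        assert abs(ra.mean - rb.mean) < 3 * se

    def test_percentiles_monotone(self, standards, receptors):
        dists = {"C:Cd": ParameterDistribution("C:Cd", "lognormal", (0.512, 0.23))}
        run = run_mc(standards, receptors["child"], dists, n=2000, seed=0)
        p = run.results["TEHI:child"].percentiles
        assert p[5.0] <= p[50.0] <= p[95.0]

    def test_shrinking_sd_converges_to_deterministic(self, standards, receptors):
        det = assess({"Cd": 0.512}, standards, receptors["child"], carcinogens=["Cd"]).tcri
        gaps = []
        for sd in (0.2, 0.02, 0.002):
            dists = {"C:Cd": ParameterDistribution("C:Cd", "lognormal", (0.512, sd))}
            run = run_mc(standards, receptors["child"], dists, n=4000, seed=5)
            gaps.append(abs(run.results["TCRI:child"].mean - det))
        assert gaps[2] < gaps[0]
        assert gaps[2] / det < 1e-3

    def test_invalid_parameter_draw_aborts_with_name(self, standards, receptors):
        dists = {
            "C:Cd": ParameterDistribution("C:Cd", "point", (0.5,)),
            "BW": ParameterDistribution("BW", "normal", (0.1, 2.0), bounds=(None, 5.0)),
        }
        with pytest.raises((core.ValidationError,), match="BW"):
            run_mc(standards, receptors["child"], dists, n=200, seed=0)

    def test_unmapped_parameter_rejected(self, standards, receptors):
        dists = {
            "C:Cd": ParameterDistribution("C:Cd", "point", (0.5,)),
            "XYZ": ParameterDistribution("XYZ", "point", (1.0,)),
        }
        with pytest.raises(core.ConfigurationError, match="XYZ"):
            run_mc(standards, receptors["child"], dists, n=10, seed=0)


class TestParameterDistribution:
    def test_truncation_respected(self):
        d = ParameterDistribution("BW", "normal", (15.0, 5.0), bounds=(8.0, 30.0))
        x = d.sample(np.random.default_rng(0), 5000)
        assert x.min() >= 8.0 and x.max() <= 30.0

    def test_lognormal_matches_arithmetic_moments(self):
        d = ParameterDistribution("C", "lognormal", (0.512, 0.23))
        x = d.sample(np.random.default_rng(1), 200_000)
        assert x.mean() == pytest.approx(0.512, rel=0.01)
        assert x.std() == pytest.approx(0.23, rel=0.05)

    def test_invalid_laws_rejected(self):
        with pytest.raises(core.ConfigurationError):
            ParameterDistribution("x", "beta", (1.0, 2.0))
        with pytest.raises(core.ConfigurationError):
            ParameterDistribution("x", "uniform", (2.0, 1.0))
        with pytest.raises(core.ConfigurationError):
            ParameterDistribution("x", "triangular", (3.0, 1.0, 2.0))


class TestConvergence:
    def test_constant_samples_converge_immediately(self):
        rep = convergence_check(np.full(100, 3.0), batch=10)
        assert rep["converged"]
        assert rep["p95_rel_change"] == 0.0

    def test_standard_normal_running_mean_near_zero(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        rep = convergence_check(x, batch=1000)
        assert abs(rep["running_mean"][-1]) < 0.05

    def test_tiny_heavy_tailed_sample_not_converged(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1000.0])
        rep = convergence_check(x, batch=5)
        assert not rep["converged"]

    def test_needs_two_batches(self):
        with pytest.raises(core.ValidationError):
            convergence_check(np.ones(5), batch=5)


class TestSensitivity:
    def test_single_driver_takes_all(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=2000)
        other = np.full(2000, 7.0)
        df = sensitivity({"x": x, "c": other}, x)
        assert df.loc["x", "contribution"] == pytest.approx(100.0)
        assert df.loc["c", "contribution"] == 0.0
        assert df.loc["c", "flag"] == "zero-variance"

    def test_two_iid_drivers_split_evenly(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 10_000))
        df = sensitivity({"x": x, "y": y}, x + y)
        assert df.loc["x", "contribution"] == pytest.approx(50.0, abs=5.0)
        assert df.loc["y", "contribution"] == pytest.approx(50.0, abs=5.0)

    def test_negative_driver_keeps_sign(self):
        x = np.random.default_rng(2).standard_normal(500)
        df = sensitivity({"x": x}, -x)
        assert df.loc["x", "contribution"] == pytest.approx(-100.0)

    def test_absolute_contributions_sum_to_100(self):
        rng = np.random.default_rng(3)
        x, y, z = rng.standard_normal((3, 3000))
        df = sensitivity({"x": x, "y": y, "z": z}, 2 * x - y + 0.1 * z)
        assert df["contribution"].abs().sum() == pytest.approx(100.0, abs=1e-9)

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(4)
        x, y = rng.lognormal(size=(2, 2000))
        out = x + y
        a = sensitivity({"x": x, "y": y}, out)
        b = sensitivity({"x": np.log(x), "y": y**3}, out)
        assert np.allclose(
            a["contribution"].sort_index(), b["contribution"].sort_index(), atol=1e-9
        )
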