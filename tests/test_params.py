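"""Distribution moment matching, sampling and parameter-file validation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iemscreen.params import (
    AgeBand,
    AgeBandedValue,
    Family,
    InfeasibleVarianceError,
    ParamDist,
    SchemaError,
    fixed,
    load_parameters,
    lognormal_from_mean_se,
    moment_match_beta,
    moment_match_gamma,
)


class TestMomentMatching:
    def test_beta_uniform_case(self):
        a, b = moment_match_beta(0.5, math.sqrt(1 / 12))
        assert a == pytest.approx(1.0) and b == pytest.approx(1.0)

    def test_beta_high_mean_low_variance(self):
        a, b = moment_match_beta(0.97, 1e-4)
        assert a == pytest.approx(0.97 * (0.97 * 0.03 / 1e-8 - 1), rel=1e-12)
        assert a == pytest.approx(2.8227e6, rel=1e-3)
        assert b == pytest.approx(8.730e4, rel=1e-3)

    def test_beta_infeasible_variance(self):
        with pytest.raises(InfeasibleVarianceError):
            moment_match_beta(0.5, 0.6)

    def test_gamma_screening_cost(self):
        shape, scale = moment_match_gamma(294, 126)
        assert shape == pytest.approx((294 / 126) ** 2, rel=1e-12)
        assert shape == pytest.approx(5.444, rel=1e-3)
        assert scale == pytest.approx(54.0, rel=1e-12)

    def test_gamma_exponential_case(self):
        assert moment_match_gamma(1, 1) == pytest.approx((1.0, 1.0))

    @pytest.mark.parametrize("mean,se", [(0, 1), (-1, 1), (1, 0)])
    def test_gamma_domain_errors(self, mean, se):
        with pytest.raises(ValueError):
            moment_match_gamma(mean, se)

    def test_lognormal_degenerate(self):
        assert lognormal_from_mean_se(1, 0) == pytest.approx((0.0, 0.0))

    def test_lognormal_relative_risk(self):
        mu, sigma = lognormal_from_mean_se(0.28, 0.11)
        assert sigma == pytest.approx(math.sqrt(math.log(1 + (0.11 / 0.28) ** 2)), rel=1e-12)
        assert sigma == pytest.approx(0.3789, rel=1e-3)
        assert mu == pytest.approx(-1.3448, rel=1e-3)

    def test_lognormal_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            lognormal_from_mean_se(0.0, 0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(mean=st.floats(0.05, 0.95), frac=st.floats(0.05, 0.9))
    def test_beta_round_trip(self, mean, frac):
        """Matched (alpha, beta) reproduce the requested moments analytically."""
        se = frac * math.sqrt(mean * (1 - mean))
        a, b = moment_match_beta(mean, se)
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1))
        assert m == pytest.approx(mean, rel=1e-10)
        assert v == pytest.approx(se * se, rel=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(mean=st.floats(0.01, 1e6), frac=st.floats(0.01, 5.0))
    def test_gamma_lognormal_round_trip(self, mean, frac):
        se = frac * mean
        shape, scale = moment_match_gamma(mean, se)
        assert shape * scale == pytest.approx(mean, rel=1e-10)
        assert shape * scale**2 == pytest.approx(se * se, rel=1e-10)
        mu, sigma = lognormal_from_mean_se(mean, se)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-10)
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert var == pytest.approx(se * se, rel=1e-8)


class TestSampling:
    def test_fixed_returns_mean(self):
        d = fixed(2349.0)
        assert np.all(d.sample(np.random.default_rng(0), 5) == 2349.0)

    def test_missing_se_treated_as_fixed(self):
        d = ParamDist(Family.gamma, 294.0)
        assert d.is_fixed
        assert np.all(d.sample(np.random.default_rng(0), 3) == 294.0)

    def test_degenerate_beta_mean_is_fixed(self):
        assert ParamDist(Family.beta, 1.0, 0.05).is_fixed
        assert ParamDist(Family.beta, 0.0, 0.05).is_fixed

    def test_same_seed_same_draws(self):
        d = ParamDist(Family.beta, 0.97, 1e-4)
        x = d.sample(np.random.default_rng(12), 10)
        y = d.sample(np.random.default_rng(12), 10)
        assert np.array_equal(x, y)

    @pytest.mark.parametrize("dist,mean,var", [
        (ParamDist(Family.beta, 0.134, 0.0852), 0.134, 0.0852**2),
        (ParamDist(Family.gamma, 294.0, 126.0), 294.0, 126.0**2),
        (ParamDist(Family.lognormal, 0.28, 0.11), 0.28, 0.11**2),
    ])
    def test_empirical_moments(self, dist, mean, var):
        """Sample mean within 3 Monte-Carlo SEs; variance within 5%."""
        n = 1_000_000
        x = dist.sample(np.random.default_rng(2013), n)
        mc_se = math.sqrt(var / n)
        assert abs(x.mean() - mean) < 3 * mc_se
        assert x.var() == pytest.approx(var, rel=0.05)

    def test_log_scale_sampling_is_normal_on_log(self):
        d = ParamDist(Family.lognormal, -2.515, 0.721, log_scale=True)
        x = d.sample(np.random.default_rng(5), 200_000)
        assert x.mean() == pytest.approx(-2.515, abs=3 * 0.721 / math.sqrt(200_000))
        assert x.std() == pytest.approx(0.721, rel=0.02)

    def test_ci_bounds_clamped_to_support(self):
        assert ParamDist(Family.beta, 0.9995, 0.01).ci_bound("upper") == 1.0
        assert ParamDist(Family.gamma, 294.0, 126.0).ci_bound("lower") == pytest.approx(294 - 1.96 * 126)
        assert ParamDist(Family.gamma, 10.0, 50.0).ci_bound("lower") == 0.0


class TestAgeBands:
    def test_bands_must_be_contiguous(self):
        with pytest.raises(ValueError):
            AgeBandedValue((AgeBand(0, 3, fixed(0.1)), AgeBand(4, None, fixed(0.2))))

    def test_last_band_open_ended(self):
        with pytest.raises(ValueError):
            AgeBandedValue((AgeBand(0, 10, fixed(0.1)),))

    def test_lookup_by_age(self):
        b = AgeBandedValue((AgeBand(0, 3, fixed(0.0572)), AgeBand(3, 7, fixed(0.0646)),
                            AgeBand(7, None, fixed(0.0218))))
        got = b.at_ages(np.array([0.0, 2.9, 3.0, 6.9, 7.0, 80.0]))
        assert got == pytest.approx([0.0572, 0.0572, 0.0646, 0.0646, 0.0218, 0.0218])


class TestParameterFile:
    def test_bundled_file_complete(self, pset):
        assert len(pset.diseases) == 6
        assert {d.name for d in pset.diseases} == {"PKU", "IVA", "MMA", "PA", "MSUD", "MCD"}
        assert len(pset.tests) == 2
        assert pset.test("msms").unit_cost_thb.mean == 294.0
        assert pset.disease("MMA").topology == "B"
        assert pset.disease("PA").topology == "C"
        assert pset.settings.threshold_thb_per_qaly == 120_000

    def test_reload_is_idempotent(self, write_params):
        p = write_params()
        assert load_parameters(p) == load_parameters(p)

    def test_out_of_range_utility_rejected(self, write_params):
        def mutate(doc):
            doc["diseases"][0]["utilities"]["well"]["mean"] = 1.2

        with pytest.raises(SchemaError, match="utilities.well"):
            load_parameters(write_params(mutate))

    def test_missing_complication_named_in_error(self, write_params):
        def mutate(doc):
            mma = next(d for d in doc["diseases"] if d["name"] == "MMA")
            del mma["complications"]["renal"]

        with pytest.raises(SchemaError, match="MMA.complications.renal"):
            load_parameters(write_params(mutate))

    def test_band_gap_rejected(self, write_params):
        def mutate(doc):
            mcd = next(d for d in doc["diseases"] if d["name"] == "MCD")
            mcd["complications"]["neurological"][1]["start"] = 4  # gap after end=3

        with pytest.raises(SchemaError, match="MCD.complications.neurological"):
            load_parameters(write_params(mutate))

    def test_errors_are_aggregated(self, write_params):
        def mutate(doc):
            doc["diseases"][0]["utilities"]["well"]["mean"] = 1.2
            doc["diseases"][1]["costs"]["opd_annual"]["mean"] = -5

        with pytest.raises(SchemaError) as exc:
            load_parameters(write_params(mutate))
        assert len(exc.value.errors) >= 2

    def test_formula_band_interpolation(self, pset):
        # a printed range across ages 0..3 becomes a linear per-year schedule
        bands = pset.disease("PKU").costs.formula_annual
        ages = np.arange(6, dtype=float)
        vals = bands.at_ages(ages)
        assert vals[0] == pytest.approx(75511)
        assert vals[3] == pytest.approx(81552)
        assert np.all(np.diff(vals[:4]) > 0)
        assert vals[4] == vals[5] == pytest.approx(45306)
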