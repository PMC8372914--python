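import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ubtcea.params import (
    CI_WIDTH_SD,
    EFFECTIVENESS_CEILING,
    Parameter,
    ParameterFormatError,
    ParameterValidationError,
    derive_sampling_distribution,
    dump_parameter_table,
    load_parameter_table,
    perturb_parameters,
    truncated_beta_mean,
)

HEADER = "name,group,value,low,high,family,units,description\n"


class TestLoadTable:
    def test_single_row(self):
        ps = load_parameter_table(
            HEADER + "p_pph_incidence,probability,0.03606,0.02885,0.04327,beta,,\n"
        )
        assert len(ps) == 1
        assert ps.value("p_pph_incidence") == 0.03606

    def test_empty_data_section_is_empty_set(self):
        assert len(load_parameter_table(HEADER)) == 0

    def test_missing_column_names_it(self):
        with pytest.raises(ParameterFormatError, match="family"):
            load_parameter_table("name,group,value,low,high\nx,cost,1,0,2\n")

    def test_probability_above_one_rejected(self):
        with pytest.raises(ParameterValidationError, match="bad_p"):
            load_parameter_table(HEADER + "bad_p,probability,1.2,0.5,1.5,beta,,\n")

    def test_value_outside_limits_rejected(self):
        with pytest.raises(ParameterValidationError, match="outside limits"):
            load_parameter_table(HEADER + "c,cost,5,10,20,gamma,,\n")

    def test_duplicate_name_rejected(self):
        rows = "c,cost,5,1,20,gamma,,\nc,cost,6,1,20,gamma,,\n"
        with pytest.raises(ParameterValidationError, match="duplicate"):
            load_parameter_table(HEADER + rows)

    def test_wrong_family_for_group_rejected(self):
        with pytest.raises(ParameterValidationError, match="beta or fixed"):
            load_parameter_table(HEADER + "p,probability,0.5,0.4,0.6,gamma,,\n")

    def test_reads_from_stream(self):
        ps = load_parameter_table(io.StringIO(HEADER + "c,cost,5,1,20,gamma,INR,x\n"))
        assert ps["c"].units == "INR"


class TestRoundTrip:
    def test_reference_round_trips_field_by_field(self, ref):
        again = load_parameter_table(dump_parameter_table(ref))
        assert len(again) == len(ref)
        for p in ref:
            q = again[p.name]
            assert p == q

    def test_perturbed_set_round_trips(self, ref):
        ps = perturb_parameters(ref, scale=1.0, seed=3)
        again = load_parameter_table(dump_parameter_table(ps))
        for p in ps:
            assert again[p.name] == p


class TestReferenceFixture:
    @pytest.mark.parametrize(
        "name, value",
        [
            ("deliveries_public", 20_785_669),
            ("cohort_ubt_eligible", 59_962),
            ("p_eff_condom", 0.923),
            ("p_eff_esm", 0.953),
            ("p_eff_bakri", 0.843),
            ("dw_severe_haem", 0.324),
            ("cost_referral", 1001),
            ("cost_training", 375),
            ("cost_oope", 2755),
            ("wtp_per_daly", 24_211),
            ("gdp_per_capita", 127_816),
            ("usd_rate", 64.5),
            ("life_expectancy_remaining", 53.79),
            ("duration_haemorrhage", 0.11),
            ("duration_infertility", 25),
        ],
    )
    def test_lookup(self, ref, name, value):
        assert ref.value(name) == value

    def test_effectiveness_limits(self, ref):
        p = ref["p_eff_condom"]
        assert (p.low, p.high) == (0.738, 0.983)


class TestDeriveSamplingDistribution:
    def test_icu_controlled_beta_moments(self, ref):
        # method-of-moments oracle: mean 0.025, sd (0.030-0.020)/3.92
        spec = derive_sampling_distribution(ref["p_icu_controlled"])
        assert spec.family == "beta"
        m, sd = 0.025, 0.01 / CI_WIDTH_SD
        nu = m * (1 - m) / sd**2 - 1
        assert spec.hyper1 == pytest.approx(m * nu, rel=1e-12)
        assert spec.hyper2 == pytest.approx((1 - m) * nu, rel=1e-12)
        assert spec.hyper1 == pytest.approx(93.614, abs=0.01)
        assert spec.hyper2 == pytest.approx(3650.95, abs=0.1)

    def test_icu_cost_gamma_moments(self, ref):
        spec = derive_sampling_distribution(ref["cost_icu_tertiary"])
        assert spec.family == "gamma"
        sd = (6746 - 3244) / CI_WIDTH_SD
        assert spec.hyper1 == pytest.approx((4896 / sd) ** 2, rel=1e-12)
        assert spec.hyper2 == pytest.approx(sd**2 / 4896, rel=1e-12)
        assert spec.hyper1 == pytest.approx(30.03, abs=0.01)
        assert spec.hyper2 == pytest.approx(163.0, abs=0.05)

    def test_degenerate_interval_is_fixed(self):
        p = Parameter("k", "cost", 5.0, 5.0, 5.0, "gamma")
        spec = derive_sampling_distribution(p)
        assert spec.family == "fixed" and spec.hyper1 == 5.0

    def test_infeasible_beta_variance_falls_back_to_fixed(self, caplog):
        # variance (high-low)/3.92 squared exceeds m(1-m) near the edge
        p = Parameter("p", "probability", 0.001, 0.0, 1.0, "beta")
        with caplog.at_level("WARNING"):
            spec = derive_sampling_distribution(p)
        assert spec.family == "fixed"
        assert "infeasible" in caplog.text

    def test_analytic_moments_match_formula(self, ref):
        for p in ref:
            spec = derive_sampling_distribution(p)
            if spec.family == "fixed" or spec.truncation_high is not None:
                continue
            assert spec.mean == pytest.approx(p.value, abs=1e-9)
            assert spec.sd == pytest.approx((p.high - p.low) / CI_WIDTH_SD, abs=1e-9)

    def test_effectiveness_truncated_mean_recovers_value(self, ref):
        for name in ("p_eff_condom", "p_eff_esm", "p_eff_bakri"):
            spec = derive_sampling_distribution(ref[name])
            assert spec.truncation_high == EFFECTIVENESS_CEILING
            assert truncated_beta_mean(
                spec.hyper1, spec.hyper2, EFFECTIVENESS_CEILING
            ) == pytest.approx(ref.value(name), abs=1e-9)

    def test_sample_means_recover_values(self, ref):
        rng = np.random.default_rng(11)
        for p in ref:
            spec = derive_sampling_distribution(p)
            if spec.family == "fixed":
                continue
            x = spec.sample(rng, 10_000)
            se = x.std() / math.sqrt(len(x))
            assert abs(x.mean() - p.value) < 4 * se, p.name

    def test_truncation_respected(self, ref):
        rng = np.random.default_rng(5)
        spec = derive_sampling_distribution(ref["p_eff_esm"])
        assert spec.sample(rng, 20_000).max() <= EFFECTIVENESS_CEILING


@st.composite
def beta_like(draw):
    value = draw(st.floats(0.05, 0.95))
    half = draw(st.floats(0.005, 0.2))
    low = max(0.0, value - half)
    high = min(1.0, value + half)
    return Parameter("p", "proportion", value, low, high, "beta")


class TestMomentProperties:
    @settings(max_examples=60, derandomize=True)
    @given(beta_like())
    def test_beta_mean_always_recovered(self, p):
        spec = derive_sampling_distribution(p)
        if spec.family == "beta":
            assert spec.mean == pytest.approx(p.value, abs=1e-9)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.floats(1.0, 1e6),
        st.floats(0.01, 0.8),
    )
    def test_gamma_moments_always_recovered(self, value, spread):
        p = Parameter("c", "cost", value, value * (1 - spread), value * (1 + spread),
                      "gamma")
        spec = derive_sampling_distribution(p)
        assert spec.mean == pytest.approx(value, rel=1e-9)
        assert spec.sd == pytest.approx((p.high - p.low) / CI_WIDTH_SD, rel=1e-9)


class TestPerturb:
    def test_same_seed_identical(self, ref):
        a = perturb_parameters(ref, 0.5, seed=9)
        b = perturb_parameters(ref, 0.5, seed=9)
        for p in a:
            assert b[p.name] == p

    def test_tiny_scale_stays_near_base(self, ref):
        out = perturb_parameters(ref, 1e-9, seed=2)
        for p in ref:
            assert out.value(p.name) == pytest.approx(p.value, rel=1e-6, abs=1e-7)

    def test_scale_bounds_enforced(self, ref):
        with pytest.raises(ValueError):
            perturb_parameters(ref, 0.0, seed=1)
        with pytest.raises(ValueError):
            perturb_parameters(ref, 1.5, seed=1)

    def test_full_scale_replicate_means_near_base(self, ref):
        # sampling-mean oracle on a handful of parameters over replicates
        names = ["p_icu_controlled", "cost_icu_tertiary", "dw_severe_haem"]
        draws = {n: [] for n in names}
        for seed in range(400):
            out = perturb_parameters(ref, 1.0, seed=seed)
            for n in names:
                draws[n].append(out.value(n))
        for n in names:
            x = np.asarray(draws[n])
            se = x.std() / math.sqrt(len(x))
            assert abs(x.mean() - ref.value(n)) < 3 * se
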