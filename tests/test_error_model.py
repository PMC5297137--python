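import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import linkvar as lv


def _error_frame(err_i, err_j, hospital=None):
    """Matched-pair table with given dob/sex error indicators, postcode clean."""
    frame = pd.DataFrame(
        {
            "agree_date_of_birth": 1 - np.asarray(err_i, dtype=np.int8),
            "agree_sex": 1 - np.asarray(err_j, dtype=np.int8),
            "agree_postcode": np.ones(len(err_i), dtype=np.int8),
            "is_match": True,
        }
    )
    if hospital is not None:
        frame["hospital_id"] = hospital
    return frame


class TestBuildErrorRecords:
    def test_cardinality(self, schema):
        pairs = [
            lv.ComparisonPair(lv.AgreementPattern((1, 1, 0)), is_match=True)
            for _ in range(10)
        ] + [lv.ComparisonPair(lv.AgreementPattern((0, 0, 0)), is_match=False)]
        records = lv.build_error_records(pairs, schema)
        assert len(records) == 30  # 10 matched pairs x 3 identifiers

    def test_indicator_is_complement_of_bit(self, schema):
        pairs = [lv.ComparisonPair(lv.AgreementPattern((1, 1, 0)), is_match=True)]
        records = lv.build_error_records(pairs, schema)
        by_ident = records.set_index("identifier")["error"]
        assert by_ident["postcode"] == 1
        assert by_ident["date_of_birth"] == 0 and by_ident["sex"] == 0

    def test_error_rate_equals_one_minus_m(self, schema, medium_population):
        _, pairs, _ = medium_population
        records = lv.build_error_records(pairs, schema)
        mu = lv.estimate_mu_independent(pairs, schema)
        for name in schema.names:
            rate = records.loc[records.identifier == name, "error"].mean()
            # shared counting: identical up to the clamp on extreme cells
            assert rate == pytest.approx(1 - mu.m(name), abs=1 / mu.n_matches)

    def test_requires_matches(self, schema):
        pairs = [lv.ComparisonPair(lv.AgreementPattern((1, 1, 1)), is_match=False)]
        with pytest.raises(lv.DataError):
            lv.build_error_records(pairs, schema)


class TestFitErrorModel:
    def test_matches_closed_form_two_by_two(self):
        # balanced single-predictor data: log-OR has a closed form
        n = 4000
        err_j = np.repeat([0, 1], n // 2)
        p = np.where(err_j == 1, 0.3, 0.1)
        rng = np.random.default_rng(4)
        err_i = (rng.random(n) < p).astype(int)
        records = pd.DataFrame({"error": err_i, "sex": np.where(err_j == 1, "female", "male")})
        fit = lv.fit_error_model(records, include_random_effect=False)
        a = ((err_i == 1) & (err_j == 1)).sum()
        b = ((err_i == 0) & (err_j == 1)).sum()
        c = ((err_i == 1) & (err_j == 0)).sum()
        d = ((err_i == 0) & (err_j == 0)).sum()
        closed_form = np.log(a * d / (b * c))
        assert fit.fixed_effects["sex[female]"][0] == pytest.approx(closed_form, abs=1e-6)

    def test_null_effects_recovered(self, schema):
        cfg = lv.GeneratorConfig(
            n_individuals=20_000,
            readmission_prob=1.0,
            n_nonmatch_pairs=10,
            attribute_effects={},
            hospital_sd=0.0,
            n_hospitals=10,
            seed=8,
        )
        pairs, _ = lv.generate_population(cfg)
        fit = lv.fit_error_model(
            lv.build_error_records(pairs, schema), include_random_effect=False
        )
        for term in ("sex[female]", "age_cohort[5-6]", "ethnic_group[Asian]"):
            or_, lo, hi = fit.odds_ratio(term)
            assert lo < 1.0 < hi

    def test_planted_or_recovered(self, schema):
        # female-vs-male odds ratio planted at 0.5
        cfg = lv.GeneratorConfig(
            n_individuals=50_000,
            readmission_prob=1.0,
            n_nonmatch_pairs=10,
            attribute_effects={"sex": {"female": 0.5}},
            hospital_sd=0.0,
            n_hospitals=10,
            seed=9,
        )
        pairs, _ = lv.generate_population(cfg)
        fit = lv.fit_error_model(
            lv.build_error_records(pairs, schema), include_random_effect=False
        )
        assert 0.45 <= fit.odds_ratio("sex[female]")[0] <= 0.55

    def test_zero_between_hospital_variance(self, schema):
        cfg = lv.GeneratorConfig(
            n_individuals=15_000,
            readmission_prob=1.0,
            n_nonmatch_pairs=10,
            hospital_sd=0.0,
            n_hospitals=30,
            seed=10,
        )
        pairs, _ = lv.generate_population(cfg)
        fit = lv.fit_error_model(
            lv.build_error_records(pairs, schema), include_random_effect=True
        )
        assert fit.method == "gauss-hermite"
        assert fit.hospital_variance == pytest.approx(0.0, abs=0.01)

    def test_agrees_with_lme4_on_small_fixture(self, tmp_path):
        # independent oracle: the same random-intercept logistic model fitted
        # by lme4::glmer (adaptive Gauss-Hermite, nAGQ=15)
        rng = np.random.default_rng(12)
        n_clusters, per = 30, 200
        cl = np.repeat(np.arange(n_clusters), per)
        u = rng.normal(0, 0.8, n_clusters)
        x = rng.integers(0, 2, n_clusters * per)
        eta = -1.0 + 0.7 * x + u[cl]
        y = (rng.random(len(eta)) < 1 / (1 + np.exp(-eta))).astype(int)
        records = pd.DataFrame(
            {
                "error": y,
                "sex": np.where(x == 1, "female", "male"),
                "hospital_id": [f"H{c}" for c in cl],
            }
        )
        fit = lv.fit_error_model(records, include_random_effect=True)

        csv = tmp_path / "d.csv"
        records.assign(x=x).to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(error ~ x + (1 | hospital_id), data = d,
                       family = binomial, nAGQ = 15)
            cat(fixef(m)["x"], sqrt(unlist(VarCorr(m))[1]), sep = "\\n")
            """
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        if out.returncode != 0:
            pytest.skip(f"lme4 fit failed: {out.stderr[-200:]}")
        beta_r, sd_r = map(float, out.stdout.split())
        assert fit.fixed_effects["sex[female]"][0] == pytest.approx(beta_r, abs=2e-3)
        assert np.sqrt(fit.hospital_variance) == pytest.approx(sd_r, abs=2e-2)


class TestPairwiseDependence:
    def test_independent_errors_give_null_or(self):
        rng = np.random.default_rng(2)
        n = 40_000
        frame = _error_frame(rng.random(n) < 0.05, rng.random(n) < 0.2)
        res = lv.test_pairwise_dependence(frame, "date_of_birth", "sex")
        assert not res.degenerate
        assert 0.8 < res.odds_ratio < 1.25
        assert res.p_value > 0.001

    def test_planted_dependence_detected(self):
        rng = np.random.default_rng(3)
        n = 100_000
        err_j = rng.random(n) < 0.2
        p_i = np.where(err_j, 0.10, 0.05)  # doubled error risk
        frame = _error_frame(rng.random(n) < p_i, err_j)
        res = lv.test_pairwise_dependence(frame, "date_of_birth", "sex")
        assert res.odds_ratio > 1.5
        assert res.p_value < 1e-6

    def test_self_test_is_degenerate(self, medium_population):
        _, pairs, _ = medium_population
        res = lv.test_pairwise_dependence(pairs, "sex", "sex")
        assert res.degenerate and np.isinf(res.odds_ratio)

    def test_empty_margin_flagged(self):
        frame = _error_frame([0, 1, 0, 1], [0, 0, 0, 0])
        res = lv.test_pairwise_dependence(frame, "date_of_birth", "sex")
        assert res.degenerate


class TestFunnelLimits:
    def test_hand_computed_95(self):
        lim = lv.funnel_limits(0.5, [100], levels=(0.95,))
        assert lim.lower[0] == pytest.approx(0.402, abs=5e-4)
        assert lim.upper[0] == pytest.approx(0.598, abs=5e-4)

    def test_truncation_at_zero(self):
        lim = lv.funnel_limits(0.01, [500], levels=(0.998,))
        assert lim.lower[0] == 0.0

    def test_limits_shrink_to_rate(self):
        lim = lv.funnel_limits(0.3, [10**8], levels=(0.95,))
        assert lim.lower[0] == pytest.approx(0.3, abs=1e-3)

    def test_symmetry_and_nesting(self):
        rate, ns = 0.4, [50, 200, 1000]
        both = lv.funnel_limits(rate, ns, levels=(0.95, 0.998))
        for n in ns:
            sub = both[both.n == n].set_index("level")
            for level in (0.95, 0.998):
                lo, hi = sub.loc[level, "lower"], sub.loc[level, "upper"]
                assert hi - rate == pytest.approx(rate - lo, abs=1e-12)
            assert sub.loc[0.998, "lower"] <= sub.loc[0.95, "lower"]
            assert sub.loc[0.998, "upper"] >= sub.loc[0.95, "upper"]

    def test_invalid_rate(self):
        with pytest.raises(lv.DataError):
            lv.funnel_limits(0.0, [10])

    def test_funnel_table_flags_outliers(self, medium_population):
        _, pairs, _ = medium_population
        records = lv.build_error_records(pairs)
        table = lv.funnel_table(records)
        assert {"rate", "n", "lower_0.95", "upper_0.998"} <= set(table.columns)
        inside = (table.rate >= table["lower_0.998"]) & (
            table.rate <= table["upper_0.998"]
        )
        assert (inside == ~table["outlier_0.998"]).all()
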