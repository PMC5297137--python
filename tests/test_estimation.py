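import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import linkvar as lv
from linkvar.estimation import MUTable


def _mu(m, u):
    names = ("date_of_birth", "sex", "postcode")
    return MUTable(
        per_identifier={n: (mi, ui) for n, mi, ui in zip(names, m, u)},
        n_matches=1000,
        n_nonmatches=1000,
    )


class TestIndependentEstimation:
    def test_counting_oracle_on_tiny_fixture(self, schema, tiny_pairs):
        # hand counts from the fixture docstring: 6 matches, 6 non-matches
        mu = lv.estimate_mu_independent(tiny_pairs, schema)
        assert mu.n_matches == 6 and mu.n_nonmatches == 6
        assert mu.m("date_of_birth") == pytest.approx(5 / 6)
        assert mu.m("sex") == pytest.approx(1 - 1 / 12)  # 6/6 clamped
        assert mu.m("postcode") == pytest.approx(4 / 6)
        assert mu.u("date_of_birth") == pytest.approx(2 / 6)
        assert mu.u("sex") == pytest.approx(3 / 6)
        assert mu.u("postcode") == pytest.approx(1 / 12)  # 0/6 clamped to floor

    def test_simple_fraction(self, schema):
        pairs = [
            lv.ComparisonPair(lv.AgreementPattern((0, 1, 0)), is_match=True)
            for _ in range(9)
        ]
        pairs += [lv.ComparisonPair(lv.AgreementPattern((0, 0, 0)), is_match=True)]
        pairs += [
            lv.ComparisonPair(lv.AgreementPattern((0, 1, 0)), is_match=False)
        ]
        pairs += [
            lv.ComparisonPair(lv.AgreementPattern((0, 0, 0)), is_match=False)
            for _ in range(9)
        ]
        mu = lv.estimate_mu_independent(pairs, schema)
        assert mu.m("sex") == pytest.approx(0.9)
        assert mu.u("sex") == pytest.approx(0.1)

    def test_boundary_clamp(self, schema):
        pairs = [
            lv.ComparisonPair(lv.AgreementPattern((1, 1, 1)), is_match=True)
            for _ in range(1000)
        ] + [lv.ComparisonPair(lv.AgreementPattern((0, 0, 0)), is_match=False)]
        mu = lv.estimate_mu_independent(pairs, schema)
        assert mu.m("sex") == pytest.approx(1 - 1 / 2000)

    def test_requires_both_classes(self, schema):
        pairs = [lv.ComparisonPair(lv.AgreementPattern((1, 1, 1)), is_match=True)]
        with pytest.raises(lv.EstimationError):
            lv.estimate_mu_independent(pairs, schema)


class TestJointEstimation:
    def test_counting_oracle(self, schema):
        pairs = [
            lv.ComparisonPair(lv.AgreementPattern((1, 1, 1)), is_match=True)
            for _ in range(3)
        ]
        pairs += [lv.ComparisonPair(lv.AgreementPattern((1, 1, 0)), is_match=True)]
        pairs += [
            lv.ComparisonPair(lv.AgreementPattern((0, 0, 0)), is_match=False)
            for _ in range(4)
        ]
        mu = lv.estimate_mu_joint(pairs, schema)
        assert mu.pattern_counts["111"] == (3, 0)
        assert mu.pattern_counts["110"] == (1, 0)
        # raw fractions before floor adjustment are 0.75 / 0.25; after the
        # floor and renormalisation they stay within the floor mass of that
        m111, _ = mu.per_pattern["111"]
        m110, _ = mu.per_pattern["110"]
        assert m111 / m110 == pytest.approx(3.0, rel=1e-9)

    def test_per_pattern_probabilities_conserve_mass(self, schema, medium_population):
        _, pairs, _ = medium_population
        mu = lv.estimate_mu_joint(pairs, schema)
        total_m = sum(v[0] for v in mu.per_pattern.values())
        total_u = sum(v[1] for v in mu.per_pattern.values())
        assert total_m == pytest.approx(1.0, abs=1e-9)
        assert total_u == pytest.approx(1.0, abs=1e-9)

    def test_single_pattern_dominates(self, schema):
        pairs = [lv.ComparisonPair(lv.AgreementPattern((1, 1, 1)), is_match=True)]
        pairs += [
            lv.ComparisonPair(lv.AgreementPattern((0, 1, 0)), is_match=False)
            for _ in range(50)
        ]
        mu = lv.estimate_mu_joint(pairs, schema)
        assert mu.per_pattern["010"][1] > 0.9
        others = [v[1] for k, v in mu.per_pattern.items() if k != "010"]
        assert all(u < 0.02 for u in others)


class TestWeights:
    def test_hand_computed_traditional(self):
        mu = _mu((0.9, 0.9, 0.9), (0.1, 0.1, 0.1))
        w_all = lv.weight_traditional(lv.AgreementPattern((1, 1, 1)), mu)
        assert w_all == pytest.approx(3 * math.log2(9), abs=1e-9)
        w_two = lv.weight_traditional(lv.AgreementPattern((1, 1, 0)), mu)
        assert w_two == pytest.approx(2 * math.log2(9) + math.log2(1 / 9), abs=1e-9)

    def test_equal_mu_gives_zero_weight(self, schema):
        mu = _mu((0.4, 0.5, 0.6), (0.4, 0.5, 0.6))
        for pat in lv.enumerate_patterns(schema):
            assert lv.weight_traditional(pat, mu) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_joint(self):
        mu = MUTable(
            per_identifier={},
            n_matches=4,
            n_nonmatches=4,
            per_pattern={"111": (0.75, 0.25), "000": (0.25, 0.75)},
        )
        assert lv.weight_joint(lv.AgreementPattern((1, 1, 1)), mu) == pytest.approx(
            math.log2(3)
        )
        mu.per_pattern["111"] = (0.5, 0.5)
        assert lv.weight_joint(lv.AgreementPattern((1, 1, 1)), mu) == 0.0

    @given(st.floats(0.05, 0.94), st.floats(0.05, 0.94), st.integers(0, 7))
    def test_monotone_in_m_for_agreeing_identifier(self, m_k, delta_frac, code):
        # raising m of an identifier the pattern agrees on never lowers W
        bits = tuple((code >> (2 - i)) & 1 for i in range(3))
        m_hi = m_k + (0.95 - m_k) * delta_frac
        for pos in range(3):
            if not bits[pos]:
                continue
            base = [0.8, 0.8, 0.8]
            lo, hi = base.copy(), base.copy()
            lo[pos], hi[pos] = m_k, m_hi
            w_lo = lv.weight_traditional(lv.AgreementPattern(bits), _mu(lo, (0.1,) * 3))
            w_hi = lv.weight_traditional(lv.AgreementPattern(bits), _mu(hi, (0.1,) * 3))
            assert w_hi >= w_lo - 1e-12


class TestStratified:
    def test_attribute_strata_count(self, schema, medium_population):
        _, pairs, _ = medium_population
        model = lv.estimate_mu_stratified(
            pairs, schema, strat_by="attributes", min_stratum_matches=10
        )
        assert model.variant == "attribute"
        # 3 cohorts x 2 sexes x 6 ethnic groups all populated at this size
        assert len(model.stratum_tables) == 36

    def test_thin_stratum_falls_back(self, schema, medium_population):
        _, pairs, _ = medium_population
        model = lv.estimate_mu_stratified(
            pairs, schema, strat_by="attributes", min_stratum_matches=10**9
        )
        assert model.stratum_tables == {}
        pair = lv.frame_to_pairs(pairs.head(1), schema)[0]
        w = lv.weight_for_pair(pair, model)
        assert w == pytest.approx(
            lv.weight_traditional(pair.pattern, model.global_table)
        )

    def test_stratified_recovery_of_planted_rates(self, schema):
        # postcode error differs by cohort; stratified m should recover it
        cfg = lv.GeneratorConfig(
            n_individuals=40_000,
            readmission_prob=0.5,
            hospital_sd=0.0,
            n_hospitals=5,
            seed=31,
        )
        pairs, _ = lv.generate_population(cfg)
        model = lv.estimate_mu_stratified(pairs, schema, "attributes", 50)
        matches = pairs[pairs.is_match]
        for key, table in list(model.stratum_tables.items())[:8]:
            sel = (
                (matches.age_cohort == key[0])
                & (matches.sex == key[1])
                & (matches.ethnic_group == key[2])
            )
            observed = matches.loc[sel, "agree_postcode"].mean()
            n = sel.sum()
            se = np.sqrt(max(observed * (1 - observed), 1e-9) / n)
            assert table.m("postcode") == pytest.approx(observed, abs=3 * se + 1e-9)

    def test_unknown_strat_by(self, schema, tiny_pairs):
        with pytest.raises(lv.DataError):
            lv.estimate_mu_stratified(tiny_pairs, schema, strat_by="galaxy")


class TestWeightForPair:
    def test_traditional_dispatch_identity(self, schema, tiny_pairs):
        model = lv.fit_weight_model(tiny_pairs, schema, "traditional")
        for p in tiny_pairs[:4]:
            assert lv.weight_for_pair(p, model) == pytest.approx(
                lv.weight_traditional(p.pattern, model.global_table)
            )

    def test_missingness_raises_pattern_weight(self, schema):
        # a stratum with more postcode missingness penalises postcode
        # disagreement less, so {110} weighs more there
        rich = MUTable(
            per_identifier={"date_of_birth": (0.99, 0.01), "sex": (0.99, 0.5), "postcode": (0.9, 0.01)},
            n_matches=100,
            n_nonmatches=100,
        )
        sparse = MUTable(
            per_identifier={"date_of_birth": (0.99, 0.01), "sex": (0.99, 0.5), "postcode": (0.2, 0.01)},
            n_matches=100,
            n_nonmatches=100,
        )
        pat = lv.AgreementPattern((1, 1, 0))
        assert lv.weight_traditional(pat, sparse) > lv.weight_traditional(pat, rich)

    def test_unseen_stratum_uses_global(self, schema, medium_population):
        _, pairs, _ = medium_population
        model = lv.estimate_mu_stratified(pairs, schema, "hospital", 100)
        pair = lv.ComparisonPair(
            lv.AgreementPattern((1, 1, 1)), hospital_id="H999"
        )
        assert lv.weight_for_pair(pair, model) == pytest.approx(
            lv.weight_traditional(pair.pattern, model.global_table)
        )

    def test_vectorised_weights_match_scalar(self, schema, medium_population):
        _, pairs, _ = medium_population
        sub = pairs.sample(200, random_state=0)
        for variant in ("traditional", "joint", "attribute", "organisation"):
            model = lv.fit_weight_model(pairs, schema, variant, min_stratum_matches=50)
            vec = lv.weights_for_frame(sub, model)
            scalar = [
                lv.weight_for_pair(p, model) for p in lv.frame_to_pairs(sub, schema)
            ]
            np.testing.assert_allclose(vec, scalar, rtol=1e-12)


class TestMatchProbability:
    @pytest.mark.parametrize(
        "nm, nu, expected",
        [(14_009, 10, 0.9993), (15_924, 415_888, 0.0369), (0, 7, 0.0)],
    )
    def test_examples(self, nm, nu, expected):
        assert lv.match_probability(nm, nu) == pytest.approx(expected, abs=5e-5)

    def test_zero_total_raises(self):
        with pytest.raises(lv.DataError):
            lv.match_probability(0, 0)


class TestSerialisation:
    def test_model_json_round_trip(self, tmp_path, schema, medium_population):
        _, pairs, _ = medium_population
        for variant in ("traditional", "joint", "attribute"):
            model = lv.fit_weight_model(pairs, schema, variant, min_stratum_matches=50)
            path = tmp_path / f"{variant}.json"
            model.to_json(path)
            back = lv.WeightModel.from_json(path)
            assert back.variant == model.variant
            assert back.global_table.per_identifier == model.global_table.per_identifier
            assert set(back.stratum_tables) == set(model.stratum_tables)
            pat = lv.AgreementPattern((1, 1, 0))
            if variant == "joint":
                assert lv.weight_joint(pat, back.global_table) == pytest.approx(
                    lv.weight_joint(pat, model.global_table)
                )
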