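"""Synthetic hospital-admission linkage data and the bias simulation study.

The generator emulates a gold-standard-validated extract of hospital
admission records: individuals carry an age cohort (0-1, 5-6, 18-19 years),
sex, ethnic group and an admitting hospital; a fraction are readmitted
within the study window and so contribute a true-match record pair.
Identifier errors (date of birth, sex, postcode) occur at configurable
baseline rates modified multiplicatively on the odds scale by attributes
and by a normally distributed hospital intercept; baseline intercepts are
calibrated so that the population-marginal error rates equal the configured
values.  Non-match pairs are produced by cross-pairing records within age
cohorts and scoring chance agreement on actual identifier values.

A unique-identifier (NHS-number analogue) error scenario is then overlaid:

* ``A`` - unique id missing/incorrect completely at random in 30% of pairs;
* ``B`` - as A at 0.5%;
* ``C`` - 30% overall, but twice as likely when any other identifier errs;
* ``D`` - 30% overall, distributed across ethnic groups in proportion to a
  profile (by default the generator's own ethnic-group error effects).

:func:`run_study` links each replicate in two stages - deterministic accept
on unique-id agreement, then probabilistic classification of the remainder
under each weight variant calibrated at a target false-match rate - and
summarises readmission-rate bias and sensitivity per method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, sparse
from scipy.sparse import csgraph

from .core import (
    AGE_COHORTS,
    DataError,
    ETHNIC_GROUPS,
    IdentifierSchema,
    SEXES,
    prefilter_pairs,
)
from .estimation import WeightModel, fit_weight_model
from .linkage import (
    calibrate_threshold,
    classify,
    estimate_readmission,
    percent_bias,
    score_pairs,
)

__all__ = [
    "GeneratorConfig",
    "ScenarioConfig",
    "MethodSummary",
    "SimulationResult",
    "generate_population",
    "resample_patterns",
    "apply_uid_scenario",
    "fit_weight_models",
    "run_study",
]


def _default_error_rates() -> dict:
    # marginal disagreement rates among matched pairs: sex and date of birth
    # 0.11%, postcode 53% (dominated by missingness)
    return {"date_of_birth": 0.0011, "sex": 0.0011, "postcode": 0.53}


def _default_attribute_effects() -> dict:
    # odds multipliers on identifier-error risk, reference male / 0-1 / White
    return {
        "sex": {"female": 0.84},
        "age_cohort": {"5-6": 0.39, "18-19": 0.37},
        "ethnic_group": {
            "Missing": 1.5,
            "Mixed": 1.1,
            "Asian": 0.89,
            "Black": 1.1,
            "Other": 0.95,
        },
    }


def _default_attribute_mix() -> dict:
    return {
        "age_cohort": {"0-1": 1 / 3, "5-6": 1 / 3, "18-19": 1 / 3},
        "sex": {"female": 0.5, "male": 0.5},
        "ethnic_group": {
            "White": 0.70,
            "Mixed": 0.04,
            "Asian": 0.10,
            "Black": 0.06,
            "Other": 0.04,
            "Missing": 0.06,
        },
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic admission-pair generator."""

    n_individuals: int = 20_000
    readmission_prob: float | dict = 0.088
    identifier_error_rates: dict = field(default_factory=_default_error_rates)
    attribute_effects: dict = field(default_factory=_default_attribute_effects)
    hospital_sd: float = 0.5
    n_hospitals: int = 388
    attribute_mix: dict = field(default_factory=_default_attribute_mix)
    #: candidate non-match pairs after blocking; None -> 0.75 per individual
    n_nonmatch_pairs: int | None = None
    #: size of the birthday value space within a cohort year
    n_birthdays: int = 365
    #: size of the postcode value space within a cohort block
    n_postcodes: int = 1500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise DataError("n_individuals must be positive")
        if self.hospital_sd < 0:
            raise DataError("hospital_sd must be non-negative")
        rates = self.identifier_error_rates
        if any(not 0.0 <= r <= 1.0 for r in rates.values()):
            raise DataError("identifier error rates must lie in [0, 1]")
        for factor, levels in self.attribute_mix.items():
            valid = {
                "age_cohort": set(AGE_COHORTS),
                "sex": set(SEXES),
                "ethnic_group": set(ETHNIC_GROUPS),
            }[factor]
            unknown = set(levels) - valid
            if unknown:
                raise DataError(f"unknown {factor} categories in attribute_mix: {unknown}")
            if abs(sum(levels.values()) - 1.0) > 1e-9:
                raise DataError(f"attribute_mix[{factor!r}] must sum to 1")
        if isinstance(self.readmission_prob, dict):
            if any(not 0.0 <= p <= 1.0 for p in self.readmission_prob.values()):
                raise DataError("readmission probabilities must lie in [0, 1]")
        elif not 0.0 <= self.readmission_prob <= 1.0:
            raise DataError("readmission_prob must lie in [0, 1]")

    @property
    def schema(self) -> IdentifierSchema:
        return IdentifierSchema(tuple(self.identifier_error_rates.keys()))

    def resolved_nonmatch_pairs(self) -> int:
        if self.n_nonmatch_pairs is not None:
            return int(self.n_nonmatch_pairs)
        return int(round(0.75 * self.n_individuals))


def _scenario_default_rate(scenario: str) -> float:
    return 0.005 if scenario == "B" else 0.30


@dataclass
class ScenarioConfig:
    """Unique-identifier (NHS-number analogue) error scenario."""

    scenario: str = "A"
    overall_uid_error: float | None = None
    dependence_multiplier: float = 2.0
    ethnic_profile: dict | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C", "D"):
            raise DataError(f"scenario must be one of A-D, got {self.scenario!r}")
        if self.overall_uid_error is None:
            self.overall_uid_error = _scenario_default_rate(self.scenario)
        if not 0.0 <= self.overall_uid_error <= 1.0:
            raise DataError("overall_uid_error must lie in [0, 1]")
        if self.dependence_multiplier <= 0:
            raise DataError("dependence_multiplier must be positive")


# ---------------------------------------------------------------------------
# marginal-rate calibration


def _stratum_effect_logits(config: GeneratorConfig):
    """Log-odds offsets and weights for every attribute stratum."""
    mix = config.attribute_mix
    eff = config.attribute_effects
    offsets, weights, keys = [], [], []
    for age, w_a in mix["age_cohort"].items():
        for sex, w_s in mix["sex"].items():
            for eth, w_e in mix["ethnic_group"].items():
                off = (
                    np.log(eff.get("age_cohort", {}).get(age, 1.0))
                    + np.log(eff.get("sex", {}).get(sex, 1.0))
                    + np.log(eff.get("ethnic_group", {}).get(eth, 1.0))
                )
                offsets.append(off)
                weights.append(w_a * w_s * w_e)
                keys.append((age, sex, eth))
    return np.array(offsets), np.array(weights), keys


def _calibrate_intercept(target: float, offsets, weights, hospital_sd: float) -> float:
    """Solve for the baseline log-odds giving the requested marginal rate.

    The marginal integrates the inverse-logit over the attribute mix and the
    hospital random intercept (Gauss-Hermite quadrature, 21 nodes).
    """
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    nodes, gh_w = np.polynomial.hermite.hermgauss(21)
    z = np.sqrt(2.0) * nodes
    wz = gh_w / np.sqrt(np.pi)

    def marginal(b0: float) -> float:
        eta = b0 + offsets[:, None] + hospital_sd * z[None, :]
        return float((weights[:, None] * wz[None, :] * special.expit(eta)).sum())

    return optimize.brentq(lambda b0: marginal(b0) - target, -40.0, 40.0, xtol=1e-12)


def _error_probabilities(config: GeneratorConfig, hosp_intercepts: np.ndarray,
                         stratum_idx: np.ndarray, hosp_idx: np.ndarray,
                         readmit_weights: np.ndarray | None = None) -> np.ndarray:
    """Per-individual, per-identifier pair-level error probabilities."""
    offsets, weights, _ = _stratum_effect_logits(config)
    if readmit_weights is not None:
        weights = weights * readmit_weights
        weights = weights / weights.sum()
    out = np.empty((len(stratum_idx), len(config.identifier_error_rates)), dtype=np.float64)
    for k, (name, rate) in enumerate(config.identifier_error_rates.items()):
        b0 = _calibrate_intercept(rate, offsets, weights, config.hospital_sd)
        if np.isinf(b0):
            out[:, k] = 0.0 if b0 < 0 else 1.0
        else:
            eta = b0 + offsets[stratum_idx] + hosp_intercepts[hosp_idx]
            out[:, k] = special.expit(eta)
    return out


# ---------------------------------------------------------------------------
# population generation


def _draw_categorical(rng, levels_probs: dict, n: int) -> np.ndarray:
    levels = list(levels_probs.keys())
    probs = np.array(list(levels_probs.values()), dtype=float)
    return rng.choice(len(levels), size=n, p=probs / probs.sum())


def generate_population(config: GeneratorConfig, rng=None):
    """Draw a synthetic population and its labelled comparison pairs.

    Returns ``(pairs, admissions)``: a pair table (one row per candidate
    pair, matches and cross-pair non-matches, labelled) and a per-individual
    admissions table.  Matched pairs receive agreement bits directly from
    pair-level Bernoulli errors; non-match pairs agree on an identifier only
    when the two individuals' actual values coincide and neither side is
    corrupted.  ``unique_id_flag`` starts error-free (matches ``agree``,
    non-matches ``disagree``) until a scenario is applied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    mix = config.attribute_mix
    age_levels = list(mix["age_cohort"])
    sex_levels = list(mix["sex"])
    eth_levels = list(mix["ethnic_group"])

    age = _draw_categorical(rng, mix["age_cohort"], n)
    sex = _draw_categorical(rng, mix["sex"], n)
    eth = _draw_categorical(rng, mix["ethnic_group"], n)
    hosp = rng.integers(0, config.n_hospitals, size=n)
    hosp_intercepts = (
        rng.normal(0.0, config.hospital_sd, size=config.n_hospitals)
        if config.hospital_sd > 0
        else np.zeros(config.n_hospitals)
    )

    # map each individual to its attribute stratum index (order must match
    # _stratum_effect_logits: age outer, sex middle, ethnic inner)
    stratum_idx = (age * len(sex_levels) + sex) * len(eth_levels) + eth

    if isinstance(config.readmission_prob, dict):
        p_re = np.array([config.readmission_prob.get(a, 0.0) for a in age_levels])
        readmit_p = p_re[age]
        # weight the calibration mix by stratified readmission probability,
        # since marginal error rates are defined over matched pairs
        offsets, weights, keys = _stratum_effect_logits(config)
        rw = np.array([config.readmission_prob.get(k[0], 0.0) for k in keys])
        readmit_weights = rw
    else:
        readmit_p = np.full(n, float(config.readmission_prob))
        readmit_weights = None
    readmitted = rng.random(n) < readmit_p

    # actual identifier values, used to score chance agreement in non-matches
    dob_val = rng.integers(0, config.n_birthdays, size=n)
    pc_val = rng.integers(0, config.n_postcodes, size=n)

    p_err = _error_probabilities(config, hosp_intercepts, stratum_idx, hosp,
                                 readmit_weights)

    schema = config.schema
    names = list(config.identifier_error_rates.keys())

    # ----- matched pairs: one per readmitted individual
    m_idx = np.flatnonzero(readmitted)
    n_m = len(m_idx)
    match_bits = {}
    for k, name in enumerate(names):
        match_bits[f"agree_{name}"] = (rng.random(n_m) >= p_err[m_idx, k]).astype(np.int8)

    # ----- non-match pairs: cross-pairing within age-cohort blocks
    n_nm = config.resolved_nonmatch_pairs()
    cohort_share = np.array([mix["age_cohort"][a] for a in age_levels])
    nm_counts = rng.multinomial(n_nm, cohort_share / cohort_share.sum())
    a_list, b_list = [], []
    for c, cnt in enumerate(nm_counts):
        members = np.flatnonzero(age == c)
        if len(members) < 2 or cnt == 0:
            continue
        a = members[rng.integers(0, len(members), size=cnt)]
        b = members[rng.integers(0, len(members), size=cnt)]
        keep = a != b
        a_list.append(a[keep])
        b_list.append(b[keep])
    nm_a = np.concatenate(a_list) if a_list else np.array([], dtype=int)
    nm_b = np.concatenate(b_list) if b_list else np.array([], dtype=int)

    nm_bits = {}
    for k, name in enumerate(names):
        clean = (rng.random(len(nm_a)) >= p_err[nm_a, k]) & (
            rng.random(len(nm_a)) >= p_err[nm_b, k]
        )
        if name == "date_of_birth":
            same = dob_val[nm_a] == dob_val[nm_b]
        elif name == "sex":
            same = sex[nm_a] == sex[nm_b]
        elif name == "postcode":
            same = pc_val[nm_a] == pc_val[nm_b]
        else:  # unknown identifier: no chance agreement
            same = np.zeros(len(nm_a), dtype=bool)
        nm_bits[f"agree_{name}"] = (same & clean).astype(np.int8)

    def _cat(codes, levels):
        return pd.Categorical.from_codes(codes, categories=levels)

    hospital_labels = np.array([f"H{h:03d}" for h in range(config.n_hospitals)])

    match_frame = pd.DataFrame(match_bits)
    match_frame["age_cohort"] = _cat(age[m_idx], age_levels)
    match_frame["sex"] = _cat(sex[m_idx], sex_levels)
    match_frame["ethnic_group"] = _cat(eth[m_idx], eth_levels)
    match_frame["hospital_id"] = hospital_labels[hosp[m_idx]]
    match_frame["unique_id_flag"] = "agree"
    match_frame["is_match"] = True
    match_frame["id_a"] = m_idx
    match_frame["id_b"] = m_idx

    nm_frame = pd.DataFrame(nm_bits)
    nm_frame["age_cohort"] = _cat(age[nm_a], age_levels)
    nm_frame["sex"] = _cat(sex[nm_a], sex_levels)
    nm_frame["ethnic_group"] = _cat(eth[nm_a], eth_levels)
    nm_frame["hospital_id"] = hospital_labels[hosp[nm_a]]
    nm_frame["unique_id_flag"] = "disagree"
    nm_frame["is_match"] = False
    nm_frame["id_a"] = nm_a
    nm_frame["id_b"] = nm_b

    pairs = pd.concat([match_frame, nm_frame], ignore_index=True)

    admissions = pd.DataFrame(
        {
            "individual_id": np.arange(n),
            "age_cohort": _cat(age, age_levels),
            "sex": _cat(sex, sex_levels),
            "ethnic_group": _cat(eth, eth_levels),
            "hospital_id": hospital_labels[hosp],
            "n_admissions": np.where(readmitted, 2, 1),
        }
    )
    return pairs, admissions


def resample_patterns(
    reference: pd.DataFrame,
    n_matches: int,
    n_nonmatches: int,
    seed: int | None = None,
    rng=None,
) -> pd.DataFrame:
    """Stratified bootstrap of agreement patterns from a reference extract.

    Match and non-match rows are resampled with replacement within
    (age cohort, sex, ethnic group) strata; target stratum counts are drawn
    multinomially from the reference stratum frequencies so marginal pattern
    frequencies converge to the reference.  A stratum present in one class
    but absent in the other falls back to pooled resampling with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    strata_cols = ["age_cohort", "sex", "ethnic_group"]
    out = []
    labels = reference["is_match"].astype(bool)
    for want, n_want in ((True, n_matches), (False, n_nonmatches)):
        if n_want == 0:
            continue
        cls = reference[labels == want]
        if cls.empty:
            raise DataError("reference has no rows in one class")
        strata, uniques = pd.factorize(
            pd.MultiIndex.from_frame(cls[strata_cols].astype(object)), sort=False
        )
        probs = np.bincount(strata) / len(strata)
        counts = rng.multinomial(n_want, probs)
        idx_parts = []
        for s, cnt in enumerate(counts):
            if cnt == 0:
                continue
            members = np.flatnonzero(strata == s)
            if len(members) == 0:
                warnings.warn("empty reference stratum; falling back to pooled resampling")
                members = np.arange(len(cls))
            idx_parts.append(members[rng.integers(0, len(members), size=cnt)])
        idx = np.concatenate(idx_parts)
        out.append(cls.iloc[idx])
    if not out:
        return reference.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


def apply_uid_scenario(
    pairs: pd.DataFrame,
    scenario: ScenarioConfig,
    seed: int | None = None,
    rng=None,
) -> pd.DataFrame:
    """Overlay unique-identifier errors on matched pairs per scenario.

    True matches with an uncorrupted unique id get ``unique_id_flag='agree'``;
    corrupted matches get ``'missing'``; non-matches always ``'disagree'``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = pairs.copy()
    is_match = out["is_match"].to_numpy().astype(bool)
    n_m = int(is_match.sum())
    rate = float(scenario.overall_uid_error)

    if scenario.scenario in ("A", "B"):
        err_p = np.full(n_m, rate)
    elif scenario.scenario == "C":
        bit_cols = [c for c in out.columns if c.startswith("agree_")]
        any_err = (out.loc[is_match, bit_cols].to_numpy() == 0).any(axis=1)
        p_clean = float((~any_err).mean())
        mult = scenario.dependence_multiplier
        r = rate / (p_clean + mult * (1.0 - p_clean))
        if mult * r > 1.0:
            raise DataError(
                f"scenario C infeasible: dependent rate {mult * r:.3f} exceeds 1"
            )
        err_p = np.where(any_err, mult * r, r)
    else:  # D: errors distributed across ethnic groups per profile
        profile = scenario.ethnic_profile
        if profile is None:
            profile = dict(_default_attribute_effects()["ethnic_group"], White=1.0)
        eth = out.loc[is_match, "ethnic_group"].astype(str).to_numpy()
        mult = np.array([profile.get(e, 1.0) for e in eth])
        scale = rate / float(mult.mean())
        err_p = scale * mult
        if (err_p > 1.0).any():
            raise DataError("scenario D infeasible: a group error rate exceeds 1")

    flagged = rng.random(n_m) < err_p
    flags = np.where(flagged, "missing", "agree")
    uid = np.full(len(out), "disagree", dtype=object)
    uid[np.flatnonzero(is_match)] = flags
    out["unique_id_flag"] = uid
    return out


# ---------------------------------------------------------------------------
# the simulation study


@dataclass
class MethodSummary:
    readmission_rate: float
    rate_se: float
    percent_bias: float
    sensitivity: float


@dataclass
class SimulationResult:
    per_method: dict[str, MethodSummary]
    n_reps: int
    scenario: ScenarioConfig
    true_rate: float
    n_failures: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, s in self.per_method.items():
            rows.append(
                {
                    "method": method,
                    "scenario": self.scenario.scenario,
                    "pct_readmitted": 100.0 * s.readmission_rate,
                    "se": 100.0 * s.rate_se,  # percentage points
                    "pct_bias": s.percent_bias,
                    "sensitivity": s.sensitivity,
                }
            )
        return pd.DataFrame(rows)


def fit_weight_models(
    train_pairs: pd.DataFrame,
    schema: IdentifierSchema | None = None,
    min_stratum_matches: dict | None = None,
    variants=("traditional", "joint", "attribute", "organisation"),
) -> dict[str, WeightModel]:
    """Fit all requested weight variants from one labelled training extract."""
    schema = schema or IdentifierSchema()
    thresholds = min_stratum_matches or {}
    out = {}
    for variant in variants:
        out[variant] = fit_weight_model(
            train_pairs,
            schema,
            variant=variant,
            min_stratum_matches=thresholds.get(variant),
        )
    return out


def _readmission_from_links(admissions: pd.DataFrame, accepted: pd.DataFrame) -> float:
    """Cluster linked admission records and estimate the readmission rate.

    Records are nodes; accepted pairs are edges; the estimate is the fraction
    of connected components (apparent individuals) holding >= 2 records.
    """
    n_ind = len(admissions)
    two = admissions["n_admissions"].to_numpy() >= 2
    # record numbering: primary record = individual id; secondary records of
    # readmitted individuals are appended after the primaries
    sec_index = np.full(n_ind, -1, dtype=np.int64)
    sec_index[np.flatnonzero(two)] = n_ind + np.arange(int(two.sum()))
    n_rec = n_ind + int(two.sum())

    if len(accepted):
        ia = accepted["id_a"].to_numpy(dtype=np.int64)
        ib = accepted["id_b"].to_numpy(dtype=np.int64)
        is_m = accepted["is_match"].to_numpy().astype(bool)
        # a matched pair joins the individual's two records; a (false) accepted
        # non-match joins the two individuals' primary records
        rows = np.where(is_m, ia, ia)
        cols = np.where(is_m, sec_index[ib], ib)
        graph = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n_rec, n_rec)
        )
        _, comp = csgraph.connected_components(graph, directed=False)
    else:
        comp = np.arange(n_rec)
    sizes = np.bincount(comp)
    return estimate_readmission(sizes)


def run_study(
    gen: GeneratorConfig,
    scenario: ScenarioConfig,
    n_reps: int = 500,
    target_fmr: float = 0.01,
    seed: int | None = None,
    models: dict[str, WeightModel] | None = None,
    train_individuals: int = 340_000,
    train_nonmatch_pairs: int = 3_000_000,
) -> SimulationResult:
    """Run the full readmission-bias simulation for one scenario.

    Weight models are fitted once from a large training extract (an analogue
    of a gold-standard-validated sample; ~30,000 matched pairs at the default
    size), then each replicate generates a fresh study population, overlays
    the unique-id scenario, links in two stages and estimates the readmission
    rate per weight variant.  Reproducible from ``seed`` via per-replicate
    substreams.
    """
    if n_reps < 1:
        raise DataError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    train_ss, *rep_ss = ss.spawn(n_reps + 1)

    schema = gen.schema
    if models is None:
        train_cfg = replace(
            gen,
            n_individuals=train_individuals,
            n_nonmatch_pairs=train_nonmatch_pairs,
        )
        train_pairs, _ = generate_population(train_cfg, rng=np.random.default_rng(train_ss))
        train_pairs = prefilter_pairs(train_pairs, schema)
        models = fit_weight_models(train_pairs, schema)

    methods = list(models.keys())
    rates = {m: [] for m in methods}
    sens = {m: [] for m in methods}
    true_rates = []
    n_failures = 0

    for rep in range(n_reps):
        rng = np.random.default_rng(rep_ss[rep])
        try:
            pairs, admissions = generate_population(gen, rng=rng)
            pairs = apply_uid_scenario(pairs, scenario, rng=rng)
            is_match = pairs["is_match"].to_numpy().astype(bool)
            n_true = int(is_match.sum())
            true_rate = float((admissions["n_admissions"] >= 2).mean())

            uid_linked = pairs["unique_id_flag"].to_numpy() == "agree"
            remainder = pairs.loc[~uid_linked]
            remainder = prefilter_pairs(remainder, schema)

            for method in methods:
                scored = score_pairs(remainder, models[method])
                thr = calibrate_threshold(scored, target_fmr)
                accepted_mask = classify(scored, thr.cutoff)
                accepted = pd.concat(
                    [pairs.loc[uid_linked], scored.loc[accepted_mask]],
                    ignore_index=True,
                )
                n_tp = int(accepted["is_match"].sum())
                sens[method].append(n_tp / n_true)
                rates[method].append(_readmission_from_links(admissions, accepted))
            true_rates.append(true_rate)
        except Exception:
            n_failures += 1
            continue

    if not true_rates:
        raise DataError("every replicate failed")
    mean_true = float(np.mean(true_rates))
    per_method = {}
    for m in methods:
        arr = np.asarray(rates[m])
        per_method[m] = MethodSummary(
            readmission_rate=float(arr.mean()),
            rate_se=float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
            percent_bias=percent_bias(float(arr.mean()), mean_true),
            sensitivity=float(np.mean(sens[m])),
        )
    return SimulationResult(
        per_method=per_method,
        n_reps=len(true_rates),
        scenario=scenario,
        true_rate=mean_true,
        n_failures=n_failures,
    )
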