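"""m/u-probability estimation and match-weight calculation.

Fellegi-Sunter linkage scores a candidate pair by the log-likelihood ratio of
its agreement evidence under the match (M) and non-match (U) hypotheses.  For
identifier k, ``m_k = P(agree on k | M)`` and ``u_k = P(agree on k | U)``.
Four weight families are supported:

* ``traditional`` - independence across identifiers,
  ``W = sum_k [ bit_k log2(m_k/u_k) + (1-bit_k) log2((1-m_k)/(1-u_k)) ]``;
* ``joint`` - probabilities estimated per full agreement pattern phi,
  ``W = log2(m_phi / u_phi)``, dropping the independence assumption;
* ``attribute`` - traditional-form weights with m/u estimated separately per
  (age cohort, sex, ethnic group) stratum;
* ``organisation`` - traditional-form weights with m/u per hospital.

Stratified variants fall back to the global table when a stratum has too few
matches to support estimation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    AgreementPattern,
    ComparisonPair,
    DataError,
    IdentifierSchema,
    as_frame,
    enumerate_patterns,
    pattern_codes,
)

__all__ = [
    "EstimationError",
    "MUTable",
    "WeightModel",
    "VARIANTS",
    "estimate_mu_independent",
    "estimate_mu_joint",
    "estimate_mu_stratified",
    "fit_weight_model",
    "weight_traditional",
    "weight_joint",
    "weight_for_pair",
    "weights_for_frame",
    "match_probability",
]

VARIANTS = ("traditional", "joint", "attribute", "organisation")

#: default minimum match counts before a stratum falls back to the global table
MIN_STRATUM_MATCHES = {"attribute": 100, "organisation": 500}

LOG_BASE = 2.0


class EstimationError(ValueError):
    """Raised when m/u probabilities cannot be estimated from the data given."""


def _clamp(p: float, n: int) -> float:
    """Clamp an estimated probability to [1/(2n), 1 - 1/(2n)].

    Keeps every log-ratio finite without materially moving well-estimated
    cells; n is the denominator the probability was estimated from.
    """
    lo = 1.0 / (2.0 * n)
    return min(max(p, lo), 1.0 - lo)


@dataclass
class MUTable:
    """m- and u-probabilities per identifier and (optionally) per pattern."""

    per_identifier: dict[str, tuple[float, float]]
    n_matches: int
    n_nonmatches: int
    per_pattern: dict[str, tuple[float, float]] | None = None
    #: raw (match, non-match) counts per pattern string, for reporting
    pattern_counts: dict[str, tuple[int, int]] | None = None

    def m(self, identifier: str) -> float:
        return self.per_identifier[identifier][0]

    def u(self, identifier: str) -> float:
        return self.per_identifier[identifier][1]

    def to_dict(self) -> dict:
        return {
            "per_identifier": {k: list(v) for k, v in self.per_identifier.items()},
            "n_matches": self.n_matches,
            "n_nonmatches": self.n_nonmatches,
            "per_pattern": (
                None
                if self.per_pattern is None
                else {k: list(v) for k, v in self.per_pattern.items()}
            ),
            "pattern_counts": (
                None
                if self.pattern_counts is None
                else {k: list(v) for k, v in self.pattern_counts.items()}
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MUTable":
        return cls(
            per_identifier={k: tuple(v) for k, v in d["per_identifier"].items()},
            n_matches=d["n_matches"],
            n_nonmatches=d["n_nonmatches"],
            per_pattern=(
                None
                if d.get("per_pattern") is None
                else {k: tuple(v) for k, v in d["per_pattern"].items()}
            ),
            pattern_counts=(
                None
                if d.get("pattern_counts") is None
                else {k: tuple(v) for k, v in d["pattern_counts"].items()}
            ),
        )


def _split_labels(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "is_match" not in frame.columns or frame["is_match"].isna().any():
        raise EstimationError("every pair must carry an is_match label")
    labels = frame["is_match"].to_numpy().astype(bool)
    if not labels.any():
        raise EstimationError("no matches in the labelled pair set")
    if labels.all():
        raise EstimationError("no non-matches in the labelled pair set")
    return labels, ~labels


def estimate_mu_independent(pairs, schema: IdentifierSchema | None = None) -> MUTable:
    """Per-identifier m/u probabilities by direct counting.

    ``m_k`` is the fraction of matched pairs agreeing on identifier k, ``u_k``
    the same fraction among non-matches.  Zero/one cells are clamped to keep
    weights finite.
    """
    schema = schema or IdentifierSchema()
    frame = as_frame(pairs, schema)
    is_m, is_u = _split_labels(frame)
    n_m, n_u = int(is_m.sum()), int(is_u.sum())
    per_identifier = {}
    for name, col in zip(schema.names, schema.bit_columns):
        bits = frame[col].to_numpy()
        m_k = _clamp(bits[is_m].mean(), n_m)
        u_k = _clamp(bits[is_u].mean(), n_u)
        per_identifier[name] = (float(m_k), float(u_k))
    return MUTable(per_identifier=per_identifier, n_matches=n_m, n_nonmatches=n_u)


def estimate_mu_joint(pairs, schema: IdentifierSchema | None = None) -> MUTable:
    """Joint (pattern-level) m/u probabilities over all 2^k patterns.

    Unobserved patterns receive the clamping floor 1/(2N); each class'
    probabilities are renormalised to sum to one afterwards.
    """
    schema = schema or IdentifierSchema()
    frame = as_frame(pairs, schema)
    is_m, is_u = _split_labels(frame)
    n_m, n_u = int(is_m.sum()), int(is_u.sum())
    codes = pattern_codes(frame, schema)
    n_pat = 2**schema.k
    counts_m = np.bincount(codes[is_m], minlength=n_pat).astype(float)
    counts_u = np.bincount(codes[is_u], minlength=n_pat).astype(float)

    def _pattern_probs(counts: np.ndarray, n: int) -> np.ndarray:
        p = np.array([_clamp(c / n, n) for c in counts])
        return p / p.sum()

    p_m = _pattern_probs(counts_m, n_m)
    p_u = _pattern_probs(counts_u, n_u)
    patterns = enumerate_patterns(schema)
    per_pattern = {
        pat.as_string(): (float(p_m[pat.index]), float(p_u[pat.index]))
        for pat in patterns
    }
    pattern_counts = {
        pat.as_string(): (int(counts_m[pat.index]), int(counts_u[pat.index]))
        for pat in patterns
    }
    base = estimate_mu_independent(frame, schema)
    return MUTable(
        per_identifier=base.per_identifier,
        n_matches=n_m,
        n_nonmatches=n_u,
        per_pattern=per_pattern,
        pattern_counts=pattern_counts,
    )


@dataclass
class WeightModel:
    """A fitted weighting scheme with stratum fallback rules."""

    variant: str
    global_table: MUTable
    schema: IdentifierSchema = field(default_factory=IdentifierSchema)
    stratum_tables: dict = field(default_factory=dict)
    min_stratum_matches: int = 0
    log_base: float = LOG_BASE

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise DataError(f"unknown weight variant {self.variant!r}")

    def table_for(self, key) -> MUTable:
        """Stratum table for a key, falling back to the global table."""
        return self.stratum_tables.get(key, self.global_table)

    def to_dict(self) -> dict:
        def _key_str(key) -> str:
            if isinstance(key, tuple):
                return "|".join(str(k) for k in key)
            return str(key)

        return {
            "variant": self.variant,
            "schema": list(self.schema.names),
            "log_base": self.log_base,
            "min_stratum_matches": self.min_stratum_matches,
            "global_table": self.global_table.to_dict(),
            "stratum_tables": {
                _key_str(k): v.to_dict() for k, v in self.stratum_tables.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "WeightModel":
        variant = d["variant"]

        def _key(key_str: str):
            return tuple(key_str.split("|")) if variant == "attribute" else key_str

        return cls(
            variant=variant,
            global_table=MUTable.from_dict(d["global_table"]),
            schema=IdentifierSchema(tuple(d["schema"])),
            stratum_tables={
                _key(k): MUTable.from_dict(v) for k, v in d["stratum_tables"].items()
            },
            min_stratum_matches=d.get("min_stratum_matches", 0),
            log_base=d.get("log_base", LOG_BASE),
        )

    @classmethod
    def from_json(cls, path) -> "WeightModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


_STRATUM_FIELDS = {
    "attribute": ("age_cohort", "sex", "ethnic_group"),
    "organisation": ("hospital_id",),
}


def estimate_mu_stratified(
    pairs,
    schema: IdentifierSchema | None = None,
    strat_by: str = "attributes",
    min_stratum_matches: int | None = None,
) -> WeightModel:
    """Per-stratum independence-style m/u tables with global fallback.

    ``strat_by='attributes'`` keys strata by (age cohort, sex, ethnic group);
    ``strat_by='hospital'`` keys them by hospital.  Stratified tables use the
    per-identifier (independence) form only: pattern-level estimation within
    strata is not supported because pattern counts per stratum are too sparse
    to be stable.
    """
    schema = schema or IdentifierSchema()
    if strat_by == "attributes":
        variant = "attribute"
    elif strat_by == "hospital":
        variant = "organisation"
    else:
        raise DataError(f"strat_by must be 'attributes' or 'hospital', got {strat_by!r}")
    if min_stratum_matches is None:
        min_stratum_matches = MIN_STRATUM_MATCHES[variant]

    frame = as_frame(pairs, schema)
    fields = _STRATUM_FIELDS[variant]
    for f in fields:
        if f not in frame.columns or frame[f].isna().any():
            raise DataError(f"stratifying field {f!r} missing or incomplete")
    global_table = estimate_mu_independent(frame, schema)

    stratum_tables = {}
    grouped = frame.groupby(list(fields), observed=True, sort=False)
    for key, sub in grouped:
        key = key if len(fields) > 1 else key
        if len(fields) == 1 and isinstance(key, tuple):
            key = key[0]
        labels = sub["is_match"].to_numpy().astype(bool)
        n_m = int(labels.sum())
        if n_m < min_stratum_matches or n_m == len(sub):
            continue  # thin or degenerate stratum: falls back to global table
        if n_m == 0:
            continue
        stratum_tables[key] = estimate_mu_independent(sub, schema)
    return WeightModel(
        variant=variant,
        global_table=global_table,
        schema=schema,
        stratum_tables=stratum_tables,
        min_stratum_matches=min_stratum_matches,
    )


def fit_weight_model(
    pairs,
    schema: IdentifierSchema | None = None,
    variant: str = "traditional",
    min_stratum_matches: int | None = None,
) -> WeightModel:
    """Fit any of the four weight variants from a labelled pair set."""
    schema = schema or IdentifierSchema()
    if variant == "traditional":
        return WeightModel("traditional", estimate_mu_independent(pairs, schema), schema)
    if variant == "joint":
        return WeightModel("joint", estimate_mu_joint(pairs, schema), schema)
    if variant == "attribute":
        return estimate_mu_stratified(pairs, schema, "attributes", min_stratum_matches)
    if variant == "organisation":
        return estimate_mu_stratified(pairs, schema, "hospital", min_stratum_matches)
    raise DataError(f"unknown weight variant {variant!r}")


def weight_traditional(pattern: AgreementPattern, mu: MUTable) -> float:
    """Independence-form match weight for one agreement pattern (log2 units)."""
    if not mu.per_identifier:
        raise DataError("MUTable has no per-identifier probabilities")
    if len(pattern) != len(mu.per_identifier):
        raise DataError("pattern length does not match the m/u table")
    w = 0.0
    for bit, (m_k, u_k) in zip(pattern.bits, mu.per_identifier.values()):
        if bit:
            w += math.log2(m_k / u_k)
        else:
            w += math.log2((1.0 - m_k) / (1.0 - u_k))
    return w


def weight_joint(pattern: AgreementPattern, mu: MUTable) -> float:
    """Pattern-level match weight ``log2(m_phi / u_phi)``."""
    if mu.per_pattern is None:
        raise DataError("MUTable has no per-pattern probabilities; fit the joint variant")
    key = pattern.as_string()
    if key not in mu.per_pattern:
        raise KeyError(f"pattern {key} absent from per-pattern table")
    m_phi, u_phi = mu.per_pattern[key]
    return math.log2(m_phi / u_phi)


def _stratum_key(pair: ComparisonPair, variant: str):
    if variant == "attribute":
        if None in (pair.age_cohort, pair.sex, pair.ethnic_group):
            raise DataError("pair lacks attribute fields required by the attribute variant")
        return (pair.age_cohort, pair.sex, pair.ethnic_group)
    if pair.hospital_id is None:
        raise DataError("pair lacks hospital_id required by the organisation variant")
    return pair.hospital_id


def weight_for_pair(pair: ComparisonPair, model: WeightModel) -> float:
    """Weight of one pair under a fitted model, applying stratum fallback."""
    if model.variant == "traditional":
        return weight_traditional(pair.pattern, model.global_table)
    if model.variant == "joint":
        return weight_joint(pair.pattern, model.global_table)
    table = model.table_for(_stratum_key(pair, model.variant))
    return weight_traditional(pair.pattern, table)


def _weight_lookup(table: MUTable, schema: IdentifierSchema, joint: bool) -> np.ndarray:
    """Vector of weights indexed by pattern code."""
    pats = enumerate_patterns(schema)
    if joint:
        return np.array([weight_joint(p, table) for p in pats])
    return np.array([weight_traditional(p, table) for p in pats])


def weights_for_frame(frame: pd.DataFrame, model: WeightModel) -> np.ndarray:
    """Vectorised :func:`weight_for_pair` over a pair table."""
    schema = model.schema
    codes = pattern_codes(frame, schema)
    if model.variant in ("traditional", "joint"):
        lut = _weight_lookup(model.global_table, schema, joint=model.variant == "joint")
        return lut[codes]

    fields = list(_STRATUM_FIELDS[model.variant])
    for f in fields:
        if f not in frame.columns or frame[f].isna().any():
            raise DataError(f"pair table lacks complete {f!r} needed by {model.variant}")
    if len(fields) == 1:
        keys = frame[fields[0]].to_numpy()
        stratum_idx, uniques = pd.factorize(keys)
        key_list = list(uniques)
    else:
        stratum_idx, uniques = pd.factorize(
            pd.MultiIndex.from_frame(frame[fields]), sort=False
        )
        key_list = [tuple(u) for u in uniques]
    luts = np.stack(
        [
            _weight_lookup(model.table_for(key), schema, joint=False)
            for key in key_list
        ]
    )
    return luts[stratum_idx, codes]


def match_probability(n_matches_phi: int, n_nonmatches_phi: int) -> float:
    """Fraction of pairs in a pattern class that are true matches."""
    if n_matches_phi < 0 or n_nonmatches_phi < 0:
        raise DataError("counts must be non-negative")
    total = n_matches_phi + n_nonmatches_phi
    if total == 0:
        raise DataError("pattern class has no pairs")
    return n_matches_phi / total
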