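"""Identifier schemas, agreement patterns and comparison-pair handling.

Probabilistic record linkage compares candidate record pairs on a fixed,
ordered set of identifiers (here: date of birth, sex, postcode).  Each pair
is summarised by a binary *agreement pattern*: one bit per identifier, 1 when
the two records agree and 0 when they disagree or either value is missing.
Everything downstream (m/u-probability estimation, match weights, threshold
calibration) operates on these patterns plus the pair's attributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_IDENTIFIERS",
    "AGE_COHORTS",
    "SEXES",
    "ETHNIC_GROUPS",
    "UID_FLAGS",
    "SchemaError",
    "DataError",
    "IdentifierSchema",
    "AgreementPattern",
    "ComparisonPair",
    "encode_agreement",
    "enumerate_patterns",
    "excluded_patterns",
    "prefilter_pairs",
    "cross_pair_count",
    "pairs_to_frame",
    "frame_to_pairs",
    "as_frame",
]

DEFAULT_IDENTIFIERS = ("date_of_birth", "sex", "postcode")
AGE_COHORTS = ("0-1", "5-6", "18-19")
SEXES = ("female", "male")
ETHNIC_GROUPS = ("Missing", "White", "Mixed", "Asian", "Black", "Other")
UID_FLAGS = ("agree", "disagree", "missing")

#: attribute columns that define a comparison pair beyond its pattern
ATTRIBUTE_COLUMNS = ("age_cohort", "sex", "ethnic_group")


class SchemaError(ValueError):
    """Raised when values or columns do not line up with the identifier schema."""


class DataError(ValueError):
    """Raised for invalid pair data (bad categories, missing labels, ...)."""


@dataclass(frozen=True)
class IdentifierSchema:
    """Ordered set of identifier labels; order fixes pattern bit positions."""

    names: tuple[str, ...] = DEFAULT_IDENTIFIERS

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise SchemaError("identifier schema must be non-empty")
        if len(set(names)) != len(names):
            raise SchemaError(f"identifier labels must be unique, got {names}")

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def bit_columns(self) -> tuple[str, ...]:
        """Column names used for agreement bits in pair tables."""
        return tuple(f"agree_{name}" for name in self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"identifier {name!r} not in schema {self.names}") from None


@dataclass(frozen=True)
class AgreementPattern:
    """Binary agree/disagree vector aligned to an :class:`IdentifierSchema`."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise SchemaError(f"pattern bits must be 0/1, got {self.bits}")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)

    def as_string(self) -> str:
        """Pattern as e.g. ``'110'`` in schema bit order."""
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "AgreementPattern":
        return cls(tuple(int(c) for c in s))

    @property
    def index(self) -> int:
        """Integer code of the pattern, first identifier = most significant bit."""
        code = 0
        for b in self.bits:
            code = (code << 1) | b
        return code


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return value is pd.NA


def _canonical(value) -> str:
    return str(value).strip().casefold()


def encode_agreement(
    values_a: Sequence, values_b: Sequence, schema: IdentifierSchema
) -> AgreementPattern:
    """Encode two identifier-value lists as an agreement pattern.

    A bit is 1 only when both values are non-missing and equal under exact
    string comparison after trimming and case-folding.  Missing values on
    either side (or both) count as disagreement.
    """
    if len(values_a) != len(schema.names) or len(values_b) != len(schema.names):
        raise SchemaError(
            f"value lists of length {len(values_a)}/{len(values_b)} do not match "
            f"schema of length {schema.k}"
        )
    bits = []
    for a, b in zip(values_a, values_b):
        if _is_missing(a) or _is_missing(b):
            bits.append(0)
        else:
            bits.append(int(_canonical(a) == _canonical(b)))
    return AgreementPattern(tuple(bits))


def enumerate_patterns(schema: IdentifierSchema) -> list[AgreementPattern]:
    """All 2^k agreement patterns in binary-ascending order."""
    k = schema.k
    out = []
    for code in range(2**k):
        bits = tuple((code >> (k - 1 - i)) & 1 for i in range(k))
        out.append(AgreementPattern(bits))
    return out


def excluded_patterns(schema: IdentifierSchema) -> list[AgreementPattern]:
    """Patterns treated as certain non-matches and dropped before estimation.

    The all-zero pattern (no agreement on any identifier) is always excluded;
    if the schema contains a ``sex`` identifier, agreement on sex alone is
    excluded as well, since chance agreement on a two-category field carries
    no linkage evidence.
    """
    zero = AgreementPattern((0,) * schema.k)
    out = [zero]
    if "sex" in schema.names:
        bits = [0] * schema.k
        bits[schema.index_of("sex")] = 1
        out.append(AgreementPattern(tuple(bits)))
    return out


@dataclass
class ComparisonPair:
    """One candidate record pair: agreement pattern plus pair attributes."""

    pattern: AgreementPattern
    age_cohort: str | None = None
    sex: str | None = None
    ethnic_group: str | None = None
    hospital_id: str | None = None
    unique_id_flag: str | None = None
    is_match: bool | None = None

    def __post_init__(self) -> None:
        if self.age_cohort is not None and self.age_cohort not in AGE_COHORTS:
            raise DataError(f"unknown age cohort {self.age_cohort!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise DataError(f"unknown sex {self.sex!r}")
        if self.ethnic_group is not None and self.ethnic_group not in ETHNIC_GROUPS:
            raise DataError(f"unknown ethnic group {self.ethnic_group!r}")
        if self.unique_id_flag is not None and self.unique_id_flag not in UID_FLAGS:
            raise DataError(f"unknown unique-id flag {self.unique_id_flag!r}")


def pairs_to_frame(
    pairs: Iterable[ComparisonPair], schema: IdentifierSchema
) -> pd.DataFrame:
    """Tabulate comparison pairs; one agreement-bit column per identifier."""
    pairs = list(pairs)
    data: dict[str, list] = {col: [] for col in schema.bit_columns}
    for extra in ("age_cohort", "sex", "ethnic_group", "hospital_id", "unique_id_flag", "is_match"):
        data[extra] = []
    for p in pairs:
        if len(p.pattern) != schema.k:
            raise SchemaError(
                f"pattern {p.pattern.as_string()} does not match schema length {schema.k}"
            )
        for col, bit in zip(schema.bit_columns, p.pattern.bits):
            data[col].append(bit)
        data["age_cohort"].append(p.age_cohort)
        data["sex"].append(p.sex)
        data["ethnic_group"].append(p.ethnic_group)
        data["hospital_id"].append(p.hospital_id)
        data["unique_id_flag"].append(p.unique_id_flag)
        data["is_match"].append(p.is_match)
    frame = pd.DataFrame(data)
    for col in schema.bit_columns:
        frame[col] = frame[col].astype(np.int8)
    return frame


def frame_to_pairs(frame: pd.DataFrame, schema: IdentifierSchema) -> list[ComparisonPair]:
    """Inverse of :func:`pairs_to_frame`."""
    missing = [c for c in schema.bit_columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"pair table lacks agreement columns {missing}")
    out = []
    bit_arrays = [frame[c].to_numpy() for c in schema.bit_columns]

    def _get(row_idx: int, col: str):
        if col not in frame.columns:
            return None
        v = frame[col].iloc[row_idx]
        if pd.isna(v):
            return None
        return bool(v) if col == "is_match" else v

    for i in range(len(frame)):
        pattern = AgreementPattern(tuple(int(a[i]) for a in bit_arrays))
        out.append(
            ComparisonPair(
                pattern=pattern,
                age_cohort=_get(i, "age_cohort"),
                sex=_get(i, "sex"),
                ethnic_group=_get(i, "ethnic_group"),
                hospital_id=_get(i, "hospital_id"),
                unique_id_flag=_get(i, "unique_id_flag"),
                is_match=_get(i, "is_match"),
            )
        )
    return out


def as_frame(pairs, schema: IdentifierSchema) -> pd.DataFrame:
    """Accept either a pair table or a list of pairs; return the table form."""
    if isinstance(pairs, pd.DataFrame):
        missing = [c for c in schema.bit_columns if c not in pairs.columns]
        if missing:
            raise SchemaError(f"pair table lacks agreement columns {missing}")
        return pairs
    return pairs_to_frame(pairs, schema)


def pattern_codes(frame: pd.DataFrame, schema: IdentifierSchema) -> np.ndarray:
    """Integer pattern code per row (first identifier = most significant bit)."""
    codes = np.zeros(len(frame), dtype=np.int64)
    for col in schema.bit_columns:
        codes = (codes << 1) | frame[col].to_numpy().astype(np.int64)
    return codes


def prefilter_pairs(pairs, schema: IdentifierSchema | None = None):
    """Drop pairs assumed non-matches a priori: no agreement at all, or
    agreement on sex only.  Order is preserved; the operation is idempotent.

    Accepts and returns either a list of :class:`ComparisonPair` or a pair
    table (DataFrame).
    """
    schema = schema or IdentifierSchema()
    dropped = {p.index for p in excluded_patterns(schema)}
    if isinstance(pairs, pd.DataFrame):
        codes = pattern_codes(pairs, schema)
        keep = ~np.isin(codes, list(dropped))
        return pairs.loc[keep]
    return [p for p in pairs if p.pattern.index not in dropped]


def cross_pair_count(n_a: int, n_b: int, n_matches: int) -> int:
    """Number of candidate non-match pairs under full cross-pairing.

    Linking files of ``n_a`` and ``n_b`` records with ``n_matches`` true
    matches yields ``n_a * n_b - n_matches`` non-match comparisons.
    """
    if n_a < 0 or n_b < 0 or n_matches < 0:
        raise DataError("record and match counts must be non-negative")
    if n_matches > min(n_a, n_b):
        raise DataError(
            f"n_matches={n_matches} exceeds the smaller file size {min(n_a, n_b)}"
        )
    return n_a * n_b - n_matches
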