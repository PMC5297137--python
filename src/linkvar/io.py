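"""Reading and writing pair tables, weight tables and run configuration.

Pair tables are UTF-8 comma-separated files with a header row.  Agreement
may be supplied pre-encoded (one 0/1 column per identifier, named
``agree_<identifier>``) or as raw values (columns ``<identifier>_a`` and
``<identifier>_b``), which are encoded on read with missing values counting
as disagreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    AGE_COHORTS,
    ETHNIC_GROUPS,
    SEXES,
    UID_FLAGS,
    DataError,
    IdentifierSchema,
    SchemaError,
    as_frame,
    enumerate_patterns,
    excluded_patterns,
)
from .estimation import WeightModel, match_probability, weight_joint, weight_traditional

log = logging.getLogger("linkvar")

__all__ = ["read_pairs", "write_pairs", "write_weight_table", "RunConfig", "load_config"]

_CATEGORY_DOMAINS = {
    "age_cohort": set(AGE_COHORTS),
    "sex": set(SEXES),
    "ethnic_group": set(ETHNIC_GROUPS),
    "unique_id_flag": set(UID_FLAGS),
}


def _encode_raw(frame: pd.DataFrame, schema: IdentifierSchema) -> pd.DataFrame:
    out = frame.copy()
    for name in schema.names:
        a, b = f"{name}_a", f"{name}_b"
        if a not in frame.columns or b not in frame.columns:
            raise SchemaError(
                f"pair table lacks both agree_{name} and raw columns {a}/{b}"
            )
        va = frame[a].astype("string").str.strip().str.casefold()
        vb = frame[b].astype("string").str.strip().str.casefold()
        agree = (va == vb) & va.notna() & vb.notna() & (va != "") & (vb != "")
        out[f"agree_{name}"] = agree.astype(np.int8)
        out = out.drop(columns=[a, b])
    return out


def read_pairs(path, schema: IdentifierSchema | None = None) -> pd.DataFrame:
    """Read a comparison-pair table, encoding raw identifier values if needed."""
    schema = schema or IdentifierSchema()
    frame = pd.read_csv(path, dtype={"hospital_id": "string"})
    if frame.empty:
        log.warning("pair table %s is empty", path)
    pre_encoded = all(c in frame.columns for c in schema.bit_columns)
    if not pre_encoded:
        frame = _encode_raw(frame, schema)
    for col in schema.bit_columns:
        bad = ~frame[col].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"non-binary agreement value in {col!r} at row {row + 2}")
        frame[col] = frame[col].astype(np.int8)
    for col, domain in _CATEGORY_DOMAINS.items():
        if col not in frame.columns:
            continue
        values = frame[col]
        bad = values.notna() & ~values.isin(list(domain))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"invalid {col} value {values.iloc[row]!r} at row {row + 2}"
            )
    if "is_match" in frame.columns:
        frame["is_match"] = frame["is_match"].map(
            {True: True, False: False, 1: True, 0: False, "True": True, "False": False}
        )
    return frame


def write_pairs(pairs, path, schema: IdentifierSchema | None = None) -> None:
    """Write a pair table as CSV (missing values as empty strings)."""
    schema = schema or IdentifierSchema()
    frame = as_frame(pairs, schema)
    frame.to_csv(path, index=False)


def write_weight_table(model: WeightModel, path) -> None:
    """Table-style report: one row per agreement pattern, weights to 1 dp.

    Excluded patterns (no agreement, or sex-only agreement) are annotated.
    For stratified variants one weight column per stratum is emitted in
    addition to the global column.
    """
    schema = model.schema
    patterns = enumerate_patterns(schema)
    excluded = {p.as_string() for p in excluded_patterns(schema)}
    rows = []
    counts = model.global_table.pattern_counts or {}
    for pat in patterns:
        key = pat.as_string()
        row = {"pattern": key, "excluded": key in excluded}
        if key in counts:
            n_m, n_u = counts[key]
            row["n_matches"] = n_m
            row["n_nonmatches"] = n_u
            if n_m + n_u > 0:
                row["match_probability"] = round(match_probability(n_m, n_u), 4)
        if model.variant == "joint":
            row["weight"] = round(weight_joint(pat, model.global_table), 1)
        else:
            row["weight"] = round(weight_traditional(pat, model.global_table), 1)
        if model.variant in ("attribute", "organisation"):
            for skey in sorted(model.stratum_tables, key=str):
                label = "|".join(skey) if isinstance(skey, tuple) else str(skey)
                row[f"weight[{label}]"] = round(
                    weight_traditional(pat, model.stratum_tables[skey]), 1
                )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_KNOWN_KEYS = {
    "schema",
    "variant",
    "target_fmr",
    "min_stratum_matches",
    "generator",
    "scenario",
    "seed",
    "output_dir",
    "log_level",
    "n_reps",
}


@dataclass
class RunConfig:
    """Resolved run configuration; unknown keys are rejected on load."""

    schema: IdentifierSchema = field(default_factory=IdentifierSchema)
    variant: str = "traditional"
    target_fmr: float = 0.01
    min_stratum_matches: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    seed: int | None = None
    output_dir: str = "."
    log_level: str = "INFO"
    n_reps: int = 500

    def to_dict(self) -> dict:
        return {
            "schema": list(self.schema.names),
            "variant": self.variant,
            "target_fmr": self.target_fmr,
            "min_stratum_matches": self.min_stratum_matches,
            "generator": self.generator,
            "scenario": self.scenario,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "n_reps": self.n_reps,
        }

    def dump(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Load YAML (or JSON, a YAML subset) run configuration with strict keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataError(f"config {path} must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "schema" in kwargs:
        kwargs["schema"] = IdentifierSchema(tuple(kwargs["schema"]))
    return RunConfig(**kwargs)
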