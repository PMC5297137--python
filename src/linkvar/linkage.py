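"""Scoring, threshold calibration and linkage quality metrics.

Candidate pairs are scored with a fitted :class:`~linkvar.estimation.WeightModel`,
rank-ordered by weight, and classified with a single cut-off chosen as the
smallest observed weight whose acceptance region keeps the false-match rate
(the fraction of accepted pairs that are truly non-matches) at or below a
target, conventionally 1%.  Ties at the cut-off are accepted together, which
makes calibration deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ComparisonPair, DataError, IdentifierSchema, as_frame
from .estimation import WeightModel, weights_for_frame

__all__ = [
    "ScoredPair",
    "ThresholdResult",
    "LinkageMetrics",
    "score_pairs",
    "calibrate_threshold",
    "classify",
    "linkage_metrics",
    "estimate_readmission",
    "percent_bias",
]


@dataclass
class ScoredPair:
    pair: ComparisonPair
    weight: float


@dataclass
class ThresholdResult:
    cutoff: float
    achieved_fmr: float
    target_fmr: float
    n_accepted: int


@dataclass
class LinkageMetrics:
    sensitivity: float
    false_match_rate: float
    n_true_matches: int
    n_accepted: int


def score_pairs(pairs, model: WeightModel):
    """Weight every candidate pair; input order is preserved.

    A list of :class:`ComparisonPair` returns a list of :class:`ScoredPair`;
    a pair table returns a copy with a ``weight`` column.
    """
    if isinstance(pairs, pd.DataFrame):
        out = pairs.copy()
        out["weight"] = weights_for_frame(pairs, model) if len(pairs) else []
        return out
    pairs = list(pairs)
    if not pairs:
        return []
    frame = as_frame(pairs, model.schema)
    weights = weights_for_frame(frame, model)
    return [ScoredPair(pair=p, weight=float(w)) for p, w in zip(pairs, weights)]


def _weights_and_labels(scored) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scored, pd.DataFrame):
        if "weight" not in scored.columns:
            raise DataError("scored table lacks a 'weight' column")
        if "is_match" not in scored.columns or scored["is_match"].isna().any():
            raise DataError("calibration requires is_match labels on every pair")
        return (
            scored["weight"].to_numpy(dtype=float),
            scored["is_match"].to_numpy().astype(bool),
        )
    weights, labels = [], []
    for sp in scored:
        if sp.pair.is_match is None:
            raise DataError("calibration requires is_match labels on every pair")
        weights.append(sp.weight)
        labels.append(bool(sp.pair.is_match))
    return np.asarray(weights, dtype=float), np.asarray(labels, dtype=bool)


def calibrate_threshold(scored, target_fmr: float = 0.01) -> ThresholdResult:
    """Choose the lowest observed-weight cut-off meeting a false-match target.

    The cut-off is the smallest observed weight c such that, among pairs with
    weight >= c, the fraction of non-matches does not exceed ``target_fmr``.
    If no observed weight qualifies, the cut-off is ``+inf`` and nothing is
    accepted.
    """
    if not 0.0 < target_fmr < 1.0:
        raise DataError("target_fmr must lie in (0, 1)")
    weights, labels = _weights_and_labels(scored)
    if len(weights) == 0:
        return ThresholdResult(np.inf, 0.0, target_fmr, 0)

    order = np.argsort(-weights, kind="stable")
    w_sorted = weights[order]
    nonmatch_sorted = (~labels[order]).astype(np.int64)
    cum_nonmatch = np.cumsum(nonmatch_sorted)
    cum_total = np.arange(1, len(weights) + 1)
    # candidate cut-offs are tie-group boundaries (last index of each weight)
    is_boundary = np.r_[w_sorted[1:] != w_sorted[:-1], True]
    fmr = cum_nonmatch / cum_total
    ok = is_boundary & (fmr <= target_fmr)
    if not ok.any():
        return ThresholdResult(np.inf, 0.0, target_fmr, 0)
    idx = np.flatnonzero(ok)[-1]  # lowest qualifying observed weight
    return ThresholdResult(
        cutoff=float(w_sorted[idx]),
        achieved_fmr=float(fmr[idx]),
        target_fmr=target_fmr,
        n_accepted=int(cum_total[idx]),
    )


def classify(scored, cutoff: float):
    """Accept pairs with weight >= cutoff (``+inf`` accepts nothing)."""
    if isinstance(scored, pd.DataFrame):
        return scored["weight"].to_numpy(dtype=float) >= cutoff
    if len(scored) and isinstance(scored[0], ScoredPair):
        return [sp.weight >= cutoff for sp in scored]
    return np.asarray(scored, dtype=float) >= cutoff


def linkage_metrics(decisions, truth) -> LinkageMetrics:
    """Sensitivity and false-match rate of a set of accept decisions."""
    decisions = np.asarray(decisions, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if len(decisions) != len(truth):
        raise DataError("decisions and truth differ in length")
    n_matches = int(truth.sum())
    if n_matches == 0:
        raise DataError("no true matches in the evaluation set")
    n_accepted = int(decisions.sum())
    tp = int((decisions & truth).sum())
    fp = n_accepted - tp
    return LinkageMetrics(
        sensitivity=tp / n_matches,
        false_match_rate=fp / n_accepted if n_accepted else 0.0,
        n_true_matches=n_matches,
        n_accepted=n_accepted,
    )


def estimate_readmission(admission_counts) -> float:
    """Fraction of individuals with two or more linked admission records."""
    counts = np.asarray(list(admission_counts), dtype=np.int64)
    if counts.size == 0:
        raise DataError("no individuals")
    return float((counts >= 2).mean())


def percent_bias(estimated: float, true_value: float) -> float:
    """Percentage difference between an estimate and the true value."""
    if true_value <= 0:
        raise DataError("true_value must be positive")
    return 100.0 * (estimated - true_value) / true_value
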