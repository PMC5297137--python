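"""Identifier-error risk modelling.

Errors are defined against a gold standard: in a matched record pair, an
identifier "error" is any disagreement or missing value (``1 - agreement
bit``).  This module

* stacks matched pairs into per-(pair x identifier) error records,
* fits a logistic regression of error risk on age cohort, sex and ethnic
  group, optionally with a hospital random intercept (a multilevel model,
  fitted by maximum likelihood with Gauss-Hermite quadrature over the
  random effect),
* tests pairwise dependence between identifier errors, and
* computes funnel-plot control limits for between-hospital comparison of
  error proportions.

Reference levels follow the epidemiological convention of the source data:
male, infants (0-1), White ethnic group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import DataError, IdentifierSchema, as_frame

__all__ = [
    "ErrorModelFit",
    "DependenceResult",
    "build_error_records",
    "fit_error_model",
    "test_pairwise_dependence",
    "funnel_limits",
    "funnel_table",
]

REFERENCE_LEVELS = {"sex": "male", "age_cohort": "0-1", "ethnic_group": "White"}

_GH_NODES = 15


def build_error_records(pairs, schema: IdentifierSchema | None = None) -> pd.DataFrame:
    """One row per (matched pair, identifier) with a binary error indicator.

    ``error = 1 - agreement bit``; only pairs labelled as matches contribute,
    since errors are defined against the gold-standard pairing.
    """
    schema = schema or IdentifierSchema()
    frame = as_frame(pairs, schema)
    if "is_match" not in frame.columns:
        raise DataError("pairs must carry is_match labels")
    matches = frame[frame["is_match"].astype(bool)]
    if matches.empty:
        raise DataError("no matched pairs to derive error records from")
    keep = [
        c
        for c in ("age_cohort", "sex", "ethnic_group", "hospital_id")
        if c in matches.columns
    ]
    records = []
    for name, col in zip(schema.names, schema.bit_columns):
        sub = matches[keep].copy()
        sub["identifier"] = name
        sub["error"] = (1 - matches[col].to_numpy()).astype(np.int8)
        records.append(sub)
    out = pd.concat(records, ignore_index=True)
    return out[["identifier", "error"] + keep]


@dataclass
class ErrorModelFit:
    """Result of a (multilevel) logistic error-risk fit."""

    fixed_effects: dict[str, tuple[float, float]]  # name -> (log-odds, SE)
    hospital_variance: float
    converged: bool
    n_obs: int
    method: str = "glm"

    def odds_ratio(self, name: str) -> tuple[float, float, float]:
        """Odds ratio and 95% CI for one fixed effect."""
        est, se = self.fixed_effects[name]
        return (
            float(np.exp(est)),
            float(np.exp(est - 1.96 * se)),
            float(np.exp(est + 1.96 * se)),
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, (est, se) in self.fixed_effects.items():
            or_, lo, hi = self.odds_ratio(name)
            rows.append(
                {
                    "term": name,
                    "estimate": est,
                    "se": se,
                    "odds_ratio": or_,
                    "or_ci_low": lo,
                    "or_ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def _design(records: pd.DataFrame) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Treatment-coded design matrix with fixed reference levels."""
    cols = {"intercept": np.ones(len(records))}
    factors = [("identifier", None), ("age_cohort", "0-1"), ("sex", "male"), ("ethnic_group", "White")]
    for factor, ref in factors:
        if factor not in records.columns:
            continue
        levels = [str(v) for v in pd.unique(records[factor].dropna())]
        if len(levels) < 2:
            continue
        if ref is None:
            ref = sorted(levels)[0]
        if ref not in levels:
            ref = sorted(levels)[0]
        values = records[factor].astype(str).to_numpy()
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{factor}[{lev}]"] = (values == lev).astype(float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    return X, names, records


def _aggregate(X: np.ndarray, y: np.ndarray, clusters: np.ndarray):
    """Collapse rows sharing (cluster, covariate pattern) to binomial counts."""
    df = pd.DataFrame(X)
    df["_cluster"] = clusters
    df["_y"] = y
    grouped = df.groupby(["_cluster"] + list(range(X.shape[1])), sort=True)
    agg = grouped["_y"].agg(["sum", "count"]).reset_index()
    Xa = agg[list(range(X.shape[1]))].to_numpy(dtype=float)
    succ = agg["sum"].to_numpy(dtype=float)
    trials = agg["count"].to_numpy(dtype=float)
    cl = pd.factorize(agg["_cluster"].to_numpy())[0]
    order = np.argsort(cl, kind="stable")
    return Xa[order], succ[order], trials[order], cl[order]


def _glm_logit(X, succ, trials):
    import statsmodels.api as sm

    endog = np.column_stack([succ, trials - succ])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return res.params, res.bse, res.converged if hasattr(res, "converged") else True


def _agq_nll(params, X, succ, trials, cluster_bounds, cluster_of_row):
    """Negative marginal log-likelihood with a N(0, sigma^2) random intercept.

    Adaptive Gauss-Hermite quadrature: for each cluster the integrand is
    recentred at its mode (found by Newton iteration) and rescaled by the
    local curvature before applying the quadrature rule.  Rows must be
    sorted by cluster; ``cluster_bounds`` are the reduceat offsets.
    """
    beta, sigma = params[:-1], params[-1]
    eta0 = X @ beta
    n_clusters = len(cluster_bounds)

    # Newton iterations for the per-cluster mode of
    #   h(z) = sum_i [s_i log p_i + (n_i - s_i) log q_i] - z^2 / 2
    z_hat = np.zeros(n_clusters)
    for _ in range(25):
        eta = eta0 + sigma * z_hat[cluster_of_row]
        p = special.expit(eta)
        score_rows = succ - trials * p
        info_rows = trials * p * (1.0 - p)
        h1 = sigma * np.add.reduceat(score_rows, cluster_bounds) - z_hat
        h2 = -(sigma**2) * np.add.reduceat(info_rows, cluster_bounds) - 1.0
        step = h1 / h2
        z_hat = z_hat - step
        if np.max(np.abs(step)) < 1e-10:
            break
    tau = 1.0 / np.sqrt(-h2)  # local curvature scale at the mode

    nodes, gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
    log_w = np.log(gh_w)
    z_nodes = z_hat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    eta = eta0[:, None] + sigma * z_nodes[cluster_of_row]
    row_ll = succ[:, None] * special.log_expit(eta) + (trials - succ)[
        :, None
    ] * special.log_expit(-eta)
    S = np.add.reduceat(row_ll, cluster_bounds, axis=0)
    g = S - 0.5 * z_nodes**2  # h(z) at the shifted nodes
    A = log_w[None, :] + nodes[None, :] ** 2 + g
    ll_c = (
        0.5 * np.log(2.0) + np.log(tau) + special.logsumexp(A, axis=1)
        - 0.5 * np.log(2.0 * np.pi)
    )
    return -float(ll_c.sum())


def _fit_random_intercept(X, succ, trials, clusters, beta0):
    cluster_bounds = np.flatnonzero(np.r_[True, np.diff(clusters) != 0])
    x0 = np.append(beta0, 0.3)
    args = (X, succ, trials, cluster_bounds, clusters)
    lb = [-np.inf] * X.shape[1] + [0.0]
    ub = [np.inf] * X.shape[1] + [10.0]
    res = optimize.minimize(
        _agq_nll,
        x0,
        args=args,
        method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": 500, "ftol": 1e-11},
    )
    params = res.x
    # observed-information SEs from a finite-difference Hessian
    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(params, _agq_nll, args=args)
    H = 0.5 * (H + H.T)
    n_par = len(params)
    se = np.full(n_par, np.nan)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        try:
            cov_b = np.linalg.inv(H[:-1, :-1])
            se[:-1] = np.sqrt(np.maximum(np.diag(cov_b), 0.0))
        except np.linalg.LinAlgError:
            pass
    converged = bool(res.success) and np.isfinite(params).all()
    return params[:-1], se[:-1], float(params[-1]) ** 2, converged


def fit_error_model(records: pd.DataFrame, include_random_effect: bool = True) -> ErrorModelFit:
    """Logistic regression of identifier-error risk on record attributes.

    With ``include_random_effect`` a hospital random intercept is added and
    the marginal likelihood is maximised (15-node Gauss-Hermite quadrature).
    Non-convergence and separation are flagged on the result, not raised.
    """
    if "error" not in records.columns:
        raise DataError("records must contain an 'error' column")
    X, names, _ = _design(records)
    y = records["error"].to_numpy(dtype=float)
    have_clusters = "hospital_id" in records.columns and records["hospital_id"].nunique() > 1
    clusters = (
        records["hospital_id"].to_numpy()
        if have_clusters
        else np.zeros(len(records), dtype=int)
    )
    Xa, succ, trials, cl = _aggregate(X, y, clusters)

    beta, bse, glm_ok = _glm_logit(Xa, succ, trials)
    separated = bool(np.any(np.abs(beta) > 15) or not np.isfinite(bse).all())

    if include_random_effect and have_clusters and not separated:
        est, se, var, ok = _fit_random_intercept(Xa, succ, trials, cl, beta)
        fixed = {n: (float(e), float(s)) for n, e, s in zip(names, est, se)}
        return ErrorModelFit(
            fixed_effects=fixed,
            hospital_variance=var,
            converged=ok and np.isfinite(se).all(),
            n_obs=len(records),
            method="gauss-hermite",
        )
    fixed = {n: (float(e), float(s)) for n, e, s in zip(names, beta, bse)}
    return ErrorModelFit(
        fixed_effects=fixed,
        hospital_variance=0.0,
        converged=bool(glm_ok) and not separated,
        n_obs=len(records),
        method="glm",
    )


@dataclass
class DependenceResult:
    """Association between errors in two identifiers among matched pairs."""

    odds_ratio: float
    p_value: float
    degenerate: bool = False
    note: str = ""


def test_pairwise_dependence(
    pairs,
    identifier_i: str,
    identifier_j: str,
    schema: IdentifierSchema | None = None,
    include_random_effect: bool = True,
) -> DependenceResult:
    """Logistic regression of error in identifier i on error in identifier j.

    Restricted to matched pairs.  Returns the association odds ratio and a
    Wald p-value; degenerate 2x2 tables (an empty margin, or i == j) are
    flagged rather than raised.
    """
    schema = schema or IdentifierSchema()
    col_i = f"agree_{identifier_i}"
    col_j = f"agree_{identifier_j}"
    frame = as_frame(pairs, schema)
    for ident in (identifier_i, identifier_j):
        if ident not in schema.names:
            raise DataError(f"identifier {ident!r} not in schema")
    if identifier_i == identifier_j:
        return DependenceResult(np.inf, np.nan, degenerate=True, note="identifier tested against itself")
    matches = frame[frame["is_match"].astype(bool)]
    if matches.empty:
        raise DataError("no matched pairs")
    err_i = 1 - matches[col_i].to_numpy(dtype=float)
    err_j = 1 - matches[col_j].to_numpy(dtype=float)
    tab = np.array(
        [
            [np.sum((err_i == 0) & (err_j == 0)), np.sum((err_i == 0) & (err_j == 1))],
            [np.sum((err_i == 1) & (err_j == 0)), np.sum((err_i == 1) & (err_j == 1))],
        ]
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return DependenceResult(np.nan, np.nan, degenerate=True, note="empty margin in 2x2 table")

    X = np.column_stack([np.ones(len(err_i)), err_j])
    have_clusters = (
        include_random_effect
        and "hospital_id" in matches.columns
        and matches["hospital_id"].nunique() > 1
    )
    clusters = (
        matches["hospital_id"].to_numpy() if have_clusters else np.zeros(len(err_i), dtype=int)
    )
    Xa, succ, trials, cl = _aggregate(X, err_i, clusters)
    beta, bse, _ = _glm_logit(Xa, succ, trials)
    if have_clusters:
        try:
            est, se, _, ok = _fit_random_intercept(Xa, succ, trials, cl, beta)
            if ok and np.isfinite(se[1]) and se[1] > 0:
                beta, bse = est, se
        except Exception:  # fall back to the fixed-effects fit
            pass
    if not np.isfinite(bse[1]) or bse[1] == 0:
        return DependenceResult(float(np.exp(beta[1])), np.nan, degenerate=True, note="unstable SE")
    zval = beta[1] / bse[1]
    p = 2.0 * stats.norm.sf(abs(zval))
    return DependenceResult(float(np.exp(beta[1])), float(p))


def funnel_limits(
    overall_rate: float,
    denominators,
    levels=(0.95, 0.998),
    method: str = "normal",
) -> pd.DataFrame:
    """Binomial control limits around an overall proportion.

    For denominator n and two-sided coverage level, the normal-approximation
    limits are ``rate +/- z * sqrt(rate (1 - rate) / n)``, truncated to
    [0, 1]; ``method='exact'`` uses the binomial quantile function instead.
    """
    if not 0.0 < overall_rate < 1.0:
        raise DataError("overall_rate must lie strictly inside (0, 1)")
    denominators = np.asarray(list(denominators), dtype=float)
    if (denominators <= 0).any():
        raise DataError("denominators must be positive")
    rows = []
    for level in levels:
        if method == "normal":
            z = stats.norm.ppf(0.5 + level / 2.0)
            half = z * np.sqrt(overall_rate * (1.0 - overall_rate) / denominators)
            lower = np.clip(overall_rate - half, 0.0, 1.0)
            upper = np.clip(overall_rate + half, 0.0, 1.0)
        elif method == "exact":
            alpha = (1.0 - level) / 2.0
            lower = stats.binom.ppf(alpha, denominators, overall_rate) / denominators
            upper = stats.binom.ppf(1.0 - alpha, denominators, overall_rate) / denominators
        else:
            raise DataError(f"unknown funnel method {method!r}")
        for n, lo, hi in zip(denominators, lower, upper):
            rows.append({"n": n, "level": level, "lower": float(lo), "upper": float(hi)})
    return pd.DataFrame(rows)


def funnel_table(
    records: pd.DataFrame, levels=(0.95, 0.998), method: str = "normal"
) -> pd.DataFrame:
    """Per-hospital error proportions with control limits and outlier flags."""
    if "hospital_id" not in records.columns:
        raise DataError("records lack hospital_id")
    per_hosp = (
        records.groupby("hospital_id", observed=True)["error"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "rate", "count": "n"})
        .reset_index()
    )
    overall = float(records["error"].mean())
    out = per_hosp.copy()
    out["overall_rate"] = overall
    for level in levels:
        lim = funnel_limits(overall, per_hosp["n"], levels=(level,), method=method)
        out[f"lower_{level}"] = lim["lower"].to_numpy()
        out[f"upper_{level}"] = lim["upper"].to_numpy()
        out[f"outlier_{level}"] = (out["rate"] < out[f"lower_{level}"]) | (
            out["rate"] > out[f"upper_{level}"]
        )
    return out
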