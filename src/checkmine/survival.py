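"""Disease-free-survival analysis: exclusions, optimal percentile cutpoint,
Kaplan-Meier / log-rank, and univariate-then-multivariate proportional
hazards with missing-indicator covariate encoding.

The two-group log-rank statistic is implemented directly (sum over event
times of (O - E)^2 / V with hypergeometric variance, 1 df) in a vectorized
form that evaluates many candidate splits of the same cohort in one pass —
this is what makes the minimum-p percentile scan and its permutation
adjustment cheap.  Proportional-hazards fitting delegates to lifelines.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable

log = logging.getLogger("checkmine.survival")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def exclude_zero_dfs(clinical: ClinicalTable) -> ClinicalTable:
    """Drop patients with a DFS of zero months (study convention)."""
    keep = clinical.data["dfs_months"].to_numpy(dtype=float) > 0
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all patients have zero DFS; nothing to analyse")
    if n_drop:
        log.info("excluded %d patients with DFS of zero months", n_drop)
    return ClinicalTable(data=clinical.data.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Percentile split
# ---------------------------------------------------------------------------

def percentile_split(
    expression: np.ndarray | pd.Series, percentile: int
) -> tuple[float, np.ndarray]:
    """Nearest-rank percentile split of an expression vector.

    The threshold is the ceil(p/100 * n)-th smallest value; samples strictly
    above it are 'high', ties at the threshold fall into 'low'.  Returns
    (threshold, labels) where labels is a string array of high/low.
    """
    values = np.asarray(expression, dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression vector contains missing values")
    if not 1 <= percentile <= 99:
        raise ValueError("percentile must lie in [1, 99]")
    if np.all(values == values[0]):
        raise ValueError("all expression values equal; split undefined")
    n = len(values)
    k = math.ceil(percentile / 100.0 * n)
    threshold = float(np.sort(values)[k - 1])
    labels = np.where(values > threshold, "high", "low")
    return threshold, labels


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time: n_at_risk, n_events,
    n_censored and the right-continuous survival probability S(t) after
    that time; S(0) = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    uniq = t[starts]
    d = np.add.reduceat(e.astype(float), starts)
    block_n = np.add.reduceat(np.ones_like(t), starts)
    at_risk = len(t) - starts
    surv = np.cumprod(1.0 - d / at_risk)
    return pd.DataFrame({
        "time": uniq,
        "n_at_risk": at_risk.astype(int),
        "n_events": d.astype(int),
        "n_censored": (block_n - d).astype(int),
        "survival": surv,
    })


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a km_curve step function at time t (right-continuous)."""
    below = curve[curve["time"] <= t]
    return 1.0 if below.empty else float(below["survival"].iloc[-1])


def _logrank_scan(
    times: np.ndarray, events: np.ndarray, high_matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank for many splits of one cohort at once.

    ``high_matrix`` is (n_splits, n_samples) boolean; returns (chi2, p)
    arrays.  Degenerate splits (one empty group, or zero variance) yield
    chi2 = 0, p = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    G = np.atleast_2d(np.asarray(high_matrix, dtype=bool))
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    Gs = G[:, order]

    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e.astype(float), starts)
    ev_blocks = d > 0
    n_at_risk = (len(t) - starts).astype(float)

    total1 = Gs.sum(axis=1).astype(float)
    cum1 = np.cumsum(Gs, axis=1)
    before = np.where(starts > 0, cum1[:, np.maximum(starts - 1, 0)], 0.0)
    n1_at_risk = total1[:, None] - before

    d1 = np.add.reduceat((Gs & e[None, :]).astype(float), starts, axis=1)

    d_e = d[ev_blocks]
    n_e = n_at_risk[ev_blocks]
    n1_e = n1_at_risk[:, ev_blocks]
    d1_e = d1[:, ev_blocks]

    frac = n1_e / n_e
    E1 = (d_e * frac).sum(axis=1)
    O1 = d1_e.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = d_e * frac * (1.0 - frac) * (n_e - d_e) / (n_e - 1.0)
    var_t = np.where(n_e[None, :] > 1, var_t, 0.0)
    V = var_t.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (O1 - E1) ** 2 / V
    chi2 = np.where(V > 0, chi2, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(V > 0, p, 1.0)
    return chi2, p


def logrank_test(
    times: np.ndarray, events: np.ndarray, group_labels: Sequence
) -> tuple[float, float]:
    """Two-group log-rank test: chi2 on 1 df and its upper-tail p."""
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {len(uniq)}")
    high = labels == uniq[0]
    chi2, p = _logrank_scan(times, events, high[None, :])
    return float(chi2[0]), float(p[0])


# ---------------------------------------------------------------------------
# Optimal cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    """Minimum-p percentile split of an expression vector against DFS."""

    percentile: int
    threshold_value: float
    group_labels: pd.Series  # high/low per sample
    logrank_chi2: float
    logrank_p: float
    scan_trace: list[tuple[int, float]] = field(default_factory=list)
    permutation_adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if self.logrank_chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if not 0 < self.logrank_p <= 1:
            raise ValueError("p must lie in (0, 1]")


def _split_matrix(
    values: np.ndarray, percentiles: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """High-group indicator rows for each scanned percentile; drops
    percentiles whose split leaves a group empty."""
    n = len(values)
    sorted_vals = np.sort(values)
    ks = np.ceil(percentiles / 100.0 * n).astype(int) - 1
    thresholds = sorted_vals[ks]
    high = values[None, :] > thresholds[:, None]
    n_high = high.sum(axis=1)
    ok = (n_high > 0) & (n_high < n)
    return high[ok], thresholds[ok], percentiles[ok]


def optimal_cutpoint(
    expression: np.ndarray | pd.Series,
    clinical: ClinicalTable,
    scan_lo: int = 10,
    scan_hi: int = 90,
    step: int = 1,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutpointResult:
    """Scan percentile splits, pick the minimum log-rank p.

    Ties go to the lower percentile.  With ``n_permutations`` > 0 the min-p
    selection optimism is corrected by re-running the scan on label
    permutations of the expression vector; the adjusted p is the fraction of
    permutation minima at or below the observed minimum (never reported
    below the nominal minimum p itself).
    """
    values = np.asarray(expression, dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression vector contains missing values")
    times = clinical.data["dfs_months"].to_numpy(dtype=float)
    events = clinical.data["dfs_event"].to_numpy(dtype=bool)
    if len(values) != len(times):
        raise ValueError("expression and clinical table lengths differ")

    percentiles = np.arange(scan_lo, scan_hi + 1, step)
    high, thresholds, kept = _split_matrix(values, percentiles)
    n_skipped = len(percentiles) - len(kept)
    if n_skipped:
        warnings.warn(f"{n_skipped} scanned percentiles produced a "
                      "degenerate split and were skipped", stacklevel=2)
    if len(kept) == 0:
        raise ValueError("every scanned percentile produced a degenerate split")

    chi2, p = _logrank_scan(times, events, high)
    best = int(np.argmin(p))  # first minimum = lower percentile on ties
    min_p = float(p[best])

    adjusted = None
    if n_permutations > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        worse = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(values))
            _, p_b = _logrank_scan(times, events, high[:, perm])
            if p_b.min() <= min_p:
                worse += 1
        adjusted = max(min_p, (1 + worse) / (n_permutations + 1))

    labels = np.where(high[best], "high", "low")
    return CutpointResult(
        percentile=int(kept[best]),
        threshold_value=float(thresholds[best]),
        group_labels=pd.Series(labels, index=clinical.sample_ids),
        logrank_chi2=float(chi2[best]),
        logrank_p=min_p,
        scan_trace=[(int(q), float(pv)) for q, pv in zip(kept, p)],
        permutation_adjusted_p=adjusted,
    )


# ---------------------------------------------------------------------------
# Missing-indicator encoding
# ---------------------------------------------------------------------------

def missing_indicator_encode(covariates: pd.DataFrame) -> pd.DataFrame:
    """Design matrix with the missing-indicator method.

    Numeric covariates: missing values imputed with the observed mean and a
    binary <name>_missing column added.  Categorical covariates: dummy
    columns against the first observed level as reference; missing rows get
    the reference encoding plus the indicator.  Covariates that are entirely
    missing are dropped with a warning.  Row count never changes.
    """
    pieces = []
    for name in covariates.columns:
        col = covariates[name]
        miss = col.isna()
        if miss.all():
            warnings.warn(f"covariate {name!r} is 100% missing; dropped",
                          stacklevel=2)
            continue
        if pd.api.types.is_numeric_dtype(col):
            filled = col.astype(float).fillna(float(col.dropna().mean()))
            pieces.append(filled.rename(name))
        else:
            levels = sorted(col.dropna().astype(str).unique())
            for level in levels[1:]:
                pieces.append((col.astype("string") == level)
                              .fillna(False).astype(float)
                              .rename(f"{name}_{level}"))
        if miss.any():
            pieces.append(miss.astype(float).rename(f"{name}_missing"))
    if not pieces:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(pieces, axis=1)


# ---------------------------------------------------------------------------
# Proportional hazards
# ---------------------------------------------------------------------------

class TermResult(NamedTuple):
    name: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class HazardModelResult:
    terms: list[TermResult]

    def __post_init__(self) -> None:
        for t in self.terms:
            if not t.ci_low <= t.hazard_ratio <= t.ci_high:
                raise ValueError(f"CI does not bracket HR for term {t.name!r}")

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms,
                            columns=["term", "hazard_ratio", "ci_low",
                                     "ci_high", "p"])


class CoxStages(NamedTuple):
    univariate: HazardModelResult
    multivariate: HazardModelResult | None
    selected_terms: list[str]


def _fit_cox(df: pd.DataFrame, term_names: Sequence[str],
             label: str) -> HazardModelResult:
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message=".*complete separation.*")
            cph.fit(df, duration_col="__T", event_col="__E")
    except ConvergenceError as err:
        raise ValueError(
            f"proportional-hazards fit failed to converge for "
            f"{label}: {', '.join(term_names)}") from err
    summ = cph.summary
    terms = [
        TermResult(
            name=str(idx),
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
        )
        for idx, row in summ.iterrows()
    ]
    return HazardModelResult(terms=terms)


def cox_univariate_then_multivariate(
    design: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    alpha: float = 0.05,
    allowlist: Sequence[str] = (),
) -> CoxStages:
    """Single-term Cox fits, then one joint fit of the selected terms.

    Terms with univariate p < alpha enter the joint model; ``allowlist``
    names clinically relevant terms carried forward regardless of their
    univariate p.  An empty selection skips the multivariate stage.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    base = pd.DataFrame({"__T": times, "__E": events.astype(int)},
                        index=design.index)

    uni_terms: list[TermResult] = []
    for name in design.columns:
        df = pd.concat([design[[name]], base], axis=1)
        res = _fit_cox(df, [name], "univariate term")
        uni_terms.append(res.terms[0])
    univariate = HazardModelResult(terms=uni_terms)

    selected = [t.name for t in uni_terms
                if t.p < alpha or t.name in allowlist]
    for name in allowlist:
        if name in design.columns and name not in selected:
            selected.append(name)

    if not selected:
        log.info("no term passed univariate selection at alpha=%g; "
                 "multivariate stage skipped", alpha)
        return CoxStages(univariate, None, [])

    df = pd.concat([design[selected], base], axis=1)
    multivariate = _fit_cox(df, selected, "multivariate model")
    return CoxStages(univariate, multivariate, selected)
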