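"""Survival-based validation of a continuous prognostic marker.

Implements the validation protocol for a slide-level marker: Kaplan–Meier
stratification with log-rank testing, cross-validated cutoff selection,
conservative combined statistics across folds, Harrell's concordance
index, and univariate/multivariate Cox proportional-hazards regression.

The cutoff search evaluates candidate thresholds (by default the deciles
of the training marker distribution) by the log-rank p of the resulting
two-group split, subject to a minimum group-size fraction. In k-fold
cross-validation the cutoff is chosen on the training part of each fold
and evaluated on the held-out part; the combined p-value is the
conservative min(1, 2 x median of fold p-values) and the combined C-index
the mean +/- SD over folds.

Estimators are delegated to lifelines (product-limit KM, log-rank
chi-square, Cox partial likelihood with Efron tie handling); this module
owns the protocol around them. The marker direction convention is
higher marker = worse prognosis throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_cindex

from .errors import CoxConvergenceError, EmptyFoldError, NoFeasibleCutoffError

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "StratificationResult",
    "CVSummary",
    "CoxTerm",
    "CoxResult",
    "records_to_frame",
    "read_survival",
    "kaplan_meier",
    "logrank_test",
    "concordance_index",
    "stratify_at_cutoff",
    "find_optimal_cutoff",
    "cross_validate_marker",
    "combine_fold_stats",
    "cox_fit",
]

DEFAULT_MIN_GROUP_FRACTION = 0.10
DEFAULT_CUTOFF_QUANTILES = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time (months), event flag, marker, covariates."""

    patient_id: str
    time: float
    event: int
    marker: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(f"time must be finite and positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({"patient_id": r.patient_id, "time": r.time, "event": r.event,
                     "marker": r.marker, **r.covariates})
    return pd.DataFrame(rows)


def read_survival(path, time_col: str = "time_months", event_col: str = "event",
                  marker_col: str = "marker") -> pd.DataFrame:
    """Read a per-patient survival CSV into the canonical column layout."""
    df = pd.read_csv(path)
    return df.rename(columns={time_col: "time", event_col: "event", marker_col: "marker"})


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(list(data))


@dataclass
class KMCurve:
    """Product-limit survival curve: step function plus at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class StratificationResult:
    cutoff: float
    group_high: np.ndarray  # boolean per patient, marker > cutoff
    logrank_stat: float
    logrank_p: float
    c_index: float
    km_low: KMCurve
    km_high: KMCurve


@dataclass
class CVSummary:
    """Cross-validated marker evaluation.

    combined_p = min(1, 2 x median of held-out fold p-values); combined_c
    is (mean, SD) of held-out fold C-indices; chosen_cutoff the median of
    per-fold training cutoffs.
    """

    per_fold: list[tuple[float, float, float]]  # (cutoff, p, c_index)
    combined_p: float
    combined_c_mean: float
    combined_c_sd: float
    chosen_cutoff: float


@dataclass(frozen=True)
class CoxTerm:
    name: str
    coef: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p: float


@dataclass
class CoxResult:
    terms: list[CoxTerm]
    model_type: str  # UNIVARIATE or MULTIVARIATE

    def term(self, name: str) -> CoxTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def kaplan_meier(data) -> KMCurve:
    """Kaplan–Meier product-limit estimator over distinct event times."""
    df = _as_frame(data)
    if len(df) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv.to_numpy(dtype=float), at_risk=at_risk)


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    a, b = _as_frame(group_a), _as_frame(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if a["event"].sum() + b["event"].sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def concordance_index(data, binary_cutoff: float | None = None) -> float:
    """Harrell's C of a marker against survival, higher marker = worse.

    Ties in the marker contribute 0.5 per Harrell's convention. With
    ``binary_cutoff`` the marker is first binarized at that threshold.
    Returns NaN when no comparable pair exists.
    """
    df = _as_frame(data)
    if len(df) < 2:
        raise ValueError("need at least two records")
    marker = df["marker"].to_numpy(dtype=float)
    if binary_cutoff is not None:
        marker = (marker > binary_cutoff).astype(float)
    try:
        # lifelines scores higher prediction = longer survival; negate.
        return float(_ll_cindex(df["time"], -marker, df["event"]))
    except ZeroDivisionError:
        return float("nan")


def stratify_at_cutoff(data, cutoff: float) -> StratificationResult:
    """Split at a fixed cutoff (high = marker > cutoff) and evaluate."""
    df = _as_frame(data)
    high = df["marker"].to_numpy(dtype=float) > cutoff
    if high.all() or not high.any():
        raise NoFeasibleCutoffError(f"cutoff {cutoff} leaves one group empty")
    stat, p = logrank_test(df[~high], df[high])
    return StratificationResult(
        cutoff=cutoff,
        group_high=high,
        logrank_stat=stat,
        logrank_p=p,
        c_index=concordance_index(df),
        km_low=kaplan_meier(df[~high]),
        km_high=kaplan_meier(df[high]),
    )


def find_optimal_cutoff(
    data,
    candidates: np.ndarray | None = None,
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
) -> float:
    """Cutoff minimizing the two-group log-rank p over a candidate grid.

    Default candidates are the training-marker deciles (10%..90%). Only
    cutoffs leaving at least ``min_group_fraction`` of patients in each
    group are feasible; p-value ties resolve to the smaller cutoff.
    """
    df = _as_frame(data)
    marker = df["marker"].to_numpy(dtype=float)
    if candidates is None:
        candidates = np.unique(np.quantile(marker, DEFAULT_CUTOFF_QUANTILES))
    n = len(df)
    best: tuple[float, float] | None = None  # (p, cutoff)
    for cut in np.sort(np.asarray(candidates, dtype=float)):
        high = marker > cut
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_group_fraction * n or n_high in (0, n):
            continue
        _, p = logrank_test(df[~high], df[high])
        if best is None or p < best[0]:
            best = (p, float(cut))
    if best is None:
        raise NoFeasibleCutoffError("no candidate satisfies the group-size constraint")
    return best[1]


def _stratified_folds(events: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Event-stratified fold assignment (test-index arrays)."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for value in (1, 0):
        idx = np.nonzero(events == value)[0]
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate_marker(
    data,
    k: int = 3,
    seed: int = 0,
    candidates: np.ndarray | None = None,
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
) -> CVSummary:
    """k-fold cross-validated cutoff selection and held-out evaluation.

    Folds are event-stratified and seeded. For each fold the cutoff is
    selected on the training part and the log-rank p and C-index are
    computed on the held-out part.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    df = _as_frame(data).reset_index(drop=True)
    events = df["event"].to_numpy(dtype=int)
    folds = _stratified_folds(events, k, seed)
    per_fold: list[tuple[float, float, float]] = []
    for test_idx in folds:
        if events[test_idx].sum() == 0:
            raise EmptyFoldError("a fold has no events; refit with stratified folding")
        train = df.drop(index=test_idx)
        test = df.loc[test_idx]
        cutoff = find_optimal_cutoff(train, candidates, min_group_fraction)
        high = test["marker"].to_numpy(dtype=float) > cutoff
        if high.all() or not high.any():
            p = 1.0
        else:
            _, p = logrank_test(test[~high], test[high])
        c = concordance_index(test)
        per_fold.append((cutoff, p, c))
    return combine_fold_stats(per_fold)


def combine_fold_stats(per_fold: list[tuple[float, float, float]]) -> CVSummary:
    """Aggregate (cutoff, p, C) fold triples into the combined statistics.

    combined p = min(1, 2 x median fold p), a conservative estimate;
    combined C = mean +/- SD; reported cutoff = median of fold cutoffs.
    """
    ps = np.array([p for _, p, _ in per_fold])
    cs = np.array([c for _, _, c in per_fold])
    return CVSummary(
        per_fold=list(per_fold),
        combined_p=float(min(1.0, 2.0 * np.median(ps))),
        combined_c_mean=float(np.mean(cs)),
        combined_c_sd=float(np.std(cs)),
        chosen_cutoff=float(np.median([c for c, _, _ in per_fold])),
    )


def cox_fit(data, terms: list[str], model_type: str = "MULTIVARIATE") -> CoxResult:
    """Cox proportional-hazards regression over the named covariates.

    MULTIVARIATE fits all terms jointly; UNIVARIATE fits one single-term
    model per covariate. Ties are handled by Efron's method (lifelines'
    default). Constant covariates are dropped with HR fixed to 1 by
    convention; non-convergence raises a named error.
    """
    df = _as_frame(data)
    if df["event"].sum() == 0:
        raise ValueError("no events in the data")
    model_type = model_type.upper()
    if model_type not in ("UNIVARIATE", "MULTIVARIATE"):
        raise ValueError(f"unknown model_type {model_type!r}")

    out_terms: list[CoxTerm] = []
    groups = [[t] for t in terms] if model_type == "UNIVARIATE" else [terms]
    for group in groups:
        active = [t for t in group if df[t].nunique() > 1]
        for t in group:
            if t not in active:
                out_terms.append(CoxTerm(name=t, coef=0.0, hazard_ratio=1.0,
                                         ci_lower=1.0, ci_upper=1.0, p=1.0))
        if not active:
            continue
        cph = CoxPHFitter()
        sub = df[["time", "event", *active]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # default stopping precision leaves ~1e-4 coefficient error
                cph.fit(sub, duration_col="time", event_col="event",
                        fit_options={"precision": 1e-9})
        except ConvergenceError as exc:
            raise CoxConvergenceError(str(exc)) from exc
        summary = cph.summary
        for t in active:
            row = summary.loc[t]
            out_terms.append(CoxTerm(
                name=t,
                coef=float(row["coef"]),
                hazard_ratio=float(row["exp(coef)"]),
                ci_lower=float(row["exp(coef) lower 95%"]),
                ci_upper=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
            ))
    return CoxResult(terms=out_terms, model_type=model_type)
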