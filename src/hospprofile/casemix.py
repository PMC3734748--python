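"""Case-mix adjustment: cohort filters, covariate banding, logistic risk
model, and per-hospital observed/expected deaths.

Covariate ranges are closed intervals.  Death status is analysed as
complete cases throughout (no imputation): records with a missing
status contribute to hospital-level missingness screening but not to
the risk model or to the O/E sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from hospprofile.cohort import AGE_BAND_LABELS, AGE_EDGES, DIAGNOSES

REFERENCE_DIAGNOSIS = "chest_pain"


class EmptyCohortError(ValueError):
    """No patients survive the exclusion rules."""


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (separation or degeneracy)."""


@dataclass(frozen=True)
class ExclusionRules:
    age_range: tuple[float, float] = (18.0, 100.0)
    sbp_range: tuple[float, float] = (49.0, 250.0)
    hr_range: tuple[float, float] = (20.0, 200.0)
    min_admissions: int = 2
    min_deaths: int = 5
    max_missing: float = 0.5

    def __post_init__(self) -> None:
        for name in ("age_range", "sbp_range", "hr_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0, 1]")


@dataclass(frozen=True)
class ExclusionReport:
    patients_in: int
    patients_out: int
    removed_age: int
    removed_sbp: int
    removed_hr: int
    hospitals_in: int
    hospitals_out: int
    hospitals_removed_few_admissions: int
    hospitals_removed_few_deaths: int
    hospitals_removed_missingness: int
    patients_removed_with_hospitals: int

    def lines(self) -> list[str]:
        """Structured log lines, one per removal reason."""
        return [
            f"exclusions: patients {self.patients_in} -> {self.patients_out}",
            f"exclusions: removed by age range: {self.removed_age}",
            f"exclusions: removed by SBP range: {self.removed_sbp}",
            f"exclusions: removed by heart-rate range: {self.removed_hr}",
            f"exclusions: hospitals {self.hospitals_in} -> {self.hospitals_out}",
            "exclusions: hospitals removed (too few admissions): "
            f"{self.hospitals_removed_few_admissions}",
            "exclusions: hospitals removed (too few deaths): "
            f"{self.hospitals_removed_few_deaths}",
            "exclusions: hospitals removed (excess missing status): "
            f"{self.hospitals_removed_missingness}",
            "exclusions: patients removed with excluded hospitals: "
            f"{self.patients_removed_with_hospitals}",
        ]


@dataclass(frozen=True)
class BandEdges:
    """Realised cut points: fixed age edges, empirical fifths for SBP/HR.

    A value v falls in band k iff edges[k-1] <= v < edges[k] (first and
    last bands unbounded below/above).
    """

    age: tuple[float, ...] = AGE_EDGES
    sbp: tuple[float, ...] = ()
    hr: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in ("age", "sbp", "hr"):
            e = np.asarray(getattr(self, name), dtype=float)
            if e.size and np.any(np.diff(e) <= 0):
                raise ValueError(f"{name} band edges must be strictly increasing")


@dataclass(frozen=True)
class RiskModel:
    intercept: float
    category_effects: dict[str, float]  # term -> log-odds (reference levels absent)
    standard_errors: dict[str, float]
    band_edges: BandEdges
    c_statistic: float
    c_statistic_ci: tuple[float, float]
    converged: bool = True
    n_iterations: int = 0
    log_likelihood: float = float("nan")


def apply_exclusions(
    patients: pd.DataFrame, rules: ExclusionRules
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop out-of-range patients, then whole hospitals with sparse or
    poorly recorded data.  Rules are applied in that order; a patient
    failing several range checks counts against the first (age, SBP,
    heart rate)."""
    n_in = len(patients)
    hospitals_in = patients["hospital_id"].nunique()

    ok_age = patients["age"].between(*rules.age_range)
    ok_sbp = patients["sbp"].between(*rules.sbp_range)
    ok_hr = patients["heart_rate"].between(*rules.hr_range)
    removed_age = int((~ok_age).sum())
    removed_sbp = int((ok_age & ~ok_sbp).sum())
    removed_hr = int((ok_age & ok_sbp & ~ok_hr).sum())
    kept = patients[ok_age & ok_sbp & ok_hr]

    if kept.empty:
        raise EmptyCohortError("no patients survive the covariate range filters")

    grp = kept.groupby("hospital_id")["died_30d"]
    n_adm = grp.size()
    n_missing = grp.apply(lambda s: int(s.isna().sum()))
    n_deaths = grp.apply(lambda s: int((s == 1).sum()))
    frac_missing = n_missing / n_adm

    few_adm = n_adm < rules.min_admissions
    few_deaths = ~few_adm & (n_deaths < rules.min_deaths)
    too_missing = ~few_adm & ~few_deaths & (frac_missing > rules.max_missing)
    bad = few_adm | few_deaths | too_missing

    bad_ids = set(n_adm.index[bad])
    out = kept[~kept["hospital_id"].isin(bad_ids)].reset_index(drop=True)
    if out.empty:
        raise EmptyCohortError("all hospitals fail the sparsity rules")

    report = ExclusionReport(
        patients_in=n_in,
        patients_out=len(out),
        removed_age=removed_age,
        removed_sbp=removed_sbp,
        removed_hr=removed_hr,
        hospitals_in=hospitals_in,
        hospitals_out=out["hospital_id"].nunique(),
        hospitals_removed_few_admissions=int(few_adm.sum()),
        hospitals_removed_few_deaths=int(few_deaths.sum()),
        hospitals_removed_missingness=int(too_missing.sum()),
        patients_removed_with_hospitals=int(kept["hospital_id"].isin(bad_ids).sum()),
    )
    return out, report


def derive_bands(patients: pd.DataFrame) -> BandEdges:
    """Fixed age bands; SBP and heart rate cut at the pooled empirical
    20/40/60/80th percentiles."""
    edges = {}
    for col in ("sbp", "heart_rate"):
        values = patients[col].to_numpy(dtype=float)
        if len(np.unique(values)) < 5:
            raise ValueError(f"{col}: need >= 5 distinct values to form fifths")
        e = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{col}: quintile edges are not strictly increasing")
        edges[col] = tuple(float(x) for x in e)
    return BandEdges(age=AGE_EDGES, sbp=edges["sbp"], hr=edges["heart_rate"])


def band_index(values: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """0-based band of each value given increasing cut points."""
    return np.searchsorted(np.asarray(edges, dtype=float), values, side="right")


def _term_names() -> list[str]:
    names = [f"age:{lab}" for lab in AGE_BAND_LABELS[1:]]
    names += [f"sbp:q{k}" for k in range(2, 6)]
    names += [f"hr:q{k}" for k in range(2, 6)]
    names += [f"diagnosis:{d}" for d in DIAGNOSES if d != REFERENCE_DIAGNOSIS]
    return names


def design_matrix(patients: pd.DataFrame, edges: BandEdges) -> tuple[np.ndarray, list[str]]:
    """Indicator-coded design matrix (including intercept column)."""
    n = len(patients)
    age_b = band_index(patients["age"].to_numpy(dtype=float), edges.age)
    sbp_b = band_index(patients["sbp"].to_numpy(dtype=float), edges.sbp)
    hr_b = band_index(patients["heart_rate"].to_numpy(dtype=float), edges.hr)
    diag = patients["diagnosis"].to_numpy()

    cols = [np.ones(n)]
    for k in range(1, 5):
        cols.append((age_b == k).astype(float))
    for k in range(1, 5):
        cols.append((sbp_b == k).astype(float))
    for k in range(1, 5):
        cols.append((hr_b == k).astype(float))
    for d in DIAGNOSES:
        if d != REFERENCE_DIAGNOSIS:
            cols.append((diag == d).astype(float))
    return np.column_stack(cols), ["intercept"] + _term_names()


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares; converges on the log-likelihood to ``tol``."""
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(p) + (1 - y) @ np.log1p(-p))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        w = p * (1 - p)
        z = eta + (y - p) / w
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"singular information matrix: {err}") from err
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30:
            raise SeparationError("coefficients diverged (likely separation)")
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = np.clip(p * (1 - p), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, ll_old, it, converged


def c_statistic(
    predicted: np.ndarray, outcomes: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Area under the ROC curve with a normal-approximation interval.

    Equals the proportion of (death, survivor) pairs in which the death
    received the higher predicted probability, ties counted one half.
    The interval uses the Hanley-McNeil variance.
    """
    predicted = np.asarray(predicted, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic requires both outcome classes")
    ranks = rankdata(predicted)
    auc = (ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    half = norm.ppf(0.5 + level / 2) * np.sqrt(max(var, 0.0))
    return float(auc), (float(auc - half), float(auc + half))


def fit_risk_model(patients: pd.DataFrame, edges: BandEdges) -> RiskModel:
    """Fit the banded logistic risk model on complete cases."""
    cc = patients[patients["died_30d"].notna()]
    y = cc["died_30d"].to_numpy(dtype=float)
    X, names = design_matrix(cc, edges)

    occupied = X.sum(axis=0) > 0
    occupied[0] = True  # intercept
    for factor in ("age", "sbp", "hr", "diagnosis"):
        factor_cols = [i for i, nm in enumerate(names) if nm.startswith(factor + ":")]
        if factor_cols and not any(occupied[i] for i in factor_cols):
            raise ValueError(f"factor {factor!r} has a single observed level")

    # Levels absent from the data contribute nothing to the likelihood;
    # drop their columns so the information matrix stays non-singular.
    kept_names = [nm for nm, occ in zip(names, occupied) if occ]
    X = X[:, occupied]

    try:
        beta, se, ll, n_iter, converged = _irls_logistic(X, y)
    except SeparationError:
        raise
    if not converged:
        raise SeparationError(f"IRLS failed to converge in {n_iter} iterations")

    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    auc, ci = c_statistic(p, y.astype(int))
    effects = dict(zip(kept_names[1:], beta[1:].tolist()))
    ses = dict(zip(kept_names, se.tolist()))
    return RiskModel(
        intercept=float(beta[0]),
        category_effects=effects,
        standard_errors=ses,
        band_edges=edges,
        c_statistic=auc,
        c_statistic_ci=ci,
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=ll,
    )


def predict_probabilities(patients: pd.DataFrame, model: RiskModel) -> np.ndarray:
    """Per-patient predicted death probability.  Levels unseen at fit
    time fall back to the reference (effect 0)."""
    X, names = design_matrix(patients, model.band_edges)
    beta = np.array(
        [model.intercept] + [model.category_effects.get(nm, 0.0) for nm in names[1:]]
    )
    return 1.0 / (1.0 + np.exp(-(X @ beta)))


def expected_deaths(patients: pd.DataFrame, model: RiskModel) -> pd.DataFrame:
    """Per-hospital summaries: valid admissions, observed deaths O_i and
    case-mix expected deaths E_i (sum of predicted probabilities).

    Complete cases only; raises if a hospital has no valid patients.
    """
    cc = patients[patients["died_30d"].notna()].copy()
    empty = set(patients["hospital_id"].unique()) - set(cc["hospital_id"].unique())
    if empty:
        raise ValueError(f"hospitals with zero valid patients: {sorted(empty)}")
    cc["_p"] = predict_probabilities(cc, model)
    cc["_d"] = cc["died_30d"].astype(int)
    out = (
        cc.groupby("hospital_id")
        .agg(
            n_admissions=("_d", "size"),
            observed_deaths=("_d", "sum"),
            expected_deaths=("_p", "sum"),
        )
        .reset_index()
    )
    return out
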