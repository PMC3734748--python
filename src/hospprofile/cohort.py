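"""Synthetic patient-level cohort generator.

Produces admission records (hospital, age, systolic blood pressure,
heart rate, discharge diagnosis, 30-day death status) with a known
ground truth: hospital effects are drawn from a normal distribution on
the log-SMR scale and enter each patient's death logit directly.  For
event rates near 10% the induced log-SMR is approximately equal to the
logit shift; this approximation is deliberate and is what the recovery
tests rely on.

Default covariate frequencies and log-odds mimic a large UK acute
coronary syndrome audit cohort (overall 30-day mortality ~10.2%,
hospital volumes heavily right-skewed from ~20 to ~2,200 admissions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

DIAGNOSES = (
    "chest_pain",  # reference level
    "st_elevation",
    "non_st_elevation",
    "troponin_positive",
    "troponin_negative",
    "other",
)

AGE_BAND_LABELS = ("<55", "55-64", "65-74", "75-84", ">=85")
AGE_EDGES = (55.0, 65.0, 75.0, 85.0)

# Marginal frequencies of the default scenario (proportions).
_AGE_BAND_PROPS = np.array([14116, 16396, 21442, 23006, 9249], dtype=float)
_AGE_BAND_PROPS /= _AGE_BAND_PROPS.sum()
_DIAG_COUNTS = {
    "st_elevation": 29389,
    "non_st_elevation": 29462,
    "troponin_positive": 6719,
    "troponin_negative": 6326,
    "chest_pain": 3136,
    "other": 9177,
}


@dataclass(frozen=True)
class RiskCoefficients:
    """Per-category log-odds; element 0 of each array is the reference level."""

    age: tuple[float, ...] = tuple(np.log([1.0, 2.02, 5.06, 10.73, 18.03]))
    sbp: tuple[float, ...] = tuple(np.log([1.0, 0.56, 0.43, 0.33, 0.27]))
    heart_rate: tuple[float, ...] = tuple(np.log([1.0, 1.10, 1.38, 1.84, 2.55]))
    diagnosis: dict[str, float] = field(
        default_factory=lambda: {
            "chest_pain": 0.0,
            "st_elevation": float(np.log(8.59)),
            "non_st_elevation": float(np.log(5.29)),
            "troponin_positive": float(np.log(2.59)),
            "troponin_negative": float(np.log(0.67)),
            "other": float(np.log(4.68)),
        }
    )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters controlling cohort generation.

    ``size_min``/``size_median``/``size_max`` parameterise a clipped
    log-normal law for admissions per hospital; ``sigma0_true`` is the
    SD of true hospital effects on the log-SMR scale.
    """

    n_hospitals: int = 128
    size_min: int = 20
    size_median: int = 300
    size_max: int = 2200
    baseline_rate: float = 0.102
    risk_coefficients: RiskCoefficients = field(default_factory=RiskCoefficients)
    mu0_true: float = 0.0
    sigma0_true: float = 0.15
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        if not 0.0 < self.baseline_rate < 1.0:
            raise ValueError("baseline_rate must lie in (0, 1)")
        if self.sigma0_true < 0:
            raise ValueError("sigma0_true must be >= 0")
        if self.size_min < 1:
            raise ValueError("size_min must be >= 1")
        if self.size_max < self.size_min:
            raise ValueError("degenerate size law: size_max < size_min")
        if not self.size_min <= self.size_median <= self.size_max:
            raise ValueError("size_median must lie within [size_min, size_max]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class TrueParameters:
    """Ground truth recorded at generation time for recovery tests."""

    theta_true: np.ndarray  # per-hospital log-SMR effects
    patient_probs: np.ndarray  # per-patient true death probability
    intercept: float  # calibrated logit intercept


def _hospital_sizes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Admissions per hospital: clipped log-normal hitting the target median."""
    mu = np.log(config.size_median)
    # Put the clip ceiling roughly 2 SDs above the median so the right
    # tail is heavy but the max target is attainable.
    sigma = max((np.log(config.size_max) - mu) / 2.0, 1e-9)
    sizes = rng.lognormal(mean=mu, sigma=sigma, size=config.n_hospitals)
    return np.clip(np.round(sizes), config.size_min, config.size_max).astype(int)


def _quintile_band(values: np.ndarray) -> np.ndarray:
    edges = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(edges, values, side="right")


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """Generate one admission-level cohort plus its ground truth.

    The returned frame has columns ``hospital_id``, ``age``, ``sbp``,
    ``heart_rate``, ``diagnosis`` and ``died_30d`` (nullable integer;
    ``pd.NA`` marks a missing death status).  Generation is a pure
    function of ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    coef = config.risk_coefficients

    sizes = _hospital_sizes(config, rng)
    n_patients = int(sizes.sum())
    hospital_id = np.repeat(np.arange(1, config.n_hospitals + 1), sizes)

    theta = config.mu0_true + config.sigma0_true * rng.standard_normal(
        config.n_hospitals
    )
    if config.sigma0_true == 0:
        theta = np.full(config.n_hospitals, float(config.mu0_true))

    # Covariates.  Ages by banded frequencies, uniform within band; SBP
    # and heart rate from clipped normals so their empirical fifths are
    # well separated.
    age_band = rng.choice(5, size=n_patients, p=_AGE_BAND_PROPS)
    band_lo = np.array([18.0, 55.0, 65.0, 75.0, 85.0])
    band_hi = np.array([55.0, 65.0, 75.0, 85.0, 101.0])
    age = np.floor(
        band_lo[age_band] + rng.random(n_patients) * (band_hi[age_band] - band_lo[age_band])
    ).astype(int)

    sbp = np.clip(np.round(rng.normal(140.0, 27.0, n_patients)), 50, 249).astype(int)
    hr = np.clip(np.round(rng.normal(80.0, 26.0, n_patients)), 21, 199).astype(int)

    diag_names = list(_DIAG_COUNTS)
    diag_p = np.array([_DIAG_COUNTS[d] for d in diag_names], dtype=float)
    diag_p /= diag_p.sum()
    diagnosis = rng.choice(diag_names, size=n_patients, p=diag_p)

    # Linear predictor without intercept; banding of SBP/HR uses the
    # realised fifths of this cohort, matching how the analysis bands.
    diag_lookup = np.array([coef.diagnosis[d] for d in diagnosis])
    lp = (
        np.asarray(coef.age)[age_band]
        + np.asarray(coef.sbp)[_quintile_band(sbp)]
        + np.asarray(coef.heart_rate)[_quintile_band(hr)]
        + diag_lookup
        + theta[hospital_id - 1]
    )

    # Calibrate the intercept so the population death rate matches the
    # configured baseline exactly in expectation over this cohort.
    target = config.baseline_rate

    def _gap(b0: float) -> float:
        return float(expit(b0 + lp).mean() - target)

    intercept = brentq(_gap, -30.0, 10.0, xtol=1e-12)
    probs = expit(intercept + lp)

    died = (rng.random(n_patients) < probs).astype(int)
    died_col = pd.array(died, dtype="Int64")
    if config.missing_fraction > 0:
        missing = rng.random(n_patients) < config.missing_fraction
        died_col[missing] = pd.NA

    frame = pd.DataFrame(
        {
            "hospital_id": hospital_id,
            "age": age,
            "sbp": sbp,
            "heart_rate": hr,
            "diagnosis": diagnosis,
            "died_30d": died_col,
        }
    )
    truth = TrueParameters(theta_true=theta, patient_probs=probs, intercept=float(intercept))
    return frame, truth


def truth_path(cohort_path: str | Path) -> Path:
    """Sidecar file holding the per-hospital ground truth."""
    p = Path(cohort_path)
    return p.with_name(p.stem + ".truth.csv")


def write_cohort(
    frame: pd.DataFrame,
    truth: TrueParameters | None,
    path: str | Path,
    seed: int | None = None,
) -> Path:
    """Write the cohort as headered CSV (plus a truth sidecar if given).

    The seed is recorded as a leading ``# seed=N`` comment line in both
    files so a run can be traced back to its generator.
    """
    path = Path(path)
    header = f"# seed={seed}\n" if seed is not None else ""
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)
    if truth is not None:
        tp = truth_path(path)
        truth_frame = pd.DataFrame(
            {
                "hospital_id": np.arange(1, len(truth.theta_true) + 1),
                "theta_true": truth.theta_true,
            }
        )
        with open(tp, "w") as fh:
            fh.write(header)
            fh.write(f"# intercept={truth.intercept!r}\n")
            truth_frame.to_csv(fh, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    frame["died_30d"] = pd.array(frame["died_30d"], dtype="Int64")
    return frame
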