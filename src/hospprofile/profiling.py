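"""Outlier classification from posterior draws.

Two rules are applied to each model's draws:

* RAMR exceedance — a hospital is a high (low) outlier when the
  posterior probability that its risk-adjusted mortality rate exceeds
  (1 + delta) * mu30 (falls below (1 - delta) * mu30) is at least
  ``prob_cutoff``.
* rank intervals — hospitals are ranked per retained iteration by RAMR
  (rank 1 = lowest mortality, ties mid-ranked); a hospital whose
  equal-tailed rank interval lies entirely inside the bottom (top)
  quartile of ranks is a low (high) outlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from hospprofile.bayes import PosteriorDraws, posterior_summary

LABELS = ("low", "normal", "high")


@dataclass(frozen=True)
class ProfilingConfig:
    mu30: float = 10.2  # overall 30-day mortality, percent
    delta: float = 0.20
    prob_cutoff: float = 0.75
    rank_level: float = 0.95
    rank_quantiles: tuple[float, float] = (0.25, 0.75)
    ramr_level: float = 0.95

    def __post_init__(self) -> None:
        if self.mu30 <= 0:
            raise ValueError("mu30 must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.5 < self.prob_cutoff <= 1.0:
            raise ValueError("prob_cutoff must lie in (0.5, 1]")


def plug_in_ramr(observed: float, expected: float, mu30: float = 10.2) -> float:
    """Point-estimate risk-adjusted rate: mu30 * O/E, in percent."""
    if expected <= 0:
        raise ValueError("expected deaths must be positive")
    return mu30 * observed / expected


def ramr_draws(theta: np.ndarray, mu30: float = 10.2) -> np.ndarray:
    """Elementwise mu30 * exp(theta); strictly monotone in theta."""
    return mu30 * np.exp(np.asarray(theta, dtype=float))


def classify_ramr(
    draws: np.ndarray, config: ProfilingConfig
) -> tuple[float, float, str]:
    """Exceedance probabilities and label for one hospital's RAMR draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws")
    high_bound = (1.0 + config.delta) * config.mu30
    low_bound = (1.0 - config.delta) * config.mu30
    p_high = float(np.mean(draws > high_bound))
    p_low = float(np.mean(draws < low_bound))
    if p_high >= config.prob_cutoff:
        label = "high"
    elif p_low >= config.prob_cutoff:
        label = "low"
    else:
        label = "normal"
    return p_high, p_low, label


def rank_draws(theta: np.ndarray) -> np.ndarray:
    """Per-iteration ascending ranks across hospitals (ties mid-ranked).

    ``theta`` has shape (n_draws, n_hospitals); ranks of RAMR equal
    ranks of theta because the transform is strictly increasing.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2:
        raise ValueError("expected a (n_draws, n_hospitals) matrix")
    return rankdata(theta, axis=1)


def rank_quartile_cutoffs(
    n_hospitals: int, rank_quantiles: tuple[float, float] = (0.25, 0.75)
) -> tuple[float, float]:
    """Linear-interpolation quantiles of the integer ranks 1..n."""
    if n_hospitals < 2:
        raise ValueError("need >= 2 hospitals")
    lo_q, hi_q = rank_quantiles
    return 1 + lo_q * (n_hospitals - 1), 1 + hi_q * (n_hospitals - 1)


def classify_rank(
    rank_interval: tuple[float, float], cutoffs: tuple[float, float]
) -> str:
    """Low if the whole interval sits at or below the lower cutoff, high
    if at or above the upper cutoff, otherwise normal."""
    lo, hi = rank_interval
    if lo > hi:
        raise ValueError("inverted rank interval")
    low_cut, high_cut = cutoffs
    if hi <= low_cut:
        return "low"
    if lo >= high_cut:
        return "high"
    return "normal"


def build_profiles(
    summaries: pd.DataFrame, draws: PosteriorDraws, config: ProfilingConfig
) -> pd.DataFrame:
    """One row per hospital: SMR, plug-in and posterior RAMR summaries,
    exceedance probabilities, rank summaries, and both labels."""
    summaries = summaries.sort_values("hospital_id").reset_index(drop=True)
    order = np.argsort(draws.hospital_ids)
    theta = draws.theta_combined()[:, order]
    ids = draws.hospital_ids[order]
    if not np.array_equal(ids, summaries["hospital_id"].to_numpy()):
        raise ValueError("draws and summaries cover different hospitals")

    ramr = ramr_draws(theta, config.mu30)
    ramr_sum = posterior_summary(ramr, level=config.ramr_level)
    ranks = rank_draws(theta)
    rank_sum = posterior_summary(ranks, level=config.rank_level)
    cutoffs = rank_quartile_cutoffs(len(ids), config.rank_quantiles)

    rows = []
    for j, hid in enumerate(ids):
        O = float(summaries.loc[j, "observed_deaths"])
        E = float(summaries.loc[j, "expected_deaths"])
        p_high, p_low, ramr_label = classify_ramr(ramr[:, j], config)
        rank_interval = (float(rank_sum["lower"][j]), float(rank_sum["upper"][j]))
        rows.append(
            {
                "hospital_id": hid,
                "n_admissions": int(summaries.loc[j, "n_admissions"]),
                "observed_deaths": O,
                "expected_deaths": E,
                "smr": O / E,
                "ramr_plugin": plug_in_ramr(O, E, config.mu30),
                "ramr_mean": float(ramr_sum["mean"][j]),
                "ramr_median": float(ramr_sum["median"][j]),
                "ramr_lower": float(ramr_sum["lower"][j]),
                "ramr_upper": float(ramr_sum["upper"][j]),
                "p_high": p_high,
                "p_low": p_low,
                "ramr_label": ramr_label,
                "rank_median": float(rank_sum["median"][j]),
                "rank_lower": rank_interval[0],
                "rank_upper": rank_interval[1],
                "rank_label": classify_rank(rank_interval, cutoffs),
            }
        )
    return pd.DataFrame(rows)
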