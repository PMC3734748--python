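import numpy as np
import pandas as pd
import pytest

from hospprofile import (
    CohortConfig,
    ExclusionRules,
    McmcConfig,
    ModelSpec,
    apply_exclusions,
    derive_bands,
    expected_deaths,
    fit_risk_model,
    generate_cohort,
)

# Published 3x3 cross-classifications (rows = first-named method) used
# as fixed worked examples; labels ordered (low, normal, high).
PUBLISHED_CROSSTABS = {
    ("fixed_ramr", "fixed_rank"): [[20, 0, 0], [7, 88, 0], [0, 9, 4]],
    ("fixed_ramr", "hierarchical_ramr"): [[6, 14, 0], [0, 95, 0], [0, 8, 5]],
    ("fixed_rank", "hierarchical_ramr"): [[6, 21, 0], [0, 96, 1], [0, 0, 4]],
    ("hierarchical_rank", "fixed_ramr"): [[2, 0, 0], [18, 95, 8], [0, 0, 5]],
    ("hierarchical_rank", "fixed_rank"): [[2, 0, 0], [25, 96, 0], [0, 1, 4]],
    ("hierarchical_rank", "hierarchical_ramr"): [[2, 0, 0], [4, 117, 0], [0, 0, 5]],
}

PUBLISHED_KAPPAS = {
    ("fixed_ramr", "fixed_rank"): 0.71,
    ("fixed_ramr", "hierarchical_ramr"): 0.46,
    ("fixed_rank", "hierarchical_ramr"): 0.44,
    ("hierarchical_rank", "fixed_ramr"): 0.32,
    ("hierarchical_rank", "fixed_rank"): 0.29,
    ("hierarchical_rank", "hierarchical_ramr"): 0.77,
}

# Published top/bottom-five table: hospital -> (n, observed, expected, RAMR).
PUBLISHED_RAMR_ROWS = {
    1: (737, 39, 89.65, 4.54),
    2: (167, 5, 10.58, 4.82),
    3: (232, 9, 18.99, 4.83),
    4: (209, 10, 20.10, 5.07),
    5: (2158, 71, 123.56, 5.86),
    124: (289, 42, 27.43, 15.62),
    125: (24, 5, 3.21, 15.90),
    126: (21, 4, 2.50, 16.31),
    127: (348, 63, 37.45, 17.16),
    128: (97, 19, 9.97, 19.44),
}

# Rows whose printed RAMR equals 10.2 * O / E at 2 dp exactly.  Hospital
# 1 is a documented discrepancy; 125 and 126 are off by 0.01, which is
# consistent with the printed expected deaths being rounded to 2 dp.
EXACT_RAMR_HOSPITALS = (2, 3, 4, 5, 124, 127, 128)
ROUNDED_E_HOSPITALS = (125, 126)


def labels_from_crosstab(counts) -> tuple[list[str], list[str]]:
    """Reconstruct a pair of label vectors realising a 3x3 table."""
    order = ("low", "normal", "high")
    a, b = [], []
    for i in range(3):
        for j in range(3):
            a += [order[i]] * counts[i][j]
            b += [order[j]] * counts[i][j]
    return a, b


@pytest.fixture(scope="session")
def small_cohort():
    config = CohortConfig(
        n_hospitals=30, size_min=20, size_median=120, size_max=600, seed=11
    )
    frame, truth = generate_cohort(config)
    return config, frame, truth


@pytest.fixture(scope="session")
def small_summaries(small_cohort):
    _, frame, _ = small_cohort
    filtered, _ = apply_exclusions(frame, ExclusionRules())
    edges = derive_bands(filtered)
    model = fit_risk_model(filtered, edges)
    return expected_deaths(filtered, model)


def simulate_counts(
    n_hospitals: int,
    sigma0: float,
    seed: int,
    mu0: float = 0.0,
    size_median: int = 300,
    size_max: int = 2200,
    rate: float = 0.102,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Hospital-level O/E data straight from the Poisson model (no
    patient level), for fast recovery and property studies."""
    rng = np.random.default_rng(seed)
    mu = np.log(size_median)
    sigma = (np.log(size_max) - mu) / 2.0
    sizes = np.clip(
        np.round(rng.lognormal(mu, sigma, n_hospitals)), 20, size_max
    ).astype(int)
    theta = mu0 + sigma0 * rng.standard_normal(n_hospitals)
    E = sizes * rate
    O = rng.poisson(E * np.exp(theta))
    summaries = pd.DataFrame(
        {
            "hospital_id": np.arange(1, n_hospitals + 1),
            "n_admissions": sizes,
            "observed_deaths": O,
            "expected_deaths": E,
        }
    )
    return summaries, theta


FAST_MCMC = McmcConfig(n_chains=3, n_iterations=2000, burn_in=500, seed=0)
FIXED_SPEC = ModelSpec(kind="fixed")
HIER_SPEC = ModelSpec(kind="hierarchical")
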