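"""Pairwise agreement between outlier-classification methods.

Labels are ordinal (low < normal < high); agreement is summarised by a
3x3 cross-tabulation, observed and chance-expected (weighted) agreement
and Cohen's weighted kappa.  The default weights are linear,
w_ij = 1 - |i - j| / (k - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from hospprofile.profiling import LABELS

WEIGHT_SCHEMES = ("linear", "quadratic", "unweighted")


@dataclass(frozen=True)
class CrossTab:
    """counts[i][j] = hospitals labelled LABELS[i] by method A and
    LABELS[j] by method B."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (3, 3):
            raise ValueError("cross-tabulation must be 3x3")
        if np.any(counts < 0) or counts.sum() != self.n:
            raise ValueError("counts must be nonnegative and sum to n")

    def transpose(self) -> "CrossTab":
        return CrossTab(counts=np.asarray(self.counts).T.copy(), n=self.n)


@dataclass(frozen=True)
class AgreementResult:
    observed_agreement: float
    weighted_agreement: float
    expected_weighted_agreement: float
    kappa: float
    weight_scheme: str

    @property
    def qualitative(self) -> str:
        """Conventional banding: marginal < 0.4 <= good <= 0.75 < excellent."""
        if np.isnan(self.kappa):
            return "undefined"
        if self.kappa > 0.75:
            return "excellent"
        if self.kappa >= 0.4:
            return "good"
        return "marginal"


def _label_indices(labels: Sequence[str]) -> np.ndarray:
    lookup = {lab: i for i, lab in enumerate(LABELS)}
    try:
        return np.array([lookup[l] for l in labels], dtype=int)
    except KeyError as err:
        raise ValueError(f"unknown label {err.args[0]!r}") from err


def cross_tabulate(labels_a: Sequence[str], labels_b: Sequence[str]) -> CrossTab:
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    ia, ib = _label_indices(labels_a), _label_indices(labels_b)
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (ia, ib), 1)
    return CrossTab(counts=counts, n=len(labels_a))


def _weights(scheme: str, k: int = 3) -> np.ndarray:
    i, j = np.indices((k, k))
    if scheme == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if scheme == "quadratic":
        return 1.0 - ((i - j) / (k - 1)) ** 2
    if scheme == "unweighted":
        return (i == j).astype(float)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(tab: CrossTab, weight_scheme: str = "linear") -> AgreementResult:
    """Chance-corrected agreement: kappa = (Po_w - Pe_w) / (1 - Pe_w),
    with Pe_w from the products of the marginals."""
    counts = np.asarray(tab.counts, dtype=float)
    if tab.n <= 0:
        raise ValueError("empty table")
    p = counts / tab.n
    w = _weights(weight_scheme)
    po_w = float((w * p).sum())
    pe_w = float((w * np.outer(p.sum(axis=1), p.sum(axis=0))).sum())
    if pe_w >= 1.0 - 1e-12:
        raise ValueError("degenerate marginals: chance agreement is 1, kappa undefined")
    return AgreementResult(
        observed_agreement=float(np.trace(p)),
        weighted_agreement=po_w,
        expected_weighted_agreement=pe_w,
        kappa=(po_w - pe_w) / (1.0 - pe_w),
        weight_scheme=weight_scheme,
    )


def pairwise_comparisons(
    method_labels: Mapping[str, Sequence[str]], weight_scheme: str = "linear"
) -> dict[tuple[str, str], tuple[CrossTab, AgreementResult]]:
    """All unordered pairs of methods; rows of each table belong to the
    first method of the pair."""
    lengths = {name: len(v) for name, v in method_labels.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"methods label different hospital sets: {lengths}")
    out = {}
    for a, b in combinations(method_labels, 2):
        tab = cross_tabulate(method_labels[a], method_labels[b])
        try:
            result = weighted_kappa(tab, weight_scheme)
        except ValueError:
            # Both methods put every hospital in one category: chance
            # agreement is 1 and kappa is undefined; flag with NaN.
            p = np.asarray(tab.counts, dtype=float) / tab.n
            w = _weights(weight_scheme)
            result = AgreementResult(
                observed_agreement=float(np.trace(p)),
                weighted_agreement=float((w * p).sum()),
                expected_weighted_agreement=1.0,
                kappa=float("nan"),
                weight_scheme=weight_scheme,
            )
        out[(a, b)] = (tab, result)
    return out


def format_pair_report(
    pair: tuple[str, str], tab: CrossTab, result: AgreementResult
) -> str:
    """Human-readable block for one method pair."""
    a, b = pair
    lines = [f"{a} (rows) vs {b} (columns), n = {tab.n}"]
    header = "".join(f"{lab:>10}" for lab in LABELS)
    lines.append(" " * 10 + header)
    for i, lab in enumerate(LABELS):
        row = "".join(f"{int(tab.counts[i, j]):>10}" for j in range(3))
        lines.append(f"{lab:>10}{row}")
    lines.append(
        f"observed agreement = {result.observed_agreement:.3f}; "
        f"weighted agreement = {result.weighted_agreement:.3f}; "
        f"kappa ({result.weight_scheme}) = {result.kappa:.2f} [{result.qualitative}]"
    )
    return "\n".join(lines)
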