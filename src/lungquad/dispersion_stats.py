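"""Dispersion statistics over included quadrats and group comparisons.

The index of dispersion D = sigma^2 / mu (variance-to-mean ratio of per-cell
counts) is the primary statistic: under complete spatial randomness the
counts are Poisson and D = 1, D >> 1 indicates clustering, and D < 1
indicates an unusually even (low-variance) pattern. The coefficient of
variation c_v = sigma / mu corroborates it; because c_v is scale-invariant
while D scales linearly with the counts, the pair distinguishes genuine
clustering from mere magnitude differences, and D's variance numerator
weights the extreme deposition hot-spots that matter here.

Variance convention defaults to the sample form (n - 1): the analysed cells
are a finite sample of tissue, and the sample form is the one written for
c_v (s / x-bar). The convention is switchable and always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .grid_quadrat import QuadratTable

__all__ = [
    "DispersionSummary",
    "GroupComparison",
    "NoAnalyzableTissueError",
    "summarize",
    "classify_pattern",
    "compare_groups",
]


class NoAnalyzableTissueError(ValueError):
    """No grid cell met the tissue-coverage criterion."""


@dataclass(frozen=True)
class DispersionSummary:
    """Mean, variance, D and c_v over the included cells of one specimen.

    When the mean is zero, D and c_v are undefined: they are carried as NaN
    with ``defined=False`` rather than coerced to 0, because a zero would
    fabricate "perfect uniformity" out of empty tissue.
    """

    n_cells: int
    mean: float
    variance: float
    index_of_dispersion: float
    coefficient_of_variation: float
    variance_convention: Literal["sample", "population"]
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "mean": self.mean,
            "variance": self.variance,
            "index_of_dispersion": self.index_of_dispersion,
            "coefficient_of_variation": self.coefficient_of_variation,
            "variance_convention": self.variance_convention,
            "defined": self.defined,
        }


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided comparison of a per-specimen statistic between groups."""

    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    statistic_name: str
    statistic: float
    p_value: float
    test_spec: str

    def to_dict(self) -> dict:
        return {
            "group_a": list(self.group_a),
            "group_b": list(self.group_b),
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "test_spec": self.test_spec,
        }


def summarize(
    table_or_values: QuadratTable | Sequence[float],
    variance_convention: Literal["sample", "population"] = "sample",
) -> DispersionSummary:
    """Dispersion statistics over the included cells of a quadrat table.

    Accepts a :class:`QuadratTable` (only cells passing the coverage
    criterion enter) or a bare sequence of per-cell signals.
    """
    if isinstance(table_or_values, QuadratTable):
        values = table_or_values.included_signals
    else:
        values = np.asarray(table_or_values, dtype=float)
    n = values.size
    if n == 0:
        raise NoAnalyzableTissueError("zero included cells: no analyzable tissue")
    ddof = 1 if variance_convention == "sample" else 0
    if variance_convention == "sample" and n < 2:
        raise ValueError("sample variance needs at least 2 included cells")
    mean = float(values.mean())
    variance = float(values.var(ddof=ddof))
    if mean > 0:
        d = variance / mean
        cv = float(np.sqrt(variance)) / mean
        defined = True
    else:
        d = float("nan")
        cv = float("nan")
        defined = False
    return DispersionSummary(
        n_cells=int(n), mean=mean, variance=variance,
        index_of_dispersion=d, coefficient_of_variation=cv,
        variance_convention=variance_convention, defined=defined,
    )


def classify_pattern(summary: DispersionSummary, delta: float = 0.2) -> str:
    """Label the spatial pattern by where D falls relative to the Poisson
    anchor D = 1: ``"clustered"`` above ``1 + delta``, ``"underdispersed"``
    below ``1 - delta``, else ``"poisson_like"``. Undefined D propagates as
    ``"unclassifiable"``."""
    if not summary.defined or not np.isfinite(summary.index_of_dispersion):
        return "unclassifiable"
    d = summary.index_of_dispersion
    if d > 1.0 + delta:
        return "clustered"
    if d < 1.0 - delta:
        return "underdispersed"
    return "poisson_like"


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: Literal["welch_t", "permutation"] = "welch_t",
    statistic_name: str = "per_specimen_value",
    n_resamples: int = 10_000,
    rng_seed: int = 0,
) -> GroupComparison:
    """Two-sided comparison of per-specimen values (e.g. D or variance).

    Default is Welch's unequal-variance t-test: large variance differences
    between exposure groups are exactly what this analysis detects, making
    the pooled-variance t inappropriate. A mean-difference permutation test
    (seeded; exact when the group sizes allow fewer than ``n_resamples``
    distinct splits) is available for small or non-normal samples.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.size < 2 or b_arr.size < 2:
        raise ValueError("each group needs at least 2 specimens")
    if test == "welch_t":
        res = stats.ttest_ind(a_arr, b_arr, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
        spec = "Welch two-sample t-test, two-sided, unequal variances"
    elif test == "permutation":
        res = stats.permutation_test(
            (a_arr, b_arr),
            lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=n_resamples,
            rng=np.random.default_rng(rng_seed),
        )
        statistic, p = float(res.statistic), float(res.pvalue)
        spec = (f"permutation test on difference of means, two-sided, "
                f"n_resamples={n_resamples}, seed={rng_seed}")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        group_a=tuple(a_arr), group_b=tuple(b_arr),
        statistic_name=statistic_name, statistic=statistic,
        p_value=p, test_spec=spec,
    )
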