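"""Model-vs-data comparison: usage curves, curve distance, ensemble summary.

The usage curve of a network is the complementary cumulative count of
lines per usage level: curve(k) = number of lines used at least k times.
The distance between an observed and a simulated curve is the area enclosed
between them on the integer usage grid — with unit-width columns this is
simply sum_k |a(k) - b(k)|.  An ensemble of simulations yields a
distribution for each statistic (distance, fitted exponent, maximum degree,
largest-component size, founder advantage) against which the observed value
is placed as a percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .powerlaw import fit_discrete_powerlaw
from .simulate import ReplicateSummary

__all__ = [
    "UsageCurve",
    "ComparisonReport",
    "cumulative_usage_curve",
    "curve_distance",
    "ensemble_summary",
]


@dataclass
class UsageCurve:
    """Complementary cumulative line counts per usage level.

    ``values[i]`` is the number of lines with usage >= ``support[i]``;
    ``support`` is ``1..kmax``.  ``values`` is non-increasing and
    ``values[0]`` equals the total number of used lines.
    """

    support: np.ndarray
    values: np.ndarray

    def at(self, k: int) -> int:
        """Curve value at any positive integer level (0 beyond kmax)."""
        if k < 1:
            raise ValueError("usage level must be >= 1")
        if k > len(self.values):
            return 0
        return int(self.values[k - 1])


def cumulative_usage_curve(degrees) -> UsageCurve:
    """Build the usage curve from a vector of line usage counts."""
    degrees = np.asarray(degrees, dtype=np.int64)
    if len(degrees) == 0:
        raise ValueError("degree vector is empty")
    if (degrees < 1).any():
        raise ValueError("usage counts must be positive")
    kmax = int(degrees.max())
    hist = np.bincount(degrees, minlength=kmax + 1)[1:]
    ccdf = np.cumsum(hist[::-1])[::-1]
    return UsageCurve(support=np.arange(1, kmax + 1), values=ccdf)


def curve_distance(a: UsageCurve, b: UsageCurve, log_scale: bool = False) -> float:
    """Area enclosed between two usage curves on the integer grid.

    With ``log_scale=False`` (default): sum over k of |a(k) - b(k)| on the
    raw count scale.  With ``log_scale=True`` the counts are log10
    transformed first (levels where either curve has reached zero are
    skipped), mirroring a comparison drawn on log axes.
    """
    kmax = max(len(a.values), len(b.values))
    av = np.zeros(kmax, dtype=float)
    bv = np.zeros(kmax, dtype=float)
    av[: len(a.values)] = a.values
    bv[: len(b.values)] = b.values
    if log_scale:
        ok = (av > 0) & (bv > 0)
        return float(np.abs(np.log10(av[ok]) - np.log10(bv[ok])).sum())
    return float(np.abs(av - bv).sum())


@dataclass
class ComparisonReport:
    """Ensemble distributions with the observed network placed among them."""

    replicates: pd.DataFrame  # one row per replicate: distance, alpha, ...
    empirical: dict[str, float]
    percentiles: dict[str, float]  # percentile of each empirical value
    best_fit_index: int  # replicate with minimal distance to the data

    def quantiles(self, column: str, q=(0.025, 0.5, 0.975)) -> dict[float, float]:
        return {qq: float(self.replicates[column].quantile(qq)) for qq in q}


def _percentile_of(sample: np.ndarray, value: float) -> float:
    """Mid-rank percentile of `value` within `sample` (0–100)."""
    sample = np.asarray(sample, dtype=float)
    below = (sample < value).sum()
    equal = (sample == value).sum()
    return float(100.0 * (below + 0.5 * equal) / len(sample))


def ensemble_summary(
    summaries: list[ReplicateSummary],
    empirical_degrees,
    xmin: int = 3,
    log_scale: bool = False,
) -> ComparisonReport:
    """Compare an ensemble of simulated networks against observed usage.

    For each replicate: distance of its usage curve to the empirical curve,
    fitted power-law exponent (fixed ``xmin``), maximum degree,
    largest-component line count and founder-vs-later mean usage.  The
    empirical statistics are reported with their percentile within the
    ensemble; the replicate with the smallest distance is flagged as the
    best fit (ties broken by lowest index, so the result does not depend on
    replicate ordering).
    """
    if not summaries:
        raise ValueError("empty ensemble")
    emp_curve = cumulative_usage_curve(empirical_degrees)
    emp_fit = fit_discrete_powerlaw(empirical_degrees, xmin=xmin)

    rows = []
    for rep in summaries:
        curve = cumulative_usage_curve(rep.degrees)
        fit = fit_discrete_powerlaw(rep.degrees, xmin=xmin)
        rows.append(
            {
                "distance": curve_distance(emp_curve, curve, log_scale=log_scale),
                "alpha": fit.alpha,
                "max_degree": rep.max_degree,
                "n_lines": rep.n_lines,
                "largest_component_lines": rep.largest_component_lines,
                "founder_mean_usage": rep.founder_mean_usage,
                "nonfounder_mean_usage": rep.nonfounder_mean_usage,
            }
        )
    df = pd.DataFrame(rows)

    empirical_degrees = np.asarray(empirical_degrees, dtype=np.int64)
    empirical = {
        "alpha": emp_fit.alpha,
        "max_degree": float(empirical_degrees.max()),
        "n_lines": float(len(empirical_degrees)),
    }
    percentiles = {
        key: _percentile_of(df[col].to_numpy(), val)
        for key, col, val in [
            ("alpha", "alpha", empirical["alpha"]),
            ("max_degree", "max_degree", empirical["max_degree"]),
            ("n_lines", "n_lines", empirical["n_lines"]),
        ]
    }
    best = int(df["distance"].to_numpy().argmin())  # first minimum
    return ComparisonReport(
        replicates=df,
        empirical=empirical,
        percentiles=percentiles,
        best_fit_index=best,
    )
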