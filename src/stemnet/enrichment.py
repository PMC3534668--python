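"""Share summaries and hypergeometric enrichment of formerly-approved-line use.

The question: within a subset of studies (a funder's portfolio, a country,
a time window), is the use of formerly-NIH-approved cell lines
over-represented relative to the study population?  The unit of analysis is
the *study* — a study "uses" the category if at least one of its lines is
formerly approved — and the test is the one-sided hypergeometric upper
tail, i.e. sampling studies without replacement from the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .io_model import has_funder

__all__ = [
    "ShareTable",
    "EnrichmentResult",
    "share_summary",
    "hypergeom_tail",
    "subset_enrichment",
    "study_level_table",
]


@dataclass
class ShareTable:
    """Named category counts over studies, with explicit denominators.

    ``denominator_of`` maps a category to the category whose count is its
    denominator when computing percentage shares (default ``denominator``).
    ``partitions`` lists (parts, whole) pairs whose counts must sum exactly;
    they are checked on construction.
    """

    counts: dict[str, int]
    denominator: str = "total"
    denominator_of: dict[str, str] = field(default_factory=dict)
    partitions: list[tuple[list[str], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for parts, whole in self.partitions:
            total = sum(self.counts[p] for p in parts)
            if total != self.counts[whole]:
                raise ValueError(
                    f"partition {parts} sums to {total} != {whole}={self.counts[whole]}"
                )
        for cat in self.counts:
            denom = self.counts[self.denominator_of.get(cat, self.denominator)]
            if self.counts[cat] > denom:
                raise ValueError(f"category {cat!r} exceeds its denominator")

    def denominator_count(self, category: str) -> int:
        return self.counts[self.denominator_of.get(category, self.denominator)]


@dataclass
class EnrichmentResult:
    """One-sided hypergeometric over-representation test.

    Population of ``population`` studies of which ``successes`` use the
    category; ``draws`` studies fall in the subset, ``observed`` of them
    using the category; ``p_value`` = P(X >= observed).
    """

    population: int
    successes: int
    draws: int
    observed: int
    p_value: float


def share_summary(table: ShareTable, decimals: int = 1) -> dict[str, float]:
    """Percentage share per category (100·count/denominator), rounded.

    Shares are reported at one decimal, the convention of the summaries
    this mirrors; categories may overlap (most studies use several lines),
    so shares need not sum to 100.
    """
    out = {}
    for cat, count in table.counts.items():
        denom = table.denominator_count(cat)
        if denom <= 0:
            raise ZeroDivisionError(f"zero denominator for category {cat!r}")
        out[cat] = round(100.0 * count / denom, decimals)
    return out


def hypergeom_tail(population: int, successes: int, draws: int, observed: int) -> float:
    """Upper tail P(X >= observed) for X ~ Hypergeom(population, successes, draws).

    Accumulated in log space (logsumexp over log-pmf terms) for stability in
    the far tail.
    """
    m, k_tot, n, k = population, successes, draws, observed
    if not (0 <= k_tot <= m and 0 <= n <= m):
        raise ValueError("need successes <= population and draws <= population")
    if not 0 <= k <= min(k_tot, n):
        if k > min(k_tot, n):
            raise ValueError(
                f"observed={k} exceeds min(successes={k_tot}, draws={n})"
            )
        raise ValueError("observed must be non-negative")
    if k <= max(0, n + k_tot - m):  # below the support: the event is certain
        return 1.0
    support = np.arange(k, min(k_tot, n) + 1)
    logp = hypergeom.logpmf(support, m, k_tot, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def study_level_table(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse a usage table to one row per study.

    Columns: ``study_id``, ``pub_year``, ``country``, ``funders``,
    ``uses_formerly_approved`` (any edge to a formerly approved line).
    """
    approved = set(meta.loc[meta["formerly_approved"].astype(bool), "line_id"])
    t = table.copy()
    t["_appr"] = t["line_id"].isin(approved)
    agg = t.groupby("study_id", sort=False).agg(
        pub_year=("pub_year", "first"),
        country=("country", "first"),
        funders=("funders", "first"),
        uses_formerly_approved=("_appr", "any"),
    )
    return agg.reset_index()


def subset_enrichment(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    subset_filter: Callable[[pd.DataFrame], pd.Series],
    window: tuple[int, int] | None = None,
) -> EnrichmentResult:
    """Test over-representation of formerly-approved-line use within a subset.

    Parameters
    ----------
    subset_filter
        Predicate on the study-level table returning a boolean mask (e.g.
        ``lambda s: s["country"] == "US"`` or a funder-tag filter).
    window
        Optional (start, end) publication-year window defining the
        population; inclusive on both ends.
    """
    studies = study_level_table(table, meta)
    if window is not None:
        lo, hi = window
        studies = studies[(studies["pub_year"] >= lo) & (studies["pub_year"] <= hi)]
    if not len(studies):
        raise ValueError("no studies in the requested window")
    mask = np.asarray(subset_filter(studies), dtype=bool)
    if not mask.any():
        raise ValueError("subset filter selects no studies")
    m = len(studies)
    k_tot = int(studies["uses_formerly_approved"].sum())
    n = int(mask.sum())
    k = int(studies.loc[mask, "uses_formerly_approved"].sum())
    return EnrichmentResult(
        population=m,
        successes=k_tot,
        draws=n,
        observed=k,
        p_value=hypergeom_tail(m, k_tot, n, k),
    )


def funder_filter(tag: str) -> Callable[[pd.DataFrame], pd.Series]:
    return lambda studies: has_funder(studies, tag)


def country_filter(code: str) -> Callable[[pd.DataFrame], pd.Series]:
    return lambda studies: studies["country"] == code


def bonferroni(p_values: list[float]) -> list[float]:
    """Family-wise corrected p-values (supplementary output only)."""
    k = len(p_values)
    return [min(1.0, p * k) for p in p_values]
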