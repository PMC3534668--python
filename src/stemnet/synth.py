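"""Synthetic corpus generator and in-text reference count fixtures.

The curated literature corpus behind the empirical analysis (2,338 hESC
papers, 1998–2011, plus 512 hiPSC papers) is not publicly deposited, so this
module generates usage tables with the statistical structure the analysis
assumes: heavy-tailed line-usage counts produced by the cumulative-advantage
growth model itself, a mean of ~2.47 lines per study, usage negatively
correlated with a line's year of first publication, country profiles
dominated by a few large producers, and funder/eligibility annotations.

By default study countries and funders are assigned independently of which
lines a study used — the policy-independence null.  Setting
``policy_bias > 1`` makes studies that used at least one formerly approved
line correspondingly more likely to fall in ``bias_country``, which gives
the enrichment stage a controlled alternative for power experiments.

Counts printed in the source analysis (the CIRM funding breakdown and the
hiPSC lab-provenance shares) are shipped as fixtures so the share/enrichment
stages have exact, deterministic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import ShareTable
from .simulate import grow_bipartite

__all__ = [
    "SynthConfig",
    "generate_usage_table",
    "plant_outlier_lines",
    "fixture_cirm_counts",
    "fixture_cirm_no_nih_counts",
    "fixture_hipsc_counts",
]

# 14-country profile, US-dominant, loosely mirroring national shares of
# pluripotent stem-cell output; weights sum to 1
_DEFAULT_COUNTRIES = {
    "US": 0.35, "CN": 0.09, "GB": 0.08, "DE": 0.07, "JP": 0.06, "KR": 0.05,
    "IL": 0.04, "AU": 0.04, "CA": 0.04, "SE": 0.04, "ES": 0.04, "FR": 0.04,
    "SG": 0.03, "FI": 0.03,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic corpus.

    ``lines_per_study_mean`` targets the empirical 2.47 lines per
    publication; per-study counts are ``1 + Poisson(mean - 1)``.
    ``novelty_prob`` and ``n_founders`` parameterize the underlying
    cumulative-advantage growth.  ``growth_rate`` is the annual
    multiplicative growth of publication volume used to spread studies over
    ``year_range``.  ``approved_cutoff_year`` marks lines derived in or
    before that year as formerly eligible for federal funding.
    """

    n_studies: int = 2000
    lines_per_study_mean: float = 2.47
    novelty_prob: float = 0.15
    n_founders: int = 5
    year_range: tuple[int, int] = (1998, 2011)
    growth_rate: float = 1.35
    country_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTRIES)
    )
    cirm_fraction: float = 0.08
    nih_fraction: float = 0.40
    approved_cutoff_year: int = 2001
    derivation_lag_mean: float = 1.0
    n_labs: int = 25
    policy_bias: float = 1.0
    bias_country: str = "US"
    seed: int | None = None

    def validate(self) -> None:
        if self.lines_per_study_mean < 1:
            raise ValueError("lines_per_study_mean must be >= 1")
        if not 0 <= self.novelty_prob <= 1:
            raise ValueError("novelty_prob must be in [0, 1]")
        for p in (self.cirm_fraction, self.nih_fraction):
            if not 0 <= p <= 1:
                raise ValueError("funder fractions must be in [0, 1]")
        w = np.array(list(self.country_weights.values()))
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("country weights must be non-negative and sum to 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be ordered")
        if self.policy_bias <= 0:
            raise ValueError("policy_bias must be positive")


def _study_years(n_studies: int, year_range: tuple[int, int], growth_rate: float) -> np.ndarray:
    """Non-decreasing publication years with geometrically growing volume."""
    y0, y1 = year_range
    years = np.arange(y0, y1 + 1)
    w = growth_rate ** np.arange(len(years), dtype=float)
    cum = np.cumsum(w) / w.sum()
    # study i sits at quantile (i + 0.5)/n of the volume curve
    q = (np.arange(n_studies) + 0.5) / n_studies
    return years[np.searchsorted(cum, q, side="left")]


def generate_usage_table(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a usage table and matching line metadata.

    Returns ``(usage, meta)`` where ``usage`` has one row per (study, line)
    edge with columns ``study_id, line_id, pub_year, country, funders,
    cell_class`` and ``meta`` has one row per line.  Deterministic given
    ``config.seed`` (or an explicit generator).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    sizes = 1 + rng.poisson(config.lines_per_study_mean - 1.0, size=config.n_studies)
    net = grow_bipartite(sizes, config.novelty_prob, config.n_founders, rng)

    n_studies_total = net.n_studies  # includes the bootstrap founding project
    study_year = _study_years(n_studies_total, config.year_range, config.growth_rate)

    # line-level metadata: first publication = year of the introducing study
    first_pub = study_year[net.line_first_study]
    lag = rng.poisson(config.derivation_lag_mean, size=net.n_lines)
    derivation = first_pub - lag
    approved = derivation <= config.approved_cutoff_year
    labs = rng.integers(0, config.n_labs, size=net.n_lines)
    line_ids = np.array([f"L{j:04d}" for j in range(net.n_lines)])

    # per-study: does the study use >= 1 formerly approved line?
    uses_approved = np.zeros(n_studies_total, dtype=bool)
    np.logical_or.at(uses_approved, net.edge_study, approved[net.edge_line])

    # country assignment: independent of line usage under the null; with
    # policy_bias > 1 the bias country's odds are multiplied for studies
    # that used a formerly approved line
    codes = np.array(list(config.country_weights.keys()))
    base_w = np.array(list(config.country_weights.values()))
    u = rng.random(n_studies_total)
    base_cdf = np.cumsum(base_w)
    country_idx = np.searchsorted(base_cdf, u * base_cdf[-1], side="right")
    if config.policy_bias != 1.0:
        biased_w = base_w.copy()
        biased_w[codes == config.bias_country] *= config.policy_bias
        biased_cdf = np.cumsum(biased_w)
        u2 = rng.random(n_studies_total)
        biased_idx = np.searchsorted(biased_cdf, u2 * biased_cdf[-1], side="right")
        country_idx = np.where(uses_approved, biased_idx, country_idx)
    country = codes[country_idx]

    cirm = rng.random(n_studies_total) < config.cirm_fraction
    nih = rng.random(n_studies_total) < config.nih_fraction
    funders = np.array(
        [
            ";".join(t for t, on in (("CIRM", c), ("NIH", n)) if on) or "OTHER"
            for c, n in zip(cirm, nih)
        ]
    )

    study_ids = np.array([f"S{i:05d}" for i in range(n_studies_total)])
    usage = pd.DataFrame(
        {
            "study_id": study_ids[net.edge_study],
            "line_id": line_ids[net.edge_line],
            "pub_year": study_year[net.edge_study],
            "country": country[net.edge_study],
            "funders": funders[net.edge_study],
            "cell_class": "hESC",
        }
    )
    meta = pd.DataFrame(
        {
            "line_id": line_ids,
            "first_pub_year": first_pub,
            "derivation_year": derivation,
            "formerly_approved": approved,
            "provenance_lab": [f"lab{j:02d}" for j in labs],
        }
    )
    return usage, meta


def plant_outlier_lines(
    usage: pd.DataFrame,
    meta: pd.DataFrame,
    n_planted: int = 5,
    usage_factor: float = 20.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Inflate the usage of a few later-published lines by ``usage_factor``.

    Emulates lines that circulated widely before their first peer-reviewed
    publication: their usage is far above their first-publication-year
    cohort.  Picks ``n_planted`` lines from distinct cohorts in the later
    half of the year range and attaches new single-line studies until each
    reaches ``usage_factor`` times its original usage.  Returns new
    (usage, meta) tables — inputs are not modified — plus the planted ids.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    counts = usage.groupby("line_id").size()
    meta_idx = meta.set_index("line_id")
    years = meta_idx["first_pub_year"]
    mid = (years.min() + years.max()) / 2.0
    eligible = [
        ln
        for ln in counts.index
        if years[ln] > mid and counts[ln] >= 1
    ]
    # one line per cohort year, latest cohorts first, for cohort-relative contrast
    by_year: dict[int, list[str]] = {}
    for ln in eligible:
        by_year.setdefault(int(years[ln]), []).append(ln)
    planted: list[str] = []
    for yr in sorted(by_year, reverse=True):
        if len(planted) >= n_planted:
            break
        cands = by_year[yr]
        planted.append(cands[int(rng.integers(len(cands)))])
    if len(planted) < n_planted:
        raise ValueError("not enough late-cohort lines to plant outliers")

    extra_rows = []
    next_id = len(usage["study_id"].unique())
    for ln in planted:
        target = int(np.ceil(counts[ln] * usage_factor))
        for _ in range(target - int(counts[ln])):
            extra_rows.append(
                {
                    "study_id": f"P{next_id:05d}",
                    "line_id": ln,
                    "pub_year": int(years[ln]),
                    "country": "US",
                    "funders": "OTHER",
                    "cell_class": "hESC",
                }
            )
            next_id += 1
    out = pd.concat([usage, pd.DataFrame(extra_rows)], ignore_index=True)
    return out, meta.copy(), planted


def fixture_cirm_counts() -> ShareTable:
    """Published breakdown of 185 CIRM-(co)funded hESC studies, 2008–2011.

    Categories: studies using >=1 formerly approved line; exclusively
    formerly approved lines; formerly approved plus other lines (mixed);
    none; and the NIH-co-funded subset.  Exclusive + mixed + none partition
    the total (143 + 28 + 14 = 185).
    """
    return ShareTable(
        counts={
            "total": 185,
            "any_formerly_approved": 171,
            "exclusively_formerly_approved": 143,
            "mixed": 28,
            "none_formerly_approved": 14,
            "nih_cofunded": 110,
        },
        denominator="total",
        partitions=[
            (
                ["exclusively_formerly_approved", "mixed", "none_formerly_approved"],
                "total",
            )
        ],
    )


def fixture_cirm_no_nih_counts() -> ShareTable:
    """The 75 CIRM-funded studies without additional NIH support."""
    return ShareTable(
        counts={
            "total": 75,
            "any_formerly_approved": 63,
            "exclusively_formerly_approved": 50,
            "none_formerly_approved": 12,
        },
        denominator="total",
    )


def fixture_hipsc_counts() -> ShareTable:
    """Lab provenance of the 201 studies reusing established hiPSC lines.

    Provenance (Thomson / Yamanaka / Daley labs, the 2007 first movers) is
    the proxy for line identity, since hiPSC nomenclature is inconsistent.
    ``external_only`` counts the studies that used exclusively lines derived
    in other laboratories.
    """
    return ShareTable(
        counts={
            "total": 201,
            "thomson": 54,
            "yamanaka": 29,
            "daley": 28,
            "external_only": 93,
        },
        denominator="total",
    )
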