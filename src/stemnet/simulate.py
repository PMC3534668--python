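"""Cumulative-advantage (Yule–Simon) simulator for bipartite usage networks.

The model grows a bipartite study–line network.  A single bootstrap project
creates ``n_founders`` founder lines.  Each subsequent study uses exactly
``lines_per_study`` (N) distinct lines: ``k ~ Binomial(N, p)`` of them are
novel lines created by the study, and the remaining ``N - k`` are drawn from
the pre-existing lines with probability proportional to each line's prior
usage count ("rich-get-richer").  Counts are frozen during a study — a
study's own usage does not feed back within that study — and a line enters
the pool with weight 1, its introducing edge.

With S studies the network has exactly ``n_founders + N*S`` edges and
``n_founders + (number of novel draws)`` lines.  For large S the line-degree
tail approaches a power law with exponent ``1 + 1/(1 - p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "EnsembleConfig",
    "SimulatedNetwork",
    "ReplicateSummary",
    "draw_novel_count",
    "select_preexisting",
    "simulate_network",
    "simulate_ensemble",
    "grow_bipartite",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated corpus.

    Defaults follow the reference setting: N = 2 lines per study, novelty
    probability p = 0.15 (chosen from the candidate grid 0.05–0.30 by
    comparison with empirical usage curves), S = 2,927 studies so that
    2 × S matches the empirical citation total, and 5 founder lines.
    """

    n_studies: int = 2927
    lines_per_study: int = 2
    novelty_prob: float = 0.15
    n_founders: int = 5
    seed: int | None = None

    def validate(self) -> None:
        if self.lines_per_study < 1:
            raise ValueError("lines_per_study must be >= 1")
        if not 0.0 <= self.novelty_prob <= 1.0:
            raise ValueError("novelty_prob must be in [0, 1]")
        if self.n_studies < 0:
            raise ValueError("n_studies must be >= 0")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")


@dataclass(frozen=True)
class EnsembleConfig:
    """An ensemble of independent replicates of one configuration."""

    n_replicates: int = 1000
    base: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.base.validate()


@dataclass
class SimulatedNetwork:
    """One realized study–line network.

    ``edge_study``/``edge_line`` give the endpoints of every edge in creation
    order.  Study 0 is the bootstrap founding project (its ``n_founders``
    edges are the first ones), so that citation totals can be reported with
    or without the bootstrap.  Lines are numbered in order of introduction;
    lines ``0 .. n_founders-1`` are the founders.
    """

    config: SimulationConfig
    edge_study: np.ndarray
    edge_line: np.ndarray
    line_usage: np.ndarray  # usage count (degree) per line
    line_first_study: np.ndarray  # study index that introduced each line

    @property
    def n_lines(self) -> int:
        return len(self.line_usage)

    @property
    def n_studies(self) -> int:
        """Number of studies including the bootstrap project."""
        return self.config.n_studies + 1

    @property
    def n_edges(self) -> int:
        return len(self.edge_study)

    @property
    def founder_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_lines, dtype=bool)
        mask[: self.config.n_founders] = True
        return mask

    @property
    def n_novel(self) -> int:
        """Lines created after the bootstrap project."""
        return self.n_lines - self.config.n_founders

    def degrees(self, include_bootstrap: bool = True) -> np.ndarray:
        """Line usage counts; optionally excluding the bootstrap edges."""
        if include_bootstrap:
            return self.line_usage.copy()
        deg = self.line_usage.copy()
        deg[: self.config.n_founders] -= 1
        return deg


@dataclass
class ReplicateSummary:
    """Per-replicate statistics retained from an ensemble run."""

    degrees: np.ndarray
    max_degree: int
    n_lines: int
    largest_component_lines: int
    founder_mean_usage: float
    nonfounder_mean_usage: float


def draw_novel_count(n: int, p: float, rng: np.random.Generator) -> int:
    """Number of novel lines a study introduces: Binomial(n, p)."""
    return int(rng.binomial(n, p))


def select_preexisting(
    usage_counts: Sequence[float] | np.ndarray, m: int, rng: np.random.Generator
) -> list[int]:
    """Select ``m`` distinct lines proportional to prior usage counts.

    Sequential draws without replacement: each draw is proportional to the
    usage counts of the lines not yet picked.  Counts are NOT updated between
    draws (the selecting study's own usage does not count).
    """
    weights = np.asarray(usage_counts, dtype=float).copy()
    if (weights < 0).any():
        raise ValueError("usage counts must be non-negative")
    if int((weights > 0).sum()) < m:
        raise ValueError(f"pool of {int((weights > 0).sum())} lines is smaller than m={m}")
    picked: list[int] = []
    for _ in range(m):
        cdf = np.cumsum(weights)
        u = rng.random() * cdf[-1]
        idx = int(np.searchsorted(cdf, u, side="right"))
        picked.append(idx)
        weights[idx] = 0.0
    return picked


def grow_bipartite(
    study_sizes: Sequence[int],
    novelty_prob: float,
    n_founders: int,
    rng: np.random.Generator,
) -> SimulatedNetwork:
    """Grow a bipartite usage network, one study at a time.

    ``study_sizes[i]`` is the number of distinct lines study ``i+1`` uses
    (study 0 is the bootstrap project holding the founders).  This is the
    shared engine behind :func:`simulate_network` (constant N) and the
    synthetic-corpus generator (random per-study sizes).

    The preferential draw is implemented with an urn holding one entry per
    existing edge; a uniform pick from the urn is proportional to usage, and
    re-picking an already-chosen line is resolved by rejection, which is
    equivalent to the sequential without-replacement rule of
    :func:`select_preexisting`.
    """
    study_sizes = np.asarray(study_sizes, dtype=np.int64)
    if (study_sizes < 1).any():
        raise ValueError("every study must use at least one line")
    n_edges_total = int(n_founders + study_sizes.sum())

    edge_study = np.empty(n_edges_total, dtype=np.int64)
    edge_line = np.empty(n_edges_total, dtype=np.int64)
    urn = np.empty(n_edges_total, dtype=np.int64)  # one entry per edge
    line_first_study: list[int] = [0] * n_founders

    urn[:n_founders] = np.arange(n_founders)
    edge_study[:n_founders] = 0
    edge_line[:n_founders] = np.arange(n_founders)
    n_urn = n_founders
    n_lines = n_founders

    novel_draws = rng.binomial(study_sizes, novelty_prob)

    # uniform buffer refilled in blocks: cheaper than per-draw Generator calls
    buf = rng.random(max(4 * n_edges_total, 64))
    buf_i = 0

    def next_u() -> float:
        nonlocal buf, buf_i
        if buf_i >= len(buf):
            buf = rng.random(len(buf))
            buf_i = 0
        u = buf[buf_i]
        buf_i += 1
        return u

    e = n_founders
    for s in range(len(study_sizes)):
        study = s + 1
        size = int(study_sizes[s])
        k = int(novel_draws[s])
        n_pre = size - k
        if n_pre > n_lines:
            # pool smaller than requested (possible only early, when founders
            # are few): cover the deficit with extra novel lines so the study
            # still uses `size` distinct lines
            k += n_pre - n_lines
            n_pre = n_lines
        lines = list(range(n_lines, n_lines + k))
        for _ in range(k):
            line_first_study.append(study)
        n_lines += k
        if n_pre:
            picked: set[int] = set()
            while len(picked) < n_pre:
                cand = int(urn[int(next_u() * n_urn)])
                if cand not in picked:
                    picked.add(cand)
                    lines.append(cand)
        for ln in lines:
            edge_study[e] = study
            edge_line[e] = ln
            urn[n_urn] = ln
            e += 1
            n_urn += 1

    line_usage = np.bincount(edge_line, minlength=n_lines)
    return SimulatedNetwork(
        config=SimulationConfig(
            n_studies=len(study_sizes),
            lines_per_study=int(study_sizes[0]) if len(study_sizes) else 1,
            novelty_prob=novelty_prob,
            n_founders=n_founders,
        ),
        edge_study=edge_study,
        edge_line=edge_line,
        line_usage=line_usage,
        line_first_study=np.asarray(line_first_study, dtype=np.int64),
    )


def simulate_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedNetwork:
    """Simulate one network at a fixed number of lines per study."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = np.full(config.n_studies, config.lines_per_study, dtype=np.int64)
    net = grow_bipartite(sizes, config.novelty_prob, config.n_founders, rng)
    net.config = config
    return net


def _largest_component_lines(net: SimulatedNetwork) -> int:
    """Number of lines in the largest connected component (by union-find
    over edges; study nodes and line nodes live in one disjoint-set forest)."""
    n_l = net.n_lines
    n_s = net.n_studies
    parent = np.arange(n_l + n_s, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for s, ln in zip(net.edge_study, net.edge_line):
        rs, rl = find(n_l + int(s)), find(int(ln))
        if rs != rl:
            parent[rs] = rl
    roots = np.fromiter((find(int(ln)) for ln in range(n_l)), dtype=np.int64, count=n_l)
    _, counts = np.unique(roots, return_counts=True)
    return int(counts.max()) if len(counts) else 0


def summarize_network(net: SimulatedNetwork) -> ReplicateSummary:
    degrees = net.line_usage
    founders = net.founder_mask
    nonfounder = degrees[~founders]
    return ReplicateSummary(
        degrees=degrees.copy(),
        max_degree=int(degrees.max()),
        n_lines=net.n_lines,
        largest_component_lines=_largest_component_lines(net),
        founder_mean_usage=float(degrees[founders].mean()),
        nonfounder_mean_usage=float(nonfounder.mean()) if len(nonfounder) else float("nan"),
    )


def replicate_seeds(seed: int | None, n: int) -> list[np.random.Generator]:
    """Independent per-replicate generators from one documented seed stream."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_ensemble(config: EnsembleConfig) -> list[ReplicateSummary]:
    """Run independent replicates and retain per-replicate summaries."""
    config.validate()
    out = []
    for rng in replicate_seeds(config.seed, config.n_replicates):
        net = simulate_network(config.base, rng=rng)
        out.append(summarize_network(net))
    return out
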