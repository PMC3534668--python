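# stemnet

Cumulative-advantage modelling of pluripotent stem-cell-line usage
networks.

## The problem

A handful of human embryonic stem-cell (hESC) lines — chiefly H1 and H9,
derived in 1998 — dominate basic and preclinical research, and this has
widely been attributed to the 2001–2009 US federal funding restriction to
21 "eligible" lines.  `stemnet` implements the competing, policy-free
explanation: usage of cell lines behaves like a citation network growing
under **cumulative advantage** (a Yule–Simon / preferential-attachment
process), in which early "founder" lines accumulate a disproportionate
share of use simply because each new study preferentially picks lines
already in wide use.

The package is aimed at bibliometrics / science-of-science analyses of
study–resource usage tables.  It provides:

- a bipartite Yule–Simon simulator: each study uses `N = 2` distinct
  lines, creates `k ~ Binomial(N, p)` novel ones (`p = 0.15`), and picks
  the rest with probability proportional to prior usage;
- discrete power-law fitting of usage tails,
  `p(x) = x^(−α)/ζ(α, xmin)` with fixed `xmin = 3`;
- ensemble-vs-data comparison by the area between cumulative usage curves;
- an outlier detector for lines used far more than their
  first-publication year explains (robust log-linear regression, inverse
  year prediction, cohort z-scores; flags at gap ≥ 4 years and z > 2);
- one-sided hypergeometric enrichment of formerly-NIH-approved line usage
  within study subsets;
- country-profile clustering (1 − Spearman, average linkage);
- a synthetic corpus generator standing in for the undeposited literature
  corpus, plus the published CIRM/hiPSC count tables as exact fixtures.

## Worked example

```python
import numpy as np
from stemnet.simulate import SimulationConfig, EnsembleConfig, simulate_ensemble
from stemnet.powerlaw import fit_discrete_powerlaw

ens = simulate_ensemble(EnsembleConfig(n_replicates=200,
                                       base=SimulationConfig(), seed=20130))
alphas = [fit_discrete_powerlaw(r.degrees, xmin=3).alpha for r in ens]
print(f"edges per replicate: {ens[0].degrees.sum()}")
print(f"median exponent: {np.median(alphas):.3f}")
wins = np.mean([r.founder_mean_usage > r.nonfounder_mean_usage for r in ens])
print(f"founder advantage in {100*wins:.1f}% of replicates")
```

prints

```
edges per replicate: 5859
median exponent: 1.981
founder advantage in 100.0% of replicates
```

— every replicate conserves exactly `F + N·S = 5 + 2×2927 = 5,859` edges;
the simulated exponent distribution (95% band ≈ [1.89, 2.07]) comfortably
covers the published empirical estimate of 1.94; and the five founder
lines out-cite later lines in essentially every replicate (the
"first-mover advantage").

The full analysis is the numbered scripts under `analysis/`
(`01_synthesize_corpus.py` → `08_cluster_countries.py`), each a thin
driver over the library that prints what it found and writes its tables
under `results/`.  The same steps are exposed as a CLI
(`stemnet synth|simulate|fit-powerlaw|compare|outliers|enrich|cluster`).

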