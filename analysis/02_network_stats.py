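"""Build the bipartite co-citation network and report its descriptive stats.

Reads results/usage.tsv (run 01_synthesize_corpus.py first), builds the
study-line graph, and writes the component table and GraphML export.  The
largest connected component should dominate, with small satellite
components around rarely-reused lines.
"""

import argparse
from pathlib import Path

from stemnet import io_model, network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    usage = io_model.read_usage_table(args.out_dir / "usage.tsv")
    g = network.build_network(usage)
    stats = network.usage_stats(g)
    components = network.component_stats(g)

    io_model.write_results(components, args.out_dir / "components.tsv")
    network.write_graphml(g, args.out_dir / "network.graphml")
    stats.line_degrees.rename("usage").rename_axis("line_id").reset_index().to_csv(
        args.out_dir / "line_usage.tsv", sep="\t", index=False
    )

    top = components.iloc[0]
    print(f"{stats.n_studies} studies x {stats.n_lines} lines, {stats.n_edges} edges; "
          f"mean lines/study {stats.mean_lines_per_study:.2f}")
    print(f"max usage: {stats.max_usage} ({stats.line_degrees.index[0]})")
    print(f"{len(components)} components; largest holds {top.n_studies} studies "
          f"and {top.n_lines} lines "
          f"({100 * top.n_nodes / (stats.n_studies + stats.n_lines):.0f}% of nodes)")


if __name__ == "__main__":
    main()
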