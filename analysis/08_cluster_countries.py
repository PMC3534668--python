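"""Cluster national usage profiles (1 - Spearman, average linkage).

Countries with at least 30 publications in the corpus get a line-usage
profile; profiles are compared by Spearman rank correlation and
agglomerated by UPGMA.  Writes the distance matrix and the dendrogram in
Newick format.
"""

import argparse
from pathlib import Path

from stemnet import clustering, io_model


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--min-pubs", type=int, default=30)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    usage = io_model.read_usage_table(args.out_dir / "usage.tsv")
    cfg = clustering.ClusteringConfig(min_publications=args.min_pubs)
    matrix = clustering.country_usage_matrix(usage, cfg)
    distances = clustering.spearman_distance_matrix(matrix)
    tree = clustering.average_linkage_tree(distances)

    distances.to_csv(args.out_dir / "country_distances.tsv", sep="\t")
    (args.out_dir / "country_dendrogram.nwk").write_text(tree.to_newick() + "\n")

    print(f"{len(matrix)} countries with >= {args.min_pubs} publications: "
          f"{', '.join(matrix.index)}")
    first_left, first_right, h, _ = tree.merges[0]
    print(f"closest profiles: {'+'.join(first_left)} and {'+'.join(first_right)} "
          f"(distance {h:.3f})")
    print(f"dendrogram: {args.out_dir / 'country_dendrogram.nwk'}")


if __name__ == "__main__":
    main()
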