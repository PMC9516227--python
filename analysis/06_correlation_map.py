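"""Within-group protein co-regulation map: all pairwise Pearson
correlations among case-group samples, average-linkage clustering on
1 - r, and cluster extraction.

Reads results/proteins.tsv; writes results/corr_case.tsv and
results/corr_clusters.tsv.
"""

import argparse
from pathlib import Path

from sheddex.corrmap import correlation_map, extract_clusters
from sheddex.io import read_group_map, read_protein_table


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    parser.add_argument("--group", default="case")
    parser.add_argument("--k", type=int, default=6)
    args = parser.parse_args()
    out = args.results_dir

    groups = read_group_map(out / "sim" / "groups.tsv")
    groups = {k: v for k, v in groups.items() if v != "reference"}
    proteins = read_protein_table(out / "proteins.tsv", groups)
    cmap = correlation_map(proteins, args.group, n_min=5)
    labels, members = extract_clusters(
        cmap, k=min(args.k, len(cmap.protein_ids))
    )
    cmap.corr.to_csv(out / f"corr_{args.group}.tsv", sep="\t", na_rep="NA")
    labels.to_frame().to_csv(out / "corr_clusters.tsv", sep="\t")

    sizes = labels.value_counts().sort_index()
    print(f"{len(cmap.protein_ids)} proteins in the {args.group}-group "
          f"correlation map; {labels.nunique()} clusters of sizes "
          f"{sizes.tolist()}")
    masked = int(cmap.corr.isna().to_numpy().sum())
    print(f"{masked} pairs masked for < {cmap.n_min} shared observations")


if __name__ == "__main__":
    main()
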