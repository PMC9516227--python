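"""Roll peptides up to proteins, normalize to the pooled reference,
filter for 75% per-group completeness, and run QC (PCA outlier flagging,
sample dendrogram).

Reads results/sim/, writes proteins.tsv, qc.json, samples.nwk under
results/.
"""

import argparse
import json
from pathlib import Path

from sheddex.io import (
    read_group_map,
    read_peptide_table,
    write_protein_table,
)
from sheddex.preprocess import (
    filter_completeness,
    hier_cluster,
    linkage_to_newick,
    normalize_to_reference,
    pca_outliers,
    rollup_protein,
)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    groups = read_group_map(args.sim_dir / "groups.tsv")
    peptides = read_peptide_table(args.sim_dir / "peptides.tsv", groups)
    matrix = rollup_protein(peptides)
    proteins = normalize_to_reference(matrix, groups)
    n_before = len(proteins.values)
    proteins = filter_completeness(proteins, 0.75)
    print(f"{n_before} proteins rolled up; {len(proteins.values)} pass the "
          "75% per-group completeness filter")

    qc = pca_outliers(proteins, k_mad=4.0)
    print(f"PCA on {qc.n_proteins_used} complete-case proteins; "
          f"PC1/PC2 explain "
          f"{100 * qc.explained_variance[0]:.1f}%/"
          f"{100 * qc.explained_variance[1]:.1f}%; "
          f"outliers: {qc.outliers or 'none'}")

    dend = hier_cluster(proteins, axis="samples")
    write_protein_table(proteins, out / "proteins.tsv")
    (out / "samples.nwk").write_text(linkage_to_newick(dend) + "\n")
    (out / "qc.json").write_text(json.dumps(
        {
            "outliers": qc.outliers,
            "explained_variance": [float(v) for v in qc.explained_variance],
            "protein_counts": qc.protein_counts.to_dict(),
        }, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
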