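"""Annotate called substrates with membrane topology and candidate
upstream proteases, and rank sheddases by substrate support.

Because the dataset is simulated, the annotation tables are synthetic
fixtures generated here: planted shed proteins are enriched for
single-pass type I topology (as real shedding substrates are), and a
protease-substrate table links a focal sheddase (ADAM10) to 60% of the
planted substrates with four other proteases at 10% each.

Reads results/sim/ and results/calls.tsv; writes results/annotated.tsv,
results/sheddase_ranking.tsv, results/topology_counts.tsv and the
synthetic topology/db fixtures under results/sim/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sheddex.annotate import (
    annotate_substrates,
    classify_topology,
    map_proteases,
    topology_enrichment,
)
from sheddex.io import (
    read_fasta,
    write_protease_db,
    write_topology_table,
)

PROTEASES = ["ADAM10", "ADAM17", "BACE1", "BACE2", "FURIN"]


def synthetic_annotations(protein_ids, shed_ids, rng):
    """Synthetic topology + protease-substrate fixtures for the simulated
    catalog (stand-ins for UniProt topology and MEROPS/literature data)."""
    classes = ["single-pass type I", "single-pass type II", "GPI-anchored",
               "multi-pass", "secreted", "other"]
    topo = {}
    for pid in protein_ids:
        if pid in shed_ids:
            # shedding substrates are mostly type-I membrane proteins
            topo[pid] = rng.choice(classes, p=[0.6, 0.15, 0.1, 0.02, 0.1,
                                               0.03])
        else:
            topo[pid] = rng.choice(classes, p=[0.08, 0.05, 0.04, 0.08, 0.55,
                                               0.2])
    shed = sorted(shed_ids)
    rows = [("ADAM10", pid, "knockdown-screen")
            for pid in rng.choice(shed, int(0.6 * len(shed)),
                                  replace=False)]
    for other in PROTEASES[1:]:
        rows += [(other, pid, "merops")
                 for pid in rng.choice(shed, int(0.1 * len(shed)),
                                       replace=False)]
    db = pd.DataFrame(rows, columns=["protease_id", "substrate_id",
                                     "evidence"])
    return pd.Series(topo, name="topology"), db


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    out = args.results_dir
    sim = out / "sim"

    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    seqs = read_fasta(sim / "catalog.fasta")
    truth = pd.read_csv(sim / "truth.tsv", sep="\t")
    shed_ids = set(truth.loc[truth["event"] == "shed", "protein_id"])

    rng = np.random.default_rng(args.seed + 50)
    topology, db = synthetic_annotations(list(seqs), shed_ids, rng)
    write_topology_table(topology, sim / "topology.synthetic.tsv")
    write_protease_db(db, sim / "protease_db.synthetic.tsv")

    annotated = annotate_substrates(calls, topology, db)
    annotated.to_csv(out / "annotated.tsv", sep="\t", index=False)
    _, counts = classify_topology(calls, topology)
    counts.rename("n").to_csv(out / "topology_counts.tsv", sep="\t")
    ranking, incidence = map_proteases(calls, db)
    ranking.to_csv(out / "sheddase_ranking.tsv", sep="\t", index=False)
    incidence.to_csv(out / "incidence.tsv", sep="\t")

    print("topology of called substrates:", counts.to_dict())
    enr = topology_enrichment(calls, topology, list(seqs))
    t1 = enr[enr["topology"] == "single-pass type I"]
    if len(t1):
        row = t1.iloc[0]
        print(f"single-pass type I enrichment: {row['n_called']} called "
              f"vs {row['expected']:.1f} expected (Fisher p = "
              f"{row['p']:.2e})")
    print("top sheddases:")
    for row in ranking.head(3).itertuples():
        print(f"  {row.protease_id}: {row.n_substrates} substrates")


if __name__ == "__main__":
    main()
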