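"""Topology classification and protease attribution of called substrates.

Annotation is pure decoration: it attaches a membrane-topology class
(UniProt-style controlled vocabulary) and candidate upstream proteases
(from a MEROPS-style curated relationship table) to each cleavage call,
without touching the calls or their statistics. Sheddases are ranked by
how many called substrates they are known to cleave.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import TOPOLOGY_CLASSES

UNKNOWN = "unknown"


def classify_topology(
    calls: pd.DataFrame, topology: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Label each call with its topology class; unannotated -> 'unknown'.

    Returns (annotated calls, class counts). Unknown class tokens in the
    annotation table are rejected.
    """
    bad = set(topology.unique()) - set(TOPOLOGY_CLASSES)
    if bad:
        raise ValueError(f"unknown topology class(es): {sorted(bad)}")
    annotated = calls.copy()
    annotated["topology"] = (
        annotated["protein_id"].map(topology).fillna(UNKNOWN)
    )
    counts = (
        annotated["topology"].value_counts().sort_values(ascending=False)
    )
    counts = counts.sort_index().sort_values(ascending=False, kind="stable")
    return annotated, counts


def map_proteases(
    calls: pd.DataFrame, db: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match called substrates against a protease-substrate table.

    Returns (ranking, incidence). The incidence matrix has one row per
    called substrate and one boolean column per protease appearing in the
    db; a cell is True iff the (protease, substrate) pair is curated. The
    ranking lists per protease the number and identity of supported
    substrates, sorted by count descending then protease_id.
    """
    substrates = sorted(calls["protein_id"].unique())
    proteases = sorted(db["protease_id"].unique()) if len(db) else []
    incidence = pd.DataFrame(
        False, index=pd.Index(substrates, name="protein_id"),
        columns=proteases, dtype=bool,
    )
    if len(db):
        pairs = db[db["substrate_id"].isin(substrates)]
        for row in pairs.itertuples():
            incidence.loc[row.substrate_id, row.protease_id] = True
    counts = incidence.sum(axis=0)
    ranking = pd.DataFrame(
        {
            "protease_id": counts.index,
            "n_substrates": counts.to_numpy(dtype=int),
            "substrates": [
                ";".join(incidence.index[incidence[c]]) for c in counts.index
            ],
        }
    ).sort_values(
        ["n_substrates", "protease_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ranking, incidence


def annotate_substrates(
    calls: pd.DataFrame, topology: pd.Series, db: pd.DataFrame
) -> pd.DataFrame:
    """Full annotation: topology class plus a semicolon-joined candidate
    protease list per call."""
    annotated, _ = classify_topology(calls, topology)
    _, incidence = map_proteases(calls, db)
    prot_lists = {
        pid: ";".join(incidence.columns[incidence.loc[pid]])
        for pid in incidence.index
    }
    annotated["candidate_proteases"] = (
        annotated["protein_id"].map(prot_lists).fillna("")
    )
    return annotated


def topology_enrichment(
    calls: pd.DataFrame,
    topology: pd.Series,
    background_ids: list[str],
) -> pd.DataFrame:
    """Fisher exact enrichment of each topology class among called
    substrates versus the background of all quantified proteins.

    This makes class over-representation (e.g. of single-pass type I
    membrane proteins among shedding substrates) a computable quantity.
    """
    called = set(calls["protein_id"])
    bg = pd.Series(
        [topology.get(pid, UNKNOWN) for pid in background_ids],
        index=list(background_ids),
    )
    rows = []
    for cls in list(TOPOLOGY_CLASSES) + [UNKNOWN]:
        in_cls = bg == cls
        a = int(sum(1 for pid in called if bg.get(pid) == cls))
        b = len(called) - a
        c = int(in_cls.sum()) - a
        d = len(bg) - len(called) - c
        if a + c == 0:
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"topology": cls, "n_called": a, "n_background": a + c,
             "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["expected"] = (
            out["n_background"] / max(len(bg), 1) * len(called)
        )
    return out
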