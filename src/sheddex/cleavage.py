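"""Terminal-block detection of differential proteolytic cleavage.

The detector asks, protein by protein, whether group differences in
peptide abundance are concentrated in one terminal segment of the protein
rather than spread uniformly — the signature of differential ectodomain
shedding, as opposed to differential secretion, which moves every peptide
together.

For each protein, candidate cleavage boundaries are swept from 5% to 95%
of the protein length in 1% increments (91 boundaries). At each boundary
b the peptides are partitioned by midpoint fraction into an N-terminal
block (midpoint <= b) and the rest. A "factor" — the difference of median
peptide log2 fold changes between block and rest — measures how strongly
the two segments separate, and a two-sample Student t-test on the peptide
log2FC values (p_sep) screens the separation for significance. A protein
is called a putative cleavage substrate when, at some boundary, the
changed segment carries multiple individually significant peptides, the
factor magnitude reaches the fold threshold, the separation is
significant, and the unchanged segment is flat (the guard that rejects
purely secretion-shifted proteins). Because the sweep anchors blocks at
the N terminus, a C-terminal event shows up with the *rest* as the
changed segment; the changed terminus is assigned post hoc by which side
moved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import PeptideQuantTable

N_SIDE = "N_side"
C_SIDE = "C_side"

REDUCED = "reduced_in_case"
INCREASED = "increased_in_case"

CALL_COLUMNS = [
    "protein_id",
    "boundary",
    "side",
    "direction",
    "n_sig_block",
    "factor",
    "p_sep",
    "n_block",
    "n_rest",
]


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test with degenerate handling:
    zero pooled variance gives p=1 for equal means, p=0 otherwise."""
    n1, n2 = len(a), len(b)
    diff = float(np.mean(a) - np.mean(b))
    df = n1 + n2 - 2
    if df <= 0:
        return np.nan, 1.0
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    if sp2 <= 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff)) * np.inf, 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def peptide_stats(
    table: PeptideQuantTable,
    protein_lengths: dict[str, int],
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-peptide group comparison on log2 reference-ratio values.

    Only peptides quantified in over min_frac of samples within each group
    are retained. Columns: protein_id, peptide, start, end, midpoint_frac,
    log2fc (case minus control mean), t, p (pooled Student t, two-sided),
    n_case_obs, n_control_obs.
    """
    missing = set(table.data["protein_id"]) - set(protein_lengths)
    if missing:
        raise KeyError(f"protein length unknown for: {sorted(missing)[:5]}")
    case = table.data[table.samples_in("case")].to_numpy()
    ctrl = table.data[table.samples_in("control")].to_numpy()
    n1_tot, n2_tot = case.shape[1], ctrl.shape[1]
    n1 = np.sum(~np.isnan(case), axis=1)
    n2 = np.sum(~np.isnan(ctrl), axis=1)
    keep = (n1 > min_frac * n1_tot) & (n2 > min_frac * n2_tot) & (n1 >= 2) & (n2 >= 2)

    meta = table.data[["protein_id", "peptide", "start", "end"]].loc[keep]
    case, ctrl, n1, n2 = case[keep], ctrl[keep], n1[keep], n2[keep]

    m1 = np.nanmean(case, axis=1)
    m2 = np.nanmean(ctrl, axis=1)
    v1 = np.nanvar(case, axis=1, ddof=1)
    v2 = np.nanvar(ctrl, axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore"):
        t = np.where(
            sp2 <= 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t
        )
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.nan_to_num(t)), df)
    )
    p = np.where((sp2 <= 0) & (diff == 0), 1.0, p)

    lengths = meta["protein_id"].map(protein_lengths).to_numpy(dtype=float)
    midpoint = (meta["start"].to_numpy() + meta["end"].to_numpy()) / (2.0 * lengths)

    out = meta.reset_index(drop=True).copy()
    out["midpoint_frac"] = midpoint
    out["log2fc"] = diff
    out["t"] = t
    out["p"] = p
    out["n_case_obs"] = n1
    out["n_control_obs"] = n2
    return out


def boundary_grid(
    b_start: float = 0.05, b_end: float = 0.95, b_step: float = 0.01
) -> np.ndarray:
    n = int(round((b_end - b_start) / b_step)) + 1
    return np.round(b_start + b_step * np.arange(n), 10)


def sweep_boundaries(
    stats_df: pd.DataFrame,
    b_start: float = 0.05,
    b_end: float = 0.95,
    b_step: float = 0.01,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    min_count: int = 2,
) -> pd.DataFrame:
    """Evaluate every candidate boundary for one protein.

    stats_df holds the peptide_stats rows of a single protein (>= 4 rows).
    For each boundary the N-anchored block is peptides with
    midpoint_frac <= b. Boundaries where either segment has fewer than
    min_count peptides are emitted flagged invalid with p_sep = 1.

    Returns one row per boundary: boundary, n_block, n_rest, factor
    (median block log2fc minus median rest log2fc), p_sep, per-segment
    medians and median absolute log2fc, and sign-matched significant
    peptide counts (raw p < alpha, |log2fc| >= log2(fc_min), sign equal to
    the segment median's sign).
    """
    if len(stats_df) < 4:
        raise ValueError("boundary sweep requires at least 4 peptides")
    if stats_df["protein_id"].nunique() != 1:
        raise ValueError("sweep_boundaries expects a single protein")
    boundaries = boundary_grid(b_start, b_end, b_step)
    mids = stats_df["midpoint_frac"].to_numpy()
    lfc = stats_df["log2fc"].to_numpy()
    pvals = stats_df["p"].to_numpy()
    lfc_min = np.log2(fc_min)
    sig_raw = (pvals < alpha) & (np.abs(lfc) >= lfc_min)

    order = np.argsort(mids, kind="stable")
    mids_sorted = mids[order]
    lfc_sorted = lfc[order]
    sig_sorted = sig_raw[order]

    # boundaries falling between the same adjacent midpoints induce the
    # same partition; evaluate each distinct split once
    splits = np.searchsorted(mids_sorted, boundaries, side="right")
    cache: dict[int, dict] = {}
    m = len(lfc_sorted)
    for k in np.unique(splits):
        block = lfc_sorted[:k]
        rest = lfc_sorted[k:]
        row = {"n_block": int(k), "n_rest": int(m - k)}
        if k < min_count or m - k < min_count:
            row.update(
                valid=False, factor=np.nan, p_sep=1.0,
                median_block=np.nan, median_rest=np.nan,
                median_abs_block=np.nan, median_abs_rest=np.nan,
                n_sig_block=0, n_sig_rest=0,
            )
        else:
            med_b = float(np.median(block))
            med_r = float(np.median(rest))
            _, p_sep = _pooled_t(block, rest)
            sign_b = np.sign(med_b)
            sign_r = np.sign(med_r)
            row.update(
                valid=True,
                factor=med_b - med_r,
                p_sep=p_sep,
                median_block=med_b,
                median_rest=med_r,
                median_abs_block=float(np.median(np.abs(block))),
                median_abs_rest=float(np.median(np.abs(rest))),
                n_sig_block=int(
                    np.sum(sig_sorted[:k] & (np.sign(block) == sign_b))
                ),
                n_sig_rest=int(
                    np.sum(sig_sorted[k:] & (np.sign(rest) == sign_r))
                ),
            )
        cache[int(k)] = row

    rows = [dict(boundary=float(b), **cache[int(k)]) for b, k in zip(boundaries, splits)]
    out = pd.DataFrame(rows)
    out.insert(0, "protein_id", stats_df["protein_id"].iloc[0])
    return out


def call_substrates(
    sweeps: pd.DataFrame,
    fc_min: float = 1.5,
    alpha: float = 0.05,
    min_sig: int = 2,
) -> pd.DataFrame:
    """Apply the substrate-call criteria to swept boundary profiles.

    `sweeps` is the concatenation of sweep_boundaries outputs (any number
    of proteins). At each valid boundary the *changed* segment is
    whichever of block/rest has the larger median |log2fc|. A boundary
    qualifies when (i) the changed segment has >= min_sig sign-matched
    significant peptides, (ii) |factor| >= log2(fc_min), (iii)
    p_sep < alpha, and (iv) the unchanged segment's median |log2fc| is
    below log2(fc_min) — the guard that rejects uniform secretion shifts.
    The best boundary minimizes p_sep (ties to the smallest boundary); the
    changed terminus and direction are read off the winning segment.
    """
    if min_sig < 2:
        raise ValueError("min_sig must be >= 2")
    if fc_min < 1 or not 0 < alpha < 1:
        raise ValueError("invalid thresholds")
    lfc_min = np.log2(fc_min)
    calls = []
    for pid, prof in sweeps.groupby("protein_id", sort=True):
        valid = prof[prof["valid"]]
        if valid.empty:
            continue
        block_changed = valid["median_abs_block"] >= valid["median_abs_rest"]
        n_sig = np.where(block_changed, valid["n_sig_block"], valid["n_sig_rest"])
        unchanged_med = np.where(
            block_changed, valid["median_abs_rest"], valid["median_abs_block"]
        )
        qualify = (
            (n_sig >= min_sig)
            & (valid["factor"].abs() >= lfc_min)
            & (valid["p_sep"] < alpha)
            & (unchanged_med < lfc_min)
        )
        q = valid[qualify.to_numpy()]
        if q.empty:
            continue
        best = q.sort_values(["p_sep", "boundary"], kind="stable").iloc[0]
        changed_is_block = best["median_abs_block"] >= best["median_abs_rest"]
        side = N_SIDE if changed_is_block else C_SIDE
        changed_median = (
            best["median_block"] if changed_is_block else best["median_rest"]
        )
        direction = REDUCED if changed_median < 0 else INCREASED
        calls.append(
            {
                "protein_id": pid,
                "boundary": float(best["boundary"]),
                "side": side,
                "direction": direction,
                "n_sig_block": int(
                    best["n_sig_block"] if changed_is_block else best["n_sig_rest"]
                ),
                "factor": float(best["factor"]),
                "p_sep": float(best["p_sep"]),
                "n_block": int(best["n_block"]),
                "n_rest": int(best["n_rest"]),
            }
        )
    return pd.DataFrame(calls, columns=CALL_COLUMNS)


def detect_substrates(
    table: PeptideQuantTable,
    protein_lengths: dict[str, int],
    min_frac: float = 0.5,
    b_start: float = 0.05,
    b_end: float = 0.95,
    b_step: float = 0.01,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    min_sig: int = 2,
    min_peptides: int = 4,
    return_profiles: bool = False,
):
    """End-to-end detection on a log2-ratio peptide table.

    Runs peptide_stats, sweeps every protein with at least min_peptides
    retained peptides, and applies the call criteria. Returns the calls
    frame, or (calls, profiles) when return_profiles is set.
    """
    pstats = peptide_stats(table, protein_lengths, min_frac=min_frac)
    profiles = []
    for _, prot_stats in pstats.groupby("protein_id", sort=True):
        if len(prot_stats) < min_peptides:
            continue
        profiles.append(
            sweep_boundaries(
                prot_stats, b_start=b_start, b_end=b_end, b_step=b_step,
                alpha=alpha, fc_min=fc_min,
            )
        )
    if profiles:
        sweeps = pd.concat(profiles, ignore_index=True)
        calls = call_substrates(sweeps, fc_min=fc_min, alpha=alpha, min_sig=min_sig)
    else:
        sweeps = pd.DataFrame()
        calls = pd.DataFrame(columns=CALL_COLUMNS)
    if return_profiles:
        return calls, sweeps
    return calls


def site_report(
    calls: pd.DataFrame,
    known_sites: dict[str, list[int]],
    protein_lengths: dict[str, int],
) -> pd.DataFrame:
    """Compare called boundaries with annotated cleavage residues.

    For each call on a protein with annotated sites, reports the implied
    cleavage residue (boundary x length, rounded) and the residue distance
    to the nearest annotated site. Calls without annotations are omitted.
    No thresholding is applied — this is a reporting layer.
    """
    rows = []
    for _, call in calls.iterrows():
        pid = call["protein_id"]
        sites = known_sites.get(pid)
        if not sites:
            continue
        length = protein_lengths[pid]
        implied = int(round(call["boundary"] * length))
        nearest = min(sites, key=lambda s: abs(implied - s))
        rows.append(
            {
                "protein_id": pid,
                "boundary": call["boundary"],
                "implied_residue": implied,
                "nearest_site": nearest,
                "distance": abs(implied - nearest),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "boundary", "implied_residue", "nearest_site",
                 "distance"],
    )
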