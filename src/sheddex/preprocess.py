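"""Protein-level normalization, filtering, and quality control.

The pipeline mirrors standard isobaric-label practice: peptide abundances
are rolled up to proteins by summation, expressed as log2 ratios over the
pooled reference channel, filtered for per-group completeness, and
inspected by PCA (with robust outlier flagging) and hierarchical
clustering on z-scored values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import META_COLS, PeptideQuantTable, ProteinQuantTable


def rollup_protein(table: PeptideQuantTable) -> pd.DataFrame:
    """Protein x sample abundance matrix: per-sample sum of each protein's
    non-missing peptide abundances; missing iff all peptides missing."""
    cols = table.sample_cols
    return table.data.groupby("protein_id", sort=True)[cols].sum(min_count=1)


def normalize_to_reference(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    reference_column: str = "reference",
) -> ProteinQuantTable:
    """log2(sample / reference) per cell; the reference column is consumed.

    Cells whose reference is missing or nonpositive become missing (with a
    warning in the nonpositive case — that indicates corrupt input).
    """
    if reference_column not in matrix.columns:
        raise KeyError(f"reference column '{reference_column}' absent")
    ref = matrix[reference_column]
    samples = [c for c in matrix.columns if c != reference_column]
    bad_ref = ref.notna() & (ref <= 0)
    if bad_ref.any():
        warnings.warn(
            f"{int(bad_ref.sum())} nonpositive reference value(s); "
            "affected cells set missing",
            stacklevel=2,
        )
    safe_ref = ref.where(ref > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(matrix[samples].div(safe_ref, axis=0))
    values[matrix[samples].isna()] = np.nan
    out_groups = {s: g for s, g in groups.items() if s in samples}
    table = ProteinQuantTable(values=values, groups=out_groups)
    table.validate()
    return table


def normalize_peptides_to_reference(table: PeptideQuantTable) -> PeptideQuantTable:
    """Peptide-level analogue: replace abundances with log2 ratios to the
    pooled reference; the reference column is dropped from the output."""
    ref_col = table.reference_col
    if ref_col is None:
        raise ValueError("peptide table has no reference column")
    samples = [c for c in table.sample_cols if c != ref_col]
    ref = table.data[ref_col].where(table.data[ref_col] > 0)
    data = table.data[[c for c in META_COLS if c in table.data.columns]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        data[samples] = np.log2(table.data[samples].div(ref, axis=0))
    groups = {s: g for s, g in table.groups.items() if s in samples}
    return PeptideQuantTable(data=data, groups=groups)


def filter_completeness(
    table: ProteinQuantTable, min_frac_per_group: float = 0.75
) -> ProteinQuantTable:
    """Retain proteins quantified in at least min_frac_per_group of the
    samples within EVERY group (default 75%)."""
    if not 0.0 < min_frac_per_group <= 1.0:
        raise ValueError("min_frac_per_group must be in (0, 1]")
    keep = pd.Series(True, index=table.values.index)
    for g in ("case", "control"):
        cols = table.samples_in(g)
        frac = table.values[cols].notna().mean(axis=1)
        keep &= frac >= min_frac_per_group
    return ProteinQuantTable(
        values=table.values.loc[keep].copy(), groups=dict(table.groups)
    )


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score over non-missing entries (population sd, ddof=1)."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    return values.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)


@dataclass
class QCReport:
    """Per-sample QC: quantified counts, PCA coordinates, outlier flags."""

    protein_counts: pd.Series
    pca_coords: pd.DataFrame
    explained_variance: np.ndarray
    outliers: list[str]
    n_proteins_used: int
    linkage_samples: np.ndarray | None = None
    sample_order: list[str] = field(default_factory=list)


def _complete_case_z(
    table: ProteinQuantTable, constant_rows: str = "drop"
) -> pd.DataFrame:
    """z-scored complete-case proteins; constant rows are dropped
    (correlation distance is undefined for them) or kept as zeros (they
    carry no variance and cannot move a PCA)."""
    complete = table.values.dropna(axis=0)
    z = zscore_rows(complete)
    if constant_rows == "zero":
        return z.fillna(0.0)
    return z.dropna(axis=0)


def pca_outliers(
    table: ProteinQuantTable, k_mad: float = 4.0, n_components: int = 2
) -> QCReport:
    """PCA of samples on z-scored complete-case proteins, with robust
    outlier flagging.

    A sample is flagged when, on PC1 or PC2, it lies more than
    k_mad * MAD from the component median. Component signs follow the
    convention that the largest-magnitude protein loading is positive.
    """
    samples = list(table.values.columns)
    if len(samples) < 3:
        raise ValueError("PCA requires at least 3 samples")
    z = _complete_case_z(table, constant_rows="zero")
    if len(z) < 3:
        raise ValueError(
            f"only {len(z)} complete-case protein(s); at least 3 required"
        )
    x = z.to_numpy().T  # samples x proteins; rows of z are mean 0
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: per component, largest-|loading| positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    n_components = min(n_components, len(s))
    coords = u[:, :n_components] * s[:n_components]
    total = float(np.sum(s**2))
    explained = (s[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    coords_df = pd.DataFrame(
        coords,
        index=samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    flagged: set[str] = set()
    for i in range(min(2, n_components)):
        pc = coords[:, i]
        med = np.median(pc)
        mad = np.median(np.abs(pc - med))
        dev = np.abs(pc - med)
        thresh = k_mad * mad
        for sample, d in zip(samples, dev):
            if d > thresh:
                flagged.add(sample)
    return QCReport(
        protein_counts=table.values.notna().sum(axis=0),
        pca_coords=coords_df,
        explained_variance=explained,
        outliers=sorted(flagged),
        n_proteins_used=len(z),
    )


def correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed pairwise 1 - Pearson distance between rows of x."""
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    d[d < 0] = 0.0
    return squareform(d, checks=False)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]


def hier_cluster(
    table: ProteinQuantTable, axis: str = "samples"
) -> ClusterResult:
    """Average-linkage agglomerative clustering on z-scored values with
    1 - Pearson correlation distance.

    axis='samples' clusters samples (complete-case proteins as features);
    axis='proteins' clusters proteins. Zero-variance rows are excluded
    with a warning. scipy's linkage on a fixed input is deterministic;
    ties resolve by cluster index.
    """
    z = _complete_case_z(table)
    n_dropped = len(table.values.dropna(axis=0)) - len(z)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} zero-variance protein(s) excluded from clustering",
            stacklevel=2,
        )
    if axis == "samples":
        x = z.to_numpy().T
        labels = list(z.columns)
    elif axis == "proteins":
        x = z.to_numpy()
        labels = list(z.index)
    else:
        raise ValueError("axis must be 'samples' or 'proteins'")
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    link = hierarchy.linkage(correlation_distance(x), method="average")
    order = [labels[i] for i in hierarchy.leaves_list(link)]
    return ClusterResult(linkage=link, labels=labels, leaf_order=order)


def linkage_to_newick(result: ClusterResult) -> str:
    """Serialize a dendrogram as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{result.labels[node.id]}:{parent_height - 0.0:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(length, 0.0):.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"
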