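"""Within-group protein co-regulation maps.

All pairwise Pearson correlations between proteins are computed over the
samples of one group (pairwise-complete, with a minimum-overlap mask),
then clustered by average linkage on 1 - r distance; clusters are
extracted by cutting the dendrogram at a requested count or height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ProteinQuantTable


@dataclass
class CorrelationMap:
    """Protein x protein Pearson matrix within one group.

    `corr` is symmetric with unit diagonal; pairs with fewer than n_min
    complete observations are masked (NaN). `n_obs` holds the per-pair
    complete-observation counts.
    """

    corr: pd.DataFrame
    n_obs: pd.DataFrame
    group: str
    n_min: int

    @property
    def protein_ids(self) -> list[str]:
        return list(self.corr.index)


def correlation_map(
    table: ProteinQuantTable, group: str, n_min: int = 5
) -> CorrelationMap:
    """Pairwise-complete Pearson correlations within `group`.

    Zero-variance proteins are excluded with a warning; pairs sharing
    fewer than n_min observations are masked.
    """
    cols = table.samples_in(group)
    if not cols:
        raise KeyError(f"group '{group}' has no samples")
    if len(cols) < n_min:
        raise ValueError(f"group '{group}' has fewer than n_min={n_min} samples")
    sub = table.values[cols]
    sd = sub.std(axis=1, ddof=1)
    flat = (sd == 0) | sd.isna()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance protein(s) excluded from the "
            "correlation map",
            stacklevel=2,
        )
        sub = sub.loc[~flat]
    corr = sub.T.corr(min_periods=n_min)
    obs = sub.notna().astype(int)
    n_obs = pd.DataFrame(
        obs.to_numpy() @ obs.to_numpy().T, index=sub.index, columns=sub.index
    )
    corr = corr.where(n_obs >= n_min)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return CorrelationMap(corr=corr, n_obs=n_obs, group=group, n_min=n_min)


def _distance_condensed(cmap: CorrelationMap) -> np.ndarray:
    d = 1.0 - cmap.corr.to_numpy(copy=True)
    # masked pairs carry no evidence either way; treat as uncorrelated
    d[np.isnan(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    return squareform(d, checks=False)


def extract_clusters(
    cmap: CorrelationMap,
    k: int | None = None,
    height: float | None = None,
) -> tuple[pd.Series, dict[int, list[str]]]:
    """Cut the average-linkage dendrogram of the correlation map.

    Exactly one of k (cluster count) or height (cophenetic distance on the
    1 - r scale) must be given. Returns (labels per protein, members per
    cluster). Cluster ids are renumbered 1..n in order of first appearance
    along the protein index, so labeling is deterministic.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    ids = cmap.protein_ids
    if k is not None and k > len(ids):
        raise ValueError(f"k={k} exceeds protein count {len(ids)}")
    link = hierarchy.linkage(_distance_condensed(cmap), method="average")
    if k is not None:
        raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(link, t=height, criterion="distance")
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    series = pd.Series(labels, index=pd.Index(ids, name="protein_id"),
                       name="cluster")
    members = {
        c: [pid for pid, lab in series.items() if lab == c]
        for c in sorted(set(labels))
    }
    return series, members
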