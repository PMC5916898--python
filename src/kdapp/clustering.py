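"""Cross-bait binding-profile matrices, hierarchical clustering and group tests.

Proteins are described by their log10 Kd_app (nM) across baits.  Proteins
without an accepted fit for some bait are imputed at the assay ceiling (the
top titration concentration) — "no measurable binding up to the top of the
titration" — and flagged.  Profiles are grouped by deterministic hierarchical
agglomerative clustering and summarized as a cluster x bait mean-log10-Kd
table, the data behind the published heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class KdMatrix:
    """Proteins x baits matrix of log10 Kd_app with a missing-value mask."""

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    imputed_value: float

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def baits(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterModel:
    """A flat cut of the agglomerative tree: protein -> cluster id (1..k)."""

    k: int
    linkage: str
    metric: str
    assignments: dict[str, int]
    cluster_sizes: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        sizes: dict[int, int] = {}
        for cid in self.assignments.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        self.cluster_sizes = sizes


@dataclass
class ClusterSummary:
    """Cluster x bait mean log10 Kd table with per-cluster sizes."""

    means: pd.DataFrame
    sizes: pd.Series
    imputed_cells: pd.DataFrame


def _kd_of(entry) -> float:
    return float(entry.kd_app) if hasattr(entry, "kd_app") else float(entry)


def build_kd_matrix(
    accepted_fits_by_bait: Mapping[str, Mapping[str, object]],
    ceiling: float = 3000.0,
    drop_incomplete: bool = False,
) -> KdMatrix:
    """Assemble the log10 Kd matrix from per-bait accepted fits.

    ``accepted_fits_by_bait`` maps bait -> {protein: Kd_app in nM or HillFit}.
    Proteins missing for a bait get ``log10(ceiling)`` with the mask set, or
    are dropped entirely when ``drop_incomplete`` is true.
    """
    baits = list(accepted_fits_by_bait)
    if not baits:
        raise ValueError("need at least one bait")
    proteins = sorted({p for fits in accepted_fits_by_bait.values() for p in fits})
    imputed = float(np.log10(ceiling))
    values = pd.DataFrame(imputed, index=proteins, columns=baits, dtype=float)
    mask = pd.DataFrame(True, index=proteins, columns=baits, dtype=bool)
    for bait, fits in accepted_fits_by_bait.items():
        for protein, entry in fits.items():
            kd = _kd_of(entry)
            if kd <= 0 or not np.isfinite(kd):
                raise ValueError(f"non-positive Kd for {protein}/{bait}: {kd}")
            values.loc[protein, bait] = np.log10(kd)
            mask.loc[protein, bait] = False
    if drop_incomplete:
        keep = ~mask.any(axis=1)
        values, mask = values.loc[keep], mask.loc[keep]
    return KdMatrix(values=values, missing_mask=mask, imputed_value=imputed)


def cluster_profiles(
    m: KdMatrix, k: int, linkage: str = "average", metric: str = "euclidean"
) -> ClusterModel:
    """Hierarchical agglomerative clustering of binding profiles, cut at k.

    Deterministic given the matrix; cluster ids are relabeled 1..k in order of
    first appearance down the protein list so reruns are stable.
    """
    n = len(m.proteins)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    X = m.values.to_numpy(dtype=float)
    if n == 1:
        raw = np.array([1])
    else:
        Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for protein, cid in zip(m.proteins, raw):
        if cid not in relabel:
            relabel[cid] = len(relabel) + 1
        assignments[protein] = relabel[cid]
    return ClusterModel(k=k, linkage=linkage, metric=metric, assignments=assignments)


def cluster_summary(m: KdMatrix, cm: ClusterModel) -> ClusterSummary:
    """Mean log10 Kd per cluster-bait cell, over non-missing values only.

    A cluster-bait cell with no measured value falls back to the imputed
    ceiling and is flagged in ``imputed_cells``.
    """
    missing = set(m.proteins) - set(cm.assignments)
    if missing:
        raise ValueError(f"assignments missing for {sorted(missing)[:3]}...")
    ids = sorted(set(cm.assignments.values()))
    means = pd.DataFrame(index=ids, columns=m.baits, dtype=float)
    flags = pd.DataFrame(False, index=ids, columns=m.baits, dtype=bool)
    sizes = pd.Series(0, index=ids, dtype=int)
    groups: dict[int, list[str]] = {i: [] for i in ids}
    for protein, cid in cm.assignments.items():
        groups[cid].append(protein)
    for cid, members in groups.items():
        sizes[cid] = len(members)
        vals = m.values.loc[members]
        obs = ~m.missing_mask.loc[members]
        for bait in m.baits:
            col = vals[bait][obs[bait]]
            if len(col):
                means.loc[cid, bait] = col.mean()
            else:
                means.loc[cid, bait] = m.imputed_value
                flags.loc[cid, bait] = True
    return ClusterSummary(means=means, sizes=sizes, imputed_cells=flags)


def compare_groups(kds_a: Sequence[float], kds_b: Sequence[float]) -> dict[str, float]:
    """Welch two-sided t test between two groups of Kd_app values.

    Used to compare subunits of a complex or paralog groups; each group needs
    at least two measurements.
    """
    a = np.asarray(kds_a, dtype=float)
    b = np.asarray(kds_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two Kd values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t) and np.allclose(a.mean(), b.mean()):
        # zero-variance identical groups: no difference by construction
        t, p = 0.0, 1.0
    return {"t": float(t), "p": float(p)}
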