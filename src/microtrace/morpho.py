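"""Arbor morphometry, cell clustering, and device-distance progression.

Feature definitions are the standard neuromorphology ones (cable length,
branch/tip counts, path tortuosity, hull volume). Grouping of microglia
morphological states uses z-scored k-means as a documented simple stand-in
with the same interface as more elaborate co-clustering methods, and the
progression summary orders clusters by mean distance to the implanted
device, reporting per-feature Spearman rank trends along that ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import KMeans

from .imgio import ArborTrace, Volume

__all__ = [
    "ArborFeatures",
    "ProgressionSummary",
    "arbor_features",
    "features_table",
    "cluster_cells",
    "device_distance",
    "progression",
]


@dataclass
class ArborFeatures:
    cell_id: int
    cable_length_um: float
    n_branch_points: int
    n_tips: int
    max_path_length_um: float
    mean_tortuosity: float
    hull_volume_um3: float
    n_nodes: int
    degenerate: bool = False      # single-node tree

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("cell_id", "cable_length_um", "n_branch_points", "n_tips",
                 "max_path_length_um", "mean_tortuosity", "hull_volume_um3", "n_nodes")}


def arbor_features(trace: ArborTrace) -> ArborFeatures:
    """Morphometry of one rooted tree.

    Cable length sums inter-node Euclidean steps; a branch point has >= 2
    children; a tip is a leaf; tortuosity of a root-to-tip path is path
    length over straight-line distance.
    """
    n = trace.n_nodes
    if n <= 1:
        return ArborFeatures(trace.cell_id, 0.0, 0, 0, 0.0, 1.0, 0.0, n, degenerate=True)
    pos = trace.positions_um
    par = trace.parents
    steps = np.zeros(n)
    for i in range(n):
        if par[i] >= 0:
            steps[i] = np.linalg.norm(pos[i] - pos[par[i]])
    cable = float(steps.sum())
    children = trace.children()
    n_children = np.array([len(c) for c in children])
    root = int(np.flatnonzero(par < 0)[0])
    branch_pts = int(np.sum(n_children[np.arange(n) != root] >= 2)
                     + (n_children[root] >= 2))
    tips = np.flatnonzero((n_children == 0) & (np.arange(n) != root))
    # path length from root to every node
    path_len = np.zeros(n)
    order = _topo_order(par, root)
    for i in order:
        if par[i] >= 0:
            path_len[i] = path_len[par[i]] + steps[i]
    torts = []
    for t in tips:
        straight = np.linalg.norm(pos[t] - pos[root])
        torts.append(path_len[t] / straight if straight > 1e-9 else 1.0)
    hull = 0.0
    if n >= 5:
        try:
            hull = float(ConvexHull(pos).volume)
        except QhullError:
            hull = 0.0
    return ArborFeatures(
        cell_id=trace.cell_id,
        cable_length_um=cable,
        n_branch_points=branch_pts,
        n_tips=int(len(tips)),
        max_path_length_um=float(path_len[tips].max()) if len(tips) else float(path_len.max()),
        mean_tortuosity=float(np.mean(torts)) if torts else 1.0,
        hull_volume_um3=hull,
        n_nodes=n,
    )


def _topo_order(parents, root):
    n = len(parents)
    children = [[] for _ in range(n)]
    for i, p in enumerate(parents):
        if p >= 0:
            children[p].append(i)
    order, stack = [], [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(children[i])
    return order


def features_table(traces: list[ArborTrace]) -> pd.DataFrame:
    return pd.DataFrame([arbor_features(t).as_dict() for t in traces])


def cluster_cells(features: pd.DataFrame, k: int, seed: int = 0) -> np.ndarray:
    """z-score + k-means with seeded restarts (stand-in clustering)."""
    if k < 2:
        raise ValueError(f"need k >= 2, got {k}")
    cols = [c for c in features.columns if c != "cell_id"]
    X = features[cols].to_numpy(dtype=float)
    if len(X) <= k:
        raise ValueError(f"need more cells ({len(X)}) than clusters ({k})")
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping constant feature columns: "
                      f"{[c for c, f in zip(cols, const) if f]}")
        X = X[:, ~const]
        sd = sd[~const]
    if X.shape[1] == 0:
        return np.zeros(len(features), int)
    Xs = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(Xs)


def device_distance(centroids_vox: np.ndarray, device_mask: Volume | np.ndarray,
                    spacing=None) -> np.ndarray:
    """Distance (µm) from each cell centroid to the device surface.

    Euclidean distance transform of the mask complement, scaled by voxel
    spacing, sampled at the centroid voxels. Zero on/inside the device.
    """
    if isinstance(device_mask, Volume):
        mask = device_mask.data.astype(bool)
        spacing = device_mask.spacing
    else:
        mask = np.asarray(device_mask, bool)
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
    if not mask.any():
        raise ValueError("device mask is empty")
    dt = ndimage.distance_transform_edt(~mask, sampling=spacing)
    pos = np.asarray(centroids_vox, float).reshape(-1, 3)
    idx = tuple(np.clip(np.round(pos).astype(int), 0, np.array(mask.shape) - 1).T)
    return dt[idx]


@dataclass
class ProgressionSummary:
    cluster_order: np.ndarray          # cluster ids sorted by mean device distance
    cluster_mean_distance: np.ndarray  # µm, aligned with cluster_order
    cluster_mean_features: pd.DataFrame
    feature_trend: pd.DataFrame        # per-feature Spearman rho & p vs device distance
    unstable: bool = False


def progression(features: pd.DataFrame, assignments: np.ndarray,
                device_distances_um: np.ndarray) -> ProgressionSummary:
    """Order morphological clusters along distance to the device.

    Clusters are ranked by mean device distance; each feature's monotone
    trend along the spatial axis is summarized by its Spearman rank
    correlation against per-cell device distance.
    """
    assignments = np.asarray(assignments, int)
    d = np.asarray(device_distances_um, float)
    cl = np.unique(assignments)
    if len(cl) < 2:
        raise ValueError("need >= 2 clusters for a progression")
    means = np.array([d[assignments == c].mean() for c in cl])
    order = cl[np.argsort(means)]
    unstable = bool(np.ptp(d) < 1e-9)
    cols = [c for c in features.columns if c != "cell_id"]
    mean_feats = pd.DataFrame(
        [features.loc[assignments == c, cols].mean() for c in order], index=order)
    rows = []
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        if np.ptp(x) < 1e-12 or unstable:
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(x, d)
        rows.append(dict(feature=c, spearman_rho=float(rho), p_value=float(p)))
    return ProgressionSummary(
        cluster_order=order,
        cluster_mean_distance=np.sort(means),
        cluster_mean_features=mean_feats,
        feature_trend=pd.DataFrame(rows),
        unstable=unstable,
    )
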