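"""Microglia arbor reconstruction.

Seed detection is learned: small 3-D patches around candidate voxels are
sparse-coded in an overcomplete dictionary trained jointly with a linear
two-class classifier (seed / background),

    min_{D, L, Gamma}  ||Y - D Gamma||^2 + beta ||H - L Gamma||^2
                       s.t. for all i, ||gamma_i||_0 <= T,

optimized by alternating orthogonal matching pursuit against the stacked
dictionary [D; sqrt(beta) L] and K-SVD-style rank-1 atom updates. A candidate
with code gamma is a seed iff l1 > l2 where L gamma = [l1, l2]^T.

Arbors are then grown per microglia root by an adaptation of Prim's
algorithm in a geodesic image metric: the unconnected seed closest (by exact
Dijkstra shortest path, edge weight = step length in micrometres times the
mean endpoint brightness penalty w(I) = 1 / (1 + (I/I_ref)^2)) to the tree's
connected seed/root nodes is attached, and the connecting geodesic path
becomes the new branch. K roots always yield K trees. A dice-and-trace mode
crops a box around every microglia centroid (neighbouring centroids join as
competing roots) so memory stays bounded by the dice, not the montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .imgio import ArborTrace, Volume

__all__ = [
    "PatchDictionary",
    "SeedSet",
    "extract_patches",
    "omp_code",
    "learn_dictionary",
    "classify_seeds",
    "candidate_positions",
    "GeodesicGraph",
    "geodesic_distance",
    "grow_mst",
    "dice_and_trace",
]


# ---------------------------------------------------------------------------
# patches & sparse coding
# ---------------------------------------------------------------------------

# atoms more coherent than this are collapsed during dictionary cleaning
COHERENCE_CLEAN = 0.95

def extract_patches(v: Volume | np.ndarray, positions, patch_shape=(3, 7, 7),
                    return_degenerate: bool = False):
    """Column matrix of standardized patches around voxel positions.

    Each column is the (z, y, x)-ordered vectorization of the patch centered
    at a position (mirror padding near borders), made zero-mean and
    unit-norm. Constant patches have no direction and come back as all-zero
    columns, flagged degenerate.
    """
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    patch_shape = tuple(int(s) for s in patch_shape)
    if any(p > s for p, s in zip(patch_shape, data.shape)):
        raise ValueError(f"patch {patch_shape} larger than volume {data.shape}")
    half = [p // 2 for p in patch_shape]
    padded = np.pad(data.astype(np.float64), [(h, h) for h in half], mode="reflect")
    positions = np.asarray(positions, int).reshape(-1, 3)
    n = int(np.prod(patch_shape))
    Y = np.empty((n, len(positions)))
    for k, (z, y, x) in enumerate(positions):
        Y[:, k] = padded[z:z + patch_shape[0], y:y + patch_shape[1],
                         x:x + patch_shape[2]].ravel()
    Y -= Y.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Y, axis=0)
    degenerate = norms < 1e-12
    Y[:, ~degenerate] /= norms[~degenerate]
    Y[:, degenerate] = 0.0
    if return_degenerate:
        return Y, degenerate
    return Y


def omp_code(Y: np.ndarray, D: np.ndarray, T: int, tol: float = 1e-12) -> np.ndarray:
    """Greedy orthogonal matching pursuit, at most T atoms per signal.

    Atoms of D must be unit-norm. Selection: atom with maximal absolute
    correlation to the residual; after each selection the coefficients are
    re-solved by least squares on the current support.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] == D.shape[0] and Y.ndim == 2:
        pass
    n, N = Y.shape
    n_atoms = D.shape[1]
    if T > n_atoms:
        raise ValueError(f"sparsity T={T} exceeds number of atoms {n_atoms}")
    G = np.zeros((n_atoms, N))
    if T == 0:
        return G
    for i in range(N):
        y = Y[:, i]
        r = y.copy()
        support: list[int] = []
        for _ in range(T):
            if r @ r <= tol:
                break
            corr = np.abs(D.T @ r)
            corr[support] = -1.0
            a = int(np.argmax(corr))
            support.append(a)
            coef, *_ = np.linalg.lstsq(D[:, support], y, rcond=None)
            r = y - D[:, support] @ coef
        if support:
            G[support, i] = coef
    return G


@dataclass
class PatchDictionary:
    """Learned dictionary D, classifier L, and training codes Gamma."""

    D: np.ndarray                    # (n, n_atoms), unit-norm columns
    L: np.ndarray                    # (2, n_atoms)
    Gamma: np.ndarray                # (n_atoms, N) training codes
    patch_shape: tuple
    T: int
    beta: float
    objective_history: np.ndarray = field(default_factory=lambda: np.zeros(0))


def learn_dictionary(Y: np.ndarray, H: np.ndarray, n_atoms: int, T: int = 5,
                     beta: float = 1.0, iterations: int = 10, seed: int = 0,
                     patch_shape=(3, 7, 7)) -> PatchDictionary:
    """Joint dictionary + classifier learning (label-consistent K-SVD style).

    Alternates (i) OMP coding of the stacked signals [Y; sqrt(beta) H] in the
    stacked dictionary, accepting a signal's new code only if it lowers that
    signal's residual, and (ii) rank-1 (SVD) updates of every atom over the
    signals using it. The objective
    ``||Y - D Gamma||^2 + beta ||H - L Gamma||^2`` is therefore
    non-increasing across iterations; its value after each iteration is kept
    in ``objective_history``.
    """
    Y = np.asarray(Y, float)
    H = np.asarray(H, float)
    n, N = Y.shape
    if H.shape != (2, N):
        raise ValueError(f"H must be (2, N), got {H.shape}")
    if N < n_atoms:
        raise ValueError(f"need N >= n_atoms, got N={N}, n_atoms={n_atoms}")
    class_of = np.argmax(H, axis=0)
    if len(np.unique(class_of)) < 2:
        raise ValueError("both classes must be present in H")
    rng = np.random.default_rng(seed)

    sb = np.sqrt(beta)
    Yext = np.vstack([Y, sb * H])
    # class-stratified initialization from training patches, picking within
    # each class the signals least coherent with the atoms chosen so far
    idx0 = np.flatnonzero(class_of == 0)
    idx1 = np.flatnonzero(class_of == 1)
    k0 = max(1, int(round(n_atoms * len(idx0) / N)))
    k0 = min(k0, n_atoms - 1)
    Yn = Yext / np.maximum(np.linalg.norm(Yext, axis=0, keepdims=True), 1e-12)
    pick = []
    for pool, want in ((idx0, k0), (idx1, n_atoms - k0)):
        cand = list(rng.permutation(pool))
        chosen = [cand.pop(0)]
        while len(chosen) < want and cand:
            coh = np.abs(Yn[:, cand].T @ Yn[:, chosen]).max(axis=1)
            j = int(np.argmin(coh))
            chosen.append(cand.pop(j))
        while len(chosen) < want:
            chosen.append(int(rng.choice(pool)))
        pick.extend(chosen)
    Dext = Yext[:, pick].copy()
    nz = np.linalg.norm(Dext, axis=0)
    nz[nz < 1e-12] = 1.0
    Dext /= nz

    G = np.zeros((n_atoms, N))
    resid2 = np.sum((Yext - Dext @ G) ** 2, axis=0)
    history = []
    for _ in range(iterations):
        # (i) sparse coding with per-signal acceptance guard
        G_new = omp_code(Yext, Dext, T)
        R = Yext - Dext @ G_new
        r2_new = np.sum(R ** 2, axis=0)
        better = r2_new <= resid2
        G[:, better] = G_new[:, better]
        resid2 = np.minimum(resid2, r2_new)
        # signals the greedy pass could not improve: subspace-pursuit style
        # support refinement (swap in the atoms most correlated with the
        # residual, re-solve, keep the T largest), accepted only if better
        for i in np.flatnonzero(~better):
            supp = list(np.flatnonzero(G[:, i] != 0))
            y = Yext[:, i]
            for _ in range(3):
                r = y - Dext[:, supp] @ np.linalg.lstsq(Dext[:, supp], y, rcond=None)[0] \
                    if supp else y
                corr = np.abs(Dext.T @ r)
                cand = list(dict.fromkeys(supp + list(np.argsort(-corr)[:T])))
                coef, *_ = np.linalg.lstsq(Dext[:, cand], y, rcond=None)
                keep = np.argsort(-np.abs(coef))[:T]
                new_supp = sorted(int(cand[k]) for k in keep)
                if new_supp == supp:
                    break
                supp = new_supp
            if supp:
                coef, *_ = np.linalg.lstsq(Dext[:, supp], y, rcond=None)
                r2 = float(np.sum((y - Dext[:, supp] @ coef) ** 2))
                if r2 < resid2[i]:
                    G[:, i] = 0.0
                    G[supp, i] = coef
                    resid2[i] = r2
        # (ii) atom-wise K-SVD update
        E_base = Yext - Dext @ G
        for a in range(n_atoms):
            users = np.flatnonzero(G[a] != 0)
            if users.size == 0:
                continue
            E = E_base[:, users] + np.outer(Dext[:, a], G[a, users])
            try:
                U, S, Vt = np.linalg.svd(E, full_matrices=False)
            except np.linalg.LinAlgError:
                continue
            d_new = U[:, 0]
            g_new = S[0] * Vt[0]
            # rank-1 step with fixed support can only reduce the residual
            Dext[:, a] = d_new
            G[a, users] = g_new
            E_base[:, users] = E - np.outer(d_new, g_new)
        resid2 = np.sum((Yext - Dext @ G) ** 2, axis=0)
        # dictionary cleaning: collapse near-duplicate atoms when the exact
        # least-squares transfer of their codes does not raise the objective,
        # freeing the duplicate to be re-seeded from a badly coded signal
        gram = np.abs(Dext.T @ Dext - np.eye(n_atoms))
        for a in range(n_atoms):
            b = int(np.argmax(gram[a]))
            if gram[a, b] < COHERENCE_CLEAN:
                continue
            users = np.flatnonzero(G[a] != 0)
            if users.size == 0:
                continue
            new_codes, new_r2 = [], []
            for i in users:
                supp = [s for s in np.flatnonzero(G[:, i]) if s != a]
                if b not in supp:
                    supp.append(b)
                coef, *_ = np.linalg.lstsq(Dext[:, supp], Yext[:, i], rcond=None)
                new_codes.append((supp, coef))
                new_r2.append(float(np.sum((Yext[:, i] - Dext[:, supp] @ coef) ** 2)))
            if sum(new_r2) <= resid2[users].sum() + 1e-12:
                for i, (supp, coef), r2 in zip(users, new_codes, new_r2):
                    G[:, i] = 0.0
                    G[supp, i] = coef
                    resid2[i] = r2
                gram[a, :] = gram[:, a] = 0.0
        # guarded re-seed of rarely used atoms: propose replacing the atom
        # with the worst-represented signal and recoding the affected
        # signals; commit only when the objective drops
        usage = (G != 0).sum(axis=1)
        low = np.argsort(usage)
        for a in low[:3]:
            if usage[a] == 0 or usage[a] > max(4, N // n_atoms):
                continue
            worst_order = np.argsort(-resid2)
            affected = np.unique(np.concatenate(
                [np.flatnonzero(G[a] != 0), worst_order[: max(16, int(usage[a]))]]))
            committed = False
            for w0 in worst_order[:3]:
                nrm = float(np.linalg.norm(Yext[:, w0]))
                if committed or nrm < 1e-12 or resid2[w0] < 1e-12:
                    continue
                D_try = Dext.copy()
                D_try[:, a] = Yext[:, w0] / nrm
                G_try = omp_code(Yext[:, affected], D_try, T)
                r2_try = np.sum((Yext[:, affected] - D_try @ G_try) ** 2, axis=0)
                if r2_try.sum() <= resid2[affected].sum() + 1e-12:
                    Dext = D_try
                    G[:, affected] = G_try
                    resid2[affected] = r2_try
                    committed = True
        # revive unused atoms with the worst-represented signal; the atom's
        # code stays zero so the objective is untouched
        used = np.abs(G).sum(axis=1)
        worst = np.argsort(-resid2)
        w_i = 0
        for a in np.flatnonzero(used < 1e-12):
            while w_i < N and resid2[worst[w_i]] < 1e-12:
                w_i += 1
            if w_i >= N:
                break
            sig = Yext[:, worst[w_i]]
            nrm = np.linalg.norm(sig)
            if nrm > 1e-12:
                Dext[:, a] = sig / nrm
            w_i += 1
        history.append(float(resid2.sum()))

    D = Dext[:n]
    L = Dext[n:] / sb if sb > 0 else np.zeros((2, n_atoms))
    nu = np.linalg.norm(D, axis=0)
    nu[nu < 1e-12] = 1.0
    D = D / nu
    L = L / nu
    Gamma = omp_code(Y, D, T)
    return PatchDictionary(D=D, L=L, Gamma=Gamma, patch_shape=tuple(patch_shape),
                           T=T, beta=beta, objective_history=np.array(history))


@dataclass
class SeedSet:
    positions: np.ndarray            # (M, 3) candidate voxels
    l1: np.ndarray
    l2: np.ndarray

    @property
    def is_seed(self) -> np.ndarray:
        return self.l1 > self.l2     # ties -> not a seed

    @property
    def seed_positions(self) -> np.ndarray:
        return self.positions[self.is_seed]


def classify_seeds(v: Volume, pdict: PatchDictionary, candidates) -> SeedSet:
    """Sparse-code candidate patches in D and classify: seed iff l1 > l2."""
    candidates = np.asarray(candidates, int).reshape(-1, 3)
    if len(candidates) == 0:
        return SeedSet(candidates.reshape(0, 3), np.zeros(0), np.zeros(0))
    Y = extract_patches(v, candidates, pdict.patch_shape)
    G = omp_code(Y, pdict.D, pdict.T)
    scores = pdict.L @ G
    return SeedSet(candidates, scores[0], scores[1])


def candidate_positions(v: Volume, percentile: float = 80.0,
                        min_spacing: int = 2) -> np.ndarray:
    """Candidate voxels for seed classification: local maxima of the
    (enhanced) microglia channel above a percentile intensity floor."""
    data = v.data.astype(np.float64)
    nz = data[data > 0]
    if nz.size == 0:
        return np.zeros((0, 3), int)
    floor = np.percentile(nz, percentile)
    size = 2 * min_spacing + 1
    mx = ndimage.maximum_filter(data, size=size, mode="nearest")
    pk = (data >= mx) & (data > floor)
    return np.stack(np.nonzero(pk), axis=1)


# ---------------------------------------------------------------------------
# geodesic metric
# ---------------------------------------------------------------------------

_STEPS_26 = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
             if (dz, dy, dx) > (0, 0, 0)]


class GeodesicGraph:
    """26-connected voxel graph with brightness-penalized step costs.

    Edge weight = physical step length (µm) x mean of the endpoint penalties
    ``w(I) = 1 / (1 + (I/I_ref)^2)`` with ``I_ref`` the foreground median, so
    travel is cheap along bright (structure) voxels.
    """

    def __init__(self, v: Volume, i_ref: float | None = None):
        self.shape = v.shape
        self.spacing = np.array(v.spacing)
        data = v.data.astype(np.float64)
        if i_ref is None:
            nz = data[data > 0]
            i_ref = float(np.median(nz)) if nz.size else 1.0
        self.i_ref = max(i_ref, 1e-9)
        self.penalty = 1.0 / (1.0 + (data / self.i_ref) ** 2)
        Z, Y, X = self.shape
        idx = np.arange(data.size).reshape(self.shape)
        rows, cols, vals = [], [], []
        for dz, dy, dx in _STEPS_26:
            sl_a = tuple(slice(0, s - d) if d > 0 else slice(-d, s)
                         for s, d in zip(self.shape, (dz, dy, dx)))
            sl_b = tuple(slice(d, s) if d > 0 else slice(0, s + d)
                         for s, d in zip(self.shape, (dz, dy, dx)))
            a = idx[sl_a].ravel()
            b = idx[sl_b].ravel()
            step = float(np.linalg.norm(self.spacing * (dz, dy, dx)))
            w = step * 0.5 * (self.penalty[sl_a].ravel() + self.penalty[sl_b].ravel())
            rows.append(a)
            cols.append(b)
            vals.append(w)
        self.graph = csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(data.size, data.size),
        )

    def lin(self, pos) -> int:
        return int(np.ravel_multi_index(tuple(np.asarray(pos, int)), self.shape))

    def unlin(self, lin: int):
        return np.unravel_index(int(lin), self.shape)

    def distances(self, sources: list[int]):
        out = dijkstra(self.graph, directed=False, indices=sources,
                       return_predecessors=True, min_only=True)
        dist, pred = out[0], out[1]
        return dist, pred

    def path_from(self, pred: np.ndarray, target: int) -> list[int]:
        path = [int(target)]
        while pred[path[-1]] >= 0:
            path.append(int(pred[path[-1]]))
        return path[::-1]


def geodesic_distance(v: Volume, a, b, graph: GeodesicGraph | None = None,
                      max_cost: float = np.inf):
    """Exact Dijkstra geodesic between voxel ``a`` and voxel(s) ``b``.

    ``b`` may be a single voxel or a list of voxels (a tree front). Returns
    ``(cost, path)`` with the path as a voxel chain from b-side to a;
    unreachable (or above ``max_cost``) gives ``(inf, [])``.
    """
    g = graph or GeodesicGraph(v)
    b = np.asarray(b, int)
    sources = [g.lin(p) for p in b.reshape(-1, 3)]
    target = g.lin(a)
    if target in sources:
        return 0.0, [tuple(int(c) for c in np.asarray(a, int))]
    dist, pred = g.distances(sources)
    c = float(dist[target])
    if not np.isfinite(c) or c > max_cost:
        return np.inf, []
    chain = g.path_from(pred, target)
    return c, [tuple(int(q) for q in g.unlin(p)) for p in chain]


# ---------------------------------------------------------------------------
# Prim-adapted MST growth
# ---------------------------------------------------------------------------

@dataclass
class _GrownTree:
    root_vox: np.ndarray
    nodes_vox: list                  # [(z, y, x), ...]
    parents: list
    node_of_lin: dict                # voxel lin -> node index
    attach_sources: list             # lin indices of root + attached seeds
    seed_nodes: dict = field(default_factory=dict)   # seed lin -> (node idx, cost)
    total_cost: float = 0.0


def _grow_forest(graph: GeodesicGraph, roots_vox: np.ndarray, seeds_vox: np.ndarray,
                 max_link_cost: float):
    """Competitive Prim growth of one tree per root over a shared seed pool."""
    trees = []
    for r in np.asarray(roots_vox, int).reshape(-1, 3):
        lin = graph.lin(r)
        trees.append(_GrownTree(root_vox=r, nodes_vox=[tuple(int(c) for c in r)],
                                parents=[-1], node_of_lin={lin: 0}, attach_sources=[lin]))
    seeds_vox = np.asarray(seeds_vox, int).reshape(-1, 3)
    root_lins = {t.attach_sources[0] for t in trees}
    pool = {}
    for s in seeds_vox:
        sl = graph.lin(s)
        if sl not in root_lins:
            pool[sl] = tuple(int(c) for c in s)
    unassigned = dict(pool)
    cache: dict[int, tuple] = {}
    while unassigned:
        best = None   # (cost, tree idx, seed lin)
        for k, t in enumerate(trees):
            if k not in cache:
                cache[k] = graph.distances(t.attach_sources)
            dist, pred = cache[k]
            for sl in unassigned:
                c = dist[sl]
                if np.isfinite(c) and (best is None or c < best[0] - 1e-12 or
                                       (abs(c - best[0]) <= 1e-12 and (k, sl) < best[1:])):
                    best = (float(c), k, sl)
        if best is None or best[0] > max_link_cost:
            break
        cost, k, sl = best
        t = trees[k]
        dist, pred = cache[k]
        chain = graph.path_from(pred, sl)
        # the chain starts at a source voxel already on the tree
        parent_idx = t.node_of_lin[chain[0]]
        for lin_v in chain[1:]:
            if lin_v in t.node_of_lin:
                parent_idx = t.node_of_lin[lin_v]
                continue
            t.nodes_vox.append(tuple(int(c) for c in graph.unlin(lin_v)))
            t.parents.append(parent_idx)
            parent_idx = len(t.nodes_vox) - 1
            t.node_of_lin[lin_v] = parent_idx
        t.seed_nodes[sl] = (t.node_of_lin[sl], cost)
        t.total_cost += cost
        t.attach_sources.append(sl)
        del unassigned[sl]
        del cache[k]
    return trees, list(unassigned.values())


def _radius_map(v: Volume) -> np.ndarray:
    data = v.data.astype(np.float64)
    nz = data[data > 0]
    thr = np.median(nz) * 0.5 if nz.size else 0.5
    return ndimage.distance_transform_edt(data > thr, sampling=v.spacing)


def _to_arbor(t: _GrownTree, spacing, radius_map, cell_id=-1) -> ArborTrace:
    pos = np.asarray(t.nodes_vox, float).reshape(-1, 3)
    radii = radius_map[tuple(pos.astype(int).T)] if radius_map is not None else None
    if radii is not None:
        radii = np.maximum(radii, 0.25 * float(np.mean(spacing)))
    return ArborTrace(positions_um=pos * np.asarray(spacing), parents=np.asarray(t.parents),
                      radii_um=radii, cell_id=cell_id)


def grow_mst(roots, seeds: SeedSet | np.ndarray, v: Volume,
             max_link_cost: float = np.inf, graph: GeodesicGraph | None = None,
             cell_ids=None):
    """Grow one geodesic minimum spanning tree per root.

    Prim adaptation: repeatedly attach the unconnected seed with minimal
    geodesic distance to the growing tree's connected seed/root nodes; the
    connecting geodesic path becomes the new branch. Trees compete for the
    shared seed pool, every attached seed lands in exactly one tree, and the
    number of output trees always equals the number of roots. Seeds beyond
    ``max_link_cost`` from every tree are reported as unassigned.

    Returns ``(traces, info)`` with ``info['tree_costs']`` the summed link
    costs (equal to the MST cost of the seed geodesic-distance matrix) and
    ``info['unassigned']`` the unreachable seeds.
    """
    roots = np.asarray(roots, int).reshape(-1, 3)
    if len(roots) == 0:
        raise ValueError("roots must be nonempty")
    seeds_vox = seeds.seed_positions if isinstance(seeds, SeedSet) else np.asarray(seeds, int)
    g = graph or GeodesicGraph(v)
    trees, unassigned = _grow_forest(g, roots, seeds_vox.reshape(-1, 3), max_link_cost)
    rmap = _radius_map(v)
    ids = cell_ids if cell_ids is not None else list(range(len(trees)))
    traces = [_to_arbor(t, v.spacing, rmap, cid) for t, cid in zip(trees, ids)]
    info = {
        "tree_costs": [t.total_cost for t in trees],
        "n_attached": [len(t.seed_nodes) for t in trees],
        "unassigned": unassigned,
    }
    return traces, info


# ---------------------------------------------------------------------------
# dice-and-trace
# ---------------------------------------------------------------------------

def _prune_subtree(t: _GrownTree, node_idx: int):
    """Drop a node and all its descendants, rebuilding contiguous arrays."""
    n = len(t.nodes_vox)
    children = [[] for _ in range(n)]
    for i, p in enumerate(t.parents):
        if p >= 0:
            children[p].append(i)
    drop = np.zeros(n, bool)
    stack = [node_idx]
    while stack:
        i = stack.pop()
        drop[i] = True
        stack.extend(children[i])
    keep = np.flatnonzero(~drop)
    remap = {int(o): k for k, o in enumerate(keep)}
    t.nodes_vox = [t.nodes_vox[i] for i in keep]
    t.parents = [(-1 if t.parents[i] < 0 else remap[t.parents[i]]) for i in keep]
    t.node_of_lin = {l: remap[i] for l, i in t.node_of_lin.items() if not drop[i]}
    new_seed_nodes = {}
    for sl, (ni, c) in t.seed_nodes.items():
        if not drop[ni]:
            new_seed_nodes[sl] = (remap[ni], c)
        else:
            t.total_cost -= c
    t.seed_nodes = new_seed_nodes


def dice_and_trace(v: Volume, microglia_centroids_vox, seeds: SeedSet | np.ndarray,
                   max_arbor_um: float = 30.0, margin_um: float = 10.0,
                   max_link_cost: float = np.inf, patch_shape=(3, 7, 7),
                   cell_ids=None, dice_order=None):
    """Trace every microglia in its own dice and merge into a montage forest.

    One dice per microglia centroid, sized by the maximum expected arbor
    length plus a neighbor-context margin; other centroids falling inside the
    dice participate as competing roots so arbors stop where a neighbour's
    territory begins. Only the center cell's tree is kept per dice. A seed
    claimed by two kept trees keeps its lower-cost attachment (the other
    tree's subtree at that seed is pruned). The output is independent of the
    dice processing order.
    """
    roots = np.asarray(microglia_centroids_vox, int).reshape(-1, 3)
    if len(roots) == 0:
        raise ValueError("no microglia roots")
    half_um = max_arbor_um + margin_um
    half = np.maximum(np.round(half_um / np.asarray(v.spacing)).astype(int), 1)
    if np.any(2 * half < 2 * np.asarray(patch_shape)):
        raise ValueError(f"dice half-size {half.tolist()} smaller than twice the patch "
                         f"{patch_shape}")
    seeds_vox = seeds.seed_positions if isinstance(seeds, SeedSet) else np.asarray(seeds, int)
    seeds_vox = seeds_vox.reshape(-1, 3)
    ids = list(cell_ids) if cell_ids is not None else list(range(len(roots)))
    order = list(dice_order) if dice_order is not None else list(range(len(roots)))

    kept: dict[int, _GrownTree] = {}
    spacing = np.asarray(v.spacing)
    for k in order:
        c = roots[k]
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half + 1, v.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub = Volume(v.data[sl], spacing=v.spacing, depth=v.depth, channel=v.channel)
        in_box = np.all((roots >= lo) & (roots < hi), axis=1)
        local_roots = roots[in_box] - lo
        which = np.flatnonzero(in_box)
        s_in = np.all((seeds_vox >= lo) & (seeds_vox < hi), axis=1)
        local_seeds = seeds_vox[s_in] - lo
        g = GeodesicGraph(sub)
        trees, _ = _grow_forest(g, local_roots, local_seeds, max_link_cost)
        center_slot = int(np.flatnonzero(which == k)[0])
        t = trees[center_slot]
        # back to montage coordinates
        t.nodes_vox = [tuple(int(a + b) for a, b in zip(p, lo)) for p in t.nodes_vox]
        t.root_vox = c
        full_shape = v.shape
        t.node_of_lin = {int(np.ravel_multi_index(p, full_shape)): i
                         for i, p in enumerate(t.nodes_vox)}
        t.seed_nodes = {
            int(np.ravel_multi_index(tuple(np.array(g.unlin(slin)) + lo), full_shape)): nc
            for slin, nc in t.seed_nodes.items()
        }
        kept[k] = t

    # resolve duplicate seed claims: lower attachment cost wins (tie: lower cell id)
    claims: dict[int, list] = {}
    for k in sorted(kept):
        for slin, (ni, c) in kept[k].seed_nodes.items():
            claims.setdefault(slin, []).append((c, k))
    for slin, lst in claims.items():
        if len(lst) < 2:
            continue
        lst.sort()
        for c, k in lst[1:]:
            t = kept[k]
            ni = t.seed_nodes[slin][0]
            _prune_subtree(t, ni)

    rmap = _radius_map(v)
    traces = [_to_arbor(kept[k], spacing, rmap, ids[k]) for k in sorted(kept)]
    info = {"tree_costs": [kept[k].total_cost for k in sorted(kept)],
            "n_attached": [len(kept[k].seed_nodes) for k in sorted(kept)]}
    return traces, info
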