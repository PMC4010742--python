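"""Tile registration and montage composition.

A translation-only model: step-and-repeat stage acquisition means the
transform between adjacent tiles is almost entirely a lateral shift. Pairwise
shifts are estimated on maximum-intensity axial projections (phase
correlation, then local normalized-cross-correlation refinement), refined in
3-D over a small search window, made globally consistent by a score-weighted
least-squares solve over the pair graph, and composed with feathered
averaging over only the bounding box actually requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix
from skimage.registration import phase_cross_correlation

from .imgio import Volume

__all__ = [
    "TileSet",
    "PairShift",
    "MontageLayout",
    "pairwise_shift_2d",
    "refine_shift_3d",
    "joint_registration",
    "compose_montage",
    "register_tileset",
]

MIN_OVERLAP_VOX = 8


@dataclass
class TileSet:
    tiles: list                      # list[Volume]
    nominal_offsets: np.ndarray      # (n, 3) int, stage positions (z, y, x)
    pairs: list                      # adjacency [(i, j), ...]
    grid: tuple[int, int] = (1, 1)

    def __post_init__(self):
        self.nominal_offsets = np.asarray(self.nominal_offsets, int).reshape(-1, 3)


@dataclass
class PairShift:
    i: int
    j: int
    offset: np.ndarray               # estimated (z, y, x) translation of tile j relative to i
    score: float                     # NCC at the optimum, in [-1, 1]
    low_confidence: bool = False

    def __post_init__(self):
        self.offset = np.asarray(self.offset, int).reshape(3)


@dataclass
class MontageLayout:
    translations: np.ndarray         # (n, 3) int global translation per tile
    bbox_lo: np.ndarray
    bbox_hi: np.ndarray
    anchor: int = 0
    residuals: dict = field(default_factory=dict)   # (i, j) -> residual norm (voxels)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    d = np.sqrt((a @ a) * (b @ b))
    if d == 0:
        return 0.0
    return float((a @ b) / d)


def _overlap_views(a: np.ndarray, b: np.ndarray, offset: np.ndarray):
    """Views of a and b over their intersection when b sits at `offset` in a's frame."""
    offset = np.asarray(offset, int)
    lo = np.maximum(offset, 0)
    hi = np.minimum(np.array(a.shape), np.array(b.shape) + offset)
    if np.any(hi - lo < 1):
        return None, None
    sl_a = tuple(slice(l, h) for l, h in zip(lo, hi))
    sl_b = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, offset))
    return a[sl_a], b[sl_b]


def _ncc_at(a, b, offset) -> float:
    va, vb = _overlap_views(a, b, offset)
    if va is None or va.size < MIN_OVERLAP_VOX:
        return -np.inf
    return _ncc(va, vb)


def pairwise_shift_2d(a: Volume, b: Volume, nominal_offset) -> PairShift:
    """Estimate the lateral shift of tile b relative to tile a.

    `nominal_offset` is the stage-reported (z, y, x) offset of b in a's frame.
    The shift is estimated on maximum-intensity axial projections by phase
    correlation of the nominal overlap regions, then refined to the integer
    shift maximizing NCC in a +/-3 voxel window. If the optimum leaves fewer
    than 8 overlap voxels or the correlation is weak, the estimate falls back
    to the nominal offset with a low-confidence flag.
    """
    nominal_offset = np.asarray(nominal_offset, int)
    A = a.data.max(axis=0).astype(np.float64)
    B = b.data.max(axis=0).astype(np.float64)
    nom2 = nominal_offset[1:]
    sa, sb = _overlap_views(A, B, nom2)
    if sa is None or min(sa.shape) < 4:
        return PairShift(0, 0, nominal_offset, 0.0, low_confidence=True)
    try:
        resid, _, _ = phase_cross_correlation(sa, sb, normalization=None)
    except Exception:
        resid = np.zeros(2)
    resid = np.round(resid).astype(int)
    # resid is the displacement of sb relative to sa; actual offset = nominal - resid
    # (sign fixed by the NCC refinement below either way)
    best_off, best_score = nom2.copy(), _ncc_at(A, B, nom2)
    for base in (nom2 - resid, nom2 + resid):
        for dy in range(-3, 4):
            for dx in range(-3, 4):
                cand = base + np.array([dy, dx])
                s = _ncc_at(A, B, cand)
                if s > best_score:
                    best_score, best_off = s, cand
    offset = np.array([nominal_offset[0], best_off[0], best_off[1]])
    va, vb = _overlap_views(A, B, offset[1:])
    low = va is None or va.size < MIN_OVERLAP_VOX or best_score < 0.2
    if low:
        offset = nominal_offset.copy()
        best_score = max(best_score, 0.0) if np.isfinite(best_score) else 0.0
    return PairShift(0, 0, offset, float(best_score), low_confidence=bool(low))


def refine_shift_3d(a: Volume, b: Volume, lateral: PairShift,
                    z_window: int = 5, lateral_window: int = 1) -> PairShift:
    """Refine the z (and small lateral) components by exhaustive voxelwise NCC.

    The search covers dz in +/-z_window and dy, dx in +/-lateral_window around
    the lateral estimate; the starting point is always a candidate, so the
    refined NCC never falls below the unrefined one.
    """
    base = lateral.offset.copy()
    va, vb = _overlap_views(a.data, b.data, base)
    if va is None:
        raise ValueError(f"empty overlap between tiles at offset {base.tolist()}")
    best_off = base.copy()
    best_score = _ncc_at(a.data, b.data, base)
    for dz in range(-z_window, z_window + 1):
        for dy in range(-lateral_window, lateral_window + 1):
            for dx in range(-lateral_window, lateral_window + 1):
                cand = base + np.array([dz, dy, dx])
                s = _ncc_at(a.data, b.data, cand)
                if s > best_score:
                    best_score, best_off = s, cand
    return PairShift(lateral.i, lateral.j, best_off, float(best_score),
                     low_confidence=lateral.low_confidence)


def joint_registration(shifts: list[PairShift], n_tiles: int, anchor: int = 0) -> MontageLayout:
    """Globally consistent tile translations from pairwise estimates.

    Minimizes the score-weighted sum of squared residuals between
    ``t_j - t_i`` and the pairwise offsets, with the anchor fixed at zero.
    Weights are NCC scores clipped to [0.1, 1].
    """
    if n_tiles == 1:
        return MontageLayout(np.zeros((1, 3), int), np.zeros(3, int), np.zeros(3, int), anchor)
    rows, cols, vals = [], [], []
    for k, s in enumerate(shifts):
        rows += [k, k]
        cols += [s.i, s.j]
        vals += [1, 1]
    adj = csr_matrix((vals, (rows, cols)), shape=(len(shifts), n_tiles))
    n_comp, comp = connected_components(adj.T @ adj, directed=False)
    if n_comp > 1:
        groups = [np.flatnonzero(comp == c).tolist() for c in range(n_comp)]
        raise ValueError(f"pair graph is disconnected; components: {groups}")

    free = [t for t in range(n_tiles) if t != anchor]
    col_of = {t: k for k, t in enumerate(free)}
    A = np.zeros((len(shifts), len(free)))
    rhs = np.zeros((len(shifts), 3))
    w = np.zeros(len(shifts))
    for k, s in enumerate(shifts):
        w[k] = np.clip(s.score, 0.1, 1.0)
        if s.i != anchor:
            A[k, col_of[s.i]] = -1.0
        if s.j != anchor:
            A[k, col_of[s.j]] = 1.0
        rhs[k] = s.offset
    sw = np.sqrt(w)[:, None]
    sol, *_ = np.linalg.lstsq(A * sw, rhs * sw, rcond=None)
    t = np.zeros((n_tiles, 3))
    for tile, k in col_of.items():
        t[tile] = sol[k]
    residuals = {}
    for k, s in enumerate(shifts):
        residuals[(s.i, s.j)] = float(np.linalg.norm(t[s.j] - t[s.i] - s.offset))
    t = np.round(t).astype(int)
    return MontageLayout(t, t.min(axis=0), t.max(axis=0), anchor, residuals)


def register_tileset(ts: TileSet, refine_3d: bool = True, anchor: int = 0) -> MontageLayout:
    """Full registration: pairwise 2-D + 3-D refinement + joint solve."""
    shifts = []
    for (i, j) in ts.pairs:
        nominal = ts.nominal_offsets[j] - ts.nominal_offsets[i]
        ps = pairwise_shift_2d(ts.tiles[i], ts.tiles[j], nominal)
        ps.i, ps.j = i, j
        if refine_3d and not ps.low_confidence:
            ps = refine_shift_3d(ts.tiles[i], ts.tiles[j], ps)
        shifts.append(ps)
    layout = joint_registration(shifts, len(ts.tiles), anchor=anchor)
    return layout


def compose_montage(ts: TileSet, layout: MontageLayout, roi=None,
                    feather: int = 8) -> Volume:
    """Compose tiles into a montage over the requested ROI only.

    Overlaps are blended by a feathered weighted average (separable linear
    ramp of `feather` voxels at tile borders). `roi` is a
    ``((z0, z1), (y0, y1), (x0, x1))`` box in montage-array coordinates
    (0 at the bounding-box origin); default is the full bounding box. Tiles
    that do not intersect the ROI are never touched.
    """
    t = layout.translations - layout.translations.min(axis=0)
    shapes = np.array([tile.shape for tile in ts.tiles])
    full_hi = (t + shapes).max(axis=0)
    if roi is None:
        lo = np.zeros(3, int)
        hi = full_hi
    else:
        lo = np.array([r[0] for r in roi], int)
        hi = np.array([r[1] for r in roi], int)
        lo = np.clip(lo, 0, full_hi)
        hi = np.clip(hi, 0, full_hi)
        if np.any(hi <= lo):
            raise ValueError(f"empty ROI {roi}")
    out_shape = tuple(hi - lo)
    num = np.zeros(out_shape, np.float64)
    den = np.zeros(out_shape, np.float64)

    touched = False
    for k, tile in enumerate(ts.tiles):
        tlo, thi = t[k], t[k] + np.array(tile.shape)
        ilo = np.maximum(tlo, lo)
        ihi = np.minimum(thi, hi)
        if np.any(ihi <= ilo):
            continue
        touched = True
        w_axes = []
        for ax in range(3):
            n = tile.shape[ax]
            idx = np.arange(n, dtype=np.float64)
            f = max(1, min(feather, n // 2))
            ramp = np.minimum(np.minimum(idx + 1, n - idx), f) / f
            w_axes.append(ramp)
        w = w_axes[0][:, None, None] * w_axes[1][None, :, None] * w_axes[2][None, None, :]
        sl_out = tuple(slice(a - b, c - b) for a, c, b in zip(ilo, ihi, lo))
        sl_in = tuple(slice(a - b, c - b) for a, c, b in zip(ilo, ihi, tlo))
        num[sl_out] += w[sl_in] * tile.data[sl_in].astype(np.float64)
        den[sl_out] += w[sl_in]
    if not touched:
        raise ValueError("ROI disjoint from all tiles")
    blended = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    ref = ts.tiles[0]
    if np.issubdtype(ref.data.dtype, np.integer):
        data = np.clip(np.round(blended), 0, 2**ref.depth - 1).astype(ref.data.dtype)
    else:
        data = blended.astype(ref.data.dtype)
    return Volume(data, spacing=ref.spacing, depth=ref.depth, channel=ref.channel)
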