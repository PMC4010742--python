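"""Synthetic multi-channel brain-tissue phantoms with complete ground truth.

The generator emulates the structure of confocal montages of cortex around an
implanted recording device: Hoechst-style nuclei of several cell classes
rendered as ellipsoidal blobs, microglia arbors rendered as tubes of decaying
radius rooted at microglia somata, an optional device void with a cell-density
gradient toward its surface, a smooth multiplicative illumination bias, and
photon (Poisson) plus read (Gaussian) noise. Every random choice flows from a
single seeded generator, so a fixed spec reproduces byte-identical volumes.

Intensities are generated in a 14-bit range (stored in 16-bit containers), the
bit depth of the acquisitions the pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import ArborTrace, Volume
from .mosaic import TileSet

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "generate_phantom",
    "split_tiles",
    "simulate_cell_features",
]

MAX_14BIT = 2**14 - 1
CLASS_NAMES = ("microglia", "astrocyte", "neuron")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without violating a constraint."""


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (32, 96, 96)          # (z, y, x) voxels
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)  # µm, isotropic default
    cell_counts: dict = field(default_factory=lambda: {"microglia": 4, "astrocyte": 4, "neuron": 4})
    nucleus_radius_um: tuple[float, float] = (1.8, 2.6)
    class_separation: float = 4.0        # pooled-SD units, for simulated feature tables
    n_arbors: int | None = None          # default: one arbor per microglia
    branch_order_range: tuple[int, int] = (2, 3)
    segment_length_um: tuple[float, float] = (5.0, 10.0)
    tube_radius_um: float = 0.8
    device_box: tuple | None = None      # ((z0, z1), (y0, y1), (x0, x1)) voxels, or None
    density_gradient_um: float = 50.0    # e-folding scale of the density boost near the device
    bias_amplitude: float = 0.15         # fraction of signal
    photon_scale: float = 0.05           # Poisson counts per intensity unit; 0 disables
    read_noise_sd: float = 40.0          # additive Gaussian SD (14-bit units); 0 disables
    tile_grid: tuple[int, int] = (1, 1)  # (rows, cols) over (y, x)
    overlap: float = 0.25                # fraction of tile extent shared by neighbours
    tile_shifts: list | None = None      # per-tile true (dz, dy, dx) integer shifts
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.overlap <= 0.5):
            raise ValueError(f"overlap fraction must be in (0, 0.5], got {self.overlap}")
        if self.nucleus_radius_um[0] <= 0 or self.tube_radius_um <= 0:
            raise ValueError("all radii must be > 0")
        if any(n < 0 for n in self.cell_counts.values()):
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return sum(self.cell_counts.values())


@dataclass
class GroundTruth:
    centroids_vox: np.ndarray        # (N, 3) float voxel coords (z, y, x)
    class_labels: list[str]
    nucleus_radii_vox: np.ndarray    # (N, 3) per-axis ellipsoid radii
    arbors: list[ArborTrace]         # node positions in µm, rooted at microglia centroids
    arbor_cells: list[int]           # cell index owning each arbor
    tile_shifts: np.ndarray | None   # (n_tiles, 3) true integer shifts
    device_mask: np.ndarray | None   # boolean (z, y, x), True inside the device
    device_distance_um: np.ndarray   # per-cell distance to device surface (inf if no device)

    @property
    def centroids_um(self) -> np.ndarray:
        return self.centroids_vox * np.array(self._spacing)

    _spacing: tuple = (1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _place_cells(spec: PhantomSpec, rng: np.random.Generator):
    shape = np.array(spec.shape, float)
    sp = np.array(spec.spacing)
    r_mean_vox = np.mean(spec.nucleus_radius_um) / sp.mean()
    min_sep_vox = 2.1 * r_mean_vox
    margin = np.maximum(spec.nucleus_radius_um[1] / sp, 1.0)

    dev_dist_vox = None
    if spec.device_box is not None:
        dev = np.zeros(spec.shape, bool)
        (z0, z1), (y0, y1), (x0, x1) = spec.device_box
        dev[z0:z1, y0:y1, x0:x1] = True
        dev_dist_vox = ndimage.distance_transform_edt(~dev, sampling=spec.spacing)

    positions, labels = [], []
    order = [(name, spec.cell_counts.get(name, 0)) for name in CLASS_NAMES]
    for name, count in order:
        placed = 0
        attempts = 0
        budget = 400 * max(count, 1)
        while placed < count:
            if attempts > budget:
                raise PlacementError(
                    f"could not place {count} {name} cells with min separation "
                    f"{min_sep_vox:.1f} voxels in volume {spec.shape} (retry budget exhausted)"
                )
            attempts += 1
            p = margin + rng.random(3) * (shape - 2 * margin)
            if dev_dist_vox is not None:
                d_um = dev_dist_vox[tuple(p.astype(int))]
                if d_um <= 0:
                    continue  # inside the device void
                if spec.density_gradient_um > 0:
                    accept = 0.15 + 0.85 * np.exp(-d_um / spec.density_gradient_um)
                    if rng.random() > accept:
                        continue
            if positions and np.min(
                np.linalg.norm(np.array(positions) - p, axis=1)
            ) < min_sep_vox:
                continue
            positions.append(p)
            labels.append(name)
            placed += 1
    if not positions:
        return np.zeros((0, 3)), []
    return np.array(positions), labels


# ---------------------------------------------------------------------------
# arbor growth: recursive bifurcation with per-step direction jitter
# ---------------------------------------------------------------------------

def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _jitter(direction, rng, kappa_deg=12.0):
    d = direction + np.deg2rad(kappa_deg) * rng.standard_normal(3)
    return d / np.linalg.norm(d)


def _rotate_away(direction, rng, angle_deg):
    axis = np.cross(direction, _random_unit(rng))
    n = np.linalg.norm(axis)
    if n < 1e-9:
        return _random_unit(rng)
    axis /= n
    a = np.deg2rad(angle_deg)
    # Rodrigues rotation
    d = (direction * np.cos(a) + np.cross(axis, direction) * np.sin(a)
         + axis * np.dot(axis, direction) * (1 - np.cos(a)))
    return d / np.linalg.norm(d)


def _grow_arbor(root_vox, spec: PhantomSpec, rng):
    """Grow one tree in voxel coordinates; returns (nodes, parents, radii_vox, orders)."""
    sp = np.array(spec.spacing)
    step_vox = 1.5
    min_order, max_order = spec.branch_order_range
    nodes = [np.asarray(root_vox, float)]
    parents = [-1]
    orders = [0]
    r0_vox = spec.tube_radius_um / sp.mean()
    radii = [r0_vox * 1.6]
    lo = np.ones(3)
    hi = np.array(spec.shape, float) - 2.0

    # initial trunks leaving the soma in distinct directions
    n_trunks = 2 if max_order >= 2 else 1
    stack = []
    d0 = _random_unit(rng)
    stack.append((0, d0, 1))
    if n_trunks == 2:
        stack.append((0, _rotate_away(d0, rng, 140 + rng.random() * 40), 1))

    while stack:
        parent_idx, direction, order = stack.pop()
        seg_len_um = rng.uniform(*spec.segment_length_um)
        n_steps = max(2, int(round(seg_len_um / (step_vox * sp.mean()))))
        idx = parent_idx
        alive = True
        for _ in range(n_steps):
            direction = _jitter(direction, rng)
            p = nodes[idx] + direction * step_vox
            if np.any(p < lo) or np.any(p >= hi):
                alive = False
                break
            nodes.append(p)
            parents.append(idx)
            orders.append(order)
            radii.append(max(0.45, r0_vox * 0.85 ** (order - 1)))
            idx = len(nodes) - 1
        if not alive:
            continue
        if order < max_order:
            branch_p = 1.0 if order < min_order else 0.5
            if rng.random() < branch_p:
                a = 25 + rng.random() * 20
                stack.append((idx, _rotate_away(direction, rng, a), order + 1))
                stack.append((idx, _rotate_away(direction, rng, -a), order + 1))
            elif order < max_order and rng.random() < 0.5:
                stack.append((idx, direction, order + 1))
    return np.array(nodes), np.array(parents, int), np.array(radii), np.array(orders, int)


def _render_tubes(shape, polylines, rng=None):
    """Distance-to-polyline rendering with a 1-voxel soft edge.

    ``polylines`` is a list of (nodes_vox, parents, radii_vox). Returns a float
    intensity field in [0, 1].
    """
    mask = np.zeros(shape, bool)
    radius_at = np.zeros(shape, np.float32)
    any_pts = False
    for nodes, parents, radii in polylines:
        for i, p in enumerate(parents):
            if p < 0:
                continue
            a, b = nodes[p], nodes[i]
            n = max(2, int(np.ceil(np.linalg.norm(b - a) / 0.25)) + 1)
            ts = np.linspace(0.0, 1.0, n)[:, None]
            pts = a[None] * (1 - ts) + b[None] * ts
            r = radii[p] * (1 - ts[:, 0]) + radii[i] * ts[:, 0]
            iz, iy, ix = np.round(pts.T).astype(int)
            iz = np.clip(iz, 0, shape[0] - 1)
            iy = np.clip(iy, 0, shape[1] - 1)
            ix = np.clip(ix, 0, shape[2] - 1)
            mask[iz, iy, ix] = True
            np.maximum.at(radius_at, (iz, iy, ix), r.astype(np.float32))
            any_pts = True
    if not any_pts:
        return np.zeros(shape, np.float32)
    dist, (nz, ny, nx) = ndimage.distance_transform_edt(~mask, return_indices=True)
    r_near = radius_at[nz, ny, nx]
    # linear falloff over a 1-voxel soft edge beyond the tube radius
    return np.clip(r_near + 1.0 - dist, 0.0, 1.0).astype(np.float32)


def _render_ellipsoids(shape, centers, radii_vox, peaks):
    out = np.zeros(shape, np.float32)
    for c, r, peak in zip(centers, radii_vox, peaks):
        lo = np.maximum(np.floor(c - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + r + 2).astype(int), shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
        q = (((zz - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + ((xx - c[2]) / r[2]) ** 2)
        blob = peak * np.clip(1.0 - q, 0.0, 1.0) ** 0.7
        region = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(region, blob, out=region)
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[list[Volume], GroundTruth]:
    """Render the four channels (nuclei, microglia, astrocyte, neuron) + truth."""
    rng = np.random.default_rng(spec.seed)
    sp = np.array(spec.spacing)
    shape = spec.shape

    centers, labels = _place_cells(spec, rng)
    n_cells = len(labels)
    radii_vox = np.zeros((n_cells, 3))
    for i in range(n_cells):
        radii_vox[i] = rng.uniform(*spec.nucleus_radius_um, size=3) / sp
    peaks = 0.55 + 0.15 * rng.random(n_cells)

    # arbors rooted at microglia nuclei
    mg_idx = [i for i, l in enumerate(labels) if l == "microglia"]
    n_arb = len(mg_idx) if spec.n_arbors is None else min(spec.n_arbors, len(mg_idx))
    arbor_polys, arbors, arbor_cells = [], [], []
    for i in mg_idx[:n_arb]:
        nodes, parents, radii, _ = _grow_arbor(centers[i], spec, rng)
        arbor_polys.append((nodes, parents, radii))
        arbors.append(ArborTrace(positions_um=nodes * sp, parents=parents,
                                 radii_um=radii * sp.mean(), cell_id=i))
        arbor_cells.append(i)

    nuclei = _render_ellipsoids(shape, centers, radii_vox, peaks)
    microglia = _render_tubes(shape, arbor_polys)
    if mg_idx:
        sel = np.array(mg_idx)
        microglia = np.maximum(
            microglia,
            _render_ellipsoids(shape, centers[sel], radii_vox[sel] * 0.8, 0.8 * peaks[sel]),
        )
    chans = {"nuclei": nuclei, "microglia": microglia}
    for name in ("astrocyte", "neuron"):
        idx = [i for i, l in enumerate(labels) if l == name]
        if idx:
            sel = np.array(idx)
            chans[name] = _render_ellipsoids(shape, centers[sel], radii_vox[sel] * 1.2,
                                             0.9 * peaks[sel])
        else:
            chans[name] = np.zeros(shape, np.float32)

    device_mask = None
    if spec.device_box is not None:
        device_mask = np.zeros(shape, bool)
        (z0, z1), (y0, y1), (x0, x1) = spec.device_box
        device_mask[z0:z1, y0:y1, x0:x1] = True

    # illumination bias (shared across channels), then photon + read noise
    if spec.bias_amplitude > 0:
        g = ndimage.gaussian_filter(rng.standard_normal(shape),
                                    sigma=[max(2, s / 4) for s in shape])
        g = g / (np.abs(g).max() + 1e-12)
        bias = 1.0 + spec.bias_amplitude * g
    else:
        bias = np.ones(shape, np.float32)

    volumes = []
    for name in ("nuclei", "microglia", "astrocyte", "neuron"):
        sig = chans[name] * MAX_14BIT
        if device_mask is not None:
            sig[device_mask] = 0.0
        sig = sig * bias
        if spec.photon_scale > 0:
            sig = rng.poisson(np.clip(sig, 0, None) * spec.photon_scale) / spec.photon_scale
        if spec.read_noise_sd > 0:
            sig = sig + rng.normal(0.0, spec.read_noise_sd, shape)
        data = np.clip(np.round(sig), 0, MAX_14BIT).astype(np.uint16)
        volumes.append(Volume(data, spacing=spec.spacing, depth=14, channel=name))

    if device_mask is not None and n_cells:
        ddist = ndimage.distance_transform_edt(~device_mask, sampling=spec.spacing)
        dev_d = ddist[tuple(centers.astype(int).T)]
    else:
        dev_d = np.full(n_cells, np.inf)

    n_tiles = spec.tile_grid[0] * spec.tile_grid[1]
    shifts = np.zeros((n_tiles, 3), int)
    if spec.tile_shifts is not None:
        shifts = np.asarray(spec.tile_shifts, int).reshape(n_tiles, 3)

    truth = GroundTruth(
        centroids_vox=centers, class_labels=labels, nucleus_radii_vox=radii_vox,
        arbors=arbors, arbor_cells=arbor_cells, tile_shifts=shifts,
        device_mask=device_mask, device_distance_um=dev_d,
    )
    truth._spacing = spec.spacing
    return volumes, truth


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def split_tiles(channel: Volume, spec: PhantomSpec) -> TileSet:
    """Cut a channel into an overlapping tile grid with known true shifts.

    Nominal "stage" offsets follow the regular grid; each tile's actual crop
    offset adds its true shift, emulating stage-positioning error.
    """
    rows, cols = spec.tile_grid
    Z, Y, X = channel.shape
    ov = spec.overlap

    n_tiles = rows * cols
    shifts = np.zeros((n_tiles, 3), int)
    if spec.tile_shifts is not None:
        shifts = np.asarray(spec.tile_shifts, int).reshape(n_tiles, 3)

    # reserve a border margin equal to the largest shift so every shifted
    # crop stays inside the volume
    my = int(np.abs(shifts[:, 1]).max())
    mx = int(np.abs(shifts[:, 2]).max())
    Yu, Xu = Y - 2 * my, X - 2 * mx
    ty = int(np.floor(Yu / (1 + (rows - 1) * (1 - ov)))) if rows > 1 else Yu
    tx = int(np.floor(Xu / (1 + (cols - 1) * (1 - ov)))) if cols > 1 else Xu
    if ty < 4 or tx < 4:
        raise ValueError(f"tile grid {spec.tile_grid} too large for volume {channel.shape}")
    if rows > 1 and int(round(ty * ov)) < 8:
        raise ValueError(f"overlap {ov} yields {int(round(ty * ov))} voxels (< 8) along y")
    if cols > 1 and int(round(tx * ov)) < 8:
        raise ValueError(f"overlap {ov} yields {int(round(tx * ov))} voxels (< 8) along x")

    # z handling: tiles share a fixed z window large enough to absorb any dz
    z_pad = int(np.abs(shifts[:, 0]).max())
    tz = Z - 2 * z_pad
    if tz < 1:
        raise ValueError(f"z shifts {shifts[:, 0].tolist()} too large for depth {Z}")

    y_starts = (np.round(np.linspace(0, Yu - ty, rows)).astype(int) + my) if rows > 1 else [my]
    x_starts = (np.round(np.linspace(0, Xu - tx, cols)).astype(int) + mx) if cols > 1 else [mx]
    tiles, nominal = [], []
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c
            oy = int(y_starts[r])
            ox = int(x_starts[c])
            nominal.append((z_pad, oy, ox))
            dz, dy, dx = shifts[k]
            az, ay, ax = z_pad + dz, oy + dy, ox + dx
            if not (0 <= az <= Z - tz and 0 <= ay <= Y - ty and 0 <= ax <= X - tx):
                raise ValueError(f"tile {k}: shift {tuple(shifts[k])} puts crop out of bounds")
            sub = channel.data[az:az + tz, ay:ay + ty, ax:ax + tx]
            tiles.append(Volume(sub.copy(), spacing=channel.spacing,
                                depth=channel.depth, channel=channel.channel))
    pairs = []
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c
            if c + 1 < cols:
                pairs.append((k, k + 1))
            if r + 1 < rows:
                pairs.append((k, k + cols))
    return TileSet(tiles=tiles, nominal_offsets=np.array(nominal, int), pairs=pairs,
                   grid=(rows, cols))


# ---------------------------------------------------------------------------
# feature-table simulator (test harness for cell-type classification)
# ---------------------------------------------------------------------------

def simulate_cell_features(
    n: int, separation: float, seed: int, n_features: int = 6
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two balanced multivariate-normal classes with a stated pooled-SD separation.

    The class-mean difference vector has Euclidean norm ``separation`` in
    pooled-SD units (unit isotropic covariance), so the Bayes accuracy is
    ``Phi(separation / 2)``.
    """
    if separation < 0:
        raise ValueError(f"separation must be >= 0, got {separation}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    rng = np.random.default_rng(seed)
    delta = np.ones(n_features) / np.sqrt(n_features) * separation
    n0 = n // 2
    y = np.array([0] * n0 + [1] * (n - n0))
    X = rng.standard_normal((n, n_features))
    X[y == 1] += delta
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    df.insert(0, "cell_id", np.arange(n))
    return df, y
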