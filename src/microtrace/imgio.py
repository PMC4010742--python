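"""Image, trace and run-record input/output.

Conventions used throughout the package (asserted in tests):

* voxel indices are 0-based with axis order ``(z, y, x)``;
* voxel spacing is micrometres per axis, ``(z, y, x)``;
* SWC files are emitted in physical micrometres with columns ``x, y, z``;
* 14-bit acquisitions are stored in 16-bit containers with the true bit
  depth recorded in metadata.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "ArborTrace",
    "RunRecord",
    "FormatError",
    "StructureError",
    "read_stack",
    "write_stack",
    "read_swc",
    "write_swc",
    "append_record",
    "save_record",
    "load_record",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected on-disk format."""


class StructureError(ValueError):
    """Raised when a tree/record violates its structural invariants."""


_SUPPORTED_DEPTHS = (8, 14, 16)


@dataclass
class Volume:
    """One channel's 3-D voxel grid.

    Parameters
    ----------
    data:
        ``(z, y, x)`` intensity array, non-negative, within the bit depth.
    spacing:
        micrometres per voxel along ``(z, y, x)``.
    depth:
        acquisition bit depth; 14-bit data lives in a 16-bit container.
    channel:
        free-form channel tag (``"nuclei"``, ``"microglia"``, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    depth: int = 16
    channel: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D (z, y, x), got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.depth not in _SUPPORTED_DEPTHS:
            raise FormatError(f"unsupported bit depth {self.depth}; supported: {_SUPPORTED_DEPTHS}")
        if self.data.size and np.issubdtype(self.data.dtype, np.integer):
            lo, hi = int(self.data.min()), int(self.data.max())
            if lo < 0 or hi > 2**self.depth - 1:
                raise ValueError(
                    f"intensities [{lo}, {hi}] outside [0, {2**self.depth - 1}] for depth {self.depth}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


@dataclass
class ArborTrace:
    """A rooted tree for one cell arbor (SWC-serializable).

    ``positions_um`` holds node coordinates in micrometres, axis order
    ``(z, y, x)``. ``parents`` holds the parent node index per node, ``-1``
    for the single root (node 0 by convention).
    """

    positions_um: np.ndarray  # (N, 3) float, (z, y, x) micrometres
    parents: np.ndarray       # (N,) int, -1 for root
    radii_um: np.ndarray | None = None
    cell_id: int = -1
    node_types: np.ndarray | None = None

    def __post_init__(self):
        self.positions_um = np.asarray(self.positions_um, dtype=float).reshape(-1, 3)
        self.parents = np.asarray(self.parents, dtype=int).reshape(-1)
        n = len(self.parents)
        if self.positions_um.shape[0] != n:
            raise StructureError("positions and parents length mismatch")
        if self.radii_um is None:
            self.radii_um = np.ones(n)
        self.radii_um = np.asarray(self.radii_um, dtype=float).reshape(-1)
        if self.node_types is None:
            self.node_types = np.full(n, 3, dtype=int)  # SWC type 3 = dendrite/process
        if n:
            self._validate()

    def _validate(self):
        roots = np.flatnonzero(self.parents < 0)
        if len(roots) != 1:
            raise StructureError(f"tree must have exactly one root, found {len(roots)}")
        n = len(self.parents)
        if (self.parents >= n).any():
            raise StructureError("parent index out of range")
        # cycle / connectivity check: every node must reach the root
        root = roots[0]
        for i in range(n):
            seen, j = set(), i
            while j != root:
                if j in seen:
                    raise StructureError("cycle detected in parent links")
                seen.add(j)
                j = self.parents[j]

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                out[p].append(i)
        return out


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(volume: Volume, path: str | os.PathLike) -> str:
    """Write a volume as a multi-page TIFF, metadata in the image description."""
    meta = {
        "spacing_um_zyx": list(volume.spacing),
        "depth": volume.depth,
        "channel": volume.channel,
    }
    data = volume.data
    if np.issubdtype(data.dtype, np.integer) and volume.depth in (14, 16):
        data = data.astype(np.uint16, copy=False)
    elif np.issubdtype(data.dtype, np.integer) and volume.depth == 8:
        data = data.astype(np.uint8, copy=False)
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")
    return str(path)


def read_stack(path: str | os.PathLike) -> Volume:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    Plain third-party TIFFs are accepted too; missing metadata falls back to
    unit spacing and a depth inferred from the dtype.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise FormatError(f"mixed page shapes in {path}: {sorted(shapes)}")
            data = tf.asarray()
            desc = tf.pages[0].description or ""
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises assorted errors on corruption
        size = os.path.getsize(path) if os.path.exists(path) else -1
        raise FormatError(f"cannot read TIFF {path} (file size {size} bytes): {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    depth = int(meta.get("depth", data.dtype.itemsize * 8 if data.dtype.kind == "u" else 16))
    if depth not in _SUPPORTED_DEPTHS:
        raise FormatError(f"unsupported bit depth {depth} in {path}")
    spacing = tuple(meta.get("spacing_um_zyx", (1.0, 1.0, 1.0)))
    return Volume(data, spacing=spacing, depth=depth, channel=meta.get("channel", ""))


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def write_swc(trace: ArborTrace, path: str | os.PathLike) -> str:
    """Write a tree in SWC: 1-based ids, parent -1 for root, coords in µm (x, y, z)."""
    if trace.n_nodes == 0:
        raise StructureError("refusing to write an empty tree")
    lines = ["# SWC written by microtrace; coordinates in micrometres (x, y, z)"]
    lines.append(f"# cell_id {trace.cell_id}")
    for i in range(trace.n_nodes):
        z, y, x = trace.positions_um[i]
        parent = trace.parents[i] + 1 if trace.parents[i] >= 0 else -1
        lines.append(
            f"{i + 1} {int(trace.node_types[i])} {x:.6g} {y:.6g} {z:.6g} "
            f"{trace.radii_um[i]:.6g} {parent}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def read_swc(path: str | os.PathLike) -> ArborTrace:
    ids, types, pos, radii, parents = [], [], [], [], []
    cell_id = -1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if line.startswith("# cell_id"):
                    cell_id = int(line.split()[-1])
                continue
            if not line:
                continue
            f = line.split()
            if len(f) != 7:
                raise FormatError(f"malformed SWC line: {line!r}")
            ids.append(int(f[0]))
            types.append(int(f[1]))
            pos.append((float(f[4]), float(f[3]), float(f[2])))  # file x y z -> (z, y, x)
            radii.append(float(f[5]))
            parents.append(int(f[6]))
    if not ids:
        raise FormatError(f"no nodes in SWC file {path}")
    order = np.argsort(ids)
    id_to_idx = {ids[i]: rank for rank, i in enumerate(order)}
    par = np.array(
        [-1 if parents[i] == -1 else id_to_idx[parents[i]] for i in order], dtype=int
    )
    return ArborTrace(
        positions_um=np.array(pos)[order],
        parents=par,
        radii_um=np.array(radii)[order],
        node_types=np.array(types)[order],
        cell_id=cell_id,
    )


# ---------------------------------------------------------------------------
# Run records
# ---------------------------------------------------------------------------

@dataclass
class RunRecord:
    """Append-only log of executed pipeline stages with parameter snapshots."""

    entries: list[dict] = field(default_factory=list)

    def stage_names(self) -> list[str]:
        return [e["stage"] for e in self.entries]


def append_record(
    record: RunRecord,
    stage: str,
    params: dict,
    status: str = "ok",
    t_start: float = 0.0,
    t_end: float = 0.0,
    inputs: str = "",
    outputs: str = "",
) -> RunRecord:
    """Append one stage entry; duplicate stage ids within a run are an error."""
    if stage in record.stage_names():
        raise ValueError(f"stage {stage!r} already recorded in this run")
    if t_end < t_start:
        raise ValueError(f"stage {stage!r}: end time {t_end} precedes start {t_start}")
    if record.entries and t_start < record.entries[-1]["t_start"]:
        raise ValueError(f"stage {stage!r}: out-of-order timestamp {t_start}")
    record.entries.append(
        dict(stage=stage, params=dict(params), status=status,
             t_start=float(t_start), t_end=float(t_end), inputs=inputs, outputs=outputs)
    )
    return record


def save_record(record: RunRecord, csv_path: str, log_path: str | None = None) -> None:
    """Serialize as machine-readable CSV plus a human-readable text log."""
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stage", "status", "t_start", "t_end", "inputs", "outputs", "params_json"])
        for e in record.entries:
            w.writerow([e["stage"], e["status"], e["t_start"], e["t_end"],
                        e["inputs"], e["outputs"], json.dumps(e["params"], sort_keys=True)])
    if log_path:
        with open(log_path, "w") as fh:
            for e in record.entries:
                fh.write(f"[{e['t_start']:.3f} -> {e['t_end']:.3f}] {e['stage']}: "
                         f"{e['status']}  params={json.dumps(e['params'], sort_keys=True)}\n")


def load_record(csv_path: str) -> RunRecord:
    rec = RunRecord()
    with open(csv_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for r in rows:
        append_record(rec, r["stage"], json.loads(r["params_json"]), r["status"],
                      float(r["t_start"]), float(r["t_end"]), r["inputs"], r["outputs"])
    return rec
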