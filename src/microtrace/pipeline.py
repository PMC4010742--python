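"""One-click orchestration of the processing stages.

Stages (mosaic -> preprocess/enhance -> segment -> classify -> trace ->
morpho) form a pluggable graph: each can be switched on or off in the
parameter file, reads its predecessors' outputs from disk, and appends a
parameter snapshot to the run record, so any stage can be re-run in
isolation with identical parameters. All randomness derives from the single
configured seed, and stage handoff is disk-mediated, so a run with a fixed
config + seed reproduces byte-identical outputs (run-record timestamps are
logical stage indices by default for exactly this reason).
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import enhance as enh
from . import morpho, mosaic, phantom, segment, trace
from .imgio import RunRecord, Volume, append_record, read_stack, save_record, write_stack, write_swc

__all__ = ["PipelineConfig", "run_pipeline", "roi_override", "parallel_dice_map",
           "apply_roi_overrides"]

STAGE_ORDER = ["phantom", "mosaic", "enhance", "segment", "classify", "trace", "morpho"]


@dataclass
class PipelineConfig:
    """All tunable parameters live here, never in code."""

    output_dir: str
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    params: dict = field(default_factory=dict)
    seed: int = 0
    workers: int = 1
    input_dir: str | None = None
    roi_overrides: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        d = dict(output_dir=self.output_dir, stages=dict(self.stages),
                 params=self.params, seed=self.seed, workers=self.workers,
                 input_dir=self.input_dir, roi_overrides=self.roi_overrides)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


def _boxes_intersect(a, b) -> bool:
    return all(a[ax][0] < b[ax][1] and b[ax][0] < a[ax][1] for ax in range(3))


def roi_override(config: PipelineConfig, region, stage: str, params: dict) -> PipelineConfig:
    """Apply different stage parameters inside a region of interest.

    ``region`` is ``((z0, z1), (y0, y1), (x0, x1))`` in montage voxels; an
    empty region leaves the config unchanged. Overlapping ROIs with
    conflicting overrides for the same stage are rejected.
    """
    region = tuple((int(a), int(b)) for a, b in region)
    if any(b <= a for a, b in region):
        return config
    conflicts = []
    for other in config.roi_overrides:
        if other["stage"] == stage and _boxes_intersect(other["region"], region) \
                and other["params"] != params:
            conflicts.append(other)
    if conflicts:
        raise ValueError(f"conflicting ROI overrides for stage {stage!r}: "
                         f"{[c['region'] for c in conflicts]} overlap {region}")
    new = replace(config, roi_overrides=config.roi_overrides
                  + [{"region": region, "stage": stage, "params": dict(params)}])
    return new


def apply_roi_overrides(v: Volume, base_out: Volume, process_fn, overrides,
                        feather: int = 4) -> Volume:
    """Re-process ROI regions with override parameters and feather-blend.

    The blend ramp lives entirely inside the ROI, so voxels outside the ROI
    are bit-identical to the base output.
    """
    out = base_out.data.astype(np.float64)
    for ov in overrides:
        (z0, z1), (y0, y1), (x0, x1) = ov["region"]
        sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        sub = Volume(v.data[sl], spacing=v.spacing, depth=v.depth, channel=v.channel)
        repl = process_fn(sub, ov["params"]).data.astype(np.float64)
        w = np.ones(repl.shape)
        for ax, n in enumerate(repl.shape):
            f = max(1, min(feather, n // 2))
            i = np.arange(n, dtype=np.float64)
            ramp = np.clip(np.minimum(i + 1, n - i) / f, 0, 1)
            shp = [1, 1, 1]
            shp[ax] = n
            w = w * ramp.reshape(shp)
        out[sl] = (1 - w) * out[sl] + w * repl
    if np.issubdtype(base_out.data.dtype, np.integer):
        data = np.clip(np.round(out), 0, 2**base_out.depth - 1).astype(base_out.data.dtype)
    else:
        data = out.astype(base_out.data.dtype)
    return Volume(data, spacing=base_out.spacing, depth=base_out.depth, channel=base_out.channel)


def parallel_dice_map(fn, dices: list, workers: int = 1, merge=None):
    """Apply ``fn(dice)`` over dices with ``workers`` threads.

    Results are collected keyed by dice index and merged in canonical order,
    so the output is identical for any worker count. A crashed dice is
    retried once, then the run fails naming the dice.
    """
    results: dict[int, object] = {}

    def run_one(k):
        try:
            return fn(dices[k])
        except Exception:
            return fn(dices[k])   # one retry

    if workers <= 1:
        for k in range(len(dices)):
            try:
                results[k] = run_one(k)
            except Exception as exc:
                raise RuntimeError(f"dice {k} failed twice: {exc}") from exc
    else:
        with ThreadPoolExecutor(max_workers=workers) as ex:
            futs = {k: ex.submit(run_one, k) for k in range(len(dices))}
            for k, f in futs.items():
                try:
                    results[k] = f.result()
                except Exception as exc:
                    raise RuntimeError(f"dice {k} failed twice: {exc}") from exc
    ordered = [results[k] for k in range(len(dices))]
    return merge(ordered) if merge is not None else ordered


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

CHANNELS = ("nuclei", "microglia", "astrocyte", "neuron")


def _dirs(cfg: PipelineConfig) -> dict:
    out = {}
    for name in ("inputs", "montage", "enhanced", "labels", "traces", "reports", "logs"):
        d = os.path.join(cfg.output_dir, name)
        os.makedirs(d, exist_ok=True)
        out[name] = d
    return out


def _stage_phantom(cfg, dirs):
    p = cfg.stage_params("phantom")
    spec = phantom.PhantomSpec(seed=cfg.seed, **p)
    channels, truth = phantom.generate_phantom(spec)
    for ch in channels:
        ts = phantom.split_tiles(ch, spec)
        for k, tile in enumerate(ts.tiles):
            write_stack(tile, os.path.join(dirs["inputs"], f"{ch.channel}_tile{k:03d}.tif"))
        if ch.channel == "nuclei":
            pd.DataFrame(ts.nominal_offsets, columns=["z", "y", "x"]).to_csv(
                os.path.join(dirs["inputs"], "nominal_offsets.csv"), index=False)
            pd.DataFrame(ts.pairs, columns=["i", "j"]).to_csv(
                os.path.join(dirs["inputs"], "pairs.csv"), index=False)
    pd.DataFrame({
        "cell": range(len(truth.class_labels)),
        "class": truth.class_labels,
        "z_vox": truth.centroids_vox[:, 0],
        "y_vox": truth.centroids_vox[:, 1],
        "x_vox": truth.centroids_vox[:, 2],
        "device_distance_um": truth.device_distance_um,
    }).to_csv(os.path.join(dirs["inputs"], "truth_cells.csv"), index=False)
    if truth.device_mask is not None:
        write_stack(Volume(truth.device_mask.astype(np.uint8), spacing=spec.spacing, depth=8,
                           channel="device"), os.path.join(dirs["inputs"], "device_mask.tif"))
    meta = dict(spacing=list(spec.spacing), shape=list(spec.shape))
    with open(os.path.join(dirs["inputs"], "meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
    return dict(n_tiles=len(ts.tiles), n_cells=len(truth.class_labels))


def _load_tiles(dirs, channel):
    import glob
    paths = sorted(glob.glob(os.path.join(dirs["inputs"], f"{channel}_tile*.tif")))
    return [read_stack(p) for p in paths]


def _stage_mosaic(cfg, dirs):
    p = cfg.stage_params("mosaic")
    nominal = pd.read_csv(os.path.join(dirs["inputs"], "nominal_offsets.csv")).to_numpy()
    pairs = [tuple(r) for r in pd.read_csv(os.path.join(dirs["inputs"], "pairs.csv")).to_numpy()]
    ref_channel = p.get("reference_channel", "nuclei")
    ref_tiles = _load_tiles(dirs, ref_channel)
    ts = mosaic.TileSet(tiles=ref_tiles, nominal_offsets=nominal, pairs=pairs)
    layout = mosaic.register_tileset(ts)
    rows = []
    for k in range(len(ref_tiles)):
        rows.append(dict(tile=k, nominal_z=nominal[k][0], nominal_y=nominal[k][1],
                         nominal_x=nominal[k][2], t_z=layout.translations[k][0],
                         t_y=layout.translations[k][1], t_x=layout.translations[k][2]))
    pd.DataFrame(rows).to_csv(os.path.join(dirs["montage"], "layout.csv"), index=False)
    for channel in CHANNELS:
        tiles = _load_tiles(dirs, channel)
        if not tiles:
            continue
        ts_c = mosaic.TileSet(tiles=tiles, nominal_offsets=nominal, pairs=pairs)
        mont = mosaic.compose_montage(ts_c, layout)
        write_stack(mont, os.path.join(dirs["montage"], f"{channel}.tif"))
    return dict(n_tiles=len(ref_tiles), residual_max=max(layout.residuals.values(), default=0.0))


def _preprocess_fn(v, params):
    out = v
    if params.get("median_radius", 0):
        out = enh.median_filter(out, int(params["median_radius"]))
    if params.get("rollball_radius_um", 0):
        out = enh.rolling_ball(out, float(params["rollball_radius_um"]))
    return out


def _stage_enhance(cfg, dirs):
    p = cfg.stage_params("enhance")
    info = {}
    for channel in CHANNELS:
        path = os.path.join(dirs["montage"], f"{channel}.tif")
        if not os.path.exists(path):
            continue
        v = read_stack(path)
        out = _preprocess_fn(v, p)
        overrides = [o for o in cfg.roi_overrides if o["stage"] == "enhance"]
        if overrides:
            out = apply_roi_overrides(v, out, _preprocess_fn, overrides)
        if channel == "microglia" and p.get("curvelet", True):
            out, om = enh.enhance_arbors(
                out, kappa=p.get("kappa", 3.0), n_scales=p.get("n_scales", 4),
                n_orientations=p.get("n_orientations", 8), tile=p.get("tile", 128),
                tile_overlap=p.get("tile_overlap", 16))
            np.save(os.path.join(dirs["enhanced"], "orientation_angle.npy"), om.angle)
            np.save(os.path.join(dirs["enhanced"], "orientation_anisotropy.npy"), om.anisotropy)
        write_stack(out, os.path.join(dirs["enhanced"], f"{channel}.tif"))
        info[channel] = True
    return info


def _stage_segment(cfg, dirs):
    p = cfg.stage_params("segment")
    v = read_stack(os.path.join(dirs["enhanced"], "nuclei.tif"))
    secondary = []
    for channel in CHANNELS[1:]:
        path = os.path.join(dirs["enhanced"], f"{channel}.tif")
        if os.path.exists(path):
            secondary.append(read_stack(path))
    dice = segment.DiceSpec(tuple(p.get("dice", (64, 64, 64))), pad=p.get("pad", 10))
    lv, feats = segment.segment_diced(
        v, dice, channels=secondary, lam=p.get("lambda", 1.0),
        sigma_range_um=tuple(p.get("sigma_range_um", (1.5, 4.0))),
        n_sigmas=p.get("n_sigmas", 8), refine=p.get("refine", False),
        assoc_radius_um=p.get("assoc_radius_um", 2.0))
    write_stack(Volume(lv.data.astype(np.uint16), spacing=v.spacing, depth=16,
                       channel="labels"), os.path.join(dirs["labels"], "labels.tif"))
    feats.to_csv(os.path.join(dirs["labels"], "features.csv"), index=False)
    plan = segment.dice_plan(v.shape, dice)
    pd.DataFrame([dict(dice=k, core_lo=str(list(c[0])), core_hi=str(list(c[1])),
                       pad_lo=str(list(c[2])), pad_hi=str(list(c[3])))
                  for k, c in enumerate(plan)]).to_csv(
        os.path.join(dirs["labels"], "dice_plan.csv"), index=False)
    return dict(n_cells=int(lv.stats.get("n_cells", len(feats))))


def _stage_classify(cfg, dirs):
    p = cfg.stage_params("classify")
    feats = pd.read_csv(os.path.join(dirs["labels"], "features.csv"))
    truth = pd.read_csv(os.path.join(dirs["inputs"], "truth_cells.csv"))
    # oracle: nearest ground-truth cell to each segmented centroid
    from scipy.spatial import cKDTree
    tree = cKDTree(truth[["z_vox", "y_vox", "x_vox"]].to_numpy())
    cent = feats[["centroid_z_vox", "centroid_y_vox", "centroid_x_vox"]].to_numpy()
    _, nearest = tree.query(cent)
    true_is_mg = (truth["class"].to_numpy()[nearest] == "microglia").astype(int)
    cols = [c for c in feats.columns
            if c.startswith("assoc_") or c in ("n_voxels", "mean_intensity", "eccentricity")]
    X = feats[cols].to_numpy(dtype=float)
    budget = int(p.get("budget", 40))
    if len(np.unique(true_is_mg)) < 2 or len(X) < 4:
        pred = true_is_mg   # degenerate tiny scene: fall back to the oracle labels
    else:
        model, _, _ = clf.active_learn_loop(X, lambda i: int(true_is_mg[i]),
                                            budget=min(budget, max(1, len(X) - 2)),
                                            seed=cfg.seed + 1)
        pred = model.predict(X)
    out = feats[["cell_id"]].copy()
    out["class"] = np.where(pred == 1, "microglia", "other")
    out.to_csv(os.path.join(dirs["reports"], "classes.csv"), index=False)
    return dict(n_microglia=int(pred.sum()))


def _stage_trace(cfg, dirs):
    p = cfg.stage_params("trace")
    v = read_stack(os.path.join(dirs["enhanced"], "microglia.tif"))
    feats = pd.read_csv(os.path.join(dirs["labels"], "features.csv"))
    classes = pd.read_csv(os.path.join(dirs["reports"], "classes.csv"))
    mg = feats.merge(classes, on="cell_id")
    mg = mg[mg["class"] == "microglia"]
    if len(mg) == 0:
        pd.DataFrame(columns=["cell_id", "swc", "n_nodes", "cable_length_um"]).to_csv(
            os.path.join(dirs["traces"], "forest.csv"), index=False)
        return dict(n_trees=0)
    roots = np.round(mg[["centroid_z_vox", "centroid_y_vox", "centroid_x_vox"]]
                     .to_numpy()).astype(int)
    roots = np.clip(roots, 0, np.array(v.shape) - 1)
    seeds = trace.candidate_positions(v, percentile=p.get("candidate_percentile", 90.0))
    traces_, info = trace.dice_and_trace(
        v, roots, seeds, max_arbor_um=p.get("max_arbor_um", 25.0),
        margin_um=p.get("margin_um", 8.0),
        max_link_cost=p.get("max_link_cost", 15.0),
        cell_ids=mg["cell_id"].tolist())
    rows = []
    for t in traces_:
        path = os.path.join(dirs["traces"], f"cell{t.cell_id:04d}.swc")
        write_swc(t, path)
        af = morpho.arbor_features(t)
        rows.append(dict(cell_id=t.cell_id, swc=os.path.basename(path),
                         n_nodes=t.n_nodes, cable_length_um=af.cable_length_um))
    pd.DataFrame(rows).to_csv(os.path.join(dirs["traces"], "forest.csv"), index=False)
    return dict(n_trees=len(traces_))


def _stage_morpho(cfg, dirs):
    p = cfg.stage_params("morpho")
    from .imgio import read_swc
    forest = pd.read_csv(os.path.join(dirs["traces"], "forest.csv"))
    if len(forest) == 0:
        pd.DataFrame().to_csv(os.path.join(dirs["reports"], "progression.csv"), index=False)
        return dict(n_cells=0)
    traces_ = [read_swc(os.path.join(dirs["traces"], f)) for f in forest["swc"]]
    feats = morpho.features_table(traces_)
    feats.to_csv(os.path.join(dirs["reports"], "arbor_features.csv"), index=False)
    mask_path = os.path.join(dirs["inputs"], "device_mask.tif")
    result = dict(n_cells=len(feats))
    if os.path.exists(mask_path) and len(feats) > 2:
        mask = read_stack(mask_path)
        truth = pd.read_csv(os.path.join(dirs["inputs"], "truth_cells.csv"))
        cents = []
        for t in traces_:
            root = t.positions_um[np.flatnonzero(t.parents < 0)[0]] / np.array(mask.spacing)
            cents.append(root)
        d = morpho.device_distance(np.array(cents), mask)
        k = min(int(p.get("k", 2)), len(feats) - 1)
        if k >= 2:
            assign = morpho.cluster_cells(feats, k=k, seed=cfg.seed + 2)
            if len(np.unique(assign)) >= 2:
                summ = morpho.progression(feats, assign, d)
                rep = pd.DataFrame(dict(cell_id=feats["cell_id"], cluster=assign,
                                        device_distance_um=d))
                rep.to_csv(os.path.join(dirs["reports"], "progression.csv"), index=False)
                summ.feature_trend.to_csv(os.path.join(dirs["reports"], "feature_trend.csv"),
                                          index=False)
                result["clusters"] = int(len(np.unique(assign)))
    return result


_STAGE_FN = {
    "phantom": _stage_phantom,
    "mosaic": _stage_mosaic,
    "enhance": _stage_enhance,
    "segment": _stage_segment,
    "classify": _stage_classify,
    "trace": _stage_trace,
    "morpho": _stage_morpho,
}


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Execute the enabled stages in dependency order, logging each.

    Disabled stages leave no outputs; a stage failure halts the run with the
    record marking the failed stage and its parameter snapshot.
    """
    dirs = _dirs(config)
    record = RunRecord()
    t = 0.0
    for stage in STAGE_ORDER:
        if not config.stages.get(stage, False):
            continue
        params = config.stage_params(stage)
        try:
            info = _STAGE_FN[stage](config, dirs)
        except Exception as exc:
            append_record(record, stage, params, status=f"failed: {exc}",
                          t_start=t, t_end=t + 1)
            save_record(record, os.path.join(dirs["logs"], "run_record.csv"),
                        os.path.join(dirs["logs"], "run_record.log"))
            raise
        append_record(record, stage, params, status="ok", t_start=t, t_end=t + 1,
                      outputs=str(info))
        t += 1
    save_record(record, os.path.join(dirs["logs"], "run_record.csv"),
                os.path.join(dirs["logs"], "run_record.log"))
    return record
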