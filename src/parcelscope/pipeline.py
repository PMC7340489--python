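"""Make-style incremental orchestration of the processing chain.

The workflow is a per-site directed acyclic graph: each scene is registered to
the master, cloud- and tree-masked, and reduced to per-field signature CSVs.
Reprocessing only what is necessary is achieved the way Make does it, but with
content fingerprints instead of timestamps: every stage output is a node keyed
by a SHA-256 hash of its input files plus a canonical encoding of its
parameters, and a node is stale when its fingerprint changed, its output is
missing, or any ancestor is stale. Dependency rules are generated
programmatically per scene (no reliance on filename patterns), so adding one
scene to a finished site schedules exactly that scene's chain.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import yaml

from . import coregister, field_stats, masks, raster_io
from .errors import ConfigError

log = logging.getLogger("parcelscope")


@dataclass
class RunConfig:
    """Site-level configuration, loadable from YAML."""

    scenes_dir: str
    fields_path: str
    out_dir: str
    master: str = "auto"
    seed: int = 0
    model: str = "translation"
    search_radius_m: float = 20.0
    inlier_tol_m: float = 3.0
    match_min_score_frac: float = 0.4
    resampling: str = "nearest"
    detector: coregister.DetectorConfig = field(default_factory=coregister.DetectorConfig)
    tree: masks.TreeMaskConfig = field(default_factory=masks.TreeMaskConfig)
    extraction: field_stats.ExtractionParams = field(default_factory=field_stats.ExtractionParams)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = coregister.DetectorConfig(**raw.pop("detector", {}))
        tree = masks.TreeMaskConfig(**raw.pop("tree", {}))
        extraction_raw = raw.pop("extraction", {})
        vi = field_stats.VIParams(**extraction_raw.pop("vi", {}))
        extraction = field_stats.ExtractionParams(vi=vi, **extraction_raw)
        return cls(detector=det, tree=tree, extraction=extraction, **raw)

    def params_dict(self) -> dict:
        d = asdict(self)
        d.pop("scenes_dir")
        d.pop("out_dir")
        d.pop("log_level")
        return d


@dataclass
class Node:
    name: str
    stage: str
    inputs: list[Path]
    outputs: list[Path]
    params: dict
    deps: list[str]
    func: Callable[[], None]


@dataclass
class PipelinePlan:
    nodes: dict[str, Node]
    order: list[str]  # topological
    stale: set[str]
    master_id: str


def _fingerprint(node: Node) -> str | None:
    """Hash of input file contents + canonical parameters; None if an input is absent."""
    h = hashlib.sha256()
    for p in node.inputs:
        if not Path(p).exists():
            return None
        h.update(Path(p).read_bytes())
    h.update(json.dumps(node.params, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _toposort(nodes: dict[str, Node]) -> list[str]:
    order: list[str] = []
    seen: dict[str, int] = {}

    def visit(name: str) -> None:
        state = seen.get(name, 0)
        if state == 1:
            raise ConfigError("internal error: cyclic dependency in pipeline graph")
        if state == 2:
            return
        seen[name] = 1
        for d in nodes[name].deps:
            visit(d)
        seen[name] = 2
        order.append(name)

    for name in sorted(nodes):
        visit(name)
    return order


def _discover_scenes(scenes_dir: Path) -> list[tuple[str, Path, Path]]:
    out = []
    for tif in sorted(scenes_dir.glob("*.tif")):
        meta = tif.with_suffix(".json")
        if meta.exists():
            out.append((tif.stem, tif, meta))
    if not out:
        raise ConfigError(f"scenes_dir {scenes_dir}: no <id>.tif + <id>.json scene pairs found")
    return out


def build_plan(config: RunConfig, state: dict[str, str]) -> PipelinePlan:
    """Construct the per-site dependency graph and mark stale nodes.

    The master is chosen from the scene metadata at plan time; its identity is
    a parameter of every downstream node, so a master change invalidates the
    whole site while a new non-master scene invalidates only its own chain.
    """
    scenes_dir = Path(config.scenes_dir)
    out_dir = Path(config.out_dir)
    fields_path = Path(config.fields_path)
    scene_list = _discover_scenes(scenes_dir)
    metas = {sid: raster_io.SceneMetadata.from_json(mp) for sid, _, mp in scene_list}
    if config.master == "auto":
        master_id = coregister.select_master(list(metas.values()))
    else:
        master_id = config.master
        if master_id not in metas:
            raise ConfigError(f"master scene {master_id!r} not found in scenes_dir")

    reg_dir = out_dir / "registered"
    mask_dir = out_dir / "masks"
    csv_dir = out_dir / "csv"
    master_tif = scenes_dir / f"{master_id}.tif"
    master_meta_path = scenes_dir / f"{master_id}.json"
    reg_master = reg_dir / f"{master_id}.tif"
    blobs_path = out_dir / "blobs_master.json"
    tree_master_path = mask_dir / "tree_master.tif"

    det_params = asdict(config.detector)
    tree_params = asdict(config.tree)
    reg_params = {
        "master_id": master_id,
        "model": config.model,
        "search_radius_m": config.search_radius_m,
        "inlier_tol_m": config.inlier_tol_m,
        "match_min_score_frac": config.match_min_score_frac,
        "resampling": config.resampling,
        "seed": config.seed,
        "detector": det_params,
    }

    nodes: dict[str, Node] = {}

    def _register_scene(sid: str, tif: Path, meta_path: Path) -> None:
        for d in (reg_dir, mask_dir, csv_dir):
            d.mkdir(parents=True, exist_ok=True)
        scene, meta = raster_io.read_scene(tif, meta_path)
        out_tif = reg_dir / f"{sid}.tif"
        if sid == master_id:
            raster_io.write_scene(scene, out_tif)
            return
        master_scene, master_meta = raster_io.read_scene(master_tif, master_meta_path)
        mblobs = coregister.detect_blobs(master_scene, "nir1", config.detector)
        tblobs = coregister.detect_blobs(scene, "nir1", config.detector)
        mblobs = coregister.filter_blobs_near_bright(master_scene, mblobs)
        tblobs = coregister.filter_blobs_near_bright(scene, tblobs)
        mblobs = coregister.correct_parallax(mblobs, master_meta, config.tree.canopy_height_m)
        tblobs = coregister.correct_parallax(tblobs, meta, config.tree.canopy_height_m)
        pairs = coregister.match_tiepoints(
            mblobs, tblobs, config.search_radius_m, min_score_frac=config.match_min_score_frac
        )
        corr = coregister.estimate_correction(
            pairs, config.model, config.inlier_tol_m, seed=config.seed
        )
        corrected = coregister.apply_correction(scene, corr, config.resampling)
        raster_io.write_scene(corrected, out_tif)
        (out_dir / f"correction_{sid}.json").write_text(
            json.dumps(
                {
                    "model": corr.model,
                    "parameters": list(corr.parameters),
                    "rmse_x_m": corr.rmse_x_m,
                    "rmse_y_m": corr.rmse_y_m,
                    "n_inliers": corr.n_inliers,
                    "n_pairs": len(pairs),
                },
                indent=2,
            )
        )

    def _blobs_master() -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        scene, _ = raster_io.read_scene(reg_master, master_meta_path)
        blobs = coregister.detect_blobs(scene, "nir1", config.detector)
        blobs_path.write_text(
            json.dumps([[b.x_m, b.y_m, b.sigma_m, b.response] for b in blobs])
        )

    def _cloud(sid: str) -> None:
        scene, meta = raster_io.read_scene(reg_dir / f"{sid}.tif", scenes_dir / f"{sid}.json")
        m = masks.cloud_mask(scene, meta)
        raster_io.write_mask_raster(
            m.grid, scene.geotransform, scene.crs_id, mask_dir / f"cloud_{sid}.tif"
        )

    def _tree_master() -> None:
        scene, _ = raster_io.read_scene(reg_master, master_meta_path)
        blobs = [
            coregister.Blob(*vals) for vals in json.loads(blobs_path.read_text())
        ]
        m = masks.tree_mask_master(scene, blobs, config.tree, master_id)
        raster_io.write_mask_raster(m.grid, scene.geotransform, scene.crs_id, tree_master_path)

    def _tree(sid: str) -> None:
        grid, gt, crs = raster_io.read_mask_raster_with_transform(tree_master_path)
        meta = raster_io.SceneMetadata.from_json(scenes_dir / f"{sid}.json")
        master_mask = masks.Mask(grid, "tree", master_id, (gt[2], gt[3]))
        adapted = masks.adapt_tree_mask(master_mask, meta, config.tree)
        raster_io.write_mask_raster(adapted.grid, gt, crs, mask_dir / f"tree_{sid}.tif")

    def _stats(sid: str) -> None:
        scene, meta = raster_io.read_scene(reg_dir / f"{sid}.tif", scenes_dir / f"{sid}.json")
        fields = raster_io.read_fields(fields_path)
        _, _, pw, ph = scene.geotransform
        cloud = masks.Mask(
            raster_io.read_mask_raster(mask_dir / f"cloud_{sid}.tif"), "cloud", sid, (pw, ph)
        )
        tree = masks.Mask(
            raster_io.read_mask_raster(mask_dir / f"tree_{sid}.tif"), "tree", sid, (pw, ph)
        )
        spectral, texture = field_stats.extract_all(
            scene, meta, fields, [cloud, tree], config.extraction
        )
        raster_io.write_spectral_csv(spectral, csv_dir / f"{sid}_spectral.csv")
        raster_io.write_texture_csv(texture, csv_dir / f"{sid}_texture.csv")

    for sid, tif, meta_path in scene_list:
        reg_inputs = [tif, meta_path] if sid == master_id else [tif, meta_path, master_tif, master_meta_path]
        nodes[f"register:{sid}"] = Node(
            name=f"register:{sid}",
            stage="register",
            inputs=reg_inputs,
            outputs=[reg_dir / f"{sid}.tif"],
            params=reg_params,
            deps=[],
            func=(lambda s=sid, t=tif, m=meta_path: _register_scene(s, t, m)),
        )
        nodes[f"cloud_mask:{sid}"] = Node(
            name=f"cloud_mask:{sid}",
            stage="cloud_mask",
            inputs=[reg_dir / f"{sid}.tif", meta_path],
            outputs=[mask_dir / f"cloud_{sid}.tif"],
            params={"master_id": master_id},
            deps=[f"register:{sid}"],
            func=(lambda s=sid: _cloud(s)),
        )
    nodes["tree_blobs:master"] = Node(
        name="tree_blobs:master",
        stage="tree_blobs",
        inputs=[reg_master, master_meta_path],
        outputs=[blobs_path],
        params={"master_id": master_id, "detector": det_params},
        deps=[f"register:{master_id}"],
        func=_blobs_master,
    )
    nodes["tree_mask:master"] = Node(
        name="tree_mask:master",
        stage="tree_mask",
        inputs=[reg_master, blobs_path],
        outputs=[tree_master_path],
        params={"master_id": master_id, "tree": tree_params},
        deps=["tree_blobs:master", f"register:{master_id}"],
        func=_tree_master,
    )
    for sid, tif, meta_path in scene_list:
        nodes[f"tree_mask:{sid}"] = Node(
            name=f"tree_mask:{sid}",
            stage="tree_mask",
            inputs=[tree_master_path, meta_path],
            outputs=[mask_dir / f"tree_{sid}.tif"],
            params={"master_id": master_id, "tree": tree_params},
            deps=["tree_mask:master"],
            func=(lambda s=sid: _tree(s)),
        )
        nodes[f"stats:{sid}"] = Node(
            name=f"stats:{sid}",
            stage="stats",
            inputs=[
                reg_dir / f"{sid}.tif",
                meta_path,
                mask_dir / f"cloud_{sid}.tif",
                mask_dir / f"tree_{sid}.tif",
                fields_path,
            ],
            outputs=[csv_dir / f"{sid}_spectral.csv", csv_dir / f"{sid}_texture.csv"],
            params={"master_id": master_id, "extraction": asdict(config.extraction)},
            deps=[f"register:{sid}", f"cloud_mask:{sid}", f"tree_mask:{sid}"],
            func=(lambda s=sid: _stats(s)),
        )

    order = _toposort(nodes)
    stale: set[str] = set()
    for name in order:
        node = nodes[name]
        if any(d in stale for d in node.deps):
            stale.add(name)
            continue
        fp = _fingerprint(node)
        if fp is None or fp != state.get(name) or not all(Path(o).exists() for o in node.outputs):
            stale.add(name)
    return PipelinePlan(nodes=nodes, order=order, stale=stale, master_id=master_id)


def load_state(path: str | Path) -> dict[str, str]:
    p = Path(path)
    if p.exists():
        return json.loads(p.read_text())
    return {}


def save_state(state: dict[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(state, indent=2, sort_keys=True))


def run(plan: PipelinePlan, config: RunConfig, state: dict[str, str]) -> dict:
    """Execute the stale nodes in topological order.

    Returns an execution report; nodes downstream of a failure are skipped and
    the report's ``ok`` flag is False. ``state`` is updated in place with the
    fingerprints of the successfully executed nodes.
    """
    report: dict = {
        "master_id": plan.master_id,
        "seed": config.seed,
        "stages": {},
        "ok": True,
        "n_executed": 0,
    }
    failed: set[str] = set()
    for name in plan.order:
        node = plan.nodes[name]
        if any(d in failed for d in node.deps):
            failed.add(name)
            report["stages"][name] = {"status": "skipped"}
            continue
        if name not in plan.stale:
            report["stages"][name] = {"status": "up-to-date"}
            continue
        t0 = time.perf_counter()
        try:
            node.func()
            fp = _fingerprint(node)
            if fp is None:
                raise RuntimeError(f"{name}: inputs vanished during execution")
            state[name] = fp
            dt = time.perf_counter() - t0
            log.info("%s: executed in %.2fs", name, dt)
            report["stages"][name] = {"status": "executed", "seconds": round(dt, 3)}
            report["n_executed"] += 1
        except Exception as exc:  # noqa: BLE001 - report and continue other branches
            log.error("%s: failed: %s", name, exc)
            state.pop(name, None)
            failed.add(name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            report["ok"] = False
    return report
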