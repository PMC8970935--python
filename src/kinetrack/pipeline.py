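"""End-to-end orchestration: scene -> preprocessing -> background ->
tracking -> damage classification -> graph feature management.

Batch (offline) processing with a single structured config; every stage
writes its artifacts under the output directory and records them in a
:class:`RunReport` manifest.  Runs are fully deterministic given the
config and its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import background as bg
from . import damage, graphnet, imageproc, synthetic, tracker
from .frames import load_frames, write_image

log = logging.getLogger("kinetrack")


@dataclass
class PipelineConfig:
    """All stage parameters, with documented ranges.

    ``frames_dir=None`` makes the run start from the synthetic generator's
    default scene.  Stage toggles switch whole stages off; the graph stage
    additionally requires tracking output.
    """

    frames_dir: str | None = None
    out_dir: str = "kinetrack_out"
    seed: int = 0
    n_frames: int = 40
    warmup_frames: int = 30
    # stage toggles
    run_background: bool = True
    run_moments: bool = True
    run_tracking: bool = True
    run_classify: bool = True
    run_graph: bool = True
    # background
    K: int = 3
    learning_rate: float = 0.05
    diff_threshold: float = 0.1
    # tracking
    n_bins: int = 16
    conf_ratio: float = 0.3
    init_window: tuple[float, float, float, float] | None = None  # r, c, hr, hc
    # classifier
    retention: float = damage.DEFAULT_RETENTION
    n_classes: int = 3
    n_train_per_class: int = 10
    n_test_per_class: int = 5
    # graph
    radius: float = 20.0
    embedding_dim: int = 3


_RANGES = {
    "K": (lambda v: v >= 1, "must be >= 1"),
    "learning_rate": (lambda v: 0 < v < 1, "must be in (0, 1)"),
    "diff_threshold": (lambda v: 0 < v <= 1, "must be in (0, 1]"),
    "n_bins": (lambda v: v >= 2, "must be >= 2"),
    "conf_ratio": (lambda v: 0 < v < 1, "must be in (0, 1)"),
    "retention": (lambda v: 0 < v <= 1, "must be in (0, 1]"),
    "radius": (lambda v: v > 0, "must be positive"),
    "n_frames": (lambda v: v >= 2, "must be >= 2"),
    "warmup_frames": (lambda v: v >= 0, "must be >= 0"),
    "n_classes": (lambda v: v >= 2, "must be >= 2"),
    "n_train_per_class": (lambda v: v >= 2, "must be >= 2"),
    "n_test_per_class": (lambda v: v >= 1, "must be >= 1"),
    "embedding_dim": (lambda v: v >= 1, "must be >= 1"),
}


def validate_config(raw: dict) -> PipelineConfig | list[str]:
    """Validate a parsed config mapping.

    Returns the typed :class:`PipelineConfig` when everything checks out, or
    the full list of violation strings (unknown keys and out-of-range
    values, all of them) otherwise.
    """
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    violations = [f"unknown key: {k}" for k in raw if k not in known]
    merged = {k: v for k, v in raw.items() if k in known}
    cfg = PipelineConfig(**merged)
    for name, (ok, msg) in _RANGES.items():
        v = getattr(cfg, name)
        if not ok(v):
            violations.append(f"{name}={v}: {msg}")
    return violations if violations else cfg


def load_config(path: str | Path) -> PipelineConfig | list[str]:
    """Read a YAML config file and validate it."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        return ["config file must contain a mapping"]
    return validate_config(raw)


@dataclass
class RunReport:
    version: str = __version__
    params: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # name -> {records, seconds}
    manifest: dict = field(default_factory=dict)  # name -> file path(s)
    skipped: dict = field(default_factory=dict)  # name -> reason
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


def _setup_logging(out_dir: Path) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


class _Runner:
    """Runs the stage chain; shared state lives on the instance."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out_dir = Path(config.out_dir)
        self.report = RunReport(params=dataclasses.asdict(config))
        self.gt = None
        self.scene_cfg = synthetic.default_scene_config(config.seed,
                                                        config.n_frames)
        self.seq = None
        self.gray: list[np.ndarray] = []
        self.masks: list[np.ndarray] | None = None
        self.trk: tracker.Track | None = None

    def run_stage(self, name: str, fn) -> None:
        if not getattr(self.config, f"run_{name}"):
            self.report.skipped[name] = "disabled in config"
            log.info("stage %s skipped: disabled in config", name)
            return
        t0 = time.perf_counter()
        try:
            records = fn()
        except Exception:
            self.report.failed_stage = name
            self.report.to_json(self.out_dir / "report.json")
            log.exception("stage %s failed; partial outputs preserved", name)
            raise
        dt = time.perf_counter() - t0
        self.report.stages[name] = {"records": records, "seconds": round(dt, 4)}
        log.info("stage %s: %d records in %.2fs", name, records, dt)

    def load_input(self) -> None:
        cfg = self.config
        if cfg.frames_dir is None:
            self.seq, self.gt = synthetic.make_scene(self.scene_cfg)
            self.report.manifest.update(
                synthetic.export_scene(self.seq, self.gt, self.out_dir / "scene"))
            log.info("simulated default scene: %d frames %s",
                     len(self.seq), self.seq.shape)
        else:
            frames_dir = Path(cfg.frames_dir)
            if not frames_dir.is_dir():
                raise FileNotFoundError(f"frames directory not found: {frames_dir}")
            self.seq = load_frames(frames_dir)
            log.info("loaded %d frames from %s", len(self.seq), frames_dir)
        self.gray = [imageproc.to_gray(f) for f in self.seq]

    def stage_background(self) -> int:
        cfg = self.config
        params = bg.GMMParams(learning_rate=cfg.learning_rate)
        if cfg.frames_dir is None and cfg.warmup_frames > 0:
            warm = synthetic.render_background(self.scene_cfg, cfg.warmup_frames)
            model = bg.init_gmm(imageproc.to_gray(warm[0]), cfg.K, params)
            for f in warm.frames[1:]:
                bg.update_gmm(model, imageproc.to_gray(f))
        else:
            model = bg.init_gmm(self.gray[0], cfg.K, params)
        mask_dir = self.out_dir / "masks"
        self.masks = []
        for i, g in enumerate(self.gray):
            bg.update_gmm(model, g)
            fm = bg.foreground_mask(model, g, cfg.diff_threshold, i)
            self.masks.append(fm.mask)
            write_image(mask_dir / f"mask_{i:04d}.png", fm.mask.astype(float))
        self.report.manifest["masks"] = str(mask_dir)
        return len(self.masks)

    def stage_moments(self) -> int:
        source = self.masks if self.masks is not None else self.gray
        docs = {}
        for i, grid in enumerate(source):
            weights = np.asarray(grid, dtype=float)
            if weights.sum() <= 0:
                continue
            cm = imageproc.central_moments(weights, max_order=4)
            docs[i] = imageproc.moments_to_json(cm, imageproc.normalized_moments(cm))
        path = self.out_dir / "moments.json"
        path.write_text(json.dumps(docs, indent=2))
        self.report.manifest["moments"] = str(path)
        return len(docs)

    def stage_tracking(self) -> int:
        cfg = self.config
        if cfg.init_window is not None:
            r, c, hr, hc = cfg.init_window
        elif self.gt is not None:
            r, c = self.gt.trajectories[0, 0]
            hr, hc = self.scene_cfg.blobs[0].axes
        else:
            raise ValueError("init_window required when tracking real frames")
        params = tracker.TrackParams(n_bins=cfg.n_bins, conf_ratio=cfg.conf_ratio)
        self.trk = tracker.track(self.seq, tracker.SearchWindow((r, c), (hr, hc)),
                                 params)
        path = self.out_dir / "track.csv"
        self.trk.to_csv(path)
        self.report.manifest["track"] = str(path)
        return len(self.trk.windows)

    def stage_classify(self) -> int:
        cfg = self.config
        per_class = cfg.n_train_per_class + cfg.n_test_per_class
        samples, labels = synthetic.make_damage_gallery(
            cfg.n_classes, per_class, seed=cfg.seed)
        train_idx = [i for i in range(len(samples))
                     if i % per_class < cfg.n_train_per_class]
        test_idx = sorted(set(range(len(samples))) - set(train_idx))
        sub = damage.fit_subspace([samples[i] for i in train_idx], cfg.retention)
        gal = damage.build_gallery([samples[i] for i in train_idx],
                                   labels[train_idx], sub)
        correct = 0
        for i in test_idx:
            lab, _ = damage.classify_nn(damage.project(samples[i], sub), gal)
            correct += int(lab == labels[i])
        doc = damage.classification_report([samples[i] for i in test_idx],
                                           sub, gal)
        doc["accuracy"] = correct / len(test_idx)
        path = self.out_dir / "classification.json"
        path.write_text(json.dumps(doc, indent=2))
        self.report.manifest["classification"] = str(path)
        return len(test_idx)

    def stage_graph(self) -> int:
        cfg = self.config
        feats = np.array([[w.center[0], w.center[1], c]
                          for w, c in zip(self.trk.windows, self.trk.confidences)])
        graph = graphnet.build_detection_graph([self.trk], [feats], cfg.radius)
        layers = graphnet.random_layers([feats.shape[1], cfg.embedding_dim],
                                        seed=cfg.seed)
        H, _pooled = graphnet.manage_features(graph, layers)
        self.report.manifest.update(
            graphnet.export_graph(graph, self.out_dir / "graph"))
        emb_path = self.out_dir / "embeddings.csv"
        graphnet.export_embeddings(graph, H, emb_path)
        self.report.manifest["embeddings"] = str(emb_path)
        return graph.n_nodes

    def run(self) -> RunReport:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        _setup_logging(self.out_dir)
        self.load_input()
        self.run_stage("background", self.stage_background)
        self.run_stage("moments", self.stage_moments)
        self.run_stage("tracking", self.stage_tracking)
        self.run_stage("classify", self.stage_classify)
        if self.config.run_graph and self.trk is None:
            self.report.skipped["graph"] = "tracking produced no output"
            log.info("stage graph skipped: tracking produced no output")
        else:
            self.run_stage("graph", self.stage_graph)
        report_path = self.out_dir / "report.json"
        self.report.manifest["report"] = str(report_path)
        self.report.to_json(report_path)
        return self.report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order and write all artifacts."""
    return _Runner(config).run()
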