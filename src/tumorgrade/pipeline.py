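"""End-to-end orchestration of the two-phase grading pipeline.

Phase 1 takes every image from the labeled class folders through
nearest-neighbor resizing to the 600x600 standard, adaptive Wiener
denoising, adaptive thresholding and the 22x22 morphological opening;
phase 2 trains the binary CNN on the resulting masks of the ~90% training
split and evaluates it on the held-out ~10%.  A run writes the processed
masks, the model checkpoint, the per-epoch training report, the metric
suite and a machine-readable run manifest, and is bit-reproducible from
(dataset, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, UnidentifiedImageError

from . import __version__
from .bcnn import BCNNConfig, evaluate, save_model, train
from .binarize import StructuringElement, ThresholdParams, adaptive_threshold, clean_mask
from .imageio import read_gray, write_gray_png
from .phantom import CLASSES
from .preprocess import WienerParams, resize_nearest, wiener_filter

__all__ = ["PipelineConfig", "load_dataset", "split_dataset", "run_pipeline"]

log = logging.getLogger("tumorgrade")

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


def _label_from_folder(name: str) -> str | None:
    """Map a folder name to a class label, case-insensitively.

    Tolerates the " Tumor" suffix of the labeled-folder convention
    ("Grade I Tumor" ... "Healthy Brain MRI image").
    """
    n = " ".join(name.strip().lower().split())
    for cls in CLASSES:
        c = cls.lower()
        if n == c or n.startswith(c + " "):
            return cls
    return None


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of a full run, with reproducibility-relevant defaults.

    The threshold window (201 at the 600x600 standard size) is deliberately
    wider than the largest calibrated tumor blob so the neighborhood mean
    stays below the blob intensity across its whole interior; the
    `mean_plus_c` mode keeps near-constant tissue in the background.  The
    literal mean-minus-C rule remains available via ``threshold_mode``.
    """

    size: int = 600
    wiener_window: int = 3
    noise_variance: float | None = None  # None = estimate from the image
    threshold_window: int = 201
    threshold_c: float = 50.0
    threshold_mode: str = "mean_plus_c"
    se_size: int = 22
    split_fraction: float = 0.9
    seed: int = 0
    bcnn: BCNNConfig = field(default_factory=BCNNConfig)

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must lie in (0, 1)")

    def threshold_params(self) -> ThresholdParams:
        return ThresholdParams(window=self.threshold_window, c=self.threshold_c,
                               mode=self.threshold_mode)

    def wiener_params(self) -> WienerParams:
        return WienerParams(window_height=self.wiener_window,
                            window_width=self.wiener_window,
                            noise_variance=self.noise_variance)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML or JSON; the `bcnn` key nests BCNNConfig."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        bcnn = BCNNConfig(**data.pop("bcnn", {}))
        return cls(bcnn=bcnn, **data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_dataset(root_dir: str | Path) -> pd.DataFrame:
    """Scan labeled class folders into a manifest (path, label).

    One row per readable image, in deterministic lexicographic order;
    unreadable files are logged and skipped.
    """
    root = Path(root_dir)
    rows = []
    skipped = 0
    class_dirs = sorted((d for d in root.iterdir() if d.is_dir()),
                        key=lambda d: d.name)
    recognized = [(d, _label_from_folder(d.name)) for d in class_dirs]
    recognized = [(d, l) for d, l in recognized if l is not None]
    if not recognized:
        raise ValueError(f"no recognized class folders under {root}")
    for d, label in recognized:
        for p in sorted(d.iterdir(), key=lambda p: p.name):
            if not p.is_file() or p.suffix.lower() not in _IMAGE_SUFFIXES:
                if p.is_file():
                    skipped += 1
                    log.warning("skipping non-image file %s", p)
                continue
            try:
                with Image.open(p) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError):
                skipped += 1
                log.warning("skipping unreadable image %s", p)
                continue
            rows.append({"path": str(p), "label": label})
    if not rows:
        raise ValueError(f"no readable images under {root}")
    if skipped:
        log.warning("skipped %d unreadable/non-image files", skipped)
    return pd.DataFrame(rows, columns=["path", "label"])


def split_dataset(manifest: pd.DataFrame, fraction: float = 0.9,
                  seed: int = 0) -> pd.DataFrame:
    """Stratified train/test split: per class, round(fraction * n) go to train.

    The assignment is a seeded shuffle within each class and is fully
    reproducible; every class must have at least 2 images so both sides
    of the split are non-empty overall.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    out = manifest.copy()
    out["split"] = ""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 23]))
    for label in sorted(out["label"].unique()):
        idx = out.index[out["label"] == label].to_numpy()
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 images")
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(len(idx))
        out.loc[idx[perm[:n_train]], "split"] = "train"
        out.loc[idx[perm[n_train:]], "split"] = "test"
    return out


def _phase1_mask(img: np.ndarray, config: PipelineConfig,
                 se: StructuringElement) -> np.ndarray:
    resized = resize_nearest(img, config.size, config.size)
    denoised = wiener_filter(resized, config.wiener_params()).image
    binary = adaptive_threshold(denoised, config.threshold_params())
    return clean_mask(binary, se)


def run_pipeline(config: PipelineConfig, root_dir: str | Path,
                 out_dir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Returns the run report (also written as ``run_manifest.json``); the
    metric suite lands in ``metrics.json``, the per-epoch training history
    in ``train_report.csv``, the model in ``model.npz`` and the processed
    masks as 0/255 PNGs under ``masks/``.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        manifest = load_dataset(root_dir)
        log.info("stage=load images=%d", len(manifest))

        stage = "split"
        manifest = split_dataset(manifest, config.split_fraction, config.seed)
        log.info("stage=split train=%d test=%d",
                 (manifest["split"] == "train").sum(),
                 (manifest["split"] == "test").sum())

        stage = "phase1"
        se = StructuringElement.square(config.se_size)
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        masks: list[np.ndarray] = []
        t_stage = time.time()
        for i, row in manifest.iterrows():
            mask = _phase1_mask(read_gray(row["path"]), config, se)
            masks.append(mask)
            write_gray_png(mask_dir / f"{i:05d}_{Path(row['path']).stem}.png",
                           mask * 255)
        log.info("stage=phase1 masks=%d elapsed=%.1fs", len(masks),
                 time.time() - t_stage)

        stage = "train"
        is_train = (manifest["split"] == "train").to_numpy()
        train_masks = [m for m, t in zip(masks, is_train) if t]
        train_labels = list(manifest.loc[is_train, "label"])
        model, report = train(config.bcnn, train_masks, train_labels)
        report.to_frame().to_csv(out / "train_report.csv", index=False)
        save_model(model, out / "model.npz")
        log.info("stage=train epochs=%d final_acc=%.2f%%",
                 len(report.epochs), report.final_train_accuracy)

        stage = "evaluate"
        test_masks = [m for m, t in zip(masks, is_train) if not t]
        test_labels = list(manifest.loc[~is_train, "label"])
        metrics = evaluate(model, test_masks, test_labels)
        (out / "metrics.json").write_text(
            json.dumps(metrics.to_dict(), indent=2, sort_keys=True) + "\n")
        log.info("stage=evaluate n=%d accuracy=%.2f%%", metrics.n, metrics.accuracy)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest.to_csv(out / "manifest.csv", index=False)
    run_report = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"tumorgrade": __version__, "numpy": np.__version__},
        "n_images": int(len(manifest)),
        "n_train": int((manifest["split"] == "train").sum()),
        "n_test": int((manifest["split"] == "test").sum()),
        "epochs_run": len(report.epochs),
        "final_train_accuracy": report.final_train_accuracy,
        "metrics": metrics.to_dict(),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(run_report, indent=2, sort_keys=True, default=str) + "\n")
    return run_report
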