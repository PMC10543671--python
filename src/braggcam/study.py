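"""End-to-end study driver: simulate -> train -> evaluate -> explain -> invert.

Stage seeds are derived from the global seed by fixed offsets (simulate +1,
five-class training +2, hit/miss training +3, explanation frame choice +4,
inversion +5), so the whole study is reproducible from (config, seed) and the
stages stay decoupled.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import metrics as _metrics
from .classifier import DiffractionClassifier
from .frames import CLASS_NAMES, HIT_CLASSES, binarize_labels, generate_dataset, peak_mask
from .gradcam import activation_histogram, gradcam, localization_score
from .inversion import InversionConfig, invert_per_layer, sigma_from_frames
from .io import validate_report, write_frames, write_report
from .models import NetworkSpec, desk_alexnet_spec, save_checkpoint
from .spotfinder import SpotFinderParams, classify_hit
from .training import TrainConfig

__all__ = ["PipelineConfig", "StageError", "run_study"]

SEED_OFFSETS = {
    "simulate": 1,
    "train_five": 2,
    "train_binary": 3,
    "explain": 4,
    "invert": 5,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Full study configuration; YAML round-trip stable."""

    n_per_class: int = 600
    test_fraction: float = 1.0 / 6.0
    image_size: int = 64
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    spotfinder: SpotFinderParams = field(default_factory=SpotFinderParams)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    explain_frames_per_class: int = 20
    mask_radius: float = 3.0
    invert_frames: int = 3
    out_dir: str = "study_out"
    write_panels: bool = True

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        if "spotfinder" in d:
            d["spotfinder"] = SpotFinderParams(**d["spotfinder"])
        if "inversion" in d:
            d["inversion"] = InversionConfig(**d["inversion"])
        return cls(**d)


def _stage(report: dict, out_dir: Path, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                # persist partial outputs before surfacing the stage failure
                write_report(report, out_dir)
                raise StageError(name, exc) from exc
            report.setdefault("timings_s", {})[name] = round(time.time() - self.t0, 2)
            return False

    return _Ctx()


def run_study(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and return the report (also written to disk)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": yaml.safe_load(cfg.to_yaml())}
    seed = cfg.seed

    with _stage(report, out_dir, "simulate"):
        ds = generate_dataset(
            cfg.n_per_class,
            seed=seed + SEED_OFFSETS["simulate"],
            test_fraction=cfg.test_fraction,
            image_size=cfg.image_size,
        )
        ds = binarize_labels(ds)
        write_frames(out_dir / "data.h5", ds)
        report["simulate"] = {
            "n_frames": len(ds),
            "n_train": int((~ds.is_test).sum()),
            "n_test": int(ds.is_test.sum()),
            "image_size": cfg.image_size,
        }

    with _stage(report, out_dir, "train"):
        five = DiffractionClassifier(
            ds,
            spec=desk_alexnet_spec(n_classes=5, input_size=cfg.image_size),
            train_config=dataclasses.replace(
                cfg.train, seed=seed + SEED_OFFSETS["train_five"]
            ),
            seed=seed + SEED_OFFSETS["train_five"],
        ).fit()
        binary = DiffractionClassifier(
            ds,
            spec=desk_alexnet_spec(n_classes=2, input_size=cfg.image_size),
            train_config=dataclasses.replace(
                cfg.train, seed=seed + SEED_OFFSETS["train_binary"]
            ),
            binary=True,
            seed=seed + SEED_OFFSETS["train_binary"],
        ).fit()
        save_checkpoint(five.network, out_dir / "model_five.ckpt.h5")
        save_checkpoint(binary.network, out_dir / "model_binary.ckpt.h5")
        report["train"] = {
            "five_class": {"history": five.history},
            "binary": {"history": binary.history},
        }

    with _stage(report, out_dir, "evaluate"):
        cm = five.confusion("test")
        test = ds.test_set()
        sf_pred = np.array(
            [1 if classify_hit(f, cfg.spotfinder)[0] == "hit" else 0 for f in test.frames]
        )
        true_bin = test.binary_labels
        cnn_bin = binary.predictions("test")
        report["evaluate"] = {
            "five_class_confusion": cm.counts.tolist(),
            "five_class_accuracy_pct": _metrics.round1(_metrics.accuracy(cm)),
            "five_class_recall_pct": [
                None if v is None else _metrics.round1(v)
                for v in _metrics.per_class_recall(cm)
            ],
            "five_class_precision_pct": [
                None if v is None else _metrics.round1(v)
                for v in _metrics.per_class_precision(cm)
            ],
            "binary_accuracy_pct": _metrics.round1(
                _metrics.accuracy(binary.confusion("test"))
            ),
            "cnn_vs_spotfinder": {
                "cnn_vs_truth": _metrics.hit_miss_table(true_bin, cnn_bin),
                "spotfinder_vs_truth": _metrics.hit_miss_table(true_bin, sf_pred),
            },
        }

    with _stage(report, out_dir, "explain"):
        rng = np.random.default_rng(seed + SEED_OFFSETS["explain"])
        layer = five.network.spec.last_conv_layer
        per_class_raw: Dict[str, List[float]] = {n: [] for n in CLASS_NAMES}
        loc_scores: List[float] = []
        mask_fracs: List[float] = []
        hist_by_class: Dict[str, list] = {}
        for ci, name in enumerate(CLASS_NAMES):
            idx = np.flatnonzero(test.labels == ci)
            take = rng.permutation(idx)[: cfg.explain_frames_per_class]
            for n, i in enumerate(take):
                frame = test.frames[i]
                res = gradcam(five.network, frame, layer=layer)
                per_class_raw[name].append(float(res.raw_map.mean()))
                if name in HIT_CLASSES:
                    # peak localization is scored on the hit/miss-merged
                    # model, whose class evidence is the Bragg peaks
                    res_bin = gradcam(binary.network, frame)
                    if res_bin.heatmap.sum() > 0:
                        mask = peak_mask(frame, cfg.mask_radius)
                        loc_scores.append(localization_score(res_bin.heatmap, mask))
                        mask_fracs.append(float(mask.mean()))
                if n == 0:
                    edges, counts = activation_histogram(res.heatmap, n_bins=20)
                    hist_by_class[name] = [edges.tolist(), counts.tolist()]
                    if cfg.write_panels:
                        _write_panel(out_dir, five.network, frame, res, name)
        report["explain"] = {
            "layer": layer,
            "mean_localization_hit": float(np.mean(loc_scores)) if loc_scores else None,
            "mask_area_fraction": float(np.mean(mask_fracs)) if mask_fracs else None,
            "mean_raw_map_by_class": {
                k: float(np.mean(v)) for k, v in per_class_raw.items() if v
            },
            "heatmap_histograms": hist_by_class,
        }

    with _stage(report, out_dir, "invert"):
        layers = [
            n for n in five.network.spec.layer_names if n.startswith(("conv", "stage"))
        ]
        sigma = sigma_from_frames(five.network, ds.train_set().frames[:200])
        inv_cfg = dataclasses.replace(
            cfg.inversion, sigma=sigma, seed=seed + SEED_OFFSETS["invert"]
        )
        rng = np.random.default_rng(seed + SEED_OFFSETS["invert"])
        hit_idx = np.flatnonzero(test.binary_labels == 1)
        chosen = rng.permutation(hit_idx)[: cfg.invert_frames]
        pearson: Dict[str, List[float]] = {l: [] for l in layers}
        for i in chosen:
            frame = test.frames[i]
            x0 = five.network.preprocess(frame)[0].mean(axis=0)
            results = invert_per_layer(five.network, frame, layers, inv_cfg)
            for res in results:
                rec = res.x_star.mean(axis=0)
                pearson[res.layer].append(
                    float(np.corrcoef(rec.ravel(), x0.ravel())[0, 1])
                )
            if cfg.write_panels and i == chosen[0]:
                _write_inversion_panel(out_dir, x0, results)
        report["invert"] = {
            "layers": layers,
            "pearson_by_layer": {k: float(np.mean(v)) for k, v in pearson.items()},
        }

    validate_report(report)
    write_report(report, out_dir)
    return report


def _write_panel(out_dir: Path, model, frame, res, class_name: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .gradcam import guided_backprop, guided_gradcam, overlay_heatmap

    guided = guided_backprop(model, frame, class_index=res.class_index)
    gg = guided_gradcam(res, guided)
    fig, axes = plt.subplots(1, 4, figsize=(12, 3))
    axes[0].imshow(frame.pixels, cmap="gray")
    axes[0].set_title(f"{class_name} frame")
    axes[1].imshow(res.heatmap, cmap="jet", vmin=0, vmax=1)
    axes[1].set_title(f"Grad-CAM ({res.layer})")
    axes[2].imshow(overlay_heatmap(frame, res.heatmap))
    axes[2].set_title("overlay")
    axes[3].imshow(gg, cmap="seismic")
    axes[3].set_title("guided Grad-CAM")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_dir / f"gradcam_{class_name}.png", dpi=100)
    plt.close(fig)


def _write_inversion_panel(out_dir: Path, x0: np.ndarray, results) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results) + 1, figsize=(3 * (len(results) + 1), 3))
    axes[0].imshow(x0, cmap="gray")
    axes[0].set_title("input")
    for ax, res in zip(axes[1:], results):
        ax.imshow(res.x_star.mean(axis=0), cmap="gray")
        ax.set_title(res.layer)
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_dir / "inversion_panel.png", dpi=100)
    plt.close(fig)
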