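"""Model/Results interface over the training engine.

``DiffractionClassifier`` is built from a :class:`~braggcam.frames.LabelledDataset`
plus a network spec and training configuration; ``fit()`` returns a
:class:`ClassifierResults` carrying the fitted network, the optimization
history, predictions and evaluation tables, with the explanation methods
(Grad-CAM, representation inversion) hanging off the results object.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from . import metrics as _metrics
from .frames import CLASS_NAMES, LabelledDataset, binarize_labels
from .models import CNNModel, NetworkSpec, build_model, desk_alexnet_spec
from .training import TrainConfig, predict, train

__all__ = ["DiffractionClassifier", "ClassifierResults"]


class DiffractionClassifier:
    """A CNN hit/miss (or five-class) classifier for diffraction frames.

    Parameters
    ----------
    dataset:
        Labelled frames with a train/test split.
    spec:
        Network architecture; defaults to the desk-scale AlexNet-style spec
        sized to the dataset's frames and class count.
    train_config:
        Optimization recipe; defaults to the desk preset.
    binary:
        Train on hit/miss labels (attached automatically if missing) instead
        of the five-class labels.
    seed:
        Weight-initialization seed.
    """

    def __init__(
        self,
        dataset: LabelledDataset,
        spec: Optional[NetworkSpec] = None,
        train_config: Optional[TrainConfig] = None,
        binary: bool = False,
        seed: int = 0,
    ) -> None:
        if binary and dataset.binary_labels is None:
            dataset = binarize_labels(dataset)
        self.dataset = dataset
        n_classes = 2 if binary else len(CLASS_NAMES)
        if spec is None:
            size = dataset.frames[0].pixels.shape[0]
            spec = desk_alexnet_spec(n_classes=n_classes, input_size=size)
        if spec.n_classes != n_classes:
            raise ValueError(
                f"spec has {spec.n_classes} classes but the task needs {n_classes}"
            )
        self.spec = spec
        self.train_config = train_config or TrainConfig()
        self.binary = binary
        self.seed = seed

    @classmethod
    def from_hdf5(cls, path, **kwargs) -> "DiffractionClassifier":
        from .io import read_frames

        return cls(read_frames(path), **kwargs)

    @property
    def class_names(self) -> Sequence[str]:
        return ("miss", "hit") if self.binary else CLASS_NAMES

    def fit(self, verbose: bool = False) -> "ClassifierResults":
        model = build_model(self.spec, seed=self.seed)
        model, history = train(
            model, self.dataset, self.train_config, binary=self.binary, verbose=verbose
        )
        return ClassifierResults(self, model, history)


class ClassifierResults:
    """Fitted classifier: weights, history, predictions and explanations."""

    def __init__(
        self,
        model: DiffractionClassifier,
        network: CNNModel,
        history: List[Dict[str, float]],
    ) -> None:
        self.model = model
        self.network = network
        self.history = history
        self._pred_cache: Dict[str, np.ndarray] = {}

    # ------------------------------------------------------------- predictions
    def _true_labels(self, subset: str) -> np.ndarray:
        ds = self.model.dataset
        y = ds.binary_labels if self.model.binary else ds.labels
        mask = ds.is_test if subset == "test" else ~ds.is_test
        return y[mask]

    def predictions(self, subset: str = "test") -> np.ndarray:
        if subset not in ("train", "test"):
            raise ValueError("subset must be 'train' or 'test'")
        if subset not in self._pred_cache:
            ds = self.model.dataset
            part = ds.test_set() if subset == "test" else ds.train_set()
            labels, _ = predict(self.network, part.frames)
            self._pred_cache[subset] = labels
        return self._pred_cache[subset]

    def predict(self, frames):
        return predict(self.network, frames)

    # -------------------------------------------------------------- evaluation
    def confusion(self, subset: str = "test") -> "_metrics.ConfusionMatrix":
        return _metrics.confusion(
            self._true_labels(subset),
            self.predictions(subset),
            n_classes=self.model.spec.n_classes,
            class_names=self.model.class_names,
        )

    def accuracy(self, subset: str = "test") -> float:
        return _metrics.accuracy(self.confusion(subset))

    # ------------------------------------------------------------ explanations
    def gradcam(self, frame, class_index: Optional[int] = None,
                layer: Optional[str] = None):
        from .gradcam import gradcam

        return gradcam(self.network, frame, class_index=class_index, layer=layer)

    def invert(self, frame, layers: Optional[Sequence[str]] = None, config=None):
        from .inversion import InversionConfig, invert_per_layer

        if layers is None:
            spec = self.model.spec
            layers = [n for n in spec.layer_names if n.startswith(("conv", "stage"))]
        return invert_per_layer(self.network, frame, layers,
                                config or InversionConfig())

    # ----------------------------------------------------------------- summary
    def summary(self) -> str:
        cm = self.confusion("test")
        lines = [
            "Diffraction frame classifier",
            "=" * 60,
            f"architecture     : {self.model.spec.arch}"
            f" ({self.network.parameter_count():,} parameters)",
            f"input            : {self.model.spec.input_size}x"
            f"{self.model.spec.input_size}, {self.model.spec.in_channels} channel(s)",
            f"task             : {'hit/miss' if self.model.binary else 'five-class'}",
            f"epochs           : {len(self.history)}"
            f" (final lr {self.history[-1]['lr']:.2e})",
            f"final train loss : {self.history[-1]['train_loss']:.4f}",
            f"train accuracy   : {100 * self.history[-1]['train_accuracy']:.1f}%",
            f"test accuracy    : {_metrics.accuracy(cm):.1f}%",
            "",
            _metrics.format_confusion(cm),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ClassifierResults arch={self.model.spec.arch!r} "
            f"binary={self.model.binary} epochs={len(self.history)}>"
        )
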