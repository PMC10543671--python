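"""HDF5 dataset layout, atomic writers and the machine-readable report.

Dataset layout::

    /frames          (N, H, W) float32   intensity frames
    /labels          (N,)      int8      five-class labels (canonical order)
    /split           (N,)      int8      0 = train, 1 = test
    /binary_labels   (N,)      int8      optional, 0 = miss / 1 = hit
    /peaks/<i>       (k, 3)    float32   per-frame (row, col, amplitude)
    attrs: class_names                   fixes the label <-> index map

All writes go to a temporary file in the target directory followed by an
atomic rename, so readers never observe a partially written file.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Union

import h5py
import numpy as np

from .frames import CLASS_NAMES, DetectorFrame, LabelledDataset

__all__ = [
    "MissingDatasetError",
    "write_frames",
    "read_frames",
    "write_json",
    "write_report",
    "REPORT_SCHEMA",
    "validate_report",
]

PathLike = Union[str, os.PathLike]


class MissingDatasetError(KeyError):
    """An expected HDF5 dataset path is absent from the file."""

    def __init__(self, path: str, filename: str) -> None:
        super().__init__(path)
        self.path = path
        self.filename = filename

    def __str__(self) -> str:
        return f"missing dataset {self.path!r} in {self.filename}"


def _atomic_target(path: PathLike):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix + ".tmp")
    os.close(fd)
    return path, Path(tmp)


def write_frames(path: PathLike, dataset: LabelledDataset) -> None:
    path, tmp = _atomic_target(path)
    try:
        with h5py.File(tmp, "w") as f:
            frames = np.stack([fr.pixels for fr in dataset.frames]).astype(np.float32)
            f.create_dataset("frames", data=frames)
            f.create_dataset("labels", data=dataset.labels.astype(np.int8))
            f.create_dataset("split", data=dataset.split.astype(np.int8))
            if dataset.binary_labels is not None:
                f.create_dataset(
                    "binary_labels", data=dataset.binary_labels.astype(np.int8)
                )
            peaks = f.create_group("peaks")
            for i, fr in enumerate(dataset.frames):
                peaks.create_dataset(str(i), data=fr.peaks.astype(np.float32))
            f.attrs["class_names"] = list(CLASS_NAMES)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def read_frames(path: PathLike) -> LabelledDataset:
    with h5py.File(path, "r") as f:
        for key in ("frames", "labels", "split"):
            if key not in f:
                raise MissingDatasetError(f"/{key}", str(path))
        pixels = f["frames"][()]
        labels = f["labels"][()]
        split = f["split"][()]
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs.get("class_names", CLASS_NAMES)
        ]
        frames = []
        for i in range(len(pixels)):
            pk_path = f"peaks/{i}"
            if pk_path in f:
                peaks = f[pk_path][()]
            else:
                peaks = np.zeros((0, 3), np.float32)
            frames.append(
                DetectorFrame(pixels=pixels[i], peaks=peaks, label=names[int(labels[i])])
            )
        binary = f["binary_labels"][()].astype(np.int64) if "binary_labels" in f else None
    return LabelledDataset(frames=frames, split=split, binary_labels=binary)


def write_json(path: PathLike, obj) -> None:
    path, tmp = _atomic_target(path)
    try:
        tmp.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


#: Minimal structural schema for the study report: required blocks and the
#: required keys inside each block.
REPORT_SCHEMA = {
    "config": dict,
    "simulate": {"n_frames": (int,), "n_train": (int,), "n_test": (int,)},
    "train": {"five_class": dict, "binary": dict},
    "evaluate": {
        "five_class_confusion": list,
        "five_class_accuracy_pct": (int, float),
        "binary_accuracy_pct": (int, float),
        "cnn_vs_spotfinder": dict,
    },
    "explain": {
        "layer": str,
        "mean_localization_hit": (int, float),
        "mask_area_fraction": (int, float),
        "mean_raw_map_by_class": dict,
    },
    "invert": {"layers": list, "pearson_by_layer": dict},
}


def validate_report(report: dict) -> None:
    """Raise ValueError if the report does not match :data:`REPORT_SCHEMA`."""
    for block, spec in REPORT_SCHEMA.items():
        if block not in report:
            raise ValueError(f"report missing block {block!r}")
        if isinstance(spec, dict):
            if not isinstance(report[block], dict):
                raise ValueError(f"report block {block!r} must be an object")
            for key, types in spec.items():
                if key not in report[block]:
                    raise ValueError(f"report block {block!r} missing key {key!r}")
                if isinstance(types, tuple) and not isinstance(report[block][key], types):
                    raise ValueError(f"report key {block}.{key} has wrong type")
                if types is dict and not isinstance(report[block][key], dict):
                    raise ValueError(f"report key {block}.{key} must be an object")
                if types is str and not isinstance(report[block][key], str):
                    raise ValueError(f"report key {block}.{key} must be a string")
        elif not isinstance(report[block], spec):
            raise ValueError(f"report block {block!r} has wrong type")


def write_report(report: dict, out_dir: PathLike) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    target = out_dir / "report.json"
    write_json(target, report)
    return target
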