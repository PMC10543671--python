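"""Synthetic diffraction-like frames with known Bragg-peak ground truth.

The generator emulates the statistical structure of the five-class DiffraNet
taxonomy used for serial-crystallography hit finding:

* ``Blank``      -- detector noise only, no X-rays;
* ``NoCrystal``  -- amorphous (ring-shaped) scattering background, no crystal;
* ``Weak`` / ``Good`` / ``Strong`` -- Bragg peaks of increasing count and
  amplitude on top of a weak amorphous background.

A frame is composed additively as ``peaks + rings + noise`` and clipped at
zero.  Bragg peaks are isotropic 2-D Gaussians at integer pixel centres with a
minimum pairwise separation, so every planted peak is a strict local maximum
of the noise-free image and peak counts are unambiguous for brute-force
oracles.  The first two classes carry no peaks and binarize to *miss*, the
last three to *hit*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "MISS_CLASSES",
    "HIT_CLASSES",
    "SceneParams",
    "DetectorFrame",
    "LabelledDataset",
    "OvercrowdedSceneError",
    "default_scene_params",
    "simulate_frame",
    "generate_dataset",
    "binarize_labels",
    "peak_mask",
]

#: Canonical label order; fixes the label <-> index map everywhere (HDF5 attr,
#: confusion matrices, CLI output).
CLASS_NAMES: Tuple[str, ...] = ("Blank", "NoCrystal", "Weak", "Good", "Strong")

MISS_CLASSES = frozenset({"Blank", "NoCrystal"})
HIT_CLASSES = frozenset({"Weak", "Good", "Strong"})

#: Gaussian peak profiles are truncated (set to zero) beyond this many sigmas
#: from the centre; keeps peak support compact so that separated peaks stay
#: separated for connected-component analysis.
PEAK_TRUNCATION_SIGMAS = 4.0


class OvercrowdedSceneError(ValueError):
    """Requested peak count cannot be placed under the separation constraint."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene (a single class-conditional frame).

    Intensities are in arbitrary detector units (ADU); lengths in pixels.
    """

    image_size: int = 64
    class_label: str = "Strong"
    n_peaks_range: Tuple[int, int] = (13, 20)
    peak_amplitude_range: Tuple[float, float] = (34.0, 60.0)
    peak_sigma: float = 1.5
    ring_amplitude: float = 3.0
    ring_radii: Tuple[float, ...] = ()
    ring_width: float = 3.0
    noise_sigma: float = 1.0
    poisson: bool = False
    seed: int = 0
    #: Minimum pairwise centre separation; ``None`` -> 7 * peak_sigma
    #: (always >= the 4 * sigma floor that keeps peak counts unambiguous; the
    #: wider default keeps the above-threshold footprints of even the
    #: brightest peaks disconnected for threshold-based spot finding).
    min_separation: Optional[float] = None

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        lo, hi = self.n_peaks_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid n_peaks_range")
        alo, ahi = self.peak_amplitude_range
        if alo > ahi or alo < 0:
            raise ValueError("invalid peak_amplitude_range")
        if self.class_label in MISS_CLASSES and hi != 0:
            raise ValueError(f"{self.class_label} frames must have n_peaks = 0")
        if self.class_label == "Blank" and self.ring_amplitude != 0:
            raise ValueError("Blank frames must have ring_amplitude = 0")
        if self.class_label == "NoCrystal" and self.ring_amplitude <= 0:
            raise ValueError("NoCrystal frames must have ring_amplitude > 0")
        sep = self.separation
        if sep < 4.0 * self.peak_sigma:
            raise ValueError("min_separation must be >= 4 * peak_sigma")

    @property
    def separation(self) -> float:
        return (
            7.0 * self.peak_sigma
            if self.min_separation is None
            else float(self.min_separation)
        )


@dataclass
class DetectorFrame:
    """A 2-D non-negative intensity array plus ground truth.

    ``peaks`` is a ``(k, 3)`` float array of (row, col, amplitude) for the
    planted Bragg-peak centres; empty exactly for miss-class frames.
    """

    pixels: np.ndarray
    peaks: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.peaks = np.asarray(self.peaks, dtype=np.float32).reshape(-1, 3)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if (len(self.peaks) == 0) != (self.label in MISS_CLASSES):
            raise ValueError("peaks must be empty iff the frame is a miss class")
        h, w = self.pixels.shape
        if len(self.peaks):
            r, c = self.peaks[:, 0], self.peaks[:, 1]
            if (r < 0).any() or (r > h - 1).any() or (c < 0).any() or (c > w - 1).any():
                raise ValueError("peak centres must lie inside the frame")

    @property
    def label_index(self) -> int:
        return CLASS_NAMES.index(self.label)

    @property
    def is_hit(self) -> bool:
        return self.label in HIT_CLASSES


@dataclass
class LabelledDataset:
    """Frames with five-class labels, a stratified split, optional hit/miss labels.

    ``split`` is 0 for train, 1 for test; ``binary_labels`` (if attached by
    :func:`binarize_labels`) is 0 for miss, 1 for hit.
    """

    frames: List[DetectorFrame]
    split: np.ndarray
    binary_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.split = np.asarray(self.split, dtype=np.int8)
        if len(self.split) != len(self.frames):
            raise ValueError("split length must match number of frames")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def labels(self) -> np.ndarray:
        return np.array([f.label_index for f in self.frames], dtype=np.int64)

    @property
    def is_test(self) -> np.ndarray:
        return self.split.astype(bool)

    def subset(self, mask: np.ndarray) -> "LabelledDataset":
        idx = np.flatnonzero(np.asarray(mask))
        return LabelledDataset(
            frames=[self.frames[i] for i in idx],
            split=self.split[idx],
            binary_labels=None if self.binary_labels is None else self.binary_labels[idx],
        )

    def train_set(self) -> "LabelledDataset":
        return self.subset(~self.is_test)

    def test_set(self) -> "LabelledDataset":
        return self.subset(self.is_test)


def _default_ring_radii(image_size: int) -> Tuple[float, ...]:
    half = image_size / 2.0
    return (0.30 * half, 0.55 * half, 0.80 * half)


def default_scene_params(
    class_label: str, image_size: int = 64, seed: int = 0, **overrides
) -> SceneParams:
    """Class-conditional default scene parameters (the study conditions).

    Peak-count and amplitude ranges are disjoint and ordered across
    Weak < Good < Strong, mirroring the taxonomy's "increasingly higher
    intensity" definition; ring radii scale with the frame size.
    """
    table: Dict[str, dict] = {
        "Blank": dict(n_peaks_range=(0, 0), peak_amplitude_range=(0.0, 0.0),
                      ring_amplitude=0.0, ring_radii=()),
        "NoCrystal": dict(n_peaks_range=(0, 0), peak_amplitude_range=(0.0, 0.0),
                          ring_amplitude=6.0),
        "Weak": dict(n_peaks_range=(3, 6), peak_amplitude_range=(8.0, 14.0),
                     ring_amplitude=3.0),
        "Good": dict(n_peaks_range=(7, 12), peak_amplitude_range=(16.0, 30.0),
                     ring_amplitude=3.0),
        "Strong": dict(n_peaks_range=(13, 20), peak_amplitude_range=(34.0, 60.0),
                       ring_amplitude=3.0),
    }
    if class_label not in table:
        raise ValueError(f"unknown class label {class_label!r}")
    kwargs = dict(table[class_label])
    # peak counts in the table are stated for 64x64 frames; scale with area so
    # smaller/larger frames keep a comparable peak density (and stay placeable
    # under the separation constraint)
    lo, hi = kwargs["n_peaks_range"]
    if hi > 0 and image_size != 64:
        factor = (image_size / 64.0) ** 2
        lo = max(1, int(round(lo * factor)))
        hi = max(lo, int(round(hi * factor)))
        kwargs["n_peaks_range"] = (lo, hi)
    kwargs.setdefault("ring_radii", _default_ring_radii(image_size))
    kwargs.update(image_size=image_size, class_label=class_label, seed=seed)
    kwargs.update(overrides)
    return SceneParams(**kwargs)


def _place_peaks(
    n: int,
    size: int,
    margin: float,
    separation: float,
    rng: np.random.Generator,
    restarts: int = 25,
) -> np.ndarray:
    """Rejection-sample integer peak centres with a minimum pairwise distance.

    Each pass places peaks greedily with up to 1000 candidate draws per peak;
    a fragmented layout triggers a fresh pass.  Only a genuinely overcrowded
    scene exhausts every pass.
    """
    lo = int(np.ceil(margin))
    hi = size - 1 - lo
    if hi < lo:
        raise OvercrowdedSceneError("frame too small for the requested margin")
    for _pass in range(restarts):
        centres: List[Tuple[int, int]] = []
        for _ in range(n):
            for _attempt in range(1000):
                r = int(rng.integers(lo, hi + 1))
                c = int(rng.integers(lo, hi + 1))
                if all(
                    (r - r0) ** 2 + (c - c0) ** 2 >= separation**2 for r0, c0 in centres
                ):
                    centres.append((r, c))
                    break
            else:
                break  # layout fragmented; restart the pass
        if len(centres) == n:
            return np.array(centres, dtype=float).reshape(-1, 2)
    raise OvercrowdedSceneError(
        f"could not place {n} peaks with separation >= {separation:.1f}px "
        f"(1000 attempts per peak, {restarts} placement passes)"
    )


def _peak_image(
    size: int, centres: np.ndarray, amplitudes: np.ndarray, sigma: float
) -> np.ndarray:
    img = np.zeros((size, size))
    if len(centres) == 0:
        return img
    rr, cc = np.mgrid[0:size, 0:size]
    cutoff2 = (PEAK_TRUNCATION_SIGMAS * sigma) ** 2
    for (r0, c0), amp in zip(centres, amplitudes):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        g = amp * np.exp(-d2 / (2.0 * sigma**2))
        g[d2 > cutoff2] = 0.0
        img += g
    return img


def _ring_image(size: int, amplitude: float, radii: Sequence[float], width: float) -> np.ndarray:
    if amplitude == 0 or not len(radii):
        return np.zeros((size, size))
    centre = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    r = np.hypot(rr - centre, cc - centre)
    img = np.zeros((size, size))
    for r0 in radii:
        img += amplitude * np.exp(-((r - r0) ** 2) / (2.0 * width**2))
    return img


def simulate_frame(
    params: SceneParams, rng: Optional[np.random.Generator] = None
) -> DetectorFrame:
    """Render one frame: Gaussian peaks + amorphous rings + detector noise.

    Identical ``(params, seed)`` produce a bit-identical frame.  The noiseless
    mean image is optionally Poisson-resampled (photon counting), then additive
    Gaussian read noise is applied, and the result is clipped at zero.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    size = params.image_size
    n_lo, n_hi = params.n_peaks_range
    n_peaks = int(rng.integers(n_lo, n_hi + 1)) if n_hi > 0 else 0

    if n_peaks > 0:
        margin = 3.0 * params.peak_sigma
        centres = _place_peaks(n_peaks, size, margin, params.separation, rng)
        alo, ahi = params.peak_amplitude_range
        amplitudes = rng.uniform(alo, ahi, size=n_peaks)
    else:
        centres = np.zeros((0, 2))
        amplitudes = np.zeros(0)

    mean = _peak_image(size, centres, amplitudes, params.peak_sigma)
    mean += _ring_image(size, params.ring_amplitude, params.ring_radii, params.ring_width)

    img = rng.poisson(np.clip(mean, 0, None)).astype(float) if params.poisson else mean
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=(size, size))
    img = np.clip(img, 0.0, None).astype(np.float32)

    peaks = np.column_stack([centres, amplitudes]) if n_peaks else np.zeros((0, 3))
    return DetectorFrame(pixels=img, peaks=peaks, label=params.class_label)


def generate_dataset(
    n_per_class: int,
    params_by_class: Optional[Dict[str, SceneParams]] = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    image_size: int = 64,
) -> LabelledDataset:
    """Generate ``5 * n_per_class`` frames with a stratified train/test split.

    Per-frame randomness is drawn from :class:`numpy.random.SeedSequence`
    children of ``seed``, so the dataset is fully reproducible and individual
    frames are independent of ``n_per_class`` ordering.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    if params_by_class is None:
        params_by_class = {
            name: default_scene_params(name, image_size=image_size) for name in CLASS_NAMES
        }
    missing = set(CLASS_NAMES) - set(params_by_class)
    if missing:
        raise ValueError(f"params_by_class missing classes: {sorted(missing)}")
    lower_bounds = [params_by_class[c].peak_amplitude_range[0] for c in ("Weak", "Good", "Strong")]
    if not (lower_bounds[0] < lower_bounds[1] < lower_bounds[2]):
        raise ValueError("peak amplitude lower bounds must be ordered Weak < Good < Strong")

    ss = np.random.SeedSequence(seed)
    frame_seeds = ss.spawn(5 * n_per_class + 1)
    split_rng = np.random.default_rng(frame_seeds[-1])

    frames: List[DetectorFrame] = []
    split = np.zeros(5 * n_per_class, dtype=np.int8)
    n_test = int(round(n_per_class * test_fraction))
    for ci, name in enumerate(CLASS_NAMES):
        base = params_by_class[name]
        for i in range(n_per_class):
            rng = np.random.default_rng(frame_seeds[ci * n_per_class + i])
            frames.append(simulate_frame(base, rng))
        test_idx = split_rng.choice(n_per_class, size=n_test, replace=False)
        split[ci * n_per_class + test_idx] = 1
    return LabelledDataset(frames=frames, split=split)


def binarize_labels(dataset: LabelledDataset) -> LabelledDataset:
    """Attach hit/miss labels: {Blank, NoCrystal} -> miss(0), the rest -> hit(1).

    Five-class labels are retained on the frames; a new dataset object is
    returned (the input is not mutated).
    """
    binary = np.array([1 if f.is_hit else 0 for f in dataset.frames], dtype=np.int64)
    return LabelledDataset(
        frames=list(dataset.frames), split=dataset.split.copy(), binary_labels=binary
    )


def peak_mask(frame: DetectorFrame, dilation_radius: float) -> np.ndarray:
    """Boolean mask, true within ``dilation_radius`` (Euclidean) of any peak centre."""
    if len(frame.peaks) == 0:
        raise ValueError(f"frame of class {frame.label!r} has no ground-truth peaks")
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    h, w = frame.pixels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for r0, c0, _amp in frame.peaks:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= dilation_radius**2
    return mask
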