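"""Reconstructing an input image from a layer's representation.

Given the representation :math:`\\Phi_0 = \\Phi(x_0)` of a frame at a chosen
layer, find

.. math::

    x^* = \\arg\\min_x \\; \\ell(\\Phi(\\sigma x), \\Phi_0)
            + \\lambda_\\alpha R_\\alpha(x) + \\lambda_{TV} R_{TV}(x)

where :math:`\\ell` is the squared Euclidean distance normalized by
:math:`\\lVert\\Phi_0\\rVert^2`, :math:`R_\\alpha(x) = \\sum_i |x_i - \\bar x|^\\alpha`
penalizes a wide spread of pixel values, and the total-variation prior

.. math::

    R_{TV}(x) = \\sum_{i,j} ((x_{i,j+1} - x_{i,j})^2 + (x_{i+1,j} - x_{i,j})^2)^{\\beta/2}

with :math:`\\beta = 1` favours piecewise-smooth images (forward differences;
out-of-range differences are zero).  The scaling :math:`\\sigma` is the
average Euclidean norm of (preprocessed) training images, so the optimizer
works on unit-scale variables while the network sees naturally scaled input.

The optimizer is gradient descent with momentum from a seeded random-noise
start.  The step is auto-calibrated once, at the first iteration, so that the
initial update moves the worst pixel by ``step_size`` normalized units; the
step then decays x0.5 every ceil(iterations/3).  The iterate is clipped to a
plausibility band (default +/-6 normalized units, wide enough that Bragg-peak
intensities many sigma above background remain representable) each iteration and the best-loss iterate is
returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .frames import DetectorFrame
from .models import CNNModel

__all__ = [
    "InversionConfig",
    "InversionResult",
    "rep_distance",
    "alpha_norm_prior",
    "tv_prior",
    "invert",
    "invert_per_layer",
    "representation",
    "sigma_from_frames",
]

FrameLike = Union[DetectorFrame, np.ndarray]
_EPS = 1e-12


@dataclass(frozen=True)
class InversionConfig:
    layer: str = "conv5"
    lambda_alpha: float = 1e-5
    alpha_exponent: float = 6.0
    lambda_tv: float = 1e-3
    beta: float = 1.0
    sigma: float = 1.0
    iterations: int = 300
    #: maximum per-pixel update magnitude (normalized units) at iteration 0
    step_size: float = 0.05
    momentum: float = 0.9
    seed: int = 0
    clip: float = 6.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.alpha_exponent < 1:
            raise ValueError("alpha_exponent must be >= 1")


@dataclass
class InversionResult:
    layer: str
    x_star: np.ndarray
    loss_trace: List[Dict[str, float]]
    final_rep_distance: float


# ----------------------------------------------------------------- components
def representation(model: CNNModel, x: np.ndarray, layer: str) -> np.ndarray:
    """Phi(x) on an already-preprocessed (C, H, W) or raw 2-D array.

    ``layer='input'`` is the identity representation (useful for closed-form
    checks of the optimizer).
    """
    x = np.asarray(x, float)
    if x.ndim == 2:
        x = x[None, :, :]
    if layer == "input":
        return x.copy()
    return model.net.activations(x[None], layer)[0]


def rep_distance(
    model: CNNModel, x: np.ndarray, phi0: np.ndarray, layer: str
) -> float:
    """Normalized squared Euclidean distance ||Phi(x) - Phi0||^2 / ||Phi0||^2."""
    phi = representation(model, x, layer)
    if phi.shape != phi0.shape:
        raise ValueError(f"representation shape {phi.shape} != phi0 {phi0.shape}")
    denom = float((phi0**2).sum()) + _EPS
    return float(((phi - phi0) ** 2).sum() / denom)


def alpha_norm_prior(x: np.ndarray, alpha_exponent: float) -> float:
    """R_alpha = sum_i |x_i - mean(x)|^alpha over the vectorized image."""
    z = np.asarray(x, float).ravel()
    z = z - z.mean()
    return float((np.abs(z) ** alpha_exponent).sum())


def _alpha_norm_grad(x: np.ndarray, alpha_exponent: float) -> np.ndarray:
    z = np.asarray(x, float) - np.mean(x)
    g = alpha_exponent * np.abs(z) ** (alpha_exponent - 1) * np.sign(z)
    return g - g.mean()  # chain rule through the mean subtraction


def tv_prior(x: np.ndarray, beta: float) -> float:
    """Total-variation prior with forward differences (out-of-range diffs = 0)."""
    x = np.asarray(x, float)
    if x.ndim != 2:
        raise ValueError("tv_prior expects a 2-D image")
    dcol = np.zeros_like(x)
    drow = np.zeros_like(x)
    dcol[:, :-1] = x[:, 1:] - x[:, :-1]   # x_{i,j+1} - x_{i,j}
    drow[:-1, :] = x[1:, :] - x[:-1, :]   # x_{i+1,j} - x_{i,j}
    return float(((dcol**2 + drow**2) ** (beta / 2.0)).sum())


def _tv_grad(x: np.ndarray, beta: float, eps: float = 1e-8) -> np.ndarray:
    x = np.asarray(x, float)
    dcol = np.zeros_like(x)
    drow = np.zeros_like(x)
    dcol[:, :-1] = x[:, 1:] - x[:, :-1]
    drow[:-1, :] = x[1:, :] - x[:-1, :]
    w = (beta / 2.0) * (dcol**2 + drow**2 + eps) ** (beta / 2.0 - 1.0)
    gc = 2.0 * w * dcol
    gr = 2.0 * w * drow
    g = -(gc + gr)
    g[:, 1:] += gc[:, :-1]
    g[1:, :] += gr[:-1, :]
    return g


def _rep_and_grad(
    model: CNNModel, x_scaled: np.ndarray, phi0: np.ndarray, layer: str
) -> Tuple[float, np.ndarray]:
    """Normalized distance and its gradient w.r.t. the *scaled* input."""
    xb = x_scaled[None]
    denom = float((phi0**2).sum()) + _EPS
    if layer == "input":
        diff = x_scaled - phi0
        with np.errstate(invalid="ignore", over="ignore"):
            return float((diff**2).sum() / denom), 2.0 * diff / denom
    _, named, caches = model.net.forward(xb, want_caches=True)
    phi = named[layer][0]
    diff = phi - phi0
    seed = (2.0 * diff / denom)[None]
    dx = model.net.input_gradient_from(layer, seed, caches)
    return float((diff**2).sum() / denom), dx[0]


# ------------------------------------------------------------------ optimizer
def invert(
    model: CNNModel, phi0: np.ndarray, cfg: InversionConfig
) -> InversionResult:
    """Minimize the inversion objective from a seeded random-noise start."""
    if cfg.layer == "input":
        shape = (1,) + tuple(phi0.shape[-2:]) if phi0.ndim == 2 else tuple(phi0.shape)
        phi0 = np.asarray(phi0, float).reshape(shape)
    else:
        size = model.spec.input_size
        shape = (model.spec.in_channels, size, size)
    rng = np.random.default_rng(cfg.seed)
    x = rng.normal(0.0, 0.1, size=shape)
    velocity = np.zeros_like(x)

    decay_every = max(1, int(np.ceil(cfg.iterations / 3)))
    step = cfg.step_size
    trace: List[Dict[str, float]] = []
    best: Tuple[float, np.ndarray, float] = (np.inf, x.copy(), np.inf)

    for it in range(cfg.iterations):
        if it > 0 and it % decay_every == 0:
            step *= 0.5
        dist, gdist = _rep_and_grad(model, cfg.sigma * x, phi0, cfg.layer)
        gdist = cfg.sigma * gdist  # chain rule through sigma * x
        img = x.mean(axis=0)  # priors act on the (channel-averaged) image plane
        r_alpha = alpha_norm_prior(img, cfg.alpha_exponent)
        r_tv = tv_prior(img, cfg.beta)
        total = dist + cfg.lambda_alpha * r_alpha + cfg.lambda_tv * r_tv
        if not np.isfinite(total):
            bad = {
                "representation distance": dist,
                "alpha-norm prior": r_alpha,
                "TV prior": r_tv,
            }
            offender = next((k for k, v in bad.items() if not np.isfinite(v)), "objective")
            raise FloatingPointError(f"non-finite {offender} at iteration {it}")
        trace.append(
            {
                "iteration": it,
                "total": total,
                "rep_distance": dist,
                "alpha_norm": r_alpha,
                "tv": r_tv,
            }
        )
        if total < best[0]:
            best = (total, x.copy(), dist)

        grad = gdist
        gprior = (
            cfg.lambda_alpha * _alpha_norm_grad(img, cfg.alpha_exponent)
            + cfg.lambda_tv * _tv_grad(img, cfg.beta)
        ) / x.shape[0]
        grad = grad + gprior[None]

        if it == 0:
            # calibrate once: the first update moves the worst pixel by
            # step_size normalized units; the scale then stays fixed so the
            # iteration can settle as the gradient shrinks
            grad_scale = 1.0 / (np.abs(grad).max() + _EPS)
        velocity = cfg.momentum * velocity - step * grad_scale * grad
        x = np.clip(x + velocity, -cfg.clip, cfg.clip)

    return InversionResult(cfg.layer, best[1], trace, best[2])


def sigma_from_frames(model: CNNModel, frames: Sequence[FrameLike]) -> float:
    """Average Euclidean norm of the preprocessed training images."""
    x = model.preprocess(list(frames))
    return float(np.mean(np.sqrt((x**2).sum(axis=(1, 2, 3)))))


def invert_per_layer(
    model: CNNModel,
    frame: FrameLike,
    layers: Sequence[str],
    cfg: InversionConfig = InversionConfig(),
) -> List[InversionResult]:
    """One reconstruction per layer from the same frame and seed."""
    x0 = model.preprocess(frame)[0]
    results = []
    for layer in layers:
        phi0 = representation(model, x0, layer)
        results.append(invert(model, phi0, replace(cfg, layer=layer)))
    return results
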