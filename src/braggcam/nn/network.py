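"""A feed-forward network of named layers with activation taps.

``taps`` maps a public layer name (``conv1`` .. ``conv5``, ``fc1`` .. ``fc3``,
``stage1`` .. , ``head``) to the index of the primitive layer whose *output*
realises it.  For convolutional taps this is the post-ReLU feature map (the
A^k the class-activation machinery operates on), taken before any pooling.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .layers import Layer

Array = np.ndarray


class Network:
    def __init__(self, layers: List[Layer], taps: Dict[str, int]) -> None:
        self.layers = layers
        self.taps = dict(taps)
        for name, idx in self.taps.items():
            if not (0 <= idx < len(layers)):
                raise ValueError(f"tap {name!r} points at invalid layer index {idx}")

    # ------------------------------------------------------------------ params
    def param_items(self):
        for layer in self.layers:
            yield from layer.param_items()

    def parameter_count(self) -> int:
        return sum(layer.params[name].size for layer, name in self.param_items())

    def state_arrays(self) -> List[np.ndarray]:
        return [layer.params[name] for layer, name in self.param_items()]

    def set_state_arrays(self, arrays: List[np.ndarray]) -> None:
        items = list(self.param_items())
        if len(items) != len(arrays):
            raise ValueError("state array count mismatch")
        for (layer, name), arr in zip(items, arrays):
            if layer.params[name].shape != arr.shape:
                raise ValueError("state array shape mismatch")
            layer.params[name] = np.asarray(arr)

    # ----------------------------------------------------------------- forward
    def forward(self, x: Array, want_caches: bool = False):
        """Run the stack; returns (logits, acts, caches)."""
        caches = []
        acts: Dict[int, Array] = {}
        tap_idx = set(self.taps.values())
        for i, layer in enumerate(self.layers):
            x, c = layer.forward(x)
            caches.append(c if want_caches else None)
            if i in tap_idx:
                acts[i] = x
        named = {name: acts[idx] for name, idx in self.taps.items()}
        return x, named, (caches if want_caches else None)

    def activations(self, x: Array, layer_name: str) -> Array:
        if layer_name == "input":
            return x
        if layer_name not in self.taps:
            raise KeyError(f"unknown layer {layer_name!r}; have {sorted(self.taps)}")
        _, named, _ = self.forward(x)
        return named[layer_name]

    # ---------------------------------------------------------------- backward
    def backward(
        self,
        dlogits: Array,
        caches: List[object],
        stop_layer: Optional[str] = None,
        guided: bool = False,
    ) -> Tuple[Array, Dict[str, Array]]:
        """Backprop a gradient seeded at the logits.

        Returns ``(dx, grads_at)`` where ``grads_at[name]`` is the gradient of
        the seeded scalar w.r.t. the tap's output.  If ``stop_layer`` is given
        the walk stops once that tap's gradient has been recorded (``dx`` is
        then the gradient w.r.t. that tap's output, not the input).
        """
        idx_to_name = {idx: name for name, idx in self.taps.items()}
        grads_at: Dict[str, Array] = {}
        d = dlogits
        for i in range(len(self.layers) - 1, -1, -1):
            name = idx_to_name.get(i)
            if name is not None:
                grads_at[name] = d
                if stop_layer is not None and name == stop_layer:
                    return d, grads_at
            d = self.layers[i].backward(d, caches[i], guided=guided)
        if stop_layer is not None and stop_layer != "input":
            raise KeyError(f"unknown layer {stop_layer!r}")
        grads_at["input"] = d
        return d, grads_at

    def input_gradient_from(
        self, layer_name: str, seed: Array, caches: List[object], guided: bool = False
    ) -> Array:
        """Gradient w.r.t. the network input of a scalar whose gradient at the
        named tap's output is ``seed`` (used by representation inversion)."""
        if layer_name == "input":
            return seed
        if layer_name not in self.taps:
            raise KeyError(f"unknown layer {layer_name!r}")
        d = seed
        for i in range(self.taps[layer_name], -1, -1):
            d = self.layers[i].backward(d, caches[i], guided=guided)
        return d
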