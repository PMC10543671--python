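import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest

import braggcam as bc
from braggcam.training import TrainConfig, train


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy five-class dataset reused by fast unit tests."""
    return bc.binarize_labels(bc.generate_dataset(8, seed=123, test_fraction=0.25))


@pytest.fixture(scope="session")
def desk_study():
    """The desk-scale study conditions: 500 train + 100 test frames per class,
    five-class and hit/miss AlexNet-style models trained with the desk recipe."""
    ds = bc.binarize_labels(bc.generate_dataset(600, seed=11, test_fraction=1 / 6))
    five = bc.build_model(bc.desk_alexnet_spec(), seed=7)
    five, hist5 = train(five, ds, TrainConfig(seed=5))
    binary = bc.build_model(bc.desk_alexnet_spec(n_classes=2), seed=8)
    binary, hist2 = train(binary, ds, TrainConfig(seed=6), binary=True)
    return SimpleNamespace(
        dataset=ds, five=five, binary=binary, hist_five=hist5, hist_binary=hist2
    )


def make_model(net, input_size, n_classes, last_conv="conv1", layer_names=()):
    """Wrap a hand-built Network in the CNNModel interface for explanation tests."""
    from braggcam.models import CNNModel

    spec = SimpleNamespace(
        input_size=input_size,
        in_channels=1,
        n_classes=n_classes,
        last_conv_layer=last_conv,
        layer_names=tuple(layer_names) or tuple(net.taps),
    )
    return CNNModel(spec, net)
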