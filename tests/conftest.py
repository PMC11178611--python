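import numpy as np
import pytest

from xrelcam import netkit, synthcle


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic dataset (seed 0) + toy CNN trained on it.

    Trained once per session; used by integration and acceptance-style
    tests. Returns (model, samples, test_split).
    """
    cfg = synthcle.SynthConfig()
    samples = synthcle.generate_dataset(cfg)
    x_tr, y_tr = synthcle.as_arrays(synthcle.samples_by_split(samples, "train"))
    x_va, y_va = synthcle.as_arrays(synthcle.samples_by_split(samples, "val"))
    model = netkit.build_toy_cnn(n_classes=2, image_size=cfg.image_size,
                                 seed=0)
    model, log = netkit.train_classifier(model, x_tr, y_tr, x_va, y_va,
                                         netkit.TrainConfig(seed=0))
    return model, samples, synthcle.samples_by_split(samples, "test")


@pytest.fixture(scope="session")
def dropout_benchmark(benchmark):
    """Dropout-enabled (rate 0.1) model trained on the same benchmark data."""
    _, samples, test = benchmark
    x_tr, y_tr = synthcle.as_arrays(synthcle.samples_by_split(samples, "train"))
    x_va, y_va = synthcle.as_arrays(synthcle.samples_by_split(samples, "val"))
    model = netkit.build_toy_cnn(n_classes=2, image_size=64,
                                 dropout_rate=0.1, seed=0)
    model, _ = netkit.train_classifier(
        model, x_tr, y_tr, x_va, y_va,
        netkit.TrainConfig(seed=0, dropout_rate=0.1))
    return model, test


@pytest.fixture()
def small_model():
    """Untrained narrow 4-stage CNN on 32x32 inputs, for fast unit tests."""
    return netkit.build_toy_cnn(n_classes=2, image_size=32,
                                widths=(4, 8, 8, 8), seed=7)


@pytest.fixture()
def small_image():
    rng = np.random.default_rng(3)
    return rng.random((32, 32))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small fast dataset for training-behaviour tests (not the benchmark)."""
    cfg = synthcle.SynthConfig(image_size=32, n_per_class=10, seed=1,
                               blob_radius_range=(3, 6))
    return synthcle.generate_dataset(cfg)
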