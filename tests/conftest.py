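import numpy as np
import pytest

from drybench import synthgen
from drybench.preprocess import EpochSet


@pytest.fixture(scope="session")
def default_layout():
    return synthgen.gen_layout()


@pytest.fixture(scope="session")
def quiet_field_config():
    """Single wide band, no burst/ERP/noise — a bare spatial Gaussian field."""
    return synthgen.GeneratorConfig(
        fs=200.0,
        duration_s=60.0,
        bands=(synthgen.BandSpec("Wide", 2.0, 30.0, 5.0, 60.0),),
        burst=None,
        erp=None,
        noise=synthgen.NoiseSpec(0.0, 1.0, 0.0, 0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_synthetic(default_layout):
    """Short default-condition recording at the full 2 kHz rate."""
    cfg = synthgen.default_config(duration_s=30.0, seed=11)
    return synthgen.gen_recording(cfg, default_layout)


def make_epochset(data, fs, labels, kind="regular", window=(0.0, 2.0)):
    data = np.asarray(data, dtype=float)
    return EpochSet(
        data=data,
        fs=fs,
        labels=list(labels),
        kind=kind,
        window_s=window,
        baseline_s=None,
        starts=np.zeros(data.shape[0], dtype=np.int64),
    )
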