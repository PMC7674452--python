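import numpy as np
import pytest

from dropletquant import (
    DetectConfig,
    SyntheticSpec,
    delineate_roi,
    generate_stack,
    iterative_detect,
)


@pytest.fixture(scope="session")
def benchmark():
    """The standard fixed-seed benchmark: stack, ground truth, and ROI."""
    spec = SyntheticSpec()
    stack, truth = generate_stack(spec)
    roi = delineate_roi(stack)
    return spec, stack, truth, roi


@pytest.fixture(scope="session")
def benchmark_particles(benchmark):
    """Raw (pre-dedup) detections on the benchmark at default config."""
    _, stack, _, roi = benchmark
    return iterative_detect(stack, roi, DetectConfig(), brain_id="benchmark")


@pytest.fixture()
def two_blob_slice():
    """One bright and one dim blob on flat background; 64x64 single slice."""
    img = np.full((64, 64), 10, dtype=np.uint8)
    yy, xx = np.mgrid[0:64, 0:64]
    img[(yy - 20) ** 2 + (xx - 20) ** 2 <= 16] = 200  # bright, r=4
    img[(yy - 45) ** 2 + (xx - 45) ** 2 <= 16] = 60  # dim, r=4
    return img
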