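import numpy as np
import pytest

from clupaq.peaks import PeakDetectionParams
from clupaq.simulate import Peak, make_misaligned_cohort


@pytest.fixture(scope="session")
def misaligned_cohort():
    """10 spectra, 8192 points, 15 peaks, global shifts in [-50, 50], SNR ~ 20."""
    rng = np.random.default_rng(42)
    apexes = np.sort(rng.choice(np.arange(300, 7900, 80), 15, replace=False))
    template = [
        Peak(int(a), float(h), float(w))
        for a, h, w in zip(apexes, rng.uniform(60, 150, 15), rng.uniform(4, 10, 15))
    ]
    sset, truth = make_misaligned_cohort(
        template, 10, length=8192, shift_range=(-50, 50), noise_sd=5.0, seed=7
    )
    return sset, truth


@pytest.fixture(scope="session")
def detect_params():
    return PeakDetectionParams(segment_size=1024, baseline_thresh=20.0)
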