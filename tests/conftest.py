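import numpy as np
import pytest

import ventrivol as vv


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free two-mode phantom: cavity 30, brain 120, shell 220."""
    return vv.generate_phantom(vv.PhantomSpec(speckle_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study-condition phantom (speckle sigma 0.05)."""
    return vv.generate_phantom(vv.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_dataset(noisy_phantom):
    """A small slice corpus from one phantom (narrowed ROI for speed)."""
    vol, lab = noisy_phantom
    roi = vv.auto_roi(lab)
    mid = (roi.first + roi.last) // 2
    roi = vv.SagittalROI(mid - 10, mid + 10)
    return vv.build_dataset([vol], [lab], [roi], seed=3)
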