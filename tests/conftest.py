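import numpy as np
import pytest

import siftstab as st


@pytest.fixture(scope="session")
def phantom_256():
    """One fixed 256x256 phantom shared across tests."""
    return st.generate_phantom(st.PhantomSpec(width=256, height=256, seed=1))


@pytest.fixture(scope="session")
def phantom_128():
    return st.generate_phantom(st.PhantomSpec(width=128, height=128, seed=2))


@pytest.fixture(scope="session")
def detected_256(phantom_256):
    """Keypoints + scale space of the shared phantom at default thresholds."""
    kps, ss, counts = st.detect_keypoints(phantom_256)
    return kps, ss, counts


def make_keypoint(x=10.0, y=12.0, octave=0, contrast=0.05, evr=2.0,
                  orientation=float("nan")):
    """Minimal keypoint stub for geometry-only tests."""
    return st.Keypoint(x_oct=x / 2 ** octave, y_oct=y / 2 ** octave,
                       octave=octave, level=1, sigma=1.6 * 2 ** octave,
                       x_base=x, y_base=y, contrast=contrast, evr=evr,
                       orientation=orientation)
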