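import numpy as np
import pytest

from bezridge.synthgen import (PatternSpec, arc_skeleton, generate,
                               grating_skeleton, y_skeleton)


@pytest.fixture(scope="session")
def grating():
    return grating_skeleton((128, 128), period=8)


@pytest.fixture(scope="session")
def arcs():
    return arc_skeleton((160, 160), period=8)


@pytest.fixture(scope="session")
def y_fixture():
    skel, bif = y_skeleton((96, 128), period=8)
    return skel, np.array(bif)


@pytest.fixture(scope="session")
def whorl_sample():
    return generate(PatternSpec(pattern="whorl", size=(300, 300), seed=3))


@pytest.fixture(scope="session")
def arch_sample():
    return generate(PatternSpec(pattern="plain-arch", size=(300, 300), seed=5))
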