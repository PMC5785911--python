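import numpy as np
import pytest

from voxmc.scene import make_benchmark


@pytest.fixture(scope="session")
def b1():
    return make_benchmark("B1")


@pytest.fixture(scope="session")
def b2():
    return make_benchmark("B2")


@pytest.fixture(scope="session")
def warm_kernel(b1):
    """Compile the transport kernel once per session on a tiny run."""
    import voxmc

    scene, src = b1
    voxmc.run(scene, src, nphoton=10, seed=0)


@pytest.fixture()
def rng0():
    from voxmc.rng import RandomStream

    return RandomStream(seed=42, stream_id=0)
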