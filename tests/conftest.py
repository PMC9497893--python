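import numpy as np
import pytest

# the eight grouped-layer configurations of the published per-layer table,
# as (ic, f, ch) -> expected (GK1, FgK1, GK2, GL1, FgL1, GL2, total, pct)
TABLE1 = {
    (14, 10, 4): (4, 2, 2, 3, 3, 1, 80, 57.14),
    (160, 3840, 16): (10, 384, 0, 0, 0, 0, 61440, 10.00),
    (160, 3840, 32): (5, 768, 0, 0, 0, 0, 122880, 20.00),
    (192, 1152, 16): (12, 96, 0, 0, 0, 0, 18432, 8.33),
    (192, 1152, 32): (6, 192, 0, 0, 0, 0, 36864, 16.67),
    (1152, 320, 16): (72, 4, 32, 20, 16, 0, 10240, 2.78),
    (1152, 320, 32): (36, 8, 32, 10, 32, 0, 20480, 5.56),
    (3840, 640, 16): (240, 2, 160, 40, 16, 0, 20480, 0.83),
    (3840, 640, 32): (120, 5, 40, 20, 32, 0, 40960, 1.67),
}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
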