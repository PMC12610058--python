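import numpy as np
import pytest

from veinfed.synthetic import (
    ClientSpec,
    SyntheticFederationSpec,
    generate_federation,
)


class StubEncoder:
    """Encoder contract stub returning preset unit vectors by class label."""

    def __init__(self, d=8, table=None):
        self.d = d
        self.table = table or {}
        self._params = np.zeros(1)

    def embed(self, images):
        rows = []
        for im in np.asarray(images, dtype=float):
            key = round(float(im.mean()), 6)
            if key in self.table:
                rows.append(self.table[key])
            else:
                v = np.zeros(self.d)
                v[hash(key) % self.d] = 1.0
                rows.append(v)
        return np.stack(rows)

    def get_flat_params(self):
        return self._params

    def set_flat_params(self, flat):
        self._params = np.asarray(flat)


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticFederationSpec(
        clients=(
            ClientSpec(n_classes=4, samples_per_class=3, image_height=32,
                       image_width=64, noise_sd=3.0),
            ClientSpec(n_classes=3, samples_per_class=2, image_height=32,
                       image_width=64, contrast_level=0.7, noise_sd=6.0),
        ),
        master_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_federation(tiny_spec):
    return generate_federation(tiny_spec)


@pytest.fixture(scope="session")
def small_encoder():
    from veinfed.encoder import SmallConvEncoder

    return SmallConvEncoder(seed=3, d=16)
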