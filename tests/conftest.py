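import numpy as np
import pandas as pd
import pytest

import dapquant as dq

AX = ["x_nm", "y_nm", "z_nm"]


@pytest.fixture(scope="session")
def outer_ring():
    """Noise-free ninefold ring at the outer-ring scale (513.4 nm)."""
    cfg = dq.RingConfig(diameter_nm=513.4)
    field, truth = dq.gen_ring_image(cfg)
    return field, truth


@pytest.fixture(scope="session")
def inner_ring():
    """Noise-free ninefold ring at the inner-ring scale (308.6 nm)."""
    cfg = dq.RingConfig(diameter_nm=308.6)
    field, truth = dq.gen_ring_image(cfg)
    return field, truth


def make_cluster(n, center, sigmas, seed, channel=0):
    """Anisotropic Gaussian localization cloud with 10 nm-scale CRLB noise."""
    rng = np.random.default_rng(seed)
    crlb = np.clip(rng.normal(10.0, 3.0, n), 2.0, None)
    pts = np.asarray(center, float) + rng.normal(size=(n, 3)) * np.asarray(sigmas, float)
    pts[:, :2] += rng.normal(size=(n, 2)) * crlb[:, None]
    pts[:, 2] += rng.normal(size=n) * 1.5 * crlb
    return pd.DataFrame(
        {
            "frame": rng.integers(0, 1000, n),
            "x_nm": pts[:, 0],
            "y_nm": pts[:, 1],
            "z_nm": pts[:, 2],
            "photons": 2000.0,
            "crlb_xy_nm": crlb,
            "channel": channel,
        }
    )
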