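import numpy as np
import pytest

from myoquant import synthetic


@pytest.fixture(scope="session")
def small_field():
    """One deterministic 600x600 simulated field at the myoblast regime."""
    spec = synthetic.ImageSimSpec(
        field_shape_px=(600, 600), n_nuclei=5, interior_to_rim_ratio=0.4, seed=7
    )
    return synthetic.simulate_image_field(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_label_mask(rng: np.random.Generator, shape=(32, 32), n_blobs=2) -> np.ndarray:
    """Small random label grid built from overlapping random disks."""
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for lab in range(1, n_blobs + 1):
        cr, cc = rng.integers(4, shape[0] - 4), rng.integers(4, shape[1] - 4)
        r = rng.integers(3, 9)
        disk = (yy - cr) ** 2 + (xx - cc) ** 2 <= r**2
        labels[disk & (labels == 0)] = lab
    # keep only connected components of each label (disks may be split by earlier labels)
    from skimage import measure

    out = np.zeros(shape, dtype=np.int32)
    nxt = 1
    for lab in range(1, n_blobs + 1):
        comp = measure.label(labels == lab, connectivity=2)
        for c in range(1, comp.max() + 1):
            out[comp == c] = nxt
            nxt += 1
    return out
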