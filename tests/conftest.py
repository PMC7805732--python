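import numpy as np
import pytest

import kneegrade as kg


def oracle_raw_moment(image, p, q):
    """Explicit nested-loop raw moment; x = column, y = row."""
    total = 0.0
    for y in range(image.shape[0]):
        for x in range(image.shape[1]):
            total += (x**p) * (y**q) * float(image[y, x])
    return total


def oracle_central_moment(image, p, q):
    m00 = oracle_raw_moment(image, 0, 0)
    xbar = oracle_raw_moment(image, 1, 0) / m00
    ybar = oracle_raw_moment(image, 0, 1) / m00
    total = 0.0
    for y in range(image.shape[0]):
        for x in range(image.shape[1]):
            total += ((x - xbar) ** p) * ((y - ybar) ** q) * float(image[y, x])
    return total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def random_images(rng):
    """50 small random intensity images with positive mass."""
    images = []
    for _ in range(50):
        shape = (int(rng.integers(2, 17)), int(rng.integers(2, 17)))
        images.append(rng.integers(0, 256, size=shape).astype(float) + 1.0)
    return images


@pytest.fixture(scope="session")
def noise_free_phantom():
    return kg.generate_phantom(
        kg.PhantomSpec(grade=kg.KLGrade.NORMAL, noise_sd=0.0, seed=5)
    )


@pytest.fixture(scope="session")
def blob():
    return kg.smooth_blob(256)
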