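import numpy as np
import pytest

from tspoquant import PipelineConfig
from tspoquant.synthetic import ImageSimParams, generate_multiplex_image

# ~80 nuclei on 512 px: fast enough for per-module tests
SMALL = dict(shape=(512, 512))

# ~300 nuclei on 1024 px: the benchmark condition
BENCH = dict(
    shape=(1024, 1024),
    n_spherical=150,
    n_elliptical=45,
    n_bilobed=30,
    n_cluster=15,
    n_debris=10,
)


@pytest.fixture(scope="session")
def small_image():
    params = ImageSimParams(**SMALL)
    image, truth = generate_multiplex_image(params, seed=11)
    return params, image, truth


@pytest.fixture(scope="session")
def small_config(small_image):
    params, _, _ = small_image
    return PipelineConfig(thresholds=params.default_thresholds())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def match_nuclei(truth, nuclei, max_dist=3.0):
    """One-to-one truth/segmentation matching by centroid distance."""
    from scipy.optimize import linear_sum_assignment

    tc = truth.nuclei[["centroid_y", "centroid_x"]].to_numpy()
    if not nuclei:
        return {}, len(tc), 0
    sc = np.array([n.centroid for n in nuclei])
    D = np.linalg.norm(tc[:, None, :] - sc[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(D)
    match = {int(i): int(j) for i, j in zip(ri, ci) if D[i, j] <= max_dist}
    return match, len(tc), len(sc)
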