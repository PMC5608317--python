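import numpy as np
import pytest

from grassvlad.manifold import GrassmannPoint, TangentVector, exp_map


def rand_orth(rng, n=3):
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def rand_point(rng, p=9, r=3) -> GrassmannPoint:
    q, _ = np.linalg.qr(rng.standard_normal((p, r)))
    return GrassmannPoint(q)


def perturb(point: GrassmannPoint, rng, scale=0.05) -> GrassmannPoint:
    """Small random geodesic step away from a point (stays near it)."""
    X = point.basis
    D = rng.standard_normal(X.shape) * scale
    D = D - X @ (X.T @ D)
    return exp_map(point, TangentVector(delta=D, base=point))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small 2-class synthetic dataset for pipeline-level tests."""
    from grassvlad.synthetic import SyntheticDatasetSpec, make_dataset

    out = tmp_path_factory.mktemp("tiny_ds")
    spec = SyntheticDatasetSpec(
        n_classes=2, images_per_class=6, image_size=32, patch_size=8,
        patients_per_class=3, seed=7,
    )
    manifest = make_dataset(spec, out)
    return manifest
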