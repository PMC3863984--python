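import numpy as np
import pytest

from hearmri import CohortSpec, TwoLayerModel, generate_cohort, loocv
from hearmri.model import PipelineConfig
from hearmri.sift import SiftFeature


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_feature(
    x=(0.0, 0.0, 0.0),
    sigma=1.0,
    orient=0.0,
    appearance=None,
    subject_id="s1",
    group="HI",
    cube_index=(0, 0, 0),
    orientation="axial",
    rng=None,
):
    """Construct a SiftFeature with a unit-normalized appearance descriptor."""
    if appearance is None:
        appearance = (
            rng.standard_normal(128) if rng is not None else np.ones(128)
        )
    appearance = np.asarray(appearance, dtype=float)
    appearance = appearance / np.linalg.norm(appearance)
    return SiftFeature(
        x=np.asarray(x, dtype=float),
        sigma=float(sigma),
        orient=float(orient),
        appearance=appearance,
        subject_id=subject_id,
        group=group,
        cube_index=tuple(cube_index),
        orientation=orientation,
    )


def random_features(n, rng, spread=4.0, **kwargs):
    """A bank of random features in one (cube, orientation) group."""
    feats = []
    for i in range(n):
        feats.append(
            make_feature(
                x=rng.uniform(0, spread, 3),
                sigma=float(np.exp(rng.normal(np.log(2.0), 0.4))),
                orient=float(rng.uniform(0, 2 * np.pi)),
                appearance=rng.standard_normal(128),
                subject_id=kwargs.get("subject_id", f"s{i % 6}"),
                group=("HI" if (i % 6) < 3 else "NH"),
            )
        )
    return feats


def clustered_features(rng, n_clusters=4, per_cluster=12):
    """Tight feature clusters (nonempty similar sets) with mixed group origins."""
    feats = []
    for c in range(n_clusters):
        proto_a = rng.standard_normal(128)
        proto_a /= np.linalg.norm(proto_a)
        proto_x = rng.uniform(2, 15, 3)
        proto_o = rng.uniform(0, 2 * np.pi)
        # skew group membership differently per cluster
        n_hi = (c * per_cluster) // n_clusters
        for i in range(per_cluster):
            a = proto_a + rng.normal(0, 0.02, 128)
            feats.append(
                make_feature(
                    x=proto_x + rng.normal(0, 0.2, 3),
                    sigma=float(2.0 * np.exp(rng.normal(0, 0.05))),
                    orient=float((proto_o + rng.normal(0, 0.1)) % (2 * np.pi)),
                    appearance=a,
                    subject_id=f"{'p' if i < n_hi else 'c'}{i % 3}",
                    group=("HI" if i < n_hi else "NH"),
                )
            )
    return feats


STRONG_SPEC = CohortSpec(
    n_hi=3,
    n_nh=3,
    grid_shape=(40, 40, 20),
    seed=0,
    blob_effect=2.5,
    activation_effect=2.5,
    noise_sd=0.05,
    subject_variability=0.2,
)


@pytest.fixture(scope="session")
def strong_cohort():
    """A small cohort with an overwhelming planted group effect."""
    return generate_cohort(STRONG_SPEC)


@pytest.fixture(scope="session")
def strong_model(strong_cohort):
    return TwoLayerModel(strong_cohort, PipelineConfig())


@pytest.fixture(scope="session")
def strong_loocv(strong_model):
    return loocv(strong_model)
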