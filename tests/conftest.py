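import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from noduletrack.synthetic import NoduleCountSpec, SyntheticConfig
from noduletrack.types import NoduleRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_affine(rng, max_rot_deg=10.0, scale_range=(0.95, 1.05), max_trans=20.0):
    """A random invertible affine inside the jitter ranges the pipeline is
    designed for."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg))
    linear = rng.uniform(*scale_range) * Rotation.from_rotvec(angle * axis).as_matrix()
    translation = rng.uniform(-max_trans, max_trans, size=3)
    return linear, translation


def make_record(lesion_id, centroid, diameter_mm=8.0, **kw):
    defaults = dict(
        exam_id="exam", localization="parenchymal", texture="solid", case_id="case"
    )
    defaults.update(kw)
    return NoduleRecord(
        lesion_id=lesion_id, centroid=centroid, diameter_mm=diameter_mm, **defaults
    )


def clean_config(**overrides):
    """Study conditions with every error source switched off: affine-only
    deformation, full detection, well-separated nodules."""
    base = dict(
        n_cases=20,
        seed=7,
        nodules_per_case=NoduleCountSpec(kind="fixed", n=6),
        dropout_prob=0.0,
        dropout_count_coupling=0.0,
        localization_dropout_factors=(1.0, 1.0, 1.0, 1.0),
        fp_rate=0.0,
        disappear_prob=0.0,
        subsolid_prob=0.0,
        diaphragm_shift_mm=0.0,
        residual_jitter_mm=0.0,
        occlusion_per_nodule=0.0,
        min_separation_mm=35.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
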