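import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytoscreen.annotio import LabelSet, NucleusAnnotation
from cytoscreen.activeloop import FieldRecord
from cytoscreen.synthcyto import SceneSpec, generate_field

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SEPARABLE_MIX = (0.80, 0.10, 0.10)  # abnormal-enriched fields, well-separated classes
NORMAL_MIX = (0.996, 0.004, 0.0)


def make_field_record(seed: int, mix=SEPARABLE_MIX, n_cells: int = 24) -> FieldRecord:
    """One rendered synthetic field wrapped as a dataset record."""
    spec = SceneSpec(n_cells=n_cells, class_mix=mix, seed=seed)
    image, anns = generate_field(spec)
    image_id = f"img{seed:06d}"
    anns = [NucleusAnnotation(image_id, a.polygon, a.cls) for a in anns]
    return FieldRecord(
        image_id=image_id,
        image=image,
        truth=LabelSet(image_id, spec.field_size[0], spec.field_size[1], anns),
    )


def make_dataset(base_seed: int, n_images: int, abnormal_fraction: float = 0.5):
    """A mixed dataset of abnormal-enriched and normal fields."""
    rng = np.random.default_rng(base_seed)
    records = []
    for i in range(n_images):
        mix = SEPARABLE_MIX if rng.random() < abnormal_fraction else NORMAL_MIX
        records.append(make_field_record(int(base_seed * 10_000 + i), mix=mix))
    return records


@pytest.fixture(scope="session")
def separable_dataset():
    """40 separable fields shared by detector and protocol tests."""
    return make_dataset(7, 40)


@pytest.fixture(scope="session")
def trained_detector(separable_dataset):
    from cytoscreen.cellnet import train_detector

    train = separable_dataset[:30]
    return train_detector(
        [r.image for r in train], [r.truth for r in train], seed=0
    )
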