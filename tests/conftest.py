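import numpy as np
import pytest

from wbcnet.dataset_io import CLASS_NAMES, ImageRecord, LabeledDataset
from wbcnet.synthetic_cells import SyntheticConfig, generate_dataset
from wbcnet.preprocess import preprocess_pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_raw_dataset():
    """Small raw synthetic set: 3/2/2/2/2 images per class at 361x360."""
    counts = dict(zip(CLASS_NAMES, (3, 2, 2, 2, 2)))
    return generate_dataset(SyntheticConfig(counts=counts, seed=42))


@pytest.fixture(scope="session")
def tiny_preprocessed_dataset(tiny_raw_dataset):
    return preprocess_pipeline(tiny_raw_dataset)


def make_label_dataset(counts: dict[str, int]) -> LabeledDataset:
    """1x1-pixel records with labels only; for fold/metric tests."""
    records = []
    for cname, n in counts.items():
        for i in range(n):
            records.append(ImageRecord(np.zeros((1, 1, 3), dtype=np.uint8),
                                       label=cname, source_path=f"{cname}/{i}"))
    return LabeledDataset(records)
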