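import numpy as np
import pytest

from tautrace.ihc_morphometry import segment_objects
from tautrace.synthetic_data import gen_ihc_section

DEFAULT_COUNTS = {"NFT": 50, "CB": 50, "TA": 70, "TF": 30}
EXEMPLAR_COUNTS = {"NFT": 20, "CB": 20, "TA": 20, "TF": 20}
SEG_THRESHOLD = 30.0  # background 10 + noise sd 2 << 30 << object intensity >= 50


def match_truth_labels(objects, truth):
    """Map segmented objects to planted class labels via the object map."""
    labels = []
    for obj in objects:
        ids = truth.object_map[obj.coords[:, 0], obj.coords[:, 1]]
        ids = ids[ids > 0]
        if len(ids) == 0:
            labels.append(None)
            continue
        labels.append(truth.objects[np.bincount(ids).argmax() - 1].label)
    return labels


@pytest.fixture
def truth_matcher():
    return match_truth_labels


@pytest.fixture(scope="session")
def ihc_section():
    """Default mixed section: 100 NFT/CB-channel + 100 TA/TF-channel objects."""
    image, truth = gen_ihc_section(counts=DEFAULT_COUNTS, seed=1)
    return image, truth


@pytest.fixture(scope="session")
def segmented_section(ihc_section):
    image, truth = ihc_section
    objects = segment_objects(image, intensity_threshold=SEG_THRESHOLD)
    return image, truth, objects


@pytest.fixture(scope="session")
def exemplar_section():
    """Held-out exemplar section (separate seed) for rule calibration."""
    image, truth = gen_ihc_section(counts=EXEMPLAR_COUNTS, seed=1001)
    objects = segment_objects(image, intensity_threshold=SEG_THRESHOLD)
    labels = match_truth_labels(objects, truth)
    return objects, labels
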