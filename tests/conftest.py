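import numpy as np
import pytest

from ldscreen import PROFILES, SceneSpec, render_field
from ldscreen.imaging import segment_cells, segment_nuclei, segment_puncta


@pytest.fixture(scope="session")
def patient_field():
    """One rendered patient-phenotype field plus its ground truth (session
    scope: rendering + segmentation is reused across read-only tests)."""
    img, gt = render_field(SceneSpec(), PROFILES["patient"], seed=3)
    return img, gt


@pytest.fixture(scope="session")
def segmented(patient_field):
    img, gt = patient_field
    nuclei = segment_nuclei(img)
    cells = segment_cells(img, nuclei)
    puncta = segment_puncta(img, cells)
    return img, gt, nuclei, cells, puncta


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
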