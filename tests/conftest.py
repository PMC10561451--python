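import numpy as np
import pytest

import fociscreen as fs
from fociscreen.synthdata import make_single_cell_crops


@pytest.fixture(scope="session")
def small_config():
    """Small field for fast unit tests; statistics match the defaults."""
    return fs.SimConfig(image_size=(256, 256), cells_per_field=10)


@pytest.fixture(scope="session")
def labeled_crops():
    """Generator-rendered single-cell crops with exact truth labels."""
    crops, labels, cells = make_single_cell_crops(700, fs.SimConfig(), seed=11)
    return crops, labels, cells


@pytest.fixture(scope="session")
def trained_classifier(labeled_crops):
    crops, labels, _ = labeled_crops
    clf = fs.CellClassifier(random_state=0)
    clf.fit(crops[:450], labels[:450])
    return clf


@pytest.fixture(scope="session")
def dox_field(small_config):
    """One DOX-treated small field plus its ground truth."""
    return fs.generate_field(
        small_config, fs.Treatment(dose_uM=0.5, role="dox"), seed=42
    )
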