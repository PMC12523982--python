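import numpy as np
import pytest

from qpihuvec import (CellPhantomSpec, OpticsConfig, render_cell, segment,
                      measure)


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def hemisphere_case(optics):
    """Rendered hemisphere phantom (radius 15 µm, 0.5 µm/px) with truth."""
    spec = CellPhantomSpec("spherical_cap", (15.0, 15.0), 15.0)
    image, truth = render_cell(spec, optics=optics, canvas=(128, 128))
    return image, truth


@pytest.fixture(scope="session")
def hemisphere_record(hemisphere_case):
    image, truth = hemisphere_case
    labels = segment(image)
    records = measure(image, labels)
    assert len(records) == 1
    return records[0], truth.objects[0]


def measure_single(spec, optics=None, canvas=(160, 160)):
    """Render one phantom, segment and measure it; return (record, truth)."""
    image, truth = render_cell(spec, optics=optics, canvas=canvas)
    labels = segment(image)
    records = measure(image, labels)
    assert len(records) == 1, f"expected one object, segmented {len(records)}"
    return records[0], truth.objects[0]
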