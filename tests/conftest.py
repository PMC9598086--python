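import numpy as np
import pytest

from osteotrace.core import AssemblageStore, SpecimenRecord
from osteotrace.simulate import make_template


@pytest.fixture(scope="session")
def template():
    """Standard bone-like template used across suites."""
    return make_template("femur", "left", 240.0, 12.0, (28.0, 30.0), 4000, seed=1)


@pytest.fixture(scope="session")
def uniform_tube():
    """Nearly constant-radius tube: x density of surface points ~ uniform."""
    return make_template("tibia", "right", 200.0, 12.0, (13.0, 13.0), 4000, seed=2)


@pytest.fixture()
def store(template):
    s = AssemblageStore()
    s.add_template(template)
    s.add_specimen(
        SpecimenRecord(
            specimen_id="SP1",
            site="siteA",
            taxon="cervid",
            element="femur",
            side="left",
            size_class=3,
            template_id=template.template_id,
        )
    )
    return s


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
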