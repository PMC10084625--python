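import pytest

from markerclust.io_model import read_alignments
from markerclust.simulate import (
    detection_floor_scenario,
    generate_fixture,
)


@pytest.fixture
def floor_fixture(tmp_path):
    """Detection-floor bundle: 2 perfect reads on 2 markers of one taxon."""
    return generate_fixture(detection_floor_scenario(), seed=7, out_dir=tmp_path)


@pytest.fixture
def floor_alignments(floor_fixture):
    return read_alignments(str(floor_fixture.sam))


def records_for(scenario, tmp_path, seed=7, prefix="fixture"):
    """Materialize a scenario and read its alignments back."""
    paths = generate_fixture(scenario, seed=seed, out_dir=tmp_path, prefix=prefix)
    return paths, read_alignments(str(paths.sam))
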