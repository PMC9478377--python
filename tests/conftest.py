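import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# hand-written 12-particle fixture: 2 samples, known tallies
PARTICLE_TSV = """\
sample_id	region	depth_layer	size_class	shape	color	polymer
A1	SD	0-20 cm	<0.5 mm	fiber	black	Rayon
A1	SD	0-20 cm	<0.5 mm	fiber	transparent	Rayon
A1	SD	0-20 cm	0.5-1 mm	fiber	white	PE
A1	SD	0-20 cm	1-2 mm	pellet	blue	PP
A1	SD	0-20 cm	2-5 mm	fragment	black	PET
A1	SD	0-20 cm	<0.5 mm	fiber	other	Polyester
B1	HE	20-40 cm	<0.5 mm	fiber	black	Rayon
B1	HE	20-40 cm	<0.5 mm	fiber	black	Polyester
B1	HE	20-40 cm	0.5-1 mm	foam	transparent	PS
B1	HE	20-40 cm	<0.5 mm	film	white	PA
B1	HE	20-40 cm	1-2 mm	fiber	blue	PP+PE
B1	HE	20-40 cm	<0.5 mm	fiber	transparent	Acrylic
"""

META_TSV = """\
sample_id	region	depth_layer	replicate	soil_mass_g
A1	SD	0-20 cm	1	10
B1	HE	20-40 cm	1	10
"""


@pytest.fixture
def particle_fixture() -> pd.DataFrame:
    from mpcommunity import read_particle_table

    return read_particle_table(io.StringIO(PARTICLE_TSV))


@pytest.fixture
def meta_fixture() -> pd.DataFrame:
    from mpcommunity import io as mio

    return mio.read_sample_meta(io.StringIO(META_TSV))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
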