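import numpy as np
import pytest

from ahremd import make_domain_bead_model, make_double_well
from ahremd.config import RunConfig, SystemBlock, build_cvs
from ahremd.cv import AtomGroup, CVDefinition


from _helpers import origin_cv  # noqa: F401  (shared test helper)


@pytest.fixture
def dw_spec():
    return make_double_well(6.0, 1.0)


@pytest.fixture
def dw_cvs(dw_spec):
    return build_cvs(RunConfig(system=SystemBlock(fixture="double_well")), dw_spec)


@pytest.fixture
def bead_spec():
    return make_domain_bead_model(n_domains=3, beads_per_domain=4,
                                  inter_domain=(4.0, 4.0, 8.0), seed=7)


@pytest.fixture
def bead_cvs(bead_spec):
    def grp(name):
        idx = bead_spec.groups[name]
        return AtomGroup(name=name, indices=idx, masses=bead_spec.masses[idx])

    return [
        CVDefinition(name="CV_1", group_a=grp("domain_0"), group_b=grp("domain_1")),
        CVDefinition(name="CV_2", group_a=grp("domain_1"), group_b=grp("domain_2")),
    ]
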