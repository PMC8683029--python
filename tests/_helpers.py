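import numpy as np

from ahremd.cv import AtomGroup, CVDefinition


def origin_cv(name="CV_1", indices=(0,), masses=None):
    """CV: COM distance of a particle group to the origin (|x| for 1D toys)."""
    idx = np.asarray(indices, dtype=int)
    m = np.ones(len(idx)) if masses is None else np.asarray(masses, dtype=float)
    return CVDefinition(name=name, group_a=AtomGroup(name="a", indices=idx,
                                                     masses=m))
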