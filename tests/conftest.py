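import numpy as np
import pytest

from radsurv.imaging import DiscretizedVolume


def make_dv(bins, valid=None, spacing=(1.0, 1.0, 5.0)) -> DiscretizedVolume:
    """DiscretizedVolume straight from a small integer grid."""
    bins = np.asarray(bins, dtype=np.int64)
    if valid is None:
        valid = np.ones_like(bins, dtype=bool)
    return DiscretizedVolume(bins=np.where(valid, bins, -1), valid=valid, spacing=spacing)


@pytest.fixture(scope="session")
def small_phantom():
    """A compact heterogeneous phantom shared across tests."""
    from radsurv.synthetic import PhantomConfig, make_phantom

    cfg = PhantomConfig(shape=(40, 40, 12), spacing=(1.5, 1.5, 5.0),
                        tumor_semiaxes_mm=(10.0, 8.0, 10.0), seed=7)
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """n=60, p=30 cohort with 4 informative features at shift 1.5."""
    from radsurv.synthetic import CohortSpec, make_feature_cohort

    names = [f"F{i:02d}" for i in range(30)]
    spec = CohortSpec(n=60, seed=11, informative={n: 1.5 for n in names[:4]})
    table, labels, informative = make_feature_cohort(spec, names)
    return table, labels, informative
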