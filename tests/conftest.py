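import numpy as np
import pytest

from fetallineage.filtering import FilterConfig
from fetallineage.synthetic import SyntheticReference
from fetallineage.variant_io import SampleCall, SampleMeta, VariantRecord


def make_call(gt=(0, 1), gq=99, dp=30, ad=(15, 15)):
    return SampleCall(gt=gt, gq=gq, dp=dp, ad_ref=ad[0], ad_alt=ad[1])


def make_record(contig="chr1", pos=1000, ref="A", alt="T", qual=200.0, mq=60.0,
                clone="clone1", bulk="bulk1",
                clone_call=None, bulk_call=None, **kwargs):
    calls = kwargs.pop("calls", None)
    if calls is None:
        calls = {
            clone: clone_call if clone_call is not None else make_call(),
            bulk: bulk_call if bulk_call is not None else make_call(
                gt=(0, 0), gq=60, dp=30, ad=(30, 0)),
        }
    alts = (alt,) if isinstance(alt, str) else tuple(alt)
    return VariantRecord(contig=contig, pos=pos, ref=ref, alts=alts, qual=qual,
                         mq=mq, calls=calls, **kwargs)


@pytest.fixture
def filter_cfg():
    return FilterConfig()


@pytest.fixture
def meta_pair():
    return [
        SampleMeta("clone1", "d1", "clone", "HSPC", False, "F", 0.25),
        SampleMeta("bulk1", "d1", "bulk", "other", False, "F", 0.25),
    ]


@pytest.fixture
def meta_t21():
    return [
        SampleMeta("clone1", "d1", "clone", "HSPC", True, "F", 0.25),
        SampleMeta("bulk1", "d1", "bulk", "other", True, "F", 0.25),
    ]


@pytest.fixture
def meta_male():
    return [
        SampleMeta("clone1", "d1", "clone", "HSPC", False, "M", 0.25),
        SampleMeta("bulk1", "d1", "bulk", "other", False, "M", 0.25),
    ]


SMALL_GENOME = (("chr1", 200_000), ("chr2", 200_000), ("chr3", 200_000))


@pytest.fixture(scope="session")
def small_reference():
    """Shared reference for replicate-heavy simulations."""
    return SyntheticReference(SMALL_GENOME, seed=99)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
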