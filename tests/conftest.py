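import numpy as np
import pytest

from radres.synth import sim_signature_matrix
from radres.variants import VariantCall


@pytest.fixture(scope="session")
def sig_matrix():
    """A 10-signature synthetic spectrum matrix shared across tests."""
    return sim_signature_matrix(n_signatures=10, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_call(chrom="chr1", pos=100, ref="C", alt="T", caller="m", rep="rep1",
              sample="S", effect=None, context=None):
    return VariantCall(
        sample_id=sample, replicate_id=rep, caller_id=caller,
        chrom=chrom, pos=pos, ref=ref, alt=alt, effect=effect, context=context,
    )
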