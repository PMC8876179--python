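import numpy as np
import pytest

from ktdfe import MultiOmicsBlock, MultiOmicsTensorSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_set(rng):
    """Two blocks, 20 and 12 features, sharing 4x3 sample modes."""
    blocks = [
        MultiOmicsBlock(omics_id="expr", values=rng.normal(size=(20, 4, 3))),
        MultiOmicsBlock(omics_id="prot", values=rng.normal(size=(12, 4, 3))),
    ]
    return MultiOmicsTensorSet(blocks=blocks)


@pytest.fixture
def psd_kernel(rng):
    """A single PSD m=1 kernel slice wrapped as a (1, 6, 6) kernel tensor."""
    from ktdfe import KernelTensor, ModeRoles

    x = rng.normal(size=(15, 6))
    k = x.T @ x
    return KernelTensor(values=k[None, :, :], mode_roles=ModeRoles(1), omics_ids=["x"])
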