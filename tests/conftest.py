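import numpy as np
import pytest

from mrphewas import SummaryAssociation, SyntheticTruth, instrument_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ldl_truth():
    """A statin-mimic scenario: 56 independent instruments, theta = -1."""
    return SyntheticTruth(
        theta={"both": -1.0, "men": -1.0, "women": -1.0}, seed=7
    )


@pytest.fixture
def ldl_panel(ldl_truth):
    return instrument_panel(ldl_truth)


def make_assoc(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    **kw,
):
    return SummaryAssociation(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        **kw,
    )
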