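import hypothesis
import pytest

from estro_mr.harmonisation import HarmonisedPair
from estro_mr.summary_data import VariantAssociation

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


def make_assoc(**overrides) -> VariantAssociation:
    """A valid association record with keyword overrides."""
    base = dict(
        rsid="rs1",
        chrom="6",
        pos=151_700_000,
        effect_allele="A",
        other_allele="G",
        beta=0.05,
        se=0.002,
        p=1e-20,
        eaf=0.3,
        trait="bone mineral density",
        study_id="STUDY",
        n=400_000,
        ancestry="European",
        sex="combined",
    )
    base.update(overrides)
    return VariantAssociation(**base)


def make_pair(bx, by, sy, sx=0.001, rsid="rs1", **overrides) -> HarmonisedPair:
    base = dict(
        rsid=rsid,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        flipped=False,
        palindromic=False,
        status="kept",
    )
    base.update(overrides)
    return HarmonisedPair(**base)


@pytest.fixture
def assoc_factory():
    return make_assoc


@pytest.fixture
def pair_factory():
    return make_pair
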