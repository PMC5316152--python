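import pytest

from ribotrans.models import GeneModel
from ribotrans.simulate import EffectConfig, LengthParams, simulate_dataset


@pytest.fixture(scope="session")
def mixed_strand_dataset():
    """Small two-strand dataset with a few planted effects, reads emitted."""
    cfg = EffectConfig(
        mean_depth=150,
        frac_tx_up=0.05,
        frac_te_up=0.05,
        n_class1=3,
        n_class2=3,
        n_class3=3,
        seed=42,
    )
    lengths = LengthParams(minus_strand_fraction=0.5, utr5_min=25)
    return simulate_dataset(80, cfg, lengths)


@pytest.fixture
def plus_gene():
    # 5'UTR [1000,1060), CDS [1060,1360), 3'UTR [1360,1460)
    return GeneModel("gplus", "chrT", "+", tss=1000, cds_start=1060, cds_end=1360, utr3_end=1460)


@pytest.fixture
def minus_gene():
    # transcript runs right-to-left: 5'UTR [1400,1460), CDS [1100,1400), 3'UTR [1000,1100)
    return GeneModel("gminus", "chrT", "-", tss=1460, cds_start=1400, cds_end=1100, utr3_end=1000)
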