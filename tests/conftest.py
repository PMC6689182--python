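import warnings

import numpy as np
import pytest

from cisrate.data_model import Dataset, MRnaRecord
from cisrate.synthetic_data import GeneratorConfig, generate

warnings.filterwarnings("ignore", message="rank-deficient design")


def make_record(
    gene_id="g1",
    utr5="ACGCAUCGUA",
    body="GCUUAUGAAGCU",
    tr=2.0,
    rpkm=5.0,
):
    """Handmade record: CDS = AUG + body + UAA."""
    cds = "AUG" + body + "UAA"
    rec = MRnaRecord(
        gene_id=gene_id,
        seq=utr5 + cds,
        utr5_len=len(utr5),
        cds_len=len(cds),
        tr=tr,
        mrna_abundance=rpkm,
    )
    rec.validate()
    return rec


@pytest.fixture
def record():
    return make_record()


@pytest.fixture(scope="session")
def small_dataset():
    d, gt = generate(GeneratorConfig(n_genes=300, seed=42, target_r2=0.6))
    return d, gt


@pytest.fixture(scope="session")
def tiny_dataset():
    recs = [
        make_record(f"g{i}", utr5="ACGCAU" * (i + 1), tr=float(i + 1), rpkm=2.0 + i)
        for i in range(30)
    ]
    return Dataset(recs, name="tiny")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
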