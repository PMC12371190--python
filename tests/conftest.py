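import numpy as np
import pytest

from mbdmethyl.core import GenomicInterval, SampleRecord
from mbdmethyl.fixtures import load_discovery_cohort
from mbdmethyl.peaks import GeneModel


@pytest.fixture(scope="session")
def discovery():
    return load_discovery_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def toy_fasta(tmp_path):
    """Small FASTA with known CpG structure, indexed by pyfaidx."""
    import pyfaidx

    rng = np.random.default_rng(7)
    seqs = {
        "chrA": "ACGCGT" * 200,
        "chrB": "".join(rng.choice(list("ACGTacgtN"), size=5000)),
        "chrC": "CCCC" * 50,
    }
    path = tmp_path / "toy.fa"
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return pyfaidx.Fasta(str(path)), seqs


@pytest.fixture()
def gene_models():
    return [
        GeneModel(
            "G1",
            GenomicInterval("chr1", 10_000, 20_000),
            "+",
            exons=[GenomicInterval("chr1", 10_000, 10_500), GenomicInterval("chr1", 15_000, 15_800)],
        ),
        GeneModel(
            "G2",
            GenomicInterval("chr1", 50_000, 60_000),
            "-",
            exons=[GenomicInterval("chr1", 59_000, 60_000)],
        ),
    ]


def make_samples(groups, tissue="brain", seed=0, spike=1.0):
    """Quick cohort builder: groups is {classification: n}."""
    rng = np.random.default_rng(seed)
    out = []
    i = 0
    for cls in sorted(groups):
        for _ in range(groups[cls]):
            i += 1
            out.append(
                SampleRecord(
                    sample_id=f"t{i:03d}_{tissue}",
                    subject_id=f"t{i:03d}",
                    tissue=tissue,
                    classification=cls,
                    gender="M" if rng.random() < 0.5 else "F",
                    age_years=float(rng.uniform(5, 60)),
                    spike_enrichment_ratio=spike,
                )
            )
    return out
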