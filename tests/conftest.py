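import numpy as np
import pytest

from introdelta import PFM


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


TOY_GTF = """\
##description: toy annotation
chr1\tTEST\tgene\t101\t1100\t.\t+\t.\tgene_id "GENE1";
chr1\tTEST\ttranscript\t101\t1100\t.\t+\t.\tgene_id "GENE1"; transcript_id "GENE1.T1";
chr1\tTEST\texon\t101\t300\t.\t+\t.\tgene_id "GENE1"; transcript_id "GENE1.T1";
chr1\tTEST\texon\t601\t800\t.\t+\t.\tgene_id "GENE1"; transcript_id "GENE1.T1";
chr1\tTEST\ttranscript\t101\t1100\t.\t+\t.\tgene_id "GENE1"; transcript_id "GENE1.T2";
chr1\tTEST\texon\t901\t1100\t.\t+\t.\tgene_id "GENE1"; transcript_id "GENE1.T2";
chr2\tTEST\tgene\t1\t500\t.\t-\t.\tgene_id "GENE2";
chr2\tTEST\ttranscript\t1\t500\t.\t-\t.\tgene_id "GENE2"; transcript_id "GENE2.T1";
chr2\tTEST\texon\t1\t500\t.\t-\t.\tgene_id "GENE2"; transcript_id "GENE2.T1";
"""


@pytest.fixture
def toy_gtf():
    return TOY_GTF


@pytest.fixture
def simple_pfm():
    # strong AT-rich motif, length 5
    m = np.array([
        [0.90, 0.03, 0.03, 0.04],
        [0.05, 0.05, 0.05, 0.85],
        [0.05, 0.05, 0.05, 0.85],
        [0.05, 0.05, 0.05, 0.85],
        [0.90, 0.03, 0.03, 0.04],
    ])
    return PFM("M001", "TOYRBP", m)


def random_pfm(motif_id, rng, length=7, conc=0.3):
    return PFM(motif_id, motif_id, rng.dirichlet([conc] * 4, size=length))
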