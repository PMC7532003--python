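import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from apashift.genome import GeneRecord, GenomeBundle, revcomp
from apashift import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Hand-crafted 3'UTR windows (sense orientation, 40 nt each).  gP is a
# plus-strand gene; its offset 20 is a T followed by a 4-nt genomic A-run.
# gM is a minus-strand gene; its offset 12 is followed by a 2-nt A-run.
UTR_P = "CGTACGGTCTGCTTGCAGGT" + "AAAAGCCGTTAACGGATCCG"
UTR_M = "GGCTACGATCCGAACTGAGC" + "TTCTTGCACCAGGTCACCTT"
ORF_P = "ATGGCCATTGTAATGGGCCG"
SPACER = "GTCCGATTAC"
ORF_M_FWD = "CATGGCCTTACGGATCCGTA"


@pytest.fixture(scope="session")
def micro_bundle() -> GenomeBundle:
    seq = ORF_P + UTR_P + SPACER + revcomp(UTR_M) + ORF_M_FWD
    genes = [
        GeneRecord("gP", "chrT", "+", 1, 20, utr_len=40),
        GeneRecord("gM", "chrT", "-", 111, 130, utr_len=40),
    ]
    return GenomeBundle({"chrT": seq}, genes)


@pytest.fixture(scope="session")
def small_sim():
    """30-gene simulated dataset shared by read-through tests."""
    spec = synthetic.SyntheticSpec(
        n_genes=30, depth_per_replicate=2000, sensitive_fraction=0.2, seed=7
    )
    bundle, truth, counts = synthetic.simulate(spec)
    return spec, bundle, truth, counts


def counts_frame(rows):
    """Long count table from (condition, replicate, gene, offset, count) rows."""
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "gene", "offset", "count"]
    )
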