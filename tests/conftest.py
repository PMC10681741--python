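import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import panelkit as pk


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """200 samples x 300 sites, common AFs, with an error-injected arm."""
    spec = pk.CohortSpec(
        n_samples=200, n_sites=300,
        af_model=pk.AFModel("uniform", (0.05, 0.5)), seed=11,
    )
    sites, truth = pk.simulate_truth_cohort(spec)
    err = pk.ErrorModel(e_rr=0.02, e_ra=0.02, e_aa=0.02, dosage_sd=0.1)
    imp_sites, imputed = pk.simulate_imputed(truth, sites, err, seed=12)
    return sites, truth, imp_sites, imputed


@pytest.fixture
def handcrafted_vcf(tmp_path):
    """Three samples, two records (one multiallelic), literal text."""
    text = "\n".join([
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="AC">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="AN">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">',
        '##INFO=<ID=ExcessHet,Number=1,Type=Float,Description="EH">',
        '##INFO=<ID=DR2,Number=1,Type=Float,Description="DR2">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2\tNA3",
        "1\t100\trs1\tA\tG\t.\tPASS\tAC=3;AN=6;AF=0.5;ExcessHet=3.01;DR2=0.95"
        "\tGT:GQ\t0|1:99\t1|1:35\t0|0:12",
        "1\t200\t.\tC\tT,G\t.\tq10\tAN=4\tGT:GQ\t1/2:60\t0/1:45\t./.:0",
    ]) + "\n"
    path = tmp_path / "hand.vcf"
    path.write_text(text)
    return path
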