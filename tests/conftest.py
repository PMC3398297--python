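import numpy as np
import pytest

from vqtlscan import DosageMatrix, write_dosage_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_dosage_matrix():
    """2 SNPs x 3 samples with one missing dose, values at 6 decimals."""
    return DosageMatrix(
        snp_ids=["rs1", "rs2"],
        a1=["A", "C"],
        a2=["G", "T"],
        samples=["s1", "s2", "s3"],
        dose=np.array([[0.123456, 1.0, 1.987654], [0.5, np.nan, 2.0]]),
    )


@pytest.fixture
def dosage_file(tmp_path, small_dosage_matrix):
    path = tmp_path / "dose.txt"
    write_dosage_table(small_dosage_matrix, path)
    return path


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alt allele dosage">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
1\t100\trs_ds\tA\tG\t.\tPASS\t.\tGT:DS\t0/0:0.12\t0/1:1.0\t1/1:1.9\t0/0:0.0
1\t200\trs_gp\tC\tT\t.\tPASS\t.\tGT:GP\t0/0:0.81,0.18,0.01\t0/1:0.1,0.8,0.1\t1/1:0.0,0.05,0.95\t0/0:1.0,0.0,0.0
1\t300\trs_both\tG\tA\t.\tPASS\t.\tGT:DS:GP\t0/1:1.37:0.1,0.8,0.1\t0/0:0.2:0.9,0.1,0.0\t0/0:0.0:1.0,0.0,0.0\t0/1:1.0:0.0,1.0,0.0
1\t400\trs_multi\tT\tA,C\t.\tPASS\t.\tGT:DS\t0/0:0.1\t0/0:0.2\t0/0:0.3\t0/0:0.4
1\t500\trs_gt_only\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0
"""


@pytest.fixture
def vcf_file(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    return path
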