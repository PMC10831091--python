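import numpy as np
import pysam
import pytest

from ffpefilter import (
    SplitSpec,
    SyntheticConfig,
    no_signal_config,
    run_benchmark,
    two_feature_oracle,
)

MUTECT_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=weak_evidence,Description="Mutation does not meet likelihood threshold">
##contig=<ID=chr1,length=1000000>
##INFO=<ID=ECNT,Number=1,Type=Integer,Description="events in haplotype">
##INFO=<ID=MBQ,Number=R,Type=Float,Description="median base quality by allele">
##INFO=<ID=MMQ,Number=R,Type=Float,Description="median mapping quality by allele">
##INFO=<ID=MFRL,Number=R,Type=Float,Description="median fragment length by allele">
##INFO=<ID=MPOS,Number=A,Type=Float,Description="median distance from end of read">
##INFO=<ID=TLOD,Number=A,Type=Float,Description="log odds of variant">
##INFO=<ID=POPAF,Number=A,Type=Float,Description="neg log10 population AF">
##INFO=<ID=GERMQ,Number=1,Type=Float,Description="not germline quality">
##INFO=<ID=SEQQ,Number=1,Type=Float,Description="not sequencing error quality">
##INFO=<ID=STRANDQ,Number=1,Type=Float,Description="strand bias quality">
##INFO=<ID=ROQ,Number=1,Type=Float,Description="not orientation artifact quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="read depth">
##FORMAT=<ID=F1R2,Number=R,Type=Integer,Description="F1R2 counts">
##FORMAT=<ID=F2R1,Number=R,Type=Integer,Description="F2R1 counts">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
"""

# rec1: PASS SNV; rec2: weak_evidence (and missing MMQ); rec3: PASS bi-allelic
MUTECT_VCF_BODY = """\
chr1\t100\t.\tC\tT\t.\tPASS\tECNT=1;MBQ=32,30;MMQ=60,60;MFRL=220,150;MPOS=20;TLOD=30.5;POPAF=6;GERMQ=90;SEQQ=80;STRANDQ=30;ROQ=40\tGT:AD:AF:DP:F1R2:F2R1\t0/1:90,10:0.1:100:45,8:45,2
chr1\t200\t.\tG\tA\t.\tweak_evidence\tECNT=1;MBQ=28,25;MFRL=210,140;MPOS=8;TLOD=3.1;POPAF=6;GERMQ=85;SEQQ=70;STRANDQ=20;ROQ=22\tGT:AD:AF:DP:F1R2:F2R1\t0/1:95,3:0.031:98:40,3:55,0
chr1\t300\t.\tG\tA,T\t.\tPASS\tECNT=2;MBQ=33,31,29;MMQ=60,55,50;MFRL=200,180,160;MPOS=25,11;TLOD=10.1,8.2;POPAF=5,5.5;GERMQ=88;SEQQ=75;STRANDQ=28;ROQ=35\tGT:AD:AF:DP:F1R2:F2R1\t0/1:60,5,3:0.073,0.044:70:30,5,1:28,0,2
"""


@pytest.fixture()
def mutect_vcf(tmp_path):
    """Three-record MuTect2-dialect fixture: 2 PASS (one bi-allelic), 1 filtered."""
    path = tmp_path / "fixture.vcf"
    path.write_text(MUTECT_VCF_HEADER + MUTECT_VCF_BODY)
    return str(path)


def make_read(
    proper=True,
    duplicate=False,
    secondary=False,
    supplementary=False,
    mapq=60,
    tlen=147,
    name="r1",
):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": "chr1", "LN": 1000000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "A" * 50
    a.reference_id = 0
    a.reference_start = 1000
    a.cigarstring = "50M"
    a.mapping_quality = mapq
    a.template_length = tlen
    a.flag = 0x1 | 0x40
    if proper:
        a.flag |= 0x2
    if duplicate:
        a.flag |= 0x400
    if secondary:
        a.flag |= 0x100
    if supplementary:
        a.flag |= 0x800
    return a


@pytest.fixture(scope="session")
def benchmark():
    """Full pipeline run on the default well-separated synthetic benchmark."""
    return run_benchmark(SyntheticConfig(seed=1), split=SplitSpec(seed=42))


@pytest.fixture(scope="session")
def oracle_metrics():
    """Two-feature (MAF, SOB) baseline on the same draw and split."""
    return two_feature_oracle(SyntheticConfig(seed=1), split=SplitSpec(seed=42))


@pytest.fixture(scope="session")
def no_signal_result():
    """Pipeline run with identical class distributions (chance-level control)."""
    return run_benchmark(no_signal_config(seed=1, n=5000), split=SplitSpec(seed=42))
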