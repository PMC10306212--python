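import pytest

from varburden import QualifyConfig, SimConfig, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A small deterministic synthetic study (null, 60 genes)."""
    return simulate(SimConfig(seed=7, n_genes=60))


@pytest.fixture(scope="session")
def base_qualify_config():
    return QualifyConfig()


@pytest.fixture()
def write_vcf(tmp_path):
    """Write VCF body lines under a minimal two-sample header."""

    def _write(body_lines, samples=("S1", "S2"), name="test.vcf"):
        header = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=1000000>",
            '##FILTER=<ID=PASS,Description="ok">',
            '##FILTER=<ID=VQSRTrancheSNP99.90to100.00,Description="fail">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        ]
        path = tmp_path / name
        path.write_text("\n".join(header + list(body_lines)) + "\n")
        return path

    return _write
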