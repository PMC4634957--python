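import pytest

from recgene import simulate


@pytest.fixture(scope="session")
def cohort():
    """One default-design synthetic cohort shared across read-only tests."""
    return simulate.generate_cohort(simulate.SimConfig(seed=11))


@pytest.fixture()
def toy_vcf(tmp_path):
    """A small hand-written VCF in the documented subset dialect."""
    text = "\n".join([
        "##fileformat=VCFv4.2",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tP3",
        "3\t133667736\t.\tG\tA\t.\t.\tGENE=SLCO2A1;FUNC=splice_site\tGT\t1/1\t0/1\t0/0",
        "3\t133674014\trs148547180\tG\tT\t.\t.\tGENE=SLCO2A1;FUNC=nonsense\tGT\t0|1\t0/0\t./.",
        "5\t1000\t.\tC\tA,T\t.\t.\tGENE=DEMO;FUNC=missense,synonymous\tGT\t1/2\t0/1\t2/2",
    ]) + "\n"
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path
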