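import numpy as np
import pytest

import ovisweep as ov

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\trs1\tA\tT\t.\t.\t.\tGT\t0|0\t0|1\t1|1
chr1\t200\t.\tC\tG\t.\t.\t.\tGT\t.|.\t0|1\t1|1
chr1\t300\t.\tG\tA,T\t.\t.\t.\tGT\t0|1\t0|2\t0|0
chr1\t400\t.\tT\tC\t.\t.\t.\tGT\t0/1\t0|0\t1|1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240402)


def matrix_from_dosage(dosage, alt=None, chrom="1", spacing=100):
    """Build a GenotypeMatrix from a dosage array (het coded as 0|1)."""
    from ovisweep.genotype_io import MISSING

    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    alt = alt or [("T",)] * m
    sites = [ov.VariantSite(chrom, spacing * (j + 1), None, "A", alt[j])
             for j in range(m)]
    alleles = np.empty((n, m, 2), dtype=np.int8)
    alleles[:, :, 0] = np.where(dosage == 2, 1, 0)
    alleles[:, :, 1] = np.where(dosage >= 1, 1, 0)
    alleles[dosage == MISSING] = -1
    return ov.GenotypeMatrix(
        sites=sites, samples=[f"s{i}" for i in range(n)],
        dosage=dosage, alleles=alleles,
        phased=np.ones((n, m), dtype=bool))


def random_haplotypes(rng, n_hap, n_sites, spacing=1000):
    """Random polymorphic haplotype matrix for property tests."""
    while True:
        hap = (rng.random((n_hap, n_sites)) < rng.uniform(
            0.1, 0.9, size=n_sites)).astype(np.uint8)
        k = hap.sum(axis=0)
        if ((k > 0) & (k < n_hap)).all():
            break
    sites = [ov.VariantSite("1", (j + 1) * spacing, None, "A", ("T",))
             for j in range(n_sites)]
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return ov.HaplotypeMatrix(sites=sites, samples=samples, haplotypes=hap)
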