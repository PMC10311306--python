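import numpy as np
import pytest

from fedstrat import GenotypeMatrix, SyntheticConfig, simulate_populations


@pytest.fixture
def tiny_matrix():
    """4 samples x 3 SNPs with per-column MAFs 0.25, 0.0, 0.375."""
    values = np.array(
        [
            [1, 0, 2],
            [0, 0, 1],
            [1, 0, 0],
            [0, 0, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        values, ["s1", "s2", "s3", "s4"], ["rs1", "rs2", "rs3"]
    )


@pytest.fixture(scope="session")
def cohort3():
    """Three well-separated populations, 50 samples each, 2000 SNPs.

    Session-scoped for speed; tests must not mutate it in place.
    """
    cfg = SyntheticConfig(
        n_populations=3, samples_per_population=50, n_snps=2000, fst=0.1, seed=11
    )
    return simulate_populations(cfg)


@pytest.fixture
def vcf_path(tmp_path):
    """A small hand-written VCF: 3 samples, 4 usable SNPs plus 1 multi-allelic.

    rs2 has ALT frequency 5/6 > 0.5, so its REF allele is minor and the
    dosage must be 2 - ALT count. rs4 has a missing genotype. The record at
    position 500 is multi-allelic and must be skipped. The record at
    position 600 has no ID and falls back to CHROM:POS.
    """
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC",
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1",
            "1\t500\trs3\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2",
            "1\t300\trs4\tG\tA\t.\tPASS\t.\tGT\t./.\t0/1\t0/0",
            "1\t600\t.\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1",
        ]
    )
    path = tmp_path / "mini.vcf"
    path.write_text(text + "\n")
    return path
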