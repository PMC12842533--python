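import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crabsnp.genotypes import Genotype, GenotypeTable, SnpLocus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Per-group haplotype expected counts as printed in the case-control
# haplotype association table (tolerant total 98 chromosomes, intolerant 96).
PRINTED_HAPLOTYPE_COUNTS_TOL = {
    "GGGG": 45.53,
    "GGTT": 9.49,
    "TGGG": 13.00,
    "GGTG": 5.98,
    "TCGG": 15.41,
    "TCGT": 1.06,
    "TCTG": 0.08,
    "TCTT": 7.45,
}
PRINTED_HAPLOTYPE_COUNTS_INTOL = {"GGGG": 93.00, "GGTT": 1.00, "TGGG": 2.00}


@pytest.fixture
def printed_haplotype_counts():
    return dict(PRINTED_HAPLOTYPE_COUNTS_TOL), dict(PRINTED_HAPLOTYPE_COUNTS_INTOL)


def make_table(genotype_rows, phenotypes, loci=None):
    """Build a GenotypeTable from rows of Genotype codes."""
    calls = np.array(genotype_rows, dtype=np.int8)
    n_loci = calls.shape[1]
    if loci is None:
        loci = [
            SnpLocus(f"locus{j + 1}G>T", "G", "T") for j in range(n_loci)
        ]
    samples = [f"S{i + 1:03d}" for i in range(calls.shape[0])]
    return GenotypeTable(samples=samples, loci=list(loci), calls=calls, phenotype=list(phenotypes))


@pytest.fixture
def two_group_table():
    """Tolerant: 3 het + 7 hom_ref; intolerant: 1 het + 9 hom_ref (one locus)."""
    rows = [[Genotype.HET]] * 3 + [[Genotype.HOM_REF]] * 7
    rows += [[Genotype.HET]] * 1 + [[Genotype.HOM_REF]] * 9
    phen = ["tolerant"] * 10 + ["intolerant"] * 10
    return make_table(rows, phen)
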