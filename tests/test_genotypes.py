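"""Genotype containers, peak-ratio calling and MAF filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crabsnp.genotypes import (
    Genotype,
    GenotypeTable,
    PeakObservation,
    SnpLocus,
    allele_frequencies,
    call_genotype_from_peaks,
    call_genotypes_from_peak_table,
    filter_loci_by_maf,
)

from conftest import make_table

LOCUS = SnpLocus("g.72037G>T", "G", "T", region="exon", effect="nonsense")


class TestSnpLocus:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError):
            SnpLocus("x", "G", "G")

    def test_rejects_non_nucleotide(self):
        with pytest.raises(ValueError):
            SnpLocus("x", "G", "X")

    def test_from_label_parses_ref_alt(self):
        loc = SnpLocus.from_label("g.74293G>T")
        assert loc.alleles == ("G", "T")


class TestPeakCalling:
    @pytest.mark.parametrize(
        "primary,secondary,expected",
        [
            ((("G", 1000.0)), ("T", 500.0), Genotype.HET),  # ratio 0.50 >= 30%
            ((("G", 1000.0)), ("T", 100.0), Genotype.HOM_REF),  # ratio 0.10 < 20%: noise
            ((("T", 1000.0)), ("G", 100.0), Genotype.HOM_ALT),  # primary base is alt
            ((("G", 1000.0)), ("T", 250.0), Genotype.MISSING),  # 20-30% ambiguous band
            ((("G", 1000.0)), ("T", 300.0), Genotype.HET),  # exactly at 30%
            ((("G", 1000.0)), ("T", 200.0), Genotype.MISSING),  # exactly at 20%
        ],
    )
    def test_ratio_bands(self, primary, secondary, expected):
        obs = PeakObservation(primary[0], primary[1], secondary[0], secondary[1])
        assert call_genotype_from_peaks(obs, LOCUS) == expected

    def test_zero_primary_is_missing_with_warning(self):
        obs = PeakObservation("G", 0.0, "T", 0.0)
        with pytest.warns(UserWarning, match="no signal"):
            assert call_genotype_from_peaks(obs, LOCUS) == Genotype.MISSING

    def test_invalid_thresholds_rejected(self):
        obs = PeakObservation("G", 1000.0, "T", 500.0)
        with pytest.raises(ValueError):
            call_genotype_from_peaks(obs, LOCUS, het_ratio=0.2, noise_ratio=0.3)

    def test_off_locus_base_is_error(self):
        obs = PeakObservation("A", 1000.0, "T", 500.0)
        with pytest.raises(ValueError, match="allele"):
            call_genotype_from_peaks(obs, LOCUS)

    @given(secondary=st.floats(min_value=0.0, max_value=1000.0), lower=st.floats(0.0, 1000.0))
    def test_calling_is_monotone_in_secondary_height(self, secondary, lower):
        """Raising the secondary peak can never turn a het into a homozygote."""
        lo, hi = sorted([lower, secondary])
        call_lo = call_genotype_from_peaks(PeakObservation("G", 1000.0, "T", lo), LOCUS)
        call_hi = call_genotype_from_peaks(PeakObservation("G", 1000.0, "T", hi), LOCUS)
        rank = {Genotype.HOM_REF: 0, Genotype.MISSING: 1, Genotype.HET: 2}
        assert rank[call_hi] >= rank[call_lo]


class TestAlleleFrequencies:
    def test_all_het_gives_half(self):
        gt = make_table([[Genotype.HET]] * 10, ["tolerant"] * 10)
        af = allele_frequencies(gt, gt.loci[0])
        assert af.freqs["T"] == pytest.approx(0.5)
        assert abs(sum(af.freqs.values()) - 1.0) < 1e-12

    def test_four_minor_alleles_of_64(self):
        # 32 samples: 4 alt alleles carried by 4 hets
        rows = [[Genotype.HET]] * 4 + [[Genotype.HOM_REF]] * 28
        gt = make_table(rows, ["tolerant"] * 32)
        af = allele_frequencies(gt, gt.loci[0])
        assert af.maf == pytest.approx(0.0625)

    def test_missing_excluded_from_denominator(self):
        rows = [[Genotype.HOM_REF]] * 5 + [[Genotype.MISSING]] * 5
        gt = make_table(rows, ["tolerant"] * 10)
        af = allele_frequencies(gt, gt.loci[0])
        assert af.freqs["T"] == 0.0
        assert af.n_typed == 5

    def test_all_missing_is_error(self):
        gt = make_table([[Genotype.MISSING]] * 3, ["tolerant"] * 3)
        with pytest.raises(ValueError, match="no typed"):
            allele_frequencies(gt, gt.loci[0])

    def test_sample_order_invariant(self):
        rng = np.random.default_rng(7)
        rows = rng.choice([0, 1, 2], size=(20, 1)).tolist()
        gt = make_table(rows, ["tolerant"] * 20)
        perm = rng.permutation(20)
        gt2 = gt.subset_samples([gt.samples[i] for i in perm])
        assert allele_frequencies(gt, gt.loci[0]).freqs == allele_frequencies(gt2, gt2.loci[0]).freqs


class TestMafFilter:
    def _table(self, minor_count, n=32):
        rows = [[Genotype.HET]] * minor_count + [[Genotype.HOM_REF]] * (n - minor_count)
        return make_table(rows, ["tolerant"] * n)

    def test_three_of_64_dropped_four_retained(self):
        assert filter_loci_by_maf(self._table(3)).n_loci == 0
        assert filter_loci_by_maf(self._table(4)).n_loci == 1

    def test_monomorphic_dropped(self):
        assert filter_loci_by_maf(self._table(0)).n_loci == 0

    def test_idempotent(self):
        gt = self._table(4)
        once = filter_loci_by_maf(gt)
        twice = filter_loci_by_maf(once)
        assert [l.id for l in once.loci] == [l.id for l in twice.loci]
        assert np.array_equal(once.calls, twice.calls)

    def test_samples_unchanged(self):
        gt = self._table(3)
        assert filter_loci_by_maf(gt).samples == gt.samples


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        rows = [[0, 1], [2, -1], [1, 0]]
        gt = make_table(rows, ["tolerant", "intolerant", "unlabelled"])
        path = tmp_path / "gt.tsv"
        gt.to_tsv(path)
        back = GenotypeTable.from_tsv(path)
        assert back.samples == gt.samples
        assert back.phenotype == gt.phenotype
        assert np.array_equal(back.calls, gt.calls)
        assert [l.alleles for l in back.loci] == [l.alleles for l in gt.loci]

    def test_third_allele_raises_with_sample_and_locus(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sample_id\tphenotype\tg.72037G>T\n"
            "S1\ttolerant\tG/T\n"
            "S2\ttolerant\tG/A\n"
        )
        with pytest.raises(ValueError, match="S2"):
            GenotypeTable.from_tsv(path)

    def test_malformed_genotype_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tphenotype\tlocusA\nS1\ttolerant\tGT\n")
        with pytest.raises(ValueError, match="locusA"):
            GenotypeTable.from_tsv(path)

    def test_vcf_reader_gt_field(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "chr1\t72037\tg.72037G>T\tG\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t./.\n"
            "chr1\t74293\tg.74293G>T\tG\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1\n"
        )
        gt = GenotypeTable.from_vcf(vcf, phenotype={"S1": "tolerant"})
        assert gt.samples == ["S1", "S2", "S3"]
        assert gt.phenotype == ["tolerant", "unlabelled", "unlabelled"]
        assert gt.calls.tolist() == [[0, 2], [1, 0], [-1, 1]]


def test_peak_table_calling_round_trip():
    """A peak table generated from known genotypes calls back to them."""
    loci = [SnpLocus("g.72037G>T", "G", "T"), SnpLocus("g.72122G>C", "G", "C")]
    gt = make_table([[0, 1], [1, 2], [2, 0]], ["tolerant"] * 3, loci=loci)
    import pandas as pd

    rows = []
    for i, s in enumerate(gt.samples):
        for j, loc in enumerate(loci):
            code = Genotype(gt.calls[i, j])
            if code == Genotype.HET:
                rows.append((s, loc.id, loc.ref_allele, 1000, loc.alt_allele, 500))
            else:
                base = loc.ref_allele if code == Genotype.HOM_REF else loc.alt_allele
                other = loc.alt_allele if code == Genotype.HOM_REF else loc.ref_allele
                rows.append((s, loc.id, base, 1000, other, 50))
    peaks = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "locus", "primary_base", "primary_height",
            "secondary_base", "secondary_height",
        ],
    )
    called = call_genotypes_from_peak_table(peaks, loci)
    assert np.array_equal(called.calls, gt.calls)
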