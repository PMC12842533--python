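"""Synthetic-data generator: determinism and statistical structure."""

import numpy as np
import pandas as pd
import pytest

from crabsnp.classifier import cumulative_accuracy_curve
from crabsnp.expression import relative_expression
from crabsnp.genotypes import Genotype, call_genotypes_from_peak_table
from crabsnp.growth import correlation_pca
from crabsnp.haplotypes import em_haplotype_frequencies
from crabsnp.association import carrier_contingency, odds_ratio
from crabsnp.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_growth,
    simulate_peak_table,
    simulate_population,
    write_simulated_inputs,
)


class TestPopulation:
    def test_fixed_haplotype_gives_all_hom_ref(self):
        cfg = SimulationConfig(
            seed=0,
            haplotype_freqs_tol={"GGGG": 1.0},
            haplotype_freqs_intol={"GGGG": 1.0},
            missing_rate=0.0,
        )
        gt = simulate_population(cfg)
        assert np.all(gt.calls == Genotype.HOM_REF)

    def test_empirical_frequencies_near_truth_at_large_n(self):
        cfg = SimulationConfig(seed=12, n_tolerant=2000, n_intolerant=2000, missing_rate=0.0)
        gt = simulate_population(cfg)
        est = em_haplotype_frequencies(gt, "tolerant", seed=1).frequencies
        for hap, truth in cfg.haplotype_freqs_tol.items():
            if truth >= 0.05:
                assert est.get(hap, 0.0) == pytest.approx(truth, abs=0.02)

    def test_same_seed_identical_tables(self, tmp_path):
        a = simulate_population(SimulationConfig(seed=42))
        b = simulate_population(SimulationConfig(seed=42))
        assert a.samples == b.samples and np.array_equal(a.calls, b.calls)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_tsv(pa)
        b.to_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_missing_rate_injected(self):
        cfg = SimulationConfig(seed=3, n_tolerant=500, n_intolerant=500, missing_rate=0.1)
        gt = simulate_population(cfg)
        frac = np.mean(gt.calls == Genotype.MISSING)
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(haplotype_freqs_tol={"GGGG": 0.5})


class TestGrowth:
    def test_full_correlation_gives_single_component(self):
        cfg = SimulationConfig(seed=5, trait_correlation=1.0, carrier_size_shift=0.0,
                               missing_rate=0.0)
        gt = simulate_population(cfg)
        pca = correlation_pca(simulate_growth(cfg, gt))
        assert pca.variance_explained[0] == pytest.approx(100.0, abs=1e-6)

    def test_pc1_variance_band_at_default_correlation(self):
        cfg = SimulationConfig(seed=6, n_tolerant=56, missing_rate=0.0)
        gt = simulate_population(cfg)
        pca = correlation_pca(simulate_growth(cfg, gt))
        assert 90.0 <= pca.variance_explained[0] <= 99.0

    def test_null_carrier_shift_balances_groups(self):
        cfg = SimulationConfig(seed=7, n_tolerant=400, carrier_size_shift=0.0,
                               missing_rate=0.0)
        gt = simulate_population(cfg)
        records = simulate_growth(cfg, gt)
        from crabsnp.growth import assign_growth_groups, growth_group_genotype_table

        fast, slow = assign_growth_groups(correlation_pca(records), n_per_group=150)
        df = growth_group_genotype_table(gt, fast, slow)
        # equal carrier frequencies within binomial noise
        assert abs(df["fast_freq"].mean() - 0.5) < 0.1

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            SimulationConfig(trait_correlation=1.5)


class TestExpression:
    def test_shift_recovered_as_fold_change(self):
        cfg = SimulationConfig(seed=8, hom_alt_ct_shift=1.0)
        gt = simulate_population(cfg)
        folds = relative_expression(simulate_expression(cfg, gt), calibrator="GG")
        locus = gt.loci[0].id
        sub = folds[folds.locus == locus]
        tt = sub[sub.genotype == "TT"]["fold"]
        if len(tt):
            assert tt.mean() == pytest.approx(2.0, abs=0.3)

    def test_zero_shift_gives_flat_folds(self):
        cfg = SimulationConfig(seed=9, het_ct_shift=0.0, hom_alt_ct_shift=0.0)
        gt = simulate_population(cfg)
        folds = relative_expression(simulate_expression(cfg, gt), calibrator="GG")
        assert folds["fold"].mean() == pytest.approx(1.0, abs=0.15)

    def test_requested_absent_genotype_is_error(self):
        cfg = SimulationConfig(
            seed=1, haplotype_freqs_tol={"GGGG": 1.0},
            haplotype_freqs_intol={"GGGG": 1.0}, missing_rate=0.0,
        )
        gt = simulate_population(cfg)
        with pytest.raises(ValueError, match="absent"):
            simulate_expression(cfg, gt, genotypes=[Genotype.HOM_ALT])

    def test_layout_three_by_three(self):
        cfg = SimulationConfig(seed=10)
        gt = simulate_population(cfg)
        records = simulate_expression(cfg, gt)
        df = pd.DataFrame([r.__dict__ for r in records])
        reps = df.groupby(["locus", "sample_id"])["replicate"].count()
        assert set(reps) == {3}

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=11)
        gt = simulate_population(cfg)
        assert simulate_expression(cfg, gt) == simulate_expression(cfg, gt)


class TestPeaks:
    def test_round_trip_reproduces_genotypes(self):
        cfg = SimulationConfig(seed=13, ambiguous_fraction=0.0, missing_rate=0.0)
        gt = simulate_population(cfg)
        peaks = simulate_peak_table(cfg, gt)
        called = call_genotypes_from_peak_table(
            peaks, gt.loci, phenotype=dict(zip(gt.samples, gt.phenotype))
        )
        assert np.array_equal(called.calls, gt.calls)

    def test_ambiguous_fraction_becomes_missing(self):
        cfg = SimulationConfig(seed=14, ambiguous_fraction=0.1, missing_rate=0.0,
                               n_tolerant=250, n_intolerant=250)
        gt = simulate_population(cfg)
        called = call_genotypes_from_peak_table(simulate_peak_table(cfg, gt), gt.loci)
        frac = np.mean(called.calls == Genotype.MISSING)
        assert frac == pytest.approx(0.1, abs=0.04)

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=15)
        gt = simulate_population(cfg)
        assert simulate_peak_table(cfg, gt).equals(simulate_peak_table(cfg, gt))


class TestEndToEnd:
    def test_pipeline_recovers_generating_structure(self):
        """EM recovery, carrier enrichment, and classifier accuracy on data
        simulated at n = 500/group from the default group distributions."""
        passes = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, n_tolerant=500, n_intolerant=500)
            gt = simulate_population(cfg)
            ok = True
            for group, truth in (
                ("tolerant", cfg.haplotype_freqs_tol),
                ("intolerant", cfg.haplotype_freqs_intol),
            ):
                est = em_haplotype_frequencies(gt, group, seed=seed).frequencies
                for hap, f in truth.items():
                    if f >= 0.05 and abs(est.get(hap, 0.0) - f) > 0.03:
                        ok = False
            for locus in gt.loci:
                or_ = odds_ratio(carrier_contingency(gt, locus))
                if or_ is not None and or_ <= 1.0:
                    ok = False
            curve = cumulative_accuracy_curve(gt)
            four = curve[(curve.kind == "cumulative") & (curve.k == 4)].accuracy_r.iloc[0]
            if four <= 70.0:
                ok = False
            passes += ok
        assert passes >= 9

    def test_write_simulated_inputs_bundle(self, tmp_path):
        cfg = SimulationConfig(seed=2)
        paths = write_simulated_inputs(cfg, tmp_path / "sim")
        for name in ("genotypes", "growth", "expression", "peaks", "manifest"):
            assert (tmp_path / "sim").joinpath(paths[name].split("/")[-1]).exists()
        import json

        manifest = json.loads(open(paths["manifest"]).read())
        assert manifest["seed"] == 2
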