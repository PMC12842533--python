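"""Seeded synthetic data with the structure the analysis assumes.

The generating model mirrors the study design: two phenotype groups of ~50
genotyped animals; four biallelic SNPs in one candidate gene whose genotypes
arise by drawing two haplotypes per individual from group-specific haplotype
frequency distributions (so linkage disequilibrium between the loci is
implicit in the haplotype structure); three collinear growth traits driven
by one latent body-size factor, shifted upward for mutant-allele carriers;
qPCR Ct values whose target-gene cycles drop (expression rises) in mutant
genotype classes; and chromatogram peak tables whose secondary/primary
height ratios land in clearly heterozygous, clearly homozygous, or
deliberately ambiguous bands.

Default haplotype frequencies are the case/control distributions the
analysis is designed around: a wild-type haplotype near fixation in the
intolerant group and a diverse spread of mutant-bearing haplotypes in the
tolerant group.  Everything is reproducible from a single integer seed; the
four generators draw from independent seeded streams so adding one output
does not perturb another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import Genotype, GenotypeTable, SnpLocus
from .growth import GrowthRecord
from .expression import ExpressionRecord

__all__ = [
    "DEFAULT_LOCI",
    "TOLERANT_HAPLOTYPE_FREQS",
    "INTOLERANT_HAPLOTYPE_FREQS",
    "SimulationConfig",
    "simulate_population",
    "simulate_growth",
    "simulate_expression",
    "simulate_peak_table",
    "write_simulated_inputs",
]

DEFAULT_LOCI: tuple[SnpLocus, ...] = (
    SnpLocus("g.72037G>T", "G", "T", region="exon", effect="nonsense"),
    SnpLocus("g.72122G>C", "G", "C", region="intron", effect="intronic"),
    SnpLocus("g.74293G>T", "G", "T", region="exon", effect="missense"),
    SnpLocus("g.74433G>T", "G", "T", region="exon", effect="missense"),
)


def _normalized(freqs: Mapping[str, float]) -> dict[str, float]:
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError("degenerate haplotype frequency vector")
    return {h: f / total for h, f in freqs.items()}


# Group-specific haplotype distributions (one allele per locus, in the locus
# order above).  The tolerant group carries a diverse mix of mutant-bearing
# haplotypes; the intolerant group is nearly fixed for the all-wild GGGG.
TOLERANT_HAPLOTYPE_FREQS: dict[str, float] = _normalized(
    {
        "GGGG": 0.465,
        "TCGG": 0.157,
        "TGGG": 0.133,
        "GGTT": 0.097,
        "TCTT": 0.076,
        "GGTG": 0.061,
        "TCGT": 0.011,
        "TCTG": 0.001,
    }
)
INTOLERANT_HAPLOTYPE_FREQS: dict[str, float] = _normalized(
    {"GGGG": 0.969, "TGGG": 0.021, "GGTT": 0.010}
)


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the study conditions."""

    n_tolerant: int = 50
    n_intolerant: int = 50
    haplotype_freqs_tol: dict[str, float] = field(
        default_factory=lambda: dict(TOLERANT_HAPLOTYPE_FREQS)
    )
    haplotype_freqs_intol: dict[str, float] = field(
        default_factory=lambda: dict(INTOLERANT_HAPLOTYPE_FREQS)
    )
    missing_rate: float = 0.02
    # growth traits: juvenile-scale means/SDs; one latent size factor carries
    # the inter-trait correlation, mutant carriers get a positive shift on it
    trait_means: dict[str, float] = field(
        default_factory=lambda: {
            "carapace_length": 20.0,  # mm
            "carapace_width": 28.0,  # mm
            "body_weight": 5.0,  # g
        }
    )
    trait_sds: dict[str, float] = field(
        default_factory=lambda: {
            "carapace_length": 3.0,
            "carapace_width": 4.0,
            "body_weight": 1.5,
        }
    )
    trait_correlation: float = 0.95
    carrier_size_shift: float = 0.8  # latent-factor SD units
    # expression: target Ct = reference + baseline dCt - genotype shift + noise
    ref_ct_mean: float = 15.0
    ref_ct_sd: float = 0.3
    baseline_delta_ct: float = 8.0
    het_ct_shift: float = 0.5  # cycles; 2^0.5 ~ 1.4-fold
    hom_alt_ct_shift: float = 1.0  # cycles; 2-fold
    ct_noise_sd: float = 0.1
    # chromatogram peaks
    het_peak_range: tuple[float, float] = (0.35, 0.90)
    hom_peak_range: tuple[float, float] = (0.0, 0.15)
    ambiguous_range: tuple[float, float] = (0.20, 0.30)
    ambiguous_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, freqs in (
            ("haplotype_freqs_tol", self.haplotype_freqs_tol),
            ("haplotype_freqs_intol", self.haplotype_freqs_intol),
        ):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9 or any(f < 0 for f in freqs.values()):
                raise ValueError(f"{name}: frequencies must be nonnegative and sum to 1")
            lengths = {len(h) for h in freqs}
            if lengths != {len(DEFAULT_LOCI)}:
                raise ValueError(f"{name}: haplotype strings must cover all loci")
        for name, rate in (
            ("missing_rate", self.missing_rate),
            ("ambiguous_fraction", self.ambiguous_fraction),
        ):
            if not (0 <= rate <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 <= self.trait_correlation <= 1):
            raise ValueError(
                "trait_correlation must be in [0, 1] for a positive-definite "
                "one-factor correlation structure"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


_STREAM_POPULATION = 1
_STREAM_GROWTH = 2
_STREAM_EXPRESSION = 3
_STREAM_PEAKS = 4


def simulate_population(cfg: SimulationConfig) -> GenotypeTable:
    """Draw two haplotypes per individual from its group's distribution and
    record the unphased per-locus genotypes, with missing calls injected at
    ``missing_rate``."""
    rng = cfg.rng(_STREAM_POPULATION)
    loci = list(DEFAULT_LOCI)
    samples: list[str] = []
    phenotype: list[str] = []
    rows: list[np.ndarray] = []
    for prefix, group, n, freqs in (
        ("T", "tolerant", cfg.n_tolerant, cfg.haplotype_freqs_tol),
        ("I", "intolerant", cfg.n_intolerant, cfg.haplotype_freqs_intol),
    ):
        haps = list(freqs)
        p = np.array([freqs[h] for h in haps])
        for i in range(n):
            h1, h2 = rng.choice(len(haps), size=2, p=p)
            codes = np.empty(len(loci), dtype=np.int8)
            for j, loc in enumerate(loci):
                a, b = haps[h1][j], haps[h2][j]
                n_alt = (a == loc.alt_allele) + (b == loc.alt_allele)
                codes[j] = Genotype(n_alt)
            samples.append(f"{prefix}{i + 1:03d}")
            phenotype.append(group)
            rows.append(codes)
    calls = np.stack(rows)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = Genotype.MISSING
    return GenotypeTable(samples=samples, loci=loci, calls=calls, phenotype=phenotype)


def _is_carrier(gt: GenotypeTable, i: int) -> bool:
    row = gt.calls[i]
    return bool(np.any((row == Genotype.HET) | (row == Genotype.HOM_ALT)))


def simulate_growth(
    cfg: SimulationConfig, gt: GenotypeTable, group: str = "tolerant"
) -> list[GrowthRecord]:
    """Correlated growth traits for one phenotype group.

    Each trait is ``mean + sd * (sqrt(rho) * F + sqrt(1 - rho) * e)`` with a
    shared latent size factor F, giving exactly the configured inter-trait
    correlation; mutant-allele carriers receive ``carrier_size_shift`` on F.
    Values are truncated to stay positive.
    """
    rng = cfg.rng(_STREAM_GROWTH)
    rho = cfg.trait_correlation
    idx = np.nonzero(gt.group_mask(group))[0]
    records = []
    for i in idx:
        f_latent = rng.normal()
        if _is_carrier(gt, int(i)):
            f_latent += cfg.carrier_size_shift
        values = {}
        for trait in ("carapace_length", "carapace_width", "body_weight"):
            e = rng.normal()
            z = np.sqrt(rho) * f_latent + np.sqrt(1.0 - rho) * e
            v = cfg.trait_means[trait] + cfg.trait_sds[trait] * z
            values[trait] = max(v, 0.05 * cfg.trait_means[trait])
        records.append(GrowthRecord(sample_id=gt.samples[int(i)], **values))
    return records


def simulate_expression(
    cfg: SimulationConfig,
    gt: GenotypeTable,
    loci: Sequence[SnpLocus] | None = None,
    genotypes: Sequence[Genotype] | None = None,
    group: str = "tolerant",
    n_individuals: int = 3,
    n_replicates: int = 3,
) -> list[ExpressionRecord]:
    """qPCR records: ``n_individuals`` per genotype class per locus, each with
    ``n_replicates`` technical replicates.

    By default every genotype class observed in the group is emitted
    (sampling at most ``n_individuals`` animals per class); explicitly
    requested absent genotypes raise.
    """
    rng = cfg.rng(_STREAM_EXPRESSION)
    chosen = list(loci) if loci is not None else list(gt.loci)
    shift = {
        int(Genotype.HOM_REF): 0.0,
        int(Genotype.HET): cfg.het_ct_shift,
        int(Genotype.HOM_ALT): cfg.hom_alt_ct_shift,
    }
    mask = gt.group_mask(group)
    records = []
    for loc in chosen:
        j = gt.locus_index(loc)
        col = gt.calls[:, j]
        wanted = (
            list(genotypes)
            if genotypes is not None
            else [g for g in (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
                  if np.any(mask & (col == g))]
        )
        for code in wanted:
            candidates = np.nonzero(mask & (col == code))[0]
            if candidates.size == 0:
                raise ValueError(
                    f"genotype {Genotype(code).name} absent at locus {loc.id!r}"
                )
            take = rng.choice(
                candidates, size=min(n_individuals, candidates.size), replace=False
            )
            label = gt.alleles_at(int(take[0]), j).replace("/", "")
            for i in take:
                for rep in range(1, n_replicates + 1):
                    ct_ref = rng.normal(cfg.ref_ct_mean, cfg.ref_ct_sd)
                    ct_tgt = (
                        ct_ref
                        + cfg.baseline_delta_ct
                        - shift[int(code)]
                        + rng.normal(0.0, cfg.ct_noise_sd)
                    )
                    records.append(
                        ExpressionRecord(
                            sample_id=gt.samples[int(i)],
                            locus=loc.id,
                            genotype=label,
                            replicate=rep,
                            ct_target=float(ct_tgt),
                            ct_reference=float(ct_ref),
                        )
                    )
    return records


def simulate_peak_table(cfg: SimulationConfig, gt: GenotypeTable) -> pd.DataFrame:
    """Chromatogram peak heights consistent with the genotype table.

    Heterozygotes emit secondary/primary ratios in ``het_peak_range``,
    homozygotes in ``hom_peak_range``; a seeded ``ambiguous_fraction`` of
    rows (and every missing call) lands in ``ambiguous_range`` instead, which
    the peak-ratio caller maps back to missing.
    """
    rng = cfg.rng(_STREAM_PEAKS)
    rows = []
    for i, sample in enumerate(gt.samples):
        for j, loc in enumerate(gt.loci):
            code = Genotype(gt.calls[i, j])
            primary_height = rng.uniform(800.0, 1200.0)
            if code == Genotype.MISSING or rng.random() < cfg.ambiguous_fraction:
                ratio = rng.uniform(*cfg.ambiguous_range)
                primary, secondary = loc.ref_allele, loc.alt_allele
            elif code == Genotype.HET:
                ratio = rng.uniform(*cfg.het_peak_range)
                primary, secondary = loc.ref_allele, loc.alt_allele
            else:
                ratio = rng.uniform(*cfg.hom_peak_range)
                primary = loc.ref_allele if code == Genotype.HOM_REF else loc.alt_allele
                secondary = loc.alt_allele if code == Genotype.HOM_REF else loc.ref_allele
            rows.append(
                {
                    "sample_id": sample,
                    "locus": loc.id,
                    "primary_base": primary,
                    "primary_height": round(primary_height, 1),
                    "secondary_base": secondary,
                    "secondary_height": round(primary_height * ratio, 1),
                }
            )
    return pd.DataFrame(rows)


def write_simulated_inputs(cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Write genotype/growth/expression/peak files plus a manifest of the
    configuration and seed; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gt = simulate_population(cfg)
    growth = simulate_growth(cfg, gt)
    expression = simulate_expression(cfg, gt)
    peaks = simulate_peak_table(cfg, gt)

    from .growth import write_growth_tsv
    from .expression import write_expression_tsv

    paths = {
        "genotypes": str(out / "genotypes.tsv"),
        "growth": str(out / "growth.tsv"),
        "expression": str(out / "expression.tsv"),
        "peaks": str(out / "peaks.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    gt.to_tsv(paths["genotypes"])
    write_growth_tsv(growth, paths["growth"])
    write_expression_tsv(expression, paths["expression"])
    peaks.to_csv(paths["peaks"], sep="\t", index=False)
    manifest = dataclasses.asdict(cfg)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
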