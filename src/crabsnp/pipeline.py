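"""End-to-end orchestration of the candidate-gene association analysis.

Stages: (optional) peak-ratio genotype calling -> MAF locus filter ->
per-locus case-control association -> diversity summaries -> per-group EM
haplotype inference -> haplotype association table -> genotype-frequency
classifier with accuracy curve -> (optional) growth PCA and growth-group
genotype contrast -> (optional) ddCt expression analysis.  Every threshold
actually used is logged, all numbers in the emitted tables come from the
corresponding library operation, and identical inputs + config + seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .association import association_table, write_association_tsv
from .classifier import (
    accuracy_r,
    classify,
    cumulative_accuracy_curve,
    fit_frequency_model,
    predictions_frame,
)
from .diversity import diversity_table, write_diversity_tsv
from .expression import expression_summary, read_expression_tsv, relative_expression
from .genotypes import (
    GenotypeTable,
    call_genotypes_from_peak_table,
    filter_loci_by_maf,
    read_peak_table,
)
from .growth import (
    assign_growth_groups,
    correlation_pca,
    growth_group_genotype_table,
    pca_summary_frame,
    read_growth_tsv,
)
from .haplotype_assoc import build_haplotype_table, write_haplotype_tsv
from .haplotypes import em_haplotype_frequencies

log = logging.getLogger("crabsnp")

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    genotype_path: str | None = None
    peak_path: str | None = None
    growth_path: str | None = None
    expression_path: str | None = None
    outdir: str = "crabsnp_out"
    locus_order: Sequence[str] | None = None
    maf_threshold: float = 0.05
    rare_threshold: float = 0.03
    smoothing: float = 0.005
    het_ratio: float = 0.30
    noise_ratio: float = 0.20
    alpha: float = 0.05
    posthoc: str = "tukey"
    calibrator: str = "GG"
    n_per_growth_group: int = 25
    evaluation_mode: str = "resubstitution"
    tie_rule: str = "intolerant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype_path is None and self.peak_path is None:
            raise ValueError("need a genotype table or a peak table")
        if not (0 <= self.noise_ratio < self.het_ratio <= 1):
            raise ValueError("peak thresholds must satisfy 0 <= noise < het <= 1")
        for name, v in (
            ("maf_threshold", self.maf_threshold),
            ("rare_threshold", self.rare_threshold),
            ("alpha", self.alpha),
        ):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} out of range [0, 1]")
        if self.evaluation_mode not in ("resubstitution", "loo"):
            raise ValueError("evaluation_mode must be 'resubstitution' or 'loo'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Plain key=value config text; '#' starts a comment."""
        kwargs: dict = {}
        numeric = {
            "maf_threshold", "rare_threshold", "smoothing", "het_ratio",
            "noise_ratio", "alpha",
        }
        integer = {"n_per_growth_group", "seed"}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "locus_order":
                kwargs[key] = [v.strip() for v in value.split(",") if v.strip()]
            elif key in numeric:
                kwargs[key] = float(value)
            elif key in integer:
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %-22s %.2fs", name, time.perf_counter() - self.t0)

    return _T()


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every applicable stage and write the paper-style output tables.

    Returns a dict of in-memory results; files land under ``cfg.outdir``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "thresholds: het_ratio=%.2f noise_ratio=%.2f maf=%.3f rare=%.3f "
        "smoothing=%.4f alpha=%.2f mode=%s seed=%d",
        cfg.het_ratio, cfg.noise_ratio, cfg.maf_threshold, cfg.rare_threshold,
        cfg.smoothing, cfg.alpha, cfg.evaluation_mode, cfg.seed,
    )
    results: dict = {"config": cfg}

    with _timed("ingest"):
        if cfg.genotype_path is not None:
            gt = GenotypeTable.from_tsv(cfg.genotype_path)
        else:
            peaks = read_peak_table(cfg.peak_path)
            raise ValueError(
                "peak-only runs need locus definitions; use the call-genotypes "
                "subcommand to produce a genotype table first"
            )
        if cfg.peak_path is not None and cfg.genotype_path is not None:
            peaks = read_peak_table(cfg.peak_path)
            called = call_genotypes_from_peak_table(
                peaks, gt.loci,
                phenotype={s: p for s, p in zip(gt.samples, gt.phenotype)},
                het_ratio=cfg.het_ratio, noise_ratio=cfg.noise_ratio,
            )
            called.to_tsv(out / "called_genotypes.tsv")
            results["called"] = called

    with _timed("maf_filter"):
        gt = filter_loci_by_maf(gt, cfg.maf_threshold)
        if cfg.locus_order:
            gt = gt.subset_loci(list(cfg.locus_order))
        if gt.n_loci == 0:
            raise ValueError("maf_filter: no locus passed the MAF threshold")
        results["genotypes"] = gt

    with _timed("association"):
        assoc = association_table(gt)
        write_association_tsv(assoc, out / "locus_association.tsv")
        results["association"] = assoc

    with _timed("diversity"):
        div = diversity_table(gt)
        write_diversity_tsv(div, out / "diversity.tsv")
        results["diversity"] = div

    with _timed("haplotypes"):
        dist_tol = em_haplotype_frequencies(gt, "tolerant", seed=cfg.seed)
        dist_intol = em_haplotype_frequencies(gt, "intolerant", seed=cfg.seed)
        results["haplotypes"] = {"tolerant": dist_tol, "intolerant": dist_intol}
        rows = build_haplotype_table(dist_tol, dist_intol, cfg.rare_threshold)
        write_haplotype_tsv(rows, out / "haplotype_association.tsv")
        results["haplotype_table"] = rows

    with _timed("classifier"):
        model = fit_frequency_model(gt, smoothing=cfg.smoothing)
        res = classify(model, gt, tie_rule=cfg.tie_rule)
        truth = {s: p for s, p in zip(gt.samples, gt.phenotype)}
        predictions_frame(res, truth).to_csv(
            out / "classifier_predictions.tsv", sep="\t", index=False
        )
        curve = cumulative_accuracy_curve(
            gt, smoothing=cfg.smoothing, mode=cfg.evaluation_mode,
            tie_rule=cfg.tie_rule,
        )
        curve.to_csv(out / "classifier_accuracy.tsv", sep="\t", index=False)
        results["classifier_curve"] = curve
        results["classifier_accuracy"] = accuracy_r(res, truth)

    if cfg.growth_path is not None:
        with _timed("growth_pca"):
            records = read_growth_tsv(cfg.growth_path)
            pca = correlation_pca(records)
            pca_summary_frame(pca).to_csv(
                out / "growth_pca.tsv", sep="\t", index=False, float_format="%.4f"
            )
            fast, slow = assign_growth_groups(pca, cfg.n_per_growth_group)
            table5 = growth_group_genotype_table(gt, fast, slow)
            table5.to_csv(
                out / "growth_genotypes.tsv", sep="\t", index=False,
                float_format="%.4f", na_rep="-",
            )
            results["pca"] = pca
            results["growth_groups"] = (fast, slow)
            results["growth_genotypes"] = table5

    if cfg.expression_path is not None:
        with _timed("expression"):
            records = read_expression_tsv(cfg.expression_path)
            folds = relative_expression(records, calibrator=cfg.calibrator)
            summary = expression_summary(folds, alpha=cfg.alpha, method=cfg.posthoc)
            folds.to_csv(out / "expression_folds.tsv", sep="\t", index=False)
            summary.to_csv(out / "expression_summary.tsv", sep="\t", index=False)
            results["expression"] = summary

    summary_json = {
        "version": __version__,
        "seed": cfg.seed,
        "n_samples": gt.n_samples,
        "n_loci": gt.n_loci,
        "loci": [loc.id for loc in gt.loci],
        "thresholds": {
            "het_ratio": cfg.het_ratio,
            "noise_ratio": cfg.noise_ratio,
            "maf_threshold": cfg.maf_threshold,
            "rare_threshold": cfg.rare_threshold,
            "smoothing": cfg.smoothing,
            "alpha": cfg.alpha,
        },
        "classifier_accuracy_r": results.get("classifier_accuracy"),
        "evaluation_mode": cfg.evaluation_mode,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True)
    results["summary"] = summary_json
    return results
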