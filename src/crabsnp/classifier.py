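"""Genotype-frequency phenotype classifier and validation accuracy.

The discrimination rule is deliberately simple (it is meant to be applied at
the bench during marker-assisted selection): estimate the relative frequency
of every genotype in each phenotype group, score a candidate animal by the
product of its genotype frequencies across the chosen loci in each group,
and assign the phenotype with the larger composite score.  With a single
locus this reduces to "call tolerant when the genotype is more frequent in
the tolerant group".  Validation accuracy is

    R = N_correct / N_all * 100%

over the classified samples.  A genotype never observed in a group would
zero out that group's product; by default such genotypes receive a small
pseudo-frequency instead (smoothing), with ``smoothing=0`` reproducing the
strict literal rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import Genotype, GenotypeTable, SnpLocus

__all__ = [
    "ClassifierModel",
    "ClassificationResult",
    "fit_frequency_model",
    "classify",
    "accuracy_r",
    "cumulative_accuracy_curve",
    "leave_one_out_accuracy",
]

_GENO_CODES = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


@dataclass(frozen=True)
class ClassifierModel:
    loci: tuple[str, ...]
    freq_tol: Mapping[str, Mapping[int, float]]
    freq_intol: Mapping[str, Mapping[int, float]]
    smoothing: float = 0.005


@dataclass
class ClassificationResult:
    samples: list[str]
    predicted: list[str]
    score_tol: np.ndarray
    score_intol: np.ndarray
    excluded: list[str]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _group_frequencies(
    gt: GenotypeTable, group: str, loci_idx: Sequence[int], smoothing: float
) -> dict[str, dict[int, float]]:
    mask = gt.group_mask(group)
    out: dict[str, dict[int, float]] = {}
    for j in loci_idx:
        col = gt.calls[mask, j]
        typed = col[col != Genotype.MISSING]
        if typed.size == 0:
            raise ValueError(
                f"group {group!r} has no typed samples at locus {gt.loci[j].id!r}"
            )
        freqs: dict[int, float] = {}
        for code in _GENO_CODES:
            n = int(np.sum(typed == code))
            freqs[int(code)] = n / typed.size if n > 0 else smoothing
        out[gt.loci[j].id] = freqs
    return out


def fit_frequency_model(
    gt: GenotypeTable,
    loci: Sequence["SnpLocus | str"] | None = None,
    smoothing: float = 0.005,
) -> ClassifierModel:
    """Estimate per-group per-locus genotype relative frequencies.

    Frequencies are over typed samples in each group; genotype codes unseen
    in a group get the ``smoothing`` pseudo-frequency (0 disables).
    """
    chosen = loci if loci is not None else gt.loci
    idx = [gt.locus_index(l) for l in chosen]
    if not any(gt.group_mask("tolerant")) or not any(gt.group_mask("intolerant")):
        raise ValueError("both phenotype groups must be non-empty")
    return ClassifierModel(
        loci=tuple(gt.loci[j].id for j in idx),
        freq_tol=_group_frequencies(gt, "tolerant", idx, smoothing),
        freq_intol=_group_frequencies(gt, "intolerant", idx, smoothing),
        smoothing=smoothing,
    )


def classify(
    model: ClassifierModel, gt: GenotypeTable, tie_rule: str = "intolerant"
) -> ClassificationResult:
    """Score every sample and predict the group with the larger product.

    Ties go to ``tie_rule`` (default ``intolerant``: conservative for a
    tolerance-selection marker).  Samples missing a call at any model locus
    are excluded.
    """
    if tie_rule not in ("tolerant", "intolerant"):
        raise ValueError("tie_rule must be 'tolerant' or 'intolerant'")
    idx = [gt.locus_index(l) for l in model.loci]
    kept, predicted, s_tol, s_intol, excluded = [], [], [], [], []
    for i, sample in enumerate(gt.samples):
        codes = gt.calls[i, idx]
        if np.any(codes == Genotype.MISSING):
            excluded.append(sample)
            continue
        pt = pi = 1.0
        for lid, code in zip(model.loci, codes):
            pt *= model.freq_tol[lid][int(code)]
            pi *= model.freq_intol[lid][int(code)]
        if pt > pi:
            label = "tolerant"
        elif pt < pi:
            label = "intolerant"
        else:
            label = tie_rule
        kept.append(sample)
        predicted.append(label)
        s_tol.append(pt)
        s_intol.append(pi)
    return ClassificationResult(
        samples=kept,
        predicted=predicted,
        score_tol=np.array(s_tol),
        score_intol=np.array(s_intol),
        excluded=excluded,
    )


def accuracy_r(
    result: ClassificationResult, truth: Mapping[str, str]
) -> float:
    """Validation accuracy R = 100 * N_correct / N_all over classified samples."""
    if not result.samples:
        raise ValueError("no classified samples (N_all = 0)")
    n_correct = sum(
        1 for s, p in zip(result.samples, result.predicted) if truth[s] == p
    )
    return 100.0 * n_correct / len(result.samples)


def _truth_of(gt: GenotypeTable) -> dict[str, str]:
    return {s: p for s, p in zip(gt.samples, gt.phenotype)}


def _labelled(gt: GenotypeTable) -> GenotypeTable:
    keep = [s for s, p in zip(gt.samples, gt.phenotype) if p != "unlabelled"]
    return gt.subset_samples(keep)


def cumulative_accuracy_curve(
    gt: GenotypeTable,
    locus_order: Sequence["SnpLocus | str"] | None = None,
    smoothing: float = 0.005,
    mode: str = "resubstitution",
    tie_rule: str = "intolerant",
) -> pd.DataFrame:
    """Single-locus and cumulative multi-locus validation accuracies.

    Returns one row per evaluated locus set with columns ``kind`` ("single"
    or "cumulative"), ``k``, ``loci``, ``n_all``, ``n_correct`` and
    ``accuracy_r``.  ``mode`` is resubstitution (fit and evaluate on the same
    labelled samples) or ``"loo"`` for leave-one-out.
    """
    chosen = list(locus_order) if locus_order is not None else list(gt.loci)
    if not chosen:
        raise ValueError("need at least one locus")
    labelled = _labelled(gt)
    truth = _truth_of(labelled)
    rows = []

    def evaluate(loci_subset, kind, k):
        if mode == "resubstitution":
            model = fit_frequency_model(labelled, loci_subset, smoothing)
            res = classify(model, labelled, tie_rule=tie_rule)
            acc = accuracy_r(res, truth)
            n_all = len(res.samples)
            n_correct = round(acc * n_all / 100.0)
        elif mode == "loo":
            acc, n_correct, n_all = leave_one_out_accuracy(
                labelled, loci_subset, smoothing, tie_rule
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        ids = [l.id if isinstance(l, SnpLocus) else l for l in loci_subset]
        rows.append(
            {
                "kind": kind,
                "k": k,
                "loci": "+".join(ids),
                "n_all": n_all,
                "n_correct": int(n_correct),
                "accuracy_r": acc,
            }
        )

    for locus in chosen:
        evaluate([locus], "single", 1)
    for k in range(1, len(chosen) + 1):
        evaluate(chosen[:k], "cumulative", k)
    return pd.DataFrame(rows)


def leave_one_out_accuracy(
    gt: GenotypeTable,
    loci: Sequence["SnpLocus | str"],
    smoothing: float = 0.005,
    tie_rule: str = "intolerant",
) -> tuple[float, int, int]:
    """Leave-one-out accuracy: refit the frequency model without each sample
    before classifying it.  Returns (R%, n_correct, n_all)."""
    labelled = _labelled(gt)
    truth = _truth_of(labelled)
    n_correct = 0
    n_all = 0
    for held in labelled.samples:
        rest = labelled.subset_samples([s for s in labelled.samples if s != held])
        model = fit_frequency_model(rest, loci, smoothing)
        res = classify(model, labelled.subset_samples([held]), tie_rule=tie_rule)
        if not res.samples:
            continue
        n_all += 1
        if res.predicted[0] == truth[held]:
            n_correct += 1
    if n_all == 0:
        raise ValueError("no classifiable samples (N_all = 0)")
    return 100.0 * n_correct / n_all, n_correct, n_all


def predictions_frame(
    result: ClassificationResult, truth: Mapping[str, str] | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample": result.samples,
            "score_tol": result.score_tol,
            "score_intol": result.score_intol,
            "predicted": result.predicted,
        }
    )
    if truth is not None:
        df["truth"] = [truth.get(s, "unlabelled") for s in result.samples]
    return df
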