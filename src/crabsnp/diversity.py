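"""Per-group, per-locus genetic diversity summaries (Ho, He, Ne, PIC).

Estimators, over the allele frequencies p_i of typed genotypes in a group:

* observed heterozygosity      Ho  = #het / n_typed
* expected heterozygosity      He  = 1 - sum(p_i^2)   (plug-in gene diversity,
  no small-sample correction, so He = 1 - 1/Ne holds as an exact identity)
* effective number of alleles  Ne  = 1 / sum(p_i^2)
* polymorphic information content
                               PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import Genotype, GenotypeTable, SnpLocus, allele_frequencies

__all__ = [
    "DiversitySummary",
    "expected_heterozygosity",
    "effective_allele_number",
    "polymorphic_information_content",
    "diversity_summary",
    "diversity_table",
    "write_diversity_tsv",
]


@dataclass(frozen=True)
class DiversitySummary:
    ho: float
    he: float
    ne: float
    pic: float


def _check_freqs(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must be nonnegative and sum to 1")
    return p


def expected_heterozygosity(freqs: Sequence[float]) -> float:
    p = _check_freqs(freqs)
    return float(1.0 - np.sum(p**2))


def effective_allele_number(freqs: Sequence[float]) -> float:
    p = _check_freqs(freqs)
    return float(1.0 / np.sum(p**2))


def polymorphic_information_content(freqs: Sequence[float]) -> float:
    p = _check_freqs(freqs)
    cross = sum(2.0 * p[i] ** 2 * p[j] ** 2 for i, j in combinations(range(p.size), 2))
    return float(1.0 - np.sum(p**2) - cross)


def diversity_summary(
    gt: GenotypeTable, locus: "SnpLocus | str", group: str
) -> DiversitySummary:
    """Ho/He/Ne/PIC for one locus within one phenotype group.

    Computed over typed genotypes only; a monomorphic locus gives
    (0, 0, 1, 0).
    """
    j = gt.locus_index(locus)
    col = gt.calls[gt.group_mask(group), j]
    typed = col[col != Genotype.MISSING]
    if typed.size == 0:
        raise ValueError(f"group {group!r} has no typed genotypes at locus")
    ho = float(np.sum(typed == Genotype.HET) / typed.size)
    af = allele_frequencies(gt, locus, group=group)
    p = [f for f in af.freqs.values() if f > 0]
    return DiversitySummary(
        ho=ho,
        he=expected_heterozygosity(p),
        ne=effective_allele_number(p),
        pic=polymorphic_information_content(p),
    )


def diversity_table(gt: GenotypeTable) -> pd.DataFrame:
    rows = []
    for group in ("intolerant", "tolerant"):
        for loc in gt.loci:
            d = diversity_summary(gt, loc, group)
            rows.append(
                {"group": group, "locus": loc.id, "Ho": d.ho, "He": d.he, "Ne": d.ne, "PIC": d.pic}
            )
    return pd.DataFrame(rows)


def write_diversity_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("Ho", "He", "Ne", "PIC"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)
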