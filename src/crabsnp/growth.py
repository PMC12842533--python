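"""Correlation-matrix PCA on morphometric traits and growth-group contrasts.

Three traits are measured per animal: carapace length (mm), carapace width
(mm) and body weight (g).  Because the traits are strongly collinear, the
first principal component of their correlation matrix acts as an overall
body-size axis; animals are ranked by their PC1 score and the extremes form
fast-growing and slow-growing groups, between which mutant-genotype carrier
frequencies are compared.

Loadings are reported as eigenvector * sqrt(eigenvalue) (the trait-component
correlations), so eigenvalues sum to the number of traits and squared
loadings column-sum to the eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import Genotype, GenotypeTable

__all__ = [
    "GrowthRecord",
    "PcaResult",
    "correlation_pca",
    "assign_growth_groups",
    "growth_group_genotype_table",
    "read_growth_tsv",
    "write_growth_tsv",
    "pca_summary_frame",
]

TRAITS = ("carapace_length", "carapace_width", "body_weight")


@dataclass(frozen=True)
class GrowthRecord:
    sample_id: str
    carapace_length: float  # mm
    carapace_width: float  # mm
    body_weight: float  # g

    def __post_init__(self) -> None:
        if min(self.carapace_length, self.carapace_width, self.body_weight) <= 0:
            raise ValueError(f"sample {self.sample_id!r}: measurements must be positive")


@dataclass
class PcaResult:
    sample_ids: list[str]
    traits: tuple[str, ...]
    loadings: np.ndarray  # trait x component, eigenvector * sqrt(eigenvalue)
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # percent, sums to 100
    scores: np.ndarray  # sample x component


def _records_matrix(records: Sequence[GrowthRecord]) -> tuple[list[str], np.ndarray]:
    ids = [r.sample_id for r in records]
    X = np.array(
        [[r.carapace_length, r.carapace_width, r.body_weight] for r in records],
        dtype=float,
    )
    return ids, X


def correlation_pca(records: Sequence[GrowthRecord]) -> PcaResult:
    """PCA of the trait correlation matrix.

    Traits are standardized to zero mean and unit variance, so scale changes
    (mm vs cm, g vs kg) cannot alter the result.  Components are sorted by
    descending eigenvalue; each eigenvector's sign is fixed so its loading
    sum is nonnegative (with three positively correlated size traits this
    orients PC1 towards larger animals).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 samples for PCA")
    ids, X = _records_matrix(records)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        zero = [TRAITS[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance trait(s): {zero}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    signs = np.where(eigvecs.sum(axis=0) < 0, -1.0, 1.0)
    eigvecs = eigvecs * signs
    loadings = eigvecs * np.sqrt(eigvals)
    scores = Z @ eigvecs
    var_pct = eigvals / len(TRAITS) * 100.0
    return PcaResult(
        sample_ids=ids,
        traits=TRAITS,
        loadings=loadings,
        eigenvalues=eigvals,
        variance_explained=var_pct,
        scores=scores,
    )


def assign_growth_groups(
    pca: PcaResult, n_per_group: int = 25
) -> tuple[list[str], list[str]]:
    """Split samples into fast- and slow-growing groups by PC1 score.

    The ``n_per_group`` highest PC1 scores form the fast group and the lowest
    the slow group; animals in between stay unassigned.  PC1 is oriented so a
    larger score means a larger animal (positive body-weight loading); exact
    score ties at a boundary are broken by input order.
    """
    n = len(pca.sample_ids)
    if n < 2 * n_per_group:
        raise ValueError(f"need >= {2 * n_per_group} samples, have {n}")
    s = pca.scores[:, 0].copy()
    if pca.loadings[TRAITS.index("body_weight"), 0] < 0:
        s = -s
    desc = np.argsort(-s, kind="stable")
    asc = np.argsort(s, kind="stable")
    fast = [pca.sample_ids[i] for i in sorted(desc[:n_per_group])]
    slow = [pca.sample_ids[i] for i in sorted(asc[:n_per_group])]
    if set(fast) & set(slow):
        raise ValueError("fast and slow groups overlap; too few samples")
    return fast, slow


def growth_group_genotype_table(
    gt: GenotypeTable, fast_ids: Sequence[str], slow_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-locus mutant-carrier counts and frequencies by growth group.

    The frequency denominator is the total carrier count across both groups
    (fast + slow), so the two frequencies in a row sum to 1; rows with no
    carriers at all report no frequency.
    """
    if set(fast_ids) & set(slow_ids):
        raise ValueError("growth groups must be disjoint")
    rows = []
    for j, loc in enumerate(gt.loci):
        counts = {}
        for name, ids in (("fast", fast_ids), ("slow", slow_ids)):
            pos = {s: i for i, s in enumerate(gt.samples)}
            codes = np.array([gt.calls[pos[s], j] for s in ids])
            typed = codes[codes != Genotype.MISSING]
            counts[name] = int(
                np.sum((typed == Genotype.HET) | (typed == Genotype.HOM_ALT))
            )
        total = counts["fast"] + counts["slow"]
        rows.append(
            {
                "locus": loc.id,
                "fast_carriers": counts["fast"],
                "fast_freq": counts["fast"] / total if total else np.nan,
                "slow_carriers": counts["slow"],
                "slow_freq": counts["slow"] / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pca_summary_frame(pca: PcaResult) -> pd.DataFrame:
    """Loadings/eigenvalue/variance summary with one column per component."""
    cols = [f"PC{k + 1}" for k in range(len(pca.eigenvalues))]
    data = {"quantity": [*pca.traits, "eigenvalue", "variance_explained_pct", "cumulative_pct"]}
    cum = np.cumsum(pca.variance_explained)
    for k, c in enumerate(cols):
        data[c] = [
            *(pca.loadings[i, k] for i in range(len(pca.traits))),
            pca.eigenvalues[k],
            pca.variance_explained[k],
            cum[k],
        ]
    return pd.DataFrame(data)


def read_growth_tsv(path, sep: str = "\t") -> list[GrowthRecord]:
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "carapace_length_mm", "carapace_width_mm", "body_weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns {sorted(missing)}")
    return [
        GrowthRecord(
            sample_id=str(r.sample_id),
            carapace_length=float(r.carapace_length_mm),
            carapace_width=float(r.carapace_width_mm),
            body_weight=float(r.body_weight_g),
        )
        for r in df.itertuples(index=False)
    ]


def write_growth_tsv(records: Sequence[GrowthRecord], path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "carapace_length_mm": [r.carapace_length for r in records],
            "carapace_width_mm": [r.carapace_width for r in records],
            "body_weight_g": [r.body_weight for r in records],
        }
    ).to_csv(path, sep=sep, index=False)
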