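"""Per-locus case-control association statistics.

The design compares mutant-allele carriers (het or hom_alt) against
homozygous wild types between the tolerant and intolerant phenotype groups.
Each locus yields a 2x2 table

    N1 = carriers in the tolerant group      N2 = wild types in the tolerant group
    N3 = carriers in the intolerant group    N4 = wild types in the intolerant group

from which the odds ratio OR = (N1*N4)/(N2*N3), its Woolf log-normal
confidence interval, the Pearson chi-square statistic (no continuity
correction), Fisher's exact test and a single-predictor logistic regression
effect (log-OR) are derived.  Cells may be nonnegative reals so that the
same machinery accepts EM expected haplotype counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import Genotype, GenotypeTable, SnpLocus

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "LogisticResult",
    "carrier_contingency",
    "genotype_counts",
    "odds_ratio",
    "woolf_ci",
    "chi2_2x2",
    "chi2_pvalue_df1",
    "fisher_exact_2x2",
    "logistic_single_locus",
    "association_table",
    "write_association_tsv",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case-control counts; reals are allowed (EM expected counts)."""

    n1: float
    n2: float
    n3: float
    n4: float

    def __post_init__(self) -> None:
        cells = (self.n1, self.n2, self.n3, self.n4)
        if any(c < 0 for c in cells):
            raise ValueError("contingency cells must be nonnegative")
        if not any(c > 0 for c in cells):
            raise ValueError("contingency table must have at least one positive cell")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.n1, self.n2, self.n3, self.n4)

    @property
    def total(self) -> float:
        return self.n1 + self.n2 + self.n3 + self.n4

    def swapped_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.n3, self.n4, self.n1, self.n2)

    def rounded_half_even(self) -> "ContingencyTable":
        """Round each cell half-to-even (for exact-test procedures that
        require integer counts)."""
        return ContingencyTable(*(float(round(c)) for c in self.cells))


@dataclass(frozen=True)
class LogisticResult:
    log_or: float | None
    se: float | None
    p: float | None
    separation: bool = False


@dataclass(frozen=True)
class AssociationResult:
    locus: str
    table: ContingencyTable
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    chi2: float | None
    p_pearson: float | None
    p_fisher: float | None
    log_or: float | None
    log_or_se: float | None


def carrier_contingency(gt: GenotypeTable, locus: "SnpLocus | str") -> ContingencyTable:
    """Count mutant carriers (het + hom_alt) vs wild types per phenotype group.

    Missing genotypes are excluded from all four cells; a group with zero
    typed samples at the locus is an error.
    """
    j = gt.locus_index(locus)
    col = gt.calls[:, j]
    cells = {}
    for group, keys in (("tolerant", ("n1", "n2")), ("intolerant", ("n3", "n4"))):
        sub = col[gt.group_mask(group)]
        typed = sub[sub != Genotype.MISSING]
        if typed.size == 0:
            raise ValueError(f"group {group!r} has no typed samples at locus")
        carriers = int(np.sum((typed == Genotype.HET) | (typed == Genotype.HOM_ALT)))
        cells[keys[0]] = carriers
        cells[keys[1]] = int(typed.size) - carriers
    return ContingencyTable(**cells)


def genotype_counts(gt: GenotypeTable, locus: "SnpLocus | str") -> pd.DataFrame:
    """Per-genotype counts by phenotype group (3-row codominant view)."""
    j = gt.locus_index(locus)
    col = gt.calls[:, j]
    rows = []
    for code in (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT):
        row = {"genotype": code.name.lower()}
        for group in ("tolerant", "intolerant"):
            sub = col[gt.group_mask(group)]
            row[group] = int(np.sum(sub == code))
        rows.append(row)
    return pd.DataFrame(rows)


def odds_ratio(t: ContingencyTable) -> float | None:
    """Cross-product odds ratio N1*N4 / (N2*N3); None when incomputable
    (a zero product in numerator or denominator)."""
    num = t.n1 * t.n4
    den = t.n2 * t.n3
    if num == 0 or den == 0:
        return None
    return num / den


def woolf_ci(t: ContingencyTable, z: float = 1.96) -> tuple[float, float] | None:
    """Woolf log-normal confidence interval exp(ln OR +/- z*SE) with
    SE = sqrt(1/N1 + 1/N2 + 1/N3 + 1/N4); None if any cell is zero."""
    if any(c == 0 for c in t.cells):
        return None
    or_ = t.n1 * t.n4 / (t.n2 * t.n3)
    se = math.sqrt(sum(1.0 / c for c in t.cells))
    log_or = math.log(or_)
    try:
        return (math.exp(log_or - z * se), math.exp(log_or + z * se))
    except OverflowError:
        # a near-zero cell makes the interval numerically unbounded
        return None


def woolf_se(t: ContingencyTable) -> float | None:
    if any(c == 0 for c in t.cells):
        return None
    return math.sqrt(sum(1.0 / c for c in t.cells))


def chi2_2x2(t: ContingencyTable) -> float:
    """Pearson chi-square for a 2x2 table (closed form, no continuity
    correction); raises on a degenerate (zero) margin."""
    n1, n2, n3, n4 = t.cells
    r1, r2 = n1 + n2, n3 + n4
    c1, c2 = n1 + n3, n2 + n4
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate margin")
    n = t.total
    return n * (n1 * n4 - n2 * n3) ** 2 / (r1 * r2 * c1 * c2)


def chi2_pvalue_df1(x: float) -> float:
    """Upper-tail p-value of the chi-square distribution with 1 df."""
    if x < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    return float(stats.chi2.sf(x, df=1))


def fisher_exact_2x2(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (sum of hypergeometric probabilities
    not exceeding that of the observed table).

    Cells must be integers; EM expected counts must first be rounded with
    :meth:`ContingencyTable.rounded_half_even`.
    """
    cells = t.cells
    if any(abs(c - round(c)) > 1e-9 for c in cells):
        raise ValueError(
            "Fisher's exact test requires integer counts; round fractional "
            "expected counts with ContingencyTable.rounded_half_even() first"
        )
    a, b, c, d = (int(round(x)) for x in cells)
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def logistic_single_locus(
    gt: GenotypeTable, locus: "SnpLocus | str"
) -> LogisticResult:
    """Binary logistic regression of tolerance on carrier status.

    Fitted by iteratively reweighted least squares; for a single binary
    predictor the maximum-likelihood slope coincides with ln(OR) and its
    standard error with the Woolf standard error.  A zero cell means complete
    or quasi-complete separation and the effect is reported undefined.
    """
    t = carrier_contingency(gt, locus)
    return logistic_from_table(t)


def logistic_from_table(t: ContingencyTable) -> LogisticResult:
    if any(c == 0 for c in t.cells):
        return LogisticResult(None, None, None, separation=True)
    import statsmodels.api as sm

    # four covariate patterns weighted by their cell counts
    X = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
    y = np.array([1.0, 1.0, 0.0, 0.0])
    w = np.array(t.cells, dtype=float)
    fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(
        tol=1e-12, maxiter=200
    )
    return LogisticResult(
        log_or=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        separation=False,
    )


def associate_locus(gt: GenotypeTable, locus: "SnpLocus | str") -> AssociationResult:
    t = carrier_contingency(gt, locus)
    ci = woolf_ci(t)
    try:
        chi2 = chi2_2x2(t)
        p_pearson = chi2_pvalue_df1(chi2)
    except ValueError:
        chi2 = p_pearson = None
    p_fisher = fisher_exact_2x2(t)
    logi = logistic_from_table(t)
    lid = locus.id if isinstance(locus, SnpLocus) else locus
    return AssociationResult(
        locus=lid,
        table=t,
        odds_ratio=odds_ratio(t),
        ci_low=ci[0] if ci else None,
        ci_high=ci[1] if ci else None,
        chi2=chi2,
        p_pearson=p_pearson,
        p_fisher=p_fisher,
        log_or=logi.log_or,
        log_or_se=logi.se,
    )


def association_table(
    gt: GenotypeTable, loci: Sequence["SnpLocus | str"] | None = None
) -> pd.DataFrame:
    """Per-locus association summary over all (or the given) loci.

    p-values are reported raw, without multiple-testing correction; with four
    candidate loci the per-family error rate is the reader's to weigh.
    """
    chosen = loci if loci is not None else gt.loci
    rows = []
    for locus in chosen:
        r = associate_locus(gt, locus)
        rows.append(
            {
                "locus": r.locus,
                "n1": r.table.n1,
                "n2": r.table.n2,
                "n3": r.table.n3,
                "n4": r.table.n4,
                "OR": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "chi2": r.chi2,
                "p_pearson": r.p_pearson,
                "p_fisher": r.p_fisher,
                "log_or": r.log_or,
                "log_or_se": r.log_or_se,
            }
        )
    return pd.DataFrame(rows)


def _fmt(x, nd: int = 4) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "-"
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def write_association_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if col == "locus":
            continue
        out[col] = [_fmt(v) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)
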