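"""Case-control haplotype association tables on EM expected counts.

Each haplotype is tested against all others in a 2x2 table of expected
chromosome counts (tolerant vs intolerant).  Haplotypes rarer than
``rare_threshold`` in both groups are reported but excluded from the group
totals and carry no statistics, following the convention of standard
haplotype-association software ("lowest frequency threshold").  The odds
ratio is undefined whenever a zero cell makes the cross-product ratio
incomputable; chi-square needs only nondegenerate margins, so a haplotype
absent from one group can still have a defined chi-square but an undefined
OR.  Fisher's exact p is computed on the half-even-rounded table and is
approximate for fractional EM counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import pandas as pd

from .association import (
    ContingencyTable,
    chi2_2x2,
    chi2_pvalue_df1,
    fisher_exact_2x2,
    odds_ratio,
    woolf_ci,
)
from .haplotypes import HaplotypeDistribution

__all__ = ["HaplotypeAssociationRow", "build_haplotype_table", "haplotype_table_frame", "write_haplotype_tsv"]


@dataclass(frozen=True)
class HaplotypeAssociationRow:
    haplotype: str
    count_tol: float
    count_intol: float
    freq_tol: float
    freq_intol: float
    included: bool
    chi2: float | None
    p_pearson: float | None
    p_fisher: float | None
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None


def _as_counts(dist) -> tuple[dict[str, float], tuple[str, ...] | None]:
    if isinstance(dist, HaplotypeDistribution):
        return dict(dist.expected_counts), dist.loci
    return dict(dist), None


def build_haplotype_table(
    tol,
    intol,
    rare_threshold: float = 0.03,
    order: str = "tolerant_count",
    zero_tol: float = 1e-6,
) -> list[HaplotypeAssociationRow]:
    """Build the per-haplotype case-control association table.

    *tol* and *intol* are :class:`~crabsnp.haplotypes.HaplotypeDistribution`
    objects or plain ``haplotype -> expected count`` mappings for the tolerant
    and intolerant groups.  Relative frequencies are counts over the full
    group total; a haplotype is *included* when its frequency reaches
    ``rare_threshold`` in at least one group, and the 2x2 group totals sum
    included haplotypes only.

    ``order`` is ``"tolerant_count"`` (descending, ties by haplotype string)
    or ``"input"`` (first-appearance order, tolerant mapping first).
    """
    counts_tol, loci_tol = _as_counts(tol)
    counts_intol, loci_intol = _as_counts(intol)
    if loci_tol is not None and loci_intol is not None and loci_tol != loci_intol:
        raise ValueError(f"mismatched loci: {loci_tol} vs {loci_intol}")
    # expected counts below zero_tol chromosomes are numerical residue of the
    # EM split, not evidence the haplotype was observed: treat as exact zero
    # so undefined statistics ("-") land where a zero-frequency cell belongs
    counts_tol = {h: (0.0 if c < zero_tol else c) for h, c in counts_tol.items()}
    counts_intol = {h: (0.0 if c < zero_tol else c) for h, c in counts_intol.items()}

    haps = list(dict.fromkeys(list(counts_tol) + list(counts_intol)))
    total_tol = sum(counts_tol.values())
    total_intol = sum(counts_intol.values())
    if total_tol <= 0 or total_intol <= 0:
        raise ValueError("each group needs a positive haplotype count total")

    freq_tol = {h: counts_tol.get(h, 0.0) / total_tol for h in haps}
    freq_intol = {h: counts_intol.get(h, 0.0) / total_intol for h in haps}
    included = {
        h: (freq_tol[h] >= rare_threshold or freq_intol[h] >= rare_threshold)
        for h in haps
    }
    inc_total_tol = sum(counts_tol.get(h, 0.0) for h in haps if included[h])
    inc_total_intol = sum(counts_intol.get(h, 0.0) for h in haps if included[h])

    rows = []
    for h in haps:
        c_tol = counts_tol.get(h, 0.0)
        c_intol = counts_intol.get(h, 0.0)
        chi2 = p_pearson = p_fisher = or_ = ci_low = ci_high = None
        if included[h]:
            t = ContingencyTable(
                c_tol, inc_total_tol - c_tol, c_intol, inc_total_intol - c_intol
            )
            try:
                chi2 = chi2_2x2(t)
                p_pearson = chi2_pvalue_df1(chi2)
            except ValueError:
                pass
            if chi2 is not None:
                try:
                    p_fisher = fisher_exact_2x2(t.rounded_half_even())
                except ValueError:
                    pass
            or_ = odds_ratio(t)
            ci = woolf_ci(t)
            if ci is not None:
                ci_low, ci_high = ci
        rows.append(
            HaplotypeAssociationRow(
                haplotype=h,
                count_tol=c_tol,
                count_intol=c_intol,
                freq_tol=freq_tol[h],
                freq_intol=freq_intol[h],
                included=included[h],
                chi2=chi2,
                p_pearson=p_pearson,
                p_fisher=p_fisher,
                odds_ratio=or_,
                ci_low=ci_low,
                ci_high=ci_high,
            )
        )
    if order == "tolerant_count":
        rows.sort(key=lambda r: (-r.count_tol, r.haplotype))
    elif order != "input":
        raise ValueError(f"unknown order {order!r}")
    return rows


def haplotype_table_frame(rows: list[HaplotypeAssociationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "haplotype": r.haplotype,
                "count_tol": r.count_tol,
                "freq_tol": r.freq_tol,
                "count_intol": r.count_intol,
                "freq_intol": r.freq_intol,
                "chi2": r.chi2,
                "p_fisher": r.p_fisher,
                "p_pearson": r.p_pearson,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in rows
        ]
    )


def _fmt(x, nd=4) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "-"
    return f"{x:.{nd}f}" if isinstance(x, float) else str(x)


def write_haplotype_tsv(rows: list[HaplotypeAssociationRow], path) -> None:
    df = haplotype_table_frame(rows)
    out = pd.DataFrame(
        {
            "haplotype": df["haplotype"],
            "tolerant_count": df["count_tol"].map(lambda v: f"{v:.2f}"),
            "tolerant_freq": df["freq_tol"].map(lambda v: f"{v:.3f}"),
            "intolerant_count": df["count_intol"].map(lambda v: f"{v:.2f}"),
            "intolerant_freq": df["freq_intol"].map(lambda v: f"{v:.3f}"),
            "chi2": df["chi2"].map(_fmt),
            "p_fisher": df["p_fisher"].map(_fmt),
            "p_pearson": df["p_pearson"].map(_fmt),
            "odds_ratio": df["odds_ratio"].map(_fmt),
            "ci_low": df["ci_low"].map(_fmt),
            "ci_high": df["ci_high"].map(_fmt),
        }
    )
    out.to_csv(path, sep="\t", index=False)
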