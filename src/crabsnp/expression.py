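"""Relative gene expression by the 2^-ddCt method with ANOVA and letters.

Each qPCR observation carries a target-gene and a reference-gene threshold
cycle (Ct).  Technical replicates are averaged on the Ct scale, then

    dCt   = Ct_target - Ct_reference                  (per sample)
    ddCt  = dCt - mean dCt of the calibrator genotype (per locus)
    fold  = 2^-ddCt

so the calibrator class averages to fold 1 by construction.  Genotype classes
are compared by one-way ANOVA; pairwise differences use Tukey's HSD by
default (Duncan's multiple range test is available behind a flag), and a
compact-letter display marks groups that do not differ significantly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRecord",
    "PosthocResult",
    "read_expression_tsv",
    "write_expression_tsv",
    "relative_expression",
    "anova_posthoc",
    "expression_summary",
]


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str
    locus: str
    genotype: str  # allele-pair label, e.g. "GG", "GT"
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not (0 < ct < 45):
                raise ValueError(
                    f"sample {self.sample_id!r}: Ct {ct} outside (0, 45)"
                )


@dataclass
class PosthocResult:
    f: float
    p: float
    method: str
    letters: dict[str, str]
    pairwise: pd.DataFrame  # group_1, group_2, significant (and p_value for Tukey)


def relative_expression(
    records: Sequence[ExpressionRecord], calibrator: str = "GG"
) -> pd.DataFrame:
    """Per-sample fold changes relative to the calibrator genotype's mean dCt.

    Processed per locus.  Returns columns ``locus``, ``sample_id``,
    ``genotype``, ``delta_ct``, ``delta_delta_ct``, ``fold``.
    """
    if not records:
        raise ValueError("no expression records")
    df = pd.DataFrame(
        {
            "locus": [r.locus for r in records],
            "sample_id": [r.sample_id for r in records],
            "genotype": [r.genotype for r in records],
            "dct": [r.ct_target - r.ct_reference for r in records],
        }
    )
    # average technical replicates on the Ct scale
    per_sample = (
        df.groupby(["locus", "sample_id", "genotype"], sort=False)["dct"]
        .mean()
        .reset_index()
    )
    out = []
    for locus, sub in per_sample.groupby("locus", sort=False):
        cal = sub.loc[sub["genotype"] == calibrator, "dct"]
        if cal.empty:
            raise ValueError(
                f"locus {locus!r}: calibrator genotype {calibrator!r} has no records"
            )
        cal_mean = float(cal.mean())
        for r in sub.itertuples(index=False):
            ddct = r.dct - cal_mean
            out.append(
                {
                    "locus": locus,
                    "sample_id": r.sample_id,
                    "genotype": r.genotype,
                    "delta_ct": r.dct,
                    "delta_delta_ct": ddct,
                    "fold": 2.0 ** (-ddct),
                }
            )
    return pd.DataFrame(out)


def _compact_letters(groups: list[str], significant: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one column holding all groups; every significant pair splits
    the columns that contain both members; redundant columns are absorbed.
    Letters follow the input group order.
    """
    columns: list[set[str]] = [set(groups)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend((col - {a}, col - {b}))
            else:
                new_cols.append(col)
        # absorb: drop empty columns, duplicates, and proper subsets
        uniq: list[set[str]] = []
        for c in new_cols:
            if c and c not in uniq:
                uniq.append(c)
        columns = [c for c in uniq if not any(c < other for other in uniq)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def _duncan_significant(
    groups: list[str],
    data: list[np.ndarray],
    msw: float,
    dfw: int,
    alpha: float,
) -> dict[tuple[str, str], bool]:
    """Duncan's multiple range test with the step-down protection rule.

    Means are ranked; a span of r means uses the critical value
    q*(alpha_r, r, df) with alpha_r = 1 - (1-alpha)^(r-1); a span is only
    declared significant if no wider span containing it was non-significant.
    """
    means = np.array([np.mean(d) for d in data])
    n_harm = len(data) / np.sum([1.0 / len(d) for d in data])
    se = math.sqrt(msw / n_harm)
    order = np.argsort(means)
    k = len(groups)
    nonsig_spans: list[tuple[int, int]] = []
    sig: dict[tuple[str, str], bool] = {}
    for span in range(k, 1, -1):
        for start in range(0, k - span + 1):
            lo, hi = start, start + span - 1
            pair = (groups[order[lo]], groups[order[hi]])
            covered = any(a <= lo and hi <= b for a, b in nonsig_spans)
            if covered:
                sig[pair] = False
                nonsig_spans.append((lo, hi))
                continue
            q_crit = stats.studentized_range.ppf((1 - alpha) ** (span - 1), span, dfw)
            diff = means[order[hi]] - means[order[lo]]
            is_sig = diff > q_crit * se
            sig[pair] = bool(is_sig)
            if not is_sig:
                nonsig_spans.append((lo, hi))
    return sig


def anova_posthoc(
    folds_by_group: "Mapping[str, Sequence[float]] | pd.DataFrame",
    alpha: float = 0.05,
    method: str = "tukey",
) -> PosthocResult:
    """One-way ANOVA across genotype classes with a post-hoc letter display.

    Accepts a ``genotype -> fold values`` mapping or a DataFrame with
    ``genotype`` and ``fold`` columns.  ``method`` is ``"tukey"`` (HSD,
    default) or ``"duncan"``.
    """
    if isinstance(folds_by_group, pd.DataFrame):
        grouped = {
            str(g): sub["fold"].to_numpy(dtype=float)
            for g, sub in folds_by_group.groupby("genotype", sort=False)
        }
    else:
        grouped = {str(g): np.asarray(v, dtype=float) for g, v in folds_by_group.items()}
    groups = list(grouped)
    data = [grouped[g] for g in groups]
    if len(groups) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(d) == 0 for d in data):
        raise ValueError("degenerate ANOVA: zero within-group variance everywhere")

    f, p = stats.f_oneway(*data)
    n_total = sum(len(d) for d in data)
    dfw = n_total - len(groups)
    ssw = sum(float(np.sum((d - d.mean()) ** 2)) for d in data)
    msw = ssw / dfw

    if method == "tukey":
        res = stats.tukey_hsd(*data)
        pairs = {}
        pvals = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pv = float(res.pvalue[i, j])
                pairs[(groups[i], groups[j])] = pv < alpha
                pvals[(groups[i], groups[j])] = pv
        pairwise = pd.DataFrame(
            [
                {"group_1": a, "group_2": b, "p_value": pvals[(a, b)], "significant": s}
                for (a, b), s in pairs.items()
            ]
        )
    elif method == "duncan":
        pairs = _duncan_significant(groups, data, msw, dfw, alpha)
        pairwise = pd.DataFrame(
            [
                {"group_1": a, "group_2": b, "significant": s}
                for (a, b), s in pairs.items()
            ]
        )
    else:
        raise ValueError("method must be 'tukey' or 'duncan'")

    letters = _compact_letters(groups, pairs)
    return PosthocResult(f=float(f), p=float(p), method=method, letters=letters, pairwise=pairwise)


def expression_summary(
    folds: pd.DataFrame, alpha: float = 0.05, method: str = "tukey"
) -> pd.DataFrame:
    """Per-locus, per-genotype mean fold +/- SE with post-hoc letters."""
    rows = []
    for locus, sub in folds.groupby("locus", sort=False):
        # the test needs >= 2 genotype classes with >= 2 animals each; a
        # class observed in a single animal is summarised but not tested
        sizes = sub.groupby("genotype", sort=False)["fold"].count()
        testable = sub[sub["genotype"].isin(sizes[sizes >= 2].index)]
        post = None
        if testable["genotype"].nunique() >= 2:
            try:
                post = anova_posthoc(testable, alpha=alpha, method=method)
            except ValueError:
                post = None
        for geno, grp in sub.groupby("genotype", sort=False):
            vals = grp["fold"].to_numpy()
            rows.append(
                {
                    "locus": locus,
                    "genotype": geno,
                    "n": len(vals),
                    "mean_fold": float(vals.mean()),
                    "se_fold": float(vals.std(ddof=1) / math.sqrt(len(vals)))
                    if len(vals) > 1
                    else float("nan"),
                    "letters": post.letters.get(str(geno), "") if post else "",
                    "anova_f": post.f if post else float("nan"),
                    "anova_p": post.p if post else float("nan"),
                }
            )
    return pd.DataFrame(rows)


EXPRESSION_COLUMNS = (
    "sample_id",
    "locus",
    "genotype",
    "replicate",
    "ct_target",
    "ct_reference",
)


def read_expression_tsv(path, sep: str = "\t") -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep=sep)
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    return [
        ExpressionRecord(
            sample_id=str(r.sample_id),
            locus=str(r.locus),
            genotype=str(r.genotype),
            replicate=int(r.replicate),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_reference),
        )
        for r in df.itertuples(index=False)
    ]


def write_expression_tsv(records: Sequence[ExpressionRecord], path, sep: str = "\t") -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep=sep, index=False)
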