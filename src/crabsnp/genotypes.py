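"""Genotype containers, chromatogram peak-ratio calling, and MAF filtering.

The unit of analysis is an unphased biallelic SNP genotype in a case-control
design: each sample belongs to a low-salinity *tolerant* or *intolerant*
phenotype group (or is unlabelled) and carries, at each locus, one of
``hom_ref``, ``het``, ``hom_alt`` or ``missing``.

Genotypes are obtained by direct Sanger sequencing of PCR amplicons; a
heterozygote shows two superimposed base peaks at the SNP position.  The
caller here abstracts that chromatogram into a :class:`PeakObservation`
(primary/secondary base and peak heights) and applies the standard
peak-height-ratio rule: a secondary peak at >= 30% of the primary peak is a
heterozygote, below 20% it is noise (homozygote for the primary base), and
the 20-30% band is ambiguous and left missing for manual review.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "SnpLocus",
    "PeakObservation",
    "AlleleFrequencies",
    "GenotypeTable",
    "call_genotype_from_peaks",
    "call_genotypes_from_peak_table",
    "read_peak_table",
    "allele_frequencies",
    "filter_loci_by_maf",
]

_NUCLEOTIDES = frozenset("ACGT")
PHENOTYPES = ("tolerant", "intolerant", "unlabelled")
MISSING_TOKEN = "./."

_LOCUS_LABEL_RE = re.compile(r"([ACGT])>([ACGT])\s*$")


class Genotype(enum.IntEnum):
    """Unphased biallelic genotype code relative to a locus ref/alt pair."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic SNP with its gene-structure annotation.

    ``region`` is where the variant falls in the gene (exon or intron) and
    ``effect`` is its predicted consequence (missense, nonsense, intronic,
    synonymous, or unknown).
    """

    id: str
    ref_allele: str
    alt_allele: str
    region: str = "exon"
    effect: str = "unknown"

    def __post_init__(self) -> None:
        if self.ref_allele not in _NUCLEOTIDES or self.alt_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"locus {self.id!r}: alleles must be single nucleotides, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.id!r}: ref and alt alleles must differ")
        if self.region not in ("exon", "intron"):
            raise ValueError(f"locus {self.id!r}: region must be 'exon' or 'intron'")
        if self.effect not in ("missense", "nonsense", "intronic", "synonymous", "unknown"):
            raise ValueError(f"locus {self.id!r}: unknown effect {self.effect!r}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "SnpLocus":
        """Build a locus from a label ending in ``<ref>><alt>``, e.g. ``g.72037G>T``."""
        m = _LOCUS_LABEL_RE.search(label)
        if m is None:
            raise ValueError(f"cannot parse ref/alt alleles from locus label {label!r}")
        return cls(id=label, ref_allele=m.group(1), alt_allele=m.group(2), **kwargs)


@dataclass(frozen=True)
class PeakObservation:
    """Primary/secondary chromatogram peak at one SNP position."""

    primary_base: str
    primary_height: float
    secondary_base: str
    secondary_height: float

    def __post_init__(self) -> None:
        if self.primary_base not in _NUCLEOTIDES or self.secondary_base not in _NUCLEOTIDES:
            raise ValueError("peak bases must be single nucleotides")
        if self.secondary_height < 0 or self.primary_height < self.secondary_height:
            raise ValueError(
                "peak heights must satisfy primary_height >= secondary_height >= 0"
            )


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele frequencies at one locus, over typed (non-missing) genotypes."""

    locus: SnpLocus
    freqs: Mapping[str, float]
    n_typed: int
    counts: Mapping[str, int]

    @property
    def maf(self) -> float:
        return min(self.freqs.values())

    @property
    def maf_exact(self) -> Fraction:
        """Minor allele frequency as an exact rational of allele counts."""
        total = 2 * self.n_typed
        return Fraction(min(self.counts.values()), total)


def _code_from_alleles(a: str, b: str, locus: SnpLocus, *, context: str = "") -> Genotype:
    valid = set(locus.alleles)
    for x in (a, b):
        if x not in valid:
            raise ValueError(
                f"allele {x!r} not among {locus.alleles} at locus {locus.id!r}{context}"
            )
    if a == b:
        return Genotype.HOM_REF if a == locus.ref_allele else Genotype.HOM_ALT
    return Genotype.HET


@dataclass
class GenotypeTable:
    """Sample x locus matrix of unphased genotype codes with phenotype labels.

    ``calls`` is an ``int8`` matrix using the :class:`Genotype` codes.  Sample
    and locus order are preserved from input; all downstream statistics are
    required to be invariant to that order.
    """

    samples: list[str]
    loci: list[SnpLocus]
    calls: np.ndarray
    phenotype: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(self.phenotype) != len(self.samples):
            raise ValueError("phenotype length must match samples")
        bad = set(self.phenotype) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        valid = {int(g) for g in Genotype}
        if not set(np.unique(self.calls)).issubset(valid):
            raise ValueError("calls contain codes outside the Genotype enum")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")

    # -- indexing ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: "SnpLocus | str") -> int:
        lid = locus.id if isinstance(locus, SnpLocus) else locus
        for j, loc in enumerate(self.loci):
            if loc.id == lid:
                return j
        raise KeyError(f"locus {lid!r} not in table")

    def get_locus(self, locus: "SnpLocus | str") -> SnpLocus:
        return self.loci[self.locus_index(locus)]

    def group_mask(self, group: str | None) -> np.ndarray:
        if group is None:
            return np.ones(self.n_samples, dtype=bool)
        if group not in PHENOTYPES:
            raise ValueError(f"unknown group {group!r}")
        return np.array([p == group for p in self.phenotype], dtype=bool)

    def alleles_at(self, i: int, j: int) -> str:
        """Genotype at sample *i*, locus *j* as an allele-pair string like ``G/T``."""
        code = Genotype(self.calls[i, j])
        loc = self.loci[j]
        if code == Genotype.MISSING:
            return MISSING_TOKEN
        if code == Genotype.HOM_REF:
            return f"{loc.ref_allele}/{loc.ref_allele}"
        if code == Genotype.HOM_ALT:
            return f"{loc.alt_allele}/{loc.alt_allele}"
        return f"{loc.ref_allele}/{loc.alt_allele}"

    def subset_loci(self, loci: Sequence["SnpLocus | str"]) -> "GenotypeTable":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeTable(
            samples=list(self.samples),
            loci=[self.loci[j] for j in idx],
            calls=self.calls[:, idx].copy(),
            phenotype=list(self.phenotype),
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return GenotypeTable(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx, :].copy(),
            phenotype=[self.phenotype[i] for i in idx],
        )

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, sep: str = "\t") -> "GenotypeTable":
        """Read a genotype table: columns ``sample_id``, ``phenotype``, then one
        column per locus holding ``X/Y`` allele pairs or ``./.`` for missing.

        Locus ref/alt alleles are parsed from column labels of the form
        ``...<ref>><alt>`` (e.g. ``g.72037G>T``); otherwise the major observed
        allele is taken as ref.  A third allele at a locus is an error.
        """
        df = pd.read_csv(path, sep=sep, dtype=str)
        required = {"sample_id", "phenotype"}
        if not required.issubset(df.columns):
            raise ValueError(f"genotype table must have columns {sorted(required)}")
        locus_cols = [c for c in df.columns if c not in required]
        samples = df["sample_id"].tolist()
        phenotype = df["phenotype"].fillna("unlabelled").tolist()

        loci: list[SnpLocus] = []
        calls = np.full((len(samples), len(locus_cols)), Genotype.MISSING, dtype=np.int8)
        for j, col in enumerate(locus_cols):
            pairs: list[tuple[str, str] | None] = []
            observed: list[str] = []
            for i, raw in enumerate(df[col]):
                val = "" if pd.isna(raw) else str(raw).strip()
                if val in ("", MISSING_TOKEN, ".", "NA"):
                    pairs.append(None)
                    continue
                parts = val.split("/")
                if len(parts) != 2:
                    raise ValueError(
                        f"sample {samples[i]!r}, locus {col!r}: cannot parse genotype {val!r}"
                    )
                a, b = parts[0].strip().upper(), parts[1].strip().upper()
                pairs.append((a, b))
                observed.extend((a, b))
            locus = cls._infer_locus(col, observed, samples, pairs)
            loci.append(locus)
            for i, pair in enumerate(pairs):
                if pair is None:
                    continue
                calls[i, j] = _code_from_alleles(
                    pair[0], pair[1], locus, context=f" (sample {samples[i]!r})"
                )
        return cls(samples=samples, loci=loci, calls=calls, phenotype=phenotype)

    @staticmethod
    def _infer_locus(col: str, observed: list[str], samples, pairs) -> SnpLocus:
        uniq = sorted(set(observed))
        bad = [a for a in uniq if a not in _NUCLEOTIDES]
        if bad:
            offenders = [
                samples[i] for i, p in enumerate(pairs) if p and set(p) & set(bad)
            ]
            raise ValueError(
                f"locus {col!r}: invalid allele(s) {bad} (samples {offenders[:3]})"
            )
        m = _LOCUS_LABEL_RE.search(col)
        if m is not None:
            ref, alt = m.group(1), m.group(2)
            extra = set(uniq) - {ref, alt}
            if extra:
                offenders = [
                    samples[i] for i, p in enumerate(pairs) if p and set(p) & extra
                ]
                raise ValueError(
                    f"locus {col!r}: observed third allele(s) {sorted(extra)} "
                    f"beyond biallelic {ref}/{alt} (samples {offenders[:3]})"
                )
            return SnpLocus(id=col, ref_allele=ref, alt_allele=alt)
        if len(uniq) > 2:
            raise ValueError(f"locus {col!r}: more than two alleles observed: {uniq}")
        if len(uniq) == 0:
            raise ValueError(f"locus {col!r}: no typed genotypes and no ref/alt in label")
        if len(uniq) == 1:
            # monomorphic, unlabelled column: pick any other base as a nominal alt
            ref = uniq[0]
            alt = next(a for a in "ACGT" if a != ref)
            return SnpLocus(id=col, ref_allele=ref, alt_allele=alt)
        counts = {a: observed.count(a) for a in uniq}
        ref = max(uniq, key=lambda a: (counts[a], a))  # major allele = ref
        alt = next(a for a in uniq if a != ref)
        return SnpLocus(id=col, ref_allele=ref, alt_allele=alt)

    def to_tsv(self, path, sep: str = "\t") -> None:
        rows = []
        for i, s in enumerate(self.samples):
            row = {"sample_id": s, "phenotype": self.phenotype[i]}
            for j, loc in enumerate(self.loci):
                row[loc.id] = self.alleles_at(i, j)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)

    @classmethod
    def from_vcf(cls, path, phenotype: Mapping[str, str] | None = None) -> "GenotypeTable":
        """Minimal VCF ingestion: biallelic SNP records, GT field only.

        Phenotype labels are not part of VCF; supply a ``sample -> label``
        mapping, otherwise every sample is ``unlabelled``.
        """
        import pysam  # optional dependency, imported lazily

        vcf = pysam.VariantFile(str(path))
        samples = list(vcf.header.samples)
        loci: list[SnpLocus] = []
        columns: list[np.ndarray] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"record {rec.id or rec.pos}: only biallelic records supported")
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"record {rec.id or rec.pos}: only SNPs supported")
            lid = rec.id or f"{rec.chrom}:{rec.pos}{ref}>{alt}"
            loci.append(SnpLocus(id=lid, ref_allele=ref, alt_allele=alt))
            col = np.full(len(samples), Genotype.MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                col[i] = Genotype(sum(gt))
            columns.append(col)
        calls = (
            np.stack(columns, axis=1)
            if columns
            else np.empty((len(samples), 0), dtype=np.int8)
        )
        labels = [
            (phenotype or {}).get(s, "unlabelled") for s in samples
        ]
        return cls(samples=samples, loci=loci, calls=calls, phenotype=labels)


# ---------------------------------------------------------------------------
# Peak-ratio genotype calling
# ---------------------------------------------------------------------------


def call_genotype_from_peaks(
    obs: PeakObservation,
    locus: SnpLocus,
    het_ratio: float = 0.30,
    noise_ratio: float = 0.20,
) -> Genotype:
    """Call a genotype from chromatogram peak heights.

    With ``ratio = secondary_height / primary_height``:

    * ``ratio >= het_ratio`` (default 30%)  -> heterozygote,
    * ``ratio <  noise_ratio`` (default 20%) -> homozygote for the primary base
      (the secondary peak is noise),
    * in between -> ``missing``: the band is ambiguous and such traces are
      left for manual cross-checking rather than forced into a call.

    A zero primary peak means no signal; the call is missing (with a warning).
    """
    if not (0 <= noise_ratio < het_ratio <= 1):
        raise ValueError("thresholds must satisfy 0 <= noise_ratio < het_ratio <= 1")
    if obs.primary_height == 0:
        warnings.warn("no signal: primary peak height is zero", stacklevel=2)
        return Genotype.MISSING
    ratio = obs.secondary_height / obs.primary_height
    if ratio >= het_ratio:
        if obs.secondary_base == obs.primary_base:
            raise ValueError("heterozygous call requires two distinct peak bases")
        return _code_from_alleles(obs.primary_base, obs.secondary_base, locus)
    if ratio < noise_ratio:
        return _code_from_alleles(obs.primary_base, obs.primary_base, locus)
    return Genotype.MISSING


PEAK_COLUMNS = (
    "sample_id",
    "locus",
    "primary_base",
    "primary_height",
    "secondary_base",
    "secondary_height",
)


def read_peak_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns {sorted(missing)}")
    return df


def call_genotypes_from_peak_table(
    peaks: pd.DataFrame,
    loci: Sequence[SnpLocus],
    phenotype: Mapping[str, str] | None = None,
    het_ratio: float = 0.30,
    noise_ratio: float = 0.20,
) -> GenotypeTable:
    """Apply the peak-ratio caller to a whole peak table.

    Sample order follows first appearance in the table; (sample, locus) pairs
    with no row are missing.
    """
    by_id = {loc.id: loc for loc in loci}
    samples = list(dict.fromkeys(peaks["sample_id"].astype(str)))
    sample_pos = {s: i for i, s in enumerate(samples)}
    calls = np.full((len(samples), len(loci)), Genotype.MISSING, dtype=np.int8)
    locus_pos = {loc.id: j for j, loc in enumerate(loci)}
    for row in peaks.itertuples(index=False):
        lid = str(row.locus)
        if lid not in by_id:
            raise KeyError(f"peak table references unknown locus {lid!r}")
        obs = PeakObservation(
            primary_base=str(row.primary_base),
            primary_height=float(row.primary_height),
            secondary_base=str(row.secondary_base),
            secondary_height=float(row.secondary_height),
        )
        calls[sample_pos[str(row.sample_id)], locus_pos[lid]] = call_genotype_from_peaks(
            obs, by_id[lid], het_ratio=het_ratio, noise_ratio=noise_ratio
        )
    labels = [(phenotype or {}).get(s, "unlabelled") for s in samples]
    return GenotypeTable(samples=samples, loci=list(loci), calls=calls, phenotype=labels)


# ---------------------------------------------------------------------------
# Allele frequencies and MAF filtering
# ---------------------------------------------------------------------------


def allele_frequencies(
    gt: GenotypeTable, locus: "SnpLocus | str", group: str | None = None
) -> AlleleFrequencies:
    """Ref/alt allele frequencies at a locus over typed genotypes.

    alt frequency = (2 * #hom_alt + #het) / (2 * n_typed); missing calls are
    excluded from the denominator.
    """
    j = gt.locus_index(locus)
    loc = gt.loci[j]
    col = gt.calls[gt.group_mask(group), j]
    typed = col[col != Genotype.MISSING]
    n_typed = int(typed.size)
    if n_typed == 0:
        raise ValueError(f"no typed genotypes at locus {loc.id!r}")
    alt_count = int(2 * np.sum(typed == Genotype.HOM_ALT) + np.sum(typed == Genotype.HET))
    total = 2 * n_typed
    counts = {loc.ref_allele: total - alt_count, loc.alt_allele: alt_count}
    freqs = {a: c / total for a, c in counts.items()}
    return AlleleFrequencies(locus=loc, freqs=freqs, n_typed=n_typed, counts=counts)


def filter_loci_by_maf(gt: GenotypeTable, threshold: float = 0.05) -> GenotypeTable:
    """Keep loci whose minor allele frequency is >= *threshold*.

    The comparison is exact rational arithmetic on allele counts (e.g. 4 of 64
    alleles = 1/16 passes a 5% threshold, 3 of 64 does not), so float
    representation of the threshold cannot flip a borderline locus.
    """
    thr = Fraction(str(threshold))
    keep = []
    for loc in gt.loci:
        try:
            af = allele_frequencies(gt, loc)
        except ValueError:
            continue  # no typed genotypes: drop
        if af.maf_exact >= thr:
            keep.append(loc)
    return gt.subset_loci(keep)
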