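"""EM estimation of multi-locus haplotype frequencies from unphased genotypes.

An individual heterozygous at *h* of the loci is consistent with
``max(1, 2^(h-1))`` distinct unordered haplotype pairs.  The EM algorithm
treats phase as the latent variable: the E-step distributes each individual
over its compatible pairs with weight proportional to
``f(h1) * f(h2) * (2 - [h1 == h2])`` under the current frequency estimates
(random mating), and the M-step re-estimates each haplotype frequency as its
expected share of the ``2n`` sampled chromosomes.  The observed-data
log-likelihood is nondecreasing across iterations.

Expected counts (``2n * frequency``) are the natural output scale for
case-control haplotype tables: fractional values such as 45.53 simply record
how the algorithm splits phase-ambiguous individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import Genotype, GenotypeTable, SnpLocus

__all__ = [
    "HaplotypeDistribution",
    "enumerate_phase_configurations",
    "em_haplotype_frequencies",
]

_MAX_HET_LOCI = 20


@dataclass
class HaplotypeDistribution:
    """EM haplotype frequency estimate for one sample group."""

    loci: tuple[str, ...]
    frequencies: dict[str, float]
    expected_counts: dict[str, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_individuals: int
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")


def enumerate_phase_configurations(
    codes: Sequence[int], loci: Sequence[SnpLocus]
) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with one unphased genotype.

    ``codes`` holds one :class:`Genotype` code per locus, none missing.  With
    *h* heterozygous loci there are ``max(1, 2^(h-1))`` pairs: the phase of
    the first het locus is pinned to break the hap1/hap2 symmetry.
    """
    if len(codes) != len(loci):
        raise ValueError("codes and loci length mismatch")
    if any(c == Genotype.MISSING for c in codes):
        raise ValueError("cannot enumerate phases with missing calls")
    het_positions = [j for j, c in enumerate(codes) if c == Genotype.HET]
    if len(het_positions) > _MAX_HET_LOCI:
        raise ValueError("phase explosion: too many heterozygous loci")

    base1 = []
    base2 = []
    for j, c in enumerate(codes):
        loc = loci[j]
        if c == Genotype.HOM_REF:
            base1.append(loc.ref_allele)
            base2.append(loc.ref_allele)
        elif c == Genotype.HOM_ALT:
            base1.append(loc.alt_allele)
            base2.append(loc.alt_allele)
        else:  # het: placeholder, filled per configuration
            base1.append("")
            base2.append("")

    if not het_positions:
        hap = "".join(base1)
        return [(hap, hap)]

    pairs: list[tuple[str, str]] = []
    free = het_positions[1:]
    for mask in range(2 ** len(free)):
        h1 = list(base1)
        h2 = list(base2)
        # first het locus: hap1 carries ref (symmetry anchor)
        j0 = het_positions[0]
        h1[j0] = loci[j0].ref_allele
        h2[j0] = loci[j0].alt_allele
        for k, j in enumerate(free):
            if (mask >> k) & 1:
                h1[j] = loci[j].alt_allele
                h2[j] = loci[j].ref_allele
            else:
                h1[j] = loci[j].ref_allele
                h2[j] = loci[j].alt_allele
        pairs.append(("".join(h1), "".join(h2)))
    return pairs


def _em_run(
    configs: list[list[tuple[int, int]]],
    weights: np.ndarray,
    n_haps: int,
    init: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    """One EM run over unique-genotype phase configurations.

    ``configs[g]`` lists (hap_index_1, hap_index_2) pairs for unique genotype
    *g*; ``weights[g]`` is its multiplicity.
    """
    f = init.copy()
    n_ind = float(weights.sum())
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros(n_haps)
        loglik = 0.0
        for g, pairs in enumerate(configs):
            probs = np.array(
                [f[a] * f[b] * (1.0 if a == b else 2.0) for a, b in pairs]
            )
            total = probs.sum()
            if total <= 0:
                # current estimate assigns zero mass to every compatible
                # phase; spread evenly to keep the iteration defined
                probs = np.full(len(pairs), 1.0 / len(pairs))
                total = 1.0
                loglik += -np.inf
            else:
                probs = probs / total
                loglik += weights[g] * np.log(total)
            for (a, b), w in zip(pairs, probs):
                new[a] += weights[g] * w
                new[b] += weights[g] * w
        new /= 2.0 * n_ind
        trace.append(float(loglik))
        delta = float(np.max(np.abs(new - f)))
        f = new
        if delta < tol:
            converged = True
            break
    return f, trace[-1], it, converged, trace


def em_haplotype_frequencies(
    gt: GenotypeTable,
    group: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 3,
    seed: int | None = 0,
) -> HaplotypeDistribution:
    """Estimate haplotype frequencies for one phenotype group by EM.

    Individuals with any missing call at the loci are excluded.  The default
    initialization is the linkage-equilibrium product of observed single-locus
    allele frequencies (deterministic); ``n_restarts`` additional runs from
    seeded Dirichlet starts guard against flat or multimodal likelihoods, and
    the run with the best final log-likelihood wins.
    """
    mask = gt.group_mask(group)
    calls = gt.calls[mask]
    complete = ~np.any(calls == Genotype.MISSING, axis=1)
    calls = calls[complete]
    n_ind = calls.shape[0]
    if n_ind == 0:
        raise ValueError(f"group {group!r} has no fully typed individuals")

    # collapse identical genotype rows: EM cost depends on unique genotypes
    uniq, counts = np.unique(calls, axis=0, return_counts=True)
    hap_index: dict[str, int] = {}
    configs: list[list[tuple[int, int]]] = []
    for row in uniq:
        pairs = enumerate_phase_configurations([int(c) for c in row], gt.loci)
        idx_pairs = []
        for h1, h2 in pairs:
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            idx_pairs.append((hap_index[h1], hap_index[h2]))
        configs.append(idx_pairs)
    haps = list(hap_index)
    n_haps = len(haps)

    # linkage-equilibrium start: product of single-locus allele frequencies
    allele_freq: list[dict[str, float]] = []
    for j, loc in enumerate(gt.loci):
        col = uniq[:, j]
        alt = float(
            np.sum(counts * (2 * (col == Genotype.HOM_ALT) + (col == Genotype.HET)))
        ) / (2 * n_ind)
        allele_freq.append({loc.ref_allele: 1.0 - alt, loc.alt_allele: alt})
    le_init = np.array(
        [
            np.prod([allele_freq[j][h[j]] for j in range(len(gt.loci))])
            for h in haps
        ]
    )
    s = le_init.sum()
    le_init = le_init / s if s > 0 else np.full(n_haps, 1.0 / n_haps)

    starts = [le_init]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        starts.extend(rng.dirichlet(np.ones(n_haps)) for _ in range(n_restarts))

    best = None
    for init in starts:
        f, ll, it, conv, trace = _em_run(
            configs, counts.astype(float), n_haps, init, tol, max_iter
        )
        if best is None or ll > best[1]:
            best = (f, ll, it, conv, trace)
    f, ll, it, conv, trace = best

    freqs = {h: float(f[i]) for h, i in hap_index.items()}
    # clean residual numerical drift off the simplex
    total = sum(freqs.values())
    freqs = {h: v / total for h, v in freqs.items()}
    counts_out = {h: 2.0 * n_ind * v for h, v in freqs.items()}
    return HaplotypeDistribution(
        loci=tuple(loc.id for loc in gt.loci),
        frequencies=freqs,
        expected_counts=counts_out,
        log_likelihood=float(ll),
        n_iterations=it,
        converged=conv,
        n_individuals=n_ind,
        loglik_trace=trace,
    )
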