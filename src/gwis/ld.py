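"""Pairwise linkage disequilibrium from unphased genotype data.

Two-locus haplotype frequencies are estimated by the classic EM algorithm over
the double-heterozygote phase ambiguity, assuming Hardy–Weinberg random union
of gametes.  From the frequencies the module derives D (deviation of the
coupling-haplotype frequency from independence), D′ (|D| normalized by its
maximum attainable value given the allele frequencies) and r² (squared allelic
correlation), plus the greedy "strong LD group" labelling used to annotate
candidate lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import GenotypePanel

#: Haplotype order used throughout: alleles are (locus A, locus B) with 1 the
#: alternate/minor allele, i.e. (AB, Ab, aB, ab) = (11, 10, 01, 00).
HAPLOTYPES = ((1, 1), (1, 0), (0, 1), (0, 0))


@dataclass
class LdResult:
    """Haplotype frequencies and disequilibrium statistics for one SNP pair."""

    snp_a: str
    snp_b: str
    p_ab_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab)
    D: float
    d_prime: float
    r2: float
    em_iterations: int
    converged: bool
    defined: bool
    n_used: int = 0
    n_dropped: int = 0


def hard_call(dosages: np.ndarray, max_dev: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Round fractional dosages to {0,1,2}; mask out entries farther than
    ``max_dev`` from an integer or missing."""
    d = np.asarray(dosages, dtype=float)
    g = np.rint(d)
    keep = (~np.isnan(d)) & (np.abs(d - g) <= max_dev)
    return g.astype(int), keep


def _genotype_probs(freqs: np.ndarray) -> np.ndarray:
    """3×3 joint genotype probabilities under random union of haplotypes."""
    probs = np.zeros((3, 3))
    for i, (a1, b1) in enumerate(HAPLOTYPES):
        for j, (a2, b2) in enumerate(HAPLOTYPES):
            probs[a1 + a2, b1 + b2] += freqs[i] * freqs[j]
    return probs


def _loglik(counts: np.ndarray, freqs: np.ndarray) -> float:
    probs = _genotype_probs(freqs)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        ll = counts[mask] * np.log(np.maximum(probs[mask], 1e-300))
    return float(ll.sum())


def em_haplotype_freqs(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int, bool]:
    """EM estimate of the four two-locus haplotype frequencies.

    ``geno_a``/``geno_b`` are hard genotypes in {0,1,2} for shared subjects.
    Initialization is at linkage equilibrium (product of allele frequencies),
    so the estimate is deterministic.  The multinomial log-likelihood is
    asserted non-decreasing at every iteration.  Returns
    (frequencies (AB, Ab, aB, ab), iterations, converged).
    """
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    if ga.shape != gb.shape or ga.ndim != 1 or ga.size == 0:
        raise ValueError("genotype vectors must be equal-length and non-empty")
    if not (np.isin(ga, (0, 1, 2)).all() and np.isin(gb, (0, 1, 2)).all()):
        raise ValueError("genotypes must be hard calls in {0, 1, 2}")
    counts = np.zeros((3, 3))
    np.add.at(counts, (ga, gb), 1.0)
    n2 = 2.0 * counts.sum()

    # Phase-known haplotype counts: every genotype pair except the double
    # heterozygote resolves uniquely into two gametes.
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if (i, j) == (1, 1):
                continue
            c = counts[i, j]
            if c == 0:
                continue
            # alleles per haplotype at each locus: i in {0,1,2} splits into
            # pairs (1,1)->? handled: i copies of allele 1 distributed as
            # (i>=1) + (i==2) over the two gametes, unambiguous unless i==j==1.
            a_alleles = [1] * i + [0] * (2 - i)
            b_alleles = [1] * j + [0] * (2 - j)
            for a, b in zip(a_alleles, b_alleles):
                base[HAPLOTYPES.index((a, b))] += c
    n_dd = counts[1, 1]

    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / n2 * 2
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / n2 * 2
    pA, pB = pA / 2, pB / 2  # allele-1 frequencies
    freqs = np.array(
        [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
    )
    freqs = np.maximum(freqs, 0.0)
    if freqs.sum() == 0:
        freqs = np.full(4, 0.25)
    freqs /= freqs.sum()

    prev_ll = -np.inf
    converged = False
    iters = 0
    for iters in range(1, max_iter + 1):
        coupling = freqs[0] * freqs[3]
        repulsion = freqs[1] * freqs[2]
        denom = coupling + repulsion
        w = coupling / denom if denom > 0 else 0.5
        new = base + n_dd * np.array([w, 1 - w, 1 - w, w])
        new /= n2
        ll = _loglik(counts, new)
        if ll < prev_ll - 1e-8:
            raise RuntimeError("EM log-likelihood decreased; this is a bug")
        delta = np.max(np.abs(new - freqs))
        freqs = new
        prev_ll = ll
        if delta < tol:
            converged = True
            break
    return freqs, iters, converged


def ld_stats(freqs: np.ndarray, snp_a: str = "A", snp_b: str = "B") -> LdResult:
    """D, D′ and r² from a two-locus haplotype frequency vector (AB, Ab, aB, ab)."""
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("invalid haplotype frequency vector")
    f = np.maximum(f, 0.0)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    pa, pb = 1.0 - pA, 1.0 - pB
    if min(pA, pa) <= 0 or min(pB, pb) <= 0:
        return LdResult(
            snp_a, snp_b, f, np.nan, np.nan, np.nan, 0, True, defined=False
        )
    D = f[0] - pA * pB
    if D > 0:
        d_max = min(pA * pb, pa * pB)
    else:
        d_max = min(pA * pB, pa * pb)
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D * D / (pA * pa * pB * pb)
    return LdResult(snp_a, snp_b, f, float(D), float(d_prime), float(r2), 0, True, True)


def pairwise_ld(
    panel: GenotypePanel, snp_a: str, snp_b: str, max_dev: float = 0.1
) -> LdResult:
    """EM haplotype frequencies and LD statistics for one panel SNP pair."""
    ia, ib = panel.snp_index(snp_a), panel.snp_index(snp_b)
    ga, ka = hard_call(panel.dosages[:, ia], max_dev)
    gb, kb = hard_call(panel.dosages[:, ib], max_dev)
    keep = ka & kb
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError(f"no usable subjects for pair ({snp_a}, {snp_b})")
    freqs, iters, converged = em_haplotype_freqs(ga[keep], gb[keep])
    res = ld_stats(freqs, snp_a, snp_b)
    res.em_iterations = iters
    res.converged = converged
    res.n_used = n_used
    res.n_dropped = int(len(keep) - n_used)
    return res


def strong_ld_groups(
    snp_ids: list[str],
    panel: GenotypePanel,
    r2_threshold: float = 0.85,
    dprime_threshold: float = 0.9,
) -> dict[str, str]:
    """Greedy strong-LD grouping of candidate SNPs.

    ``snp_ids`` must already be ordered by priority (ascending interaction
    p-value).  Each SNP joins the first existing reference whose pairwise LD
    satisfies r² > r2_threshold and D′ ≥ dprime_threshold, else founds a new
    reference group.  Returns {snp_id: group_label} with labels "A", "B", ...
    """
    if not snp_ids:
        raise ValueError("need at least one SNP")
    labels: dict[str, str] = {}
    references: list[str] = []
    for sid in snp_ids:
        assigned = None
        for ref in references:
            res = pairwise_ld(panel, sid, ref)
            if (
                res.defined
                and res.r2 > r2_threshold
                and res.d_prime >= dprime_threshold - 1e-9
            ):
                assigned = labels[ref]
                break
        if assigned is None:
            assigned = chr(ord("A") + len(references))
            references.append(sid)
        labels[sid] = assigned
    return labels
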