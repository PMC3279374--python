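"""Independent oracles used across the test suite.

These deliberately re-derive the expected behaviour through a different
route than the package (Biopython sequence arithmetic, brute-force grid
search, literal step-up formula) so agreement is informative.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq


def oracle_classify(window: str, seed7: str) -> str | None:
    """Brute-force site classifier built from Biopython reverse complements.

    site8 = revcomp(seed nt2-8) + A; the three anchor rules are written out
    literally against that string.
    """
    rc7 = str(Seq(seed7).reverse_complement())  # m8 + core
    core_a = str(Seq(seed7[:6]).reverse_complement()) + "A"  # core + A
    if window == rc7 + "A":
        return "8mer"
    if window[:7] == rc7 and window[7] != "A":
        return "7mer-m8"
    if window[1:] == core_a and window[0] != rc7[0]:
        return "7mer-A1"
    return None


def oracle_scan(seq: str, seed7: str) -> list[tuple[tuple[int, int], str]]:
    """Slide every 8-nt window and classify with the brute-force oracle."""
    hits = []
    for i in range(len(seq) - 7):
        t = oracle_classify(seq[i:i + 8], seed7)
        if t == "8mer":
            hits.append(((i + 1, i + 8), t))
        elif t == "7mer-m8":
            hits.append(((i + 1, i + 7), t))
        elif t == "7mer-A1":
            hits.append(((i + 2, i + 8), t))
    return hits


def oracle_bh(pvals: np.ndarray) -> np.ndarray:
    """Literal min-over-suffix step-up formula."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = min(running, 1.0)
    return adj


def grid_p11(counts, step: float = 1e-5) -> float:
    """Grid-search maximiser of the nine-class multinomial likelihood over
    P11 within the counting/Frechet bounds (vectorised log-likelihood)."""
    from snpmprm.ld import counting_bounds

    pA, pB = counts.allele_freqs()
    lo, hi = counting_bounds(counts)
    grid = np.arange(lo, hi + step / 2, step)
    grid = np.clip(grid, lo, hi)
    P11 = grid
    P12 = pA - P11
    P21 = pB - P11
    P22 = 1.0 - pA - pB + P11
    class_probs = {
        ("R", "R"): P11 ** 2,
        ("R", "H"): 2 * P11 * P12,
        ("R", "O"): P12 ** 2,
        ("H", "R"): 2 * P11 * P21,
        ("H", "H"): 2 * P11 * P22 + 2 * P12 * P21,
        ("H", "O"): 2 * P12 * P22,
        ("O", "R"): P21 ** 2,
        ("O", "H"): 2 * P21 * P22,
        ("O", "O"): P22 ** 2,
    }
    ll = np.zeros_like(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        for key, k in counts.counts.items():
            if k:
                ll += k * np.log(class_probs[key])
    ll[~np.isfinite(ll)] = -np.inf
    return float(grid[np.argmax(ll)])


def random_two_locus_table(rng: np.random.Generator, n: int = 100):
    """A random polymorphic two-locus genotype table sampled through phased
    haplotypes at a random feasible P11."""
    from snpmprm.ld import tabulate
    from snpmprm.synthetic import gen_haplotype_pair_genotypes

    while True:
        pA = rng.uniform(0.15, 0.85)
        pB = rng.uniform(0.15, 0.85)
        lo, hi = max(0.0, pA + pB - 1), min(pA, pB)
        P11 = rng.uniform(lo, hi)
        a, b, _ = gen_haplotype_pair_genotypes(pA, pB, P11, n,
                                               int(rng.integers(2 ** 31)))
        counts = tabulate(a, b)
        fA, fB = counts.allele_freqs()
        if 0 < fA < 1 and 0 < fB < 1:
            return counts
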