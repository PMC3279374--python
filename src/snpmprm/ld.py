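"""Two-locus linkage disequilibrium from unphased recoded genotypes.

With reference-allele frequencies p_A and p_B and P11 the probability of the
haplotype carrying both reference alleles, the disequilibrium coefficient is
D = P11 - p_A p_B and

    r^2 = D^2 / (p_A (1 - p_A) p_B (1 - p_B)).

Only the double heterozygotes (HH) leave the haplotype phase ambiguous, so
P11 is estimated by maximum likelihood over the nine unphased genotype
classes under random union of gametes, iterating the gene-counting update
(whose fixed points are the roots of the classical cubic likelihood
equation) and projecting every interim estimate into a counting-based
interval that brackets the ML solution.  This projection keeps the estimate
inside the feasible haplotype simplex, which guarantees r^2 in [0, 1].

``n_hap * r^2`` with n_hap = 2N is asymptotically chi-square with 1 df under
the null of no disequilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

PHASE_COUPLING = "coupling"
PHASE_REPULSION = "repulsion"
PHASE_EQUILIBRIUM = "equilibrium"


class NoDataError(ValueError):
    """No jointly observed genotype pairs."""


class UndefinedLdError(ValueError):
    """A monomorphic locus; LD is undefined."""


@dataclass(frozen=True)
class TwoLocusCounts:
    """Nine unphased genotype-class counts for a locus pair.

    ``counts[(a, b)]`` with a, b in {R, H, O}.  N11/N12/N21/N22 alias the
    RR/RH/HR/HH classes, the only ones entering the gene-counting update
    beyond the allele frequencies.
    """

    counts: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for key, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count for class {key}")

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    @property
    def N11(self) -> int:
        return self.counts.get(("R", "R"), 0)

    @property
    def N12(self) -> int:
        return self.counts.get(("R", "H"), 0)

    @property
    def N21(self) -> int:
        return self.counts.get(("H", "R"), 0)

    @property
    def N22(self) -> int:
        return self.counts.get(("H", "H"), 0)

    def allele_freqs(self) -> tuple[float, float]:
        """Reference-allele frequencies (pA, pB) counted from the margins."""
        n = self.N
        if n == 0:
            raise NoDataError("empty contingency table")
        n_ref_a = sum(v * {"R": 2, "H": 1, "O": 0}[a] for (a, _), v in self.counts.items())
        n_ref_b = sum(v * {"R": 2, "H": 1, "O": 0}[b] for (_, b), v in self.counts.items())
        return n_ref_a / (2 * n), n_ref_b / (2 * n)


@dataclass
class LdEstimate:
    pA: float
    pB: float
    P11: float
    r2: float
    chi2: float
    p: float
    phase: str
    n: int
    iterations: int
    converged: bool


def tabulate(codes_a: Sequence[str], codes_b: Sequence[str]) -> TwoLocusCounts:
    """Nine-class contingency counts on jointly observed samples (N dropped)."""
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    keep = (a != "N") & (b != "N")
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise NoDataError("no jointly observed genotype pairs")
    counts = {(x, y): 0 for x in "RHO" for y in "RHO"}
    for x, y in zip(a, b):
        counts[(x, y)] += 1
    return TwoLocusCounts(counts)


def counting_bounds(counts: TwoLocusCounts) -> tuple[float, float]:
    """Closed interval certain to contain the ML estimate of P11.

    Lower bound: haplotypes that are unambiguously reference-reference
    (2 per RR individual, 1 per RH or HR).  Upper bound: additionally one
    possible reference-reference haplotype per HH double heterozygote.
    Intersected with the Frechet bounds implied by the allele frequencies.
    """
    n = counts.N
    if n < 1:
        raise NoDataError("empty contingency table")
    lower = (2 * counts.N11 + counts.N12 + counts.N21) / (2 * n)
    upper = (2 * counts.N11 + counts.N12 + counts.N21 + counts.N22) / (2 * n)
    pA, pB = counts.allele_freqs()
    lo = max(lower, max(0.0, pA + pB - 1.0))
    hi = min(upper, min(pA, pB))
    if lo > hi + 1e-12:
        raise RuntimeError("inconsistent counting/Frechet bounds (corrupt counts?)")
    return lo, max(lo, hi)


def _haplotype_probs(P11: float, pA: float, pB: float) -> tuple[float, float, float, float]:
    return P11, pA - P11, pB - P11, 1.0 - pA - pB + P11


def loglik_p11(P11: float, counts: TwoLocusCounts) -> float:
    """Multinomial log-likelihood of the nine genotype classes at P11
    (allele frequencies fixed at their sample values)."""
    pA, pB = counts.allele_freqs()
    P11_, P12, P21, P22 = _haplotype_probs(P11, pA, pB)
    probs = {
        ("R", "R"): P11_ ** 2,
        ("R", "H"): 2 * P11_ * P12,
        ("R", "O"): P12 ** 2,
        ("H", "R"): 2 * P11_ * P21,
        ("H", "H"): 2 * P11_ * P22 + 2 * P12 * P21,
        ("H", "O"): 2 * P12 * P22,
        ("O", "R"): P21 ** 2,
        ("O", "H"): 2 * P21 * P22,
        ("O", "O"): P22 ** 2,
    }
    ll = 0.0
    for key, k in counts.counts.items():
        if k:
            pr = probs[key]
            if pr <= 0:
                return -np.inf
            ll += k * np.log(pr)
    return ll


def estimate_p11(counts: TwoLocusCounts, tol: float = 1e-10,
                 max_iter: int = 1000) -> LdEstimate:
    """Constrained iterative ML estimate of P11 with r2, test and phase.

    Gene-counting update: the expected fraction of reference-reference
    haplotypes among the ambiguous HH class is P11*P22 / (P11*P22 + P12*P21);
    each iterate is projected into :func:`counting_bounds`.  Initialised at
    the linkage-equilibrium value pA*pB (clamped into the bounds).
    """
    n = counts.N
    pA, pB = counts.allele_freqs()
    if not (0 < pA < 1) or not (0 < pB < 1):
        raise UndefinedLdError(f"monomorphic locus (pA={pA}, pB={pB}); LD undefined")
    lo, hi = counting_bounds(counts)
    definite = 2 * counts.N11 + counts.N12 + counts.N21
    p11 = min(max(pA * pB, lo), hi)
    converged = False
    iterations = 0
    if counts.N22 == 0:
        p11 = definite / (2 * n)
        converged, iterations = True, 1
    else:
        for iterations in range(1, max_iter + 1):
            _, P12, P21, P22 = _haplotype_probs(p11, pA, pB)
            denom = p11 * P22 + P12 * P21
            w = 0.5 if denom <= 0 else p11 * P22 / denom
            new = (definite + counts.N22 * w) / (2 * n)
            new = min(max(new, lo), hi)
            if abs(new - p11) < tol:
                p11 = new
                converged = True
                break
            p11 = new
        if not converged:
            logger.warning("P11 iteration did not converge in %d steps", max_iter)
    r2 = r_squared(pA, pB, p11)
    chi2, p = ld_test(r2, 2 * n)
    return LdEstimate(pA=pA, pB=pB, P11=p11, r2=r2, chi2=chi2, p=p,
                      phase=phase(p11, pA, pB), n=n,
                      iterations=iterations, converged=converged)


def r_squared(pA: float, pB: float, P11: float) -> float:
    """Squared correlation between the two loci: D^2 normalised by the
    allele-frequency variances, D = P11 - pA*pB."""
    if not (0 < pA < 1) or not (0 < pB < 1):
        raise UndefinedLdError("allele frequency at the boundary; r2 undefined")
    D = P11 - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


def ld_test(r2: float, n_haplotypes: int) -> tuple[float, float]:
    """Chi-square test of r2 = 0: statistic = n_haplotypes * r2, df = 1."""
    chi2 = n_haplotypes * r2
    return chi2, float(stats.chi2.sf(chi2, df=1))


def phase(P11: float, pA: float, pB: float, atol: float = 0.0) -> str:
    """Coupling (D > 0: reference alleles co-occur), repulsion (D < 0), or
    equilibrium (D = 0)."""
    D = P11 - pA * pB
    if D > atol:
        return PHASE_COUPLING
    if D < -atol:
        return PHASE_REPULSION
    return PHASE_EQUILIBRIUM


_PSEUDO_CODE = {"R": 1.0, "H": 0.0, "O": -1.0}


def pseudo_ld(codes_a: Sequence[str], codes_b: Sequence[str],
              null: str = "fisher", K: int = 10000, seed: int | None = None,
              panel: np.ndarray | None = None) -> tuple[float, float]:
    """Genotype-correlation approximation to r2, with a significance test.

    R/H/O are numbered 1/0/-1 and the statistic is the squared Pearson
    correlation of the two numeric vectors — no haplotype frequencies are
    estimated.  ``null="fisher"`` tests via the Fisher z-transform;
    ``null="empirical"`` builds a null from K random locus pairs of a
    recoded genotype ``panel`` (rows = SNPs), p floored at 1/(K+1).
    """
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    keep = (a != "N") & (b != "N")
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise NoDataError("need at least 3 jointly observed pairs")
    xa = np.array([_PSEUDO_CODE[c] for c in a])
    xb = np.array([_PSEUDO_CODE[c] for c in b])
    if np.all(xa == xa[0]) or np.all(xb == xb[0]):
        raise UndefinedLdError("constant coded genotype vector; correlation undefined")
    r = float(np.corrcoef(xa, xb)[0, 1])
    stat = r * r
    if null == "fisher":
        if abs(r) >= 1.0:
            return stat, 0.0
        z = np.arctanh(r) * np.sqrt(a.size - 3)
        return stat, float(2.0 * stats.norm.sf(abs(z)))
    if null == "empirical":
        if panel is None:
            raise ValueError("empirical null requires a genotype panel")
        rng = np.random.default_rng(seed)
        n_snps = panel.shape[0]
        null_stats = np.empty(K)
        filled = 0
        while filled < K:
            i, j = rng.integers(0, n_snps, size=2)
            if i == j:
                continue
            try:
                s, _ = pseudo_ld(panel[i], panel[j], null="fisher")
            except (UndefinedLdError, NoDataError):
                continue
            null_stats[filled] = s
            filled += 1
        p = (1 + int(np.sum(null_stats >= stat))) / (K + 1)
        return stat, p
    raise ValueError(f"unknown null {null!r}")
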