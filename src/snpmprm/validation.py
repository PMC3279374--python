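"""Simulation experiments that characterise the pipeline's operating
behaviour under the generator's study conditions: type-I error and bias of
the TSE fit, accuracy of the constrained LD estimator, and planted-module
recovery of the end-to-end run.  Used by the test suite and by the
reproduction script."""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ld import TwoLocusCounts, counting_bounds, estimate_p11, tabulate
from .pipeline import RunConfig, run_exon_level, run_gene_level
from .synthetic import (LdPair, SnpSpec, gen_genotypes_hwe,
                        gen_haplotype_pair_genotypes, gen_study,
                        recovery_study_config)
from .tse import fit_tse

# study conditions: cohort of ~90 mixed-sex samples, informative-SNP MAF,
# log2-scale noise as in the generator defaults
DEFAULT_N = 90
DEFAULT_MAF = 0.3
DEFAULT_SD = 0.3


def simulate_tse_fits(beta: float, n_fits: int, seed: int, n: int = DEFAULT_N,
                      sd: float = DEFAULT_SD, maf: float = DEFAULT_MAF
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Repeated fits of the additive model on generator data with a fixed
    true beta; returns (beta_hat, p, ci_covers_truth) arrays."""
    rng = np.random.default_rng(seed)
    sex = 1 + np.arange(n) % 2
    s_vec = 0.2 * (sex == 2)
    betas, pvals, covers = [], [], []
    while len(betas) < n_fits:
        ca = rng.binomial(2, maf, size=n).astype(float)
        if np.unique(ca).size < 2:
            continue
        y = 7.0 + s_vec + beta * ca + rng.normal(0.0, sd, size=n)
        fit = fit_tse(y, sex, ca)
        betas.append(fit.beta)
        pvals.append(fit.p)
        covers.append(fit.ci_low <= beta <= fit.ci_high)
    return np.asarray(betas), np.asarray(pvals), np.asarray(covers)


def tse_type1_error(n_fits: int, seed: int, alpha: float = 0.05) -> float:
    """Rejection rate of the TSE t-test at ``alpha`` when beta = 0."""
    _, pvals, _ = simulate_tse_fits(0.0, n_fits, seed)
    return float(np.mean(pvals < alpha))


def tse_recovery(beta: float, n_reps: int, seed: int,
                 sd: float = DEFAULT_SD) -> tuple[float, float]:
    """(mean bias of beta_hat, empirical 95% CI coverage) at a true beta."""
    betas, _, covers = simulate_tse_fits(beta, n_reps, seed, sd=sd)
    return float(np.mean(betas) - beta), float(np.mean(covers))


def _grid_search_p11(counts: TwoLocusCounts, step: float = 1e-5) -> float:
    """Direct maximisation of the nine-class log-likelihood over a P11 grid
    inside the counting/Frechet bounds (reference optimiser)."""
    pA, pB = counts.allele_freqs()
    lo, hi = counting_bounds(counts)
    grid = np.arange(lo, hi + step / 2, step)
    P11 = np.clip(grid, lo, hi)
    P12, P21 = pA - P11, pB - P11
    P22 = 1.0 - pA - pB + P11
    probs = {
        ("R", "R"): P11 ** 2, ("R", "H"): 2 * P11 * P12, ("R", "O"): P12 ** 2,
        ("H", "R"): 2 * P11 * P21, ("H", "H"): 2 * P11 * P22 + 2 * P12 * P21,
        ("H", "O"): 2 * P12 * P22, ("O", "R"): P21 ** 2,
        ("O", "H"): 2 * P21 * P22, ("O", "O"): P22 ** 2,
    }
    ll = np.zeros_like(P11)
    with np.errstate(divide="ignore", invalid="ignore"):
        for key, k in counts.counts.items():
            if k:
                ll += k * np.log(probs[key])
    ll[~np.isfinite(ll)] = -np.inf
    return float(P11[np.argmax(ll)])


def random_table(rng: np.random.Generator, n: int = 100) -> TwoLocusCounts:
    """A random polymorphic unphased two-locus table via haplotype sampling."""
    while True:
        pA = rng.uniform(0.15, 0.85)
        pB = rng.uniform(0.15, 0.85)
        P11 = rng.uniform(max(0.0, pA + pB - 1), min(pA, pB))
        a, b, _ = gen_haplotype_pair_genotypes(pA, pB, P11, n,
                                               int(rng.integers(2 ** 31)))
        counts = tabulate(a, b)
        fA, fB = counts.allele_freqs()
        if 0 < fA < 1 and 0 < fB < 1:
            return counts


def ld_oracle_max_error(n_tables: int, seed: int, n: int = 100,
                        step: float = 1e-5) -> float:
    """Largest |iterative P11 - grid-search P11| over random tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        counts = random_table(rng, n)
        est = estimate_p11(counts)
        worst = max(worst, abs(est.P11 - _grid_search_p11(counts, step)))
    return worst


def ld_r2_always_in_unit_interval(n_tables: int, seed: int) -> bool:
    """r^2 from the constrained estimate stays in [0, 1] on adversarial
    multinomial tables (small N, extreme class weights)."""
    rng = np.random.default_rng(seed)
    checked = 0
    while checked < n_tables:
        probs = rng.dirichlet(np.full(9, 0.3))
        flat = rng.multinomial(int(rng.integers(10, 60)), probs)
        counts = TwoLocusCounts({(a, b): int(flat[i * 3 + j])
                                 for i, a in enumerate("RHO")
                                 for j, b in enumerate("RHO")})
        pA, pB = counts.allele_freqs()
        if not (0 < pA < 1 and 0 < pB < 1):
            continue
        est = estimate_p11(counts)
        if not 0.0 <= est.r2 <= 1.0 + 1e-12:
            return False
        checked += 1
    return True


def ld_consistency_max_error(seed: int, n: int = 10000,
                             true_r2_grid=(0.0, 0.25, 0.5, 0.75, 1.0)) -> float:
    """Max |estimated r^2 - phased-haplotype r^2| over a true-r2 grid, with
    genotypes collapsed from n phased individuals at pA = pB = 0.5."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for true_r2 in true_r2_grid:
        D = np.sqrt(true_r2 * 0.0625)
        a, b, hap = gen_haplotype_pair_genotypes(0.5, 0.5, 0.25 + D, n,
                                                 int(rng.integers(2 ** 31)))
        f = hap / hap.sum()
        pa, pb = f[0] + f[1], f[0] + f[2]
        if not (0 < pa < 1 and 0 < pb < 1):
            continue
        hap_r2 = (f[0] - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
        est = estimate_p11(tabulate(a, b))
        worst = max(worst, abs(est.r2 - hap_r2))
    return worst


@dataclass
class RecoveryResult:
    recovery_rate: float  # recovered planted modules / planted modules
    false_discovery_proportion: float  # false calls / all calls
    n_planted: int
    n_called: int


def gene_level_recovery(n_seeds: int, seed: int, n_samples: int = 90,
                        n_modules: int = 5, n_null_sites: int = 500,
                        beta: float = -0.6, noise_sd: float = 0.2,
                        work_dir: str | Path | None = None) -> RecoveryResult:
    """End-to-end planted-module recovery over seeded synthetic studies."""
    base = np.random.SeedSequence(seed).generate_state(n_seeds)
    recovered = total_planted = false_calls = total_calls = 0
    for run_seed in base.tolist():
        run_seed = int(run_seed % (2 ** 31))
        config = recovery_study_config(run_seed, n_samples=n_samples,
                                       n_modules=n_modules,
                                       n_null_sites=n_null_sites, beta=beta,
                                       noise_sd=noise_sd)
        with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
            bundle = gen_study(config, tmp)
            rc = RunConfig(
                utr_fasta=bundle.utr_fasta, snp_table=bundle.snp_table,
                genotype_table=bundle.genotype_table,
                gene_expression=bundle.gene_expression,
                sex_labels=bundle.sex_labels,
                mirna_families=bundle.mirna_families,
                mirna_detection=bundle.mirna_detection, seed=run_seed)
            result = run_gene_level(rc)
        planted = {m.snp_id for m in config.planted_modules if m.beta != 0.0}
        called = set(result.modules["SNP"])
        recovered += len(planted & called)
        total_planted += len(planted)
        false_calls += len(called - planted)
        total_calls += len(called)
    return RecoveryResult(
        recovery_rate=recovered / total_planted if total_planted else float("nan"),
        false_discovery_proportion=false_calls / total_calls if total_calls else 0.0,
        n_planted=total_planted, n_called=total_calls)


def exon_level_link_demo(seed: int, work_dir: str | Path | None = None) -> dict:
    """One planted marker -> site -> module chain, with one coupling and one
    repulsion LD pair; returns the link phases and module count."""
    config = recovery_study_config(seed, n_samples=90, n_modules=2,
                                   n_null_sites=20)
    config.snp_specs.append(SnpSpec("rsMC", 0.5, 30, "A", "G"))
    config.ld_pairs.append(LdPair("rsMC", "rs00001", 0.45))  # D = +0.10
    config.snp_specs.append(SnpSpec("rsMR", 0.5, 30, "A", "G"))
    config.ld_pairs.append(LdPair("rsMR", "rs00002", 0.25))  # D = -0.10
    config.__post_init__()
    with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
        bundle = gen_study(config, tmp)
        rc = RunConfig(
            utr_fasta=bundle.utr_fasta, snp_table=bundle.snp_table,
            genotype_table=bundle.genotype_table,
            gene_expression=bundle.gene_expression,
            sex_labels=bundle.sex_labels,
            mirna_families=bundle.mirna_families,
            mirna_detection=bundle.mirna_detection,
            exon_expression=bundle.exon_expression,
            cis_markers=bundle.cis_markers, seed=seed)
        result = run_exon_level(rc)
    links = {r.marker_snp: r for r in result.links.itertuples(index=False)}
    return {
        "coupling_link_site": links.get("rsMC").site_snp if "rsMC" in links else None,
        "coupling_phase": links.get("rsMC").phase if "rsMC" in links else None,
        "repulsion_link_site": links.get("rsMR").site_snp if "rsMR" in links else None,
        "repulsion_phase": links.get("rsMR").phase if "rsMR" in links else None,
        "n_exon_modules": int(len(result.modules)),
        "module_site_snps": sorted(result.modules["SNP2"].tolist()),
    }
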