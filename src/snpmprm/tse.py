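"""Target-site effect (TSE) estimation.

The model for one candidate site is

    y_ij = mu + s_i + beta * x_j + e_ij

where y_ij is the log2 transcript intensity (or log2 exon/gene ratio) of
sample j, s_i (i = 1, 2) a fixed sex effect, x_j the sample's
consistent-allele count (0/1/2 chromosomes carrying the intact site) and
e_ij Gaussian noise.  beta is the TSE: for a genuinely repressive site it is
negative, because each additional intact site lowers the transcript level.
A site becomes a candidate regulation module when its miRNA family is
expressed, its target is expressed, beta < 0 and the BH-adjusted p-value is
below the module alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class NoVariationError(ValueError):
    """The consistent-allele covariate is constant; the TSE is not estimable."""


class FitError(ValueError):
    """Rank-deficient or otherwise degenerate design."""


@dataclass
class TseFit:
    """One fitted site: effect size, inference, and group summaries."""

    beta: float
    se: float
    p: float
    n_used: int
    df_resid: int
    mu_hat: float
    sex_effect: Optional[float]  # s_2 - s_1 contrast; None if single-sex
    group_medians: dict[int, Optional[float]]  # CA level -> median y (None if empty)
    ci_low: float
    ci_high: float
    adj_p: float = float("nan")
    site: object = None  # optional SnpSite provenance

    @property
    def additive_ok(self) -> bool:
        medians = [m for _, m in sorted(self.group_medians.items()) if m is not None]
        return all(a >= b for a, b in zip(medians, medians[1:]))


def fit_tse(y: Sequence[float], sex: Sequence[int], ca: Sequence[float],
            ci_level: float = 0.95) -> TseFit:
    """Ordinary least squares of expression on consistent-allele count.

    Design: intercept + sex factor (treatment-coded; dropped automatically
    when only one sex is present) + CA as a numeric covariate.  ``beta`` is
    the CA coefficient with a two-sided t-test.  Samples with missing CA
    (NaN) are excluded (complete-case).
    """
    y = np.asarray(y, dtype=float)
    sex = np.asarray(sex)
    ca = np.asarray(ca, dtype=float)
    keep = np.isfinite(ca) & np.isfinite(y)
    y, sex, ca = y[keep], sex[keep], ca[keep]
    n = y.size
    levels = np.unique(ca)
    if levels.size < 2:
        raise NoVariationError("consistent-allele count is constant; site skipped")

    cols = [np.ones(n)]
    sexes = np.unique(sex)
    if sexes.size == 2:
        cols.append((sex == sexes[1]).astype(float))
    elif sexes.size > 2:
        raise FitError(f"sex must be two-level, got {sexes.tolist()}")
    else:
        logger.info("single-sex subset; sex factor dropped from the design")
    cols.append(ca)
    X = np.column_stack(cols)
    p_params = X.shape[1]
    if n <= p_params:
        raise FitError(f"too few samples ({n}) for {p_params} parameters")
    if np.linalg.matrix_rank(X) < p_params:
        raise FitError("rank-deficient design matrix")

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    dof = n - p_params
    sigma2 = float(resid @ resid) / dof
    se_all = np.sqrt(np.maximum(sigma2, 0.0) * np.diag(xtx_inv))

    beta = float(coef[-1])
    se = float(se_all[-1])
    if se == 0.0:
        pval = 0.0 if beta != 0.0 else 1.0
        tcrit = 0.0
    else:
        tstat = beta / se
        pval = float(2.0 * stats.t.sf(abs(tstat), dof))
        tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, dof))

    medians: dict[int, Optional[float]] = {}
    for level in (0, 1, 2):
        mask = ca == level
        medians[level] = float(np.median(y[mask])) if mask.any() else None

    return TseFit(
        beta=beta, se=se, p=pval, n_used=n, df_resid=dof,
        mu_hat=float(coef[0]),
        sex_effect=float(coef[1]) if sexes.size == 2 else None,
        group_medians=medians,
        ci_low=beta - tcrit * se, ci_high=beta + tcrit * se,
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{k >= i} m * p_(k) / k on the ascending order statistics,
    capped at 1.  NaN entries are excluded from the family (with a warning)
    and propagate as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} NaN p-values excluded from BH family")
    pv = p[ok]
    if pv.size == 0:
        return out
    if pv.min() < 0 or pv.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    out[ok] = multipletests(pv, method="fdr_bh")[1]
    return out


def additive_pattern(y: Sequence[float], ca: Sequence[float],
                     tol: float = 0.0) -> tuple[bool, dict[int, Optional[float]]]:
    """Whether group medians of y are non-increasing over occupied CA levels.

    Mirrors the box-plot check of a repressive dose response: more intact
    sites should not raise the transcript level.  ``tol`` allows small
    increases before the pattern is declared broken.
    """
    y = np.asarray(y, dtype=float)
    ca = np.asarray(ca, dtype=float)
    keep = np.isfinite(ca) & np.isfinite(y)
    y, ca = y[keep], ca[keep]
    medians: dict[int, Optional[float]] = {}
    for level in (0, 1, 2):
        mask = ca == level
        medians[level] = float(np.median(y[mask])) if mask.any() else None
    occupied = [m for _, m in sorted(medians.items()) if m is not None]
    if len(occupied) < 2:
        raise ValueError("need at least two occupied CA groups")
    ok = all(nxt <= prev + tol for prev, nxt in zip(occupied, occupied[1:]))
    return ok, medians


@dataclass
class ModuleRecord:
    """One called SNP-miRNA-target regulation module (a Table-style row)."""

    gene_or_exon_id: str
    snp_id: str
    mutation_class: str
    family_ids: tuple[str, ...]
    member_ids: tuple[str, ...]
    beta: float
    adj_p: float
    population_label: str
    additive_ok: bool


def call_modules(fits: Iterable[TseFit], expressed_mirna_ids: set[str],
                 expressed_gene_ids: set[str],
                 family_members: Mapping[str, Sequence[str]],
                 alpha: float = 0.05, population_label: str = "",
                 require_additive: bool = False) -> list[ModuleRecord]:
    """Select candidate modules from BH-corrected fits.

    A fit qualifies when the implicated family has at least one expressed
    member miRNA, the target feature is expressed, beta < 0 and adj_p <
    ``alpha``.  The additive-pattern flag is recorded on every record and
    only enforced when ``require_additive`` is set.
    """
    records: list[ModuleRecord] = []
    for fit in fits:
        site = fit.site
        if site is None:
            continue
        members = tuple(family_members.get(site.family_id, ()))
        if not any(m in expressed_mirna_ids for m in members):
            continue
        if site.transcript_id not in expressed_gene_ids:
            continue
        if not (fit.beta < 0 and np.isfinite(fit.adj_p) and fit.adj_p < alpha):
            continue
        additive = fit.additive_ok
        if require_additive and not additive:
            continue
        records.append(ModuleRecord(
            gene_or_exon_id=site.transcript_id, snp_id=site.snp_id,
            mutation_class=site.mutation_class,
            family_ids=(site.family_id,), member_ids=members,
            beta=fit.beta, adj_p=fit.adj_p,
            population_label=population_label, additive_ok=additive))
    records.sort(key=lambda r: r.adj_p)
    return records
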