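"""End-to-end discovery of SNP-involved miRNA regulation modules.

Gene level: informative-SNP filtering -> allele-aware site calling ->
expressed-miRNA/gene filtering -> per-site TSE fits -> BH correction ->
module selection.  Exon level: documented cis-markers are first linked to
target-site SNPs of the same gene (identity, or significant LD of the
unphased genotypes), then the TSE is fitted on the log2 exon/gene ratio of
the linked probe set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ld as ldmod
from .expression import DetectionMatrix, ExpressionMatrix, expressed_genes, expressed_mirnas
from .genotype import GenotypeTable
from .seed_sites import (MirnaFamily, SnpRecord, SnpSite, call_snp_sites,
                         filter_in_snps, read_family_table, read_snp_table,
                         read_utrs, sites_to_frame)
from .tse import (FitError, NoVariationError, TseFit, bh_adjust, call_modules,
                  fit_tse)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    utr_fasta: Path
    snp_table: Path
    genotype_table: Path
    gene_expression: Path
    sex_labels: Path
    mirna_families: Path
    mirna_detection: Path
    exon_expression: Optional[Path] = None
    cis_markers: Optional[Path] = None
    population_label: str = ""
    maf_threshold: float = 0.1  # strict: kept only if MAF > threshold
    min_gap: int = 10
    module_alpha: float = 0.05
    ld_alpha: float = 0.01
    flank: int = 10
    min_group: int = 3  # smallest occupied CA group for a fit to be attempted
    chi2_n_stat: str = "2N"  # or "N"
    expressed_gene_quantile: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "module_alpha", "ld_alpha"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.chi2_n_stat not in ("N", "2N"):
            raise ValueError("chi2_n_stat must be 'N' or '2N'")


@dataclass
class CisMarkerLink:
    marker_snp: str
    site_snp: str
    probe_set: str
    gene: str
    r2: float
    ld_p: float
    phase: str
    identical: bool


@dataclass
class RunResult:
    modules: pd.DataFrame
    fits: pd.DataFrame
    sites: pd.DataFrame
    report: dict
    links: Optional[pd.DataFrame] = None


def _load_common(config: RunConfig):
    utrs = read_utrs(config.utr_fasta)
    snps = read_snp_table(config.snp_table)
    families = read_family_table(config.mirna_families)
    genotypes = GenotypeTable.from_wide_tsv(config.genotype_table)
    detection = DetectionMatrix.from_tsv(config.mirna_detection)
    return utrs, snps, families, genotypes, detection


def _call_all_sites(utrs: dict[str, str], snps: Sequence[SnpRecord],
                    families: Sequence[MirnaFamily], config: RunConfig,
                    failures: list[dict]) -> list[SnpSite]:
    sites: list[SnpSite] = []
    for snp in snps:
        utr = utrs.get(snp.transcript_id)
        if utr is None:
            failures.append({"stage": "sites", "snp": snp.snp_id,
                             "error": "transcript missing from UTR FASTA"})
            continue
        try:
            sites.extend(call_snp_sites(utr, snp, families, flank=config.flank))
        except Exception as exc:  # keep going, census the failure
            failures.append({"stage": "sites", "snp": snp.snp_id, "error": str(exc)})
    return sites


def _fit_sites(sites: Sequence[SnpSite], genotypes: GenotypeTable,
               expr: ExpressionMatrix, feature_of, config: RunConfig,
               failures: list[dict]) -> list[TseFit]:
    """TSE fit for every site whose CA covariate is usable.

    ``feature_of(site)`` names the expression row (gene, or exon probe set).
    A fit is attempted only when >= 2 CA levels are occupied and every
    occupied level has at least ``config.min_group`` samples.
    """
    sex = expr.sex.to_numpy()
    fits: list[TseFit] = []
    for site in sites:
        feature = feature_of(site)
        if feature not in expr.values.index:
            failures.append({"stage": "fit", "snp": site.snp_id,
                             "error": f"feature {feature} missing from expression"})
            continue
        if site.snp_id not in genotypes:
            failures.append({"stage": "fit", "snp": site.snp_id,
                             "error": "SNP missing from genotype table"})
            continue
        ca = genotypes.ca_counts(site.snp_id, site.mutation_class)
        levels, counts = np.unique(ca[np.isfinite(ca)], return_counts=True)
        if levels.size < 2 or counts.min() < config.min_group:
            failures.append({"stage": "fit", "snp": site.snp_id,
                             "error": f"occupied CA groups {dict(zip(levels.astype(int).tolist(), counts.tolist()))} below min_group={config.min_group}"})
            continue
        y = expr.values.loc[feature].to_numpy(dtype=float)
        try:
            fit = fit_tse(y, sex, ca)
        except (NoVariationError, FitError) as exc:
            failures.append({"stage": "fit", "snp": site.snp_id, "error": str(exc)})
            continue
        fit.site = site
        fits.append(fit)
    return fits


def _fits_frame(fits: Sequence[TseFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        s = f.site
        rows.append({"snp_id": s.snp_id, "feature_id": s.transcript_id,
                     "family_id": s.family_id, "site_type": s.site_type,
                     "mutation_class": s.mutation_class, "beta": f.beta,
                     "se": f.se, "p": f.p, "adj_p": f.adj_p, "n_used": f.n_used,
                     "additive_ok": f.additive_ok,
                     "median_ca0": f.group_medians[0], "median_ca1": f.group_medians[1],
                     "median_ca2": f.group_medians[2]})
    return pd.DataFrame(rows, columns=["snp_id", "feature_id", "family_id", "site_type",
                                       "mutation_class", "beta", "se", "p", "adj_p",
                                       "n_used", "additive_ok", "median_ca0",
                                       "median_ca1", "median_ca2"])


def _strip_mir_prefix(member_ids: Sequence[str]) -> str:
    out = []
    for m in member_ids:
        for prefix in ("hsa-mir-", "hsa-let-", "hsa-miR-"):
            if m.startswith(prefix):
                m = m[len(prefix):]
                break
        out.append(m)
    return ", ".join(out)


def run_gene_level(config: RunConfig) -> RunResult:
    """Gene-level module discovery; returns tables and a run report."""
    failures: list[dict] = []
    utrs, snps, families, genotypes, detection = _load_common(config)
    expr = ExpressionMatrix.from_tsv(config.gene_expression, config.sex_labels)
    in_snps = filter_in_snps(snps, config.maf_threshold, config.min_gap)
    sites = _call_all_sites(utrs, in_snps, families, config, failures)
    mirna_ok = expressed_mirnas(detection, config.module_alpha)
    gene_ok = expressed_genes(expr, quantile=config.expressed_gene_quantile)
    fits = _fit_sites(sites, genotypes, expr,
                      lambda s: s.transcript_id, config, failures)
    adj = bh_adjust([f.p for f in fits])
    for f, a in zip(fits, adj):
        f.adj_p = float(a)
    members = {f.family_id: f.member_ids for f in families}
    records = call_modules(fits, mirna_ok, gene_ok, members,
                           alpha=config.module_alpha,
                           population_label=config.population_label)
    modules = pd.DataFrame(
        [{"Gene": r.gene_or_exon_id, "Mutation": r.mutation_class,
          "SNP": r.snp_id, "TSE": r.beta, "adj.p": r.adj_p,
          "miRNA": _strip_mir_prefix(r.member_ids),
          "additive_ok": r.additive_ok, "population": r.population_label}
         for r in records],
        columns=["Gene", "Mutation", "SNP", "TSE", "adj.p", "miRNA",
                 "additive_ok", "population"])
    report = make_report(snps=len(snps), in_snps=len(in_snps), sites=sites,
                         fits=fits, modules=len(modules), failures=failures,
                         config=config)
    return RunResult(modules=modules, fits=_fits_frame(fits),
                     sites=sites_to_frame(sites), report=report)


def link_cis_markers(markers: pd.DataFrame, site_snps: Sequence[SnpSite],
                     genotypes: GenotypeTable, ld_alpha: float = 0.01,
                     chi2_n_stat: str = "2N") -> list[CisMarkerLink]:
    """Link documented cis-markers to target-site SNPs of the same gene.

    A marker that is itself a site SNP links with r2 = 1 (identity);
    otherwise every site SNP of the gene is tested and pairs with LD
    p < ``ld_alpha`` (raw, not FDR-adjusted) are kept.
    """
    by_gene: dict[str, list[SnpSite]] = {}
    for s in site_snps:
        by_gene.setdefault(s.transcript_id, []).append(s)
    links: list[CisMarkerLink] = []
    for row in markers.itertuples(index=False):
        marker, gene, probe_set = row.marker_snp, row.gene, row.probe_set
        if marker not in genotypes:
            logger.warning("marker %s absent from genotype table; skipped", marker)
            continue
        seen: set[str] = set()
        for site in by_gene.get(gene, []):
            if site.snp_id in seen:
                continue
            seen.add(site.snp_id)
            if site.snp_id == marker:
                links.append(CisMarkerLink(marker, site.snp_id, probe_set, gene,
                                           r2=1.0, ld_p=0.0,
                                           phase=ldmod.PHASE_COUPLING, identical=True))
                continue
            if site.snp_id not in genotypes:
                logger.warning("site SNP %s absent from genotype table; skipped",
                               site.snp_id)
                continue
            try:
                counts = ldmod.tabulate(genotypes.row(marker), genotypes.row(site.snp_id))
                est = ldmod.estimate_p11(counts)
            except (ldmod.UndefinedLdError, ldmod.NoDataError) as exc:
                logger.warning("LD for (%s, %s) skipped: %s", marker, site.snp_id, exc)
                continue
            n_stat = est.n if chi2_n_stat == "N" else 2 * est.n
            _, p = ldmod.ld_test(est.r2, n_stat)
            if p < ld_alpha:
                links.append(CisMarkerLink(marker, site.snp_id, probe_set, gene,
                                           r2=est.r2, ld_p=p, phase=est.phase,
                                           identical=False))
    return links


def run_exon_level(config: RunConfig) -> RunResult:
    """Exon-level module discovery through documented cis-marker links."""
    if config.exon_expression is None or config.cis_markers is None:
        raise ValueError("exon-level run requires exon_expression and cis_markers")
    failures: list[dict] = []
    utrs, snps, families, genotypes, detection = _load_common(config)
    exon_expr = ExpressionMatrix.from_tsv(config.exon_expression, config.sex_labels)
    markers = pd.read_csv(config.cis_markers, sep="\t", dtype=str)
    in_snps = filter_in_snps(snps, config.maf_threshold, config.min_gap)
    sites = _call_all_sites(utrs, in_snps, families, config, failures)
    links = link_cis_markers(markers, sites, genotypes, config.ld_alpha,
                             config.chi2_n_stat)
    link_frame = pd.DataFrame([asdict(l) for l in links],
                              columns=["marker_snp", "site_snp", "probe_set", "gene",
                                       "r2", "ld_p", "phase", "identical"])
    linked = {(l.site_snp, l.gene): l for l in links}
    linked_sites = [s for s in sites if (s.snp_id, s.transcript_id) in linked]
    fits = _fit_sites(linked_sites, genotypes, exon_expr,
                      lambda s: linked[(s.snp_id, s.transcript_id)].probe_set,
                      config, failures)
    adj = bh_adjust([f.p for f in fits])
    for f, a in zip(fits, adj):
        f.adj_p = float(a)
    members = {f.family_id: f.member_ids for f in families}
    mirna_ok = expressed_mirnas(detection, config.module_alpha)
    probe_ok = set(exon_expr.values.index)  # exon ratios carry no absolute level
    rows = []
    for fit in fits:
        site = fit.site
        link = linked[(site.snp_id, site.transcript_id)]
        fam_members = members.get(site.family_id, ())
        if not any(m in mirna_ok for m in fam_members):
            continue
        if link.probe_set not in probe_ok:
            continue
        if not (fit.beta < 0 and np.isfinite(fit.adj_p) and fit.adj_p < config.module_alpha):
            continue
        rows.append({"Gene": link.gene, "Ps": link.probe_set,
                     "SNP1": link.marker_snp, "SNP2": site.snp_id,
                     "LD": round(link.r2, 3), "phase": link.phase,
                     "TSE": fit.beta, "Adj.p": fit.adj_p,
                     "miRNA": _strip_mir_prefix(fam_members),
                     "population": config.population_label})
    modules = pd.DataFrame(rows, columns=["Gene", "Ps", "SNP1", "SNP2", "LD", "phase",
                                          "TSE", "Adj.p", "miRNA", "population"])
    modules = modules.sort_values("Adj.p").reset_index(drop=True)
    report = make_report(snps=len(snps), in_snps=len(in_snps), sites=sites,
                         fits=fits, modules=len(modules), failures=failures,
                         config=config, links=len(links))
    return RunResult(modules=modules, fits=_fits_frame(fits),
                     sites=sites_to_frame(sites), report=report, links=link_frame)


def make_report(snps: int, in_snps: int, sites: Sequence[SnpSite],
                fits: Sequence[TseFit], modules: int, failures: list[dict],
                config: RunConfig, links: Optional[int] = None) -> dict:
    """Per-stage census plus the full threshold ledger for one run."""
    site_hist: dict[str, int] = {}
    for s in sites:
        key = f"{s.mutation_class}/{s.site_type}"
        site_hist[key] = site_hist.get(key, 0) + 1
    boxplot_data = [
        {"snp_id": f.site.snp_id, "feature_id": f.site.transcript_id,
         "medians": {str(k): v for k, v in f.group_medians.items()}}
        for f in fits]
    report = {
        "population": config.population_label,
        "counts": {"snps_in": snps, "in_snps_kept": in_snps,
                   "sites_called": len(sites), "fits_attempted": len(fits),
                   "modules_called": modules},
        "site_type_histogram": site_hist,
        "failure_census": failures,
        "thresholds": {"maf_threshold": config.maf_threshold,
                       "min_gap": config.min_gap,
                       "module_alpha": config.module_alpha,
                       "ld_alpha": config.ld_alpha, "flank": config.flank,
                       "min_group": config.min_group,
                       "chi2_n_stat": config.chi2_n_stat,
                       "expressed_gene_quantile": config.expressed_gene_quantile,
                       "seed": config.seed},
        "group_medians_by_site": boxplot_data,
    }
    if links is not None:
        report["counts"]["cis_marker_links"] = links
    return report


def write_outputs(result: RunResult, out_dir: str | Path, prefix: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.modules.to_csv(out / f"{prefix}_modules.tsv", sep="\t", index=False)
    result.fits.to_csv(out / f"{prefix}_fits.tsv", sep="\t", index=False)
    result.sites.to_csv(out / f"{prefix}_sites.tsv", sep="\t", index=False)
    if result.links is not None:
        result.links.to_csv(out / f"{prefix}_links.tsv", sep="\t", index=False)
    with open(out / f"{prefix}_report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
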