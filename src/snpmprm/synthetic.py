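"""Synthetic study generator with known ground truth.

Emulates the inputs of a lymphoblastoid-cell-line regulatory study:
bi-allelic genotypes under Hardy-Weinberg with configurable minor-allele
frequency and pairwise LD (sampled as phased haplotypes, then collapsed),
3'UTR sequences with seed-match sites planted over SNPs (disrupted or
created by the alternative allele), log2 expression generated under the
additive TSE model (grand mean + sex effect + beta * consistent-allele
count + Gaussian noise), miRNA detection p-values with a designated
expressed subset, and a documented cis-marker table.  Every stage of the
discovery pipeline can then be tested against the planted truth without any
external download.

It does not emulate probe-level microarray signal, hybridisation artifacts,
batch effects, or population structure beyond two-locus haplotype sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype import GenotypeTable
from .seed_sites import (CLASS_CR, CLASS_DS, SITE_7MER_A1, SITE_7MER_M8,
                         SITE_8MER, MirnaFamily, SnpRecord, scan_sites)

logger = logging.getLogger(__name__)

_CODE_FROM_REF_COUNT = {2: "R", 1: "H", 0: "O"}


class GenerationError(RuntimeError):
    """A planted site could not be realised within the retry budget."""


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: population alternative-allele frequency and UTR placement."""

    snp_id: str
    maf: float
    utr_position: int
    ref_allele: str
    alt_allele: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must lie in (0, 0.5], got {self.maf}")
        if not self.transcript_id:
            object.__setattr__(self, "transcript_id", f"tx_{self.snp_id}")


@dataclass(frozen=True)
class PlantedModule:
    """A planted SNP-site-effect triple; beta = 0 plants a null site."""

    snp_id: str
    family_id: str
    mutation_class: str  # DS | CR
    beta: float
    site_type: str = SITE_8MER

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta must be finite")
        if self.mutation_class not in (CLASS_DS, CLASS_CR):
            raise ValueError(f"mutation_class must be DS or CR")


@dataclass(frozen=True)
class LdPair:
    """Two SNPs whose genotypes are sampled from a shared haplotype
    distribution; P11 is the frequency of the reference-reference haplotype."""

    snp_a: str
    snp_b: str
    target_P11: float


@dataclass
class StudyConfig:
    n_samples: int
    snp_specs: list[SnpSpec]
    planted_modules: list[PlantedModule] = field(default_factory=list)
    ld_pairs: list[LdPair] = field(default_factory=list)
    families: list[MirnaFamily] = field(default_factory=list)
    population_label: str = "SYN"
    mu: float = 7.0
    sex_effects: tuple[float, float] = (0.0, 0.2)
    noise_sd: float = 0.3
    utr_length: int = 60
    sex_imbalance: float = 0.5  # fraction assigned sex 2
    n_decoy_mirnas: int = 50
    unexpressed_fraction: float = 0.4  # background features below the array floor
    background_mu: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        spec_by_id = {s.snp_id: s for s in self.snp_specs}
        fam_ids = {f.family_id for f in self.families}
        for m in self.planted_modules:
            if m.snp_id not in spec_by_id:
                raise ValueError(f"planted module references unknown SNP {m.snp_id}")
            if m.family_id not in fam_ids:
                raise ValueError(f"planted module references unknown family {m.family_id}")
        for pair in self.ld_pairs:
            sa, sb = spec_by_id[pair.snp_a], spec_by_id[pair.snp_b]
            pA, pB = 1 - sa.maf, 1 - sb.maf
            lo, hi = max(0.0, pA + pB - 1), min(pA, pB)
            if not lo - 1e-12 <= pair.target_P11 <= hi + 1e-12:
                raise ValueError(
                    f"target_P11={pair.target_P11} for ({pair.snp_a},{pair.snp_b}) "
                    f"outside Frechet bounds [{lo:.4g}, {hi:.4g}]")


@dataclass
class StudyBundle:
    """Paths of one written synthetic study."""

    utr_fasta: Path
    snp_table: Path
    genotype_table: Path
    gene_expression: Path
    exon_expression: Path
    sex_labels: Path
    mirna_families: Path
    mirna_detection: Path
    cis_markers: Path
    truth_table: Path


# ---------------------------------------------------------------------------
# genotypes

def gen_genotypes_hwe(maf: float, n: int, seed: int) -> np.ndarray:
    """Recoded genotypes under Hardy-Weinberg; ``maf`` is the
    alternative-allele frequency (in (0, 0.5])."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_alt = rng.binomial(2, maf, size=n)
    return np.array([_CODE_FROM_REF_COUNT[2 - k] for k in n_alt], dtype="<U1")


def gen_haplotype_pair_genotypes(pA: float, pB: float, P11: float, n: int,
                                 seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unphased genotype pair sampled through phased two-locus haplotypes.

    pA, pB are reference-allele frequencies; P11 the reference-reference
    haplotype probability.  Each individual is the union of two i.i.d.
    haplotypes.  Returns (codes_a, codes_b, true haplotype counts in order
    AB, Ab, aB, ab) so an oracle can check phase-level quantities.
    """
    probs = np.array([P11, pA - P11, pB - P11, 1 - pA - pB + P11])
    if np.any(probs < -1e-12):
        raise ValueError(f"P11={P11} infeasible for pA={pA}, pB={pB}")
    probs = np.clip(probs, 0, None)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    haps = rng.choice(4, size=(n, 2), p=probs)
    hap_counts = np.bincount(haps.ravel(), minlength=4)
    ref_a = np.isin(haps, (0, 1)).sum(axis=1)  # AB, Ab carry ref at locus A
    ref_b = np.isin(haps, (0, 2)).sum(axis=1)  # AB, aB carry ref at locus B
    codes_a = np.array([_CODE_FROM_REF_COUNT[k] for k in ref_a], dtype="<U1")
    codes_b = np.array([_CODE_FROM_REF_COUNT[k] for k in ref_b], dtype="<U1")
    return codes_a, codes_b, hap_counts


def gen_genotype_table(config: StudyConfig, seed: int) -> GenotypeTable:
    """Full SNPs x samples table: LD pairs jointly sampled, the rest HWE."""
    spec_by_id = {s.snp_id: s for s in config.snp_specs}
    sample_ids = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    rows: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(len(config.ld_pairs) + len(config.snp_specs)).tolist())
    for pair in config.ld_pairs:
        sa, sb = spec_by_id[pair.snp_a], spec_by_id[pair.snp_b]
        a, b, _ = gen_haplotype_pair_genotypes(
            1 - sa.maf, 1 - sb.maf, pair.target_P11, config.n_samples, next(child))
        rows[pair.snp_a], rows[pair.snp_b] = a, b
    for spec in config.snp_specs:
        s = next(child)
        if spec.snp_id not in rows:
            rows[spec.snp_id] = gen_genotypes_hwe(spec.maf, config.n_samples, s)
    snp_ids = [s.snp_id for s in config.snp_specs]
    codes = np.array([rows[s] for s in snp_ids])
    return GenotypeTable(sample_ids, snp_ids, codes,
                         {s.snp_id: s.ref_allele for s in config.snp_specs},
                         {s.snp_id: s.alt_allele for s in config.snp_specs})


# ---------------------------------------------------------------------------
# UTR sequences with planted sites

def _site_window(family: MirnaFamily, site_type: str,
                 rng: np.random.Generator) -> tuple[str, tuple[int, int]]:
    """An 8-nt window realising the requested site type, and the site span
    inside the window as 0-based [start, end) offsets."""
    core, m8 = family.core, family.m8
    non_a = [b for b in "CGT"]
    if site_type == SITE_8MER:
        return m8 + core + "A", (0, 8)
    if site_type == SITE_7MER_M8:
        tail = str(rng.choice(non_a))
        return m8 + core + tail, (0, 7)
    if site_type == SITE_7MER_A1:
        lead = str(rng.choice([b for b in "ACGT" if b != m8]))
        return lead + core + "A", (1, 8)
    raise ValueError(f"unknown site type {site_type!r}")


def _snp_offsets(family: MirnaFamily, site_type: str, on_allele: str) -> list[int]:
    """0-based window offsets where the SNP may sit so that the on-allele
    completes the site and the off-allele yields no site of any type.

    Core positions (window offsets 1-6) always qualify when the core base
    equals the on-allele.  The m8 anchor (offset 0) qualifies only for a
    7mer-m8 site (for an 8mer, losing m8 leaves a 7mer-A1 — a type change,
    not a clean loss); symmetrically the A1 anchor (offset 7) only for a
    7mer-A1 site.
    """
    core, m8 = family.core, family.m8
    offsets = [i + 1 for i in range(6) if core[i] == on_allele]
    if site_type == SITE_7MER_M8 and on_allele == m8:
        offsets.append(0)
    if site_type == SITE_7MER_A1 and on_allele == "A":
        offsets.append(7)
    return offsets


def _random_seq(length: int, rng: np.random.Generator) -> list[str]:
    return list(rng.choice(list("ACGT"), size=length))


def gen_utr_with_sites(config: StudyConfig, families: Sequence[MirnaFamily],
                       seed: int, max_retries: int = 200
                       ) -> tuple[dict[str, str], list[SnpRecord], pd.DataFrame]:
    """UTR sequences (one transcript per SNP) with planted sites and truth.

    For each planted (snp, family, DS|CR): the reference-allele sequence
    contains the canonical site iff the class is DS, the alternative-allele
    sequence iff CR, with the SNP inside the site span.  Background sequence
    is rejection-sampled so neither allele sequence carries any incidental
    site for the configured families.
    """
    rng = np.random.default_rng(seed)
    fam_by_id = {f.family_id: f for f in families}
    mod_by_snp: dict[str, PlantedModule] = {}
    for m in config.planted_modules:
        if m.snp_id in mod_by_snp:
            raise GenerationError(f"multiple planted modules on SNP {m.snp_id}")
        mod_by_snp[m.snp_id] = m

    utrs: dict[str, str] = {}
    records: list[SnpRecord] = []
    truth_rows = []
    for spec in config.snp_specs:
        L = config.utr_length
        pos0 = spec.utr_position - 1
        if not 0 <= pos0 < L:
            raise GenerationError(f"{spec.snp_id}: UTR position outside sequence")
        module = mod_by_snp.get(spec.snp_id)
        planted_span = None
        if module is not None:
            fam = fam_by_id[module.family_id]
            on_allele = spec.ref_allele if module.mutation_class == CLASS_DS else spec.alt_allele
            offsets = _snp_offsets(fam, module.site_type, on_allele)
            offsets = [o for o in offsets if 0 <= pos0 - o and pos0 - o + 8 <= L]
            if not offsets:
                raise GenerationError(
                    f"{spec.snp_id}: allele {on_allele} cannot complete a "
                    f"{module.site_type} site of family {module.family_id} here")
        for attempt in range(max_retries):
            seq = _random_seq(L, rng)
            if module is not None:
                off = int(rng.choice(offsets))
                window, (ws, we) = _site_window(fam, module.site_type, rng)
                win_start = pos0 - off
                seq[win_start:win_start + 8] = list(window)
                planted_span = (win_start + ws + 1, win_start + we)  # 1-based closed
            on, offb = ((spec.ref_allele, spec.alt_allele)
                        if module is None or module.mutation_class == CLASS_DS
                        else (spec.alt_allele, spec.ref_allele))
            seq[pos0] = on if module is not None else spec.ref_allele
            on_seq = "".join(seq)
            seq[pos0] = offb if module is not None else spec.alt_allele
            off_seq = "".join(seq)
            seq[pos0] = spec.ref_allele
            ok = True
            for f in families:
                on_hits = scan_sites(on_seq, f)
                off_hits = scan_sites(off_seq, f)
                if module is not None and f.family_id == module.family_id:
                    expected = [(planted_span, module.site_type)]
                    if on_hits != expected or off_hits:
                        ok = False
                        break
                elif on_hits or off_hits:
                    ok = False
                    break
            if ok:
                break
        else:
            raise GenerationError(
                f"{spec.snp_id}: no clean background in {max_retries} retries")
        utrs[spec.transcript_id] = "".join(seq)
        records.append(SnpRecord(spec.snp_id, spec.transcript_id, spec.utr_position,
                                 spec.ref_allele, spec.alt_allele, spec.maf))
        if module is not None:
            truth_rows.append({
                "snp_id": spec.snp_id, "transcript_id": spec.transcript_id,
                "family_id": module.family_id, "mutation_class": module.mutation_class,
                "site_type": module.site_type, "span_start": planted_span[0],
                "span_end": planted_span[1], "beta": module.beta})
    truth = pd.DataFrame(truth_rows, columns=["snp_id", "transcript_id", "family_id",
                                              "mutation_class", "site_type",
                                              "span_start", "span_end", "beta"])
    return utrs, records, truth


# ---------------------------------------------------------------------------
# expression and miRNA detection

def gen_sex_labels(config: StudyConfig) -> pd.Series:
    """Balanced alternating 1/2 labels by default; ``sex_imbalance`` shifts
    the fraction assigned sex 2."""
    sample_ids = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    if config.sex_imbalance == 0.5:
        sex = [1 + (i % 2) for i in range(config.n_samples)]
    else:
        n2 = int(round(config.sex_imbalance * config.n_samples))
        sex = [2] * n2 + [1] * (config.n_samples - n2)
    return pd.Series(sex, index=sample_ids, name="sex")


def gen_expression(config: StudyConfig, genotypes: GenotypeTable, seed: int,
                   mu: Optional[float] = None,
                   include_background: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Log2 expression under the additive model, one feature per transcript.

    y_j = mu + s_(sex of j) + beta * ca_j + e_j, e_j ~ N(0, noise_sd^2);
    transcripts without a planted module have beta = 0 (no genotype term).
    A fraction of unexpressed background features around ``background_mu``
    emulates the low-intensity mode of a real array, giving the
    expressed-gene filter a floor to cut at.
    """
    mod_by_snp = {m.snp_id: m for m in config.planted_modules}
    for snp_id in mod_by_snp:
        if snp_id not in genotypes:
            raise ValueError(f"planted module SNP {snp_id} absent from genotype table")
    mu = config.mu if mu is None else mu
    sex = gen_sex_labels(config)
    s_vec = np.where(sex.to_numpy() == 1, config.sex_effects[0], config.sex_effects[1])
    rng = np.random.default_rng(seed)
    rows, index = [], []
    for spec in config.snp_specs:
        y = mu + s_vec + rng.normal(0.0, config.noise_sd, size=config.n_samples)
        module = mod_by_snp.get(spec.snp_id)
        if module is not None and module.beta != 0.0:
            ca = genotypes.ca_counts(spec.snp_id, module.mutation_class)
            y = y + module.beta * np.nan_to_num(ca)
        rows.append(y)
        index.append(spec.transcript_id)
    if include_background and config.unexpressed_fraction > 0:
        n_bg = int(np.ceil(config.unexpressed_fraction * len(config.snp_specs)
                           / max(1e-9, 1 - config.unexpressed_fraction)))
        for i in range(n_bg):
            rows.append(config.background_mu
                        + rng.normal(0.0, config.noise_sd, size=config.n_samples))
            index.append(f"bg_{i + 1:04d}")
    expr = pd.DataFrame(rows, index=pd.Index(index, name="feature_id"),
                        columns=genotypes.sample_ids)
    return expr, sex


def gen_mirna_detection(expressed_ids: set[str], all_ids: Sequence[str],
                        n_samples: int, seed: int) -> pd.DataFrame:
    """Detection p-value matrix: expressed miRNAs draw Beta(1, 99) (median
    ~0.007), the rest Uniform(0, 1), so the BH median filter separates them."""
    all_ids = list(all_ids)
    if not expressed_ids <= set(all_ids):
        raise ValueError("expressed_ids must be a subset of all_ids")
    rng = np.random.default_rng(seed)
    rows = []
    for mid in all_ids:
        if mid in expressed_ids:
            rows.append(rng.beta(1.0, 99.0, size=n_samples))
        else:
            rows.append(rng.uniform(0.0, 1.0, size=n_samples))
    cols = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    return pd.DataFrame(rows, index=pd.Index(all_ids, name="mirna_id"), columns=cols)


# ---------------------------------------------------------------------------
# whole-study bundle

def default_families(k: int = 8, seed: int = 7) -> list[MirnaFamily]:
    """k distinct synthetic miRNA families with random 7-nt seeds and two
    member ids each."""
    rng = np.random.default_rng(seed)
    fams: list[MirnaFamily] = []
    seeds_seen: set[str] = set()
    i = 0
    while len(fams) < k:
        s = "".join(rng.choice(list("ACGT"), size=7))
        i += 1
        if s in seeds_seen:
            continue
        seeds_seen.add(s)
        fid = f"fam{len(fams) + 1}"
        fams.append(MirnaFamily(fid, s, (f"hsa-mir-{900 + len(fams)}",
                                         f"hsa-mir-{900 + len(fams)}b")))
    return fams


def gen_study(config: StudyConfig, out_dir: str | Path) -> StudyBundle:
    """Write a complete, mutually consistent study to ``out_dir``.

    Deterministic: identical (config, seed) reproduce identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    families = config.families or default_families()
    ss = np.random.SeedSequence(config.seed)
    s_geno, s_utr, s_expr, s_exon, s_det = ss.generate_state(5).tolist()

    genotypes = gen_genotype_table(config, s_geno)
    utrs, snp_records, truth = gen_utr_with_sites(config, families, s_utr)
    gene_expr, sex = gen_expression(config, genotypes, s_expr)
    # exon-level log2 ratios: same additive model around a zero baseline
    exon_expr, _ = gen_expression(config, genotypes, s_exon, mu=0.0,
                                  include_background=False)
    exon_expr.index = pd.Index([f"ps_{t}" for t in exon_expr.index], name="feature_id")

    member_ids = [m for f in families for m in f.member_ids]
    decoys = [f"hsa-mir-d{i}" for i in range(1, config.n_decoy_mirnas + 1)]
    detection = gen_mirna_detection(set(member_ids), member_ids + decoys,
                                    config.n_samples, s_det)

    bundle = StudyBundle(
        utr_fasta=out / "utrs.fasta", snp_table=out / "snps.tsv",
        genotype_table=out / "genotypes.tsv",
        gene_expression=out / "gene_expression.tsv",
        exon_expression=out / "exon_expression.tsv",
        sex_labels=out / "sex.tsv",
        mirna_families=out / "mirna_families.tsv",
        mirna_detection=out / "mirna_detection.tsv",
        cis_markers=out / "cis_markers.tsv",
        truth_table=out / "truth.tsv")

    with open(bundle.utr_fasta, "w") as fh:
        for tx, seq in utrs.items():
            fh.write(f">{tx}\n{seq}\n")
    pd.DataFrame([{"snp_id": r.snp_id, "transcript_id": r.transcript_id,
                   "utr_pos": r.utr_pos, "ref": r.ref_allele, "alt": r.alt_allele,
                   "maf": r.maf} for r in snp_records]
                 ).to_csv(bundle.snp_table, sep="\t", index=False)
    genotypes.to_wide_tsv(bundle.genotype_table)
    gene_expr.to_csv(bundle.gene_expression, sep="\t")
    exon_expr.to_csv(bundle.exon_expression, sep="\t")
    sex.to_frame().rename_axis("sample_id").to_csv(bundle.sex_labels, sep="\t")
    pd.DataFrame([{"family_id": f.family_id, "members": ",".join(f.member_ids),
                   "seed7": f.seed7} for f in families]
                 ).to_csv(bundle.mirna_families, sep="\t", index=False)
    detection.to_csv(bundle.mirna_detection, sep="\t")
    tx_of = {s.snp_id: s.transcript_id for s in config.snp_specs}
    pd.DataFrame([{"marker_snp": p.snp_a, "site_snp_hint": p.snp_b,
                   "gene": tx_of[p.snp_b], "probe_set": f"ps_{tx_of[p.snp_b]}"}
                  for p in config.ld_pairs]
                 ).to_csv(bundle.cis_markers, sep="\t", index=False)
    truth.to_csv(bundle.truth_table, sep="\t", index=False)
    return bundle


def recovery_study_config(seed: int, n_samples: int = 90, n_modules: int = 5,
                          n_null_sites: int = 500, beta: float = -0.6,
                          noise_sd: float = 0.2, maf: float = 0.3,
                          n_families: int = 8) -> StudyConfig:
    """The standard planted-recovery study: ``n_modules`` sites with a real
    repressive effect among ``n_null_sites`` sites with beta = 0."""
    rng = np.random.default_rng(seed)
    families = default_families(n_families)
    specs: list[SnpSpec] = []
    modules: list[PlantedModule] = []
    n_total = n_modules + n_null_sites
    classes = [CLASS_DS, CLASS_CR]
    types = [SITE_8MER, SITE_7MER_M8, SITE_7MER_A1]
    for i in range(n_total):
        fam = families[i % len(families)]
        cls = classes[i % 2]
        styp = types[i % 3]
        on = fam.core[int(rng.integers(0, 6))]
        off = str(rng.choice([b for b in "ACGT" if b != on]))
        ref, alt = (on, off) if cls == CLASS_DS else (off, on)
        specs.append(SnpSpec(f"rs{i + 1:05d}", maf, 30, ref, alt))
        modules.append(PlantedModule(f"rs{i + 1:05d}", fam.family_id, cls,
                                     beta if i < n_modules else 0.0, styp))
    return StudyConfig(n_samples=n_samples, snp_specs=specs,
                       planted_modules=modules, families=families,
                       noise_sd=noise_sd, seed=seed)
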