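"""Single-letter recoding of bi-allelic genotypes and consistent-allele counts.

Codes: R = homozygous reference, H = heterozygous, O = homozygous
alternative, N = unknown/missing.  The consistent-allele (CA) count of a
sample is the number of its chromosomes carrying the *intact* miRNA target
site: for a disrupted site the reference allele carries the site
(R/H/O -> 2/1/0), for a created site the alternative allele does
(R/H/O -> 0/1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODES = ("R", "H", "O", "N")
MISSING_MARKERS = {"N", ".", "-", "0", ""}


class UndefinedFrequencyError(ValueError):
    """Allele frequency requested on an all-missing genotype vector."""


def recode(genotype: tuple[str, str], ref_allele: str, alt_allele: str) -> str:
    """Recode one unphased allele pair to R/H/O/N."""
    a, b = (g.upper() for g in genotype)
    alleles = {ref_allele, alt_allele}
    if a in MISSING_MARKERS or b in MISSING_MARKERS:
        return "N"
    if a not in alleles or b not in alleles:
        logger.warning("unexpected allele pair %s/%s for ref=%s alt=%s; coding as N",
                       a, b, ref_allele, alt_allele)
        return "N"
    n_ref = (a == ref_allele) + (b == ref_allele)
    return {2: "R", 1: "H", 0: "O"}[n_ref]


def decode(code: str, ref_allele: str, alt_allele: str) -> tuple[str, str]:
    """Inverse of :func:`recode` for non-missing codes (H returned ref-first)."""
    return {"R": (ref_allele, ref_allele),
            "H": (ref_allele, alt_allele),
            "O": (alt_allele, alt_allele)}[code]


def maf(codes: Sequence[str]) -> float:
    """Minor-allele frequency of a recoded genotype vector (N excluded)."""
    arr = np.asarray(codes)
    n_r = int(np.sum(arr == "R"))
    n_h = int(np.sum(arr == "H"))
    n_o = int(np.sum(arr == "O"))
    n = n_r + n_h + n_o
    if n == 0:
        raise UndefinedFrequencyError("all genotypes missing; MAF undefined")
    alt_freq = (2 * n_o + n_h) / (2 * n)
    return min(alt_freq, 1.0 - alt_freq)


def consistent_alleles(code: str, mutation_class: str) -> int:
    """Number of chromosomes carrying the intact target site (0, 1 or 2)."""
    if code == "N":
        raise ValueError("missing genotype has no CA count; drop the sample")
    if mutation_class == "DS":
        return {"R": 2, "H": 1, "O": 0}[code]
    if mutation_class == "CR":
        return {"R": 0, "H": 1, "O": 2}[code]
    raise ValueError(f"mutation_class must be DS or CR, got {mutation_class!r}")


def genotype_consistent(codes_a: Sequence[str], codes_b: Sequence[str]) -> bool:
    """True iff the two recoded vectors agree wherever both are observed."""
    a, b = np.asarray(codes_a), np.asarray(codes_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    both = (a != "N") & (b != "N")
    return bool(np.all(a[both] == b[both]))


@dataclass
class GenotypeTable:
    """samples x SNPs matrix of recoded genotypes with per-SNP allele labels."""

    sample_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray  # shape (n_snps, n_samples), dtype '<U1'
    ref_alleles: dict[str, str]
    alt_alleles: dict[str, str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("codes matrix shape does not match id lists")
        bad = set(self.codes.ravel()) - set(CODES)
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        self._row = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._row

    def row(self, snp_id: str) -> np.ndarray:
        return self.codes[self._row[snp_id]]

    def maf(self, snp_id: str) -> float:
        return maf(self.row(snp_id))

    def ca_counts(self, snp_id: str, mutation_class: str) -> np.ndarray:
        """Per-sample CA counts as float, NaN where the genotype is missing."""
        codes = self.row(snp_id)
        out = np.full(codes.shape, np.nan)
        for code in "RHO":
            out[codes == code] = consistent_alleles(code, mutation_class)
        return out

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_wide_tsv(cls, path: str | Path, ref_alleles: dict[str, str] | None = None,
                      alt_alleles: dict[str, str] | None = None) -> "GenotypeTable":
        """Read a HapMap-style wide table: rows = SNPs, columns = samples,
        cells = unphased pairs like ``A/C``; columns ``snp_id``, ``ref``,
        ``alt`` if allele labels are not supplied externally."""
        df = pd.read_csv(path, sep="\t", dtype=str).set_index("snp_id")
        if ref_alleles is None:
            ref_alleles = df["ref"].to_dict()
            alt_alleles = df["alt"].to_dict()
        sample_cols = [c for c in df.columns if c not in ("ref", "alt")]
        codes = np.empty((len(df), len(sample_cols)), dtype="<U1")
        for i, (snp, row) in enumerate(df[sample_cols].iterrows()):
            ref, alt = ref_alleles[snp], alt_alleles[snp]
            for j, cell in enumerate(row):
                pair = tuple(str(cell).replace("|", "/").split("/"))
                codes[i, j] = recode(pair, ref, alt) if len(pair) == 2 else "N"
        return cls(sample_cols, list(df.index), codes, dict(ref_alleles), dict(alt_alleles))

    @classmethod
    def from_vcf(cls, path: str | Path, complement_minus_strand: bool = False) -> "GenotypeTable":
        """Read bi-allelic SNVs from a VCF (GT field; phase ignored).
        Multi-allelic records are rejected."""
        import pysam

        vf = pysam.VariantFile(str(path))
        sample_ids = list(vf.header.samples)
        snp_ids, rows, refs, alts = [], [], {}, {}
        comp = str.maketrans("ACGT", "TGCA")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{rec.id or rec.pos}: only bi-allelic SNVs supported")
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if complement_minus_strand:
                ref, alt = ref.translate(comp), alt.translate(comp)
            sid = rec.id or f"{rec.chrom}:{rec.pos}"
            row = np.empty(len(sample_ids), dtype="<U1")
            for j, s in enumerate(sample_ids):
                gt = rec.samples[s].get("GT")
                if gt is None or any(g is None for g in gt):
                    row[j] = "N"
                else:
                    row[j] = {2: "R", 1: "H", 0: "O"}[sum(g == 0 for g in gt)]
            snp_ids.append(sid)
            rows.append(row)
            refs[sid], alts[sid] = ref, alt
        return cls(sample_ids, snp_ids, np.array(rows), refs, alts)

    def to_recoded_tsv(self, path: str | Path) -> None:
        """Write the R/H/O/N matrix, rows = SNPs, columns = samples."""
        pd.DataFrame(self.codes, index=pd.Index(self.snp_ids, name="snp_id"),
                     columns=self.sample_ids).to_csv(path, sep="\t")

    def to_wide_tsv(self, path: str | Path, rng_order: Iterable[str] | None = None) -> None:
        """Write allele-pair cells (``A/C`` style) with ref/alt columns."""
        recs = []
        for i, snp in enumerate(self.snp_ids):
            ref, alt = self.ref_alleles[snp], self.alt_alleles[snp]
            cells = {"snp_id": snp, "ref": ref, "alt": alt}
            for j, samp in enumerate(self.sample_ids):
                c = self.codes[i, j]
                cells[samp] = "N/N" if c == "N" else "/".join(decode(c, ref, alt))
            recs.append(cells)
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
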