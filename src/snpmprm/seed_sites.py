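"""Allele-aware prediction of canonical miRNA target sites in 3'UTRs.

A canonical site is a perfect Watson-Crick match on the mRNA to the miRNA
seed region (mature nucleotides 2-7), optionally extended by an adenine
across from miRNA nucleotide 1 (7mer-A1), a match to nucleotide 8
(7mer-m8), or both (8mer).  Sites are called separately on the reference-
and alternative-allele sequence around each SNP: a site present only with
the reference allele is a disrupted site (DS); present only with the
alternative allele, a created site (CR).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SITE_8MER = "8mer"
SITE_7MER_M8 = "7mer-m8"
SITE_7MER_A1 = "7mer-A1"

CLASS_DS = "DS"
CLASS_CR = "CR"
CLASS_TYPE_CHANGED = "type-changed"


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside the DNA alphabet."""


class ReferenceMismatchError(ValueError):
    """The UTR base at the SNP position does not equal the stated reference allele."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise InvalidSequenceError(f"non-ACGT characters in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class MirnaFamily:
    """A miRNA family sharing one seed: mature nucleotides 2-8, 5'->3'.

    ``seed7`` is stored DNA-alphabet (U mapped to T); when constructed from a
    full mature sequence use :meth:`from_mature`.
    """

    family_id: str
    seed7: str
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seed = self.seed7.upper().replace("U", "T")
        object.__setattr__(self, "seed7", seed)
        if len(seed) != 7:
            raise ValueError(f"seed7 must be 7 nt, got {len(seed)!r} for {self.family_id}")
        _check_dna(seed)

    @classmethod
    def from_mature(cls, family_id: str, mature: str, member_ids: Sequence[str] = ()) -> "MirnaFamily":
        mature = mature.upper().replace("U", "T")
        if len(mature) < 8:
            raise ValueError("mature sequence shorter than 8 nt")
        return cls(family_id, mature[1:8], tuple(member_ids))

    @property
    def core(self) -> str:
        """Reverse complement of seed nucleotides 2-7 (6-nt core match on the mRNA)."""
        return revcomp(self.seed7[:6])

    @property
    def m8(self) -> str:
        """mRNA base complementary to miRNA nucleotide 8."""
        return self.seed7[6].translate(_COMPLEMENT)


@dataclass(frozen=True)
class SnpRecord:
    """A bi-allelic SNP located in a 3'UTR, 1-based position on the UTR."""

    snp_id: str
    transcript_id: str
    utr_pos: int
    ref_allele: str
    alt_allele: str
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles identical")
        for a in (self.ref_allele, self.alt_allele):
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"{self.snp_id}: unsupported allele {a!r} (bi-allelic SNVs only)")

    def swapped(self) -> "SnpRecord":
        """The same locus with reference and alternative labels exchanged."""
        return SnpRecord(self.snp_id, self.transcript_id, self.utr_pos,
                         self.alt_allele, self.ref_allele, self.maf)


@dataclass(frozen=True)
class SnpSite:
    """A SNP-involved candidate target site.

    ``span`` is a 1-based closed interval on the UTR; its length is 8 for an
    8mer and 7 for the two 7mer types, and it always contains the SNP position.
    """

    snp_id: str
    transcript_id: str
    family_id: str
    site_type: str
    mutation_class: str
    span: tuple[int, int]


def classify_window(window: str, family: MirnaFamily) -> Optional[str]:
    """Classify one 8-nt mRNA window (5'->3'; last base faces miRNA nt 1).

    Returns "8mer", "7mer-m8", "7mer-A1" or None.  The window layout is
    ``m8 + core + A`` for an 8mer, where core is the reverse complement of
    seed nucleotides 2-7 and m8 the complement of seed nucleotide 8.
    """
    if len(window) != 8:
        raise ValueError(f"window must be 8 nt, got {len(window)}")
    _check_dna(window)
    core, m8 = family.core, family.m8
    has_m8_core = window[0] == m8 and window[1:7] == core
    has_core_a = window[1:7] == core and window[7] == "A"
    if has_m8_core and window[7] == "A":
        return SITE_8MER
    if has_m8_core:
        return SITE_7MER_M8
    if has_core_a and window[0] != m8:
        return SITE_7MER_A1
    return None


def scan_sites(utr_seq: str, family: MirnaFamily) -> list[tuple[tuple[int, int], str]]:
    """All canonical sites of one family on a UTR, as (1-based span, type).

    Equivalent to classifying every 8-nt window, but driven by substring
    search on the 6-nt core so long sequences scan quickly.  Span
    conventions: 8mer = the full window; 7mer-m8 = window bases 1-7;
    7mer-A1 = window bases 2-8.  Overlapping sites are all reported.
    """
    utr_seq = utr_seq.upper()
    if not utr_seq:
        raise InvalidSequenceError("empty sequence")
    _check_dna(utr_seq)
    core, m8 = family.core, family.m8
    hits: list[tuple[tuple[int, int], str]] = []
    start = utr_seq.find(core, 1)  # core at offset 0 has no m8/anchor context in an 8-nt window
    while start != -1:
        # window spans [start-1, start+6] 0-based inclusive
        if start + 7 <= len(utr_seq):
            window = utr_seq[start - 1 : start + 7]
            if len(window) == 8:
                t = classify_window(window, family)
                if t == SITE_8MER:
                    hits.append(((start, start + 7), t))
                elif t == SITE_7MER_M8:
                    hits.append(((start, start + 6), t))
                elif t == SITE_7MER_A1:
                    hits.append(((start + 1, start + 7), t))
        start = utr_seq.find(core, start + 1)
    return hits


def allele_sequences(utr_seq: str, snp: SnpRecord, flank: int = 10) -> tuple[str, str, int]:
    """Reference- and alternative-allele windows around a SNP.

    Returns ``(ref_seq, alt_seq, offset)`` where both windows are
    ``utr_seq[pos-flank ... pos+flank]`` (truncated at the UTR ends) with the
    central base set to the respective allele, and ``offset`` is the 1-based
    UTR coordinate of the first window base (window coord + offset - 1 maps
    back to the UTR).
    """
    if flank < 7:
        raise ValueError("flank must be >= 7 to cover any overlapping site")
    utr_seq = utr_seq.upper()
    pos0 = snp.utr_pos - 1
    if not (0 <= pos0 < len(utr_seq)):
        raise ValueError(f"{snp.snp_id}: UTR position {snp.utr_pos} outside sequence of length {len(utr_seq)}")
    observed = utr_seq[pos0]
    if observed != snp.ref_allele:
        raise ReferenceMismatchError(
            f"{snp.snp_id}: UTR base {observed!r} at position {snp.utr_pos} "
            f"does not match reference allele {snp.ref_allele!r}")
    lo = max(0, pos0 - flank)
    hi = min(len(utr_seq), pos0 + flank + 1)
    center = pos0 - lo
    window = utr_seq[lo:hi]
    ref_seq = window[:center] + snp.ref_allele + window[center + 1:]
    alt_seq = window[:center] + snp.alt_allele + window[center + 1:]
    return ref_seq, alt_seq, lo + 1


def call_snp_sites(utr_seq: str, snp: SnpRecord, families: Iterable[MirnaFamily],
                   flank: int = 10, include_type_changed: bool = False) -> list[SnpSite]:
    """DS/CR calls for one SNP against a set of miRNA families.

    A site present on the reference-allele window only is DS, on the
    alternative-allele window only is CR; sites present with both alleles
    cancel.  A DS and a CR candidate of the same family with overlapping
    spans indicate a type change (e.g. 8mer -> 7mer-m8) and are excluded
    unless ``include_type_changed`` is set.  Only sites whose UTR span
    contains the SNP position are reported.
    """
    ref_seq, alt_seq, offset = allele_sequences(utr_seq, snp, flank=flank)
    calls: list[SnpSite] = []
    for fam in families:
        ref_hits = {(span, t) for span, t in scan_sites(ref_seq, fam)}
        alt_hits = {(span, t) for span, t in scan_sites(alt_seq, fam)}

        def to_utr(span: tuple[int, int]) -> tuple[int, int]:
            return (span[0] + offset - 1, span[1] + offset - 1)

        ds = [(to_utr(s), t) for s, t in ref_hits - alt_hits]
        cr = [(to_utr(s), t) for s, t in alt_hits - ref_hits]
        ds = [(s, t) for s, t in ds if s[0] <= snp.utr_pos <= s[1]]
        cr = [(s, t) for s, t in cr if s[0] <= snp.utr_pos <= s[1]]
        changed_ds = {i for i, (s, _) in enumerate(ds)
                      for (s2, _) in cr if s[0] <= s2[1] and s2[0] <= s[1]}
        changed_cr = {j for j, (s2, _) in enumerate(cr)
                      for (s, _) in ds if s[0] <= s2[1] and s2[0] <= s[1]}
        for i, (span, t) in enumerate(ds):
            cls = CLASS_TYPE_CHANGED if i in changed_ds else CLASS_DS
            if cls == CLASS_DS or include_type_changed:
                calls.append(SnpSite(snp.snp_id, snp.transcript_id, fam.family_id, t, cls, span))
        for j, (span, t) in enumerate(cr):
            cls = CLASS_TYPE_CHANGED if j in changed_cr else CLASS_CR
            if cls == CLASS_CR or include_type_changed:
                calls.append(SnpSite(snp.snp_id, snp.transcript_id, fam.family_id, t, cls, span))
    calls.sort(key=lambda s: (s.family_id, s.span, s.site_type))
    return calls


def filter_in_snps(snps: Sequence[SnpRecord], maf_threshold: float = 0.1,
                   min_gap: int = 10) -> list[SnpRecord]:
    """Keep informative SNPs: MAF strictly over the threshold, then drop any
    SNP closer than ``min_gap`` nt to the immediately preceding SNP of the
    same transcript (distance exactly ``min_gap`` is kept)."""
    by_tx: dict[str, list[SnpRecord]] = {}
    order = {id(s): i for i, s in enumerate(snps)}
    for s in snps:
        by_tx.setdefault(s.transcript_id, []).append(s)
    kept: list[SnpRecord] = []
    for tx, recs in by_tx.items():
        if any(recs[i].utr_pos > recs[i + 1].utr_pos for i in range(len(recs) - 1)):
            warnings.warn(f"SNPs of transcript {tx} not sorted by position; sorting internally")
            recs = sorted(recs, key=lambda r: r.utr_pos)
        recs = [r for r in recs if r.maf > maf_threshold]
        prev_pos: Optional[int] = None
        for r in recs:
            if prev_pos is not None and r.utr_pos - prev_pos < min_gap:
                prev_pos = r.utr_pos
                continue
            kept.append(r)
            prev_pos = r.utr_pos
    kept.sort(key=lambda r: order.get(id(r), 0))
    return kept


# ---------------------------------------------------------------------------
# I/O

def read_utrs(fasta_path: str | Path) -> dict[str, str]:
    """3'UTR sequences keyed by transcript id (mRNA sense strand, DNA)."""
    return {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(fasta_path), "fasta")}


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """TSV with columns snp_id, transcript_id, utr_pos (1-based), ref, alt[, maf]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        maf = float(getattr(row, "maf", "nan")) if hasattr(row, "maf") else float("nan")
        out.append(SnpRecord(row.snp_id, row.transcript_id, int(row.utr_pos),
                             row.ref.upper(), row.alt.upper(), maf))
    return out


def read_family_table(path: str | Path) -> list[MirnaFamily]:
    """TSV with columns family_id, members (comma-joined), seed7 or mature."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams = []
    for row in df.itertuples(index=False):
        members = tuple(str(row.members).split(",")) if getattr(row, "members", None) else ()
        if hasattr(row, "seed7") and isinstance(row.seed7, str):
            fams.append(MirnaFamily(row.family_id, row.seed7, members))
        else:
            fams.append(MirnaFamily.from_mature(row.family_id, row.mature, members))
    return fams


def sites_to_frame(sites: Iterable[SnpSite]) -> pd.DataFrame:
    rows = [{"snp_id": s.snp_id, "transcript_id": s.transcript_id,
             "family_id": s.family_id, "site_type": s.site_type,
             "mutation_class": s.mutation_class,
             "span_start": s.span[0], "span_end": s.span[1]} for s in sites]
    return pd.DataFrame(rows, columns=["snp_id", "transcript_id", "family_id",
                                       "site_type", "mutation_class",
                                       "span_start", "span_end"])


def write_bed6(sites: Iterable[SnpSite], path: str | Path) -> None:
    """BED6 export: 0-based half-open spans, name = snp|family|type|class."""
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.snp_id}|{s.family_id}|{s.site_type}|{s.mutation_class}"
            fh.write(f"{s.transcript_id}\t{s.span[0] - 1}\t{s.span[1]}\t{name}\t0\t+\n")
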