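"""Allele-aware site calling: classifier rules, scanning, DS/CR symmetry."""

import itertools

import numpy as np
import pytest

from helpers import oracle_classify, oracle_scan
from snpmprm.seed_sites import (CLASS_CR, CLASS_DS, InvalidSequenceError,
                                MirnaFamily, ReferenceMismatchError, SnpRecord,
                                allele_sequences, call_snp_sites, classify_window,
                                filter_in_snps, scan_sites)


@pytest.mark.parametrize("window,expected", [
    ("ATAAGCTA", "8mer"),
    ("ATAAGCTG", "7mer-m8"),
    ("GTAAGCTA", "7mer-A1"),
    ("GTAAGCTG", None),
])
def test_classify_window_anchor_rules(example_family, window, expected):
    assert classify_window(window, example_family) == expected


def test_classify_window_rejects_non_dna(example_family):
    with pytest.raises(InvalidSequenceError):
        classify_window("ATAAGCTN", example_family)


def test_family_from_mature_extracts_nt2_to_8():
    fam = MirnaFamily.from_mature("mir-x", "UAGCUUAUCAGACUGAUGUUGA")
    assert fam.seed7 == "AGCTTAT"
    assert fam.core == "TAAGCT" and fam.m8 == "A"


def test_classifier_matches_bruteforce_oracle_exhaustively(rng):
    """Implementation agrees with the independent Biopython-based oracle on
    every one of the 4^8 windows, for a random seed."""
    seed7 = "".join(rng.choice(list("ACGT"), size=7))
    fam = MirnaFamily("f", seed7)
    for bases in itertools.product("ACGT", repeat=8):
        window = "".join(bases)
        assert classify_window(window, fam) == oracle_classify(window, seed7), window


def test_site_type_partition_is_exclusive(example_family):
    """No 8-nt window is assigned more than one type: the anchors' inequality
    conditions make the three types mutually exclusive by construction, so a
    full enumeration never sees a conflict with the oracle's if-chain."""
    counts = {"8mer": 0, "7mer-m8": 0, "7mer-A1": 0, None: 0}
    for bases in itertools.product("ACGT", repeat=8):
        counts[classify_window("".join(bases), example_family)] += 1
    # one 8mer; 3 tails != A; 3 leads != m8
    assert counts["8mer"] == 1 and counts["7mer-m8"] == 3 and counts["7mer-A1"] == 3


def test_scan_sites_spans_and_overlaps(example_family):
    # no core anywhere
    assert scan_sites("ACACACACACAC", example_family) == []
    # 8mer planted at offset 10 (0-based): ...A TAAGCT A...
    seq = "C" * 9 + "ATAAGCTA" + "C" * 9
    hits = scan_sites(seq, example_family)
    assert hits == [((10, 17), "8mer")]
    # tandem duplication -> two independent hits
    seq2 = "C" * 4 + "ATAAGCTA" + "ATAAGCTA" + "C" * 4
    hits2 = scan_sites(seq2, example_family)
    assert len(hits2) == 2 and all(t == "8mer" for _, t in hits2)


def test_scan_sites_matches_window_oracle_on_random_sequences(rng):
    fam = MirnaFamily("f", "".join(rng.choice(list("ACGT"), size=7)))
    for _ in range(50):
        # seed the core into the sequence a few times to ensure hits occur
        seq = list(rng.choice(list("ACGT"), size=120))
        for _ in range(3):
            i = int(rng.integers(0, 110))
            seq[i:i + 6] = list(fam.core)
        seq = "".join(seq)
        assert scan_sites(seq, fam) == oracle_scan(seq, fam.seed7)


def test_allele_sequences_window_and_truncation():
    utr = "ACGTACGTACGT"  # 12 nt
    snp = SnpRecord("s1", "tx", 5, "A", "G")
    ref, alt, offset = allele_sequences(utr, snp, flank=7)
    assert ref == utr and offset == 1
    assert alt == "ACGTGCGTACGT"
    # away from the edges a flank of 10 gives a 21-nt window
    utr2 = "C" * 15 + "A" + "C" * 15
    ref2, alt2, off2 = allele_sequences(utr2, SnpRecord("s2", "tx", 16, "A", "T"), flank=10)
    assert len(ref2) == 21 and off2 == 6 and alt2[10] == "T"


def test_allele_sequences_reference_mismatch_names_snp():
    with pytest.raises(ReferenceMismatchError, match="s1"):
        allele_sequences("ACGT", SnpRecord("s1", "tx", 2, "A", "G"), flank=7)


def test_call_snp_sites_cr_and_ds(example_family):
    # alt allele A completes the 8mer ATAAGCTA; ref G breaks the core
    seq = "C" * 10 + "ATAGGCTA" + "C" * 10
    snp = SnpRecord("rs1", "tx", 14, "G", "A")  # core position
    calls = call_snp_sites(seq, snp, [example_family])
    assert len(calls) == 1
    site = calls[0]
    assert site.mutation_class == CLASS_CR and site.site_type == "8mer"
    assert site.span == (11, 18) and site.span[0] <= snp.utr_pos <= site.span[1]
    # swapping ref/alt turns the CR call into a DS call at the same span
    seq_sw = seq[:13] + "A" + seq[14:]
    calls_sw = call_snp_sites(seq_sw, snp.swapped(), [example_family])
    assert len(calls_sw) == 1
    assert calls_sw[0].mutation_class == CLASS_DS
    assert calls_sw[0].span == site.span and calls_sw[0].site_type == site.site_type


def test_call_snp_sites_snp_outside_window(example_family):
    seq = "ATAAGCTA" + "C" * 30
    snp = SnpRecord("rs1", "tx", 25, "C", "T")
    assert call_snp_sites(seq, snp, [example_family]) == []


def test_ds_cr_antisymmetry_on_random_planted_snps(rng):
    """Exchanging ref and alt maps every DS call to a CR call at the same
    span and vice versa, over randomly planted SNPs."""
    mapping = {CLASS_DS: CLASS_CR, CLASS_CR: CLASS_DS}
    n_nonempty = 0
    for _ in range(300):
        fam = MirnaFamily("f", "".join(rng.choice(list("ACGT"), size=7)))
        seq = list(rng.choice(list("ACGT"), size=40))
        if rng.random() < 0.7:  # plant the full 8mer so calls actually occur
            i = int(rng.integers(1, 31))
            seq[i:i + 8] = list(fam.m8 + fam.core + "A")
        pos0 = int(rng.integers(0, 40))
        ref = seq[pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snp = SnpRecord("rs", "tx", pos0 + 1, ref, alt)
        fwd = call_snp_sites("".join(seq), snp, [fam], include_type_changed=True)
        seq_sw = list(seq)
        seq_sw[pos0] = alt
        rev = call_snp_sites("".join(seq_sw), snp.swapped(), [fam],
                             include_type_changed=True)
        fwd_key = sorted((s.span, s.site_type,
                          mapping.get(s.mutation_class, s.mutation_class)) for s in fwd)
        rev_key = sorted((s.span, s.site_type, s.mutation_class) for s in rev)
        assert fwd_key == rev_key
        n_nonempty += bool(fwd)
    assert n_nonempty > 30  # the property was exercised on real calls


def test_every_emitted_site_contains_the_snp(rng):
    for _ in range(100):
        fam = MirnaFamily("f", "".join(rng.choice(list("ACGT"), size=7)))
        seq = list(rng.choice(list("ACGT"), size=60))
        i = int(rng.integers(1, 50))
        seq[i:i + 8] = list(fam.m8 + fam.core + "A")
        pos0 = int(rng.integers(max(0, i - 3), min(60, i + 11)))
        ref = seq[pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snp = SnpRecord("rs", "tx", pos0 + 1, ref, alt)
        for site in call_snp_sites("".join(seq), snp, [fam], include_type_changed=True):
            assert site.span[0] <= snp.utr_pos <= site.span[1]


def _snp(i, pos, maf, tx="tx"):
    return SnpRecord(f"rs{i}", tx, pos, "A", "G", maf)


def test_filter_in_snps_maf_is_strictly_over_threshold():
    kept = filter_in_snps([_snp(1, 100, 0.09), _snp(2, 200, 0.11), _snp(3, 300, 0.10)])
    assert [s.snp_id for s in kept] == ["rs2"]


def test_filter_in_snps_min_gap_boundary():
    # distance 5 -> second dropped; distance exactly 10 -> both kept
    kept = filter_in_snps([_snp(1, 100, 0.3), _snp(2, 105, 0.3)])
    assert [s.snp_id for s in kept] == ["rs1"]
    kept2 = filter_in_snps([_snp(1, 100, 0.3), _snp(2, 110, 0.3)])
    assert [s.snp_id for s in kept2] == ["rs1", "rs2"]


def test_filter_in_snps_gap_applies_per_transcript():
    kept = filter_in_snps([_snp(1, 100, 0.3, "txA"), _snp(2, 105, 0.3, "txB")])
    assert len(kept) == 2


def test_filter_in_snps_sorts_unsorted_input_with_warning():
    with pytest.warns(UserWarning, match="not sorted"):
        kept = filter_in_snps([_snp(2, 105, 0.3), _snp(1, 100, 0.3)])
    assert [s.snp_id for s in kept] == ["rs1"]
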