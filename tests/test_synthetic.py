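"""The synthetic-study generator against its planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from helpers import oracle_scan
from snpmprm.expression import DetectionMatrix, expressed_mirnas
from snpmprm.genotype import maf
from snpmprm.seed_sites import MirnaFamily, call_snp_sites
from snpmprm.synthetic import (GenerationError, LdPair, PlantedModule, SnpSpec,
                               StudyConfig, default_families, gen_expression,
                               gen_genotype_table, gen_genotypes_hwe,
                               gen_haplotype_pair_genotypes, gen_mirna_detection,
                               gen_study, gen_utr_with_sites, recovery_study_config)


def test_hwe_generator_rejects_monomorphic_and_bad_maf():
    with pytest.raises(ValueError):
        gen_genotypes_hwe(0.0, 10, 1)
    with pytest.raises(ValueError):
        gen_genotypes_hwe(0.6, 10, 1)


def test_hwe_generator_allele_frequency_within_sampling_error():
    codes = gen_genotypes_hwe(0.5, 10000, 42)
    # observed alt frequency within 3 binomial SEs of 0.5
    assert abs(maf(codes) - 0.5) < 3 * np.sqrt(0.25 / 20000) or maf(codes) == 0.5
    freqs = {c: np.mean(codes == c) for c in "RHO"}
    assert freqs["H"] == pytest.approx(0.5, abs=0.02)


def test_hwe_generator_genotype_frequencies_converge():
    p = 0.3  # alt-allele frequency
    codes = gen_genotypes_hwe(p, 10000, 7)
    se = 3 * np.sqrt(0.25 / 10000)
    assert np.mean(codes == "O") == pytest.approx(p * p, abs=se)
    assert np.mean(codes == "H") == pytest.approx(2 * p * (1 - p), abs=se)


def test_generators_are_deterministic():
    assert np.array_equal(gen_genotypes_hwe(0.3, 100, 5), gen_genotypes_hwe(0.3, 100, 5))
    a1, b1, h1 = gen_haplotype_pair_genotypes(0.5, 0.4, 0.3, 50, 11)
    a2, b2, h2 = gen_haplotype_pair_genotypes(0.5, 0.4, 0.3, 50, 11)
    assert np.array_equal(a1, a2) and np.array_equal(b1, b2) and np.array_equal(h1, h2)


def test_haplotype_pair_complete_coupling_only_rr_and_oo():
    a, b, hap = gen_haplotype_pair_genotypes(0.5, 0.5, 0.5, 500, 3)
    assert set(zip(a.tolist(), b.tolist())) <= {("R", "R"), ("H", "H"), ("O", "O")}
    assert hap[1] == hap[2] == 0  # only AB and ab haplotypes exist


def test_haplotype_pair_infeasible_p11_rejected():
    with pytest.raises(ValueError):
        gen_haplotype_pair_genotypes(0.2, 0.4, 0.30, 10, 1)  # > min(pA, pB)


def test_haplotype_pair_sample_r2_near_target(rng):
    # pA=0.2, pB=0.4, P11=0.14 -> population r2 = 0.09375
    r2s = []
    for _ in range(10):
        _, _, hap = gen_haplotype_pair_genotypes(0.2, 0.4, 0.14, 5000,
                                                 int(rng.integers(2 ** 31)))
        f = hap / hap.sum()
        pa, pb = f[0] + f[1], f[0] + f[2]
        r2s.append((f[0] - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))
    assert np.mean(r2s) == pytest.approx(0.09375, abs=0.01)
    _, _, hap_eq = gen_haplotype_pair_genotypes(0.5, 0.5, 0.25, 5000, 1)
    f = hap_eq / hap_eq.sum()
    assert abs(f[0] - (f[0] + f[1]) * (f[0] + f[2])) < 0.02  # ~equilibrium


def _one_site_config(mutation_class, site_type, seed=0):
    fam = MirnaFamily("famZ", "AGCTTAT", ("hsa-mir-z",))
    on = fam.core[2]  # 'A' of TAAGCT
    off = "G"
    ref, alt = (on, off) if mutation_class == "DS" else (off, on)
    spec = SnpSpec("rs1", 0.3, 25, ref, alt)
    mod = PlantedModule("rs1", "famZ", mutation_class, -0.5, site_type)
    return StudyConfig(n_samples=40, snp_specs=[spec], planted_modules=[mod],
                       families=[fam], seed=seed), fam


@pytest.mark.parametrize("cls,styp", [
    ("DS", "8mer"), ("CR", "8mer"), ("DS", "7mer-m8"), ("CR", "7mer-A1"),
])
def test_planted_site_recovered_exactly(cls, styp):
    config, fam = _one_site_config(cls, styp)
    utrs, records, truth = gen_utr_with_sites(config, [fam], seed=9)
    assert len(truth) == 1
    row = truth.iloc[0]
    assert row.mutation_class == cls and row.site_type == styp
    calls = call_snp_sites(utrs[records[0].transcript_id], records[0], [fam])
    assert len(calls) == 1
    call = calls[0]
    assert call.mutation_class == cls and call.site_type == styp
    assert call.span == (row.span_start, row.span_end)


def test_planted_ds_8mer_confirmed_by_window_oracle():
    config, fam = _one_site_config("DS", "8mer")
    utrs, records, truth = gen_utr_with_sites(config, [fam], seed=4)
    hits = oracle_scan(utrs[records[0].transcript_id], fam.seed7)
    assert hits == [((truth.iloc[0].span_start, truth.iloc[0].span_end), "8mer")]


def test_background_contains_no_incidental_matches():
    fams = default_families(6)
    specs = [SnpSpec(f"rs{i}", 0.3, 30, "A", "G") for i in range(1, 21)]
    config = StudyConfig(n_samples=10, snp_specs=specs, families=fams,
                         utr_length=500, seed=2)
    utrs, records, truth = gen_utr_with_sites(config, fams, seed=2)
    assert truth.empty
    for rec in records:
        assert call_snp_sites(utrs[rec.transcript_id], rec, fams) == []
        for fam in fams:
            assert oracle_scan(utrs[rec.transcript_id], fam.seed7) == []


def test_impossible_placement_raises():
    fam = MirnaFamily("famZ", "AAATTAT")  # core TAATTT contains no C or G
    spec = SnpSpec("rs1", 0.3, 25, "C", "G")  # DS needs ref inside the core
    mod = PlantedModule("rs1", "famZ", "DS", -0.5, "8mer")
    config = StudyConfig(n_samples=10, snp_specs=[spec], planted_modules=[mod],
                         families=[fam])
    with pytest.raises(GenerationError):
        gen_utr_with_sites(config, [fam], seed=0)


def test_expression_noise_free_limit_group_means():
    config, fam = _one_site_config("CR", "8mer")
    config.noise_sd = 1e-12
    config.sex_effects = (0.1, 0.1)
    genotypes = gen_genotype_table(config, seed=1)
    expr, sex = gen_expression(config, genotypes, seed=1, include_background=False)
    y = expr.iloc[0].to_numpy()
    ca = genotypes.ca_counts("rs1", "CR")
    for level, expected in ((0, 7.1), (1, 6.6), (2, 6.1)):  # mu + s - 0.5*ca
        if np.any(ca == level):
            assert y[ca == level] == pytest.approx(expected, abs=1e-9)


def test_expression_deterministic_and_missing_snp_rejected():
    config, fam = _one_site_config("DS", "8mer")
    genotypes = gen_genotype_table(config, seed=1)
    e1, _ = gen_expression(config, genotypes, seed=5)
    e2, _ = gen_expression(config, genotypes, seed=5)
    pd.testing.assert_frame_equal(e1, e2)
    config.planted_modules[0] = PlantedModule("rs_missing", "famZ", "DS", -0.5)
    config.snp_specs.append(SnpSpec("rs_missing", 0.3, 25, "A", "G"))
    with pytest.raises(ValueError, match="rs_missing"):
        gen_expression(config, gen_genotype_table(
            _one_site_config("DS", "8mer")[0], seed=1), seed=5)


def test_detection_generator_separates_expressed_set():
    all_ids = [f"m{i}" for i in range(700)]
    expressed = set(all_ids[:200])
    det = gen_mirna_detection(expressed, all_ids, n_samples=90, seed=8)
    recovered = expressed_mirnas(DetectionMatrix(det))
    assert len(recovered & expressed) / len(expressed) >= 0.95
    # null contract: with nothing expressed the filter returns ~nothing
    det_null = gen_mirna_detection(set(), all_ids[:100], n_samples=90, seed=8)
    assert len(expressed_mirnas(DetectionMatrix(det_null))) <= 5
    # everything expressed -> everything returned
    det_all = gen_mirna_detection(set(all_ids[:50]), all_ids[:50], 90, 8)
    assert expressed_mirnas(DetectionMatrix(det_all)) == set(all_ids[:50])


def test_gen_study_bundle_reproducible_and_consistent(tmp_path):
    config = recovery_study_config(seed=3, n_samples=30, n_modules=2, n_null_sites=8)
    b1 = gen_study(config, tmp_path / "a")
    b2 = gen_study(config, tmp_path / "b")
    for f1, f2 in zip(vars(b1).values(), vars(b2).values()):
        assert f1.read_bytes() == f2.read_bytes()
    truth = pd.read_csv(b1.truth_table, sep="\t")
    assert len(truth) == 10  # every planted site (2 effects + 8 nulls)
    assert (truth.beta != 0).sum() == 2
    # same sample ids everywhere
    geno = pd.read_csv(b1.genotype_table, sep="\t")
    expr = pd.read_csv(b1.gene_expression, sep="\t", index_col=0)
    samples = [c for c in geno.columns if c not in ("snp_id", "ref", "alt")]
    assert list(expr.columns) == samples


def test_gen_study_seed_changes_genotypes(tmp_path):
    c1 = recovery_study_config(seed=3, n_samples=30, n_modules=1, n_null_sites=4)
    c2 = recovery_study_config(seed=4, n_samples=30, n_modules=1, n_null_sites=4)
    b1 = gen_study(c1, tmp_path / "a")
    b2 = gen_study(c2, tmp_path / "b")
    assert b1.genotype_table.read_bytes() != b2.genotype_table.read_bytes()
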