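# Methods

This note documents the models, numerical choices and limitations behind
`snpmprm`, in the order the pipeline applies them.

## Canonical site model

A miRNA family is represented by its 7-nt seed (mature nucleotides 2–8,
stored DNA-alphabet; RNA input is mapped U→T because the UTR sequences are
genomic DNA on the mRNA sense strand). Writing `core` for the reverse
complement of seed nucleotides 2–7 and `m8` for the complement of
nucleotide 8, an 8-nt mRNA window (read 5′→3′, its last base facing miRNA
nucleotide 1) is classified as:

- **8mer** — window = `m8 + core + A`;
- **7mer-m8** — first 7 bases = `m8 + core`, last base ≠ A;
- **7mer-A1** — bases 2–8 = `core + A`, first base ≠ `m8`.

The inequality conditions make the three types mutually exclusive; only
perfect Watson–Crick seed complementarity counts (no wobble pairing, no
3′-compensatory sites, no context scoring, no conservation filter). Sites
are reported as 1-based closed intervals: the full window for an 8mer,
window bases 1–7 for a 7mer-m8, bases 2–8 for a 7mer-A1. Sites whose core
would begin at the first base of the sequence are not reported, because no
complete 8-nt window exists for them — consistent with the brute-force
window enumeration used as the test oracle.

**Allele-aware calling.** For each SNP a window of ±`flank` nt (default 10,
which is ≥ site length − 1 and therefore covers every site overlapping the
SNP) is excised twice, once per allele, and both versions are scanned for
every family. A site found with the reference allele only is disrupted
(DS); with the alternative only, created (CR). Sites found with both
alleles cancel; a DS and a CR candidate of the same family with overlapping
spans indicate a *type change* (e.g. 8mer → 7mer-m8 when only an anchor
base flips) and are excluded from DS/CR outputs by default, since calling
either class would overstate the event. Only sites whose span contains the
SNP position are reported. Multi-allelic variants are rejected: the design
targets bi-allelic SNP panels.

**Informative SNPs.** SNPs are kept when MAF is strictly above 0.1 (small
cohorts give unstable association estimates below that), and a SNP closer
than 10 nt to the immediately preceding SNP of the same transcript is
dropped — the preceding SNP counts whether or not it was itself retained,
and a distance of exactly 10 nt is kept (strict inequality).

## Genotype coding and the TSE model

Unphased bi-allelic genotypes are recoded R (hom. reference), H (het.),
O (hom. alternative), N (missing or unexpected allele; N is a logged sink
state, never an error). The consistent-allele count x of a sample is the
number of chromosomes carrying the *intact* site: DS maps R/H/O → 2/1/0,
CR maps R/H/O → 0/1/2, so x always counts functional sites regardless of
which allele carries them (the two mappings sum to 2 for every code).

The target-site effect is the slope β in

    y_ij = μ + s_i + β·x_j + e_ij,

fitted by ordinary least squares with an intercept, a treatment-coded sex
factor (dropped automatically, with a log entry, when only one sex is
present) and x as a *numeric* covariate — the model is additive by
construction, matching the count interpretation of x. Inference on β is
the two-sided t-test; with zero residual variance (exact data) the p-value
degenerates to 0 for β ≠ 0. Missing genotypes are handled complete-case
per fit, not imputed. A fit is attempted only when at least two CA levels
are occupied and every occupied level holds ≥ 3 samples (`min_group`),
guarding against MAF-boundary instability; skipped sites are logged in the
failure census.

BH correction is applied per population and per analysis level (gene-level
and exon-level families corrected separately), implemented via
`statsmodels.multipletests(method="fdr_bh")` behind a single `bh_adjust`
surface and verified in the tests against the literal min-over-suffix
step-up formula. A module is called when (i) the family has at least one
expressed member miRNA, (ii) the target feature is expressed, (iii) β < 0,
(iv) adj.p < 0.05. The additive-pattern check (group medians of y
non-increasing in x, tolerance 0 by default) is advisory — recorded on
every record, enforced only in strict mode — because it is a qualitative
box-plot criterion rather than a test.

**Expressed filters.** miRNAs: per-miRNA median detection p-value across
samples, BH across miRNAs, keep adj.p < 0.05. Genes: the data do not fix a
rule, so the default — median log2 intensity above the 25th percentile of
all feature medians — is explicit, overridable, and written to the run log
on every use; exon-level ratios carry no absolute abundance, so no
intensity filter is applied at that level.

## Linkage disequilibrium

With reference-allele frequencies p_A, p_B (counted directly from the
genotype margins) and P₁₁ the reference–reference haplotype probability,
D = P₁₁ − p_A·p_B and r² = D²/(p_A q_A p_B q_B). Only the double
heterozygotes (HH) are phase-ambiguous, so P₁₁ is the only free parameter;
it is estimated by maximising the nine-class multinomial likelihood under
random union of gametes using the gene-counting update

    P₁₁ ← [2N_RR + N_RH + N_HR + N_HH · w] / 2N,
    w = P₁₁P₂₂ / (P₁₁P₂₂ + P₁₂P₂₁),

whose fixed points satisfy the classical cubic likelihood equation. Every
iterate is projected into the intersection of the counting bounds
(lower: haplotypes that are unambiguously reference–reference; upper:
lower + one per double heterozygote, both over 2N) with the Fréchet bounds
[max(0, p_A+p_B−1), min(p_A, p_B)]. The constrained estimate can never
leave the feasible haplotype simplex, which is what guarantees r² ∈ [0, 1].
Initialisation is the equilibrium value p_A·p_B clamped into the bounds;
convergence tolerance 1e-10, cap 1000 iterations (non-convergence is
flagged, not raised). Tables with no double heterozygotes are solved
exactly in one step. A vectorised grid search over the same likelihood
(step 1e-5) serves as the reference optimiser in the tests and the
reproduction script; observed disagreement is below one grid step
(~5e-6 over 500 random tables).

Significance: n·r² with n = 2N haplotypes is asymptotically χ²(1) under
r² = 0; N instead of 2N is selectable (`chi2_n_stat`) since either
convention appears in practice. Phase is coupling for D > 0, repulsion for
D < 0, equilibrium at D = 0 (then r² = 0, p = 1). The pseudo-LD
alternative codes R/H/O as 1/0/−1 and squares the Pearson correlation; its
significance comes from the Fisher z-transform or from an empirical null of
K random panel locus pairs (p floored at 1/(K+1), default K = 10,000).

**Cis-marker linking.** A documented marker that is itself a site SNP of
the same gene links with r² = 1 (identity); otherwise every site SNP of
the gene is tested and pairs with raw LD p < 0.01 are kept — raw, not
FDR-adjusted, deliberately asymmetric to the BH-corrected TSE side. The
exon-level TSE is then fitted on the log2 exon/gene ratio of the linked
probe set, which cancels gene-level abundance and isolates the
exon-specific signal.

## Synthetic studies

The generator emulates the study conditions end to end with known truth:

- **Genotypes** under Hardy–Weinberg at a configured alternative-allele
  frequency; LD pairs are drawn as two i.i.d. phased haplotypes per
  individual from (P₁₁, P₁₂, P₂₁, P₂₂) and collapsed to unphased codes,
  with the true haplotype counts returned for oracle checks.
- **UTRs**: one transcript per SNP (default 60 nt). A planted DS/CR site
  embeds the exact site window with the SNP at a position where the
  "on" allele completes the match and the "off" allele breaks it — core
  positions always qualify; the m8 anchor only for 7mer-m8 and the A1
  anchor only for 7mer-A1, because anchor flips on the other types produce
  type changes, not clean gains/losses. Backgrounds are rejection-sampled
  (bounded retries) so neither allele sequence carries any incidental site
  for the *configured* families; decoy families may still match, which is
  intentional specificity realism.
- **Expression**: y = μ + s + β·x + e on the log2 scale directly (defaults
  μ = 7, sex effects (0, 0.2), noise SD 0.3 — the noise level is a
  calibration choice, not an empirical estimate; the planted-recovery
  study uses SD 0.2 with β = −0.6 at n = 90). Sex labels alternate 1/2
  (configurable imbalance). A 40% fraction of unexpressed background
  features around log2 intensity 4 reproduces the low-intensity mode of a
  real array; without it a strongly repressed module gene would be the
  lowest-intensity feature in the study and the quantile-based expressed
  filter would remove exactly the genes of interest.
- **miRNA detection p-values**: expressed miRNAs draw Beta(1, 99)
  (median ≈ 0.007), others Uniform(0, 1), a separation at which the BH
  median filter recovers essentially the whole expressed set at m ≈ 700.

Everything is deterministic given (config, seed): identical inputs produce
byte-identical bundles. What the generator does *not* emulate — probe-level
array artifacts, batch effects, expression correlation between genes,
population structure or more-than-two-locus haplotypes — bounds what
passing tests show: they validate the statistical machinery under the
stated model, not robustness to real-data violations of it.

## Problem sizes and defaults

The reproduction script and acceptance tests use: all 65,536 8-nt windows
× 5 seeds for the classifier oracle; 10,000 null fits (n = 90, SD 0.3,
MAF 0.3) for type-I error; 200 replicates at β = −0.4 for bias/coverage;
500 random tables (n = 100) against the grid oracle plus 10,000
adversarial multinomial tables for the r² range; n = 10⁴ haplotype pairs
over true r² ∈ {0, .25, .5, .75, 1} for consistency; and 20 seeded
end-to-end studies (5 planted modules, 500 null sites) for recovery and
false-discovery proportion. All randomness flows from one master seed via
`numpy.random.SeedSequence`.

## Known limitations

- Sites at the extreme 5′ edge of a UTR (core starting at base 1) are not
  callable, as no complete window exists.
- The per-fit sex factor assumes at most two levels; other designs are
  rejected rather than silently absorbed.
- `filter_in_snps` applies the spacing rule after the MAF filter, to the
  retained list; variant orderings of the two rules can keep or drop
  borderline SNPs differently.
- LD estimation fixes (p_A, p_B) at their sample frequencies rather than
  jointly maximising allele and haplotype frequencies — standard practice,
  and consistent with estimating the frequencies directly from the sample.
- The pipeline consumes already-summarised expression matrices; no
  normalisation, probe masking or summarisation is performed.
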