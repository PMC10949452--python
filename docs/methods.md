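# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Variant QC

Two sequential stages. Stage one removes a site if it fails *any* clause of

    QD < 2.0 || MQ < 40.0 || FS > 60.0 || SOR > 3.0 ||
    MQRankSum < -12.5 || ReadPosRankSum < -8.0

All comparisons are strict, so boundary values survive. A missing
annotation never triggers its clause — the convention of the variant-caller
ecosystem these thresholds come from, and the only choice that avoids
discarding sites for absent metadata. Stage two removes indels,
multi-allelic records and sites with QUAL < 70, masks genotypes with depth
< 4 to missing (masking, not site removal, is the documented semantics of
the per-genotype depth flag), and drops sites left with no called genotype.
Sites that become monomorphic after masking are retained by default;
`drop_monomorphic=True` prunes them for stages that need segregating sites.
Both filters are idempotent and never alter a genotype except to missing.

## Nucleotide diversity

Per site, the unbiased estimator π̂ = (n/(n−1))·2p(1−p) over the n
non-missing alleles of the chosen population; window π is the sum over
sites divided by the window width (default 10 kb, tiling each contig from
position 1). π is invariant to sample order and to ref/alt relabeling.

## LD and effective population size

With unphased genotypes, LD is the composite measure: the squared Pearson
correlation of dosage vectors over individuals called at both sites.
For the Ne estimator the squared correlation is additionally scaled by
(S/(S−1))², the Burrows-composite convention. This matters: the plain
squared sample correlation has null expectation ≈ 1/(S−1), while the
sampling-bias formulas used below were calibrated against the Burrows
estimator with expectation 1/S + 3.19/S² (S > 29). A null simulation
(independent binomial dosages, S = 50) reproduces that expectation to five
decimals with the scaling and shows a ~2× upward Ne bias without it.

Ne follows the random-mating LD method: pairs restricted to effectively
unlinked sites (different contigs, or beyond a configurable distance),
minor-allele frequency ≥ 0.05 by default (the usual Pcrit; the source
studies rarely print theirs), S summarized by the harmonic mean across
pairs, and

    r²_drift = mean r² − E[r²|S],   Ne = (1/3 + sqrt(1/9 − 2.76·r²_drift)) / (2·r²_drift)

for S > 29, with the small-sample variants E = 0.0018 + 0.907/S + 4.44/S²
and Ne = (0.308 + sqrt(0.308² − 2.08·r²_drift)) / (2·r²_drift) otherwise.
r²_drift ≤ 0 is reported as infinite Ne (no drift signal above sampling
noise).

## McDonald–Kreitman scan

Functional class: the codon containing a SNP is rebuilt from the reference
(strand-aware), the alternate base substituted, and both codons translated
under the standard genetic code; stop is treated as a 21st amino-acid
state. Codons carrying several variants are classified against the
reference state at the other positions — path enumeration is
under-determined without haplotypes — and a warning counts affected codons.

Segregation class from per-population alt frequencies (p₁, p₂) over
non-missing alleles: fixed difference iff {p₁,p₂} = {0,1}; polymorphic in
one population iff exactly one frequency is internal; shared iff both are.
Shared polymorphisms count once toward P_N/P_S (the species-symmetric
reading of "polymorphism within species"); per-population double counting
is available as an option. An optional within-population MAF cutoff
(default 0, since low-frequency exclusion strongly affects α and the
convention varies between studies) rounds sub-cutoff frequencies to the
nearer of 0/1 before classification, so a shared polymorphism with one
sub-cutoff side degrades gracefully rather than being discarded.

Per gene, Fisher's exact test (two-sided) on [[F_N, F_S], [P_N, P_S]];
genes are called selected when (F_N/F_S)/(P_N/P_S) > 1 *and* p < 0.05 on
the raw p-value — no multiple-testing correction enters the call, because
pooled α is the scan's false-positive correction; a Benjamini–Hochberg
column is emitted for transparency only. "Sufficient polymorphism"
defaults to P_N + P_S ≥ 1 and is reported in output metadata. Pooled
α = 1 − (ΣF_S·ΣP_N)/(ΣF_N·ΣP_S) over qualifying genes (counts pooled, not
gene-wise averaged: the pooled form is stable when individual genes have
empty cells); an optional seeded gene-level bootstrap gives a percentile
CI. The same scan runs unchanged on haploid-coded symbiont VCFs.

## Structure

PCA standardizes dosages by site (mean 2p, scale sqrt(2p(1−p))) and
mean-imputes missing entries. The admixture model is fit by EM on the
binomial likelihood with missing entries excluded (not imputed);
allele-frequency updates are clamped to [1e-6, 1−1e-6]; convergence at
1e-6 log-likelihood change or 2000 iterations. EM is slower than
quasi-Newton but monotonically ascending, which the tests assert
numerically. Cross-validation masks individual genotype cells (the same
scheme as the standard tool), refits per fold, and scores masked entries
by mean binomial deviance; the reported K minimizes this error. The NJ
tree uses allele-sharing distance (1 − matching-dosage proportion) by
default and standard neighbor joining.

## Community stage

Canonical k-mers (lexicographic minimum of a window and its reverse
complement, k = 21) are counted exactly over windows containing only
A/C/G/T. The originating study's k-mer tool does not document its distance
formula, so cosine distance on frequency vectors is the package default —
bounded in [0,1], insensitive to total depth — with euclidean and
Bray–Curtis selectable and the choice recorded in outputs; it is a
documented stand-in, not a claim about the original tool. Unhealthy
samples (pathogen mass strictly > 50%) are removed before profiling, and
depth matching subsamples reads without replacement, seeded, preserving
input order. PCoA double-centers −½d², builds axes from positive
eigenvalues and uses their sum as the explained-variance denominator,
reporting negative eigenvalues without constructing axes from them.
PERMANOVA partitions squared distances (SS_total = Σ_{i<j} d²_ij / n,
within-group analogously), with p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)
under free label permutation; separate single-factor runs correspond to
separate reported statistics. Rank-sum tests enumerate the exact
permutation null (midranks for ties) up to combined n = 20 and use the
tie/continuity-corrected normal approximation above that.

## Synthetic generators: what they emulate, and what not

`simulate_host_populations` is rate-based, not a population-genetic
engine: an ancestral stop-free coding genome; per-gene Poisson counts of
fixed differences with rate divergence × mutational opportunity
(opportunity = counts of synonymous/nonsynonymous single-base changes per
codon, to-stop changes excluded symmetrically from rates and placement);
a planted gene set whose nonsynonymous fixation rate is multiplied
(default 10×, emulating a minority of genes under strong positive
selection); and per-population polymorphisms with Poisson rate
θ × opportunity × a_n (a_n = Σ 1/i), derived-allele counts drawn from the
neutral folded SFS (P(i) ∝ 1/i) so that E[π] = θ exactly. Polymorphisms
are private to one population by default (`shared_poly_rate` exercises the
shared branch). Configs implying more than one expected mutation per codon
are rejected (multi-hit codons would dominate). The generator gives exact
closed-form control of every gene's expected MK table — the property the
recovery tests need — but deliberately omits linkage, demography beyond a
clean split, sweeps, and sequencing error. A green MK test therefore
establishes correct counting and inference on the stated model, not
robustness to demographic confounding.

Because rate-based sites are independent, cross-locus drift LD does not
exist there, and independent coalescent replicates would not carry it
either (their genealogies are independent). `simulate_ld_cohort` therefore
propagates a real forward Wright–Fisher population of unlinked biallelic
loci (random mating, N diploids) for 30 generations — ample, since LD
between unlinked loci halves each generation — and samples S individuals
without replacement. Its census N is the true Ne for recovery tests.

`simulate_metagenomes` draws per-sample compositions from host-specific
Dirichlet concentrations; exactly round(frac_unhealthy × n) samples
(default 7 of 40, matching the cohort scale the package targets) are
overridden with pathogen-dominated compositions (pathogen mass uniform on
0.55–0.95), and healthy compositions are rejection-sampled to pathogen
mass ≤ 0.5, so the planted flags are the exact truth of the > 50% rule.
Reads are uniform error-free substrings of per-taxon random references —
no error model, no shared sequence between taxa, so community distances
here are easier than between real genomes with homology.

Defaults throughout (40-sample cohorts, 20 + 20; ~10³–10⁴ SNPs; 7/40
pathogen-dominated) mirror the scale of the field studies this pipeline is
patterned on while staying desk-sized.

### Chosen regimes for calibration tests

Fisher's exact test is conservative on sparse tables: measured null
rejection at p < 0.05 is ~1–3% when per-gene counts are small, approaching
nominal only for dense, balanced tables. The neutral calibration world
(600-codon genes, divergence 0.08/site, θ 0.0085/site, giving balanced
fixed/polymorphic margins of order 10²) was chosen from a
pre-implementation probe of Fisher's size so that the near-nominal premise
of the type-I-error check holds; at that scale measured null rejection is
≈ 0.049. This is a property of the test's discreteness, not of the
implementation.

## Known limitations

- No recombination map or phased haplotypes; all LD is composite.
- The admixture EM can need many iterations near flat ridges; the CV
  procedure caps iterations per fold and relies on the argmin over K,
  which is robust to modest under-convergence.
- α is pooled-count only; the weighted-average variant is stubbed but not
  used (the originating procedure admits both readings).
- k-mer profiles are exact dictionaries — fine at desk scale, not a
  sketching engine for deep metagenomes.
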