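# Methods

`highevo` implements the computational analysis of a germline
mutagenesis experiment in which a transcription factor (TF) fused to an
activation-induced deaminase (AID) induces heritable C→T / G→A
mutations preferentially near the TF's binding sites, together with a
forward simulator that generates inputs with the statistical structure
the analysis assumes. This note describes the models, the defaults and
why they were chosen, the numerical conventions, and what the simulator
does and does not capture.

## De novo mutation identification

De novo mutations are identified from a joint multi-sample variant call
as variants *private* to a designated sample set. The model behind
this: laboratory stocks carry (i) fixed differences to the reference,
shared by every descendant; (ii) pockets of residual heterozygosity,
shared within a stock; and (iii) rare natural de novo mutations. A
variant shared between mutagenized and non-mutagenized samples must be
standing variation; a variant carried only by mutagenized samples is a
de novo candidate.

The pipeline stages, in fixed order:

1. **Site quality prefilter.** Records with QUAL < 10 are removed from
   the joint call before any subsetting (missing QUAL counts as 0).
2. **Privateness.** A variant is private to a set iff at least one set
   member carries the alternative allele (het or hom-alt, at *any*
   quality) and no sample of the full set outside it carries it — also
   at any quality. This deliberate asymmetry (any-quality vetoes) makes
   privateness strict: a marginal call in a background sample is enough
   to disqualify a candidate. Missing genotypes never count as
   carrying.
3. **Genotype filter ∪ replicate rescue.** Each carrier must have
   depth 10–200 (inclusive) and, for heterozygous calls, at least 3
   reads per allele (AO > 2 and RO > 2). A variant survives if any
   carrier passes — or if two or more samples of one replicate group
   (an isogenic line's replicates, optionally with its sequenced
   parent) carry it, regardless of depth or allele depth: replicates
   share the isogenized chromosome, so concordance is itself evidence.
4. **Cross-set coverage.** A variant private to one set is kept only if
   its site has a non-missing call in ≥ 2 samples of the opposite set;
   otherwise the absence of carriers there could be missingness, not
   absence.
5. **Introgression screen.** A sample carrying ≥ 20 private variants
   inside any 100 kb window of one chromosome (both defaults
   configurable) is flagged as carrying foreign genetic background —
   a linkage block, not independent de novo mutations — removed, and
   privateness is recomputed from scratch without it. Recomputation
   can *add* variants (a flagged carrier may have been the
   disqualifying sample); the ledger records additions separately.
6. **Mean-depth exclusion.** For counting, samples below a
   per-chromosome mean-depth threshold are dropped (defaults: 9× for
   chr2-like, 5× for chr3-like chromosomes, 5× otherwise).

Every stage writes a row to a removal ledger so the fraction of the
joint call eliminated per stage is reportable. All quoted bounds are
closed as printed: QUAL ≥ 10 kept, depth ∈ [10, 200], AO > 2 strict,
mean depth = 9.0 retained.

Multi-allelic records are decomposed on read: one biallelic record per
ALT allele; a genotype's copies of *other* ALT alleles count as
reference for that record's zygosity. AO is per-allele, RO shared.
MNPs and indels are carried verbatim as single records.

A reversion audit counts sites at which every background sample is
homozygous for the alternative allele and checks whether any mutagenized
sample reverted toward the reference — the one configuration where a
reference-matching de novo mutation would be visible.

## Mutation-rate estimation

On a chromosome isogenized from a single sampled copy, the per-base
per-generation rate is estimated as

    u = Nvar / (nbp × G)

with `Nvar` the number of private mutations carried by the line, `nbp`
the number of callable bases (positions covered by 10–200 reads in the
sample), and `G` the generation count. The isogenized chromosome
harvests one chromosome copy — half the variation of the diploid
individual — so `nbp` rather than `2·nbp` is used and `u` is on the
scale of a diploid genome. When replicates of a line disagree in
`Nvar`, the larger count is used (discordance is nearly always dropout
in the lower-coverage replicate). The aggregate is the arithmetic mean
across lines; both SE (SD/√n) and SD are exposed, since a bare "±" in a
report does not say which it is.

## Spectrum and contingency statistics

Variants are classified as deaminase-signature SNPs (C→T or G→A),
other SNPs, insertions, deletions, or MNPs; the classes partition the
set. Signature fractions are reported against both denominators (all
variants; SNPs only). Zygosity fractions are computed over carrier
*occurrences* (sum of carriers across variants), singleton fractions
over variants. Enrichment of the signature in mutagenized vs
background variants is tested with Fisher's exact test; the reported
odds ratio is the sample cross-product (a·d)/(b·c), not the
conditional MLE — the two differ for extreme tables, and the
cross-product is what the published summary statistics correspond to.
A zero off-diagonal cell yields an infinite odds ratio, flagged rather
than clipped; the p-value is computed regardless. Percentages are
rounded half-up to one decimal.

## Regulatory-proximity enrichment

PWM scanning computes log-odds scores Σ log(p_i(base)/bg(base)) on
both strands at every offset; windows containing N are skipped. A
pseudocount of 0.01 is added when a matrix cell is 0. The default hit
threshold is 60 % of the maximal achievable score (configurable, or an
absolute log-odds threshold). Hits are chained into motif clusters
while the gap between consecutive hits is ≤ 35 bp; chains with ≥ 2
hits become cluster intervals. These defaults play the role
cluster-buster-style scanners play in ChIP-era workflows and are
deliberately simple and configurable.

Distances from a 1-based variant position to a 0-based half-open
interval track are 0 inside an interval and otherwise
`min(start − p0, p0 − (end − 1))` with `p0 = pos − 1` — the symmetric
step distance where a position immediately adjacent to an interval has
distance 1. "Within W bp" means distance ≤ W. A prefix-cummax over
interval ends makes the query exact for nested and overlapping
intervals.

The enrichment test compares focal variants with a catalogue of
natural background variants: per replicate, 10,000 background
positions are drawn (without replacement when the pool allows,
otherwise with replacement, logged), a 2×2 table (focal/background ×
within/beyond 100 bp) is built per feature track, Fisher's exact test
applied, and Benjamini–Hochberg correction applied across tracks
within the replicate. 500 replicates give the distribution of odds
ratios and p-values. Distances are precomputed once per track, so
replicates only re-draw indices. Note that the focal set is fixed
across replicates by design — replicate variation reflects background
sampling only, so replicate p-values are correlated; a null-uniformity
check must therefore redraw the focal set per replicate (the test
suite does exactly that, calling the procedure with `n_reps=1` per
fresh focal draw).

200 bp windows centered on each deaminase-signature SNP (variant at
1-based position ⌈width/2⌉ = 100 of the window) are exported as FASTA
for external de novo motif discovery; windows truncated at chromosome
ends are N-padded and flagged. Mutations found in the focal sets of
two TF analyses are kept in both, with the overlap fraction (shared /
distinct positions) reported.

## The forward simulator

The simulator emulates the experiment end to end so every downstream
stage is testable without any sequencing download.

**Genome.** Random i.i.d. sequence at configurable GC (default 0.42,
typical for Drosophila euchromatin) with `n_motif_sites` planted PWM
matches (sampled from the PWM, within a mismatch allowance of the
consensus) placed uniformly without overlap, and peak intervals
(default 500 bp) centered on a subset of sites. The default PWM is a
synthetic homeodomain-style matrix built in code.

**Standing variation.** Each stock carries private fixed homozygous
differences (Poisson, default 1×10⁻⁴ per base) and pockets of residual
heterozygosity (default five 50 kb pockets with heterozygous variants
at 1×10⁻⁴ per base, shared by all individuals of the stock). Both
densities are deliberately set below the introgression screen's
default density (20 variants / 100 kb): stock variation is genuine
standing variation and in the emulated design — as in the real one —
must pass the screen. In `simulate_experiment`, individuals of stocks
other than the mutagenized founder stock enter the full sample set
only (like auxiliary balancer stocks), not the background contrast
set.

**Mutagenesis.** Discrete generations; per lineage and generation,
mutation counts are Poisson with per-base rate `base_rate` outside
target windows and `base_rate × target_rate_multiplier` inside windows
of ±100 bp around each motif site. `base_rate` defaults to the
endogenous Drosophila rate of 8.4×10⁻⁹ per base per generation
(diploid scale). The multiplier is a free knob (default 50, giving
roughly ten-fold genome-wide elevation at default window coverage —
the genome-wide elevation, not the per-site multiplier, is the
empirically anchored quantity). With probability
`deamination_fraction` (default 0.85) an induced mutation is a
deaminase event at a C or G (C→T, G→A); otherwise a uniform other
substitution at a uniform position. Each mutation is heterozygous
with probability `het_fraction` (default 0.883, matching observed
zygosity proportions) — a shortcut for explicit meiotic bookkeeping,
which is not modeled. Lineages inherit all earlier mutations;
overlapping generations and selection are not modeled.

**Isogenization.** One chromosome copy is sampled from a lineage:
heterozygous mutations survive with probability 1/2 and become
homozygous, homozygous mutations always survive; founder-stock pocket
variants on the isogenized chromosome are resolved the same way.
Replicate samples of a line share the resolved chromosome exactly.
The crossing scheme itself (balancer genetics) is abstracted away.

**Sequencing emission.** Depth per 1 kb block is negative-binomial
around `mean_depth` (default 19.2×) with variance m + φm² (φ default
0.2; φ = 0 gives constant depth). At each truth site, ALT observations
are Binomial(DP, p) with p the dosage fraction adjusted by a per-read
error rate (default 0.002); genotypes are called by allele-fraction
thresholds (≤ 0.15 hom-ref, ≥ 0.85 hom-alt, else het) and emitted
missing below a depth cutoff (default 5). True variants receive QUAL
≥ 50; injected artifact records (default 10 % of emitted records,
emulating the large low-quality fraction of raw joint calls) receive
QUAL < 10. All randomness flows from a single generator, so a fixed
seed reproduces emitted files byte for byte.

**Effective rate calibration.** The expected value of the estimator on
an isogenized chromosome is

    E[u] = base_rate × (1 + f·(m − 1)) × (h/2 + (1 − h))

with f the target-window coverage of the chromosome, m the multiplier
and h the het fraction; `calibrate_base_rate` inverts this so
simulations can be run at a prescribed effective rate. This identity
is what "parameter recovery" tests recover through the full pipeline.

**What the simulator does not capture.** Read-level errors (mapping,
duplicates), indel and MNP mutations (induced mutations are SNPs only;
the spectrum classes exist for real data), linked selection,
sterility/lethality of lines, overlapping generations, shared ancestry
among sampled individuals of one population (each lineage is
independent, so simulated diploid individuals have almost no shared
mutations), and chromosome-specific background structure. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not robustness to every artifact of
real short-read data.

## Problem sizes used in validation

Validation runs use desk-scale genomes: parameter recovery uses 20
isogenic lines (2 replicates each) on a 10 Mb chromosome at effective
rate 5×10⁻⁸ and G = 10 with noise-free sequencing (constant depth, no
errors, no missingness, no artifacts), repeated over 10 seeds;
enrichment power and null calibration use a 1 Mb genome with 100 motif
sites and 500 resampling replicates against pools of 20,000–30,000
background positions; oracle-equivalence checks use 100 randomized
joint tables of up to 500 variants × 20 samples against nested-loop
reference implementations. These sizes keep full validation runs in
the minutes range on one CPU while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- Privateness recomputation after introgression removal is done once,
  not iterated to a fixed point; a sample that becomes flaggable only
  after another's removal is not re-screened (matching the one-pass
  reading of the original design).
- The cross-set coverage rule counts all manifest samples of the
  opposite set present in the joint call, including samples later
  dropped by the mean-depth exclusion.
- `u` has no bootstrap confidence interval over sites; the aggregate
  SE across lines is the only dispersion reported.
- The enrichment test treats background-pool positions as exchangeable
  with focal positions; matching by chromosome is supported (supply
  per-chromosome pools) but no finer covariate matching is done.
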