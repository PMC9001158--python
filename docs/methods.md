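# Methods

## Data model

The pipeline's central object is a `GenotypeTable`: individuals × biallelic
loci with a genotype call (A1A1 / A1A2 / A2A2 / MISSING) and per-allele
read depths per cell, plus per-sample metadata (pond, replicate group,
total reads). Alleles are raw VCF REF/ALT; orientation to the L
(*P. lessonae*) and R (*P. ridibundus* complex) genomes is established
later by diagnostic-locus discovery. Two invariants are enforced on
validation: MISSING cells carry zero depth, and a heterozygous call is
supported by at least one read of each allele. VCF 4.x (with the `AD`
FORMAT field) is the interchange format; a long-format TSV dialect
(`individual, locus, allele1_depth, allele2_depth, genotype`) serves
intermediate files and round-trips exactly.

## PCR-duplicate removal

Library adapters carry a degenerate base region (DBR): a random tag
ligated before PCR. Two read pairs are treated as PCR duplicates only when
the prefixes of both mates **and** the DBR agree; independent template
molecules that share an insert (likely for RAD data, where loci are a
finite set of restriction fragments) receive independent DBRs and are both
kept. Choices that the data do not pin down and that are therefore
explicit parameters: the identity key uses a 30-base prefix of each mate
(robust to 3′ quality decay) rather than full-length sequence, and the
representative of each duplicate group is the pair with the highest mean
base quality, ties broken by input order. Deduplication is idempotent and
the kept count equals the number of distinct (prefix1, prefix2, DBR)
triples.

## Quality filters

The cascade runs in a fixed order, each stage on the previous stage's
output:

1. **Depth masking** — calls with summed allele depth < `min_depth`
   (default 8 reads) become MISSING;
2. **MAF** — loci with minor allele frequency < `min_maf` (default 0.05),
   computed allele-wise over called genotypes, are dropped;
3. **Per-SNP missingness** — loci with missing fraction > `mds` dropped;
4. **Per-individual missingness** — individuals with missing fraction >
   `mdi`, measured over the retained loci, dropped.

The order is a design choice: MAF is meaningful only after unreliable
calls are masked, and individual-level missingness only over the final
locus set. A per-stage removal log accounts for every locus and
individual. Technical replicates are resolved before filtering: if a
group's best replicate exceeds 300 000 reads it is kept alone, otherwise
replicates are combined by summing depths cell-wise with consensus
genotypes (conflicts become MISSING). Individuals need more than 50 000
reads to enter the analysis (100 000 for the replicate-based parameter
test).

## Error rate and sweep selection

The SNP-calling error rate is the fraction of discordant cells among those
called in both members of a replicate pair; genotype-level discordance
(any allele differs), not allele-level half-counts. Zero comparable cells
is an error, not a zero rate. A sweep evaluates each assembly setting
under the 3×3 grid of missingness caps (`mds`, `mdi` ∈ {0.30, 0.40,
0.50}), recording loci, individuals, missingness and error rate. The
published analyses of this kind pick the final setting informally ("large
and clean"); here that judgement is a deterministic lexicographic rule:
discard records above the 25th percentile of observed error rates, then
maximize individuals, then loci, then prefer the lower error rate, then
input order. Both the percentile and the grid are configurable.

## Clustering and reference panels

PCA runs on genotypes encoded as counts of allele A2 ∈ {0, 1, 2} with
per-locus mean imputation of MISSING (all-missing loci dropped with a
warning), using a full deterministic SVD. Ancestry-model fitting is out of
scope; the package consumes an externally estimated admixture (Q) matrix
and applies a strict threshold rule: an individual joins its argmax
cluster iff q strictly exceeds 0.8, else it is unassigned. Reference
panels — default ten per cluster — are the members closest to the cluster
centroid in the first two components ("centrally located" is not given a
metric in the field; centroid distance is this package's
operationalization), excluding individuals with more than 20% missing
data, ties broken by lower missingness then id.

## Diagnostic loci and genomotype classification

A locus is diagnostic when every called reference of one panel is
homozygous for the same allele, every called reference of the other panel
is heterozygous, and each panel has at most three missing calls at that
locus. The allele fixed in the homozygous panel is the L allele. Both
assignments of clusters to the homozygous/heterozygous roles are tried;
only one can yield a usable panel (≥ 10 loci by default) because
diagnostic loci require the homozygous cluster to be a pure species —
if both or neither orientation succeeds, the code refuses to guess.

Each individual's composition over called diagnostic loci gives
proportions `p_homL`, `p_homR`, `p_het` (summing to 1) and, at
heterozygous loci with depth ≥ 8, the relative L-allele coverage. The
classifier is a cascade with every threshold surfaced in
`ClassifyConfig`:

1. `p_homL ≥ 0.95` → LL; `p_homR ≥ 0.95` → RR;
2. `p_het ≥ 0.90` → ploidy by the maximum pooled binomial log-likelihood
   of the per-locus L-read counts under allele fractions 1/2, 2/3, 1/3
   (LR / LLR / LRR); requires ≥ 10 qualified heterozygous loci and a
   winning margin ≥ 2 log-units, else the individual is an edible frog of
   unknown ploidy (`E_UNKNOWN_PLOIDY`);
3. otherwise UNDETERMINED, flagged `CONTAMINATION_SUSPECT` when a
   homozygosity proportion (either genome) and `p_het` both exceed 0.25 —
   the signature of a sample carrying two individuals' DNA. The flag is
   symmetric in L and R so that swapping the panel orientation maps
   LL↔RR and LLR↔LRR while leaving LR calls fixed.

The homozygosity and heterozygosity floors (0.95 / 0.90) and the margin
are decisions, not reconstructions: the visual density-plot inspection
they replace has no recoverable thresholds. They sit well clear of both
the noise observed at 1% call error and the contamination patterns the
cascade must not absorb.

## Pond breeding systems

Rules in order, from the set of genomotypes observed in a pond: triploids
(LLR or LRR) with LR but no LL → all-hybrid **candidate** (absence of LL
in a finite sample may be a sampling artifact, hence never a firm E-E
call); LLR with LL → modified L-E; LL with LR → L-E; a single genomotype →
undetermined ("single-taxon sample"). Hybrids of unknown ploidy count as
LR-like presence for the plain L-E rule only. RR presence is noted
regardless of system — composition alone cannot distinguish invasive
*P.* cf. *bedriagae* from rare viable hybrid × hybrid offspring, which is
what the mitochondrial *ND1* assignment is for.

## Marker calls

*MND1*: the L and R alleles of the 33-bp fragment differ at exactly two
positions. Both positions in the L state → *P. lessonae*; both R → RR
genotype; both showing the two-base IUPAC ambiguity → *P.* kl.
*esculentus*; anything else (discordant, half-ambiguous, unreadable) →
unidentified. Sequences are gated by edlib edit distance to the templates
(cap 8). The method's known blind spot is preserved, not patched: RR
individuals heterozygous by descent at *MND1* are called *esculentus*.
*ND1* haplogroups are assigned by minimum Hamming distance to reference
sequences (ties → unidentified); network construction and alignment are
replaced by this alignment-free rule. Concordance between two call sets
counts matches and mismatches only over individuals identified by both
methods. The exact diagnostic *MND1* positions and real reference
haplotypes are inputs; the shipped templates and ND1 references are
synthetic stand-ins for testing.

## Synthetic data

The generator emulates the study conditions end to end. Defaults, chosen
once: 500 loci with 35% diagnostic (a 175-locus panel, the size of a real
diagnostic set, at a desk-scale total SNP count), negative-binomial depth
with mean 30 and dispersion 5 (RAD coverage is overdispersed relative to
Poisson), zero missingness and call error unless requested. Per locus,
the L and R genomes are fixed for alternative alleles at diagnostic sites;
non-diagnostic sites get allele frequencies uniform on [0.05, 0.95],
Hardy–Weinberg within each genome and shared between genomes with
probability 0.5. Each individual's allele count follows its genomotype's
genome copies; the allele-2 read count is Binomial(d, copy fraction), so
the dosage effect holds by construction.

Two deliberate refinements:

- **Calls are truth plus explicit noise.** The emitted genotype is the
  true genotype, flipped to a uniformly chosen different state with the
  configured error rate and masked i.i.d. with the missingness rate;
  depths are drawn conditional on the call (heterozygous cells get depth
  ≥ 2 with both alleles covered). This keeps container invariants exact
  and makes "no noise → perfect diagnostic structure" a construction
  guarantee rather than a high-probability event; the clipping perturbs
  the binomial dosage distribution only at depths far below the default
  mean.
- **Triploids are hemiclonal.** All LLR individuals share one clonal L
  haplotype pair (LRR likewise a clonal R pair), drawn once per locus
  model, mirroring the clonal transmission of the doubled genome in
  modified L-E systems. This is what makes triploids form their own
  cluster in genotype-space ordination, as they do in real data; with
  independent Hardy–Weinberg draws they would be nearly indistinguishable
  from diploid hybrids in PCA (their distinctness at diagnostic loci is
  pure depth signal, invisible to genotype encoding).

What the generator does **not** model: read-level sequencing error,
linkage, allele dropout correlated with depth, coalescent population
structure within genomes, or reference genomes. Passing tests therefore
demonstrate the pipeline's correctness under the stated statistical
assumptions, not robustness to every artifact of real libraries.
`simulate_country` shares one locus model across ponds so a whole survey
is coherent; `simulate_ancestry` emits a Q-matrix consistent with the
truth (ancestry estimation itself being out of scope); DBR read
simulation plants Poisson-distributed PCR copies with shared tags and
optional insert collisions; marker simulation emits 33-bp *MND1* and
336-bp *ND1* sequences consistent with each individual's species call,
hybrids carrying the maternal (lessonae-lineage) mitochondrion.

## Numerical and degenerate-input conventions

All randomness flows from integer seeds through
`numpy.random.default_rng`; same seed, same output. Q-matrix rows must sum
to 1 within 1e-6. Empty dedup input yields an empty result with a zeroed
report (not an error); a filter stage that empties the table warns rather
than raises; an individual with no called diagnostic locus is
UNDETERMINED with a `NO_DIAGNOSTIC_DATA` flag in cohort runs but an error
when profiled directly. Percentile gating in sweep selection is inclusive
(`error_rate ≤ cutoff`). PCA components are deterministic up to the sign
convention of the underlying SVD.

## Problem sizes

The test suite and the acceptance script run on simulated cohorts of 300–
1200 loci and up to 500 individuals (single ponds) or 33 ponds of 8–12
frogs (country runs) — sizes at which every statistical check (dosage
means within 0.02 of 1/2, 2/3, 1/3; error-rate recovery within three
binomial standard errors; ≥ 98% genomotype accuracy at depth 30, 30%
missingness, 1% call error) is comfortably resolved while the whole suite
completes in seconds.
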