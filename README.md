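# pelodose

Species and ploidy inference for *Pelophylax* water frogs from ddRAD SNP
data, with pond-level breeding-system classification and single-marker
(*MND1*/*ND1*) species calls.

## The problem

European water frogs are a hybridogenetic complex: the edible frog
*P.* kl. *esculentus* is a fertile hybrid carrying one genome from the pool
frog *P. lessonae* (L) and one from the *P. ridibundus* complex (R). It
persists by excluding one parental genome from its germline, so local
populations can run on different breeding systems — the classic L-E system
(LR hybrids backcross with LL), a modified L-E system with LLR triploids,
or all-hybrid (E-E) populations without LL. The frogs are hard to tell
apart in the field, but genotype plus per-allele read depth at
genome-diagnostic SNPs reveals both species and ploidy:

- a **diagnostic locus** is fixed for one allele in the L genome and the
  other in the R genome, so LL and RR individuals are homozygous (for
  opposite alleles) and every hybrid is heterozygous;
- a **dosage effect** links read counts to genome copy number: at a
  heterozygous diagnostic locus the expected L-allele read fraction equals
  the L-copy fraction — 1/2 in LR, 2/3 in LLR, 1/3 in LRR. With read depth
  *d* and L-allele count *x*, the package scores each ploidy model
  *p* ∈ {1/2, 2/3, 1/3} by the pooled binomial log-likelihood
  Σᵢ log Binom(xᵢ | dᵢ, p) over qualified heterozygous loci and calls the
  winner, demanding a configurable margin and evidence floor.

`pelodose` implements the full desk-side pipeline around that idea:
PCR-duplicate removal using degenerate-base-region (DBR) tags, sample/SNP
quality filtering, replicate-based genotyping-error estimation and
parameter-sweep selection, PCA + ancestry-threshold clustering, reference
selection, diagnostic-locus discovery, genomic-composition classification,
pond breeding-system calls, and *MND1*/*ND1* marker calls with
method-concordance statistics. A first-class synthetic-data module
generates every input with the statistical structure the analysis assumes,
so the whole pipeline is testable without any sequencing data.

## Worked example

```python
from pelodose import (PondSpec, simulate_pond, identify_diagnostic_loci,
                      classify_individuals)

spec = PondSpec("Demo", {"LL": 10, "LR": 10, "LLR": 5},
                n_loci=300, fraction_diagnostic=0.3, mean_depth=30, seed=12)
table, truth = simulate_pond(spec)

ll = list(truth.individuals[truth.individuals == "LL"].index)[:10]
lr = list(truth.individuals[truth.individuals == "LR"].index)[:10]
diag = identify_diagnostic_loci(table, refs_homo=ll, refs_het=lr)
print(len(diag))                       # 90  (the planted 300 x 0.3 panel)

calls = classify_individuals(table, diag)
print(calls["label"].value_counts().to_dict())
# {'LL': 10, 'LR': 10, 'LLR': 5}      # every genomotype recovered
```

The `calls` frame also carries each individual's composition proportions
(`p_homL`, `p_homR`, `p_het`), the number of heterozygous diagnostic loci
used, and the per-model log-likelihoods, e.g. an LLR individual at depth 30
shows `p_het = 1.0` with `loglik_LLR` exceeding `loglik_LR` by over 100
log-units. Pond-level systems follow with
`pelodose.summarize_ponds(calls)`.

The same steps are available from the shell:

```sh
pelodose simulate --pond-id Demo --counts LL=10,LR=10,LLR=5 --out demo
pelodose filter --vcf demo.vcf --meta demo.meta.tsv --out demo.filtered.vcf
pelodose classify --vcf demo.vcf --diagnostic diag.tsv --out calls.tsv
pelodose ponds --calls calls.tsv --out ponds.tsv
```

## Layout

| module | role |
| --- | --- |
| `pelodose.table` | genotype + allele-depth matrix container |
| `pelodose.io` | VCF/TSV/FASTA/FASTQ readers and writers, DBR extraction |
| `pelodose.simulate` | synthetic ponds, replicates, DBR reads, marker sequences |
| `pelodose.dedup` | DBR-aware PCR-duplicate removal |
| `pelodose.filters` | depth/MAF/missingness cascade, replicate resolution |
| `pelodose.sweep` | replicate error rate, parameter-sweep selection |
| `pelodose.cluster` | PCA, q-threshold assignment, reference panels |
| `pelodose.diagnostic` | diagnostic loci, composition profiles, dosage classifier |
| `pelodose.markers` | *MND1*/*ND1* calls and concordance tables |
| `pelodose.ponds` | breeding-system rules per pond |
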