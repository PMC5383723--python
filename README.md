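# duosnp

Downstream analysis of a two-genotype transcriptome comparison, packaged as a
reusable Python library: pairwise SNP classification between two sequenced
individuals, per-transcript SNP statistics and Venn categorization, GO-term
over-representation testing, reciprocal-best-hit (RBH) orthology, and
DnaSP-style population diversity statistics for resequenced candidate-gene
amplicons. A synthetic-data generator produces every input format with
brute-force ground truth, so the whole pipeline is testable without any raw
sequencing data.

It is aimed at researchers characterising genetic variation in non-model
plants from RNA-seq of a handful of genotypes — the setting where variants are
called per transcript ("unigene") for two individuals, candidate genes are
picked via orthology to a model species, and a few loci are then Sanger
resequenced across natural populations.

## The statistics at the core

**Pairwise SNP classification.** Each candidate site carries an unordered
diploid allele pair per sample. Sites homozygous for different bases in both
samples are *inter-individual*; sites heterozygous in exactly one sample are
*A-* or *B-specific*; identical homozygotes and double heterozygotes fall
outside the scheme. Heterozygous calls are printed as IUPAC codes
(K=T/G, M=A/C, R=A/G, S=G/C, W=A/T, Y=T/C). Two filters precede
classification: a cluster rule removing every site that lies in a 35 bp span
holding more than 3 candidate sites, and a quality rule removing sites with a
depth-normalised quality below 2.0.

**Per-unigene statistics.** SNP frequency is 100·(SNPs/length) %; unigenes
are partitioned into the 7 Venn categories given by which SNP types they
carry, and a one-way ANOVA compares frequency across categories.

**Enrichment.** For a study set of n genes from an annotated universe of N,
a term on K background and k study genes gets the upper hypergeometric tail
P(X ≥ k), Bonferroni-adjusted over the tested terms; enriched means
adjusted p < α (default 0.01).

**Orthology.** From bidirectional all-against-all hit tables, each query's
best hit is chosen by bitscore (ties: evalue, identity, subject id), and a
pair is an ortholog candidate iff the choice is mutual.

**Locus diversity.** For an aligned population amplicon: segregating sites S
with transition/transversion classes, indel events, nucleotide diversity
π (mean pairwise differences per net site), Watterson's
θ_w = S/(a·L) with a = Σ_{i=1}^{n−1} 1/i, haplotype count and haplotype
diversity Hd = n(1 − Σp_i²)/(n − 1), plus synonymous/nonsynonymous calls
under a small coding model that supports one intron. Columns containing any
gap or ambiguous base are excluded from the analyzed sites and from the net
length L (the DnaSP "net sites" convention).

## Worked example

`examples/05_locus_diversity.py` rebuilds four candidate-gene amplicons —
the heat-shock factor *HsfA1d*, the seed-size gene *DAR1* and the flowering
genes *ELF3* and *LHY* — from their population sample sizes, alignment
lengths and allele-carrier configurations, and summarizes each locus:

```
locus                 HsfA1d     DAR1     ELF3      LHY
n_genotypes               52       51       54       53
sequence_length_bp       654      459      626      849
n_indels                   0        0        0        0
n_snps                     1        1        2        4
transitions                0        0        2        3
transversions              1        1        0        1
snp_frequency          1/654    1/459    1/313    1/212
pi                   0.00032  0.00046  0.00059  0.00127
theta_w              0.00034  0.00048   0.0007  0.00104
n_haplotypes               2        2        3        3
haplotype_diversity    0.208    0.212    0.352    0.357
```

Reading the *HsfA1d* column: among 52 sequenced genotypes a single
transversion, carried by the 6 genotypes of one semi-arid population, yields
π = 0.00032 (about one difference per 3,000 bp between two random
sequences), θ_w = 0.00034, two haplotypes and Hd = 0.208 — a 21% chance that
two sampled sequences differ. The other examples
(`01`–`04`) walk through classification, categorization, enrichment and RBH
recovery on planted synthetic data.

A thin CLI mirrors the library stage by stage:

```bash
duosnp simulate genotypes --seed 7 --out sim/
duosnp classify --genotypes sim/genotypes.tsv --out-prefix classified
duosnp popgen --alignment locus.afa --trim 52:900 --cds locus.cds.json
```

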