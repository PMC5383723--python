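# Methods

## Scope and data model

`duosnp` implements the analysis layer that sits downstream of read mapping
and variant calling in a two-genotype transcriptome study. Its inputs are
tabular and text formats only: per-site genotype tables (TSV or a
two-sample VCF subset), reference transcript FASTA, gene→GO maps,
blast-tabular hit lists in both search directions, and aligned FASTA of
population amplicons. All coordinates are 1-based inclusive, matching the
VCF/BLAST convention of those formats. The upstream steps (assembly,
mapping, calling, BLAST execution, database annotation) are out of scope;
the package consumes their outputs.

## Pairwise SNP classification

Each site carries an unordered diploid allele pair for each sample.
Classification uses the zygosity pattern only:

| sample A | sample B | class |
|---|---|---|
| hom X | hom Y ≠ X | inter-individual |
| het | hom | A-specific |
| hom | het | B-specific |
| hom X | hom X | none (monomorphic) |
| het | het | none |

Both-heterozygous sites are counted as unclassifiable: the three-type
scheme has no cell for them, and calling them from two samples would
require phasing information that is absent. Sites where the two samples
share no allele (e.g. A/A vs C/T) are still classified by zygosity and
logged as multi-allelic; the scheme does not require a shared allele.
Heterozygous pairs are rendered as IUPAC ambiguity codes; the code map is
bijective over the six unordered heterozygous pairs.

### Filters

Two record-level predicates run before classification, in a fixed order
(cluster first, then quality), and the filter report reconciles exactly:
`input = removed_cluster + removed_quality + removed_unclassifiable +
retained`.

* **Cluster filter** (window 35 bp, max 3): a site is removed iff it lies
  in *any* span of 35 consecutive bases containing more than 3 candidate
  sites. The originating caller documents only the two parameters, not the
  exact operator, so this sliding-window semantics — the natural reading of
  "more than three mismatches in the adjacent 35 bp" — is adopted and
  verified against an independent brute-force oracle in the tests. A span
  "fits" when `pos_last − pos_first ≤ 34`.
* **Quality filter** (threshold 2.0): kept iff quality ≥ 2.0, i.e. sites
  *below* the threshold are removed and the boundary value survives.
  Missing quality fails the filter and is logged.

## Per-unigene statistics and Venn categories

SNP frequency per unigene is 100 × (SNP count / length), a percentage of
positions; the alternative convention (length per SNP) is reported only as
the `1/<L/S>` string in locus summaries. Unigenes partition into the seven
non-empty subsets of {inter, A-specific, B-specific}; each category gets a
stable semantic label (`inter_only`, …, `all_three`) plus a data-dependent
`SR_<memberCount>` alias, since size-derived names cannot be stable
identifiers. The ANOVA on frequencies is one-way and fixed-effects, on
untransformed percent values (no transform is assumed). It is assembled
from explicit sums of squares rather than `scipy.stats.f_oneway` because
the degenerate layouts need defined behaviour: identical group means give
F = 0, p = 1 exactly; zero within-group variance with distinct means, or
fewer than two groups of two, raise instead of returning NaN. scipy's
routine serves as the independent cross-check in the tests.

## Enrichment

One-sided over-representation only: the upper hypergeometric tail
P(X ≥ k) via `scipy.stats.hypergeom.sf(k−1, N, K, n)`. The universe is the
annotated background (genes without any annotation do not count toward N
or n). The Bonferroni family size m defaults to the number of terms with
k ≥ 1 in the study set — the common default when testing a study list —
and is configurable to all annotated terms; no GO-graph ancestor
propagation is performed, annotations being taken as given. Enriched means
adjusted p < α, default α = 0.01.

## RBH orthology

Hits are first collapsed to one row per (query, subject) by maximum
bitscore, then the best hit per query is selected by the total order
(bitscore desc, evalue asc, identity desc, subject id asc), making the
result invariant under permutation of input rows. Bitscore-first is the
conventional criterion; evalue-first can be obtained by reordering the
key. An optional evalue ceiling (default 1e−5, the usual annotation
threshold) is applied before selection. Trait-class gene lists are
user-supplied files, never hard-coded.

## Locus diversity

Statistics follow the DnaSP conventions:

* **Net sites:** any column containing a gap or an ambiguous base in any
  sequence is excluded from the analyzed set and from the net length L.
  π and θ_w are per net site. Terminal trimming of poor-quality sequence is
  user-specified as a column window, since chromatogram quality is not
  recoverable from an alignment.
* **π** = Σ pairwise differences / C(n,2) / L. Internally computed by the
  per-column allele-count identity (pairs differing at a column =
  C(n,2) − Σ_b C(c_b,2)), which is exact because analyzed columns are
  complete; the test suite holds it to an explicit O(n²L) double loop at
  1e−12.
* **θ_w** = S / (a_{n−1} L), a_{m} = Σ_{i=1}^{m} 1/i, with n the sequences
  analyzed at the locus.
* **Haplotypes** are the distinct strings over segregating columns;
  sequences with ambiguity at those columns are excluded from counting but
  still contribute to site detection. Hd = n(1 − Σp_i²)/(n − 1).
* **Indel events** are maximal runs of gap-state disagreement with the
  column-majority consensus; runs with identical coordinates in several
  sequences merge into one event.
* **Codon effects:** the reference codon takes the majority base at each
  codon position, the alternate substitutes the site's second allele;
  translation uses the standard code (complemented and read in reverse on
  the minus strand). Intronic sites are noncoding; sites in a partial
  terminal codon or inside the frame offset are NA and logged.
* Reporting precision: π and θ_w to 5 decimals, Hd to 3 — the precision of
  the published locus tables this summary format mirrors.

For a single biallelic site with minor count k, π·L and Hd both equal
2k(n−k)/(n(n−1)); this identity is asserted on fixtures as a consistency
check, and θ_w/π neutrality (ratio within [0.5, 2] over 200 coalescent
loci simulated with msprime) guards against scale errors.

## Synthetic data

The generators define the conditions every test and the acceptance script
run under:

* **Population alignments** are haplotype-structured: alt alleles are
  assigned to explicit carrier blocks, because Hd and π depend on the joint
  configuration, not per-site marginals. The four reference amplicon specs
  use the published sample sizes (52/51/54/53 genotypes), aligned lengths
  (654/459/626/849 bp) and carrier configurations (the NM-specific allele
  in six genotypes; the second ELF3 site in five JB genotypes). Three of
  the four loci are fully forced by those counts; the fourth (LHY-like)
  uses one plausible phasing, since no integer 3-haplotype configuration
  of n = 53 reproduces its published haplotype diversity — its marginals
  are under-determined, and it is therefore excluded from the headline
  reconstruction in `scripts/acceptance.py`. Its θ_w is likewise reported
  from the standard formula (≈0.00104 for S=4, n=53, L=849) rather than
  the published 0.0009, which is inconsistent with that formula.
* **Genotype tables** default to the transcriptome study's type mix scaled
  down by 100 (820 inter-individual, 35 A-specific, 204 B-specific) over
  300 unigenes with lognormal lengths (mean ≈ 730 bp, matching the
  reference assembly's average); regular sites are placed at least one
  cluster window apart so the cluster filter provably keeps them, and
  dense clusters / sub-threshold-quality sites are planted explicitly.
* **Annotation maps** annotate every universe gene (so N is exact),
  plant terms as (K background, k study) memberships, and add background
  terms at 5% prevalence. **Hit tables** plant 1:1 orthologs with
  identities Normal(55, 5) — the mid-range of published cross-species
  identity means — and decoys at 90% of the true bitscore; unpaired genes
  hit only already-paired partners, so planted recovery is provably exact.
* Every generator takes a single `numpy.random.default_rng(seed)`; same
  seed and spec give byte-identical output. Truth values are computed by
  brute-force code local to the generator module (explicit pair loops,
  subset collapsing), never by calling the analysis functions, so
  truth-vs-analysis agreement is a genuine dual-route check.

What the generators do **not** emulate: read-level error, allele-specific
expression, calling bias, paralog collapse in the assembly, real GO-term
correlation structure, or recombination within amplicons. Passing tests
therefore demonstrate correctness of the statistics and bookkeeping on
idealised inputs, not robustness to upstream artefacts.

## Problem sizes

The default suite uses tables of ~10²–10³ sites, universes of 10³ genes,
hit tables of ~10² genes per side and amplicons of ≤ 10³ bp × ≤ 54
sequences; the classification-recovery check runs 100 generator seeds.
These sizes keep every check well under a second while leaving the planted
signals unambiguous.

## Known limitations

* The cluster filter is an approximation of the upstream caller's
  proprietary operator; only its two parameters are documented.
* Codon-effect calls assume the majority allele is ancestral; for balanced
  polymorphisms the reported direction (e.g. Glu→Asp vs Asp→Glu) can flip.
* The VCF reader handles exactly the two-sample GT subset; arbitrary VCF
  feature support is out of scope.
* Haplotype-diversity exclusion of ambiguous sequences reduces n for Hd
  but not for site detection, matching the chosen convention; other tools
  may exclude per-site instead, which changes results on gappy data.
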