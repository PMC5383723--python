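"""Synthetic inputs with ground truth for every pipeline stage.

Each generator emulates one input the pipeline consumes — population
amplicon alignments, two-sample genotype tables, gene-to-GO annotation
maps, bidirectional similarity hit tables, and a reference unigene set —
and returns, alongside the data, a *truth* dictionary computed by
independent brute-force code inside this module (never by calling the
analysis functions), so that fixture tests are genuine cross-checks.

All randomness flows through one ``numpy.random.default_rng`` per call;
the same seed and spec give byte-identical outputs.

Population alignments are haplotype-structured: sequences are assigned to
haplotypes (carrier blocks), not mutated per-site i.i.d., because joint
statistics such as haplotype diversity depend on the phased configuration.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

_BASES = np.array(list("ACGT"))
_TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})


# ---------------------------------------------------------------------------
# Population alignments

@dataclass(frozen=True)
class SiteSpec:
    """One planted segregating site: ref/alt bases and the alt carriers.

    ``carriers`` lists 0-based sequence indices; when None, consecutive
    blocks are assigned automatically so that distinct sites load distinct
    haplotypes.
    """

    column: int  # 1-based
    ref: str
    alt: str
    alt_count: int
    carriers: Optional[Tuple[int, ...]] = None


@dataclass
class PopulationSpec:
    n_sequences: int
    length: int
    sites: List[SiteSpec] = field(default_factory=list)
    intron: Optional[Tuple[int, int]] = None  # 1-based inclusive
    missing_rate: float = 0.0
    gc: float = 0.39
    seed: int = 0

    def __post_init__(self):
        cols = [s.column for s in self.sites]
        if len(cols) != len(set(cols)):
            raise ValueError("site columns must be distinct")
        for s in self.sites:
            if not (1 <= s.column <= self.length):
                raise ValueError(f"site column {s.column} outside 1..{self.length}")
            if not (1 <= s.alt_count < self.n_sequences):
                raise ValueError("alt count must satisfy 1 <= count < n")
            if s.carriers is not None and len(s.carriers) != s.alt_count:
                raise ValueError("carriers length must equal alt_count")


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _assign_carriers(spec: PopulationSpec) -> List[Tuple[int, ...]]:
    carriers = []
    cursor = 0
    for s in spec.sites:
        if s.carriers is not None:
            carriers.append(tuple(s.carriers))
        else:
            # consecutive blocks; wraps modulo n when the blocks run out,
            # so alt counts are always realized exactly (overlapping
            # carrier sets then shape the joint haplotype structure)
            block = tuple((cursor + j) % spec.n_sequences
                          for j in range(s.alt_count))
            carriers.append(block)
            cursor += s.alt_count
    return carriers


def make_population_alignment(spec: PopulationSpec):
    """Build an aligned population sample realizing the planted sites.

    Returns ``(names, seqs, truth)``.  ``truth`` holds S, transition and
    transversion counts, haplotype counts, pi, theta_w and Hd, all computed
    by brute force over the emitted sequences (pairwise double loop for pi,
    set collapsing for haplotypes), honouring the net-site convention that
    columns with any N or gap are excluded.
    """
    rng = np.random.default_rng(spec.seed)
    background = _random_sequence(rng, spec.length, spec.gc)
    carriers = _assign_carriers(spec)
    for s in spec.sites:
        background[s.column - 1] = s.ref

    rows = np.tile(background, (spec.n_sequences, 1))
    for s, who in zip(spec.sites, carriers):
        for i in who:
            rows[i, s.column - 1] = s.alt

    if spec.missing_rate > 0:
        site_cols = {s.column - 1 for s in spec.sites}
        eligible = [j for j in range(spec.length) if j not in site_cols]
        mask = rng.random((spec.n_sequences, len(eligible))) < spec.missing_rate
        for i in range(spec.n_sequences):
            for jj, j in enumerate(eligible):
                if mask[i, jj]:
                    rows[i, j] = "N"

    names = [f"{'seq'}_{i:03d}" for i in range(spec.n_sequences)]
    seqs = ["".join(row) for row in rows]
    truth = _brute_force_locus_truth(seqs)
    truth["seed"] = spec.seed
    truth["intron"] = list(spec.intron) if spec.intron else None
    return names, seqs, truth


def _brute_force_locus_truth(seqs: Sequence[str]) -> dict:
    """Independent recomputation of all locus statistics from raw strings."""
    n = len(seqs)
    length = len(seqs[0])
    analyzed = [j for j in range(length)
                if all(s[j] in "ACGT" for s in seqs)]
    seg_cols, ts, tv, multi = [], 0, 0, 0
    for j in analyzed:
        obs = {s[j] for s in seqs}
        if len(obs) < 2:
            continue
        seg_cols.append(j)
        if len(obs) == 2:
            if obs in _TRANSITION_PAIRS:
                ts += 1
            else:
                tv += 1
        else:
            multi += 1
    # pi by explicit double loop over all unordered pairs
    diffs = 0
    for a, b in itertools.combinations(range(n), 2):
        diffs += sum(1 for j in analyzed if seqs[a][j] != seqs[b][j])
    n_pairs = n * (n - 1) // 2
    L = len(analyzed)
    pi = diffs / n_pairs / L if L else 0.0
    # haplotypes over segregating columns
    haps = Counter("".join(s[j] for j in seg_cols) for s in seqs)
    counts = list(haps.values())
    total = sum(counts)
    hd = (total * (1 - sum((c / total) ** 2 for c in counts)) / (total - 1)
          if total >= 2 else 0.0)
    a_n = sum(1.0 / i for i in range(1, n))
    theta = len(seg_cols) / (a_n * L) if L else 0.0
    return {
        "n": n, "net_length": L, "S": len(seg_cols),
        "transitions": ts, "transversions": tv, "multiallelic": multi,
        "pi": pi, "theta_w": theta,
        "n_haplotypes": len(haps), "haplotype_diversity": hd,
    }


def reference_locus_specs() -> Dict[str, PopulationSpec]:
    """Amplicon configurations for the four resequenced candidate genes.

    Three loci are fully determined by their published marginal counts and
    the carrier populations named in the text: HsfA1d (n=52, 654 bp, one
    T/A transversion in the six NM genotypes), DAR1 (n=51, 459 bp, one G/C
    transversion in the six NM genotypes, 125 bp intron) and ELF3 (n=54,
    626 bp, a NM-specific G/A transition plus a C/T transition in five JB
    genotypes).  The LHY-like locus (n=53, 849 bp, three transitions and
    one A/T transversion, 86 bp intron) uses one plausible phasing — NM
    carrying all four variants, JB sharing the two transitions — since the
    joint haplotype configuration at that locus is under-determined by the
    marginal site counts.
    """
    return {
        "HsfA1d": PopulationSpec(
            n_sequences=52, length=654,
            sites=[SiteSpec(column=300, ref="T", alt="A", alt_count=6)],
            seed=11),
        "DAR1": PopulationSpec(
            n_sequences=51, length=459,
            sites=[SiteSpec(column=120, ref="G", alt="C", alt_count=6)],
            intron=(200, 324), seed=12),
        "ELF3": PopulationSpec(
            n_sequences=54, length=626,
            sites=[SiteSpec(column=150, ref="G", alt="A", alt_count=6,
                            carriers=tuple(range(6))),
                   SiteSpec(column=400, ref="C", alt="T", alt_count=5,
                            carriers=tuple(range(6, 11)))],
            seed=13),
        "LHY": PopulationSpec(
            n_sequences=53, length=849,
            sites=[SiteSpec(column=100, ref="T", alt="C", alt_count=11,
                            carriers=tuple(range(11))),
                   SiteSpec(column=250, ref="C", alt="T", alt_count=11,
                            carriers=tuple(range(11))),
                   SiteSpec(column=500, ref="T", alt="C", alt_count=6,
                            carriers=tuple(range(6))),
                   SiteSpec(column=700, ref="A", alt="T", alt_count=6,
                            carriers=tuple(range(6)))],
            intron=(300, 385), seed=14),
    }


# ---------------------------------------------------------------------------
# Two-sample genotype tables

@dataclass
class GenotypeTableSpec:
    """Planted composition of a two-sample genotype call table.

    Default type counts scale the study's transcriptome-wide composition
    (inter-individual : A-specific : B-specific roughly 82 : 3.5 : 20)
    down by a factor of 100.  Regular sites are spaced more than one
    cluster window apart within each unigene so the cluster filter
    provably keeps them; dense clusters for filter testing are planted
    explicitly via ``clusters``.
    """

    n_unigenes: int = 300
    n_inter: int = 820
    n_a_specific: int = 35
    n_b_specific: int = 204
    n_both_het: int = 50
    n_monomorphic: int = 50
    n_low_quality: int = 0
    clusters: List[Tuple[int, int]] = field(default_factory=list)  # (size, span_bp)
    length_lognormal: Tuple[float, float] = (6.45, 0.55)  # mean ~ 730 bp
    min_length: int = 300
    window_bp: int = 35
    min_quality: float = 2.0
    seed: int = 0


def make_genotype_table(spec: GenotypeTableSpec):
    """Emit genotype-table rows plus the planted truth.

    Returns ``(rows, truth)`` where each row is a dict matching the TSV
    dialect (unigene_id, pos, sample_A_alleles, sample_B_alleles, quality)
    and truth records the planted per-type counts and the expected filter
    removals.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = np.maximum(
        spec.min_length,
        rng.lognormal(*spec.length_lognormal, size=spec.n_unigenes).astype(int))
    spacing = spec.window_bp + 5
    slots = []  # (unigene index, pos)
    for u, L in enumerate(lengths):
        slots.extend((u, p) for p in range(20, int(L) - 10, spacing))

    labels = (["inter"] * spec.n_inter + ["a_specific"] * spec.n_a_specific
              + ["b_specific"] * spec.n_b_specific
              + ["both_het"] * spec.n_both_het
              + ["monomorphic"] * spec.n_monomorphic
              + ["low_quality"] * spec.n_low_quality)
    if len(labels) > len(slots):
        raise ValueError(
            f"{len(labels)} sites requested but only {len(slots)} spaced "
            f"slots available; increase n_unigenes")
    chosen = rng.choice(len(slots), size=len(labels), replace=False)

    def hom(base):
        return f"{base}/{base}"

    def het(b1, b2):
        return "/".join(sorted((b1, b2)))

    rows = []
    for label, slot_idx in zip(labels, chosen):
        u, pos = slots[slot_idx]
        x, y = rng.choice(_BASES, size=2, replace=False)
        kind = label if label != "low_quality" else \
            ["inter", "a_specific", "b_specific"][rng.integers(3)]
        if kind == "inter":
            a_gt, b_gt = hom(x), hom(y)
        elif kind == "a_specific":
            a_gt, b_gt = het(x, y), hom(x)
        elif kind == "b_specific":
            a_gt, b_gt = hom(x), het(x, y)
        elif kind == "both_het":
            a_gt = b_gt = het(x, y)
        else:  # monomorphic
            a_gt = b_gt = hom(x)
        if label == "low_quality":
            quality = round(float(rng.uniform(0.0, spec.min_quality - 0.1)), 2)
        else:
            quality = round(float(spec.min_quality + rng.lognormal(2.5, 0.6)), 2)
        rows.append({
            "unigene_id": f"unigene_{u:05d}", "pos": int(pos),
            "sample_A_alleles": a_gt, "sample_B_alleles": b_gt,
            "quality": quality,
        })

    # dense clusters, one fresh unigene each, planted beyond the main set
    cluster_rows = 0
    for c, (size, span) in enumerate(spec.clusters):
        uid = f"unigene_cluster_{c:03d}"
        positions = np.linspace(50, 50 + span - 1, num=size).astype(int)
        for pos in positions:
            x, y = rng.choice(_BASES, size=2, replace=False)
            rows.append({
                "unigene_id": uid, "pos": int(pos),
                "sample_A_alleles": hom(x), "sample_B_alleles": hom(y),
                "quality": round(float(spec.min_quality + rng.lognormal(2.5, 0.6)), 2),
            })
            cluster_rows += 1
    rows.sort(key=lambda r: (r["unigene_id"], r["pos"]))

    truth = {
        "seed": spec.seed,
        "counts": {"inter_individual": spec.n_inter,
                   "a_specific": spec.n_a_specific,
                   "b_specific": spec.n_b_specific},
        "expected_removed_quality": spec.n_low_quality,
        "expected_removed_cluster": cluster_rows,
        "expected_unclassifiable": spec.n_both_het + spec.n_monomorphic,
        "unigene_lengths": {f"unigene_{u:05d}": int(L)
                            for u, L in enumerate(lengths)},
    }
    return rows, truth


# ---------------------------------------------------------------------------
# Annotation maps

@dataclass
class EnrichmentSpec:
    """Annotation universe with planted over-represented terms.

    ``planted`` lists ``(K_background, k_study)`` pairs: a term annotating
    K genes overall of which k fall in the study set.
    """

    universe_size: int = 1000
    n_background_terms: int = 50
    term_prevalence: float = 0.05
    study_size: int = 40
    planted: List[Tuple[int, int]] = field(default_factory=lambda: [(50, 30)])
    seed: int = 0


def make_annotation_map(spec: EnrichmentSpec):
    """Returns ``(gene2terms, study_set, truth)``.

    Every gene carries at least one background term, so the annotated
    universe has exactly ``universe_size`` genes.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene_{i:05d}" for i in range(spec.universe_size)]
    gene2terms: Dict[str, set] = {g: set() for g in genes}
    # guarantee annotation: one broad housekeeping-like term per gene
    for g in genes:
        gene2terms[g].add("GO:0000001")
    for t in range(spec.n_background_terms):
        term = f"GO:{t + 2:07d}"
        K = max(1, int(round(spec.term_prevalence * spec.universe_size)))
        for g in rng.choice(genes, size=K, replace=False):
            gene2terms[g].add(term)
    study = list(rng.choice(genes, size=spec.study_size, replace=False))
    planted_terms = []
    non_study = [g for g in genes if g not in set(study)]
    for i, (K, k) in enumerate(spec.planted):
        if k > spec.study_size or K - k > len(non_study) or k > K:
            raise ValueError(f"planted term {i}: infeasible (K={K}, k={k})")
        term = f"GO:9{i:06d}"
        inside = rng.choice(study, size=k, replace=False)
        outside = rng.choice(non_study, size=K - k, replace=False)
        for g in list(inside) + list(outside):
            gene2terms[g].add(term)
        planted_terms.append({"term": term, "K": K, "k": k})
    truth = {"seed": spec.seed, "planted": planted_terms,
             "universe_size": spec.universe_size,
             "study_size": spec.study_size}
    return gene2terms, study, truth


# ---------------------------------------------------------------------------
# Bidirectional hit tables

@dataclass
class RbhSpec:
    """Two gene sets with planted 1:1 orthologs and decoy paralog hits.

    Identities are drawn Normal(identity_mean, identity_sd) truncated to
    [0, 100]; decoy hits score ``decoy_bitscore_frac`` of the true hit, so
    planted pairs remain mutual best hits by construction.
    """

    n_a: int = 120
    n_b: int = 120
    ortholog_fraction: float = 0.8
    identity_mean: float = 55.0
    identity_sd: float = 5.0
    decoy_rate: float = 0.3
    decoy_bitscore_frac: float = 0.9
    seed: int = 0


def make_hit_tables(spec: RbhSpec):
    """Returns ``(hits_ab, hits_ba, truth)`` as lists of outfmt6-like dicts."""
    rng = np.random.default_rng(spec.seed)
    genes_a = [f"a_{i:04d}" for i in range(spec.n_a)]
    genes_b = [f"b_{i:04d}" for i in range(spec.n_b)]
    n_pairs = int(round(spec.ortholog_fraction * min(spec.n_a, spec.n_b)))
    perm_a = rng.permutation(spec.n_a)[:n_pairs]
    perm_b = rng.permutation(spec.n_b)[:n_pairs]

    def row(q, s, ident, bits):
        length = int(rng.integers(150, 600))
        return {
            "qseqid": q, "sseqid": s, "pident": round(float(ident), 2),
            "length": length,
            "mismatch": int(round(length * (1 - ident / 100.0))),
            "gapopen": int(rng.integers(0, 5)),
            "qstart": 1, "qend": length, "sstart": 1, "send": length,
            "evalue": float(f"{10 ** -float(rng.uniform(20, 120)):.3e}"),
            "bitscore": round(float(bits), 1),
        }

    hits_ab, hits_ba, pairs = [], [], []
    paired_b = [genes_b[j] for j in perm_b]
    for ia, ib in zip(perm_a, perm_b):
        a, b = genes_a[ia], genes_b[ib]
        ident = float(np.clip(rng.normal(spec.identity_mean, spec.identity_sd),
                              0.0, 100.0))
        bits = float(rng.uniform(150, 400))
        hits_ab.append(row(a, b, ident, bits))
        hits_ba.append(row(b, a, ident, bits))
        pairs.append({"gene_a": a, "gene_b": b, "identity": round(ident, 2)})
        if rng.random() < spec.decoy_rate:
            decoy = genes_b[int(rng.integers(spec.n_b))]
            if decoy != b:
                hits_ab.append(row(a, decoy, ident * 0.9,
                                   bits * spec.decoy_bitscore_frac))
    # unpaired genes hit only already-paired partners on the other side,
    # so they can never form an accidental mutual best pair
    unpaired_a = [genes_a[i] for i in range(spec.n_a) if i not in set(perm_a)]
    for a in unpaired_a:
        if paired_b:
            b = paired_b[int(rng.integers(len(paired_b)))]
            hits_ab.append(row(a, b, float(rng.uniform(30, 50)),
                               float(rng.uniform(60, 120))))
    truth = {"seed": spec.seed, "pairs": sorted(pairs, key=lambda p: p["gene_a"]),
             "mean_identity": (float(np.mean([p["identity"] for p in pairs]))
                               if pairs else None)}
    rng.shuffle(hits_ab)
    rng.shuffle(hits_ba)
    return hits_ab, hits_ba, truth


# ---------------------------------------------------------------------------
# Reference unigene sets

def make_unigene_set(n: int, seed: int = 0,
                     length_lognormal: Tuple[float, float] = (6.45, 0.55),
                     min_length: int = 200,
                     gc_mean: float = 0.39, gc_sd: float = 0.05):
    """Random reference transcripts with realistic length and GC spread.

    Returns a list of ``(id, sequence)`` tuples; lengths are lognormal
    (mean around 730 bp) and per-transcript GC is Normal(gc_mean, gc_sd)
    clipped to [0.2, 0.8].
    """
    rng = np.random.default_rng(seed)
    out = []
    lengths = np.maximum(min_length,
                         rng.lognormal(*length_lognormal, size=n).astype(int))
    gcs = np.clip(rng.normal(gc_mean, gc_sd, size=n), 0.2, 0.8)
    for i, (L, gc) in enumerate(zip(lengths, gcs)):
        out.append((f"unigene_{i:05d}",
                    "".join(_random_sequence(rng, int(L), float(gc)))))
    return out
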