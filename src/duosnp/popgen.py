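"""Locus-level population diversity statistics from multiple alignments.

Implements the DnaSP-style summary for a resequenced amplicon across a
population sample: segregating sites S with transition/transversion
classification, indel events, nucleotide diversity pi (average pairwise
differences per analyzed site), Watterson's theta_w = S / (a_n * L) with
a_n = sum_{i=1}^{n-1} 1/i, haplotype collapsing and haplotype diversity
Hd = n (1 - sum p_i^2) / (n - 1), and per-site codon effects (synonymous /
nonsynonymous / noncoding) under a small coding model that supports a
single intron.

Missing-data policy (the "net sites" convention): any alignment column
containing a gap or an ambiguous base in any sequence is excluded both
from the analyzed site set and from the net length L used by pi and
theta_w.  Indel events are counted on the full trimmed window, before that
exclusion.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = frozenset("ACGT")
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


@dataclass
class LocusAlignment:
    """An aligned population sample for one locus.

    ``seqs`` are equal-length uppercase strings over A, C, G, T, N and the
    gap character '-'.  Columns are 1-based.
    """

    name: str
    names: list
    seqs: list

    def __post_init__(self):
        if len(self.seqs) < 2:
            raise ValueError("a locus alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @classmethod
    def from_fasta(cls, path, name: Optional[str] = None) -> "LocusAlignment":
        from duosnp.io import read_fasta

        records = read_fasta(path)
        return cls(name=name or str(path), names=[r.id for r in records],
                   seqs=[r.sequence for r in records])

    def analyzed_columns(self) -> list:
        """1-based columns free of gaps and ambiguous bases in every row."""
        cols = []
        for j in range(self.length):
            if all(s[j] in _UNAMBIGUOUS for s in self.seqs):
                cols.append(j + 1)
        return cols

    @property
    def net_length(self) -> int:
        return len(self.analyzed_columns())


@dataclass(frozen=True)
class SegregatingSite:
    column: int  # 1-based within the (trimmed) alignment
    alleles: Tuple[Tuple[str, int], ...]  # (base, count) sorted by count desc
    change_class: str  # transition | transversion | multiallelic
    effect: Optional[str] = None  # synonymous | nonsynonymous | noncoding | NA
    aa_change: Optional[Tuple[str, str]] = None


@dataclass
class CdsModel:
    """Coding geometry of a locus: exon intervals, frame offset, strand.

    ``intervals`` are 1-based inclusive (start, end) pairs on the trimmed
    alignment; a two-interval model encodes a single spliced-out intron.
    ``frame`` counts coding bases to skip before the first complete codon;
    trailing bases that do not fill a codon are treated as a partial
    terminal codon (effect NA).
    """

    intervals: list
    frame: int = 0
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.frame <= 2:
            raise ValueError("frame must be 0, 1 or 2")
        prev_end = 0
        for start, end in self.intervals:
            if start < 1 or end < start:
                raise ValueError(f"bad interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = end

    def coding_columns(self) -> list:
        """Alignment columns in translation order, frame offset removed."""
        cols = [c for start, end in self.intervals for c in range(start, end + 1)]
        if self.strand == "-":
            cols.reverse()
        return cols[self.frame:]

    def contains(self, column: int) -> bool:
        return any(start <= column <= end for start, end in self.intervals)


@dataclass
class LocusSummary:
    """A Table-style per-locus diversity record."""

    name: str
    n_genotypes: int
    length: int  # net analyzed sites
    n_segregating: int
    n_transitions: int
    n_transversions: int
    n_indels: int
    snp_frequency: str  # "1/<round(L/S)>"
    snp_rate: float  # S / L
    pi: float
    theta_w: float
    n_haplotypes: int
    haplotype_diversity: float
    sites: list = field(default_factory=list)

    def table_row(self) -> dict:
        """Fields rounded to reporting precision (pi/theta 5 dp, Hd 3 dp)."""
        return {
            "locus": self.name,
            "n_genotypes": self.n_genotypes,
            "sequence_length_bp": self.length,
            "n_indels": self.n_indels,
            "n_snps": self.n_segregating,
            "transitions": self.n_transitions,
            "transversions": self.n_transversions,
            "snp_frequency": self.snp_frequency,
            "pi": round(self.pi, 5),
            "theta_w": round(self.theta_w, 5),
            "n_haplotypes": self.n_haplotypes,
            "haplotype_diversity": round(self.haplotype_diversity, 3),
        }


def trim_alignment(aln: LocusAlignment, window: Tuple[int, int]) -> LocusAlignment:
    """Restrict the alignment to a 1-based inclusive column window.

    Emulates removal of poor-quality sequence at the 5' and 3' termini of
    an amplicon; downstream coordinates are relative to the trimmed
    alignment.
    """
    start, end = window
    if not (1 <= start <= end <= aln.length):
        raise ValueError(
            f"window {window} empty or outside columns 1..{aln.length}")
    return LocusAlignment(
        name=aln.name, names=list(aln.names),
        seqs=[s[start - 1:end] for s in aln.seqs])


def segregating_sites(aln: LocusAlignment) -> list:
    """Polymorphic analyzed columns with allele counts and Ts/Tv class."""
    sites = []
    for col in aln.analyzed_columns():
        counts = Counter(s[col - 1] for s in aln.seqs)
        if len(counts) < 2:
            continue
        bases = frozenset(counts)
        if len(bases) == 2:
            change = "transition" if bases in _TRANSITIONS else "transversion"
        else:
            change = "multiallelic"
        alleles = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
        sites.append(SegregatingSite(column=col, alleles=alleles,
                                     change_class=change))
    return sites


def indel_events(aln: LocusAlignment) -> int:
    """Count indel events against the column-majority consensus.

    A maximal run of columns where a sequence's gap state differs from the
    consensus gap state is one event; runs with identical coordinates in
    several sequences are merged into a single event.
    """
    consensus_gap = []
    for j in range(aln.length):
        gaps = sum(1 for s in aln.seqs if s[j] == "-")
        consensus_gap.append(gaps * 2 > aln.n)
    events = set()
    for s in aln.seqs:
        run_start = None
        for j in range(aln.length):
            differs = (s[j] == "-") != consensus_gap[j]
            if differs and run_start is None:
                run_start = j
            elif not differs and run_start is not None:
                events.add((run_start + 1, j))
                run_start = None
        if run_start is not None:
            events.add((run_start + 1, aln.length))
    return len(events)


def nucleotide_diversity(aln: LocusAlignment) -> float:
    """Average pairwise differences per analyzed site (pi).

    pi = sum over unordered sequence pairs of per-pair differences at
    analyzed columns, divided by C(n, 2) and by the net length.  With the
    gap/ambiguity exclusion all rows are complete at analyzed columns, so
    the per-column allele-count identity
    ``pairs differing = C(n,2) - sum_b C(count_b, 2)`` applies exactly.
    """
    cols = aln.analyzed_columns()
    if not cols:
        raise ValueError("no analyzed columns (all contain gaps/ambiguity)")
    n = aln.n
    total_pairs = n * (n - 1) // 2
    diff_pairs = 0
    for col in cols:
        counts = Counter(s[col - 1] for s in aln.seqs)
        if len(counts) < 2:
            continue
        same = sum(c * (c - 1) // 2 for c in counts.values())
        diff_pairs += total_pairs - same
    return diff_pairs / total_pairs / len(cols)


def harmonic(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator of the per-site mutation rate: S / (a_{n-1} L)."""
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2 sequences")
    if L < 1:
        raise ValueError("net length must be >= 1")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / (harmonic(n - 1) * L)


def collapse_haplotypes(aln: LocusAlignment,
                        sites: Optional[Sequence[SegregatingSite]] = None) -> Counter:
    """Collapse sequences to haplotypes over the segregating columns.

    A haplotype is the string of bases at the segregating sites; sequences
    carrying a gap or ambiguous base at any of those columns are excluded
    from counting (they still contributed to site detection).  A
    monomorphic alignment collapses to a single haplotype.
    """
    if sites is None:
        sites = segregating_sites(aln)
    cols = [s.column for s in sites]
    haplotypes: Counter = Counter()
    for seq in aln.seqs:
        key = "".join(seq[c - 1] for c in cols)
        if any(b not in _UNAMBIGUOUS for b in key):
            logger.debug("sequence excluded from haplotype counting "
                         "(ambiguity at a segregating site)")
            continue
        haplotypes[key] += 1
    return haplotypes


def haplotype_diversity(counts) -> float:
    """Hd = n (1 - sum p_i^2) / (n - 1) over haplotype counts.

    The sample-size-corrected probability that two sampled haplotypes
    differ; 0 for a single haplotype, exactly 1 when all are distinct.
    """
    values = list(counts.values() if isinstance(counts, (dict, Counter)) else counts)
    n = sum(values)
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2 sequences")
    sum_p2 = sum((c / n) ** 2 for c in values)
    return n * (1.0 - sum_p2) / (n - 1)


def _consensus_base(aln: LocusAlignment, column: int) -> str:
    counts = Counter(s[column - 1] for s in aln.seqs
                     if s[column - 1] in _UNAMBIGUOUS)
    if not counts:
        raise ValueError(f"column {column} has no unambiguous bases")
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def codon_effect(site: SegregatingSite, cds: CdsModel,
                 aln: LocusAlignment) -> SegregatingSite:
    """Annotate a segregating site with its protein-level effect.

    The reference codon takes the major allele at each codon position; the
    alternate codon substitutes the site's second-most-frequent allele.
    Sites outside the coding intervals (e.g. in the intron) are noncoding;
    sites in a partial terminal codon get effect NA.  Translation uses the
    standard genetic code; on the minus strand bases are complemented and
    read in reverse.
    """
    from dataclasses import replace

    if not cds.contains(site.column):
        return replace(site, effect="noncoding", aa_change=None)
    coding = cds.coding_columns()
    try:
        idx = coding.index(site.column)
    except ValueError:  # trimmed off by the frame offset
        logger.warning("site %d lies in the frame offset; effect NA",
                       site.column)
        return replace(site, effect="NA", aa_change=None)
    codon_idx = idx // 3
    codon_cols = coding[3 * codon_idx: 3 * codon_idx + 3]
    if len(codon_cols) < 3:
        logger.warning("site %d in partial terminal codon; effect NA",
                       site.column)
        return replace(site, effect="NA", aa_change=None)

    major = site.alleles[0][0]
    minor = site.alleles[1][0]
    ref_codon, alt_codon = [], []
    for col in codon_cols:
        base = _consensus_base(aln, col) if col != site.column else major
        ref_codon.append(base)
        alt_codon.append(base if col != site.column else minor)
    ref_nt, alt_nt = "".join(ref_codon), "".join(alt_codon)
    if cds.strand == "-":
        ref_nt = str(Seq(ref_nt).complement())
        alt_nt = str(Seq(alt_nt).complement())
    ref_aa = str(Seq(ref_nt).translate())
    alt_aa = str(Seq(alt_nt).translate())
    effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return replace(site, effect=effect, aa_change=(ref_aa, alt_aa))


def summarize_locus(aln: LocusAlignment,
                    cds: Optional[CdsModel] = None) -> LocusSummary:
    """Full per-locus diversity summary (optionally with codon effects)."""
    sites = segregating_sites(aln)
    if cds is not None:
        sites = [codon_effect(s, cds, aln) for s in sites]
    S = len(sites)
    n_ts = sum(1 for s in sites if s.change_class == "transition")
    n_tv = sum(1 for s in sites if s.change_class == "transversion")
    L = aln.net_length
    haps = collapse_haplotypes(aln, sites)
    n_hap_seqs = sum(haps.values())
    return LocusSummary(
        name=aln.name,
        n_genotypes=aln.n,
        length=L,
        n_segregating=S,
        n_transitions=n_ts,
        n_transversions=n_tv,
        n_indels=indel_events(aln),
        snp_frequency=f"1/{round(L / S)}" if S else "0",
        snp_rate=S / L if L else 0.0,
        pi=nucleotide_diversity(aln),
        theta_w=watterson_theta(S, aln.n, L),
        n_haplotypes=len(haps),
        haplotype_diversity=(haplotype_diversity(haps)
                             if n_hap_seqs >= 2 else 0.0),
        sites=sites,
    )
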