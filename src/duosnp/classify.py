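"""Pairwise SNP filtering and classification for a two-sample comparison.

A *pairwise SNP* is a site whose genotype pattern differs between the two
sequenced individuals.  With each sample called as an unordered allele pair,
three classes exhaust the informative patterns:

* ``INTER_INDIVIDUAL`` — both samples homozygous, for different bases;
* ``A_SPECIFIC`` — sample A heterozygous, sample B homozygous;
* ``B_SPECIFIC`` — sample B heterozygous, sample A homozygous.

Sites homozygous for the same base in both samples (monomorphic) or
heterozygous in both samples fall outside the scheme and classify to ``None``.
Heterozygous calls are rendered as IUPAC ambiguity codes (K=T/G, M=A/C,
R=A/G, S=G/C, W=A/T, Y=T/C).

Two record-level filters precede classification, mirroring the variant-caller
post-filters whose tabular output this module consumes: a cluster filter
removing sites that sit in a dense run (more than ``max_in_window`` candidate
sites within any ``window_bp`` span) and a quality filter removing sites with
a depth-normalised quality score below ``min_quality``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

# unordered heterozygous pair -> ambiguity code
_IUPAC = {
    frozenset("TG"): "K",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("TC"): "Y",
}
_IUPAC_INVERSE = {code: pair for pair, code in _IUPAC.items()}


class SnpType(str, Enum):
    INTER_INDIVIDUAL = "inter_individual"
    A_SPECIFIC = "a_specific"
    B_SPECIFIC = "b_specific"


@dataclass(frozen=True)
class GenotypeSite:
    """One candidate site in one unigene with per-sample diploid calls.

    Allele pairs are unordered; they are normalised to sorted tuples so that
    ``("G", "A")`` and ``("A", "G")`` compare equal.
    """

    unigene_id: str
    pos: int  # 1-based
    alleles_a: tuple[str, str]
    alleles_b: tuple[str, str]
    quality: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "alleles_a", tuple(sorted(self.alleles_a)))
        object.__setattr__(self, "alleles_b", tuple(sorted(self.alleles_b)))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for base in (*self.alleles_a, *self.alleles_b):
            if base not in _VALID_BASES:
                raise ValueError(f"allele {base!r} not in ACGT")

    @property
    def hom_a(self) -> bool:
        return self.alleles_a[0] == self.alleles_a[1]

    @property
    def hom_b(self) -> bool:
        return self.alleles_b[0] == self.alleles_b[1]

    def swapped(self) -> "GenotypeSite":
        """Return the site with the two samples exchanged."""
        return GenotypeSite(self.unigene_id, self.pos, self.alleles_b,
                            self.alleles_a, self.quality)


@dataclass(frozen=True)
class ClassifiedSnp:
    site: GenotypeSite
    snp_type: SnpType
    iupac_a: str
    iupac_b: str


@dataclass
class FilterReport:
    """Reconciliation of how many sites each stage removed.

    Invariant: ``input_sites == removed_cluster + removed_quality +
    removed_unclassifiable + retained``.
    """

    input_sites: int = 0
    removed_cluster: int = 0
    removed_quality: int = 0
    removed_unclassifiable: int = 0
    retained: int = 0

    def check(self) -> None:
        total = (self.removed_cluster + self.removed_quality
                 + self.removed_unclassifiable + self.retained)
        if total != self.input_sites:
            raise AssertionError(
                f"filter report does not reconcile: {self} ")


def iupac_code(base1: str, base2: str) -> str:
    """IUPAC single-letter code for an unordered base pair.

    Symmetric in its arguments; a homozygous pair returns the base itself.
    """
    b1, b2 = base1.upper(), base2.upper()
    for b in (b1, b2):
        if b not in _VALID_BASES:
            raise ValueError(f"base {b!r} not in ACGT")
    if b1 == b2:
        return b1
    return _IUPAC[frozenset((b1, b2))]


def iupac_decode(code: str) -> frozenset:
    """Set of bases encoded by an IUPAC code (identity on A/C/G/T)."""
    c = code.upper()
    if c in _VALID_BASES:
        return frozenset(c)
    try:
        return _IUPAC_INVERSE[c]
    except KeyError:
        raise ValueError(f"unknown ambiguity code {code!r}") from None


def classify_site(site: GenotypeSite) -> Optional[SnpType]:
    """Classify a filtered site, or return None when it is not a pairwise SNP.

    Total on its domain: monomorphic sites (identical homozygotes) and
    both-heterozygous sites return None; every other pattern maps to exactly
    one of the three types.  Allele identity across samples is not required:
    a site like A=A/A vs B=C/T is B-specific by zygosity pattern even though
    no allele is shared (logged as multi-allelic).
    """
    hom_a, hom_b = site.hom_a, site.hom_b
    if hom_a and hom_b:
        if site.alleles_a == site.alleles_b:
            return None
        return SnpType.INTER_INDIVIDUAL
    if not hom_a and not hom_b:
        return None
    shared = set(site.alleles_a) & set(site.alleles_b)
    if not shared:
        logger.debug("multi-allelic site %s:%d (%s vs %s)", site.unigene_id,
                     site.pos, site.alleles_a, site.alleles_b)
    return SnpType.A_SPECIFIC if not hom_a else SnpType.B_SPECIFIC


def _sorted_sites(sites: Sequence[GenotypeSite]) -> list:
    keyed = [(s.unigene_id, s.pos) for s in sites]
    if keyed != sorted(keyed):
        logger.warning("genotype sites were unsorted; sorting internally")
        return sorted(sites, key=lambda s: (s.unigene_id, s.pos))
    return list(sites)


def cluster_filter(
    sites: Sequence[GenotypeSite],
    window_bp: int = 35,
    max_in_window: int = 3,
) -> tuple[list, list]:
    """Remove sites that lie in dense clusters of candidate sites.

    A site is removed iff it lies in some span of ``window_bp`` consecutive
    bases (within one unigene) containing more than ``max_in_window``
    candidate sites, itself included.  Returns ``(kept, removed)`` preserving
    the sorted order; ``kept + removed`` is a permutation of the input.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    sites = _sorted_sites(sites)
    removed_flags = [False] * len(sites)
    # group contiguous runs per unigene
    start = 0
    for end in range(1, len(sites) + 1):
        if end == len(sites) or sites[end].unigene_id != sites[start].unigene_id:
            pos = [s.pos for s in sites[start:end]]
            m = len(pos)
            j = 0
            for i in range(m):
                if j < i:
                    j = i
                while j + 1 < m and pos[j + 1] - pos[i] <= window_bp - 1:
                    j += 1
                if j - i + 1 > max_in_window:
                    for t in range(i, j + 1):
                        removed_flags[start + t] = True
            start = end
    kept = [s for s, r in zip(sites, removed_flags) if not r]
    removed = [s for s, r in zip(sites, removed_flags) if r]
    return kept, removed


def quality_filter(
    sites: Sequence[GenotypeSite], min_quality: float = 2.0
) -> tuple[list, list]:
    """Keep sites whose quality score is >= ``min_quality``.

    A missing quality is treated as failing and logged.
    """
    kept, removed = [], []
    for s in sites:
        if s.quality is None:
            logger.warning("site %s:%d has no quality score; removed",
                           s.unigene_id, s.pos)
            removed.append(s)
        elif s.quality >= min_quality:
            kept.append(s)
        else:
            removed.append(s)
    return kept, removed


def classify_table(
    sites: Sequence[GenotypeSite],
    window_bp: int = 35,
    max_in_window: int = 3,
    min_quality: float = 2.0,
) -> tuple[list, dict, FilterReport]:
    """Filter (cluster, then quality) and classify a full genotype table.

    Returns ``(classified, type_counts, report)`` where ``type_counts`` maps
    each :class:`SnpType` to its count and ``report`` reconciles exactly with
    the input size.  Deterministic given input order.
    """
    report = FilterReport(input_sites=len(sites))
    kept, removed_cluster = cluster_filter(sites, window_bp, max_in_window)
    report.removed_cluster = len(removed_cluster)
    kept, removed_quality = quality_filter(kept, min_quality)
    report.removed_quality = len(removed_quality)

    classified: list[ClassifiedSnp] = []
    counts = {t: 0 for t in SnpType}
    for site in kept:
        snp_type = classify_site(site)
        if snp_type is None:
            report.removed_unclassifiable += 1
            continue
        counts[snp_type] += 1
        classified.append(ClassifiedSnp(
            site=site,
            snp_type=snp_type,
            iupac_a=iupac_code(*site.alleles_a),
            iupac_b=iupac_code(*site.alleles_b),
        ))
    report.retained = len(classified)
    report.check()
    return classified, counts, report
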