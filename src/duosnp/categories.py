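"""Per-unigene SNP aggregation, Venn categorization and ANOVA.

Each unigene with at least one classified pairwise SNP gets a per-unigene
record: counts of the three SNP types, SNP frequency (100 x SNPs / length,
i.e. percent of positions that are SNPs), and one of the seven Venn
categories defined by which of the three type counts are nonzero
(inter-only, A-only, B-only, the three pairwise combinations, all-three).
Category summaries also carry a data-dependent ``SR_<memberCount>`` alias,
the convention of naming a Venn cell after its size.

``category_frequency_anova`` runs a one-way fixed-effects ANOVA of SNP
frequency across categories on untransformed percent values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats as sps

from duosnp.classify import ClassifiedSnp, SnpType

CATEGORY_LABELS = [
    "inter_only", "a_only", "b_only",
    "inter_a", "inter_b", "a_b", "all_three",
]


@dataclass
class UnigeneStat:
    unigene_id: str
    length: int
    n_inter: int
    n_a_specific: int
    n_b_specific: int
    category: str = ""

    @property
    def n_total(self) -> int:
        return self.n_inter + self.n_a_specific + self.n_b_specific

    @property
    def frequency_pct(self) -> float:
        return 100.0 * self.n_total / self.length


@dataclass
class CategorySummary:
    label: str
    alias: str  # SR_<memberCount>
    member_count: int
    mean_frequency_pct: float
    median_frequency_pct: float
    q1_frequency_pct: float
    q3_frequency_pct: float


def _category_of(stat: UnigeneStat) -> str:
    has = (stat.n_inter > 0, stat.n_a_specific > 0, stat.n_b_specific > 0)
    return {
        (True, False, False): "inter_only",
        (False, True, False): "a_only",
        (False, False, True): "b_only",
        (True, True, False): "inter_a",
        (True, False, True): "inter_b",
        (False, True, True): "a_b",
        (True, True, True): "all_three",
    }[has]


def per_unigene_stats(
    classified: Sequence[ClassifiedSnp], unigene_lengths: Dict[str, int]
) -> list:
    """Aggregate classified SNPs into per-unigene counts and frequencies.

    Only unigenes with at least one classified SNP appear.  A SNP on a
    unigene absent from ``unigene_lengths`` is an error naming the id.
    """
    counts: Dict[str, list] = {}
    for snp in classified:
        uid = snp.site.unigene_id
        if uid not in unigene_lengths:
            raise KeyError(f"SNP on unknown unigene {uid!r}: no length given")
        c = counts.setdefault(uid, [0, 0, 0])
        idx = {SnpType.INTER_INDIVIDUAL: 0, SnpType.A_SPECIFIC: 1,
               SnpType.B_SPECIFIC: 2}[snp.snp_type]
        c[idx] += 1
    stats = []
    for uid in sorted(counts):
        n_inter, n_a, n_b = counts[uid]
        stat = UnigeneStat(unigene_id=uid, length=unigene_lengths[uid],
                           n_inter=n_inter, n_a_specific=n_a, n_b_specific=n_b)
        stat.category = _category_of(stat)
        stats.append(stat)
    return stats


def venn_categorize(stats: Sequence[UnigeneStat]) -> tuple[dict, list]:
    """Partition unigenes into the seven Venn categories.

    Returns ``(assignment, summaries)``: a unigene_id -> label map and a
    :class:`CategorySummary` per non-empty category (in canonical label
    order), each carrying the size-derived ``SR_<count>`` alias.
    """
    if not stats:
        raise ValueError("no per-unigene statistics to categorize")
    assignment = {}
    members: Dict[str, list] = {label: [] for label in CATEGORY_LABELS}
    for stat in stats:
        label = stat.category or _category_of(stat)
        stat.category = label
        assignment[stat.unigene_id] = label
        members[label].append(stat)
    summaries = []
    for label in CATEGORY_LABELS:
        group = members[label]
        if not group:
            continue
        freqs = np.array([s.frequency_pct for s in group])
        q1, med, q3 = np.percentile(freqs, [25, 50, 75])
        summaries.append(CategorySummary(
            label=label, alias=f"SR_{len(group)}", member_count=len(group),
            mean_frequency_pct=float(freqs.mean()),
            median_frequency_pct=float(med),
            q1_frequency_pct=float(q1), q3_frequency_pct=float(q3),
        ))
    return assignment, summaries


def category_frequency_anova(stats: Sequence[UnigeneStat]) -> tuple[float, float, dict]:
    """One-way ANOVA of SNP frequency (percent) across Venn categories.

    Returns ``(F, p, per_category_means)``.  Requires at least two
    categories with at least two members each; degenerate layouts raise
    rather than returning NaN.  When all group means coincide the test is
    reported as F=0, p=1.
    """
    groups: Dict[str, list] = {}
    for s in stats:
        groups.setdefault(s.category or _category_of(s), []).append(s.frequency_pct)
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError(
            "ANOVA needs >=2 categories with >=2 members; "
            f"got {[(k, len(v)) for k, v in groups.items()]}")
    values = list(usable.values())
    grand = np.concatenate(values)
    n = grand.size
    k = len(values)
    ss_between = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in values)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in values)
    means = {label: float(g.mean()) for label, g in usable.items()}
    if ss_between == 0.0:
        return 0.0, 1.0, means
    if ss_within == 0.0:
        raise ValueError("zero within-group variance with distinct means: "
                         "F statistic undefined")
    f_stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(sps.f.sf(f_stat, k - 1, n - k))
    return float(f_stat), p, means
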