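"""Hypergeometric GO over-representation with Bonferroni adjustment.

Plants one term on 30 of 40 study genes against a 1000-gene annotated
background and checks that it is flagged at adjusted p < 0.01.
"""

from duosnp import AnnotationMap, enrich
from duosnp.simulate import EnrichmentSpec, make_annotation_map

gene2terms, study, truth = make_annotation_map(
    EnrichmentSpec(universe_size=1000, study_size=40,
                   planted=[(50, 30)], seed=11))
results = enrich(study, AnnotationMap(gene2terms=gene2terms), alpha=0.01)

print(f"{len(results)} terms tested, "
      f"{sum(r.enriched for r in results)} enriched at adj-p < 0.01")
for r in results[:5]:
    print(f"  {r.term}  k/n = {r.k}/{r.n}  K/N = {r.K}/{r.N}  "
          f"p = {r.p_raw:.3g}  adj-p = {r.p_adj:.3g}  "
          f"{'ENRICHED' if r.enriched else ''}")
print(f"planted term was {truth['planted'][0]['term']}")
print("\nk of n study genes carry the term versus K of N background genes; "
      "the p-value is the upper hypergeometric tail P(X >= k), multiplied "
      "by the number of tested terms (Bonferroni).")
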