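"""Observed vs expected StMA hits in an association-study candidate list.

Candidate genes from an association study are intersected with the StMA and
biallelic (BA) lists; the expected StMA hit count assumes hits split between
the lists in proportion to their sizes.
"""

from stmaburden import SyntheticSpec, association_enrichment, simulate_study

study = simulate_study(SyntheticSpec(rng_seed=3), with_clones=False)
stma, ba = study["stma_truth"], study["ba_truth"]

# a candidate list deliberately tilted towards StMA genes
candidates = set(list(sorted(stma))[:6]) | set(list(sorted(ba))[:10])

res = association_enrichment(candidates, stma, ba)
print(f"StMA list: {len(stma)} genes; BA list: {len(ba)} genes")
print(f"candidates hitting either list: {res.observed_stma + res.observed_ba}")
print(f"observed StMA hits: {res.observed_stma}, expected: {res.expected_stma:.2f}")
print(f"fold enrichment: {res.fold:.2f}")
print(f"test: {res.test.method.value}, p = {res.test.p_value:.4f}")
# fold > 1 means the candidate list hits StMA genes more often than the
# StMA:BA size ratio predicts
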