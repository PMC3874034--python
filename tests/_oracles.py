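"""Independent brute-force oracles used by the unit and acceptance suites.

Each oracle implements the target quantity by a different route than the
package (enumeration, per-base counting, pairwise closure) so agreement is a
genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

from stmaburden.allelic import Call, Status
from stmaburden.regions import GenomicInterval


def fisher_two_sided_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct log-factorial enumeration over all tables.

    Enumerates every table with the observed margins, computes each
    probability from log-factorials, and sums those not exceeding the
    observed table's probability (1 + 1e-7 relative tie tolerance).
    """
    lf = [0.0]
    n = a + b + c + d
    for i in range(1, n + 1):
        lf.append(lf[-1] + math.log(i))
    row1, row2, col1 = a + b, c + d, a + c

    def logp(x: int) -> float:
        # P(table with cell a = x) at fixed margins
        return (
            lf[row1] + lf[row2] + lf[col1] + lf[n - col1] - lf[n]
            - lf[x] - lf[row1 - x] - lf[col1 - x] - lf[row2 - (col1 - x)]
        )

    lo, hi = max(0, col1 - row2), min(row1, col1)
    p_obs = math.exp(logp(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(logp(x))
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def merge_by_pairwise_closure(intervals: Sequence[GenomicInterval]):
    """O(n^2) merge: repeatedly fuse any two strictly overlapping spans.

    Returns a sorted list of (chrom, start, end, n_members).
    """
    spans = [[iv.chrom, iv.start, iv.end, 1] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    spans[i] = [a[0], min(a[1], b[1]), max(a[2], b[2]), a[3] + b[3]]
                    del spans[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e, n) for c, s, e, n in spans)


def minimal_regions_by_base_counting(intervals: Sequence[GenomicInterval]):
    """Per-base coverage oracle for minimal overlap regions (small coordinates).

    Counts coverage at every base, takes maximal runs with coverage >= 2
    within each pairwise-closure cluster, and passes single-member clusters
    through unchanged.  Returns sorted (chrom, start, end) spans.
    """
    clusters = merge_by_pairwise_closure(intervals)
    out = []
    for chrom, cs, ce, n_members in clusters:
        members = [iv for iv in intervals if iv.chrom == chrom and iv.start < ce and iv.end > cs]
        if n_members == 1:
            out.append((chrom, cs, ce))
            continue
        cov = [0] * (ce - cs)
        for m in members:
            for pos in range(m.start, m.end):
                cov[pos - cs] += 1
        run_start = None
        for i, c in enumerate(cov + [0]):
            if c >= 2 and run_start is None:
                run_start = i
            elif c < 2 and run_start is not None:
                out.append((chrom, cs + run_start, cs + i))
                run_start = None
    return sorted(out)


def classify_truth_table(calls: Sequence[Call], min_clones_for_ba: int = 3) -> Status:
    """Direct transcription of the sister-clone definitions.

    StMA: some clone monoallelic and some other informative clone discordant
    with it.  BA: >= min_clones_for_ba informative clones, all biallelic.
    Consistent-MA: >= 2 informative clones, all the same monoallelic call.
    """
    inf = [c for c in calls if c != Call.NO_CALL]
    monos = [c for c in inf if c in (Call.MONO_A, Call.MONO_B)]
    has_discordant_pair = any(
        x in (Call.MONO_A, Call.MONO_B) and y != x
        for i, x in enumerate(inf)
        for j, y in enumerate(inf)
        if i != j
    )
    if monos and has_discordant_pair:
        return Status.STMA
    if inf and all(c == Call.BIALLELIC for c in inf) and len(inf) >= min_clones_for_ba:
        return Status.BA
    if len(inf) >= 2 and len(set(inf)) == 1 and inf[0] != Call.BIALLELIC:
        return Status.CONSISTENT_MA
    return Status.UNCLASSIFIED
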