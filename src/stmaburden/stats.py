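"""Enrichment measures and contingency tests for StMA gene-set burden.

Three size-bias-aware enrichment measures are computed per CNV dataset:
StMA genes per 1000 CNV-mapped genes, StMA genes per megabase of merged CNV
region, and the percentage of CNV regions containing at least one StMA gene.
Each disease dataset is compared with the merged control dataset by a 2x2
contingency test: a chi-squared test with Yates' continuity correction, or a
two-sided Fisher's exact test whenever any expected cell count falls below 5
(the condition under which the chi-squared approximation is flagged as
unreliable).

Conventions match R's ``chisq.test`` / ``fisher.test``: the Yates correction
term is ``min(0.5, |O - E|)`` so small tables cannot yield negative corrected
deviations, and the two-sided Fisher p-value sums the probabilities of all
tables (at fixed margins) no more probable than the observed one, with a
1 + 1e-7 relative tie tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .regions import CnvRegion, RegionStats, dataset_gene_set, region_stats

EXPECTED_CELL_MIN = 5.0  # Fisher fallback trigger
_TIE_REL_TOL = 1 + 1e-7  # relative tolerance for two-sided Fisher tie handling


class TestMethod(str, Enum):
    __test__ = False  # not a pytest class, despite the name

    CHI2_YATES = "CHI2_YATES"
    FISHER_EXACT = "FISHER_EXACT"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = StMA in test set, b = other test genes, c/d likewise in controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both rows of the contingency table must be non-empty")

    def expected(self) -> np.ndarray:
        obs = np.array([[self.a, self.b], [self.c, self.d]], dtype=float)
        return np.outer(obs.sum(1), obs.sum(0)) / obs.sum()


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    method: TestMethod
    p_value: float
    fold_enrichment: float  # (a/(a+b)) / (c/(c+d)); inf when the control rate is 0


def chi2_yates_p(t: ContingencyTable2x2) -> float:
    """1-df chi-squared p with Yates' correction capped at |O - E| (R behaviour)."""
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    exp = t.expected()
    if (exp == 0).any():
        return 1.0  # a margin is empty of one category; no association testable
    dev = np.abs(obs - exp)
    stat = (((dev - np.minimum(0.5, dev)) ** 2) / exp).sum()
    return float(sps.chi2.sf(stat, df=1))


def fisher_exact_p(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by enumeration over the table support.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (point-probability
    rule, with a small relative tolerance for floating-point ties).
    """
    n = t.a + t.b + t.c + t.d
    row1 = t.a + t.b
    col1 = t.a + t.c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[t.a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_REL_TOL].sum()))


def contingency_test(t: ContingencyTable2x2) -> TestResult:
    """Test a 2x2 table, choosing Fisher's exact test when any expected cell < 5."""
    rate_test = t.a / (t.a + t.b)
    rate_ctrl = t.c / (t.c + t.d)
    fold = rate_test / rate_ctrl if rate_ctrl > 0 else float("inf")
    if (t.expected() < EXPECTED_CELL_MIN).any():
        return TestResult(TestMethod.FISHER_EXACT, fisher_exact_p(t), fold)
    return TestResult(TestMethod.CHI2_YATES, chi2_yates_p(t), fold)


# ---------------------------------------------------------------------------
# per-dataset enrichment report

@dataclass
class EnrichmentReport:
    """One dataset's column of the burden summary table (rates at full precision)."""

    dataset: str
    total_genes: int
    stma_genes: int
    n_regions: int
    n_regions_with_stma: int
    total_mb: float
    stma_per_1000: float | None = None
    stma_per_mb: float | None = None
    pct_regions_with_stma: float | None = None
    genes_per_mb: float | None = None
    fold_per_1000_vs_control: float | None = None
    fold_per_mb_vs_control: float | None = None
    gene_test: TestResult | None = None
    region_test: TestResult | None = None


def stma_metrics(
    dataset: str,
    dataset_genes: set[str],
    stma_list: set[str],
    regions: Sequence[CnvRegion],
) -> EnrichmentReport:
    """Compute the three enrichment measures for one dataset (tests unfilled)."""
    n_genes = len(dataset_genes)
    n_stma = len(dataset_genes & stma_list)
    stats_ = region_stats(regions)
    n_with = sum(1 for r in regions if r.genes & stma_list)
    total_mb = stats_.total_size_mb
    return EnrichmentReport(
        dataset=dataset,
        total_genes=n_genes,
        stma_genes=n_stma,
        n_regions=stats_.n_regions,
        n_regions_with_stma=n_with,
        total_mb=total_mb,
        stma_per_1000=(1000 * n_stma / n_genes) if n_genes else None,
        stma_per_mb=(n_stma / total_mb) if total_mb > 0 else None,
        pct_regions_with_stma=(100 * n_with / stats_.n_regions) if stats_.n_regions else None,
        genes_per_mb=(n_genes / total_mb) if total_mb > 0 else None,
    )


def fold_vs_control(report: EnrichmentReport, control: EnrichmentReport) -> EnrichmentReport:
    """Fill folds and contingency tests of ``report`` relative to ``control``.

    Folds are computed at full precision from the raw counts, never from
    rounded rates.  The gene-level test contrasts (StMA, non-StMA) gene counts
    between the dataset and the control; the region-level test contrasts
    (regions with >= 1 StMA gene, regions without).
    """
    out = replace(report)
    if control.total_genes and report.total_genes:
        gene_t = ContingencyTable2x2(
            report.stma_genes, report.total_genes - report.stma_genes,
            control.stma_genes, control.total_genes - control.stma_genes,
        )
        out.gene_test = contingency_test(gene_t)
        out.fold_per_1000_vs_control = out.gene_test.fold_enrichment
    if control.n_regions and report.n_regions:
        region_t = ContingencyTable2x2(
            report.n_regions_with_stma, report.n_regions - report.n_regions_with_stma,
            control.n_regions_with_stma, control.n_regions - control.n_regions_with_stma,
        )
        out.region_test = contingency_test(region_t)
    if (
        report.stma_per_mb is not None
        and control.stma_per_mb is not None
        and control.stma_per_mb > 0
    ):
        out.fold_per_mb_vs_control = (
            (report.stma_genes / report.total_mb) / (control.stma_genes / control.total_mb)
        )
    return out


# ---------------------------------------------------------------------------
# association-study gene lists

@dataclass(frozen=True)
class AssociationResult:
    observed_stma: int
    observed_ba: int
    expected_stma: float
    fold: float | None  # None when no candidate hits either list
    test: TestResult | None


def association_enrichment(
    candidates: set[str], stma: set[str], ba: set[str]
) -> AssociationResult:
    """Observed vs expected StMA hits among association-study candidate genes.

    The expectation assumes candidate hits split between the StMA and BA lists
    in proportion to the list sizes; the test is on the 2x2 of
    (hit, not-hit) x (StMA, BA).
    """
    if stma & ba:
        raise ValueError("StMA and BA lists must be disjoint")
    obs_stma = len(candidates & stma)
    obs_ba = len(candidates & ba)
    hits = obs_stma + obs_ba
    if hits == 0:
        return AssociationResult(0, 0, 0.0, None, None)
    expected = hits * len(stma) / (len(stma) + len(ba))
    fold = obs_stma / expected if expected > 0 else float("inf")
    table = ContingencyTable2x2(
        obs_stma, len(stma) - obs_stma, obs_ba, len(ba) - obs_ba
    )
    return AssociationResult(obs_stma, obs_ba, expected, fold, contingency_test(table))


# ---------------------------------------------------------------------------
# report table

def _round_half_up(x: float, ndigits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-ndigits), ROUND_HALF_UP))


_ROW_ORDER = [
    "total_genes",
    "stma_genes",
    "perm_median_stma",
    "stma_per_1000",
    "perm_per_1000",
    "fold_per_1000_vs_control",
    "perm_fold_per_1000",
    "gene_test_p",
    "perm_median_p",
    "cnv_total_mb",
    "cnv_mean_mb",
    "n_regions",
    "n_regions_with_stma",
    "pct_regions_with_stma",
    "region_test_p",
    "genes_per_mb",
    "stma_per_mb",
    "perm_per_mb",
    "fold_per_mb_vs_control",
    "perm_fold_per_mb",
]


def build_table1(
    reports: Sequence[EnrichmentReport],
    permutation: Mapping[str, "object"] | None = None,
) -> pd.DataFrame:
    """Assemble the burden summary table, one column per dataset.

    Rates are rounded half-up at reporting precision (1 decimal for per-1000
    rates, 3 for per-Mb, 2 for Mb sizes and folds); missing quantities are
    rendered as NaN.  ``permutation`` optionally maps dataset label to a
    :class:`~stmaburden.permutation.PermutationResult` whose median rows are
    interleaved with the observed ones.
    """
    cols = {}
    for r in reports:
        mean_mb = (r.total_mb / r.n_regions) if r.n_regions else np.nan

        def rnd(x, nd):
            return _round_half_up(x, nd) if x is not None else np.nan

        col = {
            "total_genes": r.total_genes,
            "stma_genes": r.stma_genes,
            "stma_per_1000": rnd(r.stma_per_1000, 1),
            "fold_per_1000_vs_control": rnd(r.fold_per_1000_vs_control, 2),
            "gene_test_p": r.gene_test.p_value if r.gene_test else np.nan,
            "cnv_total_mb": rnd(r.total_mb, 2),
            "cnv_mean_mb": rnd(float(mean_mb), 2) if r.n_regions else np.nan,
            "n_regions": r.n_regions,
            "n_regions_with_stma": r.n_regions_with_stma,
            "pct_regions_with_stma": rnd(r.pct_regions_with_stma, 1),
            "region_test_p": r.region_test.p_value if r.region_test else np.nan,
            "genes_per_mb": rnd(r.genes_per_mb, 1),
            "stma_per_mb": rnd(r.stma_per_mb, 3),
            "fold_per_mb_vs_control": rnd(r.fold_per_mb_vs_control, 1),
        }
        if permutation and r.dataset in permutation:
            p = permutation[r.dataset]
            col["perm_median_stma"] = p.median_count
            col["perm_per_1000"] = rnd(p.median_per_1000, 1)
            col["perm_fold_per_1000"] = rnd(p.median_fold, 2) if p.median_fold is not None else np.nan
            col["perm_median_p"] = rnd(p.median_p, 4) if p.median_p is not None else np.nan
            col["perm_per_mb"] = rnd(p.median_per_mb, 3) if p.median_per_mb is not None else np.nan
        cols[r.dataset] = col
    df = pd.DataFrame(cols)
    rows = [row for row in _ROW_ORDER if row in df.index]
    return df.loc[rows]
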