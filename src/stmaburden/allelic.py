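"""Per-clone allelic expression calls and per-gene StMA / biallelic classification.

A gene is called *monoallelic* in a clone when the two alleles differ by more
than a fold threshold (2.33 by default).  Classification then compares calls
across genetically identical sister clones:

* **StMA** (stochastic monoallelic): monoallelic in at least one clone while a
  sister clone is biallelic or expresses the other allele — the signature of a
  random allelic choice made independently per clonal lineage.
* **BA** (biallelic): every informative clone biallelic, with at least
  ``min_clones_for_ba`` informative clones.
* **Consistent-MA**: the same allele is monoallelically expressed in every
  clone (two or more), the pattern expected for imprinting or a strong
  cis-acting variant; explicitly not StMA.

Classifications from several neural stem cell sources (e.g. cortex, striatum,
spinal cord) are merged into global StMA / BA gene lists by union.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLONE_TABLE_COLUMNS = ["gene", "clone_id", "cell_source", "expr_a", "expr_b"]


class Call(str, Enum):
    """Allelic expression call for one gene in one clone."""

    MONO_A = "MONO_A"
    MONO_B = "MONO_B"
    BIALLELIC = "BIALLELIC"
    NO_CALL = "NO_CALL"


class Status(str, Enum):
    """Per-gene classification across sister clones of one cell source."""

    STMA = "STMA"
    BA = "BA"
    CONSISTENT_MA = "CONSISTENT_MA"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class AllelicMeasurement:
    """Expression of the two alleles of one gene in one clone (arbitrary units)."""

    gene: str
    clone_id: str
    cell_source: str
    expr_a: float
    expr_b: float

    def __post_init__(self) -> None:
        if self.expr_a < 0 or self.expr_b < 0:
            raise ValueError(
                f"negative allelic expression for {self.gene}/{self.clone_id}: "
                f"({self.expr_a}, {self.expr_b})"
            )


@dataclass(frozen=True)
class AllelicCall:
    gene: str
    clone_id: str
    call: Call


@dataclass(frozen=True)
class GeneClassification:
    gene: str
    cell_source: str
    status: Status
    n_clones: int  # informative (non-NO_CALL) clones


@dataclass
class Parameters:
    """Tunable thresholds of the analysis.

    mono_fold_threshold
        Allelic fold difference that must be exceeded (strictly) to call a
        clone monoallelic.  Default 2.33.
    min_control_cnv_length
        Control CNVs must be strictly longer than this (bp) to be retained;
        default 100 kb.  Applied to control datasets only.
    n_permutations
        Iterations of the transcriptome-resampling null; default 10,000.
    min_clones_for_ba
        Informative clones required, all biallelic, to call a gene BA;
        default 3 (one call per sister clonal line).
    """

    mono_fold_threshold: float = 2.33
    min_control_cnv_length: int = 100_000
    n_permutations: int = 10_000
    rng_seed: int = 0
    min_clones_for_ba: int = 3

    def __post_init__(self) -> None:
        if self.mono_fold_threshold <= 1:
            raise ValueError("mono_fold_threshold must be > 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def call_allele(
    measurement: AllelicMeasurement, params: Parameters | None = None
) -> AllelicCall:
    """Call one clone mono-A / mono-B / biallelic from its two allele intensities.

    The monoallelic call requires a strictly greater than ``mono_fold_threshold``
    fold difference between the alleles (max/min ratio); a ratio of exactly the
    threshold is biallelic.  One allele at zero with the other positive is the
    strongest monoallelic signal and is called monoallelic; both alleles at
    zero is ``NO_CALL`` (the ratio is undefined).
    """
    params = params or Parameters()
    a, b = measurement.expr_a, measurement.expr_b
    if a < 0 or b < 0:  # defensive; AllelicMeasurement already validates
        raise ValueError("allelic expression values must be non-negative")
    hi, lo = max(a, b), min(a, b)
    if hi == 0:
        call = Call.NO_CALL
    elif lo == 0 or hi > params.mono_fold_threshold * lo:
        call = Call.MONO_A if a > b else Call.MONO_B
    else:
        call = Call.BIALLELIC
    return AllelicCall(measurement.gene, measurement.clone_id, call)


def classify_calls(calls: Sequence[Call], min_clones_for_ba: int = 3) -> Status:
    """Classify one gene from the multiset of its per-clone calls.

    Implements the sister-clone definitions directly; the outcome depends only
    on the multiset (clone order is irrelevant).
    """
    informative = [c for c in calls if c is not Call.NO_CALL]
    if not informative:
        return Status.UNCLASSIFIED
    counts = Counter(informative)
    n_mono = counts[Call.MONO_A] + counts[Call.MONO_B]
    if n_mono >= 1 and len(counts) >= 2:
        # a monoallelic clone with a discordant informative sister
        # (biallelic or the opposite allele): variable allelic choice
        return Status.STMA
    if counts[Call.BIALLELIC] == len(informative):
        if len(informative) >= min_clones_for_ba:
            return Status.BA
        return Status.UNCLASSIFIED
    # all informative calls are the same monoallelic call
    if n_mono == len(informative) and len(counts) == 1 and n_mono >= 2:
        return Status.CONSISTENT_MA
    return Status.UNCLASSIFIED


def classify_gene(
    calls: Sequence[AllelicCall],
    params: Parameters | None = None,
    cell_source: str = "",
) -> GeneClassification:
    """Classify one gene within one cell source from its sister-clone calls."""
    params = params or Parameters()
    if not calls:
        raise ValueError("classify_gene requires at least one call")
    genes = {c.gene for c in calls}
    if len(genes) != 1:
        raise ValueError(f"calls span multiple genes: {sorted(genes)}")
    gene = calls[0].gene
    informative = sum(1 for c in calls if c.call is not Call.NO_CALL)
    if informative == 0:
        logger.warning("gene %s has no informative calls; UNCLASSIFIED", gene)
    status = classify_calls([c.call for c in calls], params.min_clones_for_ba)
    return GeneClassification(gene, cell_source, status, informative)


def call_table(measurements: pd.DataFrame, params: Parameters | None = None) -> pd.DataFrame:
    """Vectorised :func:`call_allele` over a clone table.

    Expects columns ``gene, clone_id, cell_source, expr_a, expr_b``; returns a
    copy with a ``call`` column.
    """
    params = params or Parameters()
    missing = [c for c in CLONE_TABLE_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"clone table missing columns: {missing}")
    a = measurements["expr_a"].to_numpy(dtype=float)
    b = measurements["expr_b"].to_numpy(dtype=float)
    if (a < 0).any() or (b < 0).any():
        bad = measurements.index[(a < 0) | (b < 0)].tolist()[:5]
        raise ValueError(f"negative expression values at rows {bad}")
    out = measurements.copy()
    t = params.mono_fold_threshold
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    # max/min ratio; lo==0 with hi>0 is treated as an infinite fold difference
    mono = (hi > 0) & ((lo == 0) | (hi > t * lo))
    call = np.full(len(out), Call.BIALLELIC.value, dtype=object)
    call[mono & (a > b)] = Call.MONO_A.value
    call[mono & (b > a)] = Call.MONO_B.value
    call[(a == 0) & (b == 0)] = Call.NO_CALL.value
    out["call"] = call
    return out


def classify_table(
    called: pd.DataFrame, params: Parameters | None = None
) -> pd.DataFrame:
    """Per-gene, per-cell-source classification of a called clone table.

    Returns one row per (gene, cell_source) with columns ``status`` and
    ``n_clones``.
    """
    params = params or Parameters()
    rows = []
    for (gene, source), grp in called.groupby(["gene", "cell_source"], sort=True):
        calls = [Call(c) for c in grp["call"]]
        status = classify_calls(calls, params.min_clones_for_ba)
        informative = sum(1 for c in calls if c is not Call.NO_CALL)
        rows.append({"gene": gene, "cell_source": source, "status": status.value,
                     "n_clones": informative})
    return pd.DataFrame(rows, columns=["gene", "cell_source", "status", "n_clones"])


def merge_gene_lists(
    per_source: Iterable[Iterable[GeneClassification]] | pd.DataFrame,
) -> tuple[set[str], set[str]]:
    """Merge per-source classifications into global (StMA, BA) gene lists.

    Each list is the union over cell sources.  A gene StMA in one source and
    BA in another is assigned to the StMA list only: demonstrated allelic
    variability anywhere overrides biallelic behaviour elsewhere.  Conflicts
    are logged.
    """
    if isinstance(per_source, pd.DataFrame):
        stma = set(per_source.loc[per_source["status"] == Status.STMA.value, "gene"])
        ba = set(per_source.loc[per_source["status"] == Status.BA.value, "gene"])
    else:
        stma, ba = set(), set()
        for classifications in per_source:
            for c in classifications:
                if c.status is Status.STMA:
                    stma.add(c.gene)
                elif c.status is Status.BA:
                    ba.add(c.gene)
    conflicts = stma & ba
    if conflicts:
        logger.info(
            "%d gene(s) StMA in one source and BA in another; kept as StMA: %s",
            len(conflicts), ", ".join(sorted(conflicts)[:10]),
        )
    return stma, ba - conflicts


# ---------------------------------------------------------------------------
# plain-text I/O

def read_clone_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated clone table with header gene/clone_id/cell_source/expr_a/expr_b."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLONE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list (blank lines and '#' comments skipped)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
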