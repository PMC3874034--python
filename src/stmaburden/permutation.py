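"""Transcriptome-resampling permutation null for StMA burden enrichment.

The StMA list is replaced, at each iteration, by a uniform random sample
(without replacement, same size) of genes from the expressed-gene pool of the
assay in which the StMA genes were identified.  Each iteration's sample is
shared across all case datasets, and each dataset is tested against the
control gene set exactly as the real StMA list is.  If the observed burden
were a bias of the neural transcriptome rather than of StMA genes, the
resampled surrogates would reproduce it; medians near the control rate and
non-significant per-iteration p-values rule that out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .allelic import Parameters
from .stats import ContingencyTable2x2, contingency_test


@dataclass
class PermutationResult:
    """Per-dataset summary of the resampling null."""

    dataset: str
    n_iter: int
    sample_size: int
    per_iter_counts: np.ndarray  # surrogate-gene hits in the dataset, per iteration
    per_iter_p: np.ndarray  # dataset-vs-control test p, per iteration (NaN for the control itself)
    per_iter_fold: np.ndarray
    bonferroni_adjusted_p: np.ndarray
    median_count: float
    median_per_1000: float | None
    median_per_mb: float | None
    median_p: float | None
    median_fold: float | None
    rng_seed: int


def permute(
    expressed_genes: set[str],
    case_gene_sets: Mapping[str, set[str]],
    control_gene_set: set[str],
    params: Parameters | None = None,
    sample_size: int | None = None,
    stma_list: set[str] | None = None,
    n_iter: int | None = None,
    dataset_mb: Mapping[str, float] | None = None,
    include_control: bool = True,
    control_label: str = "control",
    compute_tests: bool = True,
) -> dict[str, PermutationResult]:
    """Run the transcriptome-resampling null.

    ``sample_size`` defaults to the size of ``stma_list`` restricted to the
    expressed pool — the only size that makes the sample a like-for-like
    surrogate for the list it replaces; one of the two must be given.
    ``dataset_mb`` optionally supplies merged-region sizes so per-Mb medians
    can be reported.  The Bonferroni multiplier is the number of case
    datasets, applied to each iteration's p-value.

    Identical seeds (``params.rng_seed``) give bit-identical per-iteration
    counts.
    """
    params = params or Parameters()
    n_iter = n_iter if n_iter is not None else params.n_permutations
    pool = np.array(sorted(expressed_genes))
    if sample_size is None:
        if stma_list is None:
            raise ValueError("give sample_size or stma_list to size the surrogate sample")
        sample_size = len(stma_list & expressed_genes)
    if sample_size > len(pool):
        raise ValueError(
            f"sample_size {sample_size} exceeds expressed-gene pool of {len(pool)}"
        )
    datasets = dict(case_gene_sets)
    n_cases = len(datasets)
    if include_control:
        datasets[control_label] = set(control_gene_set)

    masks = {
        name: np.isin(pool, sorted(genes)) for name, genes in datasets.items()
    }
    ctrl_mask = np.isin(pool, sorted(control_gene_set))
    n_ctrl = int(ctrl_mask.sum())

    rng = np.random.default_rng(params.rng_seed)
    counts = {name: np.empty(n_iter, dtype=np.int64) for name in datasets}
    pvals = {name: np.full(n_iter, np.nan) for name in datasets}
    folds = {name: np.full(n_iter, np.nan) for name in datasets}
    for it in range(n_iter):
        idx = rng.choice(len(pool), size=sample_size, replace=False)
        in_sample = np.zeros(len(pool), dtype=bool)
        in_sample[idx] = True
        c_hits = int((in_sample & ctrl_mask).sum())
        for name in datasets:
            hits = int((in_sample & masks[name]).sum())
            counts[name][it] = hits
            if not compute_tests or (name == control_label and include_control):
                continue
            n_set = int(masks[name].sum())
            if n_set == 0 or n_ctrl == 0:
                continue
            table = ContingencyTable2x2(hits, n_set - hits, c_hits, n_ctrl - c_hits)
            res = contingency_test(table)
            pvals[name][it] = res.p_value
            folds[name][it] = res.fold_enrichment

    out: dict[str, PermutationResult] = {}
    for name in datasets:
        n_set = int(masks[name].sum())
        mb = dataset_mb.get(name) if dataset_mb else None
        cts = counts[name]
        med = float(np.median(cts))
        is_ctrl = include_control and name == control_label
        p = pvals[name]
        f = folds[name]
        out[name] = PermutationResult(
            dataset=name,
            n_iter=n_iter,
            sample_size=sample_size,
            per_iter_counts=cts,
            per_iter_p=p,
            per_iter_fold=f,
            bonferroni_adjusted_p=np.minimum(1.0, p * n_cases),
            median_count=med,
            median_per_1000=(1000 * med / n_set) if n_set else None,
            median_per_mb=(med / mb) if mb else None,
            median_p=None if is_ctrl or np.isnan(p).all() else float(np.nanmedian(p)),
            median_fold=None if is_ctrl or np.isnan(f).all() else float(np.nanmedian(f)),
            rng_seed=params.rng_seed,
        )
    return out


def empirical_p(observed_count: int, per_iter_counts: Sequence[int]) -> float:
    """Permutation p-value for an observed StMA count against the null counts.

    Uses the add-one rule (1 + #{count >= observed}) / (n_iter + 1), which
    never returns 0 and is exact for the permutation distribution.
    """
    counts = np.asarray(per_iter_counts)
    if counts.size < 1:
        raise ValueError("need at least one permutation count")
    return float((1 + (counts >= observed_count).sum()) / (counts.size + 1))
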