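"""End-to-end burden analysis: CNVs -> merged regions -> mapped genes -> report.

Control datasets get the >100 kb size selection before merging (population
control sets are dominated by very short calls); disease datasets pass
unfiltered.  Each case dataset is compared with the single merged control by
the gene-level and region-level contingency tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .allelic import Parameters
from .regions import (
    CnvRegion,
    GeneAnnotation,
    GenomicInterval,
    dataset_gene_set,
    filter_min_length,
    map_genes,
    merge_maximal,
    minimal_overlap_regions,
)
from .stats import EnrichmentReport, fold_vs_control, stma_metrics


@dataclass
class DatasetResult:
    name: str
    regions: list[CnvRegion]
    genes: set[str]
    report: EnrichmentReport


def analyze_dataset(
    name: str,
    cnvs: Sequence[GenomicInterval],
    annotation: Sequence[GeneAnnotation],
    stma_list: set[str],
    mode: str = "maximal",
    is_control: bool = False,
    params: Parameters | None = None,
) -> DatasetResult:
    """Merge one dataset's CNVs, map genes and compute its enrichment metrics.

    ``mode`` selects maximal merged regions or minimal (coverage >= 2)
    overlap regions; controls are size-selected (> ``min_control_cnv_length``)
    before merging.
    """
    params = params or Parameters()
    ivs = list(cnvs)
    if is_control:
        ivs = filter_min_length(ivs, params.min_control_cnv_length)
    if mode == "maximal":
        regions = merge_maximal(ivs)
    elif mode == "minimal":
        regions = minimal_overlap_regions(ivs)
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'maximal' or 'minimal')")
    map_genes(regions, annotation)
    genes = dataset_gene_set(regions)
    report = stma_metrics(name, genes, stma_list, regions)
    return DatasetResult(name, regions, genes, report)


def run_burden_analysis(
    case_cnv_sets: Mapping[str, Sequence[GenomicInterval]],
    control_cnvs: Sequence[GenomicInterval],
    annotation: Sequence[GeneAnnotation],
    stma_list: set[str],
    mode: str = "maximal",
    params: Parameters | None = None,
    control_name: str = "controls",
) -> dict[str, DatasetResult]:
    """Analyse every case dataset against the merged control dataset.

    Returns results keyed by dataset name (the control under
    ``control_name``), with folds and tests filled on each case report.
    """
    params = params or Parameters()
    control = analyze_dataset(
        control_name, control_cnvs, annotation, stma_list,
        mode=mode, is_control=True, params=params,
    )
    control.report.fold_per_1000_vs_control = 1.0
    control.report.fold_per_mb_vs_control = 1.0
    out: dict[str, DatasetResult] = {}
    for name, cnvs in case_cnv_sets.items():
        res = analyze_dataset(name, cnvs, annotation, stma_list, mode=mode, params=params)
        res.report = fold_vs_control(res.report, control.report)
        out[name] = res
    out[control_name] = control
    return out
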