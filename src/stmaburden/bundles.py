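"""Loader for a study bundle: annotation, gene lists and per-dataset CNV tables.

A *bundle* is a directory holding everything one burden analysis needs, in
plain text:

    manifest.tsv          dataset <TAB> role (case|control) <TAB> file
    annotation.bed        chrom start end symbol  (one line per gene interval)
    stma_genes.txt        one symbol per line
    ba_genes.txt          one symbol per line (optional)
    expressed_genes.txt   one symbol per line (optional; permutation pool)
    <dataset>.bed         BED-like CNV coordinates referenced by the manifest

This is the layout into which published per-study CNV coordinate tables and
allelic-expression gene lists (e.g. spreadsheet supplements of CNV burden
studies) are exported for reproduction runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .allelic import read_gene_list
from .regions import GeneAnnotation, GenomicInterval, read_cnv_bed, read_gene_annotation


@dataclass
class StudyBundle:
    annotation: list[GeneAnnotation]
    stma_genes: set[str]
    ba_genes: set[str] = field(default_factory=set)
    expressed_genes: set[str] = field(default_factory=set)
    case_cnv_sets: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    control_cnvs: list[GenomicInterval] = field(default_factory=list)


def load_study_bundle(path: str | Path) -> StudyBundle:
    """Load a bundle directory; raises FileNotFoundError when it is absent."""
    path = Path(path)
    manifest = path / "manifest.tsv"
    if not manifest.is_file():
        raise FileNotFoundError(
            f"study bundle not found at {path} (expected manifest.tsv; see module docs)"
        )
    bundle = StudyBundle(
        annotation=read_gene_annotation(path / "annotation.bed"),
        stma_genes=read_gene_list(path / "stma_genes.txt"),
    )
    for opt, attr in [("ba_genes.txt", "ba_genes"), ("expressed_genes.txt", "expressed_genes")]:
        if (path / opt).is_file():
            setattr(bundle, attr, read_gene_list(path / opt))
    for line in manifest.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, role, fname = line.split("\t")
        cnvs = read_cnv_bed(path / fname, label=name)
        if role == "control":
            bundle.control_cnvs.extend(cnvs)
        elif role == "case":
            bundle.case_cnv_sets[name] = cnvs
        else:
            raise ValueError(f"{manifest}: unknown role {role!r} for {name}")
    return bundle
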