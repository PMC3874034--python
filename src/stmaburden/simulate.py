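"""Synthetic study generator: clonal allelic tables, a toy genome, CNV datasets.

The generator emulates the statistical structure the burden analysis assumes,
at roughly human scale by default: a few thousand assayed genes of fixed
10 kb length spread over a ~3 Gb genome, a control CNV dataset of many small
variants (exponential lengths, mean 0.49 Mb, as in population-survey control
sets) and a smaller case dataset of larger CNVs.  Case CNVs can be *enriched*
for StMA genes: each case CNV is, with probability ``q``, centred on a random
StMA gene instead of being placed uniformly.

``q`` is solved from the requested ``planted_enrichment`` fold ``F`` so that
the *measured* StMA-per-1000 fold of the case dataset relative to a uniform
control has expectation ``F``.  With per-gene background coverage probability
``c_b = 1 - exp(-mu_b)`` (``mu_b = n (L + l) / G`` for ``n`` CNVs of mean
length ``L``, gene length ``l``, genome ``G``) and StMA fraction ``rho``, the
required StMA coverage is ``c_s = r c_b`` with ``r = F (1-rho) / (1 - F rho)``,
giving a targeted-hit rate ``mu_t = -ln(1 - r c_b) - mu_b`` per StMA gene and
``q = mu_t N_stma / n``.  Requests with ``F rho >= 1``, ``r c_b >= 1`` or
``q > 1`` are infeasible for the configured geometry and raise.

Everything is deterministic under ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .allelic import Status
from .regions import GeneAnnotation, GenomicInterval

GENE_LENGTH = 10_000  # bp; fixed so per-Mb and per-gene metrics stay analytically related
EXPRESSED_MEAN = 100.0  # arbitrary intensity units
SILENCED_MEAN = 4.0  # near zero but positive: exercises the fold-ratio call path
MIN_CNV_LENGTH = 1_000  # bp floor for exponential CNV lengths


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults give a control arm resembling a merged population survey (440
    CNVs, mean 0.49 Mb, >100 kb size selection applied downstream) and a case
    arm of 150 larger CNVs (mean 1.2 Mb), with 8% of assayed genes StMA —
    small enough that strong folds are geometrically plantable, large enough
    that contingency cells stay in the chi-squared regime.
    """

    n_genes: int = 3000
    n_chromosomes: int = 20
    chrom_length: int = 150_000_000
    frac_stma: float = 0.08
    frac_ba: float = 0.62
    n_clones: int = 3
    noise_sd: float = 0.2
    n_case_cnvs: int = 150
    n_control_cnvs: int = 440
    case_cnv_mean_mb: float = 1.2
    control_cnv_mean_mb: float = 0.49
    planted_enrichment: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_stma + self.frac_ba > 1:
            raise ValueError("frac_stma + frac_ba must be <= 1")
        if self.planted_enrichment < 1:
            raise ValueError("planted_enrichment must be >= 1")
        if self.case_cnv_mean_mb <= 0 or self.control_cnv_mean_mb <= 0:
            raise ValueError("CNV mean sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chrom_length


def _rng(spec: SyntheticSpec, salt: int) -> np.random.Generator:
    # independent streams per generator stage, all derived from rng_seed
    return np.random.default_rng(np.random.SeedSequence([spec.rng_seed, salt]))


def generate_genome(spec: SyntheticSpec) -> list[GeneAnnotation]:
    """Place ``n_genes`` disjoint 10 kb genes uniformly over the chromosomes."""
    rng = _rng(spec, 1)
    per_chrom = [spec.n_genes // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_genes % spec.n_chromosomes):
        per_chrom[i] += 1
    genes: list[GeneAnnotation] = []
    gid = 0
    for ci, m in enumerate(per_chrom, start=1):
        slack = spec.chrom_length - m * GENE_LENGTH
        if slack < 0:
            raise ValueError(
                f"cannot place {m} x {GENE_LENGTH} bp genes on a "
                f"{spec.chrom_length} bp chromosome"
            )
        # sorted uniform draws in the slack, shifted by the cumulative gene
        # footprint: uniform non-overlapping placement
        offsets = np.sort(rng.integers(0, slack + 1, size=m))
        for j, off in enumerate(offsets):
            start = int(off + j * GENE_LENGTH)
            gid += 1
            genes.append(
                GeneAnnotation(f"G{gid:05d}", GenomicInterval(f"chr{ci}", start, start + GENE_LENGTH))
            )
    return genes


def generate_truth(spec: SyntheticSpec, genes: Sequence[str]) -> pd.DataFrame:
    """Assign planted statuses: frac_stma StMA, frac_ba BA, remainder consistent-MA."""
    rng = _rng(spec, 2)
    symbols = np.array(sorted(genes))
    rng.shuffle(symbols)
    n = len(symbols)
    n_stma = round(spec.frac_stma * n)
    n_ba = round(spec.frac_ba * n)
    status = np.array(
        [Status.STMA.value] * n_stma
        + [Status.BA.value] * n_ba
        + [Status.CONSISTENT_MA.value] * (n - n_stma - n_ba)
    )
    return (
        pd.DataFrame({"gene": symbols, "status": status})
        .sort_values("gene")
        .reset_index(drop=True)
    )


def generate_clones(
    spec: SyntheticSpec,
    truth: pd.DataFrame | None = None,
    cell_source: str = "cortex",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-clone allelic intensities for every gene.

    BA genes express both alleles at the same mean; StMA genes pick an allele
    per clone at random (conditioned on the clones not all agreeing, so the
    planted label is realisable whenever there are >= 2 clones); consistent-MA
    genes fix one allele across clones.  The silenced allele sits near zero
    (mean 4 vs 100) and both alleles get independent multiplicative
    log-normal noise of sd ``noise_sd`` on the log scale.

    Returns (clone table, truth table).
    """
    rng = _rng(spec, 3)
    if truth is None:
        truth = generate_truth(spec, [f"G{i + 1:05d}" for i in range(spec.n_genes)])
    k = spec.n_clones
    rows_gene, rows_clone, mean_a, mean_b = [], [], [], []
    for gene, status in truth.itertuples(index=False):
        if status == Status.BA.value:
            pattern = [None] * k  # biallelic: no silenced allele
        elif status == Status.STMA.value:
            if k >= 2:
                while True:
                    choice = rng.integers(0, 2, size=k)
                    if choice.min() != choice.max():
                        break
            else:
                choice = rng.integers(0, 2, size=k)
            pattern = list(choice)
        else:  # consistent-MA: one allele silenced in every clone
            pattern = [int(rng.integers(0, 2))] * k
        for ci, sil in enumerate(pattern, start=1):
            rows_gene.append(gene)
            rows_clone.append(f"{cell_source}_c{ci}")
            if sil is None:
                mean_a.append(EXPRESSED_MEAN)
                mean_b.append(EXPRESSED_MEAN)
            elif sil == 0:  # allele A silenced
                mean_a.append(SILENCED_MEAN)
                mean_b.append(EXPRESSED_MEAN)
            else:
                mean_a.append(EXPRESSED_MEAN)
                mean_b.append(SILENCED_MEAN)
    n_rows = len(rows_gene)
    noise = np.exp(spec.noise_sd * rng.standard_normal((n_rows, 2)))
    table = pd.DataFrame(
        {
            "gene": rows_gene,
            "clone_id": rows_clone,
            "cell_source": cell_source,
            "expr_a": np.array(mean_a) * noise[:, 0],
            "expr_b": np.array(mean_b) * noise[:, 1],
        }
    )
    return table, truth


def targeting_probability(spec: SyntheticSpec, n_stma: int, n_annotated: int) -> float:
    """Per-CNV probability of centring on an StMA gene for the planted fold.

    Solves the coverage algebra in the module docstring; raises ``ValueError``
    when the requested fold is geometrically infeasible.
    """
    F = spec.planted_enrichment
    if F == 1 or n_stma == 0:
        return 0.0
    rho = n_stma / n_annotated
    if F * rho >= 1:
        raise ValueError(
            f"planted_enrichment {F} infeasible: F * stma_fraction = {F * rho:.3f} >= 1"
        )
    G = spec.genome_length
    mean_bp = spec.case_cnv_mean_mb * 1e6
    mu_b = spec.n_case_cnvs * (mean_bp + GENE_LENGTH) / G
    c_b = 1 - math.exp(-mu_b)
    r = F * (1 - rho) / (1 - F * rho)
    if r * c_b >= 1:
        raise ValueError(
            f"planted_enrichment {F} infeasible: required StMA coverage "
            f"{r * c_b:.3f} >= 1 (reduce background coverage or the fold)"
        )
    mu_t = max(0.0, -math.log(1 - r * c_b) - mu_b)
    q = mu_t * n_stma / spec.n_case_cnvs
    if q > 1:
        raise ValueError(
            f"planted_enrichment {F} infeasible: would need targeting probability "
            f"{q:.2f} > 1 (more case CNVs or fewer StMA genes required)"
        )
    return q


def generate_cnvs(
    spec: SyntheticSpec,
    annotation: Sequence[GeneAnnotation],
    stma_truth: set[str],
) -> tuple[list[GenomicInterval], list[GenomicInterval], dict]:
    """Draw case and control CNV sets; case CNVs carry the planted enrichment.

    Control CNVs are uniform with exponential lengths (mean
    ``control_cnv_mean_mb``); case CNVs have exponential lengths (mean
    ``case_cnv_mean_mb``) and are centred on a random StMA gene with the
    solved targeting probability, otherwise placed uniformly.  Returns
    (case, control, info) where info records the realised targeting.
    """
    rng = _rng(spec, 4)
    stma_genes = [g for g in annotation if g.symbol in stma_truth]
    q = targeting_probability(spec, len(stma_genes), len({g.symbol for g in annotation}))

    def _place(n: int, mean_mb: float, targeted_q: float, prefix: str) -> list[GenomicInterval]:
        out = []
        lengths = np.maximum(MIN_CNV_LENGTH, rng.exponential(mean_mb * 1e6, size=n)).astype(int)
        targeted = rng.random(n) < targeted_q
        for i in range(n):
            L = int(lengths[i])
            if targeted[i] and stma_genes:
                g = stma_genes[int(rng.integers(0, len(stma_genes)))]
                chrom = g.interval.chrom
                center = (g.interval.start + g.interval.end) // 2
            else:
                chrom = f"chr{int(rng.integers(1, spec.n_chromosomes + 1))}"
                center = int(rng.integers(0, spec.chrom_length))
            s = max(0, center - L // 2)
            e = min(spec.chrom_length, s + L)
            s = min(s, e - 1)  # keep non-empty at chromosome edges
            out.append(GenomicInterval(chrom, s, e, f"{prefix}{i + 1}"))
        return out

    case = _place(spec.n_case_cnvs, spec.case_cnv_mean_mb, q, "case_")
    control = _place(spec.n_control_cnvs, spec.control_cnv_mean_mb, 0.0, "ctrl_")
    info = {
        "targeting_prob": q,
        "planted_enrichment": spec.planted_enrichment,
        "n_stma_genes": len(stma_genes),
    }
    return case, control, info


def simulate_study(spec: SyntheticSpec, with_clones: bool = True) -> dict:
    """Generate a full synthetic study: genome, truth, clone table, CNV sets."""
    annotation = generate_genome(spec)
    truth = generate_truth(spec, [g.symbol for g in annotation])
    stma = set(truth.loc[truth["status"] == Status.STMA.value, "gene"])
    ba = set(truth.loc[truth["status"] == Status.BA.value, "gene"])
    case, control, info = generate_cnvs(spec, annotation, stma)
    out = {
        "annotation": annotation,
        "truth": truth,
        "stma_truth": stma,
        "ba_truth": ba,
        "case_cnvs": case,
        "control_cnvs": control,
        "info": info,
    }
    if with_clones:
        clones, _ = generate_clones(spec, truth)
        out["clones"] = clones
    return out
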