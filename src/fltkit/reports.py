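"""Summary statistics of a full-length-transcriptome reconstruction.

Small report helpers shared by the pipeline summaries: per-locus
isoform and ORF diversity, translational-status proportions, and
ribo-seq support of polysome-based predictions. Each accepts either
raw counts or the corresponding collections.
"""

from __future__ import annotations

from typing import Iterable, Mapping

__all__ = [
    "isoforms_per_locus",
    "orfs_per_gene",
    "inactive_fraction_pct",
    "ribo_support_pct",
    "retained_after_expression_filter",
]


def isoforms_per_locus(n_transcripts: int, n_loci: int) -> float:
    """Mean transcript isoforms per gene locus."""
    if n_loci <= 0:
        raise ValueError("no loci")
    return n_transcripts / n_loci


def orfs_per_gene(n_unique_orfs: int, n_genes: int) -> float:
    """Mean unique ORFs per gene locus after ORFeome collapsing."""
    if n_genes <= 0:
        raise ValueError("no genes")
    return n_unique_orfs / n_genes


def inactive_fraction_pct(n_inactive: int, n_classified: int) -> float:
    """Percentage of classified isoforms predicted translationally inactive."""
    if n_classified <= 0:
        raise ValueError("no classified isoforms")
    return 100.0 * n_inactive / n_classified


def ribo_support_pct(n_with_orf: int, n_active: int) -> float:
    """Percentage of predicted-active isoforms with a called translating ORF."""
    if n_active <= 0:
        raise ValueError("no active isoforms")
    return 100.0 * n_with_orf / n_active


def retained_after_expression_filter(n_total: int, n_excluded: int) -> int:
    """Isoforms remaining after low-expression exclusion."""
    if not 0 <= n_excluded <= n_total:
        raise ValueError("excluded count out of range")
    return n_total - n_excluded
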