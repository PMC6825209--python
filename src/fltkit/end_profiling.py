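"""Tag-cluster calling and transcript end validation.

5'-end (CAGE-style) and 3'-end tag positions are reduced to clusters:
a position is *signal* when its tag count strictly exceeds the local
background, defined as the maximum of (i) the mean tag coverage in a
centred window (default 500 nt, clipped at chromosome bounds) and
(ii) the depth-normalised RNA-seq coverage in a window running from
``expr_window_up`` upstream to ``expr_window_down`` downstream in
transcript orientation. Signal positions within ``merge_distance`` on
the same strand merge into one cluster.

Transcripts qualify as full-length when both strand-aware ends lie
within ``max_end_distance`` nt (inclusive) of a same-strand cluster.
Distances are signed: positive when the transcript end lies downstream
(in transcript orientation) of the cluster.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .genome_model import GenomicInterval, Transcript

__all__ = [
    "TagCluster",
    "ClusterConfig",
    "ValidationConfig",
    "tags_to_counts",
    "call_tag_clusters",
    "end_distances",
    "validate_ends",
]


@dataclass(frozen=True)
class TagCluster:
    interval: GenomicInterval
    tag_count: int
    peak: int

    def __post_init__(self) -> None:
        if self.tag_count < 1:
            raise ValueError("cluster with no tags")
        if not (self.interval.start <= self.peak < self.interval.end):
            raise ValueError("peak outside cluster interval")


@dataclass(frozen=True)
class ClusterConfig:
    merge_distance: int = 20
    local_window: int = 500
    expr_window_up: int = 500
    expr_window_down: int = 1500
    depth_norm: float | None = None  # None: total tags / total RNA-seq coverage

    def __post_init__(self) -> None:
        for name in ("merge_distance", "local_window", "expr_window_up", "expr_window_down"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ValidationConfig:
    max_end_distance: int = 50

    def __post_init__(self) -> None:
        if self.max_end_distance <= 0:
            raise ValueError("max_end_distance must be positive")


TagCounts = dict[tuple[str, str], dict[int, int]]


def tags_to_counts(tags: Iterable[tuple[str, int, int, str, int, str]]) -> TagCounts:
    """Aggregate BED6 tag records into per-(chrom, strand) position counts.

    A record of width 1 contributes its score (or 1 if the score is 0)
    at its start position.
    """
    counts: TagCounts = defaultdict(lambda: defaultdict(int))
    for chrom, start, _end, _name, score, strand in tags:
        counts[(chrom, strand)][start] += score if score > 0 else 1
    return {k: dict(v) for k, v in counts.items()}


def call_tag_clusters(
    tags: TagCounts,
    rnaseq_coverage: dict[str, np.ndarray] | None = None,
    cfg: ClusterConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[TagCluster]:
    """Call tag clusters above the dual local/expression background."""
    cfg = cfg or ClusterConfig()
    clusters: list[TagCluster] = []
    depth_norm = cfg.depth_norm
    if depth_norm is None and rnaseq_coverage:
        total_tags = sum(c for d in tags.values() for c in d.values())
        total_cov = sum(float(np.sum(v)) for v in rnaseq_coverage.values())
        depth_norm = total_tags / total_cov if total_cov > 0 else 0.0

    for (chrom, strand), posmap in sorted(tags.items()):
        if any(c < 0 for c in posmap.values()):
            raise ValueError("negative tag counts")
        positions = np.array(sorted(posmap), dtype=np.int64)
        counts = np.array([posmap[int(p)] for p in positions], dtype=np.float64)
        chrom_len = None
        if chrom_lengths and chrom in chrom_lengths:
            chrom_len = chrom_lengths[chrom]
        half = cfg.local_window // 2
        cum = np.concatenate([[0.0], np.cumsum(counts)])

        signal: list[int] = []
        for i, p in enumerate(positions):
            lo = p - half
            hi = p + half  # centred window of local_window+1 positions
            if chrom_len is not None:
                lo = max(lo, 0)
                hi = min(hi, chrom_len - 1)
            else:
                lo = max(lo, 0)
            width = hi - lo + 1
            li = np.searchsorted(positions, lo, side="left")
            ri = np.searchsorted(positions, hi, side="right")
            local_bg = (cum[ri] - cum[li]) / width
            bg = local_bg
            if rnaseq_coverage is not None and chrom in rnaseq_coverage and depth_norm:
                cov = rnaseq_coverage[chrom]
                if strand == "+":
                    wlo, whi = p - cfg.expr_window_up, p + cfg.expr_window_down
                else:
                    wlo, whi = p - cfg.expr_window_down, p + cfg.expr_window_up
                wlo = max(wlo, 0)
                whi = min(whi, len(cov) - 1)
                if whi >= wlo:
                    expr_bg = float(np.mean(cov[wlo:whi + 1])) * depth_norm
                    bg = max(bg, expr_bg)
            if counts[i] > bg:
                signal.append(i)

        # merge signal positions within merge_distance
        run: list[int] = []
        def flush(run: list[int]) -> None:
            if not run:
                return
            ps = positions[run]
            cs = counts[run]
            peak = int(ps[int(np.argmax(cs))])
            clusters.append(
                TagCluster(
                    GenomicInterval(chrom, int(ps[0]), int(ps[-1]) + 1, strand),
                    int(cs.sum()), peak,
                )
            )
        for i in signal:
            if run and positions[i] - positions[run[-1]] > cfg.merge_distance:
                flush(run)
                run = []
            run.append(i)
        flush(run)
    return clusters


def _signed_distance(p: int, cluster: TagCluster, strand: str) -> int:
    """0 inside the cluster; else distance to the nearest boundary,
    positive when p is downstream of the cluster in transcript
    orientation."""
    s, e = cluster.interval.start, cluster.interval.end
    if s <= p < e:
        return 0
    if p >= e:
        gap = p - e
        return gap if strand == "+" else -gap
    gap = s - p
    return -gap if strand == "+" else gap


def end_distances(
    transcripts: Iterable[Transcript],
    clusters: list[TagCluster],
    which_end: Literal["5prime", "3prime"],
) -> dict[str, float]:
    """Signed distance from each transcript end to the nearest
    same-strand cluster; NaN when no cluster exists on that
    chromosome/strand."""
    by_cs: dict[tuple[str, str], list[TagCluster]] = defaultdict(list)
    for c in clusters:
        by_cs[(c.interval.chrom, c.interval.strand)].append(c)
    out: dict[str, float] = {}
    for t in transcripts:
        p = t.five_prime if which_end == "5prime" else t.three_prime
        cands = by_cs.get((t.chrom, t.strand))
        if not cands:
            out[t.id] = math.nan
            continue
        best = min(
            (_signed_distance(p, c, t.strand) for c in cands),
            key=lambda d: (abs(d), d),
        )
        out[t.id] = float(best)
    return out


def validate_ends(
    transcripts: list[Transcript],
    cage: list[TagCluster],
    threeprime: list[TagCluster],
    cfg: ValidationConfig | None = None,
) -> tuple[list[Transcript], dict[str, list[str]]]:
    """Retain transcripts with both ends within ``max_end_distance``
    (inclusive) of CAGE / 3'-end clusters; report per-transcript
    rejection reasons ("5prime" and/or "3prime") for the rest."""
    cfg = cfg or ValidationConfig()
    d5 = end_distances(transcripts, cage, "5prime")
    d3 = end_distances(transcripts, threeprime, "3prime")
    kept: list[Transcript] = []
    rejected: dict[str, list[str]] = {}
    for t in transcripts:
        reasons = []
        if not (abs(d5[t.id]) <= cfg.max_end_distance):  # NaN fails too
            reasons.append("5prime")
        if not (abs(d3[t.id]) <= cfg.max_end_distance):
            reasons.append("3prime")
        if reasons:
            rejected[t.id] = reasons
        else:
            kept.append(t)
    return kept, rejected
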