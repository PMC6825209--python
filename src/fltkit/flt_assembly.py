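"""Collapse aligned long reads into a non-redundant transcript set.

Reads mapped to the same strand-specific locus are processed in order
of decreasing exon count. A read enters the non-redundant set if any of
three criteria holds: (i) its junction chain is new; (ii) its
strand-aware 5' end lies at least ``end_distance_min`` nt from the 5'
end of every current member with the same junction chain; (iii) the
same for the 3' end. Reads failing all three are absorbed as read
support of the closest same-chain member.

Mono-exonic reads have an empty junction chain; two of them share a
"chain" only if their spans overlap, so unspliced reads across the
genome do not collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import GeneLocus, GenomicInterval, Transcript, junction_chain

__all__ = ["CollapseConfig", "CollapseResult", "collapse_reads", "cluster_loci"]


@dataclass(frozen=True)
class CollapseConfig:
    end_distance_min: int = 100
    #: compare end distances against same-chain members only (default) or all members
    same_chain_only: bool = True

    def __post_init__(self) -> None:
        if self.end_distance_min <= 0:
            raise ValueError("end_distance_min must be positive")


@dataclass
class CollapseResult:
    transcripts: list[Transcript]
    support: dict[str, list[str]] = field(default_factory=dict)

    def support_count(self, tid: str) -> int:
        return len(self.support.get(tid, []))


def _sort_key(t: Transcript) -> tuple:
    # primary: exon count desc; ties: aligned length desc, then id
    return (-t.n_exons, -t.length, t.id)


def collapse_reads(alignments: list[Transcript], cfg: CollapseConfig | None = None) -> CollapseResult:
    """Collapse read alignments (per chrom/strand) to a non-redundant set."""
    cfg = cfg or CollapseConfig()
    members: list[Transcript] = []
    chains: dict[str, tuple] = {}
    support: dict[str, list[str]] = {}
    for read in sorted(alignments, key=_sort_key):
        chain = junction_chain(read)
        if chain:
            same_chain = [
                m for m in members
                if m.chrom == read.chrom and m.strand == read.strand
                and chains[m.id] == chain
            ]
        else:
            same_chain = [
                m for m in members
                if m.chrom == read.chrom and m.strand == read.strand
                and not chains[m.id] and m.span.overlaps(read.span)
            ]
        pool = same_chain if cfg.same_chain_only else [
            m for m in members if m.chrom == read.chrom and m.strand == read.strand
        ]
        keep = (
            not same_chain
            or all(abs(read.five_prime - m.five_prime) >= cfg.end_distance_min for m in pool)
            or all(abs(read.three_prime - m.three_prime) >= cfg.end_distance_min for m in pool)
        )
        if keep:
            members.append(read)
            chains[read.id] = chain
            support[read.id] = [read.id]
        else:
            host = min(
                same_chain,
                key=lambda m: (
                    abs(read.five_prime - m.five_prime) + abs(read.three_prime - m.three_prime),
                    m.id,
                ),
            )
            support[host.id].append(read.id)
    members.sort(key=lambda t: (t.chrom, t.start, t.end, t.id))
    return CollapseResult(members, support)


def cluster_loci(transcripts: list[Transcript], prefix: str = "locus") -> list[GeneLocus]:
    """Single-linkage clustering of transcripts by span overlap per strand."""
    loci: list[GeneLocus] = []
    by_group: dict[tuple[str, str], list[Transcript]] = {}
    for t in transcripts:
        by_group.setdefault((t.chrom, t.strand), []).append(t)
    n = 0
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda t: (t.start, t.end, t.id))
        cur: list[Transcript] = []
        cur_end = -1
        def flush() -> None:
            nonlocal n
            if not cur:
                return
            n += 1
            lo = min(t.start for t in cur)
            hi = max(t.end for t in cur)
            loci.append(
                GeneLocus(f"{prefix}{n}", chrom, strand,
                          GenomicInterval(chrom, lo, hi, strand),
                          [t.id for t in cur])
            )
        for t in group:
            if cur and t.start >= cur_end:  # >=: touching spans do not overlap
                flush()
                cur = []
                cur_end = -1
            cur.append(t)
            cur_end = max(cur_end, t.end)
        flush()
    return loci
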