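"""Core genomic data types and annotation I/O.

All internal coordinates are 0-based half-open on the forward genomic
strand, regardless of transcript strand. Transcript-relative coordinates
count from the biological 5' end, so on the minus strand transcript
position 0 maps to the highest genomic coordinate. GTF/GFF3 (1-based,
closed) and BED (0-based, half-open) are converted at the I/O boundary
only.

"Strand-aware" terminal ends follow TSS/TES semantics: on the minus
strand the 5' end of a transcript is its maximal genomic coordinate.
Unstranded records are rejected rather than guessed, because locus
clustering downstream is defined per strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneLocus",
    "AnnotationError",
    "junction_chain",
    "read_annotation",
    "write_annotation",
    "read_bed6",
    "write_bed6",
    "spliced_sequence",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or invariant-violating annotation records."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    """A strand-aware chain of exon intervals on one chromosome.

    ``exons`` are (start, end) pairs in ascending genomic order,
    non-overlapping, each separated from the next by an intron of at
    least 1 nt.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.id}: no exons")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        prev_end = None
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(f"{self.id}: bad exon ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise AnnotationError(
                    f"{self.id}: exons overlap or touch at {prev_end}/{s}"
                )
            prev_end = e

    # -- span / ends ---------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def five_prime(self) -> int:
        """Genomic position of the biological 5' end (TSS)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the biological 3' end (TES)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced (exonic) length in nt."""
        return sum(e - s for s, e in self.exons)

    # -- coordinate maps ----------------------------------------------
    def genomic_positions(self) -> list[int]:
        """Genomic coordinate of every transcript position, 5'->3'."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        if self.strand == "-":
            pos.reverse()
        return pos

    def subtranscript(self, tstart: int, tend: int, new_id: str | None = None) -> "Transcript":
        """Exon structure of transcript-coordinate slice [tstart, tend)."""
        if not (0 <= tstart < tend <= self.length):
            raise ValueError(f"{self.id}: bad slice [{tstart},{tend})")
        pos = self.genomic_positions()[tstart:tend]
        pos.sort()
        exons: list[tuple[int, int]] = []
        run_start = prev = pos[0]
        for p in pos[1:]:
            if p != prev + 1:
                exons.append((run_start, prev + 1))
                run_start = p
            prev = p
        exons.append((run_start, prev + 1))
        return Transcript(new_id or self.id, self.chrom, self.strand,
                          tuple(exons), self.gene_id)


@dataclass
class GeneLocus:
    """A strand-specific cluster of overlapping transcripts."""

    id: str
    chrom: str
    strand: str
    span: GenomicInterval
    members: list[str] = field(default_factory=list)


def junction_chain(t: Transcript) -> tuple[tuple[int, int], ...]:
    """Ordered (donor-side, acceptor-side) genomic junction coordinates.

    Junctions are reported in ascending genomic order as (end of the
    upstream exon, start of the downstream exon); a single-exon
    transcript has an empty chain.
    """
    return tuple(
        (self_end, next_start)
        for (_, self_end), (next_start, _) in zip(t.exons, t.exons[1:])
    )


def spliced_sequence(t: Transcript, genome: dict[str, str]) -> str:
    """Spliced transcript sequence in 5'->3' orientation."""
    chrom = genome[t.chrom]
    seq = "".join(chrom[s:e] for s, e in t.exons)
    return revcomp(seq) if t.strand == "-" else seq


# ---------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------

def _infer_dialect(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".gtf",)):
        return "GTF"
    if lower.endswith((".gff", ".gff3")):
        return "GFF3"
    if lower.endswith((".bed", ".bed12")):
        return "BED12"
    raise AnnotationError(f"cannot infer annotation dialect from {path!r}")


def read_annotation(path: str, dialect: str | None = None) -> tuple[list[Transcript], list[GeneLocus]]:
    """Read transcripts (grouped into loci) from GTF, GFF3 or BED12.

    Loci group transcripts by their annotated gene id where present;
    use :func:`fltkit.flt_assembly.cluster_loci` for overlap-based
    clustering instead.
    """
    dialect = (dialect or _infer_dialect(path)).upper()
    if dialect == "BED12":
        transcripts = list(_read_bed12(path))
    elif dialect in ("GTF", "GFF3"):
        transcripts = list(_read_gxf(path, dialect))
    else:
        raise AnnotationError(f"unknown dialect {dialect!r}")
    loci: dict[str, GeneLocus] = {}
    for t in transcripts:
        gid = t.gene_id or t.id
        if gid not in loci:
            loci[gid] = GeneLocus(gid, t.chrom, t.strand, t.span, [t.id])
        else:
            loc = loci[gid]
            loc.members.append(t.id)
            loc.span = GenomicInterval(
                loc.chrom, min(loc.span.start, t.start),
                max(loc.span.end, t.end), loc.strand,
            )
    return transcripts, list(loci.values())


def _read_gxf(path: str, dialect: str) -> Iterator[Transcript]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str | None]] = {}
    for ex in db.features_of_type("exon"):
        if ex.strand not in ("+", "-"):
            raise AnnotationError(f"unstranded exon record at line for {ex.id}")
        if dialect == "GTF":
            tids = ex.attributes.get("transcript_id", [])
            gids = ex.attributes.get("gene_id", [None])
        else:
            tids = ex.attributes.get("Parent", [])
            gids = [None]
        if not tids:
            raise AnnotationError(f"exon without transcript id: {ex}")
        for tid in tids:
            # GTF/GFF3 are 1-based closed: convert to 0-based half-open
            exons_by_tx.setdefault(tid, []).append((ex.start - 1, ex.end))
            meta[tid] = (ex.seqid, ex.strand, gids[0])
    if dialect == "GFF3":
        for tx in db.features_of_type(("mRNA", "transcript")):
            tid = tx.id
            if tid in meta:
                gid = tx.attributes.get("Parent", [None])[0]
                meta[tid] = (meta[tid][0], meta[tid][1], gid)
    for tid, exons in exons_by_tx.items():
        chrom, strand, gid = meta[tid]
        exons.sort()
        yield Transcript(tid, chrom, strand, tuple(exons), gid)


def _read_bed12(path: str) -> Iterator[Transcript]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 needs 12 fields")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: unstranded record")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            if exons[-1][1] != end:
                raise AnnotationError(f"{path}:{lineno}: blocks do not reach chromEnd")
            try:
                yield Transcript(name, chrom, strand, exons)
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc


def write_annotation(transcripts: Iterable[Transcript], path: str, dialect: str | None = None) -> None:
    """Write transcripts as GTF or BED12, sorted by (chrom, start, id)."""
    dialect = (dialect or _infer_dialect(path)).upper()
    txs = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.end, t.id))
    with open(path, "w") as fh:
        if dialect == "GTF":
            for t in txs:
                gid = t.gene_id or t.id
                attrs = f'gene_id "{gid}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.chrom}\tfltkit\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\tfltkit\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )
        elif dialect == "BED12":
            for t in txs:
                sizes = ",".join(str(e - s) for s, e in t.exons)
                offsets = ",".join(str(s - t.start) for s, _ in t.exons)
                fh.write(
                    "\t".join(
                        [
                            t.chrom, str(t.start), str(t.end), t.id, "0", t.strand,
                            str(t.start), str(t.end), "0", str(t.n_exons), sizes, offsets,
                        ]
                    )
                    + "\n"
                )
        else:
            raise AnnotationError(f"unsupported output dialect {dialect!r}")


def read_bed6(path: str) -> list[tuple[str, int, int, str, int, str]]:
    """Read BED6 records as (chrom, start, end, name, score, strand)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise AnnotationError(f"{path}:{lineno}: BED6 needs 6 fields")
            if f[5] not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: unstranded record")
            score = int(float(f[4])) if f[4] != "." else 0
            out.append((f[0], int(f[1]), int(f[2]), f[3], score, f[5]))
    return out


def write_bed6(records: Iterable[tuple[str, int, int, str, int, str]], path: str) -> None:
    recs = sorted(records, key=lambda r: (r[0], r[1], r[2], r[5], r[3]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in recs:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
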