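"""Iterative short-read-voting error correction of long reads.

Each iteration locally aligns a pool of accurate short reads to the
current long-read sequence, builds a per-position pileup, and corrects
mismatches and indels by strict-majority voting. Corrected sequences
seed the next iteration; iteration stops once the fraction of changed
bases falls below a convergence threshold.

The alignment provider is pluggable. The built-in provider is a
seed-and-extend aligner: exact k-mer seeds locate each short read on the
long read, and a windowed local alignment (match +2, mismatch -6,
affine gap -6 to open / -3 to extend, the economy of bowtie2's
``--ma 2 --mp 6 --rdg/--rfg 3,3``) produces per-column observations.
Production-scale runs can instead import SAM local alignments of short
reads against the long reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, Sequence

import edlib
from Bio import Align

__all__ = [
    "LocalAlignment",
    "CorrectionConfig",
    "KmerSeedAligner",
    "vote_column",
    "ipec_correct",
    "accuracy",
    "alignments_from_sam",
    "DELETION",
]

#: pileup symbol voting for removal of the long-read base
DELETION = "-"


@dataclass
class LocalAlignment:
    """Columns of one short read locally aligned to a long read.

    ``columns[i]`` is the observation at long-read position
    ``long_start + i``: a base, the deletion mark, or a base preceded by
    an insertion. ``insertions`` maps a long-read position p to the
    short-read bases inserted *before* p.
    """

    long_start: int
    long_end: int
    columns: list[str]
    insertions: dict[int, str]
    short_read_id: str = ""


@dataclass(frozen=True)
class CorrectionConfig:
    min_votes: int = 3          # minimum pileup coverage to touch a base
    majority_frac: float = 0.5  # strict majority threshold
    max_iter: int = 5
    converge_frac: float = 0.01  # stop when changed bases / length falls below
    coverage_cap: int = 100      # per-column pileup depth bound

    def __post_init__(self) -> None:
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        if not 0.0 < self.majority_frac < 1.0:
            raise ValueError("majority_frac must be in (0,1)")


class AlignmentProvider(Protocol):
    def __call__(self, long_read: str, short_reads: Sequence[str]) -> list[LocalAlignment]:
        ...


class KmerSeedAligner:
    """Built-in seed-and-extend local aligner for desk-scale correction."""

    def __init__(self, k: int = 13, window_margin: int = 30, min_score: float = 30.0,
                 seed_step: int = 2):
        self.k = k
        self.window_margin = window_margin
        self.min_score = min_score
        self.seed_step = seed_step
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.match_score = 2
        self._aligner.mismatch_score = -6
        self._aligner.open_gap_score = -6
        self._aligner.extend_gap_score = -3

    def __call__(self, long_read: str, short_reads: Sequence[str]) -> list[LocalAlignment]:
        k = self.k
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(0, max(len(long_read) - k + 1, 0)):
            index[long_read[i:i + k]].append(i)
        out: list[LocalAlignment] = []
        for ridx, sr in enumerate(short_reads):
            diag_votes: Counter[int] = Counter()
            for j in range(0, max(len(sr) - k + 1, 1), self.seed_step):
                for i in index.get(sr[j:j + k], ()):
                    diag_votes[i - j] += 1
            if not diag_votes:
                continue
            best_diag, _ = max(diag_votes.items(), key=lambda kv: (kv[1], -abs(kv[0])))
            lo = max(best_diag - self.window_margin, 0)
            hi = min(best_diag + len(sr) + self.window_margin, len(long_read))
            if hi - lo < k:
                continue
            window = long_read[lo:hi]
            alns = self._aligner.align(window, sr)
            try:
                aln = alns[0]
            except IndexError:
                continue
            if aln.score < self.min_score:
                continue
            out.append(_columns_from_coordinates(window, sr, aln.coordinates, lo, f"sr{ridx}"))
        return out


def _columns_from_coordinates(window: str, short: str, coords, offset: int,
                              read_id: str) -> LocalAlignment:
    """Convert a Biopython alignment path into per-column observations."""
    t, q = coords[0], coords[1]
    long_start = offset + int(t[0])
    columns: list[str] = []
    insertions: dict[int, str] = {}
    for s in range(len(t) - 1):
        dt, dq = int(t[s + 1] - t[s]), int(q[s + 1] - q[s])
        if dt and dq:                   # aligned block
            columns.extend(short[int(q[s]):int(q[s + 1])])
        elif dt:                        # gap in short read: vote deletions
            columns.extend(DELETION * dt)
        else:                           # extra short-read bases: insertion
            pos = offset + int(t[s])
            insertions[pos] = insertions.get(pos, "") + short[int(q[s]):int(q[s + 1])]
    long_end = offset + int(t[-1])
    return LocalAlignment(long_start, long_end, columns, insertions, read_id)


def vote_column(observations: Counter | dict | Iterable[str], original: str,
                cfg: CorrectionConfig | None = None) -> str:
    """Strict-majority vote over one pileup column.

    Returns the winning symbol (a base or the deletion mark). With
    coverage below ``min_votes``, or without a strict majority, the
    original base is kept.
    """
    cfg = cfg or CorrectionConfig()
    counts = observations if isinstance(observations, Counter) else Counter(observations)
    coverage = sum(counts.values())
    if coverage < cfg.min_votes:
        return original
    symbol, n = counts.most_common(1)[0]
    if n > cfg.majority_frac * coverage:
        return symbol
    return original


def ipec_correct(
    long_read: str,
    short_reads: Sequence[str],
    aligner: AlignmentProvider | None = None,
    cfg: CorrectionConfig | None = None,
) -> tuple[str, list[int]]:
    """Iteratively correct one long read by short-read voting.

    Returns the corrected sequence and the number of changed bases per
    iteration. Positions without coverage (or without a strict majority)
    are left untouched.
    """
    cfg = cfg or CorrectionConfig()
    aligner = aligner or KmerSeedAligner()
    seq = long_read
    changes_per_iter: list[int] = []
    for _ in range(cfg.max_iter):
        if not short_reads or not seq:
            break
        alignments = aligner(seq, short_reads)
        seq, changed = _apply_votes(seq, alignments, cfg)
        changes_per_iter.append(changed)
        if changed < cfg.converge_frac * max(len(seq), 1):
            break
    return seq, changes_per_iter


def _apply_votes(seq: str, alignments: list[LocalAlignment],
                 cfg: CorrectionConfig) -> tuple[str, int]:
    n = len(seq)
    col_votes: dict[int, Counter] = defaultdict(Counter)
    col_cov: Counter[int] = Counter()
    ins_votes: dict[int, Counter] = defaultdict(Counter)
    for aln in alignments:
        for i, obs in enumerate(aln.columns):
            p = aln.long_start + i
            if p >= n or col_cov[p] >= cfg.coverage_cap:
                continue
            col_cov[p] += 1
            col_votes[p][obs] += 1
            # a read spanning the boundary before p votes for "no insertion"
            if p > aln.long_start:
                ins_votes[p][aln.insertions.get(p, "")] += 1
    changed = 0
    out: list[str] = []
    for p in range(n):
        original = seq[p]
        # insertion before p (only boundaries covered by >= min_votes reads)
        iv = ins_votes.get(p)
        if iv:
            ins = vote_column(iv, "", cfg)
            if ins:
                out.append(ins)
                changed += len(ins)
        votes = col_votes.get(p)
        if votes is None:
            out.append(original)
            continue
        winner = vote_column(votes, original, cfg)
        if winner == DELETION:
            changed += 1
        elif winner != original:
            out.append(winner)
            changed += 1
        else:
            out.append(original)
    return "".join(out), changed


def accuracy(corrected: str, truth: str) -> float:
    """Fraction of matched bases in the optimal global alignment."""
    if not corrected or not truth:
        raise ValueError("accuracy requires non-empty sequences")
    res = edlib.align(corrected, truth, mode="NW", task="path")
    matches = 0
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ln = int(num)
            num = ""
            columns += ln
            if ch == "=":
                matches += ln
    return matches / columns


def alignments_from_sam(sam_path: str, long_reads: dict[str, str]) -> dict[str, list[LocalAlignment]]:
    """Import short-vs-long local alignments from a SAM file.

    The SAM reference sequences are the long reads; per-column
    observations are reconstructed from CIGAR operations. Soft-clipped
    short-read bases are ignored.
    """
    import pysam

    out: dict[str, list[LocalAlignment]] = defaultdict(list)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            lname = rec.reference_name
            if lname not in long_reads:
                continue
            columns: list[str] = []
            insertions: dict[int, str] = {}
            qpos = 0
            rpos = rec.reference_start
            start = rpos
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):      # M/=/X
                    columns.extend(rec.query_sequence[qpos:qpos + ln])
                    qpos += ln
                    rpos += ln
                elif op == 1:            # I: insertion before current ref pos
                    insertions[rpos] = insertions.get(rpos, "") + rec.query_sequence[qpos:qpos + ln]
                    qpos += ln
                elif op == 2:            # D
                    columns.extend(DELETION * ln)
                    rpos += ln
                elif op in (4,):         # soft clip
                    qpos += ln
            out[lname].append(LocalAlignment(start, rpos, columns, insertions, rec.query_name))
    return dict(out)
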