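"""Alternative RNA-processing events and their co-occurrence statistics.

Each full-length transcript (FLT) is matched to its most similar
reference isoform (junction-set Jaccard similarity), the structural
difference is decomposed into typed events, and event-type pairs are
tested for co-occurrence enrichment/depletion across multi-event
isoforms with one-tailed binomial tests against an independence
expectation.

Event definitions (terminal before internal; precedence
intronRetention > exonSkipping > mutuallyExclusiveExons > alt splice
site when several could fire on one block):

* tandem5UTR / tandem3UTR - same terminal-exon splice junction, only
  the TSS/TES boundary differs.
* altFirstExon / altLastExon - the terminal end differs and the
  terminal exon uses a different splice junction (or does not overlap).
* exonSkipping - an internal exon of one transcript is absent from the
  other, with both flanking junction boundaries shared.
* intronRetention - an exon of one transcript completely spans an
  intron of the other, with shared flanking exonic segments.
* alt5SpliceSite / alt3SpliceSite - a donor (5'SS) or acceptor (3'SS)
  shift, named in transcript orientation.
* mutuallyExclusiveExons - substitution of non-overlapping internal
  exons between the same flanking junctions.

A terminal-exon donor/acceptor shift with an unchanged TSS/TES is
classified as an alternative splice site, not an alternative terminal
exon: alternative first/last exons require the end itself to move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from itertools import product

import numpy as np
from scipy import stats

from .genome_model import GenomicInterval, Transcript, junction_chain

__all__ = [
    "AltEvent",
    "CooccurrenceResult",
    "EVENT_TYPES",
    "closest_reference",
    "decompose_events",
    "subtype_events",
    "cooccurrence_test",
    "divisibility_stats",
    "random_isoforms",
]

EVENT_TYPES = (
    "tandem3UTR", "altFirstExon", "exonSkipping", "intronRetention",
    "tandem5UTR", "alt5SpliceSite", "alt3SpliceSite", "altLastExon",
    "mutuallyExclusiveExons",
)

_END_TYPES = {"tandem5UTR", "tandem3UTR", "altFirstExon", "altLastExon"}
_SS_TYPES = {"alt5SpliceSite", "alt3SpliceSite"}


@dataclass(frozen=True)
class AltEvent:
    type: str
    location: GenomicInterval
    subtype: str = "none"
    flt_site: int | None = None   # varying boundary in the FLT (splice-site events)
    ref_site: int | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.subtype in ("distal", "proximal") and self.type not in _END_TYPES:
            raise ValueError("distal/proximal subtype on a non-end event")
        if self.subtype in ("upstream", "downstream") and self.type not in _SS_TYPES:
            raise ValueError("upstream/downstream subtype on a non-splice-site event")


@dataclass(frozen=True)
class CooccurrenceResult:
    pair: tuple[str, str]
    observed: int
    expected: float
    ratio: float
    direction: str            # enrichment | depletion
    p_value: float
    q_value: float = math.nan


# ---------------------------------------------------------------------
# Reference matching
# ---------------------------------------------------------------------

def closest_reference(
    flt: Transcript, reference: list[Transcript]
) -> tuple[Transcript | None, float]:
    """Most similar overlapping reference isoform by junction Jaccard.

    Ties break by smaller summed |5'| + |3'| end distance, then by
    reference id. Returns (None, 0.0) for novel loci.
    """
    jf = set(junction_chain(flt))
    best: tuple[float, int, str, Transcript] | None = None
    for ref in reference:
        if not ref.span.overlaps(flt.span):
            continue
        jr = set(junction_chain(ref))
        union = jf | jr
        sim = len(jf & jr) / len(union) if union else 1.0
        enddist = abs(flt.five_prime - ref.five_prime) + abs(flt.three_prime - ref.three_prime)
        key = (-sim, enddist, ref.id)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (sim, enddist, ref.id, ref)
    if best is None:
        return None, 0.0
    return best[3], best[0]


# ---------------------------------------------------------------------
# Event decomposition
# ---------------------------------------------------------------------

def _exonic_at(t: Transcript, pos: int) -> bool:
    return any(s <= pos < e for s, e in t.exons)


def _first_exon(t: Transcript) -> tuple[int, int]:
    """Genomic exon holding the 5' end."""
    return t.exons[0] if t.strand == "+" else t.exons[-1]


def _last_exon(t: Transcript) -> tuple[int, int]:
    return t.exons[-1] if t.strand == "+" else t.exons[0]


def decompose_events(flt: Transcript, ref: Transcript) -> list[AltEvent]:
    """Typed alternative events separating ``flt`` from ``ref``.

    Identical transcripts yield an empty list; each structural
    difference is assigned exactly one event.
    """
    if flt.chrom != ref.chrom or flt.strand != ref.strand:
        raise ValueError("transcripts on different chromosome or strand")
    if not flt.span.overlaps(ref.span):
        raise ValueError("transcripts do not overlap")
    if flt.exons == ref.exons:
        return []
    plus = flt.strand == "+"
    chrom, strand = flt.chrom, flt.strand
    events: list[AltEvent] = []

    def iv(a: int, b: int) -> GenomicInterval:
        return GenomicInterval(chrom, min(a, b), max(a, b) if a != b else a + 1, strand)

    # ---- terminal events --------------------------------------------
    # comparison region boundaries, tightened as terminal events consume ends
    r_left = max(flt.start, ref.start)
    r_right = min(flt.end, ref.end)

    fe_f, fe_r = _first_exon(flt), _first_exon(ref)
    inner5_f = (fe_f[1] if plus else fe_f[0]) if flt.n_exons > 1 else None
    inner5_r = (fe_r[1] if plus else fe_r[0]) if ref.n_exons > 1 else None
    if flt.five_prime != ref.five_prime:
        overlap5 = fe_f[0] < fe_r[1] and fe_r[0] < fe_f[1]
        if overlap5 and inner5_f == inner5_r:
            events.append(AltEvent("tandem5UTR", iv(flt.five_prime, ref.five_prime)))
        else:
            events.append(AltEvent("altFirstExon", GenomicInterval(chrom, fe_f[0], fe_f[1], strand)))
        anchors = [x for x in (inner5_f, inner5_r) if x is not None]
        if anchors:
            if plus:
                r_left = max(r_left, max(anchors))
            else:
                r_right = min(r_right, min(anchors))

    le_f, le_r = _last_exon(flt), _last_exon(ref)
    inner3_f = (le_f[0] if plus else le_f[1]) if flt.n_exons > 1 else None
    inner3_r = (le_r[0] if plus else le_r[1]) if ref.n_exons > 1 else None
    if flt.three_prime != ref.three_prime:
        overlap3 = le_f[0] < le_r[1] and le_r[0] < le_f[1]
        if overlap3 and inner3_f == inner3_r:
            events.append(AltEvent("tandem3UTR", iv(flt.three_prime, ref.three_prime)))
        else:
            events.append(AltEvent("altLastExon", GenomicInterval(chrom, le_f[0], le_f[1], strand)))
        anchors = [x for x in (inner3_f, inner3_r) if x is not None]
        if anchors:
            if plus:
                r_right = min(r_right, min(anchors))
            else:
                r_left = max(r_left, max(anchors))

    # ---- internal events: membership difference blocks in [r_left, r_right)
    if r_right <= r_left:
        return events
    bounds = sorted(
        {r_left, r_right}
        | {b for t in (flt, ref) for s, e in t.exons for b in (s, e) if r_left < b < r_right}
    )
    blocks: list[tuple[int, int, bool]] = []  # (start, end, exonic-in-flt)
    for a, b in zip(bounds, bounds[1:]):
        in_f, in_r = _exonic_at(flt, a), _exonic_at(ref, a)
        if in_f != in_r:
            if blocks and blocks[-1][1] == a and blocks[-1][2] == in_f:
                blocks[-1] = (blocks[-1][0], b, in_f)
            else:
                blocks.append((a, b, in_f))

    junc_f, junc_r = set(junction_chain(flt)), set(junction_chain(ref))
    pending_exons: list[tuple[int, int, bool]] = []  # complete-exon blocks awaiting MXE pairing

    def classify(a: int, b: int, in_flt: bool) -> AltEvent | None:
        x, y = (flt, ref) if in_flt else (ref, flt)   # exonic in x, intronic in y
        jy = junc_f if x is ref else junc_r
        both_left = _exonic_at(flt, a - 1) and _exonic_at(ref, a - 1)
        both_right = _exonic_at(flt, b) and _exonic_at(ref, b)
        # intron retention: block is a complete intron of y, exonic flanks shared
        if (a, b) in jy and both_left and both_right:
            return AltEvent("intronRetention", GenomicInterval(chrom, a, b, strand))
        complete_exon = (a, b) in x.exons
        if complete_exon:
            idx = x.exons.index((a, b))
            if 0 < idx < x.n_exons - 1:
                prev_end = x.exons[idx - 1][1]
                next_start = x.exons[idx + 1][0]
                jx_other = junc_r if x is flt else junc_f
                # skipping: the other transcript splices straight across
                if (prev_end, next_start) in jx_other:
                    return AltEvent("exonSkipping", GenomicInterval(chrom, a, b, strand))
            pending_exons.append((a, b, in_flt))
            return None
        # splice-site shift: shared exon on one flank, shared intron on the other
        if both_left and not both_right:
            # left exon continues into the block for x; varying boundary on the right
            site_x, site_y = b, a
            donor = plus
        elif both_right and not both_left:
            site_x, site_y = a, b
            donor = not plus
        else:
            return AltEvent(
                "intronRetention" if both_left and both_right else "exonSkipping",
                GenomicInterval(chrom, a, b, strand),
            )
        etype = "alt5SpliceSite" if donor else "alt3SpliceSite"
        flt_site, ref_site = (site_x, site_y) if in_flt else (site_y, site_x)
        return AltEvent(etype, GenomicInterval(chrom, a, b, strand),
                        flt_site=flt_site, ref_site=ref_site)

    for a, b, in_flt in blocks:
        ev = classify(a, b, in_flt)
        if ev is not None:
            events.append(ev)

    # pair leftover complete-exon blocks into mutually exclusive exons
    used: set[int] = set()
    for i, (a1, b1, f1) in enumerate(pending_exons):
        if i in used:
            continue
        mate = None
        for j in range(i + 1, len(pending_exons)):
            a2, b2, f2 = pending_exons[j]
            if j in used or f1 == f2:
                continue
            if b1 <= a2 or b2 <= a1:  # non-overlapping
                mate = j
                break
        if mate is not None:
            a2, b2, _ = pending_exons[mate]
            used.update((i, mate))
            events.append(
                AltEvent("mutuallyExclusiveExons",
                         GenomicInterval(chrom, min(a1, a2), max(b1, b2), strand))
            )
        else:
            used.add(i)
            events.append(AltEvent("exonSkipping", GenomicInterval(chrom, a1, b1, strand)))

    events.sort(key=lambda e: (e.location.start, e.location.end, e.type))
    return events


def subtype_events(events: list[AltEvent], flt: Transcript, ref: Transcript) -> list[AltEvent]:
    """Fill distal/proximal (end events) and upstream/downstream
    (splice-site events) subtypes.

    Distal means the FLT end lies farther from the gene body than the
    reference end; upstream/downstream compare the shifted FLT splice
    site with the reference site in genomic orientation (lower
    coordinate = upstream).
    """
    plus = flt.strand == "+"
    out: list[AltEvent] = []
    for ev in events:
        if ev.type in ("tandem5UTR", "altFirstExon"):
            distal = (flt.five_prime < ref.five_prime) if plus else (flt.five_prime > ref.five_prime)
            out.append(replace(ev, subtype="distal" if distal else "proximal"))
        elif ev.type in ("tandem3UTR", "altLastExon"):
            distal = (flt.three_prime > ref.three_prime) if plus else (flt.three_prime < ref.three_prime)
            out.append(replace(ev, subtype="distal" if distal else "proximal"))
        elif ev.type in _SS_TYPES and ev.flt_site is not None and ev.ref_site is not None:
            out.append(replace(ev, subtype="upstream" if ev.flt_site < ev.ref_site else "downstream"))
        else:
            out.append(ev)
    return out


# ---------------------------------------------------------------------
# Co-occurrence statistics
# ---------------------------------------------------------------------

def cooccurrence_test(
    event_lists: dict[str, list[AltEvent]] | list[list[AltEvent]],
    include_self: bool = True,
    use_subtypes: bool = False,
) -> list[CooccurrenceResult]:
    """One-tailed binomial co-occurrence tests over multi-event isoforms.

    Only isoforms carrying >= 2 events enter. For a type pair (A, B),
    observed is the number of isoforms containing both types, expected
    is N * pA * pB with marginal fractions over the multi-event
    isoforms, and the p-value is the binomial tail on the enrichment or
    depletion side. Self pairs (A, A) use isoforms with >= 2 events of
    the type against pA^2. Benjamini-Hochberg q-values are reported
    alongside the raw p-values.
    """
    lists = list(event_lists.values()) if isinstance(event_lists, dict) else list(event_lists)
    key = (lambda e: f"{e.type}:{e.subtype}") if use_subtypes else (lambda e: e.type)
    multi = [[key(e) for e in evs] for evs in lists if len(evs) >= 2]
    n = len(multi)
    if n == 0:
        return []
    types = sorted({t for evs in multi for t in evs})
    frac = {t: sum(1 for evs in multi if t in evs) / n for t in types}
    results: list[CooccurrenceResult] = []
    for i, a in enumerate(types):
        for b in types[i:]:
            if a == b:
                if not include_self:
                    continue
                observed = sum(1 for evs in multi if evs.count(a) >= 2)
                p = frac[a] ** 2
            else:
                observed = sum(1 for evs in multi if a in evs and b in evs)
                p = frac[a] * frac[b]
            expected = n * p
            if expected <= 0:
                continue
            if observed >= expected:
                direction = "enrichment"
                pval = float(stats.binom.sf(observed - 1, n, p))
            else:
                direction = "depletion"
                pval = float(stats.binom.cdf(observed, n, p))
            results.append(
                CooccurrenceResult((a, b), observed, expected,
                                   observed / expected, direction, pval)
            )
    if results:
        qvals = stats.false_discovery_control([r.p_value for r in results], method="bh")
        results = [replace(r, q_value=float(q)) for r, q in zip(results, qvals)]
    return results


def divisibility_stats(
    lengths: list[int], in_cds: list[bool] | None = None,
    microexon_range: tuple[int, int] = (3, 27),
) -> dict:
    """3-divisibility of cassette-exon lengths, with microexon and
    in-CDS breakdowns and a one-sided exact binomial test against 1/3."""
    lengths = list(lengths)
    if any(l < 1 for l in lengths):
        raise ValueError("lengths must be >= 1")

    def block(ls: list[int]) -> dict:
        k = sum(1 for l in ls if l % 3 == 0)
        n = len(ls)
        p = float(stats.binomtest(k, n, 1 / 3, alternative="greater").pvalue) if n else math.nan
        return {"n": n, "divisible": k, "fraction": k / n if n else math.nan, "p_value": p}

    out = {"all": block(lengths)}
    lo, hi = microexon_range
    out["microexon"] = block([l for l in lengths if lo <= l <= hi])
    if in_cds is not None:
        out["in_cds"] = block([l for l, f in zip(lengths, in_cds) if f])
        out["not_in_cds"] = block([l for l, f in zip(lengths, in_cds) if not f])
    return out


# ---------------------------------------------------------------------
# In-silico random isoforms
# ---------------------------------------------------------------------

def random_isoforms(
    isoforms: list[Transcript], n: int | str, seed: int = 0, prefix: str = "rand"
) -> list[Transcript]:
    """Random (or exhaustive, ``n='all'``) recombinations of a locus.

    Constitutive blocks are exonic segments present in every isoform of
    the locus; alternative blocks are maximal segments present in some
    but not all. Each generated isoform is the constitutive scaffold
    plus an independent uniform inclusion choice per alternative block.
    """
    if not isoforms:
        raise ValueError("empty locus")
    chrom, strand = isoforms[0].chrom, isoforms[0].strand
    bounds = sorted({b for t in isoforms for s, e in t.exons for b in (s, e)})
    segs = []
    for a, b in zip(bounds, bounds[1:]):
        n_in = sum(1 for t in isoforms if _exonic_at(t, a))
        if n_in == len(isoforms):
            segs.append((a, b, "const"))
        elif n_in > 0:
            segs.append((a, b, "alt"))
    scaffold = [(a, b) for a, b, k in segs if k == "const"]
    alt_blocks: list[tuple[int, int]] = []
    for a, b, kind in segs:
        if kind != "alt":
            continue
        if alt_blocks and alt_blocks[-1][1] == a:
            alt_blocks[-1] = (alt_blocks[-1][0], b)
        else:
            alt_blocks.append((a, b))
    k = len(alt_blocks)

    def build(choice: tuple[int, ...], idx: int) -> Transcript | None:
        parts = sorted(scaffold + [alt_blocks[i] for i, c in enumerate(choice) if c])
        if not parts:
            return None
        merged = [list(parts[0])]
        for s, e in parts[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return Transcript(f"{prefix}{idx}", chrom, strand, tuple(tuple(x) for x in merged))

    out: list[Transcript] = []
    if n == "all":
        for idx, choice in enumerate(product((0, 1), repeat=k)):
            t = build(choice, idx + 1)
            if t is not None:
                out.append(t)
    else:
        rng = np.random.default_rng(seed)
        for idx in range(int(n)):
            choice = tuple(int(c) for c in rng.integers(0, 2, k))
            t = build(choice, idx + 1)
            if t is not None:
                out.append(t)
    return out
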