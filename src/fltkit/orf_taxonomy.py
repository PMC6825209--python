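"""ORF variant taxonomy and proteogenomic peptide export.

Each unique ORF is compared, on genomic codon chains, with the
reference ORF sharing the most in-frame codons and sorted into:

* ``annotated`` - identical codon chain;
* ``variant`` - shares in-frame codons; sub-typed by where the chains
  diverge (N-terminal truncation/extension/divergence, internal
  insertion/deletion/divergence, C-terminal divergence, in-frame /
  partial-in-frame);
* ``novel`` - no in-frame codon overlap; sub-typed by genomic context
  (novel locus, different frame over an annotated ORF, annotated
  5'UTR / 3'UTR / intron).

Tryptic digestion (cleavage after K/R, not before P, up to a given
number of missed cleavages) produces candidate peptides; peptides
absent from the reference peptide universe are flagged FLT-specific
for targeted proteomic validation. N-terminal truncations and internal
deletions cannot yield FLT-specific peptides by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .genome_model import Transcript
from .translation import Orf

__all__ = [
    "OrfCategory",
    "Peptide",
    "classify_orf",
    "digest",
    "flt_specific_peptides",
]

_VARIANT_SUBS = (
    "Nterm_truncation", "Nterm_extension", "Nterm_divergence",
    "internal_insertion", "internal_deletion", "internal_divergence",
    "Cterm_divergence", "partial_in_frame", "in_frame",
)
_NOVEL_SUBS = ("novel_locus", "different_frame", "utr5", "utr3", "intron")


@dataclass(frozen=True)
class OrfCategory:
    major: str                     # annotated | variant | novel
    sub: str                       # see module docstring
    best_reference: str | None = None
    shared_codons: int = 0

    def __post_init__(self) -> None:
        ok = (
            (self.major == "annotated" and self.sub == "identical")
            or (self.major == "variant" and self.sub in _VARIANT_SUBS)
            or (self.major == "novel" and self.sub in _NOVEL_SUBS)
        )
        if not ok:
            raise ValueError(f"inconsistent category {self.major}/{self.sub}")


@dataclass(frozen=True)
class Peptide:
    sequence: str
    parent: str
    missed_cleavages: int
    flt_specific: bool = False


# ---------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------

def _common_prefix(a: tuple, b: tuple) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _variant_subtype(o: tuple, r: tuple) -> str:
    """Sub-type an ORF codon chain against its best reference chain."""
    so, sr = set(o), set(r)
    if so == sr:
        return "in_frame"
    pre = _common_prefix(o, r)
    suf = _common_prefix(o[::-1], r[::-1])
    if pre == 0 and suf > 0:
        # chains share their tail only
        if len(o) < len(r) and o == r[len(r) - len(o):]:
            return "Nterm_truncation"
        if len(o) > len(r) and o[len(o) - len(r):] == r:
            return "Nterm_extension"
        return "Nterm_divergence"
    if pre > 0 and suf > 0:
        mid_o = o[pre:len(o) - suf]
        mid_r = r[pre:len(r) - suf]
        if not mid_r:
            return "internal_insertion"
        if not mid_o:
            return "internal_deletion"
        return "internal_divergence"
    if pre > 0:
        return "Cterm_divergence"
    return "partial_in_frame"


def _context_of(orf: Orf, ref_transcripts: list[Transcript],
                ref_orfs_by_tx: Mapping[str, Orf]) -> str | None:
    """utr5/utr3/intron containment of a novel ORF in any overlapping
    reference isoform."""
    pos = set(orf.genomic_positions)
    for rt in ref_transcripts:
        lo, hi = min(pos), max(pos) + 1
        if not (rt.start < hi and lo < rt.end):
            continue
        exonic = {p for s, e in rt.exons for p in range(s, e)}
        if pos <= exonic:
            ro = ref_orfs_by_tx.get(rt.id)
            if ro is None or not ro.genomic_positions:
                continue
            cds = set(ro.genomic_positions)
            if pos & cds:
                continue
            # split exonic, non-CDS space into 5' and 3' UTR by strand
            cds_lo, cds_hi = min(cds), max(cds)
            if rt.strand == "+":
                utr5 = {p for p in exonic if p < cds_lo}
                utr3 = {p for p in exonic if p > cds_hi}
            else:
                utr5 = {p for p in exonic if p > cds_hi}
                utr3 = {p for p in exonic if p < cds_lo}
            if pos <= utr5:
                return "utr5"
            if pos <= utr3:
                return "utr3"
        else:
            intronic = set(range(rt.start, rt.end)) - {
                p for s, e in rt.exons for p in range(s, e)
            }
            if pos <= intronic:
                return "intron"
    return None


def classify_orf(
    orf: Orf,
    ref_orfs: list[Orf],
    ref_transcripts: list[Transcript] | None = None,
    ref_orfs_by_tx: Mapping[str, Orf] | None = None,
) -> OrfCategory:
    """Classify one ORF against the reference ORFs of its locus.

    The best-matching reference maximises the number of shared
    genomic codons in identical frame (ties: longer reference, then
    id). Deterministic and invariant to reference input order.
    """
    chain = orf.codon_chain()
    codons = set(chain)
    best: tuple[int, int, str, Orf] | None = None
    for ro in sorted(ref_orfs, key=lambda r: r.transcript_id):
        shared = len(codons & set(ro.codon_chain()))
        # ties: longer reference wins; further ties keep the smallest id
        if best is None or (shared, len(ro.genomic_positions)) > (best[0], best[1]):
            best = (shared, len(ro.genomic_positions), ro.transcript_id, ro)
    if best is not None and best[0] > 0:
        ref = best[3]
        rchain = ref.codon_chain()
        if chain == rchain:
            return OrfCategory("annotated", "identical", ref.transcript_id, best[0])
        return OrfCategory("variant", _variant_subtype(chain, rchain),
                           ref.transcript_id, best[0])
    # novel: decide by genomic context
    pos = set(orf.genomic_positions)
    overlapping_ref_orf = None
    for ro in sorted(ref_orfs, key=lambda r: r.transcript_id):
        if pos & set(ro.genomic_positions):
            overlapping_ref_orf = ro
            break
    if ref_transcripts:
        lo, hi = min(pos), max(pos) + 1
        locus_overlap = any(rt.start < hi and lo < rt.end for rt in ref_transcripts)
    else:
        locus_overlap = overlapping_ref_orf is not None
    if not locus_overlap:
        return OrfCategory("novel", "novel_locus")
    if overlapping_ref_orf is not None:
        return OrfCategory("novel", "different_frame")
    if ref_transcripts:
        ctx = _context_of(orf, ref_transcripts, ref_orfs_by_tx or {})
        if ctx is not None:
            return OrfCategory("novel", ctx)
    return OrfCategory("novel", "different_frame" if ref_orfs else "novel_locus")


# ---------------------------------------------------------------------
# Digestion and FLT-specific peptides
# ---------------------------------------------------------------------

def digest(
    protein: str, max_missed: int = 2, len_range: tuple[int, int] = (6, 40),
    parent: str = "",
) -> list[Peptide]:
    """Tryptic peptides: cleave C-terminal to K/R except before P.

    All fragments with up to ``max_missed`` internal missed cleavage
    sites are emitted, then filtered to ``len_range`` (inclusive, amino
    acids).
    """
    protein = protein.rstrip("*")
    if not protein:
        return []
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    lo, hi = len_range
    out: list[Peptide] = []
    for i in range(len(cuts) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(cuts):
                break
            pep = protein[cuts[i]:cuts[j]]
            if lo <= len(pep) <= hi:
                out.append(Peptide(pep, parent, missed))
    return out


def flt_specific_peptides(
    orfeome_proteins: Mapping[str, str],
    reference_proteome: Mapping[str, str] | Iterable[str],
    max_missed: int = 2,
    len_range: tuple[int, int] = (6, 40),
) -> list[Peptide]:
    """Peptides of the FLT ORFeome absent from the reference peptide
    universe (digested under identical parameters; exact string match,
    I/L kept distinct)."""
    ref_seqs = (
        reference_proteome.values()
        if isinstance(reference_proteome, Mapping)
        else reference_proteome
    )
    universe = {
        p.sequence
        for seq in ref_seqs
        for p in digest(seq, max_missed, len_range)
    }
    out: list[Peptide] = []
    for name, seq in sorted(orfeome_proteins.items()):
        for p in digest(seq, max_missed, len_range, parent=name):
            out.append(
                Peptide(p.sequence, name, p.missed_cleavages,
                        flt_specific=p.sequence not in universe)
            )
    return out
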