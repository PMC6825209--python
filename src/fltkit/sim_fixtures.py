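"""Seeded synthetic-data generators for desk-scale pipeline testing.

The generators emulate the features of a hybrid long/short-read
full-length-transcriptome experiment that the toolkit consumes:

* multi-isoform gene structures built from a constitutive exon scaffold
  plus optional alternative blocks (cassette exons, tandem UTR ends,
  alternative first/last exons, alternative donors/acceptors, retained
  introns);
* long reads with ~11% uniformly placed errors (substitution,
  insertion, deletion in 1:1:1 ratio) and stochastic 5' truncation,
  mimicking reverse-transcriptase / polymerase drop-off;
* 5' (CAGE-like) and 3' end-tag pileups with Gaussian positional noise;
* ribosome footprints whose P-sites are 3-nt periodic over true ORFs;
* polysome-fraction expression tables in which translated isoforms are
  polysome-shifted and untranslated isoforms are free-fraction-shifted.

Every generator is a pure function of (truth, config): a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_model import GeneLocus, GenomicInterval, Transcript, revcomp, spliced_sequence

__all__ = [
    "SimConfig",
    "SimTruth",
    "LongRead",
    "simulate_genome_annotation",
    "simulate_long_reads",
    "simulate_short_reads",
    "simulate_end_tags",
    "simulate_ribo_footprints",
    "simulate_polysome_profiles",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment (all tunable, all seeded)."""

    seed: int = 0
    n_genes: int = 20
    n_chromosomes: int = 2
    chromosome_length: int = 120_000
    isoforms_per_gene: tuple[int, int] = (1, 4)
    n_exons_range: tuple[int, int] = (3, 7)
    exon_len_range: tuple[int, int] = (90, 300)
    intron_len_range: tuple[int, int] = (60, 400)
    # alternative-block generation probabilities (per gene)
    p_cassette: float = 0.5
    p_tandem3: float = 0.5
    p_tandem5: float = 0.4
    p_alt_ss: float = 0.3
    p_intron_retention: float = 0.3
    couple_tandem_ends: float = 0.0
    # long reads
    long_read_error_rate: float = 0.1145
    truncation_prob5: float = 0.2
    reads_per_isoform: int = 1
    # short reads
    short_read_length: int = 100
    short_read_depth: float = 50.0
    # end tags
    tag_depth: int = 20
    tss_noise_sd: float = 5.0
    # ribosome footprints
    footprint_periodicity: float = 0.9
    footprints_per_orf: int = 60
    footprint_offlength_frac: float = 0.0
    # polysome profiles
    coding_fraction: float = 0.5
    polysome_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "p_cassette", "p_tandem3", "p_tandem5", "p_alt_ss",
            "p_intron_retention", "couple_tandem_ends", "long_read_error_rate",
            "truncation_prob5", "footprint_periodicity",
            "footprint_offlength_frac", "coding_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0,1]")
        if self.exon_len_range[1] >= self.chromosome_length:
            raise SimConfigError("exon length exceeds chromosome length")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    genome: dict[str, str]
    transcripts: list[Transcript]
    loci: list[GeneLocus]
    orfs: dict[str, tuple[int, int]]          # tid -> (start, end) transcript coords
    translated: dict[str, bool]               # tid -> active translation
    config: SimConfig

    def transcript(self, tid: str) -> Transcript:
        return next(t for t in self.transcripts if t.id == tid)


@dataclass
class LongRead:
    name: str
    seq: str
    transcript_id: str
    alignment: Transcript      # true genomic exon structure of the read span
    n_sub: int
    n_ins: int
    n_del: int
    truncated_by: int          # nt removed from the 5' end


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, cfg.seed])


def _sanitize_frame(seq: list[str], phase: int) -> None:
    """Mutate in-frame stop codons (frame starting at ``phase``) in place."""
    for i in range(phase, len(seq) - 2, 3):
        if "".join(seq[i:i + 3]) in _STOPS:
            seq[i] = "C"


# ---------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------

def simulate_genome_annotation(cfg: SimConfig) -> SimTruth:
    """Build a small genome with multi-isoform genes and planted ORFs.

    Each gene is a constitutive scaffold; isoforms toggle the gene's
    alternative blocks independently. An open reading frame is planted
    on the scaffold (ATG, stop-free body, terminal stop); cassette exons
    are length-3-divisible and stop-sanitized in the scaffold CDS frame
    so inclusion usually preserves the frame. Per-isoform true ORFs are
    re-derived from the actual spliced sequence.
    """
    rng = _rng(cfg, 1)
    genome = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=cfg.chromosome_length))
        for i in range(cfg.n_chromosomes)
    }
    editable = {c: list(s) for c, s in genome.items()}

    transcripts: list[Transcript] = []
    loci: list[GeneLocus] = []
    orfs: dict[str, tuple[int, int]] = {}
    translated: dict[str, bool] = {}

    cursor = {c: 1000 for c in genome}
    chrom_names = sorted(genome)
    for g in range(cfg.n_genes):
        chrom = chrom_names[g % len(chrom_names)]
        strand = "+" if (g // len(chrom_names)) % 2 == 0 else "-"
        gene_id = f"gene{g + 1}"
        n_ex = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        exon_lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, n_ex)
        intron_lens = rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1, max(n_ex - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursor[chrom]
        if start + span + 2000 > cfg.chromosome_length:
            raise SimConfigError(
                f"gene {gene_id} does not fit on {chrom}; increase chromosome_length"
            )
        exons: list[tuple[int, int]] = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        cursor[chrom] = pos + 1500
        scaffold = Transcript(f"{gene_id}.scaffold", chrom, strand, tuple(exons), gene_id)

        # ---- alternative blocks available in this gene ----
        feats: dict[str, object] = {}
        if n_ex >= 2 and rng.random() < cfg.p_cassette:
            intron_idx = int(rng.integers(0, n_ex - 1))
            iv = (exons[intron_idx][1], exons[intron_idx + 1][0])
            max_len = iv[1] - iv[0] - 20
            if max_len >= 33:
                clen = int(rng.integers(11, min(max_len // 3, 90) + 1)) * 3
                cstart = iv[0] + 10
                feats["cassette"] = (intron_idx, (cstart, cstart + clen))
        if rng.random() < cfg.p_tandem3:
            feats["tandem3"] = int(rng.integers(120, 400))
        if rng.random() < cfg.p_tandem5:
            feats["tandem5"] = int(rng.integers(60, 200))
        if n_ex >= 3 and rng.random() < cfg.p_alt_ss:
            feats["alt5ss"] = (int(rng.integers(1, n_ex - 1)), int(rng.integers(3, 11)) * 3)
        if n_ex >= 2 and rng.random() < cfg.p_intron_retention:
            feats["retain"] = int(rng.integers(0, n_ex - 1))

        # ---- plant an ORF on the scaffold ----
        splen = scaffold.length
        gpos = scaffold.genomic_positions()

        def edit(tpos: int, base: str) -> None:
            gp = gpos[tpos]
            editable[chrom][gp] = base if strand == "+" else revcomp(base)

        utr5 = int(rng.integers(30, min(90, splen // 4)))
        cds_len = ((splen - utr5 - 40) // 3) * 3
        cds_len = min(cds_len, ((splen * 3 // 4) // 3) * 3)
        scaffold_seq = list(spliced_sequence(scaffold, {chrom: "".join(editable[chrom])}))
        for i, b in enumerate("ATG"):
            scaffold_seq[utr5 + i] = b
        body = scaffold_seq[utr5:utr5 + cds_len]
        _sanitize_frame(body, 0)
        scaffold_seq[utr5:utr5 + cds_len] = body
        scaffold_seq[utr5 + cds_len:utr5 + cds_len + 3] = list("TAA")
        for i in range(utr5, utr5 + cds_len + 3):
            edit(i, scaffold_seq[i])
        # sanitize the cassette in the CDS frame at its insertion point
        if "cassette" in feats:
            intron_idx, (cs, ce) = feats["cassette"]
            ins_tpos = sum(e - s for s, e in exons[: intron_idx + 1])
            if strand == "-":
                ins_tpos = splen - ins_tpos
            phase = (3 - (ins_tpos - utr5) % 3) % 3
            if strand == "+":
                cseq = [editable[chrom][p] for p in range(cs, ce)]
            else:
                cseq = list(revcomp("".join(editable[chrom][p] for p in range(cs, ce))))
            _sanitize_frame(cseq, phase)
            if strand == "+":
                for k, p in enumerate(range(cs, ce)):
                    editable[chrom][p] = cseq[k]
            else:
                back = revcomp("".join(cseq))
                for k, p in enumerate(range(cs, ce)):
                    editable[chrom][p] = back[k]

        # ---- realize isoforms ----
        n_iso = int(rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1))
        seen: set[tuple[tuple[int, int], ...]] = set()
        members: list[str] = []
        for k in range(n_iso):
            iso_exons = [list(e) for e in exons]
            if k > 0:  # first isoform is the scaffold itself
                if "cassette" in feats and rng.random() < 0.5:
                    idx, block = feats["cassette"]
                    iso_exons.insert(idx + 1, list(block))
                use_t5 = "tandem5" in feats and rng.random() < 0.5
                use_t3 = False
                if "tandem3" in feats:
                    if "tandem5" in feats and rng.random() < cfg.couple_tandem_ends:
                        use_t3 = use_t5
                    else:
                        use_t3 = rng.random() < 0.5
                if use_t5:
                    d = feats["tandem5"]
                    if strand == "+":
                        iso_exons[0][0] -= d
                    else:
                        iso_exons[-1][1] += d
                if use_t3:
                    d = feats["tandem3"]
                    if strand == "+":
                        iso_exons[-1][1] += d
                    else:
                        iso_exons[0][0] -= d
                if "alt5ss" in feats and rng.random() < 0.5:
                    idx, shift = feats["alt5ss"]
                    if iso_exons[idx][1] + shift < iso_exons[idx + 1][0] - 10:
                        iso_exons[idx][1] += shift
                if "retain" in feats and rng.random() < 0.4:
                    idx = feats["retain"]
                    if idx + 1 < len(iso_exons) and iso_exons[idx][1] == exons[idx][1]:
                        iso_exons[idx][1] = iso_exons[idx + 1][1]
                        del iso_exons[idx + 1]
            key = tuple(tuple(e) for e in iso_exons)
            if key in seen:
                continue
            seen.add(key)
            tid = f"{gene_id}.iso{len(members) + 1}"
            members.append(tid)
            transcripts.append(Transcript(tid, chrom, strand, key, gene_id))
        lo = min(t.start for t in transcripts if t.gene_id == gene_id)
        hi = max(t.end for t in transcripts if t.gene_id == gene_id)
        loci.append(GeneLocus(gene_id, chrom, strand,
                              GenomicInterval(chrom, lo, hi, strand), members))

    genome = {c: "".join(s) for c, s in editable.items()}

    # per-isoform true ORFs from the realized sequences
    rng2 = _rng(cfg, 2)
    for t in transcripts:
        seq = spliced_sequence(t, genome)
        orf = _longest_orf(seq)
        if orf is not None:
            orfs[t.id] = orf
        translated[t.id] = bool(orf is not None and rng2.random() < cfg.coding_fraction)

    return SimTruth(genome, transcripts, loci, orfs, translated, cfg)


def _longest_orf(seq: str) -> tuple[int, int] | None:
    """Longest ATG->stop span (stop included), transcript coordinates."""
    best: tuple[int, int] | None = None
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in _STOPS and start is not None:
                if best is None or i + 3 - start > best[1] - best[0]:
                    best = (start, i + 3)
                start = None
    return best


# ---------------------------------------------------------------------
# Long and short reads
# ---------------------------------------------------------------------

def simulate_long_reads(truth: SimTruth, cfg: SimConfig | None = None) -> list[LongRead]:
    """One (or more) error-laden long read per isoform.

    Substitutions, insertions and deletions are injected uniformly at
    ``long_read_error_rate`` in ratio 1:1:1. With probability
    ``truncation_prob5`` the read starts downstream of the true TSS, the
    truncation length uniform over the 5' half of the transcript.
    """
    cfg = cfg or truth.config
    rng = _rng(cfg, 3)
    reads: list[LongRead] = []
    for t in truth.transcripts:
        full = spliced_sequence(t, truth.genome)
        for r in range(cfg.reads_per_isoform):
            trunc = 0
            if rng.random() < cfg.truncation_prob5:
                trunc = int(rng.integers(1, max(len(full) // 2, 2)))
            tseq = full[trunc:]
            aln = t.subtranscript(trunc, t.length) if trunc else t
            out: list[str] = []
            n_sub = n_ins = n_del = 0
            for base in tseq:
                u = rng.random()
                if u < cfg.long_read_error_rate:
                    op = int(rng.integers(0, 3))
                    if op == 0:      # substitution
                        choices = [b for b in "ACGT" if b != base]
                        out.append(choices[int(rng.integers(0, 3))])
                        n_sub += 1
                    elif op == 1:    # insertion before the base
                        out.append(str(rng.choice(_BASES)))
                        out.append(base)
                        n_ins += 1
                    else:            # deletion
                        n_del += 1
                else:
                    out.append(base)
            name = f"{t.id}.read{r + 1}"
            reads.append(LongRead(name, "".join(out), t.id,
                                  Transcript(name, aln.chrom, aln.strand, aln.exons, t.gene_id),
                                  n_sub, n_ins, n_del, trunc))
    return reads


def simulate_short_reads(truth: SimTruth, cfg: SimConfig | None = None) -> dict[str, list[str]]:
    """Error-free short reads per isoform at ``short_read_depth`` coverage.

    Read start positions are uniform over the transcript; reads are
    returned in transcript (5'->3') orientation, grouped by isoform.
    """
    cfg = cfg or truth.config
    rng = _rng(cfg, 4)
    out: dict[str, list[str]] = {}
    L = cfg.short_read_length
    for t in truth.transcripts:
        seq = spliced_sequence(t, truth.genome)
        if len(seq) <= L:
            out[t.id] = [seq]
            continue
        n = int(round(cfg.short_read_depth * len(seq) / L))
        starts = rng.integers(0, len(seq) - L + 1, n)
        out[t.id] = [seq[s:s + L] for s in sorted(map(int, starts))]
    return out


# ---------------------------------------------------------------------
# End tags, footprints, polysome profiles
# ---------------------------------------------------------------------

def simulate_end_tags(
    truth: SimTruth, cfg: SimConfig | None = None
) -> tuple[list[tuple[str, int, int, str, int, str]], list[tuple[str, int, int, str, int, str]]]:
    """CAGE-like 5' tags and 3'-seq tags as BED6 records (one per tag).

    Per distinct true TSS/TES, ``tag_depth`` tags are placed at the true
    site plus rounded Gaussian noise (sd ``tss_noise_sd``), on the
    transcript's strand.
    """
    cfg = cfg or truth.config
    rng = _rng(cfg, 5)
    cage: list[tuple[str, int, int, str, int, str]] = []
    threeprime: list[tuple[str, int, int, str, int, str]] = []
    tss_sites = sorted({(t.chrom, t.strand, t.five_prime) for t in truth.transcripts})
    tes_sites = sorted({(t.chrom, t.strand, t.three_prime) for t in truth.transcripts})
    for sites, sink, tag in ((tss_sites, cage, "cage"), (tes_sites, threeprime, "tes")):
        for i, (chrom, strand, site) in enumerate(sites):
            noise = np.rint(rng.normal(0.0, cfg.tss_noise_sd, cfg.tag_depth)).astype(int)
            for j, dv in enumerate(noise):
                p = max(int(site) + int(dv), 0)
                sink.append((chrom, p, p + 1, f"{tag}{i}_{j}", 1, strand))
    return cage, threeprime


def simulate_ribo_footprints(
    truth: SimTruth, cfg: SimConfig | None = None
) -> list[tuple[str, int, int]]:
    """Footprints as (transcript_id, 5'-end transcript position, length).

    For each translated isoform's true ORF, P-sites are drawn uniformly
    over its codons (stop excluded); a P-site falls in frame 0 with
    probability ``footprint_periodicity``, otherwise uniformly in frames
    1-2. The footprint 5' end is P-site - 12. A configurable fraction of
    reads gets an off length (31 nt), which P-site assignment discards.
    """
    cfg = cfg or truth.config
    rng = _rng(cfg, 6)
    out: list[tuple[str, int, int]] = []
    for t in truth.transcripts:
        if not truth.translated.get(t.id) or t.id not in truth.orfs:
            continue
        start, end = truth.orfs[t.id]
        n_codons = (end - start) // 3 - 1  # coding codons, stop excluded
        if n_codons < 1:
            continue
        for _ in range(cfg.footprints_per_orf):
            ci = int(rng.integers(0, n_codons))
            frame = 0 if rng.random() < cfg.footprint_periodicity else int(rng.integers(1, 3))
            psite = start + 3 * ci + frame
            five = psite - 12
            if rng.random() < cfg.footprint_offlength_frac:
                length = 31
            else:
                length = int(rng.choice([28, 29, 30]))
            if five < 0 or five + length > t.length:
                continue
            out.append((t.id, five, length))
    return out


def simulate_polysome_profiles(
    truth: SimTruth, cfg: SimConfig | None = None
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Per-isoform TPM across {free, mono, poly} x {rep1, rep2}.

    Translated isoforms are polysome-shifted (poly >> free), untranslated
    ones the reverse; replicate noise is log-normal with sd
    ``polysome_noise_sd`` (log2 scale). Returns the table and the true
    active/inactive labels.
    """
    cfg = cfg or truth.config
    rng = _rng(cfg, 7)
    rows = []
    labels: dict[str, bool] = {}
    cols = [f"{frac}_rep{r}" for r in (1, 2) for frac in ("free", "mono", "poly")]
    for t in truth.transcripts:
        active = truth.translated.get(t.id, False)
        labels[t.id] = active
        base = float(2.0 ** rng.normal(4.0, 1.0))
        mix = (0.1, 0.3, 1.0) if active else (1.0, 0.3, 0.1)
        vals = []
        for _rep in (1, 2):
            for m in mix:
                vals.append(base * m * 2.0 ** rng.normal(0.0, cfg.polysome_noise_sd))
        rows.append([t.id] + vals)
    df = pd.DataFrame(rows, columns=["isoform"] + cols).set_index("isoform")
    return df, labels


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str, width: int = 80) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
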