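"""End-to-end benchmark runs used by the acceptance checks.

These drive the simulators and the pipeline at fixed desk-scale problem
sizes and return summary numbers; they contain no thresholds of their
own.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import sim_fixtures as sf
from .genome_model import spliced_sequence
from .ipec import KmerSeedAligner, accuracy, ipec_correct

__all__ = ["correction_benchmark"]


def correction_benchmark(
    seeds: list[int],
    n_transcripts: int = 50,
    error_rate: float = 0.1145,
    short_depth: float = 50.0,
) -> dict:
    """Scaled replication of long-read correction.

    Per seed: ``n_transcripts`` single-isoform genes with 1-3 kb
    transcripts, one long read each at ``error_rate`` (sub:ins:del
    1:1:1, uniform positions), error-free 100-nt short reads at
    ``short_depth``x coverage, correction with the default config and
    the built-in seed-and-extend aligner. Returns mean pre- and
    post-correction global-alignment accuracy (percent) over all reads.
    """
    aligner = KmerSeedAligner()
    pre, post = [], []
    for seed in seeds:
        cfg = sf.SimConfig(
            seed=seed,
            n_genes=n_transcripts,
            n_chromosomes=max(2, n_transcripts // 10),
            isoforms_per_gene=(1, 1),
            n_exons_range=(4, 8),
            exon_len_range=(150, 400),
            long_read_error_rate=error_rate,
            truncation_prob5=0.0,
            short_read_depth=short_depth,
        )
        truth = sf.simulate_genome_annotation(cfg)
        reads = sf.simulate_long_reads(truth)
        shorts = sf.simulate_short_reads(truth)
        for r in reads:
            ts = spliced_sequence(truth.transcript(r.transcript_id), truth.genome)
            pre.append(accuracy(r.seq, ts))
            fixed, _ = ipec_correct(r.seq, shorts[r.transcript_id], aligner)
            post.append(accuracy(fixed, ts))
    return {
        "pre_accuracy_pct": 100.0 * float(np.mean(pre)),
        "post_accuracy_pct": 100.0 * float(np.mean(post)),
        "n_reads": len(post),
    }
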