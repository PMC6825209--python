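"""Event decomposition, co-occurrence statistics, random isoforms."""

import math
import random
from fractions import Fraction

import pytest

from fltkit import sim_fixtures as sf
from fltkit.event_analysis import (
    AltEvent,
    closest_reference,
    cooccurrence_test,
    decompose_events,
    divisibility_stats,
    random_isoforms,
    subtype_events,
)
from fltkit.genome_model import GenomicInterval, Transcript


def T(tid, exons, strand="+", chrom="chr1"):
    return Transcript(tid, chrom, strand, tuple(exons))


# ---------------------------------------------------------------------
# Reference matching
# ---------------------------------------------------------------------

def test_closest_reference_identity():
    flt = T("f", [(100, 200), (300, 400)])
    ref = T("r", [(100, 200), (300, 400)])
    other = T("o", [(100, 200), (350, 400)])
    best, sim = closest_reference(flt, [other, ref])
    assert best.id == "r" and sim == 1.0


def test_closest_reference_jaccard():
    # junctions {j1,j2,j3} vs {j1,j2} -> 2/3
    flt = T("f", [(0, 100), (200, 300), (400, 500), (600, 700)])
    ref = T("r", [(0, 100), (200, 300), (400, 700)])
    _best, sim = closest_reference(flt, [ref])
    assert sim == pytest.approx(2 / 3)


def test_closest_reference_novel_locus():
    flt = T("f", [(100, 200)])
    refs = [T("r", [(10_000, 10_200)])]
    assert closest_reference(flt, refs) == (None, 0.0)


# ---------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------

def test_decompose_identity_is_empty():
    t = T("t", [(100, 200), (300, 400)])
    assert decompose_events(t, t) == []


@pytest.mark.parametrize(
    "flt_exons,ref_exons,strand,expected",
    [
        # cassette skipped in the FLT
        ([(100, 200), (500, 600)], [(100, 200), (300, 400), (500, 600)], "+",
         [("exonSkipping", 300, 400)]),
        # retained intron
        ([(100, 400)], [(100, 200), (300, 400)], "+",
         [("intronRetention", 200, 300)]),
        # distal tandem 3'UTR
        ([(100, 200), (500, 800)], [(100, 200), (500, 600)], "+",
         [("tandem3UTR", 599, 799)]),
        # tandem 5'UTR on minus strand (extension at high coordinates)
        ([(100, 200), (300, 460)], [(100, 200), (300, 400)], "-",
         [("tandem5UTR", 399, 459)]),
        # donor shift (plus strand) = alternative 5' splice site
        ([(100, 209), (300, 400)], [(100, 200), (300, 400)], "+",
         [("alt5SpliceSite", 200, 209)]),
        # acceptor shift (plus strand) = alternative 3' splice site
        ([(100, 200), (309, 400)], [(100, 200), (300, 400)], "+",
         [("alt3SpliceSite", 300, 309)]),
        # mutually exclusive internal exons
        ([(100, 200), (400, 450), (500, 600)],
         [(100, 200), (300, 350), (500, 600)], "+",
         [("mutuallyExclusiveExons", 300, 450)]),
        # alternative first exon (different promoter, different junction)
        ([(50, 120), (300, 400)], [(150, 250), (300, 400)], "+",
         [("altFirstExon", 50, 120)]),
        # two coupled events in one isoform
        ([(100, 200), (500, 800)], [(100, 200), (300, 400), (500, 600)], "+",
         [("exonSkipping", 300, 400), ("tandem3UTR", 599, 799)]),
    ],
)
def test_decompose_event_types(flt_exons, ref_exons, strand, expected):
    flt, ref = T("f", flt_exons, strand), T("r", ref_exons, strand)
    events = decompose_events(flt, ref)
    got = sorted((e.type, e.location.start, e.location.end) for e in events)
    assert got == sorted(expected)


def test_decompose_rejects_bad_inputs():
    with pytest.raises(ValueError):
        decompose_events(T("a", [(0, 100)]), T("b", [(0, 100)], strand="-"))
    with pytest.raises(ValueError):
        decompose_events(T("a", [(0, 100)]), T("b", [(500, 600)]))


@pytest.mark.parametrize("seed", range(8))
def test_event_count_symmetry(seed):
    """|decompose(a,b)| == |decompose(b,a)| on simulated isoform pairs."""
    truth = sf.simulate_genome_annotation(sf.SimConfig(seed=seed, n_genes=6,
                                                       isoforms_per_gene=(2, 4)))
    by_gene = {}
    for t in truth.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for group in by_gene.values():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                assert len(decompose_events(a, b)) == len(decompose_events(b, a))


@pytest.mark.parametrize(
    "flt_exons,ref_exons,strand,etype,sub",
    [
        ([(100, 200), (500, 800)], [(100, 200), (500, 600)], "+", "tandem3UTR", "distal"),
        ([(100, 200), (500, 560)], [(100, 200), (500, 600)], "+", "tandem3UTR", "proximal"),
        ([(60, 200), (500, 600)], [(100, 200), (500, 600)], "+", "tandem5UTR", "distal"),
        ([(100, 191), (300, 400)], [(100, 200), (300, 400)], "+", "alt5SpliceSite", "upstream"),
        ([(100, 209), (300, 400)], [(100, 200), (300, 400)], "+", "alt5SpliceSite", "downstream"),
        ([(100, 200), (291, 400)], [(100, 200), (300, 400)], "+", "alt3SpliceSite", "upstream"),
    ],
)
def test_subtypes(flt_exons, ref_exons, strand, etype, sub):
    flt, ref = T("f", flt_exons, strand), T("r", ref_exons, strand)
    events = subtype_events(decompose_events(flt, ref), flt, ref)
    assert [(e.type, e.subtype) for e in events] == [(etype, sub)]


def test_skipping_subtype_is_none():
    flt = T("f", [(100, 200), (500, 600)])
    ref = T("r", [(100, 200), (300, 400), (500, 600)])
    events = subtype_events(decompose_events(flt, ref), flt, ref)
    assert events[0].subtype == "none"


# ---------------------------------------------------------------------
# Co-occurrence statistics vs exact binomial oracle
# ---------------------------------------------------------------------

def _ev(etype):
    return AltEvent(etype, GenomicInterval("chr1", 0, 1, "+"))


def _exact_tail(observed, n, p: Fraction, upper: bool) -> float:
    total = Fraction(0)
    rng = range(observed, n + 1) if upper else range(0, observed + 1)
    for k in rng:
        total += (
            Fraction(math.comb(n, k)) * p ** k * (1 - p) ** (n - k)
        )
    return float(total)


def test_cooccurrence_worked_example():
    """N=100, pA=pB=0.5, observed 40 -> expected 25, enrichment."""
    lists = (
        [[_ev("exonSkipping"), _ev("intronRetention")]] * 40
        + [[_ev("exonSkipping"), _ev("tandem3UTR")]] * 10
        + [[_ev("intronRetention"), _ev("tandem3UTR")]] * 10
        + [[_ev("tandem3UTR"), _ev("tandem5UTR")]] * 40
    )
    res = {r.pair: r for r in cooccurrence_test(lists, include_self=False)}
    r = res[("exonSkipping", "intronRetention")]
    assert r.observed == 40
    assert r.expected == pytest.approx(25.0)
    assert r.ratio == pytest.approx(1.6)
    assert r.direction == "enrichment"
    oracle = _exact_tail(40, 100, Fraction(1, 4), upper=True)
    assert r.p_value == pytest.approx(oracle, abs=1e-12)


def test_cooccurrence_depletion_closed_form():
    """Never co-occurring pair with pA*pB=1/4: p = 0.75^100."""
    lists = (
        [[_ev("exonSkipping"), _ev("tandem3UTR")]] * 25
        + [[_ev("exonSkipping"), _ev("tandem5UTR")]] * 25
        + [[_ev("intronRetention"), _ev("tandem3UTR")]] * 25
        + [[_ev("intronRetention"), _ev("tandem5UTR")]] * 25
    )
    res = {r.pair: r for r in cooccurrence_test(lists, include_self=False)}
    r = res[("exonSkipping", "intronRetention")]
    assert r.direction == "depletion"
    assert r.p_value == pytest.approx(0.75 ** 100, rel=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_cooccurrence_matches_exact_binomial_oracle(seed):
    rng = random.Random(seed)
    types = ["exonSkipping", "intronRetention", "tandem3UTR", "tandem5UTR"]
    lists = []
    for _ in range(rng.randint(20, 60)):
        k = rng.randint(2, 4)
        lists.append([_ev(t) for t in rng.sample(types, k)])
    n = len(lists)
    for r in cooccurrence_test(lists, include_self=False):
        a, b = r.pair
        ca = sum(1 for evs in lists if any(e.type == a for e in evs))
        cb = sum(1 for evs in lists if any(e.type == b for e in evs))
        p = Fraction(ca, n) * Fraction(cb, n)
        oracle = _exact_tail(r.observed, n, p, upper=(r.direction == "enrichment"))
        assert r.p_value == pytest.approx(oracle, abs=1e-12)


def test_cooccurrence_self_pair_uses_double_events():
    lists = [[_ev("intronRetention"), _ev("intronRetention")]] * 5 + [
        [_ev("intronRetention"), _ev("exonSkipping")]
    ] * 5
    res = {r.pair: r for r in cooccurrence_test(lists)}
    r = res[("intronRetention", "intronRetention")]
    assert r.observed == 5  # only isoforms with >= 2 retention events


def test_cooccurrence_empty_input():
    assert cooccurrence_test([]) == []
    assert cooccurrence_test([[_ev("exonSkipping")]]) == []  # no multi-event isoform


def test_planted_coupling_recovered():
    """Coupled tandem-end choices produce detectable enrichment."""
    # internal events are made common so that isoforms lacking both tandem
    # events still qualify as multi-event (otherwise the conditioning on
    # >= 2 events inflates the tandem marginals and masks the coupling)
    truth = sf.simulate_genome_annotation(
        sf.SimConfig(seed=12, n_genes=60, isoforms_per_gene=(3, 5),
                     p_tandem3=1.0, p_tandem5=1.0, couple_tandem_ends=0.95,
                     p_cassette=1.0, p_alt_ss=1.0, p_intron_retention=0.8)
    )
    by_gene = {}
    for t in truth.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    lists = []
    for group in by_gene.values():
        scaffold = group[0]
        for iso in group[1:]:
            lists.append(decompose_events(iso, scaffold))
    res = {r.pair: r for r in cooccurrence_test(lists, include_self=False)}
    r = res[("tandem3UTR", "tandem5UTR")]
    assert r.direction == "enrichment"
    assert r.p_value < 0.01


# ---------------------------------------------------------------------
# Divisibility and random isoforms
# ---------------------------------------------------------------------

def test_divisibility_basic():
    rep = divisibility_stats([99, 100, 150])
    assert rep["all"]["divisible"] == 2
    assert rep["all"]["fraction"] == pytest.approx(2 / 3)


def test_microexon_boundary():
    rep = divisibility_stats([27, 28])
    assert rep["microexon"]["n"] == 1  # only 27 nt qualifies (3-27 nt)


def test_all_divisible_closed_form_p():
    n = 7
    rep = divisibility_stats([3 * k for k in range(1, n + 1)])
    assert rep["all"]["fraction"] == 1.0
    assert rep["all"]["p_value"] == pytest.approx((1 / 3) ** n, rel=1e-9)


def test_divisibility_cds_split():
    rep = divisibility_stats([9, 10, 12], in_cds=[True, True, False])
    assert rep["in_cds"]["n"] == 2 and rep["in_cds"]["divisible"] == 1
    assert rep["not_in_cds"]["divisible"] == 1


def test_random_isoforms_degenerate_locus():
    iso = T("i", [(100, 200), (300, 400)])
    out = random_isoforms([iso, iso], "all")
    assert [t.exons for t in out] == [((100, 200), (300, 400))]


def test_random_isoforms_enumerate_cassettes():
    """k independent cassette blocks enumerate to 2^k isoforms."""
    base = [(0, 100), (1000, 1100)]
    cassettes = [(200, 260), (400, 460), (600, 660)]
    isoforms = []
    for mask in range(8):
        exons = sorted(base + [c for i, c in enumerate(cassettes) if mask & (1 << i)])
        isoforms.append(T(f"i{mask}", exons))
    out = random_isoforms(isoforms, "all")
    assert len({t.exons for t in out}) == 8


def test_random_isoforms_seeded_determinism():
    iso1 = T("a", [(0, 100), (200, 300), (400, 500)])
    iso2 = T("b", [(0, 100), (400, 500)])
    s1 = [t.exons for t in random_isoforms([iso1, iso2], 10, seed=3)]
    s2 = [t.exons for t in random_isoforms([iso1, iso2], 10, seed=3)]
    assert s1 == s2
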