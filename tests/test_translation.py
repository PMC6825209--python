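"""ORFscore, ORF enumeration/selection, polysome status classification."""

import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from fltkit import sim_fixtures as sf
from fltkit.genome_model import Transcript, spliced_sequence
from fltkit.translation import (
    FrameCounts,
    Orf,
    PsiteConfig,
    TranslationStatusClassifier,
    assign_psites,
    collapse_orfeome,
    enumerate_orfs,
    exclude_low_expression,
    extract_features,
    frame_counts,
    orfscore,
    predict_status,
    select_translating_orf,
    train_status_ensemble,
    translate,
)

SMALL_GRID = dict(C_grid=[2.0, 32.0, 512.0], gamma_grid=[2.0 ** -7, 2.0 ** -3, 2.0])


# ---------------------------------------------------------------------
# ORFscore
# ---------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        ((10, 0, 0), math.log2(21)),
        ((5, 5, 5), 0.0),
        ((0, 10, 0), -math.log2(21)),
        ((30, 3, 3), math.log2(41.5)),
        ((0, 0, 0), 0.0),
    ],
)
def test_orfscore_closed_forms(counts, expected):
    assert orfscore(counts) == pytest.approx(expected, abs=1e-12)
    if counts == (30, 3, 3):
        assert orfscore(counts) > 5  # qualifies as translating


def _oracle_orfscore(f1, f2, f3):
    """Arbitrary-precision re-derivation of the frame-bias statistic."""
    n = f1 + f2 + f3
    if n == 0:
        return 0.0
    fbar = Fraction(n, 3)
    chi = sum((Fraction(f) - fbar) ** 2 / fbar for f in (f1, f2, f3))
    sign = -1.0 if (f1 < f2 or f1 < f3) else 1.0
    return sign * math.log2(float(chi) + 1.0)


def test_orfscore_matches_exact_oracle():
    rng = np.random.default_rng(0)
    for _ in range(2000):
        f = tuple(int(x) for x in rng.integers(0, 200, 3))
        assert orfscore(f) == pytest.approx(_oracle_orfscore(*f), abs=1e-12)


def test_frame_counts_excludes_stop_codon():
    orf = Orf("t", 0, 9)  # two coding codons + stop
    psites = Counter({0: 2, 3: 1, 6: 5})  # position 6 is the stop codon
    fc = frame_counts(orf, psites)
    assert (fc.f1, fc.f2, fc.f3) == (3, 0, 0)
    fc_all = frame_counts(orf, psites, include_stop=True)
    assert fc_all.f1 == 8


def test_frame_counts_validation():
    with pytest.raises(ValueError):
        FrameCounts(-1, 0, 0)


# ---------------------------------------------------------------------
# P-sites
# ---------------------------------------------------------------------

def test_psite_offset_and_length_filter():
    psites, dropped = assign_psites(
        [("t", 100, 28), ("t", 100, 29), ("t", 100, 31)], {"t": 1000})
    assert psites["t"] == Counter({112: 2})
    assert dropped == 0


def test_psite_out_of_bounds_dropped_with_warning():
    psites, dropped = assign_psites([("t", 95, 28)], {"t": 100})
    assert psites == {}
    assert dropped == 1


def test_psite_config_invariant():
    with pytest.raises(ValueError):
        PsiteConfig(allowed_lengths=frozenset({10}), offset=12)


def test_empty_footprints():
    assert assign_psites([], {"t": 100}) == ({}, 0)


# ---------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------

def test_enumerate_single_orf():
    orfs = enumerate_orfs("ATGAAATAG", min_codons=1)
    assert [(o.start, o.end) for o in orfs] == [(0, 9)]
    assert orfs[0].n_codons == 3  # includes the stop codon


def test_enumerate_no_atg():
    assert enumerate_orfs("CCCCCCTAG", min_codons=1) == []


def test_enumerate_nested_atgs_both_reported():
    seq = "ATGATGAAATAG"
    orfs = enumerate_orfs(seq, min_codons=1)
    assert {(o.start, o.end) for o in orfs} == {(0, 12), (3, 12)}


def _oracle_enumerate(seq, min_codons):
    out = set()
    stops = {"TAA", "TAG", "TGA"}
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j:j + 3] in stops:
                if (j + 3 - i) // 3 >= min_codons and "N" not in seq[i:j + 3]:
                    out.add((i, j + 3))
                break
            j += 3
    return out


@pytest.mark.parametrize("seed", range(5))
def test_enumerate_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=400))
    got = {(o.start, o.end) for o in enumerate_orfs(seq, min_codons=2)}
    assert got == _oracle_enumerate(seq, 2)


# ---------------------------------------------------------------------
# Translating-ORF selection
# ---------------------------------------------------------------------

def _periodic_psites(orf_start, n_codons, per_codon=2):
    return Counter({orf_start + 3 * i: per_codon for i in range(n_codons)})


def test_select_single_qualifying_orf():
    seq = "GG" + "ATG" + "GCA" * 20 + "TAA"
    psites = _periodic_psites(2, 15)
    best, scored = select_translating_orf("t", seq, psites, min_codons=5)
    assert best is not None and best.translating
    assert best.orfscore > 5


def test_select_prefers_longest_qualifying():
    # two ORFs in different frames, both strongly periodic
    seq = "ATG" + "GCA" * 10 + "TAA" + "C" + "ATG" + "GCA" * 40 + "TAA"
    orf2_start = 3 + 30 + 3 + 1
    psites = _periodic_psites(0, 9, 3) + _periodic_psites(orf2_start, 35, 3)
    best, _ = select_translating_orf("t", seq, psites, min_codons=5)
    assert best.start == orf2_start
    assert best.length_nt == 3 * 42


def test_select_none_below_threshold():
    seq = "ATG" + "GCA" * 20 + "TAA"
    psites = Counter({0: 1, 1: 1, 2: 1, 3: 1, 4: 1, 5: 1})  # frame-uniform
    best, scored = select_translating_orf("t", seq, psites, min_codons=5)
    assert best is None
    assert all(o.orfscore <= 5 for o in scored)


def test_recovery_and_decoys_on_simulated_footprints():
    """Periodicity 0.9 at depth >= 30: true ORFs recovered, out-of-frame
    decoys score negative, frame-shuffled decoys stay below threshold."""
    cfg = sf.SimConfig(seed=21, n_genes=15, coding_fraction=1.0,
                       footprint_periodicity=0.9, footprints_per_orf=50)
    truth = sf.simulate_genome_annotation(cfg)
    fps = sf.simulate_ribo_footprints(truth, cfg)
    lengths = {t.id: t.length for t in truth.transcripts}
    psites, _ = assign_psites(fps, lengths)
    recovered = total = 0
    neg_decoys = decoys = 0
    for t in truth.transcripts:
        if t.id not in psites:
            continue
        seq = spliced_sequence(t, truth.genome)
        start, end = truth.orfs[t.id]
        best, scored = select_translating_orf(t, seq, psites[t.id], min_codons=5)
        total += 1
        if best is not None and (best.start, best.end) == (start, end):
            recovered += 1
        for o in scored:
            # decoy: overlaps the true ORF in a shifted frame
            if o.start < end and start < o.end and (o.start - start) % 3 != 0:
                fc = frame_counts(o, psites[t.id])
                if fc.f1 + fc.f2 + fc.f3 >= 30:
                    decoys += 1
                    if orfscore(fc) < 0:
                        neg_decoys += 1
    assert total >= 10
    assert recovered / total >= 0.95
    if decoys:
        assert neg_decoys / decoys >= 0.95


# ---------------------------------------------------------------------
# Features and expression filter
# ---------------------------------------------------------------------

def test_features_symmetric_tpms_zero_ratios():
    row = {f"{fr}_rep{r}": 5.0 for fr in ("free", "mono", "poly") for r in (1, 2)}
    f = extract_features(row, 300.0)
    assert len(f) == 13
    assert np.allclose(f[6:12], 0.0)
    assert f[12] == 300.0


def test_features_zero_tpms_via_pseudocount():
    row = {f"{fr}_rep{r}": 0.0 for fr in ("free", "mono", "poly") for r in (1, 2)}
    f = extract_features(row, 0.0)
    assert np.allclose(f, 0.0)


def test_features_missing_cell_errors():
    row = {"free_rep1": 1.0}
    with pytest.raises(KeyError):
        extract_features(row, 10.0)


def test_exclude_low_expression():
    import pandas as pd

    cols = [f"{fr}_rep{r}" for r in (1, 2) for fr in ("free", "mono", "poly")]
    df = pd.DataFrame(
        [[0.0] * 6, [0.005] * 6, [0.0] * 5 + [5.0]],
        index=["zero", "tiny", "onecell"], columns=cols)
    kept, excluded = exclude_low_expression(df, tpm_floor=0.01)
    assert list(excluded.index) == ["zero", "tiny"]
    assert list(kept.index) == ["onecell"]


# ---------------------------------------------------------------------
# Status ensemble
# ---------------------------------------------------------------------

def _labelled_features(seed, n_genes=50, noise=0.3):
    cfg = sf.SimConfig(seed=seed, n_genes=n_genes, isoforms_per_gene=(2, 4),
                       n_chromosomes=max(2, n_genes // 15), polysome_noise_sd=noise)
    truth = sf.simulate_genome_annotation(cfg)
    prof, labels = sf.simulate_polysome_profiles(truth)
    X, y = [], []
    for t in truth.transcripts:
        s, e = truth.orfs.get(t.id, (0, 0))
        X.append(extract_features(prof.loc[t.id], e - s))
        y.append(int(labels[t.id]))
    return np.array(X), np.array(y)


@pytest.fixture(scope="module")
def trained_ensemble():
    X, y = _labelled_features(31, noise=0.1)
    clf, acc = train_status_ensemble(X, y, seed=0, **SMALL_GRID)
    return X, y, clf, acc


def test_separable_profiles_high_cv_accuracy(trained_ensemble):
    _X, _y, clf, acc = trained_ensemble
    assert len(clf.members_) == 21
    assert acc >= 0.95


def test_prediction_is_majority_vote(trained_ensemble):
    X, _y, clf, _acc = trained_ensemble
    votes = clf.vote_counts(X[:20])
    labels, votes2 = predict_status(clf, X[:20])
    assert np.array_equal(votes, votes2)
    assert np.array_equal(labels, (votes > 10).astype(int))


def test_ensemble_seeded_determinism():
    X, y = _labelled_features(32, n_genes=25)
    a = TranslationStatusClassifier(random_state=5, cv=5, **SMALL_GRID).fit(X, y)
    b = TranslationStatusClassifier(random_state=5, cv=5, **SMALL_GRID).fit(X, y)
    assert np.array_equal(a.predict(X), b.predict(X))
    assert a.cv_accuracy_ == b.cv_accuracy_


def test_ensemble_requires_both_classes():
    X = np.zeros((10, 13))
    with pytest.raises(ValueError):
        TranslationStatusClassifier().fit(X, np.ones(10))


def test_label_recovery_on_held_out_noise_03():
    from sklearn.model_selection import train_test_split

    X, y = _labelled_features(33, n_genes=70, noise=0.3)
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.35, random_state=0,
                                          stratify=y)
    clf, acc = train_status_ensemble(Xtr, ytr, seed=1, **SMALL_GRID)
    pred, _ = predict_status(clf, Xte)
    holdout = (pred == yte).mean()
    assert holdout >= 0.9
    # ensemble does not fall far below the mean member CV accuracy
    assert holdout >= acc - 0.05


# ---------------------------------------------------------------------
# ORFeome collapsing and translation helper
# ---------------------------------------------------------------------

def test_collapse_orfeome_utr_variants_share_orf():
    g = tuple(range(100, 130))
    a = Orf("iso1", 10, 40, g)
    b = Orf("iso2", 50, 80, g)   # same genomic codons, different UTR offset
    unique, per_gene = collapse_orfeome([a, b], {"iso1": "g1", "iso2": "g1"})
    assert len(unique) == 1
    assert per_gene == {"g1": 1}


def test_collapse_orfeome_truncation_is_distinct():
    full = Orf("iso1", 0, 30, tuple(range(100, 130)))
    trunc = Orf("iso2", 0, 24, tuple(range(106, 130)))
    unique, _ = collapse_orfeome([full, trunc])
    assert len(unique) == 2


def test_collapse_orfeome_empty():
    assert collapse_orfeome([]) == ([], {})


def test_translate_helper():
    assert translate("ATGGCATAA") == "MA*"
    assert translate("ATGNNN") == "MX"
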