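"""Translational-status prediction and translating-ORF detection.

Two independent lines of evidence are integrated per isoform:

* **Polysome profiling** - per-isoform TPM in the ribosome-free,
  monosome and polysome fractions (two replicates). A 13-dimensional
  feature vector (6 abundances, 6 pairwise log-ratios, longest-ORF
  length) feeds an ensemble of 21 RBF-kernel SVMs, each trained on a
  class-balanced subsample; the final label is a majority vote.

* **Ribosome footprinting** - footprints of length 28-30 nt are
  reduced to P-sites at +12 nt from the read 5' end. For a candidate
  ORF with per-frame P-site counts F1, F2, F3 and mean F', the ORFscore
  is::

      log2( sum_i (Fi - F')^2 / F'  + 1 )

  signed negative when F1 < F2 or F1 < F3. ORFs scoring > 5 are called
  translating; among several qualifying ORFs per isoform the longest
  wins (ties: higher score).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .genome_model import Transcript

__all__ = [
    "PsiteConfig",
    "FrameCounts",
    "Orf",
    "assign_psites",
    "enumerate_orfs",
    "orfscore",
    "frame_counts",
    "select_translating_orf",
    "extract_features",
    "exclude_low_expression",
    "TranslationStatusClassifier",
    "train_status_ensemble",
    "predict_status",
    "collapse_orfeome",
    "translate",
]

_STOPS = ("TAA", "TAG", "TGA")

_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


def translate(cds: str) -> str:
    """Translate a CDS (stop rendered as '*', unknown codons as 'X')."""
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    return "".join(
        _CODON_TABLE.get(cds[i:i + 3].upper(), "X") for i in range(0, len(cds) - 2, 3)
    )


@dataclass(frozen=True)
class PsiteConfig:
    allowed_lengths: frozenset[int] = frozenset({28, 29, 30})
    offset: int = 12

    def __post_init__(self) -> None:
        if self.allowed_lengths and self.offset >= min(self.allowed_lengths):
            raise ValueError("offset must be smaller than the shortest allowed length")


@dataclass(frozen=True)
class FrameCounts:
    f1: int
    f2: int
    f3: int

    def __post_init__(self) -> None:
        if min(self.f1, self.f2, self.f3) < 0:
            raise ValueError("negative frame counts")

    @property
    def mean(self) -> float:
        return (self.f1 + self.f2 + self.f3) / 3.0


@dataclass(frozen=True)
class Orf:
    """A candidate or called ORF in transcript coordinates.

    ``start``/``end`` delimit the ATG through the end of the stop codon
    (half-open); ``genomic_positions`` lists the genomic coordinate of
    every ORF base in transcript (5'->3') order.
    """

    transcript_id: str
    start: int
    end: int
    genomic_positions: tuple[int, ...] = ()
    orfscore: float = math.nan
    translating: bool = False
    has_stop: bool = True

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length not divisible by 3")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    def codon_chain(self) -> tuple[tuple[int, int, int], ...]:
        """Genomic positions of each codon (frame-defining identity)."""
        g = self.genomic_positions
        return tuple((g[i], g[i + 1], g[i + 2]) for i in range(0, len(g) - 2, 3))


# ---------------------------------------------------------------------
# P-sites and ORF enumeration
# ---------------------------------------------------------------------

def assign_psites(
    footprints: Iterable[tuple[str, int, int]],
    transcript_lengths: dict[str, int],
    cfg: PsiteConfig | None = None,
) -> tuple[dict[str, Counter], int]:
    """P-site position counts per transcript.

    ``footprints`` are (transcript_id, 5'-end transcript position,
    length). Reads of disallowed length are dropped; reads whose P-site
    (5' end + offset) falls outside the transcript are dropped and
    counted in the returned warning count.
    """
    cfg = cfg or PsiteConfig()
    out: dict[str, Counter] = defaultdict(Counter)
    dropped = 0
    for tid, five, length in footprints:
        if length not in cfg.allowed_lengths:
            continue
        p = five + cfg.offset
        if p < 0 or p >= transcript_lengths.get(tid, 0):
            dropped += 1
            continue
        out[tid][p] += 1
    return dict(out), dropped


def enumerate_orfs(
    seq: str, min_codons: int = 10, transcript_id: str = "",
    genomic_positions: Sequence[int] | None = None,
    include_unstopped: bool = False,
) -> list[Orf]:
    """All ATG -> first-in-frame-stop spans with >= ``min_codons`` codons.

    All three frames are scanned; nested in-frame ATGs each produce an
    ORF. The codon count includes the stop codon. Spans containing N
    are excluded.
    """
    seq = seq.upper()
    n = len(seq)
    out: list[Orf] = []
    for frame in range(3):
        starts: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in _STOPS:
                for s in starts:
                    out.append(_make_orf(seq, transcript_id, s, i + 3, genomic_positions, True, min_codons))
                starts = []
            i += 3
        if include_unstopped:
            end = frame + ((n - frame) // 3) * 3
            for s in starts:
                out.append(_make_orf(seq, transcript_id, s, end, genomic_positions, False, min_codons))
    out = [o for o in out if o is not None]
    out.sort(key=lambda o: (o.start, o.end))
    return out


def _make_orf(seq, tid, start, end, gpos, has_stop, min_codons):
    if (end - start) // 3 < min_codons:
        return None
    if "N" in seq[start:end]:
        return None
    g = tuple(gpos[start:end]) if gpos is not None else ()
    return Orf(tid, start, end, g, has_stop=has_stop)


# ---------------------------------------------------------------------
# ORFscore
# ---------------------------------------------------------------------

def orfscore(fc: FrameCounts | tuple[int, int, int]) -> float:
    """Signed log2 chi-square-like frame-bias statistic.

    All-zero counts score 0 (continuous with the uniform case); an ORF
    whose frame-0 count is not maximal is signed negative.
    """
    if not isinstance(fc, FrameCounts):
        fc = FrameCounts(*fc)
    fbar = fc.mean
    if fbar == 0:
        return 0.0
    chi = sum((f - fbar) ** 2 / fbar for f in (fc.f1, fc.f2, fc.f3))
    sign = -1.0 if (fc.f1 < fc.f2 or fc.f1 < fc.f3) else 1.0
    return sign * math.log2(chi + 1.0)


def frame_counts(orf: Orf, psites: Counter, include_stop: bool = False) -> FrameCounts:
    """Per-frame P-site counts over an ORF's codons.

    P-sites on the stop codon are excluded by default (terminating
    ribosomes distort the periodicity).
    """
    end = orf.end if (include_stop or not orf.has_stop) else orf.end - 3
    f = [0, 0, 0]
    for p, c in psites.items():
        if orf.start <= p < end:
            f[(p - orf.start) % 3] += c
    return FrameCounts(*f)


def select_translating_orf(
    transcript: Transcript | str,
    seq: str,
    psites: Counter,
    min_codons: int = 10,
    threshold: float = 5.0,
) -> tuple[Orf | None, list[Orf]]:
    """Score all candidate ORFs of one isoform and pick the translating one.

    Returns (selected ORF or None, all scored candidates). Candidates
    with ORFscore > ``threshold`` qualify; the longest qualifying ORF is
    selected, ties broken by higher score.
    """
    if isinstance(transcript, Transcript):
        tid = transcript.id
        gpos = transcript.genomic_positions()
    else:
        tid, gpos = transcript, None
    candidates = enumerate_orfs(seq, min_codons, tid, gpos)
    scored = [replace(o, orfscore=orfscore(frame_counts(o, psites))) for o in candidates]
    qualifying = [o for o in scored if o.orfscore > threshold]
    if not qualifying:
        return None, scored
    best = max(qualifying, key=lambda o: (o.length_nt, o.orfscore))
    best = replace(best, translating=True)
    return best, scored


# ---------------------------------------------------------------------
# Polysome-based status classification
# ---------------------------------------------------------------------

_FRACTIONS = ("free", "mono", "poly")
FEATURE_NAMES = tuple(
    [f"{fr}_rep{r}" for r in (1, 2) for fr in _FRACTIONS]
    + [f"log2_{a}_{b}_rep{r}" for r in (1, 2) for a, b in (("free", "mono"), ("free", "poly"), ("mono", "poly"))]
    + ["longest_orf_nt"]
)


def extract_features(
    profile_row: pd.Series | dict, longest_orf_nt: float, eps: float = 0.01
) -> np.ndarray:
    """13-feature vector: 6 TPMs, 6 pairwise log2 ratios, longest ORF length.

    Ratios use a pseudocount: log2((a + eps) / (b + eps)).
    """
    vals = {}
    for r in (1, 2):
        for fr in _FRACTIONS:
            key = f"{fr}_rep{r}"
            if key not in profile_row:
                raise KeyError(f"missing polysome cell {key}")
            vals[key] = float(profile_row[key])
    feats = [vals[f"{fr}_rep{r}"] for r in (1, 2) for fr in _FRACTIONS]
    for r in (1, 2):
        for a, b in (("free", "mono"), ("free", "poly"), ("mono", "poly")):
            feats.append(math.log2((vals[f"{a}_rep{r}"] + eps) / (vals[f"{b}_rep{r}"] + eps)))
    feats.append(float(longest_orf_nt))
    arr = np.asarray(feats, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite feature value")
    return arr


def exclude_low_expression(
    profiles: pd.DataFrame, tpm_floor: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split isoforms whose TPM is below ``tpm_floor`` in every
    fraction and replicate (expression close to zero) from the rest."""
    low = (profiles < tpm_floor).all(axis=1)
    return profiles.loc[~low], profiles.loc[low]


class TranslationStatusClassifier(BaseEstimator, ClassifierMixin):
    """Voting ensemble of class-balanced RBF-SVM members.

    Each of ``n_members`` members is trained on all inactive samples
    plus an equally sized random subsample of active samples;
    hyperparameters are grid-searched under ``cv``-fold cross
    validation. Prediction is a strict majority vote.

    Attributes (after fit): ``members_`` (fitted searches),
    ``scaler_``, ``cv_accuracy_`` (mean best CV accuracy across
    members), ``classes_``.
    """

    def __init__(
        self,
        n_members: int = 21,
        C_grid: Sequence[float] | None = None,
        gamma_grid: Sequence[float] | None = None,
        cv: int = 10,
        random_state: int | None = 0,
    ):
        self.n_members = n_members
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.random_state = random_state

    def _grids(self) -> tuple[list[float], list[float]]:
        c = list(self.C_grid) if self.C_grid is not None else [2.0 ** e for e in range(-5, 16, 2)]
        g = list(self.gamma_grid) if self.gamma_grid is not None else [2.0 ** e for e in range(-15, 4, 2)]
        return c, g

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both classes must be present")
        rng = np.random.default_rng(self.random_state)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        active_idx = np.flatnonzero(y == 1)
        inactive_idx = np.flatnonzero(y == 0)
        if len(active_idx) == 0 or len(inactive_idx) == 0:
            raise ValueError("both classes must be non-empty")
        minority, majority = (active_idx, inactive_idx) if len(active_idx) <= len(inactive_idx) else (inactive_idx, active_idx)
        c_grid, g_grid = self._grids()
        # stratified CV needs at least one sample per class per fold
        eff_cv = max(2, min(self.cv, len(minority)))
        self.members_ = []
        accs = []
        for m in range(self.n_members):
            sub = rng.choice(majority, size=len(minority), replace=False)
            idx = np.concatenate([minority, sub])
            search = GridSearchCV(
                SVC(kernel="rbf"),
                {"C": c_grid, "gamma": g_grid},
                cv=eff_cv, n_jobs=None,
            )
            search.fit(Xs[idx], y[idx])
            self.members_.append(search.best_estimator_)
            accs.append(search.best_score_)
        self.cv_accuracy_ = float(np.mean(accs))
        return self

    def vote_counts(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        votes = np.stack([m.predict(Xs) for m in self.members_])
        return (votes == 1).sum(axis=0)

    def predict(self, X) -> np.ndarray:
        votes = self.vote_counts(X)
        return (votes > self.n_members / 2).astype(int)


def train_status_ensemble(
    X, y, n_members: int = 21, seed: int = 0, cv: int = 10,
    C_grid: Sequence[float] | None = None, gamma_grid: Sequence[float] | None = None,
) -> tuple[TranslationStatusClassifier, float]:
    """Fit the voting ensemble; returns (classifier, mean CV accuracy)."""
    clf = TranslationStatusClassifier(
        n_members=n_members, C_grid=C_grid, gamma_grid=gamma_grid,
        cv=cv, random_state=seed,
    ).fit(X, y)
    return clf, clf.cv_accuracy_


def predict_status(ensemble: TranslationStatusClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels (1 = active) and per-sample vote counts."""
    votes = ensemble.vote_counts(np.atleast_2d(np.asarray(X, dtype=float)))
    labels = (votes > ensemble.n_members / 2).astype(int)
    return labels, votes


# ---------------------------------------------------------------------
# ORFeome collapsing
# ---------------------------------------------------------------------

def collapse_orfeome(
    orfs: Iterable[Orf], loci_of_transcripts: dict[str, str] | None = None
) -> tuple[list[Orf], dict[str, int]]:
    """Merge ORFs with identical genomic codon chains into a unique set.

    Returns the unique ORFs (first-seen representative, sorted by
    transcript id) and, when a transcript -> locus map is given,
    per-locus unique-ORF counts.
    """
    seen: dict[tuple, Orf] = {}
    members: dict[tuple, set[str]] = defaultdict(set)
    for orf in sorted(orfs, key=lambda o: (o.transcript_id, o.start)):
        if not orf.genomic_positions:
            raise ValueError("collapse_orfeome requires genomic_positions")
        key = orf.codon_chain()
        if key not in seen:
            seen[key] = orf
        members[key].add(orf.transcript_id)
    per_gene: dict[str, int] = defaultdict(int)
    if loci_of_transcripts:
        for key, tids in members.items():
            genes = {loci_of_transcripts[t] for t in tids if t in loci_of_transcripts}
            for g in genes:
                per_gene[g] += 1
    return list(seen.values()), dict(per_gene)
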