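"""Bootstrap k-mer naive-Bayes taxonomic classification.

The classifier follows the published RDP-style algorithm: 8-mer word
priors p(w) = (n(w) + 0.5) / (N + 1) over all training sequences, per-genus
conditionals (m_g(w) + p(w)) / (M_g + 1), and 100 bootstrap trials each
scoring ceil(W/8) of the query's W distinct words sampled with replacement.
Per-rank confidence is the fraction of bootstrap winners whose lineage
agrees with the overall winner down to that rank; the assigned lineage is
the deepest rank whose confidence meets the threshold (default 0.50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TrainedClassifier",
    "Classification",
    "train",
    "classify_bootstrap",
    "assign_deepest",
]

N_RANKS = 6
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class LineageError(ValueError):
    pass


def _kmer_indices(seq: str, k: int) -> np.ndarray:
    """Distinct k-mer codes of seq (words containing non-ACGT are skipped)."""
    seq = seq.upper()
    codes = np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    idx = (windows[valid] * powers).sum(axis=1)
    return np.unique(idx)


@dataclass
class TrainedClassifier:
    k: int
    genera: list[str]  # genus labels, training order
    lineages: list[tuple[str, ...]]  # 6-rank lineage per genus
    log_cond: np.ndarray  # (n_genera, 4**k) log conditional probabilities
    train_counts: dict[str, int]  # training sequences per genus


def train(
    sequences: Sequence[tuple[str, str]],
    lineages: Mapping[str, tuple[str, ...]],
    k: int = 8,
) -> TrainedClassifier:
    """Train the word-based naive-Bayes classifier.

    ``sequences`` are (id, sequence); ``lineages`` maps id to a 6-rank
    lineage (domain..genus).  Two training sequences mapping the same genus
    to different parent lineages raise LineageError.
    """
    if not sequences:
        raise ValueError("no training sequences")
    genus_lineage: dict[str, tuple[str, ...]] = {}
    genus_seqs: dict[str, list[str]] = {}
    for sid, seq in sequences:
        lin = tuple(lineages[sid])
        if len(lin) != N_RANKS:
            raise LineageError(
                f"{sid}: lineage must have {N_RANKS} ranks, got {len(lin)}"
            )
        genus = lin[-1]
        if genus in genus_lineage and genus_lineage[genus] != lin:
            raise LineageError(
                f"genus {genus!r} has two conflicting parent lineages"
            )
        genus_lineage.setdefault(genus, lin)
        genus_seqs.setdefault(genus, []).append(seq)

    genera = list(genus_lineage)
    n_words = 4**k
    n_total = sum(len(v) for v in genus_seqs.values())

    # word prior over all training sequences
    word_seq_count = np.zeros(n_words, dtype=np.float64)
    genus_word_count = np.zeros((len(genera), n_words), dtype=np.float64)
    for gi, genus in enumerate(genera):
        for seq in genus_seqs[genus]:
            idx = _kmer_indices(seq, k)
            word_seq_count[idx] += 1
            genus_word_count[gi, idx] += 1
    prior = (word_seq_count + 0.5) / (n_total + 1)

    m_g = np.array([len(genus_seqs[g]) for g in genera], dtype=np.float64)
    cond = (genus_word_count + prior[None, :]) / (m_g[:, None] + 1)
    return TrainedClassifier(
        k=k,
        genera=genera,
        lineages=[genus_lineage[g] for g in genera],
        log_cond=np.log(cond),
        train_counts={g: len(genus_seqs[g]) for g in genera},
    )


@dataclass(frozen=True)
class Classification:
    """Per-rank (taxon, bootstrap confidence) along the winning lineage."""

    ranks: tuple[tuple[str, float], ...]

    @property
    def lineage(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.ranks)

    @property
    def confidences(self) -> tuple[float, ...]:
        return tuple(c for _, c in self.ranks)


def classify_bootstrap(
    seq: str,
    classifier: TrainedClassifier,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> Classification:
    """Bootstrap-classify one sequence.

    Each trial samples ceil(W/8) of the W distinct query words with
    replacement and picks the maximum-likelihood genus (ties -> earliest
    training genus).  The reported lineage is the modal winning genus's;
    rank-r confidence is the fraction of trials whose winner shares the
    lineage prefix down to rank r.
    """
    words = _kmer_indices(seq, classifier.k)
    if words.size == 0:
        raise ValueError(f"sequence shorter than k={classifier.k}")
    rng = np.random.default_rng(seed)
    m = math.ceil(words.size / 8)
    draws = rng.choice(words, size=(n_bootstrap, m), replace=True)
    # scores: (n_genera, n_bootstrap)
    scores = classifier.log_cond[:, draws].sum(axis=2)
    # exact score ties (e.g. no discriminating word drawn) are broken
    # uniformly at random so that indistinguishable genera split the votes
    winners = np.empty(n_bootstrap, dtype=int)
    for b in range(n_bootstrap):
        col = scores[:, b]
        tied = np.flatnonzero(col >= col.max() - 1e-12)
        winners[b] = tied[0] if tied.size == 1 else rng.choice(tied)

    votes = np.bincount(winners, minlength=len(classifier.genera))
    best_genus = int(np.argmax(votes))
    best_lineage = classifier.lineages[best_genus]

    winner_lineages = [classifier.lineages[int(w)] for w in winners]
    ranks = []
    for r in range(N_RANKS):
        agree = sum(
            1 for lin in winner_lineages if lin[: r + 1] == best_lineage[: r + 1]
        )
        ranks.append((best_lineage[r], agree / n_bootstrap))
    return Classification(ranks=tuple(ranks))


def assign_deepest(
    classification: Classification, threshold: float = 0.50
) -> tuple[str, ...]:
    """Deepest lineage prefix whose rank confidence meets the threshold;
    the empty tuple (root) if no rank qualifies."""
    depth = 0
    for i, (_, conf) in enumerate(classification.ranks):
        if conf >= threshold:
            depth = i + 1
    return classification.lineage[:depth]
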