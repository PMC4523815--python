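"""Alignment-based sequencing-error profiling.

Reads are aligned semi-globally (end gaps on the reference are free, so a
short read lands on the region of the reference it came from) and every
column of the covered span is classified as a match, substitution, insertion
(gap in the reference) or deletion (gap in the read).  Rates are reported
as errors per 1000 reads — errors, not error-containing reads.

When a reference gene has several copies, each read is aligned against all
of them and only the best alignment is kept (score ties broken by fewest
total errors, then first copy).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import pstdev
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .readprep import QCProfile, Read, qc_filter

__all__ = [
    "Scoring",
    "PairwiseAlignment",
    "ErrorProfile",
    "align_semiglobal",
    "classify_errors",
    "profile_sample",
    "combine_replicates",
]

ERROR_TYPES = ("ins", "del", "sub")


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scoring.  A gap of length k costs
    ``gap_open + k * gap_extend`` (so the first gap base costs open+extend)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gapped query/reference strings plus the covered reference span
    (1-based inclusive) and the alignment score."""

    query_aligned: str
    ref_aligned: str
    ref_start: int
    ref_end: int
    score: float

    def __post_init__(self) -> None:
        if len(self.query_aligned) != len(self.ref_aligned):
            raise ValueError("aligned strings differ in length")


_ALIGNER_CACHE: dict[Scoring, Align.PairwiseAligner] = {}


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(scoring)
    if aligner is not None:
        return aligner
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython scores the first gap base with open_gap_score; our
    # convention charges open + extend for it.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    # free end gaps on the reference side: the read covers only part of it
    # (Biopython >= 1.88 renamed query_end_gap_score to end_deletion_score)
    try:
        aligner.end_deletion_score = 0.0
    except (AttributeError, ValueError):  # pragma: no cover
        aligner.query_end_gap_score = 0.0
    return _ALIGNER_CACHE.setdefault(scoring, aligner)


def align_semiglobal(
    query: str, reference: str, scoring: Scoring = Scoring()
) -> PairwiseAlignment:
    """Optimal end-gap-free alignment of ``query`` within ``reference``.

    End gaps on the reference (reference bases outside the read's span) are
    free; all other gaps are affine.  The traceback is deterministic: the
    first alignment in Biopython's enumeration order is returned.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    aligner = _make_aligner(scoring)
    aln = aligner.align(reference.upper(), query.upper())[0]
    ref_aligned, query_aligned = str(aln[0]), str(aln[1])

    # covered span = first..last column where the query has a base
    idx = [i for i, c in enumerate(query_aligned) if c != "-"]
    first, last = idx[0], idx[-1]
    ref_start = sum(1 for c in ref_aligned[: first + 1] if c != "-")
    ref_end = sum(1 for c in ref_aligned[: last + 1] if c != "-")
    return PairwiseAlignment(
        query_aligned=query_aligned,
        ref_aligned=ref_aligned,
        ref_start=max(ref_start, 1),
        ref_end=ref_end,
        score=float(aln.score),
    )


def classify_errors(
    aln: PairwiseAlignment,
) -> tuple[dict[str, int], list[tuple[int, str]]]:
    """Count insertions/deletions/substitutions over the covered span.

    Returns (counts, positions) where positions are (1-based reference
    coordinate, type).  Insertions are attributed to the reference position
    immediately left of the inserted run (a run of k inserted bases counts k
    insertions at that one position).  End-gap columns contribute nothing.
    """
    counts = {t: 0 for t in ERROR_TYPES}
    positions: list[tuple[int, str]] = []
    q, r = aln.query_aligned, aln.ref_aligned
    idx = [i for i, c in enumerate(q) if c != "-"]
    if not idx:
        return counts, positions
    first, last = idx[0], idx[-1]
    ref_pos = sum(1 for c in r[:first] if c != "-")  # bases consumed before span
    for i in range(first, last + 1):
        qc, rc = q[i], r[i]
        if rc != "-":
            ref_pos += 1
            if qc == "-":
                counts["del"] += 1
                positions.append((ref_pos, "del"))
            elif qc != rc:
                counts["sub"] += 1
                positions.append((ref_pos, "sub"))
        else:
            counts["ins"] += 1
            positions.append((max(ref_pos, 1), "ins"))
    return counts, positions


@dataclass
class ErrorProfile:
    """Aggregate error statistics for one read set.

    ``rates`` are errors per 1000 reads (count / n_reads * 1000).
    ``positions`` maps error type -> Counter over 1-based reference
    coordinates; each Counter's total equals the corresponding count.
    """

    n_reads: int
    qc_condition: str = "none"
    counts: dict[str, int] = field(default_factory=lambda: {t: 0 for t in ERROR_TYPES})
    positions: dict[str, Counter] = field(
        default_factory=lambda: {t: Counter() for t in ERROR_TYPES}
    )
    replicate_sd: dict[str, float] | None = None

    @property
    def rates(self) -> dict[str, float]:
        if self.n_reads == 0:
            return {t: 0.0 for t in ERROR_TYPES}
        return {t: self.counts[t] / self.n_reads * 1000 for t in ERROR_TYPES}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type": list(ERROR_TYPES),
                "count": [self.counts[t] for t in ERROR_TYPES],
                "rate_per_1000": [self.rates[t] for t in ERROR_TYPES],
                "qc_condition": self.qc_condition,
            }
        )

    def positions_dataframe(self) -> pd.DataFrame:
        rows = [
            {"position": pos, "type": t, "count": c}
            for t in ERROR_TYPES
            for pos, c in sorted(self.positions[t].items())
        ]
        return pd.DataFrame(rows, columns=["position", "type", "count"])


def profile_sample(
    reads: Sequence[Read],
    ref_copies: Sequence[str],
    n_subsample: int = 10000,
    qc: QCProfile | None = None,
    seed: int = 0,
    scoring: Scoring = Scoring(),
) -> ErrorProfile:
    """Estimate per-type error rates by aligning a read subsample to the
    reference copies.

    A uniform subsample without replacement of ``n_subsample`` reads is drawn
    first (all reads if fewer); QC — if any — is applied *after*
    subsampling.  Each surviving read is aligned against every reference
    copy and the best alignment kept.
    """
    if not ref_copies:
        raise ValueError("need at least one reference copy")
    if not reads:
        raise ValueError("need at least one read")
    rng = np.random.default_rng(seed)
    if len(reads) > n_subsample:
        picks = rng.choice(len(reads), size=n_subsample, replace=False)
        subsample = [reads[i] for i in sorted(picks)]
    else:
        subsample = list(reads)

    qc_label = "none"
    if qc is not None:
        subsample = [r for r in subsample if qc_filter(r, qc).passed]
        qc_label = qc.name
        if not subsample:
            raise ValueError("no reads survive QC")

    profile = ErrorProfile(n_reads=len(subsample), qc_condition=qc_label)
    aligner = _make_aligner(scoring)
    uppercase_refs = [r.upper() for r in ref_copies]
    for read in subsample:
        bases = read.bases.upper()
        # a read that is an exact substring of a copy attains the maximum
        # possible score (match * len) with zero errors — no alignment needed
        if any(bases in ref for ref in uppercase_refs):
            continue
        scores = [aligner.score(ref, bases) for ref in uppercase_refs]
        top = max(scores)
        best: tuple[int, int, dict, list] | None = None
        for ci, ref in enumerate(uppercase_refs):
            if scores[ci] != top:
                continue
            aln = align_semiglobal(bases, ref, scoring)
            counts, positions = classify_errors(aln)
            key = (sum(counts.values()), ci)
            if best is None or key < best[:2]:
                best = (*key, counts, positions)
        _, _, counts, positions = best
        for t in ERROR_TYPES:
            profile.counts[t] += counts[t]
        for pos, t in positions:
            profile.positions[t][pos] += 1
    return profile


def combine_replicates(profiles: Sequence[ErrorProfile]) -> ErrorProfile:
    """Pool replicate profiles; replicate_sd holds the per-type SD of the
    per-1000-read rates across replicates."""
    if not profiles:
        raise ValueError("no profiles to combine")
    combined = ErrorProfile(
        n_reads=sum(p.n_reads for p in profiles),
        qc_condition=profiles[0].qc_condition,
    )
    for p in profiles:
        for t in ERROR_TYPES:
            combined.counts[t] += p.counts[t]
            combined.positions[t].update(p.positions[t])
    combined.replicate_sd = {
        t: pstdev([p.rates[t] for p in profiles]) if len(profiles) > 1 else 0.0
        for t in ERROR_TYPES
    }
    return combined
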