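"""Read screening, trimming, pair merging and quality-control filters.

The QC rules come in two named profiles:

* lenient — reject reads with more than 5 Ns, mean quality below 30, or more
  than 10 bases below Q15;
* stringent — reject reads with 1 N or more, mean quality below 33, or more
  than 3 bases below Q20.

Boundary semantics are literal: "more than k" rejects at >= k+1, "lower
than" is strict.  Any base outside {A, C, G, T} (case-insensitive) counts
as an N.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import revcomp

__all__ = [
    "Read",
    "QCProfile",
    "LENIENT",
    "STRINGENT",
    "QCResult",
    "kmer_screen",
    "trim_primer_stagger",
    "merge_pairs",
    "window_trim",
    "truncate_read",
    "qc_filter",
    "qc_report",
]

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


@dataclass(frozen=True)
class Read:
    """A sequencing read: bases over {A,C,G,T,N} plus per-base Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]
    mate: "Read | None" = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.id}: bases/quals length mismatch "
                f"({len(self.bases)} vs {len(self.quals)})"
            )
        if self.quals and (min(self.quals) < 0 or max(self.quals) > 60):
            raise ValueError(f"{self.id}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QCProfile:
    name: str
    max_n: int
    min_avg_q: float
    low_q_threshold: int
    max_low_q_bases: int


LENIENT = QCProfile("lenient", max_n=5, min_avg_q=30, low_q_threshold=15,
                    max_low_q_bases=10)
STRINGENT = QCProfile("stringent", max_n=0, min_avg_q=33, low_q_threshold=20,
                      max_low_q_bases=3)


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def kmer_screen(
    reads: Sequence[Read],
    contaminant_seqs: Sequence[str],
    k: int = 21,
    min_hits: int = 1,
) -> tuple[list[Read], list[Read]]:
    """Partition reads into (kept, flagged) by shared k-mers with contaminants.

    A read is flagged iff at least ``min_hits`` of its k-mers (either strand)
    occur in the contaminant k-mer set.  Reads shorter than k are trivially
    kept.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if not contaminant_seqs:
        raise ValueError("contaminant set is empty")
    contam: set[str] = set()
    for seq in contaminant_seqs:
        seq = seq.upper()
        contam.update(_kmers(seq, k))
    kept: list[Read] = []
    flagged: list[Read] = []
    for read in reads:
        seq = read.bases.upper()
        hits = sum(1 for km in _kmers(seq, k) if km in contam)
        if hits < min_hits:
            hits += sum(1 for km in _kmers(revcomp(seq), k) if km in contam)
        (flagged if hits >= min_hits else kept).append(read)
    return kept, flagged


def _primer_mismatches(window: str, primer: str) -> int:
    mm = 0
    for b, p in zip(window.upper(), primer.upper()):
        if b not in IUPAC.get(p, set()):
            mm += 1
    return mm


def trim_primer_stagger(
    read: Read,
    primer: str,
    stagger_max: int = 3,
    max_mismatches: int = 1,
) -> Read | None:
    """Locate ``primer`` (IUPAC-aware) at offsets 0..stagger_max and strip
    everything through its end.

    The smallest matching offset wins (ties on mismatch count are impossible
    once the offset is fixed).  Returns None when no offset matches within
    ``max_mismatches`` — callers drop such reads.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    if not 0 <= stagger_max <= 3:
        raise ValueError("stagger_max must be in [0, 3]")
    plen = len(primer)
    best: tuple[int, int] | None = None  # (offset, mismatches)
    for off in range(stagger_max + 1):
        if off + plen > len(read):
            break
        mm = _primer_mismatches(read.bases[off : off + plen], primer)
        if mm <= max_mismatches:
            best = (off, mm)
            break
    if best is None:
        return None
    cut = best[0] + plen
    return replace(read, bases=read.bases[cut:], quals=read.quals[cut:])


def merge_pairs(
    r1: Read,
    r2: Read,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> Read | None:
    """Overlap-merge a read pair (r2 is reverse-complemented first).

    Scans overlap lengths in [min_overlap, min(len1, len2)], picking the one
    with minimal mismatch density (ties -> longest overlap).  The merge is
    accepted iff that density is <= ``max_mismatch_density``.  Disagreeing
    overlap positions take the higher-quality base (tie -> r1); merged
    quality in the overlap is the max of the two.
    """
    rc_bases = revcomp(r2.bases)
    rc_quals = r2.quals[::-1]
    n1, n2 = len(r1), len(r2)
    best: tuple[float, int] | None = None  # (density, overlap)
    for o in range(min_overlap, min(n1, n2) + 1):
        a = r1.bases[n1 - o :]
        b = rc_bases[:o]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        d = mm / o
        if best is None or d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and o > best[1]):
            best = (d, o)
    if best is None or best[0] > max_mismatch_density:
        return None
    o = best[1]
    head = r1.bases[: n1 - o]
    head_q = r1.quals[: n1 - o]
    tail = rc_bases[o:]
    tail_q = rc_quals[o:]
    mid = []
    mid_q = []
    for i in range(o):
        b1, q1 = r1.bases[n1 - o + i], r1.quals[n1 - o + i]
        b2, q2 = rc_bases[i], rc_quals[i]
        if b1 == b2:
            mid.append(b1)
        else:
            mid.append(b2 if q2 > q1 else b1)
        mid_q.append(max(q1, q2))
    return Read(
        id=r1.id,
        bases=head + "".join(mid) + tail,
        quals=tuple(head_q) + tuple(mid_q) + tuple(tail_q),
    )


def window_trim(read: Read, window: int = 20, min_mean_q: float = 30) -> Read:
    """Trim at the first sliding window (5'->3') whose mean quality drops
    below ``min_mean_q``; reads shorter than the window pass unchanged."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n < window:
        return read
    q = np.asarray(read.quals, dtype=float)
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    bad = np.flatnonzero(means < min_mean_q)
    if bad.size == 0:
        return read
    cut = int(bad[0])
    return replace(read, bases=read.bases[:cut], quals=read.quals[:cut])


def truncate_read(read: Read, length: int) -> Read:
    """Hard 3' truncation to at most ``length`` bases (platform pre-trim)."""
    if len(read) <= length:
        return read
    return replace(read, bases=read.bases[:length], quals=read.quals[:length])


def _n_count(bases: str) -> int:
    return sum(1 for b in bases.upper() if b not in "ACGT")


def qc_filter(read: Read, profile: QCProfile) -> QCResult:
    """Apply one QC profile; reports every triggered reason."""
    if len(read) == 0:
        return QCResult(False, ("empty",))
    reasons: list[str] = []
    if _n_count(read.bases) > profile.max_n:
        reasons.append("too_many_n")
    if float(np.mean(read.quals)) < profile.min_avg_q:
        reasons.append("low_mean_quality")
    if sum(1 for q in read.quals if q < profile.low_q_threshold) > profile.max_low_q_bases:
        reasons.append("too_many_low_q_bases")
    return QCResult(not reasons, tuple(reasons))


def qc_report(
    counts: Mapping[str, Mapping[str, int]]
) -> pd.DataFrame:
    """Per-sample read-fate table.

    ``counts`` maps sample -> {"total": raw reads, "assembled": reads
    surviving screening/merging (the pre-QC denominator), "qc_passed":
    reads passing QC}.  The passing percentage is qc_passed / assembled x
    100 at 2 decimals; with a zero denominator it is reported as NaN (an
    explicit undefined marker, never 0).
    """
    rows = []
    for sample, c in counts.items():
        assembled = c.get("assembled", 0)
        passed = c.get("qc_passed", 0)
        pct = round(passed / assembled * 100, 2) if assembled else float("nan")
        rows.append(
            {
                "sample": sample,
                "total_reads": c.get("total", 0),
                "assembled": assembled,
                "qc_passed": passed,
                "pct_passing": pct,
            }
        )
    return pd.DataFrame(rows)
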