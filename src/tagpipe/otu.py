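"""Dereplication, greedy identity clustering, abundance and chimera filters,
OTU tables and rarefaction.

The clustering path mirrors the classic tag-sequencing recipe: pooled
dereplication at 100% identity, denoising at 99% identity, discarding
clusters of fewer than three reads, de novo chimera flagging, then OTU
clustering at 97% identity.  Identity between two sequences is the fraction
of matching columns of a global alignment, end-gap columns excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "SeqCluster",
    "OTUTable",
    "dereplicate",
    "pairwise_identity",
    "greedy_cluster",
    "filter_min_size",
    "chimera_flag_denovo",
    "build_otu_table",
    "rarefy",
    "run_pipeline",
]


@dataclass
class SeqCluster:
    """A cluster of reads sharing (near-)identical sequence."""

    centroid: str
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return sum(self.sample_counts.values())

    def absorb(self, other: "SeqCluster") -> None:
        self.member_ids.extend(other.member_ids)
        for s, c in other.sample_counts.items():
            self.sample_counts[s] = self.sample_counts.get(s, 0) + c


def dereplicate(
    reads_by_sample: Mapping[str, Iterable[tuple[str, str]]]
) -> list[SeqCluster]:
    """Collapse identical sequences (pooled across samples) into clusters.

    ``reads_by_sample`` maps sample -> iterable of (read_id, sequence).
    Clusters come back sorted by decreasing size, ties by first occurrence.
    """
    order: dict[str, int] = {}
    clusters: dict[str, SeqCluster] = {}
    for sample, reads in reads_by_sample.items():
        for rid, seq in reads:
            cl = clusters.get(seq)
            if cl is None:
                order[seq] = len(order)
                cl = clusters[seq] = SeqCluster(centroid=seq, centroid_id=rid)
            cl.member_ids.append(rid)
            cl.sample_counts[sample] = cl.sample_counts.get(sample, 0) + 1
    return sorted(
        clusters.values(), key=lambda c: (-c.size, order[c.centroid])
    )


_ID_ALIGNER = Align.PairwiseAligner()
_ID_ALIGNER.mode = "global"
_ID_ALIGNER.match_score = 1.0
_ID_ALIGNER.mismatch_score = -1.0
_ID_ALIGNER.open_gap_score = -3.0
_ID_ALIGNER.extend_gap_score = -1.0


def _aligned_pair(a: str, b: str) -> tuple[str, str]:
    aln = _ID_ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _identity_from_columns(arow: str, brow: str) -> float:
    # end gaps excluded: clip to the span where both sequences have begun
    # and neither has ended
    n = len(arow)
    a_idx = [i for i, c in enumerate(arow) if c != "-"]
    b_idx = [i for i, c in enumerate(brow) if c != "-"]
    lo = max(a_idx[0], b_idx[0])
    hi = min(a_idx[-1], b_idx[-1])
    if hi < lo:
        return 0.0
    cols = hi - lo + 1
    matches = sum(
        1 for i in range(lo, hi + 1) if arow[i] == brow[i] and arow[i] != "-"
    )
    return matches / cols


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matching columns / alignment columns,
    end-gap columns excluded."""
    if a == b:
        return 1.0
    return _identity_from_columns(*_aligned_pair(a, b))


def _hamming_identity(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def greedy_cluster(
    clusters: Sequence[SeqCluster], identity_threshold: float
) -> list[SeqCluster]:
    """Abundance-sorted greedy centroid clustering.

    Each input cluster (processed in decreasing-size order) joins the first
    existing centroid whose pairwise identity reaches the threshold, else
    founds a new centroid.  Deterministic.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(
        range(len(clusters)), key=lambda i: (-clusters[i].size, i)
    )
    centroids: list[SeqCluster] = []
    for i in ordered:
        cand = clusters[i]
        joined = False
        for cen in centroids:
            if cand.centroid == cen.centroid:
                ident = 1.0
            elif (
                len(cand.centroid) == len(cen.centroid)
                and _hamming_identity(cand.centroid, cen.centroid)
                >= identity_threshold
            ):
                ident = 1.0  # cheap accept: hamming already clears threshold
            else:
                ident = pairwise_identity(cand.centroid, cen.centroid)
            if ident >= identity_threshold:
                cen.absorb(cand)
                joined = True
                break
        if not joined:
            centroids.append(
                SeqCluster(
                    centroid=cand.centroid,
                    centroid_id=cand.centroid_id,
                    member_ids=list(cand.member_ids),
                    sample_counts=dict(cand.sample_counts),
                )
            )
    return sorted(
        centroids, key=lambda c: -c.size
    )


def filter_min_size(
    clusters: Sequence[SeqCluster], min_size: int = 3
) -> tuple[list[SeqCluster], int]:
    """Drop clusters below ``min_size`` reads; returns (kept, reads removed)."""
    kept = [c for c in clusters if c.size >= min_size]
    removed_reads = sum(c.size for c in clusters) - sum(c.size for c in kept)
    return kept, removed_reads


def _match_vector(candidate: str, parent: str) -> np.ndarray:
    """Per-candidate-position match indicator against one parent (global
    alignment; candidate positions aligned to a gap count as mismatches)."""
    prow, crow = _aligned_pair(parent, candidate)
    vec = np.zeros(len(candidate), dtype=bool)
    ci = 0
    for pc, cc in zip(prow, crow):
        if cc != "-":
            vec[ci] = pc == cc
            ci += 1
    return vec


def chimera_flag_denovo(
    clusters: Sequence[SeqCluster],
    margin: float = 0.02,
    parent_size_ratio: float = 2.0,
    segment_min_identity: float = 0.99,
) -> list[bool]:
    """De novo two-parent chimera flags, one per input cluster.

    Clusters are scanned in decreasing-size order.  Candidate parents are
    unflagged clusters at least ``parent_size_ratio`` times the candidate's
    size.  A candidate is flagged iff some single-crossover two-parent model
    beats its best single-parent identity by ``margin`` AND both segments
    match their parents at >= ``segment_min_identity``.
    """
    order = sorted(range(len(clusters)), key=lambda i: (-clusters[i].size, i))
    flags = [False] * len(clusters)
    for rank, i in enumerate(order):
        cand = clusters[i]
        L = len(cand.centroid)
        parents = [
            clusters[j]
            for j in order[:rank]
            if not flags[j]
            and clusters[j].size >= parent_size_ratio * cand.size
        ]
        if len(parents) < 2:
            continue
        vecs = [_match_vector(cand.centroid, p.centroid) for p in parents]
        prefixes = [np.concatenate(([0], np.cumsum(v))) for v in vecs]
        totals = [int(p[-1]) for p in prefixes]
        best_single = max(t / L for t in totals)
        flagged = False
        for ai in range(len(parents)):
            for bi in range(len(parents)):
                if ai == bi:
                    continue
                pa, pb = prefixes[ai], prefixes[bi]
                # crossover after position k (left = parent A's 1..k)
                scores = pa[1:L] + (totals[bi] - pb[1:L])
                k = int(np.argmax(scores)) + 1
                model_identity = float(scores[k - 1]) / L
                if model_identity < best_single + margin:
                    continue
                left_id = float(pa[k]) / k
                right_id = float(totals[bi] - pb[k]) / (L - k)
                if (
                    left_id >= segment_min_identity
                    and right_id >= segment_min_identity
                ):
                    flagged = True
                    break
            if flagged:
                break
        flags[i] = flagged
    return flags


@dataclass
class OTUTable:
    """OTUs x samples count matrix with optional lineages."""

    counts: pd.DataFrame  # index: OTU ids, columns: samples
    lineages: dict[str, tuple[str, ...]] | None = None
    rarefaction_depth: int | None = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if not np.allclose(vals, np.rint(vals)):
            raise ValueError("OTU counts must be integers")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        if self.lineages:
            df["lineage"] = [
                ";".join(self.lineages.get(i, ())) for i in df.index
            ]
        df.to_csv(path, sep="\t", index_label="otu_id")


def build_otu_table(
    clusters: Sequence[SeqCluster],
    samples: Sequence[str] | None = None,
    lineages: Mapping[str, tuple[str, ...]] | None = None,
    exclude_domain: str | None = None,
) -> OTUTable:
    """Assemble the OTU count matrix from final clusters.

    ``lineages`` maps centroid_id -> ranked lineage; rows whose domain
    (first rank) equals ``exclude_domain`` are dropped.  Samples with zero
    reads yield a column of zeros (with a warning).
    """
    if samples is None:
        seen: list[str] = []
        for c in clusters:
            for s in c.sample_counts:
                if s not in seen:
                    seen.append(s)
        samples = seen
    rows = {}
    kept_lineages: dict[str, tuple[str, ...]] = {}
    for c in clusters:
        lin = lineages.get(c.centroid_id) if lineages else None
        if exclude_domain is not None and lin and lin[0] == exclude_domain:
            continue
        rows[c.centroid_id] = [c.sample_counts.get(s, 0) for s in samples]
        if lin:
            kept_lineages[c.centroid_id] = tuple(lin)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
    for s in samples:
        if s in df.columns and df[s].sum() == 0:
            warnings.warn(f"sample {s!r} has zero reads", stacklevel=2)
    return OTUTable(counts=df, lineages=kept_lineages or None)


def rarefy(table: OTUTable, depth: int = 2893, seed: int = 0) -> OTUTable:
    """Subsample every sample column without replacement to exactly ``depth``
    reads; columns whose total is below ``depth`` are dropped with a warning."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for s in table.counts.columns:
        col = table.counts[s].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if total < depth:
            warnings.warn(
                f"sample {s!r} has {total} < {depth} reads; dropped",
                stacklevel=2,
            )
            continue
        if total == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index)
    return OTUTable(
        counts=df, lineages=table.lineages, rarefaction_depth=depth
    )


def run_pipeline(
    reads_by_sample: Mapping[str, Iterable[tuple[str, str]]],
    denoise_identity: float = 0.99,
    otu_identity: float = 0.97,
    min_size: int = 3,
    chimera: bool = True,
    chimera_margin: float = 0.02,
) -> tuple[list[SeqCluster], dict[str, int]]:
    """Full clustering path with a read-conservation audit.

    Returns the final OTU clusters plus an audit dict whose invariant is
    ``reads_in == reads_in_otus + discarded_small + discarded_chimera``.
    """
    derep = dereplicate(reads_by_sample)
    audit = {"reads_in": sum(c.size for c in derep)}
    denoised = greedy_cluster(derep, denoise_identity)
    kept, removed = filter_min_size(denoised, min_size)
    audit["discarded_small"] = removed
    if chimera:
        flags = chimera_flag_denovo(kept, margin=chimera_margin)
        audit["discarded_chimera"] = sum(
            c.size for c, f in zip(kept, flags) if f
        )
        kept = [c for c, f in zip(kept, flags) if not f]
    else:
        audit["discarded_chimera"] = 0
    otus = greedy_cluster(kept, otu_identity)
    audit["reads_in_otus"] = sum(c.size for c in otus)
    return otus, audit
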