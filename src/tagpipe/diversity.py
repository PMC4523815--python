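"""Alpha/beta diversity and ordination comparison.

Covers observed-OTU rarefaction curves, Bray-Curtis and (un)weighted UniFrac
distances, classical-scaling PCoA, and Procrustes comparison of two
ordinations with a Monte Carlo permutation test.  The Procrustes statistic
is M2 = 1 - (sum of singular values)^2 after centering and scaling both
configurations to unit sum of squares; small M2 means concordant
ordinations, so the permutation test is one-sided on the lower tail.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .otu import OTUTable

__all__ = [
    "PCoACoordinates",
    "ProcrustesResult",
    "rarefaction_curve",
    "bray_curtis",
    "unifrac",
    "pcoa",
    "procrustes",
]


def rarefaction_curve(
    table: OTUTable,
    depths: Sequence[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +- SD observed OTUs per sample at each subsampling depth.

    Each (sample, depth) cell averages ``reps`` draws without replacement.
    Depths exceeding a sample's total skip that sample with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    rows = []
    for s in table.counts.columns:
        col = table.counts[s].to_numpy(dtype=np.int64)
        total = int(col.sum())
        for depth in depths:
            if depth > total:
                warnings.warn(
                    f"depth {depth} exceeds sample {s!r} total {total}; skipped",
                    stacklevel=2,
                )
                continue
            obs = np.empty(reps)
            for r in range(reps):
                sub = rng.multivariate_hypergeometric(col, depth)
                obs[r] = int((sub > 0).sum())
            rows.append(
                {
                    "sample": s,
                    "depth": depth,
                    "mean_observed_otus": float(obs.mean()),
                    "sd_observed_otus": float(obs.std(ddof=0)),
                }
            )
    return pd.DataFrame(rows)


def bray_curtis(table: OTUTable) -> DistanceMatrix:
    """BC(a, b) = sum|a_k - b_k| / sum(a_k + b_k); two all-zero samples get
    distance 0 (with a warning)."""
    import warnings

    counts = table.counts.to_numpy(dtype=float).T  # samples x OTUs
    n = counts.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (counts[i] + counts[j]).sum()
            if denom == 0:
                warnings.warn(
                    "two all-zero samples: Bray-Curtis defined as 0",
                    stacklevel=2,
                )
                d = 0.0
            else:
                d = np.abs(counts[i] - counts[j]).sum() / denom
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=list(table.counts.columns))


def _branch_tip_matrix(
    tree: TreeNode, tip_order: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, branch x column incidence) for every non-root branch.

    Columns follow ``tip_order`` (one per OTU row; several columns may map
    to the same tip).  Tree tips absent from ``tip_order`` contribute branch
    length but no counts.
    """
    lengths = []
    incidence = []
    for node in tree.postorder(include_self=False):
        length = node.length if node.length is not None else 0.0
        tips = {node.name} if node.is_tip() else {t.name for t in node.tips()}
        row = np.array([name in tips for name in tip_order], dtype=bool)
        lengths.append(length)
        incidence.append(row)
    return np.asarray(lengths, dtype=float), np.asarray(incidence)


def unifrac(
    table: OTUTable,
    tree: TreeNode | str,
    weighted: bool = False,
    normalized: bool = True,
    tip_map: dict[str, str] | None = None,
) -> DistanceMatrix:
    """UniFrac distances between all sample pairs of an OTU table.

    Every OTU row must map to a tree tip (directly by id, or through
    ``tip_map``); unmapped OTUs raise with the missing names listed.

    unweighted: (branch length unique to one community) / (branch length
    covered by either).  weighted: sum_b l_b |pA_b - pB_b| with p the
    community proportion descending from branch b, divided by
    sum_b l_b (pA_b + pB_b) when ``normalized``.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(_io.StringIO(tree))
    otu_ids = list(table.counts.index)
    mapped = [tip_map.get(o, o) if tip_map else o for o in otu_ids]
    tip_names = {t.name for t in tree.tips()}
    missing = [m for m in mapped if m not in tip_names]
    if missing:
        raise ValueError(f"OTUs without a tree tip: {missing}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError("tree has negative branch lengths")

    lengths, incidence = _branch_tip_matrix(tree, mapped)
    counts = table.counts.to_numpy(dtype=float)  # OTUs x samples
    # per-branch descendant count per sample: branches x samples
    branch_counts = incidence.astype(float) @ counts
    totals = counts.sum(axis=0)
    samples = list(table.counts.columns)
    n = len(samples)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = branch_counts[:, i]
            b = branch_counts[:, j]
            if weighted:
                pa = a / totals[i] if totals[i] else a
                pb = b / totals[j] if totals[j] else b
                num = float((lengths * np.abs(pa - pb)).sum())
                if normalized:
                    denom = float((lengths * (pa + pb)).sum())
                    d = num / denom if denom else 0.0
                else:
                    d = num
            else:
                in_a = a > 0
                in_b = b > 0
                either = in_a | in_b
                unique = in_a ^ in_b
                denom = float(lengths[either].sum())
                d = float(lengths[unique].sum()) / denom if denom else 0.0
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=samples)


@dataclass
class PCoACoordinates:
    """Classical-scaling coordinates, axes ordered by decreasing eigenvalue;
    only positive-eigenvalue axes are retained."""

    labels: list[str]
    coords: np.ndarray  # samples x axes
    eigenvalues: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords,
            index=self.labels,
            columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])],
        )


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> PCoACoordinates:
    """Principal coordinates analysis (Gower's classical scaling).

    Double-centers -D^2/2, eigendecomposes, keeps positive-eigenvalue axes
    and scales eigenvectors by sqrt(eigenvalue).  Per-axis sign is fixed by
    making the largest-magnitude loading positive.
    """
    d = dm.data
    n = d.shape[0]
    b = -0.5 * d**2
    row_mean = b.mean(axis=1, keepdims=True)
    col_mean = b.mean(axis=0, keepdims=True)
    b = b - row_mean - col_mean + b.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eig_tol * max(abs(eigvals[0]), 1.0)
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    coords = eigvecs * np.sqrt(eigvals)[None, :]
    for ax in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, ax])))
        if coords[i, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return PCoACoordinates(
        labels=list(dm.ids), coords=coords, eigenvalues=eigvals
    )


@dataclass(frozen=True)
class ProcrustesResult:
    m2: float
    p_value: float
    n_permutations: int


def _normalize_configuration(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    ss = np.sqrt((x**2).sum())
    if ss == 0:
        raise ValueError("degenerate configuration (all points coincide)")
    return x / ss


def _m2(a: np.ndarray, b: np.ndarray) -> float:
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(max(1.0 - s.sum() ** 2, 0.0))


def procrustes(
    coords_a: PCoACoordinates,
    coords_b: PCoACoordinates,
    n_permutations: int = 10000,
    seed: int = 0,
    max_axes: int = 3,
) -> ProcrustesResult:
    """Least-squares Procrustes comparison of two ordinations.

    Configurations are matched by sample label, truncated to the common
    axis count (capped at ``max_axes``), centered and scaled to unit sum of
    squares; the optimal rotation comes from the SVD of the cross-product.
    The Monte Carlo p-value permutes B's sample labels:
    p = (1 + #{permuted M2 <= observed}) / (1 + n_permutations).
    """
    if set(coords_a.labels) != set(coords_b.labels):
        raise ValueError("sample label sets differ")
    labels = list(coords_a.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 shared samples")
    order_b = [coords_b.labels.index(l) for l in labels]
    k = min(coords_a.coords.shape[1], coords_b.coords.shape[1], max_axes)
    a = _normalize_configuration(coords_a.coords[:, :k])
    b = _normalize_configuration(coords_b.coords[order_b, :k])
    observed = _m2(a, b)

    rng = np.random.default_rng(seed)
    n = len(labels)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    # batched cross-products and SVDs: (n_perm, k, k)
    cross = np.einsum("ji,pjl->pil", a, b[perms])
    svals = np.linalg.svd(cross, compute_uv=False)
    m2_perm = np.maximum(1.0 - svals.sum(axis=1) ** 2, 0.0)
    hits = int((m2_perm <= observed + 1e-15).sum())
    p = (1 + hits) / (1 + n_permutations)
    return ProcrustesResult(m2=observed, p_value=p, n_permutations=n_permutations)
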