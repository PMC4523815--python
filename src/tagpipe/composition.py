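"""Expected mock-community composition.

A defined DNA pool mixes known organisms at known quantities.  Because
organisms differ in genome size and rRNA operon count, the mass fractions of
the pool are not the fractions one expects to see in 16S amplicon reads.  Two
normalizations convert the design into expectations:

* MED (expected distribution) — mass normalized by genome size, i.e. the
  fraction of *genome copies* each organism contributes::

      MED(i) = (Q(i) / GS(i)) / sum_j (Q(j) / GS(j))

* MEND (expected normalized distribution) — additionally weighted by rRNA
  gene copy number, i.e. the fraction of *rRNA gene copies*, which is what
  amplicon reads actually sample::

      MEND(i) = (Q(i) * RR(i) / GS(i)) / sum_j (Q(j) * RR(j) / GS(j))

where Q is DNA quantity (μg), GS genome size (bp) and RR the per-genome rRNA
gene copy count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignRow",
    "CommunityDesign",
    "expected_composition",
    "round_half_away",
    "mock_community_design",
]


class DesignValidationError(ValueError):
    """Raised when a community design violates its invariants."""


@dataclass(frozen=True)
class DesignRow:
    """One organism of a community design."""

    organism_id: str
    quantity_ug: float
    genome_size_bp: int
    rrna_copies: int
    lineage: str | None = None


@dataclass(frozen=True)
class CommunityDesign:
    """A defined community: per-organism DNA quantity, genome size, rRNA copies.

    Invariants (checked at construction): quantities and genome sizes strictly
    positive, rRNA copy counts integer >= 1, organism ids unique, at least one
    organism.
    """

    rows: tuple[DesignRow, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.rows:
            raise DesignValidationError("community design has no organisms")
        seen: set[str] = set()
        for row in self.rows:
            if row.organism_id in seen:
                raise DesignValidationError(
                    f"duplicate organism_id: {row.organism_id!r}"
                )
            seen.add(row.organism_id)
            if not row.quantity_ug > 0:
                raise DesignValidationError(
                    f"{row.organism_id}: quantity_ug must be > 0"
                )
            if not row.genome_size_bp > 0:
                raise DesignValidationError(
                    f"{row.organism_id}: genome_size_bp must be > 0"
                )
            if int(row.rrna_copies) != row.rrna_copies or row.rrna_copies < 1:
                raise DesignValidationError(
                    f"{row.organism_id}: rrna_copies must be an integer >= 1"
                )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def organism_ids(self) -> tuple[str, ...]:
        return tuple(r.organism_id for r in self.rows)

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, float, int, int]]
    ) -> "CommunityDesign":
        return cls(tuple(DesignRow(*r) for r in rows))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CommunityDesign":
        """Read a design TSV with columns organism, quantity_ug,
        genome_size_bp, rrna_copies (and an optional lineage column)."""
        df = pd.read_csv(path, sep="\t")
        required = {"organism", "quantity_ug", "genome_size_bp", "rrna_copies"}
        missing = required - set(df.columns)
        if missing:
            raise DesignValidationError(
                f"design TSV missing columns: {sorted(missing)}"
            )
        rows = []
        for rec in df.itertuples(index=False):
            rows.append(
                DesignRow(
                    organism_id=str(rec.organism),
                    quantity_ug=float(rec.quantity_ug),
                    genome_size_bp=int(rec.genome_size_bp),
                    rrna_copies=int(rec.rrna_copies),
                    lineage=str(rec.lineage) if hasattr(rec, "lineage") else None,
                )
            )
        return cls(tuple(rows))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "organism": [r.organism_id for r in self.rows],
                "quantity_ug": [r.quantity_ug for r in self.rows],
                "genome_size_bp": [r.genome_size_bp for r in self.rows],
                "rrna_copies": [r.rrna_copies for r in self.rows],
            }
        )
        if any(r.lineage for r in self.rows):
            df["lineage"] = [r.lineage or "" for r in self.rows]
        df.to_csv(path, sep="\t", index=False)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (2.345 -> 2.35, -2.345 -> -2.35).

    Python's built-in round() uses banker's rounding; printed community
    tables round half away from zero, so composition percentages go through
    Decimal with ROUND_HALF_UP.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def expected_composition(design: CommunityDesign) -> pd.DataFrame:
    """Compute mass fraction, MED and MEND for every organism of a design.

    Returns a DataFrame with one row per organism and columns:

    ``organism``, ``fraction_of_mix`` (Q/ΣQ), ``med``, ``mend`` (exact
    fractions summing to 1), and ``pct_of_mix``, ``med_pct``, ``mend_pct``
    (×100, rounded half-away-from-zero to 2 decimals).
    """
    q = np.array([r.quantity_ug for r in design.rows], dtype=float)
    gs = np.array([r.genome_size_bp for r in design.rows], dtype=float)
    rr = np.array([r.rrna_copies for r in design.rows], dtype=float)

    frac = q / q.sum()
    med = (q / gs) / (q / gs).sum()
    mend = (q * rr / gs) / (q * rr / gs).sum()

    return pd.DataFrame(
        {
            "organism": list(design.organism_ids),
            "fraction_of_mix": frac,
            "med": med,
            "mend": mend,
            "pct_of_mix": [round_half_away(100 * v) for v in frac],
            "med_pct": [round_half_away(100 * v) for v in med],
            "mend_pct": [round_half_away(100 * v) for v in mend],
        }
    )


def mend_weights(design: CommunityDesign) -> np.ndarray:
    """MEND fractions as a plain array (read-sampling weights)."""
    q = np.array([r.quantity_ug for r in design.rows], dtype=float)
    gs = np.array([r.genome_size_bp for r in design.rows], dtype=float)
    rr = np.array([r.rrna_copies for r in design.rows], dtype=float)
    w = q * rr / gs
    return w / w.sum()


def mock_community_design() -> CommunityDesign:
    """The packaged nine-organism validation community design."""
    ref = resources.files("tagpipe").joinpath("data/mock_design.tsv")
    with resources.as_file(ref) as path:
        return CommunityDesign.from_tsv(path)
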