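"""Plain-format I/O helpers (FASTQ, FASTA, lineage maps)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, Iterable[int]]]) -> int:
    """Write (id, sequence, phred qualities) triples as Phred+33 FASTQ.

    Returns the number of records written.  A ``.gz`` suffix triggers gzip.
    """
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred qualities) from a Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with _open_text(path, "wt") as fh:
        return SeqIO.write(recs, fh, "fasta")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def write_lineage_tsv(path: str | Path, lineages: dict[str, tuple[str, ...]]) -> None:
    """sequence_id <tab> semicolon-joined lineage, one per line."""
    with open(path, "w") as fh:
        for sid, lin in lineages.items():
            fh.write(f"{sid}\t{';'.join(lin)}\n")


def read_lineage_tsv(path: str | Path) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sid, lin = line.split("\t")
            out[sid] = tuple(p.strip() for p in lin.split(";"))
    return out
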