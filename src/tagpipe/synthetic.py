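"""Synthetic mock-community generator with known ground truth.

Generates reference 16S-like genes (multi-copy, with shared primer binding
sites for three amplifiable regions), a guide tree over all gene copies, and
error-bearing amplicon reads under configurable platform error models.  Every
injected error, chimera and source template is recorded in a truth table so
that downstream stages (QC, error profiling, clustering, chimera flagging,
classification) can be validated without external data.

Two stock error models are provided:

* :meth:`PlatformErrorModel.miseq_like` — substitution-dominated, positional
  quality decay, negligible indels.
* :meth:`PlatformErrorModel.pyro454_like` — indel-rich with a homopolymer
  multiplier boosting indel probability inside runs of three or more
  identical bases.

Neither claims to match any published instrument calibration; all rates are
configurable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CommunityDesign, mend_weights
from .io import revcomp, write_fasta, write_fastq

__all__ = [
    "ReferenceGene",
    "PlatformErrorModel",
    "ReadTruth",
    "TruthTable",
    "SimulatedRead",
    "generate_reference_set",
    "simulate_sample",
    "write_fixture",
    "REGIONS",
]

BASES = np.array(list("ACGT"))

#: Region layout on the synthetic 1500 bp gene: forward primer, reverse
#: primer (given 5'->3' on the reverse strand; its reverse complement is
#: embedded on the gene), and the half-open [start, end) span of the
#: amplified region (primer sites included).
REGIONS: dict[str, dict] = {
    "V4": {
        "fwd": "GTGCCAGCAGCCGCGGTAA",
        "rev": "GGACTACTAGGGTATCTAAT",
        "start": 480,
        "end": 790,
    },
    "V6V8": {
        "fwd": "AAACTCAAATGAATTGACGG",
        "rev": "ACGGGCGGTGTGTACAAG",
        "start": 900,
        "end": 1360,
    },
    "V7V8": {
        "fwd": "GCAACGAGCGCAACCCTT",
        "rev": "ACGGGCGGTGTGTACA",
        "start": 1080,
        "end": 1365,
    },
}

GENE_LENGTH = 1500


class EmptyDesignError(ValueError):
    pass


class SimulationParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceGene:
    """A multi-copy reference gene for one organism.

    ``copies`` are full-length gene sequences; copies of one organism differ
    pairwise at <= 2% of positions and share exact primer sites.
    ``region_coords`` maps region name -> per-copy [start, end) spans.
    ``lineage`` has exactly six ranks (domain..genus).
    """

    organism_id: str
    copies: tuple[str, ...]
    lineage: tuple[str, ...]
    region_coords: Mapping[str, tuple[tuple[int, int], ...]]

    def amplicon(self, region: str, copy: int = 0) -> str:
        start, end = self.region_coords[region][copy]
        return self.copies[copy][start:end]


def _linear_decay(q0: float, q1: float, span: int) -> Callable[[int], float]:
    def decay(pos: int) -> float:
        return q0 + (q1 - q0) * min(pos, span) / span

    return decay


@dataclass(frozen=True)
class PlatformErrorModel:
    """Per-base error and quality model for one sequencing platform mode."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    homopolymer_multiplier: float = 1.0
    quality_decay: Callable[[int], float] = field(default=lambda pos: 35.0)
    quality_sd: float = 3.0
    read_length: int | None = None
    paired: bool = False
    #: Mean Phred assigned to substituted bases and to the base following a
    #: deletion, making errors co-occur with low quality.  None disables the
    #: correlation.  Inserted bases always inherit their left neighbour's
    #: quality.
    error_quality_mean: float | None = 12.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.1:
                raise SimulationParameterError(f"{name}={v} outside [0, 0.1]")
        if self.homopolymer_multiplier < 1.0:
            raise SimulationParameterError("homopolymer_multiplier must be >= 1")
        probe = [self.quality_decay(p) for p in range(0, 2000, 25)]
        if any(b > a + 1e-9 for a, b in zip(probe, probe[1:])):
            raise SimulationParameterError("quality_decay must be non-increasing")

    @classmethod
    def miseq_like(cls, **overrides) -> "PlatformErrorModel":
        kwargs = dict(
            substitution_rate=0.003,
            insertion_rate=1e-4,
            deletion_rate=1e-4,
            homopolymer_multiplier=1.0,
            quality_decay=_linear_decay(38.0, 28.0, 500),
            quality_sd=3.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def pyro454_like(cls, **overrides) -> "PlatformErrorModel":
        kwargs = dict(
            substitution_rate=0.001,
            insertion_rate=0.004,
            deletion_rate=0.004,
            homopolymer_multiplier=3.0,
            quality_decay=_linear_decay(37.0, 30.0, 500),
            quality_sd=4.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def error_free(self) -> "PlatformErrorModel":
        return replace(
            self, substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0
        )


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read."""

    read_id: str
    organism: str
    copy: int
    stagger: int
    #: (template_position_1based, type) with type in {"sub", "ins", "del"};
    #: positions are on the amplicon template, primer included, stagger
    #: prefix excluded.
    errors: tuple[tuple[int, str], ...]
    is_chimera: bool = False
    parents: tuple[str, str] | None = None
    breakpoint: int | None = None

    def error_counts(self) -> dict[str, int]:
        out = {"sub": 0, "ins": 0, "del": 0}
        for _, etype in self.errors:
            out[etype] += 1
        return out


@dataclass
class TruthTable:
    """Per-read provenance plus per-sample true composition."""

    sample_id: str
    reads: list[ReadTruth] = field(default_factory=list)

    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rt in self.reads:
            out[rt.organism] = out.get(rt.organism, 0) + 1
        return out

    def error_totals(self) -> dict[str, int]:
        out = {"sub": 0, "ins": 0, "del": 0}
        for rt in self.reads:
            for _, etype in rt.errors:
                out[etype] += 1
        return out

    def chimera_ids(self) -> set[str]:
        return {rt.read_id for rt in self.reads if rt.is_chimera}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rt in self.reads:
            c = rt.error_counts()
            rows.append(
                {
                    "sample": self.sample_id,
                    "read_id": rt.read_id,
                    "organism": rt.organism,
                    "copy": rt.copy,
                    "stagger": rt.stagger,
                    "n_sub": c["sub"],
                    "n_ins": c["ins"],
                    "n_del": c["del"],
                    "error_positions": ";".join(
                        f"{p}:{t}" for p, t in rt.errors
                    ),
                    "is_chimera": rt.is_chimera,
                    "parents": ";".join(rt.parents) if rt.parents else "",
                    "breakpoint": rt.breakpoint if rt.breakpoint is not None else "",
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str
    qualities: tuple[int, ...]
    mate_sequence: str | None = None
    mate_qualities: tuple[int, ...] | None = None


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _lineage(i: int) -> tuple[str, ...]:
    # Shared upper ranks (3 phyla, paired classes) so that rank-level
    # confidence aggregation is exercised; genus always unique.
    return (
        "Bacteria",
        f"Phylum{i % 3 + 1}",
        f"Class{i // 2 + 1}",
        f"Order{i + 1}",
        f"Family{i + 1}",
        f"Genus{i + 1}",
    )


def generate_reference_set(
    n_organisms: int,
    copies_per_organism: int = 1,
    seed: int = 0,
    gene_length: int = GENE_LENGTH,
    copy_divergence: float = 0.01,
) -> tuple[list[ReferenceGene], str]:
    """Generate reference genes and a Newick guide tree over all copies.

    Each organism gets ``copies_per_organism`` gene copies that differ at
    ``copy_divergence`` of non-primer positions (substitutions only, so
    region coordinates are shared across copies).  Primer binding sites for
    the regions in :data:`REGIONS` are embedded exactly and identically in
    every organism.  Deterministic for a given seed.
    """
    if n_organisms < 1:
        raise EmptyDesignError("n_organisms must be >= 1")
    if copies_per_organism < 1:
        raise SimulationParameterError("copies_per_organism must be >= 1")
    rng = np.random.default_rng(seed)

    primer_mask = np.zeros(gene_length, dtype=bool)
    for spec in REGIONS.values():
        fs, fe = spec["start"], spec["start"] + len(spec["fwd"])
        rs, re_ = spec["end"] - len(spec["rev"]), spec["end"]
        primer_mask[fs:fe] = True
        primer_mask[rs:re_] = True
    mutable = np.flatnonzero(~primer_mask)
    n_mut = int(round(copy_divergence * gene_length))

    genes: list[ReferenceGene] = []
    tips: list[str] = []
    subtrees: list[str] = []
    for i in range(n_organisms):
        org = f"Org{i + 1:02d}"
        base = _random_seq(rng, gene_length)
        for spec in REGIONS.values():
            fwd = np.array(list(spec["fwd"]))
            rev_site = np.array(list(revcomp(spec["rev"])))
            base[spec["start"] : spec["start"] + len(fwd)] = fwd
            base[spec["end"] - len(rev_site) : spec["end"]] = rev_site
        copies = ["".join(base)]
        for _ in range(copies_per_organism - 1):
            mut = base.copy()
            pos = rng.choice(mutable, size=n_mut, replace=False)
            for p in pos:
                choices = [b for b in "ACGT" if b != mut[p]]
                mut[p] = choices[rng.integers(0, 3)]
            copies.append("".join(mut))
        coords = {
            name: tuple(
                (spec["start"], spec["end"]) for _ in range(copies_per_organism)
            )
            for name, spec in REGIONS.items()
        }
        genes.append(
            ReferenceGene(
                organism_id=org,
                copies=tuple(copies),
                lineage=_lineage(i),
                region_coords=coords,
            )
        )
        copy_ids = [f"{org}/c{j + 1}" for j in range(copies_per_organism)]
        tips.extend(copy_ids)
        if copies_per_organism == 1:
            subtrees.append(f"{copy_ids[0]}:0.10")
        else:
            inner = ",".join(f"{cid}:0.005" for cid in copy_ids)
            subtrees.append(f"({inner}):0.10")
    newick = "(" + ",".join(subtrees) + ");"
    return genes, newick


def _homopolymer_mask(seq: str, min_run: int = 3) -> np.ndarray:
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def _mutate_template(
    template: str, model: PlatformErrorModel, rng: np.random.Generator
) -> tuple[list[str], list[str], list[tuple[int, str, int]]]:
    """Inject errors base-by-base in template order.

    Returns (output bases, per-output-base flags, events).  Flags are
    ``normal``/``sub``/``ins``/``after_del``.  Events are
    (template_pos_1based, type, output_index); deletions use the output
    index where the removed base would have appeared.
    """
    hp = _homopolymer_mask(template)
    out: list[str] = []
    flags: list[str] = []
    events: list[tuple[int, str, int]] = []
    after_del = False
    for t, base in enumerate(template):
        mult = model.homopolymer_multiplier if hp[t] else 1.0
        p_del = min(model.deletion_rate * mult, 1.0)
        p_ins = min(model.insertion_rate * mult, 1.0)
        if p_del and rng.random() < p_del:
            events.append((t + 1, "del", len(out)))
            after_del = True
        else:
            if model.substitution_rate and rng.random() < model.substitution_rate:
                choices = [b for b in "ACGT" if b != base]
                out.append(choices[rng.integers(0, 3)])
                flags.append("sub")
                events.append((t + 1, "sub", len(out) - 1))
            else:
                out.append(base)
                flags.append("after_del" if after_del else "normal")
            after_del = False
        if p_ins and rng.random() < p_ins:
            out.append(str(BASES[rng.integers(0, 4)]))
            flags.append("ins")
            events.append((t + 1, "ins", len(out) - 1))
    return out, flags, events


def _draw_qualities(
    n: int, model: PlatformErrorModel, rng: np.random.Generator
) -> np.ndarray:
    means = np.array([model.quality_decay(p) for p in range(n)])
    q = rng.normal(means, model.quality_sd)
    return np.clip(np.rint(q), 2, 41).astype(int)


def simulate_sample(
    design: CommunityDesign,
    refs: Sequence[ReferenceGene],
    region: str,
    model: PlatformErrorModel,
    n_reads: int,
    stagger_max: int = 0,
    chimera_fraction: float = 0.0,
    seed: int = 0,
    sample_id: str = "S1",
) -> tuple[list[SimulatedRead], TruthTable]:
    """Simulate amplicon reads from a community design.

    Organisms are sampled with MEND weights (reads are proportional to rRNA
    gene copies), copies uniformly.  Each read is ``stagger`` random bases +
    forward primer + error-mutated amplicon (the primer is part of the
    template, so it can also acquire errors — as on a real instrument).
    ``chimera_fraction`` of reads are two-parent crossovers with a uniform
    breakpoint in [0.25, 0.75] of the amplicon.
    """
    if not 0.0 <= chimera_fraction <= 1.0:
        raise SimulationParameterError("chimera_fraction outside [0, 1]")
    if stagger_max < 0:
        raise SimulationParameterError("stagger_max must be >= 0")
    by_id = {g.organism_id: g for g in refs}
    missing = [oid for oid in design.organism_ids if oid not in by_id]
    if missing:
        raise SimulationParameterError(f"design organisms missing from refs: {missing}")
    for oid in design.organism_ids:
        if region not in by_id[oid].region_coords:
            raise SimulationParameterError(
                f"region {region!r} not defined for {oid}"
            )

    rng = np.random.default_rng(seed)
    weights = mend_weights(design)
    org_ids = list(design.organism_ids)

    reads: list[SimulatedRead] = []
    truth = TruthTable(sample_id=sample_id)
    if n_reads == 0:
        return reads, truth

    org_draws = rng.choice(len(org_ids), size=n_reads, p=weights)
    for i in range(n_reads):
        is_chimera = chimera_fraction > 0 and rng.random() < chimera_fraction
        if is_chimera:
            o1 = int(org_draws[i])
            o2 = int(rng.choice(len(org_ids), p=weights))
            while o2 == o1 and len(org_ids) > 1:
                o2 = int(rng.choice(len(org_ids), p=weights))
            g1, g2 = by_id[org_ids[o1]], by_id[org_ids[o2]]
            c1 = int(rng.integers(0, len(g1.copies)))
            c2 = int(rng.integers(0, len(g2.copies)))
            a1, a2 = g1.amplicon(region, c1), g2.amplicon(region, c2)
            bp = int(round(len(a1) * rng.uniform(0.25, 0.75)))
            template = a1[:bp] + a2[bp : len(a1)]
            organism, copy = org_ids[o1], c1
            parents = (org_ids[o1], org_ids[o2])
        else:
            oi = int(org_draws[i])
            gene = by_id[org_ids[oi]]
            copy = int(rng.integers(0, len(gene.copies)))
            template = gene.amplicon(region, copy)
            organism, parents, bp = org_ids[oi], None, None

        stagger = int(rng.integers(0, stagger_max + 1)) if stagger_max else 0
        prefix = "".join(BASES[rng.integers(0, 4, size=stagger)])

        out, flags, events = _mutate_template(template, model, rng)
        seq = prefix + "".join(out)
        quals = _draw_qualities(len(seq), model, rng)

        # quality correlation: substituted bases, the base after a deletion
        # and the anchor base left of an insertion get low quality; the
        # inserted base itself inherits its (now low) left neighbour.
        for j, flag in enumerate(flags):
            pos = stagger + j
            if flag == "ins":
                if pos > 0:
                    if model.error_quality_mean is not None:
                        q = rng.normal(model.error_quality_mean, model.quality_sd)
                        quals[pos - 1] = int(np.clip(round(q), 2, 41))
                    quals[pos] = quals[pos - 1]
            elif flag in ("sub", "after_del") and model.error_quality_mean is not None:
                q = rng.normal(model.error_quality_mean, model.quality_sd)
                quals[pos] = int(np.clip(round(q), 2, 41))

        kept_events = events
        if model.read_length is not None and len(seq) > model.read_length:
            cut = model.read_length
            seq = seq[:cut]
            quals = quals[:cut]
            kept_events = [
                (tp, et, oi_) for tp, et, oi_ in events if stagger + oi_ < cut
            ]

        rid = f"{sample_id}_r{i + 1}"
        if model.paired and model.read_length is not None:
            full = prefix + "".join(out)
            fq = _draw_qualities(len(full), model, rng)
            fq[: len(quals)] = quals
            r2seq = revcomp(full[-model.read_length :])
            r2q = tuple(int(q) for q in fq[-model.read_length :][::-1])
            reads.append(
                SimulatedRead(rid, seq, tuple(int(q) for q in quals), r2seq, r2q)
            )
        else:
            reads.append(SimulatedRead(rid, seq, tuple(int(q) for q in quals)))
        truth.reads.append(
            ReadTruth(
                read_id=rid,
                organism=organism,
                copy=copy,
                stagger=stagger,
                errors=tuple((tp, et) for tp, et, _ in kept_events),
                is_chimera=is_chimera,
                parents=parents,
                breakpoint=bp,
            )
        )
    return reads, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(
    samples: Mapping[str, tuple[list[SimulatedRead], TruthTable]],
    refs: Sequence[ReferenceGene],
    tree_newick: str,
    design: CommunityDesign,
    outdir: str | Path,
    gzip_fastq: bool = False,
) -> dict[str, str]:
    """Write a complete simulated dataset to ``outdir``.

    Emits one FASTQ per sample, a pooled truth TSV, the design TSV, the
    references FASTA (one record per gene copy, id ``organism/cN``) and the
    Newick tree, plus a ``manifest.tsv`` of sha256 checksums.  Returns the
    manifest mapping (manifest file itself excluded).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    for sid, (reads, _) in samples.items():
        p = outdir / f"{sid}{ext}"
        write_fastq(p, ((r.id, r.sequence, r.qualities) for r in reads))
        manifest[p.name] = _sha256(p)

    truth_df = pd.concat(
        [t.to_dataframe() for _, t in samples.values()], ignore_index=True
    )
    p = outdir / "truth.tsv"
    truth_df.to_csv(p, sep="\t", index=False)
    manifest[p.name] = _sha256(p)

    p = outdir / "design.tsv"
    design.to_tsv(p)
    manifest[p.name] = _sha256(p)

    p = outdir / "references.fasta"
    write_fasta(
        p,
        (
            (f"{g.organism_id}/c{j + 1}", copy)
            for g in refs
            for j, copy in enumerate(g.copies)
        ),
    )
    manifest[p.name] = _sha256(p)

    p = outdir / "tree.nwk"
    p.write_text(tree_newick + "\n")
    manifest[p.name] = _sha256(p)

    with open(outdir / "manifest.tsv", "w") as fh:
        for name, digest in sorted(manifest.items()):
            fh.write(f"{name}\t{digest}\n")
    return manifest
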