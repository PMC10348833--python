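"""Gene models: transcripts, splice sites and the subexon partition.

A *subexon* is the smallest exonic segment bounded by splice sites or
transcript start/end sites of any transcript of a gene.  Subexons are the
atoms over which mapping signatures, fragments and event classifications are
defined.  All coordinates are internal 0-based half-open intervals; GTF I/O
converts from/to the 1-based inclusive convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


def _merge_abutting(exons: Sequence[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Merge exons of one transcript that touch (gap 0).  Overlap is an error."""
    out: list[GenomicInterval] = []
    for e in sorted(exons, key=lambda x: (x.start, x.end)):
        if out and e.start < out[-1].end:
            raise ValueError(f"overlapping exons within one transcript near {e}")
        if out and e.start == out[-1].end:
            prev = out.pop()
            e = GenomicInterval(e.chrom, prev.start, e.end, e.strand)
        out.append(e)
    return tuple(out)


@dataclass(frozen=True)
class Transcript:
    """An annotated transcript: an ordered chain of disjoint exons.

    Exons are kept in increasing genomic coordinate regardless of strand;
    touching exons are merged at construction.  ``tss``/``tes`` follow the
    genomic orientation (leftmost / rightmost coordinate).
    """

    id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        object.__setattr__(self, "exons", _merge_abutting(self.exons))
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.id} spans chromosomes {sorted(chroms)}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def tss(self) -> int:
        return self.exons[0].start

    @property
    def tes(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class SpliceSite:
    """A donor or acceptor boundary position derived from an annotated intron.

    ``pos`` is a boundary coordinate in half-open space: the left boundary of
    an intron (its start) and the right boundary (its end).  On '+' the left
    boundary is the donor and the right the acceptor; roles mirror on '-'.
    """

    gene_id: str
    pos: int
    kind: str  # "donor" | "acceptor"
    strand: str

    def __post_init__(self):
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"invalid splice-site kind {self.kind!r}")


@dataclass(frozen=True)
class Subexon:
    gene_id: str
    index: int  # 1-based, increasing genomic coordinate
    interval: GenomicInterval
    containing_transcripts: frozenset[str]

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("subexon indices start at 1")
        if not self.containing_transcripts:
            raise ValueError(f"subexon {self.index} of {self.gene_id} in no transcript")

    @property
    def length(self) -> int:
        return self.interval.length


def subexon_partition(
    transcripts: Sequence[Transcript], extra_cuts: Iterable[int] = ()
) -> list[Subexon]:
    """Cut the exonic territory of one gene into subexons.

    Cut points are the union of all exon starts and ends (plus any
    ``extra_cuts``, e.g. splice sites discovered by the refine phase).  Each
    maximal run of positions covered by at least one exon, subdivided at
    internal cut points, becomes one subexon; indices are assigned left to
    right starting at 1.
    """
    if not transcripts:
        raise ValueError("subexon_partition requires at least one transcript")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    chroms = {t.chrom for t in transcripts}
    if len(chroms) != 1:
        raise ValueError(f"gene {gene_ids.pop()} has transcripts on chromosomes {sorted(chroms)}")
    gene_id = transcripts[0].gene_id
    exons = [e for t in transcripts for e in t.exons]
    cuts = sorted({e.start for e in exons} | {e.end for e in exons} | set(extra_cuts))
    # maximal covered runs
    runs: list[tuple[int, int]] = []
    for e in sorted(exons, key=lambda x: (x.start, x.end)):
        if runs and e.start <= runs[-1][1]:
            runs[-1] = (runs[-1][0], max(runs[-1][1], e.end))
        else:
            runs.append((e.start, e.end))
    subexons: list[Subexon] = []
    idx = 0
    for rs, re_ in runs:
        inner = [c for c in cuts if rs < c < re_]
        bounds = [rs, *inner, re_]
        for a, b in zip(bounds, bounds[1:]):
            idx += 1
            iv = GenomicInterval(transcripts[0].chrom, a, b, transcripts[0].strand)
            members = frozenset(
                t.id for t in transcripts if any(e.contains(iv) for e in t.exons)
            )
            subexons.append(Subexon(gene_id, idx, iv, members))
    return subexons


def transcript_signature(t: Transcript, subexons: Sequence[Subexon]) -> tuple[int, ...]:
    """Indices of the subexons that tile transcript ``t``, in genomic order."""
    sig: list[int] = []
    for e in t.exons:
        covered = [s for s in subexons if e.contains(s.interval)]
        covered.sort(key=lambda s: s.interval.start)
        # consecutive tiling check within the exon
        pos = e.start
        for s in covered:
            if s.interval.start != pos:
                raise RuntimeError(
                    f"subexon set inconsistent with transcript {t.id}: gap at {pos}"
                )
            pos = s.interval.end
        if pos != e.end:
            raise RuntimeError(
                f"subexon set inconsistent with transcript {t.id}: exon {e} not tiled"
            )
        sig.extend(s.index for s in covered)
    if any(a >= b for a, b in zip(sig, sig[1:])):
        raise RuntimeError(f"non-increasing signature for transcript {t.id}")
    return tuple(sig)


@dataclass
class GeneModel:
    """All per-gene bookkeeping: transcripts, subexons, sites, signatures."""

    gene_id: str
    transcripts: list[Transcript]
    extra_boundaries: frozenset[int] = frozenset()
    subexons: list[Subexon] = field(default_factory=list)
    signatures: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.extra_boundaries = frozenset(self.extra_boundaries)
        if not self.subexons:
            self.subexons = subexon_partition(self.transcripts, self.extra_boundaries)
        if not self.signatures:
            self.signatures = {
                t.id: transcript_signature(t, self.subexons) for t in self.transcripts
            }

    # -- basic geometry -------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.tss for t in self.transcripts),
            max(t.tes for t in self.transcripts),
            self.strand,
        )

    def subexon(self, index: int) -> Subexon:
        s = self.subexons[index - 1]
        assert s.index == index
        return s

    @property
    def n_subexons(self) -> int:
        return len(self.subexons)

    # -- splice sites and junctions -------------------------------------
    @property
    def annotated_introns(self) -> set[tuple[int, int]]:
        return {(i.start, i.end) for t in self.transcripts for i in t.introns}

    @property
    def left_sites(self) -> set[int]:
        """Left boundaries of annotated introns (donors on '+', acceptors on '-')."""
        return {s for s, _ in self.annotated_introns}

    @property
    def right_sites(self) -> set[int]:
        return {e for _, e in self.annotated_introns}

    @property
    def splice_sites(self) -> list[SpliceSite]:
        donor_left = self.strand != "-"
        out = []
        for p in sorted(self.left_sites):
            out.append(SpliceSite(self.gene_id, p, "donor" if donor_left else "acceptor", self.strand))
        for p in sorted(self.right_sites):
            out.append(SpliceSite(self.gene_id, p, "acceptor" if donor_left else "donor", self.strand))
        return out

    def subexon_ending_at(self, pos: int) -> int | None:
        for s in self.subexons:
            if s.interval.end == pos:
                return s.index
        return None

    def subexon_starting_at(self, pos: int) -> int | None:
        for s in self.subexons:
            if s.interval.start == pos:
                return s.index
        return None

    def transcripts_overlapping(self, start: int, end: int) -> list[Transcript]:
        return [t for t in self.transcripts if t.tss < end and start < t.tes]

    def t_of(self, index: int) -> frozenset[str]:
        """t(s): the set of transcript ids containing subexon ``index``."""
        return self.subexon(index).containing_transcripts


# ----------------------------------------------------------------------
# GTF parsing
# ----------------------------------------------------------------------

def _prescan_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 8:
                raise ValueError(f"malformed GTF line {lineno}: fewer than 8 fields")


def parse_annotation(gtf_path, fasta_path=None) -> dict[str, GeneModel]:
    """Parse a GTF (+ optional genome FASTA) into per-gene models.

    Only ``exon`` features are required; ``gene_id`` and ``transcript_id``
    attributes must be present.  When a FASTA is given every referenced
    chromosome must have a sequence.
    """
    import gffutils

    gtf_path = Path(gtf_path)
    _prescan_gtf(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genome = None
    if fasta_path is not None:
        import pyfaidx

        genome = pyfaidx.Fasta(str(fasta_path))

    by_tx: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ValueError(f"exon at {feat.seqid}:{feat.start} missing {exc} attribute")
        key = (gid, tid)
        if key not in by_tx:
            by_tx[key] = []
            order.append(key)
        strand = feat.strand if feat.strand in ("+", "-") else "."
        if strand == ".":
            warnings.warn(f"unstranded exon in gene {gid}; treating as '+'")
            strand = "+"
        # GTF is 1-based inclusive
        by_tx[key].append(GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand))

    genes: dict[str, list[Transcript]] = {}
    for gid, tid in order:
        tx = Transcript(tid, gid, tuple(by_tx[(gid, tid)]))
        genes.setdefault(gid, []).append(tx)

    models: dict[str, GeneModel] = {}
    for gid, txs in genes.items():
        chroms = {t.chrom for t in txs}
        if len(chroms) != 1:
            raise ValueError(f"gene {gid} has transcripts on different chromosomes: {sorted(chroms)}")
        if genome is not None and txs[0].chrom not in genome:
            raise ValueError(f"missing sequence for chromosome {txs[0].chrom!r}")
        models[gid] = GeneModel(gid, sorted(txs, key=lambda t: t.id))
    return models


# ----------------------------------------------------------------------
# serialization (stable, documented TSV)
# ----------------------------------------------------------------------

def write_gene_models(models: Mapping[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tchrom\tstrand\texons\textra_boundaries\n")
        for gid in sorted(models):
            g = models[gid]
            extra = ";".join(map(str, sorted(g.extra_boundaries)))
            for t in sorted(g.transcripts, key=lambda t: t.id):
                exons = ",".join(f"{e.start}-{e.end}" for e in t.exons)
                fh.write(f"{gid}\t{t.id}\t{t.chrom}\t{t.strand}\t{exons}\t{extra}\n")


def read_gene_models(path) -> dict[str, GeneModel]:
    genes: dict[str, list[Transcript]] = {}
    extras: dict[str, frozenset[int]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError("not a gene-model TSV")
        for line in fh:
            gid, tid, chrom, strand, exons, extra = line.rstrip("\n").split("\t")
            ivs = tuple(
                GenomicInterval(chrom, int(a), int(b), strand)
                for a, b in (p.split("-") for p in exons.split(","))
            )
            genes.setdefault(gid, []).append(Transcript(tid, gid, ivs))
            extras[gid] = frozenset(int(x) for x in extra.split(";") if x)
    return {gid: GeneModel(gid, txs, extras[gid]) for gid, txs in genes.items()}
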