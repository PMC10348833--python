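"""Incorporation of novel splice sites found by an external spliced aligner.

Junction guessing only recombines *annotated* splice sites; genuinely novel
donors/acceptors require a conventional spliced alignment of the reads that
the pseudoalignment phase left unmapped.  This module consumes the standard
9-column junction table emitted by such aligners (the STAR ``SJ.out.tab``
dialect), filters it, splits any subexon that a discovered site falls into,
renumbers the partition, rewrites existing signature counts through the
old-to-new index remap, and rebuilds fragments for the affected genes so the
previously unmapped reads can be requantified.

Sites that fall outside every gene are skipped (no novel-exon assembly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .fragments import build_fragment_set
from .gene_model import GeneModel
from .pseudomap import SignatureCountTable, build_kmer_index, count_reads
from .virtual_splicing import Junction, build_splice_graph

log = logging.getLogger(__name__)

DEFAULT_MIN_UNIQUE = 3
DEFAULT_MIN_OVERHANG = 10

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
_CODE_STRAND = {v: k for k, v in _STRAND_CODE.items()}


@dataclass(frozen=True)
class JunctionRecord:
    """One discovered junction; intron coordinates in internal half-open form."""

    chrom: str
    start: int
    end: int
    strand: str  # "+", "-" or "." (undefined)
    motif: int
    annotated: bool
    unique_reads: int
    multi_reads: int
    max_overhang: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty intron {self.chrom}:{self.start}-{self.end}")
        if min(self.unique_reads, self.multi_reads, self.max_overhang) < 0:
            raise ValueError("junction read counts must be non-negative")


def parse_sj(path) -> list[JunctionRecord]:
    """Parse a 9-column SJ.out.tab-style file (1-based inclusive introns)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"SJ line {lineno}: expected 9 columns, found {len(cols)}")
            chrom, s1, e1, sc, motif, ann, uniq, multi, ovh = cols
            out.append(
                JunctionRecord(
                    chrom, int(s1) - 1, int(e1), _STRAND_CODE[int(sc)], int(motif),
                    bool(int(ann)), int(uniq), int(multi), int(ovh),
                )
            )
    return out


def write_sj(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start + 1}\t{r.end}\t{_CODE_STRAND[r.strand]}\t"
                f"{r.motif}\t{int(r.annotated)}\t{r.unique_reads}\t{r.multi_reads}\t"
                f"{r.max_overhang}\n"
            )


def filter_records(
    records,
    min_unique: int = DEFAULT_MIN_UNIQUE,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[JunctionRecord]:
    return [
        r for r in records if r.unique_reads >= min_unique and r.max_overhang >= min_overhang
    ]


def _remap_table(old: GeneModel, new: GeneModel) -> dict[int, list[int]]:
    """old subexon index -> successor indices in the re-cut partition."""
    remap: dict[int, list[int]] = {}
    for s in old.subexons:
        remap[s.index] = [
            n.index for n in new.subexons if s.interval.contains(n.interval)
        ]
        if not remap[s.index]:
            raise RuntimeError(f"subexon {s.index} of {old.gene_id} lost in re-partition")
    return remap


def remap_signature(sig: tuple[int, ...], remap: dict[int, list[int]]) -> tuple[int, ...]:
    """Re-express a signature in the refined index space.

    An index whose subexon was split expands to all successor indices when it
    is internal (the read covered the whole subexon), to the rightmost
    successor when it is the signature's first index and to the leftmost when
    it is the last (the only pieces guaranteed overlapped); singleton
    signatures expand to all successors.
    """
    m = len(sig)
    out: list[int] = []
    for pos, i in enumerate(sig):
        succ = remap[i]
        if m == 1 or (0 < pos < m - 1):
            out.extend(succ)
        elif pos == 0:
            out.append(succ[-1])
        else:
            out.append(succ[0])
    return tuple(out)


def incorporate_novel_sites(
    models: dict[str, GeneModel],
    records: list[JunctionRecord],
    min_unique: int = DEFAULT_MIN_UNIQUE,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
):
    """Split subexons at discovered splice sites and rebuild gene models.

    Returns ``(new_models, discovered, remaps, skipped)`` where ``discovered``
    maps gene id to its set of discovered junctions, ``remaps`` maps gene id
    to the old->new subexon index table, and ``skipped`` lists records that
    could not be anchored inside any gene.
    """
    kept = filter_records(records, min_unique, min_overhang)
    new_cuts: dict[str, set[int]] = {gid: set() for gid in models}
    discovered: dict[str, set[Junction]] = {gid: set() for gid in models}
    skipped: list[JunctionRecord] = []

    for rec in kept:
        placed = False
        for gid, g in models.items():
            span = g.span
            if g.chrom != rec.chrom or not (span.start <= rec.start and rec.end <= span.end):
                continue
            if rec.strand != "." and rec.strand != g.strand:
                continue
            if (rec.start, rec.end) in g.annotated_introns:
                placed = True
                continue
            # both intron endpoints must land on exonic territory of the gene
            ok = True
            for p, side in ((rec.start, "end"), (rec.end, "start")):
                inside = next(
                    (s for s in g.subexons if s.interval.start < p < s.interval.end), None
                )
                boundary = (
                    g.subexon_ending_at(p) if side == "end" else g.subexon_starting_at(p)
                )
                if inside is not None:
                    new_cuts[gid].add(p)
                elif boundary is None:
                    ok = False  # falls in intronic/intergenic territory: needs novel exon
                    break
            if ok:
                discovered[gid].add(Junction(gid, rec.start, rec.end, g.strand, "discovered"))
                placed = True
        if not placed:
            skipped.append(rec)
            log.info("junction %s:%d-%d outside all genes; skipped", rec.chrom, rec.start, rec.end)

    new_models: dict[str, GeneModel] = {}
    remaps: dict[str, dict[int, list[int]]] = {}
    for gid, g in models.items():
        cuts = frozenset(g.extra_boundaries | new_cuts[gid])
        if cuts == g.extra_boundaries:
            new_models[gid] = g
            remaps[gid] = {s.index: [s.index] for s in g.subexons}
        else:
            ng = GeneModel(gid, g.transcripts, cuts)
            new_models[gid] = ng
            remaps[gid] = _remap_table(g, ng)
    return new_models, discovered, remaps, skipped


def remap_counts(
    table: SignatureCountTable, remaps: dict[str, dict[int, list[int]]]
) -> SignatureCountTable:
    """Rewrite a signature-count table through per-gene index remaps.

    Count totals are conserved: each old signature maps to exactly one new
    signature.
    """
    out = SignatureCountTable(
        mapped=table.mapped, unmapped=table.unmapped, ambiguous=table.ambiguous
    )
    for (gid, sig), n in table.counts.items():
        new_sig = remap_signature(sig, remaps[gid]) if gid in remaps else sig
        key = (gid, new_sig)
        out.counts[key] = out.counts.get(key, 0) + n
    out.intron_cov = dict(table.intron_cov)
    out.pair_counts = dict(table.pair_counts)
    return out


def requant_unmapped(
    unmapped_fastq,
    models: dict[str, GeneModel],
    discovered: dict[str, set[Junction]],
    genome,
    l: int,
    changed_genes: set[str] | None = None,
    mode: str = "as",
    k: int | None = None,
    variant: str = "F",
    with_introns: bool = False,
    unmapped_out: list | None = None,
) -> SignatureCountTable:
    """Rebuild fragments for affected genes only and remap unmapped reads.

    Returns the delta table to be merged (additively) into the main table.
    """
    if changed_genes is None:
        changed_genes = {gid for gid, js in discovered.items() if js}
    if not changed_genes:
        if unmapped_out is not None:
            from .pseudomap import _fastq_records

            unmapped_out.extend(_fastq_records(unmapped_fastq))
        return SignatureCountTable()
    graphs = {
        gid: build_splice_graph(
            models[gid], mode, extra_junctions=discovered.get(gid, set())
        )
        for gid in sorted(changed_genes)
    }
    fs = build_fragment_set(graphs, genome, l, variant=variant, with_introns=with_introns)
    index = build_kmer_index(fs, k)
    return count_reads(unmapped_fastq, index, unmapped_out=unmapped_out)


def refine_counts(
    table: SignatureCountTable,
    models: dict[str, GeneModel],
    records: list[JunctionRecord],
    unmapped_fastq,
    genome,
    l: int,
    **kwargs,
):
    """Full refine phase: re-partition, remap counts, requantify, merge.

    Phase-one counts are never decreased (the merge is additive).  Running the
    phase twice with the same junction file leaves the result unchanged.
    """
    new_models, discovered, remaps, skipped = incorporate_novel_sites(
        models, records,
        min_unique=kwargs.pop("min_unique", DEFAULT_MIN_UNIQUE),
        min_overhang=kwargs.pop("min_overhang", DEFAULT_MIN_OVERHANG),
    )
    remapped = remap_counts(table, remaps)
    changed = {
        gid for gid in models
        if discovered[gid] or new_models[gid] is not models[gid]
    }
    delta = requant_unmapped(
        unmapped_fastq, new_models, discovered, genome, l,
        changed_genes=changed, **kwargs,
    )
    remapped.merge(delta)
    # requantified reads were already in the phase-1 unmapped tally
    remapped.unmapped -= delta.total_reads
    return remapped, new_models, discovered, skipped
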