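"""Guessing novel splice junctions between annotated splice sites.

The annotated transcript set of a gene is conceptually extended to a virtual
transcriptome without ever materializing novel transcripts:

* mode ``as``  — transcripts derivable from an annotated transcript by
  skipping exons and moving the remaining exon boundaries to other annotated
  sites, within the anchor's TSS/TES span.  Operationally a candidate
  donor-acceptor pair is admitted iff the event classifier types it
  ES/AD/AA/AP with respect to at least one annotated transcript.
* mode ``ap`` — more general alternative processing: every donor-before-
  acceptor combination of annotated sites, bounded only by the gene span.
* mode ``annotated`` — no guessing.

Junction sets are nested: annotated ⊆ as ⊆ ap.  The sets are carried by a
per-gene splice graph whose nodes are subexons, with unspliced (read-through)
edges between genomically adjacent subexons and spliced edges for junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .events import classify_intron
from .gene_model import GeneModel, GenomicInterval

log = logging.getLogger(__name__)

MODES = ("annotated", "as", "ap")

DEFAULT_MIN_INTRON = 20
DEFAULT_MAX_GUESSES = 50_000


@dataclass(frozen=True, order=True)
class Junction:
    """A spliced intron [start, end) between two subexons of one gene."""

    gene_id: str
    start: int
    end: int
    strand: str
    status: str = "annotated"  # annotated | guessed | discovered

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty intron {self.start}-{self.end}")
        if self.status not in ("annotated", "guessed", "discovered"):
            raise ValueError(f"invalid junction status {self.status!r}")

    @property
    def donor_pos(self) -> int:
        return self.start if self.strand != "-" else self.end

    @property
    def acceptor_pos(self) -> int:
        return self.end if self.strand != "-" else self.start


def _candidate_pairs(g: GeneModel, min_intron: int):
    """All (left, right) boundary pairs combining annotated sites, excluding
    annotated introns.  Left boundaries of annotated introns are donors on
    '+' and acceptors on '-', so the pairing is strand-symmetric."""
    annotated = g.annotated_introns
    for a in sorted(g.left_sites):
        for b in sorted(g.right_sites):
            if b - a < min_intron:
                continue
            if (a, b) in annotated:
                continue
            # both endpoints must bound a subexon (always true for annotated sites)
            if g.subexon_ending_at(a) is None or g.subexon_starting_at(b) is None:
                continue
            yield a, b


def guess_junctions_ap(
    g: GeneModel,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_guesses: int = DEFAULT_MAX_GUESSES,
) -> set[Junction]:
    """All novel donor-before-acceptor combinations of annotated sites."""
    out: set[Junction] = set()
    for a, b in _candidate_pairs(g, min_intron):
        out.add(Junction(g.gene_id, a, b, g.strand, "guessed"))
        if len(out) >= max_guesses:
            log.warning("gene %s: guessed-junction cap %d reached", g.gene_id, max_guesses)
            break
    return out


def guess_junctions_as(
    g: GeneModel,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_guesses: int = DEFAULT_MAX_GUESSES,
) -> set[Junction]:
    """Novel junctions admissible as exon skipping or alternative donor/
    acceptor/pair with respect to at least one annotated transcript.

    The anchor transcript must also contain the junction within its TSS/TES
    span: a virtual transcript keeps its anchor's start and end sites, so a
    junction reaching outside every candidate anchor cannot occur.
    """
    out: set[Junction] = set()
    for a, b in _candidate_pairs(g, min_intron):
        iv = GenomicInterval(g.chrom, a, b, g.strand)
        for t in g.transcripts_overlapping(a, b):
            if not (t.tss <= a and b <= t.tes):
                continue
            if any(i.start == a and i.end == b for i in t.introns):
                continue
            typ, _, _ = classify_intron(iv, t)
            if typ in ("ES", "AD", "AA", "AP"):
                out.add(Junction(g.gene_id, a, b, g.strand, "guessed"))
                break
        if len(out) >= max_guesses:
            log.warning("gene %s: guessed-junction cap %d reached", g.gene_id, max_guesses)
            break
    return out


@dataclass
class SpliceGraph:
    """Subexon graph of one gene: nodes are subexon indices, unspliced edges
    join genomically adjacent subexons readable through within one exon, and
    spliced edges carry annotated/guessed/discovered junctions."""

    gene: GeneModel
    mode: str
    unspliced_edges: set[tuple[int, int]] = field(default_factory=set)
    spliced_edges: dict[tuple[int, int], Junction] = field(default_factory=dict)

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def nodes(self) -> list[int]:
        return [s.index for s in self.gene.subexons]

    def successors(self, i: int) -> list[int]:
        out = [j for (a, j) in self.unspliced_edges if a == i]
        out += [j for (a, j) in self.spliced_edges if a == i]
        return sorted(set(out))

    def edges(self) -> set[tuple[int, int]]:
        return set(self.unspliced_edges) | set(self.spliced_edges)

    def junctions(self) -> list[Junction]:
        return sorted(self.spliced_edges.values())

    def is_transcript_window(self, sig: tuple[int, ...]) -> bool:
        for tsig in self.gene.signatures.values():
            for k in range(len(tsig) - len(sig) + 1):
                if tsig[k : k + len(sig)] == sig:
                    return True
        return False

    def span_admissible(self, sig: tuple[int, ...]) -> bool:
        """TSS/TES constraint: in as mode a signature must lie within the
        span of at least one annotated transcript; in ap mode only the gene
        span applies (always true for subexon sequences)."""
        if self.mode != "as":
            return True
        lo = self.gene.subexon(sig[0]).interval.start
        hi = self.gene.subexon(sig[-1]).interval.end
        return any(t.tss <= lo and hi <= t.tes for t in self.gene.transcripts)

    def is_path(self, sig: tuple[int, ...]) -> bool:
        """Membership of a signature in the graph's path language (f1)."""
        if len(sig) == 1:
            return 1 <= sig[0] <= self.gene.n_subexons
        if self.mode == "annotated":
            return self.is_transcript_window(sig)
        edges = self.edges()
        if not all((a, b) in edges for a, b in zip(sig, sig[1:])):
            return False
        return self.span_admissible(sig)


def build_splice_graph(
    g: GeneModel,
    mode: str = "as",
    min_intron: int = DEFAULT_MIN_INTRON,
    max_guesses: int = DEFAULT_MAX_GUESSES,
    extra_junctions: set[Junction] | None = None,
) -> SpliceGraph:
    """Assemble the per-gene splice graph for the requested virtual mode.

    ``extra_junctions`` lets the refine phase inject discovered junctions.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    graph = SpliceGraph(g, mode)

    # unspliced edges: adjacent subexons whose shared boundary is interior to
    # some annotated exon (no merging of touching exons across transcripts)
    for s1, s2 in zip(g.subexons, g.subexons[1:]):
        if s1.interval.end != s2.interval.start:
            continue
        p = s1.interval.end
        for t in g.transcripts:
            if any(e.start < p < e.end for e in t.exons):
                graph.unspliced_edges.add((s1.index, s2.index))
                break

    junctions: set[Junction] = {
        Junction(g.gene_id, a, b, g.strand, "annotated") for a, b in g.annotated_introns
    }
    if mode == "as":
        junctions |= guess_junctions_as(g, min_intron, max_guesses)
    elif mode == "ap":
        junctions |= guess_junctions_ap(g, min_intron, max_guesses)
    if extra_junctions:
        junctions |= set(extra_junctions)

    for j in junctions:
        i1 = g.subexon_ending_at(j.start)
        i2 = g.subexon_starting_at(j.end)
        if i1 is None or i2 is None:
            raise ValueError(
                f"junction {j.start}-{j.end} of gene {g.gene_id} does not align "
                "with subexon boundaries"
            )
        key = (i1, i2)
        prev = graph.spliced_edges.get(key)
        # annotated status wins over guessed/discovered for the same edge
        if prev is None or (prev.status != "annotated" and j.status == "annotated"):
            graph.spliced_edges[key] = j
    return graph


def write_junctions(graphs: dict[str, SpliceGraph], path) -> None:
    import pandas as pd

    rows = []
    for gid in sorted(graphs):
        g = graphs[gid]
        for j in g.junctions():
            rows.append(
                dict(gene_id=gid, chrom=g.gene.chrom, donor=j.donor_pos,
                     acceptor=j.acceptor_pos, strand=j.strand, status=j.status)
            )
    pd.DataFrame(rows, columns=["gene_id", "chrom", "donor", "acceptor", "strand", "status"]).to_csv(
        path, sep="\t", index=False
    )
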