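"""Feasible signatures and transcript-fragment construction.

Given a read length *l* and a (virtual) transcriptome represented by a splice
graph, a signature ı=(i1..im) is *feasible* iff

* (f1) it is a contiguous path in the graph's path language,
* (f2) Σ|s_i| >= l  (a read of length l fits), and
* (f3) for m >= 3 the internal subexons satisfy Σ_{j=2..m-1}|s_ij| <= l-2
  (a read can cover all of them with >= 1 nt left on each boundary subexon).

For each feasible signature the minimal fragment sequence is the concatenation
of a suffix of the first subexon, the full internal subexons, and a prefix of
the last subexon, where the boundary inclusion length is b = l - L_int - 1
(L_int the total internal length); for m = 1 the fragment is the whole
subexon.  Three fragment sets are derived:

* ``F11``  one fragment per feasible signature, minimally trimmed;
* ``Fmax`` fragments only for maximal signatures (not contiguously contained
  in any other feasible signature), with boundary subexons in full;
* ``F``    the production set: Fmax with boundary contributions trimmed to at
  most l-1 nt and every subexon of length >= l emitted additionally as a
  singleton fragment.

``F`` is correct and complete: every fragment derives from a (virtual)
transcript, and every length-l read sampled from one maps to some fragment
with its true signature recoverable by positional scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import fetch_seq
from .gene_model import GeneModel
from .virtual_splicing import SpliceGraph

VARIANTS = ("F11", "Fmax", "F")


# ----------------------------------------------------------------------
# feasible signatures
# ----------------------------------------------------------------------

def enumerate_feasible_signatures(graph: SpliceGraph, l: int) -> set[tuple[int, ...]]:
    """All feasible signatures of one gene for read length ``l``.

    Enumeration is a bounded forward walk: once the running internal length
    exceeds l-2 no extension can become feasible, so every signature is local.
    """
    if l < 2:
        raise ValueError("read length must be >= 2")
    g = graph.gene
    lens = {s.index: s.length for s in g.subexons}
    feasible: set[tuple[int, ...]] = set()

    if graph.mode == "annotated":
        # exact path language: contiguous windows of annotated signatures
        for tsig in g.signatures.values():
            n = len(tsig)
            for a in range(n):
                total = 0
                for b in range(a, n):
                    total += lens[tsig[b]]
                    sig = tsig[a : b + 1]
                    internal = total - lens[sig[0]] - (lens[sig[-1]] if len(sig) > 1 else 0)
                    if len(sig) >= 3 and internal > l - 2:
                        break
                    if total >= l:
                        feasible.add(sig)
        return feasible

    for start in graph.nodes:
        stack = [(start,)]
        while stack:
            sig = stack.pop()
            total = sum(lens[i] for i in sig)
            if total >= l and graph.span_admissible(sig):
                feasible.add(sig)
            for nxt in graph.successors(sig[-1]):
                internal = sum(lens[i] for i in sig[1:])  # sig[-1] becomes internal
                if internal > l - 2:
                    continue
                stack.append(sig + (nxt,))
    return feasible


def maximal_signatures(signatures: set[tuple[int, ...]]) -> set[tuple[int, ...]]:
    """Signatures not contiguously contained in any other feasible signature."""

    def contains_contig(big, small):
        m = len(small)
        return any(big[k : k + m] == small for k in range(len(big) - m + 1))

    out = set()
    for sig in signatures:
        if not any(o != sig and contains_contig(o, sig) for o in signatures):
            out.add(sig)
    return out


# ----------------------------------------------------------------------
# fragments
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """A stretch of a fragment mapped back to the genome."""

    kind: str  # "sub" | "intron"
    index: int | None  # subexon index (None for intron pseudo-segments)
    frag_start: int
    frag_end: int
    gstart: int
    gend: int


@dataclass(frozen=True)
class Fragment:
    name: str
    gene_id: str
    seq: str
    segments: tuple[Segment, ...]
    signature: tuple[int, ...]  # defining signature (subexon indices only)

    def __post_init__(self):
        if len(self.seq) != self.segments[-1].frag_end:
            raise ValueError(f"fragment {self.name}: sequence/breakpoint mismatch")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.frag_end != b.frag_start:
                raise ValueError(f"fragment {self.name}: non-contiguous segments")

    @property
    def breakpoints(self) -> tuple[int, ...]:
        return tuple(s.frag_end for s in self.segments[:-1])

    def scan(self, offset: int, length: int) -> tuple[tuple[int, ...], tuple[tuple[int, int], ...]]:
        """Positional scan: subexon signature and intron intervals overlapped
        by a read placed at ``offset`` with ``length`` bases."""
        lo, hi = offset, offset + length
        subs, introns = [], []
        for s in self.segments:
            if s.frag_start < hi and lo < s.frag_end:
                if s.kind == "sub":
                    subs.append(s.index)
                else:
                    introns.append((s.gstart, s.gend))
        return tuple(subs), tuple(introns)


def make_fragment_name(gene_id: str, sig: tuple[int, ...], a: int, b: int) -> str:
    return f"{gene_id}|{','.join(map(str, sig))}|{a},{b}"


def parse_fragment_name(name: str) -> tuple[str, tuple[int, ...] | tuple[str, int, int], int, int]:
    gene, sig_s, ab = name.rsplit("|", 2)
    a, b = map(int, ab.split(","))
    if sig_s.startswith("~"):
        istart, iend = map(int, sig_s[1:].split("-"))
        return gene, ("intron", istart, iend), a, b
    return gene, tuple(map(int, sig_s.split(","))), a, b


def fragment_sequence(
    sig: tuple[int, ...],
    model: GeneModel,
    genome,
    l: int,
    first_len: int | None = None,
    last_len: int | None = None,
) -> Fragment:
    """Build the fragment for one feasible signature.

    With the defaults the minimal (F11) trimming is used: boundary inclusion
    b = l - L_int - 1.  ``first_len``/``last_len`` override the included
    lengths of the boundary subexons (full length for Fmax, l-1 for F).
    """
    subs = [model.subexon(i) for i in sig]
    if len(sig) == 1:
        first = last = subs[0].length
    else:
        l_int = sum(s.length for s in subs[1:-1])
        if len(sig) >= 3 and l_int > l - 2:
            raise ValueError(f"signature {sig} infeasible for read length {l}")
        b = l - l_int - 1
        first = min(subs[0].length, b if first_len is None else first_len)
        last = min(subs[-1].length, b if last_len is None else last_len)
        if sum(s.length for s in subs) < l:
            raise ValueError(f"signature {sig} infeasible for read length {l}")

    chrom = model.chrom
    segments: list[Segment] = []
    pieces: list[str] = []
    pos = 0
    for k, s in enumerate(subs):
        gs, ge = s.interval.start, s.interval.end
        if len(sig) > 1:
            if k == 0:
                gs = ge - first  # suffix of the first subexon
            if k == len(subs) - 1:
                ge = gs + last  # prefix of the last subexon
        seq = fetch_seq(genome, chrom, gs, ge)
        segments.append(Segment("sub", s.index, pos, pos + len(seq), gs, ge))
        pieces.append(seq)
        pos += len(seq)
    name = make_fragment_name(model.gene_id, sig, segments[0].frag_end - segments[0].frag_start,
                              segments[-1].frag_end - segments[-1].frag_start)
    return Fragment(name, model.gene_id, "".join(pieces), tuple(segments), sig)


def _intron_fragments(model: GeneModel, genome, l: int) -> list[Fragment]:
    """Per fully-intronic annotated intron: flank + intron + flank, the intron
    tracked as a pseudo-segment outside signature index space (used for
    conservative intron-retention evidence)."""
    from .events import _ir_candidate_introns

    out = []
    for i in _ir_candidate_introns(model):
        left = model.subexon_ending_at(i.start)
        right = model.subexon_starting_at(i.end)
        if left is None or right is None:
            continue
        ls, rs = model.subexon(left), model.subexon(right)
        a = min(ls.length, l - 1)
        b = min(rs.length, l - 1)
        chrom = model.chrom
        seq_l = fetch_seq(genome, chrom, ls.interval.end - a, ls.interval.end)
        seq_i = fetch_seq(genome, chrom, i.start, i.end)
        seq_r = fetch_seq(genome, chrom, i.end, i.end + b)
        segments = (
            Segment("sub", left, 0, a, ls.interval.end - a, ls.interval.end),
            Segment("intron", None, a, a + len(seq_i), i.start, i.end),
            Segment("sub", right, a + len(seq_i), a + len(seq_i) + b, i.end, i.end + b),
        )
        name = f"{model.gene_id}|~{i.start}-{i.end}|{a},{b}"
        out.append(Fragment(name, model.gene_id, seq_l + seq_i + seq_r, segments, (left, right)))
    return out


@dataclass
class FragmentSet:
    variant: str
    mode: str
    read_length: int
    fragments: list[Fragment] = field(default_factory=list)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    def __len__(self):
        return len(self.fragments)

    @property
    def total_nt(self) -> int:
        return sum(len(f.seq) for f in self.fragments)

    def sorted(self) -> "FragmentSet":
        self.fragments.sort(key=lambda f: f.name)
        return self


def build_F11(signatures: set[tuple[int, ...]], model: GeneModel, genome, l: int) -> list[Fragment]:
    return [fragment_sequence(sig, model, genome, l) for sig in sorted(signatures)]


def build_Fmax(signatures: set[tuple[int, ...]], model: GeneModel, genome, l: int) -> list[Fragment]:
    out = []
    for sig in sorted(maximal_signatures(signatures)):
        big = 10**9  # boundary subexons included in full
        out.append(fragment_sequence(sig, model, genome, l, first_len=big, last_len=big))
    return out


def build_F(
    signatures: set[tuple[int, ...]],
    model: GeneModel,
    genome,
    l: int,
    with_introns: bool = False,
) -> list[Fragment]:
    frags: dict[str, Fragment] = {}
    for sig in sorted(maximal_signatures(signatures)):
        if len(sig) == 1:
            continue  # all long-enough subexons become singletons below
        f = fragment_sequence(sig, model, genome, l, first_len=l - 1, last_len=l - 1)
        frags[f.name] = f
    for s in model.subexons:
        if s.length >= l:
            f = fragment_sequence((s.index,), model, genome, l)
            frags[f.name] = f
    if with_introns:
        for f in _intron_fragments(model, genome, l):
            frags[f.name] = f
    return [frags[k] for k in sorted(frags)]


def build_fragment_set(
    graphs: dict[str, SpliceGraph],
    genome,
    l: int,
    variant: str = "F",
    with_introns: bool = False,
) -> FragmentSet:
    """Build one fragment set over all genes."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    modes = {g.mode for g in graphs.values()} or {"as"}
    fs = FragmentSet(variant, modes.pop() if len(modes) == 1 else "mixed", l)
    for gid in sorted(graphs):
        graph = graphs[gid]
        sigs = enumerate_feasible_signatures(graph, l)
        if variant == "F11":
            fs.fragments.extend(build_F11(sigs, graph.gene, genome, l))
        elif variant == "Fmax":
            fs.fragments.extend(build_Fmax(sigs, graph.gene, genome, l))
        else:
            fs.fragments.extend(build_F(sigs, graph.gene, genome, l, with_introns))
    return fs.sorted()


# ----------------------------------------------------------------------
# exhaustive correctness/completeness verification (test-scale genes)
# ----------------------------------------------------------------------

def _explicit_paths(graph: SpliceGraph, max_paths: int = 50_000) -> list[tuple[int, ...]]:
    """Explicit virtual-transcript signatures: maximal paths of the graph
    (annotated mode: the annotated signatures themselves)."""
    if graph.mode == "annotated":
        return sorted(set(graph.gene.signatures.values()))
    edges = graph.edges()
    has_pred = {b for _, b in edges}
    sources = [n for n in graph.nodes if n not in has_pred]
    paths: list[tuple[int, ...]] = []
    stack = [(s,) for s in sources]
    while stack:
        p = stack.pop()
        succ = graph.successors(p[-1])
        if not succ:
            paths.append(p)
        else:
            for nx in succ:
                stack.append(p + (nx,))
        if len(paths) > max_paths:
            raise RuntimeError("path explosion; gene too large for exhaustive verification")
    return sorted(paths)


def verify_theorem1(fragset: FragmentSet, graph: SpliceGraph, genome, l: int) -> dict:
    """Exhaustively verify fragment-set correctness and completeness.

    correctness: every fragment's defining signature is a contiguous
    subsequence of some explicit (virtual) transcript signature.
    completeness: every length-l window over every explicit transcript occurs
    in some fragment at a position whose scan returns the window's true
    signature.  Returns a report dict with any violations.
    """
    g = graph.gene
    paths = _explicit_paths(graph)
    violations: list[dict] = []

    def contains_contig(big, small):
        m = len(small)
        return any(big[k : k + m] == small for k in range(len(big) - m + 1))

    gene_frags = [f for f in fragset.fragments
                  if f.gene_id == g.gene_id and all(s.kind == "sub" for s in f.segments)]
    for f in gene_frags:
        if not any(contains_contig(p, f.signature) for p in paths):
            violations.append({"kind": "correctness", "fragment": f.name})

    # index all l-mers of the gene's fragments with their scan signatures
    occ: dict[str, set[tuple[int, ...]]] = {}
    for f in gene_frags:
        for off in range(len(f.seq) - l + 1):
            subs, _ = f.scan(off, l)
            occ.setdefault(f.seq[off : off + l], set()).add(subs)

    lens = {s.index: s.length for s in g.subexons}
    seen_windows = set()
    for p in paths:
        seq = "".join(
            fetch_seq(genome, g.chrom, g.subexon(i).interval.start, g.subexon(i).interval.end)
            for i in p
        )
        # cumulative offsets of subexon boundaries along the path
        bounds = [0]
        for i in p:
            bounds.append(bounds[-1] + lens[i])
        for off in range(len(seq) - l + 1):
            lo, hi = off, off + l
            sig = tuple(p[k] for k in range(len(p)) if bounds[k] < hi and lo < bounds[k + 1])
            key = (seq[off : off + l], sig)
            if key in seen_windows:
                continue
            seen_windows.add(key)
            if not graph.span_admissible(sig):
                continue  # outside the virtual transcriptome's declared language
            if sig not in occ.get(seq[off : off + l], set()):
                violations.append({"kind": "completeness", "path": p, "window": (off, sig)})
    return {
        "gene_id": g.gene_id,
        "n_paths": len(paths),
        "n_fragments": len(gene_frags),
        "violations": violations,
        "ok": not violations,
    }


# ----------------------------------------------------------------------
# FASTA / sidecar I/O
# ----------------------------------------------------------------------

def write_fragments(fs: FragmentSet, fasta_path, tsv_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for f in fs.fragments:
            fh.write(f">{f.name}\n{f.seq}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("name\tgene_id\tsignature\tsegments\n")
            for f in fs.fragments:
                seg = ";".join(
                    f"{s.kind}:{'' if s.index is None else s.index}:"
                    f"{s.frag_start}:{s.frag_end}:{s.gstart}:{s.gend}"
                    for s in f.segments
                )
                sig = ",".join(map(str, f.signature))
                fh.write(f"{f.name}\t{f.gene_id}\t{sig}\t{seg}\n")


def read_fragments(fasta_path, tsv_path, variant: str, mode: str, l: int) -> FragmentSet:
    seqs: dict[str, str] = {}
    import pysam

    with pysam.FastxFile(str(fasta_path)) as fh:
        for rec in fh:
            seqs[rec.name] = rec.sequence
    fs = FragmentSet(variant, mode, l)
    with open(tsv_path) as fh:
        fh.readline()
        for line in fh:
            name, gid, sig_s, seg_s = line.rstrip("\n").split("\t")
            segments = []
            for part in seg_s.split(";"):
                kind, idx, fs_, fe, gs, ge = part.split(":")
                segments.append(
                    Segment(kind, int(idx) if idx else None, int(fs_), int(fe), int(gs), int(ge))
                )
            sig = tuple(int(x) for x in sig_s.split(",")) if sig_s else ()
            fs.fragments.append(Fragment(name, gid, seqs[name], tuple(segments), sig))
    return fs.sorted()
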