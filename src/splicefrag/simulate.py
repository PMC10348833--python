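"""Deterministic synthetic fixtures: genomes, annotations, truth-labeled reads.

Every other module is testable without downloads: this module generates
random multi-transcript genes (exon skipping and alternative-boundary
isoforms over a master exon chain), a random genome, and uniform-coverage
read libraries with per-read truth records (source transcript, genomic
blocks, true mapping signature, injected error positions).

Two named fixture genes reproduce the narrative gene structures used
throughout the documentation and tests:

* ``FIXG1`` — two annotated transcripts over five subexons, with a novel
  exon-skipping transcript (t3) and a novel-TSS transcript (t4) implied but
  unannotated;
* ``FIG3G`` — three transcripts over eight subexons exercising every event
  class (ES classical/nonclassical, AD, AA, AP, IE, IR).

In hold-out mode, exon-skipping transcripts are removed from the emitted
annotation (their junctions become novel but remain guessable from the
remaining transcripts' splice sites) while reads are still sampled from them.

The simulator is position-uniform over transcript windows with uniform
substitution errors only (no indels): the pseudoalignment engine has no
gapped model.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from ._util import revcomp
from .gene_model import GeneModel, GenomicInterval, Transcript

MIN_SIM_INTRON = 20


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_genes: int = 5
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (60, 200)
    intron_length: tuple[int, int] = (60, 300)
    transcripts_per_gene: tuple[int, int] = (2, 3)
    read_length: int = 100
    n_reads: int = 10_000
    error_rate: float = 0.0
    novel_fraction: float = 0.1
    hold_out_events: bool = False
    paired: bool = False
    insert_range: tuple[int, int] = (150, 400)
    # minimum terminal-block length of spliced reads: overhangs shorter than
    # ~10 nt can be sequence-ambiguous between junctions sharing flanking
    # bases, so exact-truth libraries sample identifiable reads only
    min_anchor: int = 10

    def __post_init__(self):
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "transcripts_per_gene", "insert_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: {(lo, hi)}")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if self.intron_length[0] < MIN_SIM_INTRON:
            raise ValueError(
                f"intron length range starts below the minimum intron length "
                f"({MIN_SIM_INTRON} nt); such introns cannot be spliced"
            )
        if self.read_length < 2:
            raise ValueError("read length must be >= 2")


@dataclass(frozen=True)
class SimRead:
    id: str
    seq: str
    gene_id: str
    transcript_id: str
    blocks: tuple[tuple[int, int], ...]  # genomic half-open blocks
    signature: tuple[int, ...]
    errors: tuple[int, ...]  # 0-based positions within the emitted read
    rc: bool
    mate: int = 0


# ----------------------------------------------------------------------
# named fixture genes
# ----------------------------------------------------------------------

def fixg1_transcripts(chrom: str = "chrFIXG1") -> list[Transcript]:
    """Two annotated transcripts partitioning their gene into 5 subexons.

    The implied-but-unannotated isoforms: t3 skips t2's middle exon (novel
    junction 200-700 joining s1 to s4) and t4 starts at a novel TSS and skips
    s3 (junction 400-700), combining annotated sites of t1.
    """

    def iv(a, b):
        return GenomicInterval(chrom, a, b, "+")

    t1 = Transcript("FIXG1.t1", "FIXG1", (iv(300, 400), iv(500, 600), iv(700, 900)))
    t2 = Transcript("FIXG1.t2", "FIXG1", (iv(100, 200), iv(500, 600), iv(700, 800)))
    return [t1, t2]


def fixg1_model() -> GeneModel:
    return GeneModel("FIXG1", fixg1_transcripts())


def fig3_transcripts(chrom: str = "chrFIG3") -> list[Transcript]:
    """Three transcripts over eight subexons exercising every event type.

    Boundaries: 100,180,260,340,420 | 500,580,660 | 740,820,900 giving
    subexons s1..s4, s5..s6, s7..s8; the intron 660-740 (between s6 and s7)
    is intronic in every transcript (intron-retention candidate).
    """

    def iv(a, b):
        return GenomicInterval(chrom, a, b, "+")

    t1 = Transcript("FIG3G.t1", "FIG3G",
                    (iv(100, 260), iv(340, 420), iv(500, 660), iv(820, 900)))
    t2 = Transcript("FIG3G.t2", "FIG3G",
                    (iv(100, 420), iv(500, 660), iv(740, 900)))
    t3 = Transcript("FIG3G.t3", "FIG3G",
                    (iv(100, 180), iv(500, 580), iv(740, 900)))
    return [t1, t2, t3]


def fig3_model() -> GeneModel:
    return GeneModel("FIG3G", fig3_transcripts())


def mirror_transcripts(transcripts: list[Transcript], length: int) -> list[Transcript]:
    """Reverse the coordinate axis and flip the strand (for symmetry tests)."""
    out = []
    for t in transcripts:
        strand = "-" if t.strand == "+" else "+"
        exons = tuple(
            GenomicInterval(e.chrom, length - e.end, length - e.start, strand)
            for e in reversed(t.exons)
        )
        out.append(Transcript(t.id, t.gene_id, exons))
    return out


# ----------------------------------------------------------------------
# random genes
# ----------------------------------------------------------------------

def random_gene(rng: random.Random, gene_id: str, chrom: str, spec: FixtureSpec,
                strand: str) -> tuple[list[Transcript], list[Transcript]]:
    """One random gene: (emitted transcripts, held-out skip transcripts)."""
    n_ex = rng.randint(*spec.exons_per_gene)
    pos = rng.randint(50, 150)
    exons = []
    for i in range(n_ex):
        ln = rng.randint(*spec.exon_length)
        exons.append((pos, pos + ln))
        pos += ln + rng.randint(*spec.intron_length)

    def iv(a, b):
        return GenomicInterval(chrom, a, b, strand)

    t_full = Transcript(f"{gene_id}.t1", gene_id, tuple(iv(a, b) for a, b in exons))
    emitted = [t_full]
    held_out: list[Transcript] = []

    n_tx = rng.randint(*spec.transcripts_per_gene)
    skippable = list(range(1, n_ex - 1))
    rng.shuffle(skippable)
    k_tx = 2
    while len(emitted) + len(held_out) < n_tx:
        op = rng.choice(["skip", "alt"])
        tid = f"{gene_id}.t{k_tx}"
        if op == "skip" and skippable:
            k = skippable.pop()
            ex = [e for j, e in enumerate(exons) if j != k]
            t = Transcript(tid, gene_id, tuple(iv(a, b) for a, b in ex))
            if spec.hold_out_events and not held_out:
                held_out.append(t)
            else:
                emitted.append(t)
        else:
            k = rng.randint(1, n_ex - 2) if n_ex > 2 else 0
            a, b = exons[k]
            if b - a < 40:
                k_tx += 1
                continue
            delta = rng.randint(8, min(30, b - a - 10))
            ex = list(exons)
            ex[k] = (a + delta, b) if rng.random() < 0.5 else (a, b - delta)
            t = Transcript(tid, gene_id, tuple(iv(x, y) for x, y in ex))
            if any(t.exons == o.exons for o in emitted):
                k_tx += 1
                continue
            emitted.append(t)
        k_tx += 1
        if k_tx > n_tx + 8:
            break
    return emitted, held_out


def random_genome(rng: random.Random, lengths: dict[str, int]) -> dict[str, str]:
    return {c: "".join(rng.choices("ACGT", k=n)) for c, n in lengths.items()}


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------

def oracle_signature(blocks, model: GeneModel) -> tuple[int, ...]:
    """True mapping signature: subexons overlapped by the read's genomic
    footprint (applied directly to the known origin)."""
    out = []
    for s in model.subexons:
        if any(s.interval.start < e and b < s.interval.end for b, e in blocks):
            out.append(s.index)
    return tuple(out)


def oracle_compatibility(blocks, transcripts) -> frozenset[str]:
    """Brute-force transcript compatibility of a read with known origin:
    every block lies within an exon and every block gap is exactly an
    annotated intron of the transcript."""
    ok_ids = set()
    for t in transcripts:
        introns = {(i.start, i.end) for i in t.introns}
        if all(any(e.start <= b and ee <= e.end for e in t.exons) for b, ee in blocks) and all(
            (a_end, b_start) in introns
            for (_, a_end), (b_start, _) in zip(blocks, blocks[1:])
        ):
            ok_ids.add(t.id)
    return frozenset(ok_ids)


# ----------------------------------------------------------------------
# fixture assembly
# ----------------------------------------------------------------------

@dataclass
class Fixture:
    spec: FixtureSpec
    genome: dict[str, str]
    models: dict[str, GeneModel]  # from the emitted (partial) annotation
    emitted: list[Transcript]
    held_out: list[Transcript]
    reads: list[SimRead] = field(default_factory=list)

    @property
    def virtual_transcripts(self) -> list[Transcript]:
        """Explicit transcripts beyond the emitted annotation (held-out)."""
        return list(self.held_out)

    def truth_histogram(self) -> dict[tuple[str, tuple[int, ...]], int]:
        hist: dict[tuple[str, tuple[int, ...]], int] = {}
        for r in self.reads:
            key = (r.gene_id, r.signature)
            hist[key] = hist.get(key, 0) + 1
        return hist

    def held_out_junctions(self) -> set[tuple[str, int, int]]:
        out = set()
        annotated = {
            (t.gene_id, i.start, i.end) for t in self.emitted for i in t.introns
        }
        for t in self.held_out:
            for i in t.introns:
                key = (t.gene_id, i.start, i.end)
                if key not in annotated:
                    out.add(key)
        return out


def _transcript_layout(t: Transcript):
    """(cumulative spliced offsets, exons) for window->blocks conversion."""
    offs = [0]
    for e in t.exons:
        offs.append(offs[-1] + e.length)
    return offs


def _window_blocks(t: Transcript, u: int, ln: int) -> tuple[tuple[int, int], ...]:
    offs = _transcript_layout(t)
    lo, hi = u, u + ln
    blocks = []
    for k, e in enumerate(t.exons):
        a, b = offs[k], offs[k + 1]
        if a < hi and lo < b:
            blocks.append((e.start + max(0, lo - a), e.start + min(e.length, hi - a)))
    return tuple(blocks)


def _spliced_seq(genome, t: Transcript) -> str:
    from ._util import fetch_seq

    return "".join(fetch_seq(genome, t.chrom, e.start, e.end) for e in t.exons)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a complete deterministic dataset from one seed.

    The named gene FIXG1 is always included alongside ``n_genes`` random
    genes, each on its own chromosome.
    """
    rng = random.Random(spec.seed)
    emitted: list[Transcript] = list(fixg1_transcripts())
    held_out: list[Transcript] = []
    lengths = {"chrFIXG1": 1000}
    for gi in range(spec.n_genes):
        gid = f"G{gi + 1:03d}"
        chrom = f"chr{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        em, ho = random_gene(rng, gid, chrom, spec, strand)
        emitted.extend(em)
        held_out.extend(ho)
        lengths[chrom] = max(t.tes for t in em + ho) + 100
    genome = random_genome(rng, lengths)

    by_gene: dict[str, list[Transcript]] = {}
    for t in emitted:
        by_gene.setdefault(t.gene_id, []).append(t)
    models = {gid: GeneModel(gid, txs) for gid, txs in by_gene.items()}

    fx = Fixture(spec, genome, models, emitted, held_out)

    pool = [t for t in emitted if t.spliced_length() >= spec.read_length]
    ho_pool = [t for t in held_out if t.spliced_length() >= spec.read_length]
    l = spec.read_length
    rid = 0
    n_units = spec.n_reads // 2 if spec.paired else spec.n_reads
    if not pool and n_units > 0:
        raise ValueError("no transcript long enough for the requested read length")
    for _ in range(n_units):
        if ho_pool and rng.random() < spec.novel_fraction:
            t = rng.choice(ho_pool)
        else:
            t = rng.choice(pool)
        model = models[t.gene_id]
        splen = t.spliced_length()
        tseq = _spliced_seq(genome, t)
        def anchored(u):
            blocks = _window_blocks(t, u, l)
            sig = oracle_signature(blocks, model)
            if len(sig) <= 1:
                return True
            ok = True
            for idx in (sig[0], sig[-1]):
                iv = model.subexon(idx).interval
                ov = sum(
                    max(0, min(e, iv.end) - max(b, iv.start)) for b, e in blocks
                )
                ok = ok and ov >= min(spec.min_anchor, iv.length)
            return ok

        if spec.paired:
            for _ in range(100):
                flen = min(splen, max(l, rng.randint(*spec.insert_range)))
                u = rng.randint(0, splen - flen)
                if anchored(u) and anchored(u + flen - l):
                    break
            windows = [(u, False), (u + flen - l, True)]
        else:
            for _ in range(100):
                u = rng.randint(0, splen - l)
                if anchored(u):
                    break
            windows = [(u, rng.random() < 0.5)]
        rid += 1
        for mate, (u, as_rc) in enumerate(windows, 1 if spec.paired else 0):
            blocks = _window_blocks(t, u, l)
            sig = oracle_signature(blocks, model)
            seq = tseq[u : u + l]
            if as_rc:
                seq = revcomp(seq)
            errs = []
            chars = list(seq)
            for p in range(l):
                if spec.error_rate > 0 and rng.random() < spec.error_rate:
                    chars[p] = rng.choice([c for c in "ACGT" if c != chars[p]])
                    errs.append(p)
            name = f"r{rid:07d}" + (f"/{mate}" if spec.paired else "")
            fx.reads.append(
                SimRead(name, "".join(chars), t.gene_id, t.id, blocks, sig,
                        tuple(errs), as_rc, mate)
            )
    return fx


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path, seed: int | None = None) -> None:
    tag = f" seed={seed}" if seed is not None else ""
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}{tag}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_gtf(transcripts: list[Transcript], path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#!splicefrag-simulate seed={seed}\n")
        by_gene: dict[str, list[Transcript]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gid in sorted(by_gene):
            txs = sorted(by_gene[gid], key=lambda t: t.id)
            g_lo = min(t.tss for t in txs) + 1
            g_hi = max(t.tes for t in txs)
            chrom, strand = txs[0].chrom, txs[0].strand
            fh.write(
                f'{chrom}\tsim\tgene\t{g_lo}\t{g_hi}\t.\t{strand}\t.\tgene_id "{gid}";\n'
            )
            for t in txs:
                fh.write(
                    f'{chrom}\tsim\ttranscript\t{t.tss + 1}\t{t.tes}\t.\t{strand}\t.\t'
                    f'gene_id "{gid}"; transcript_id "{t.id}";\n'
                )
                for e in t.exons:
                    fh.write(
                        f'{chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t'
                        f'gene_id "{gid}"; transcript_id "{t.id}";\n'
                    )


def write_fastq(reads: list[SimRead], path, mate: int | None = None) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if mate is not None and r.mate != mate:
                continue
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgene_id\ttranscript_id\tblocks\tsignature\terrors\trc\n")
        for r in reads:
            blocks = ",".join(f"{a}-{b}" for a, b in r.blocks)
            sig = ",".join(map(str, r.signature))
            errs = ",".join(map(str, r.errors))
            fh.write(f"{r.id}\t{r.gene_id}\t{r.transcript_id}\t{blocks}\t{sig}\t{errs}\t{int(r.rc)}\n")


def write_virtual_list(transcripts: list[Transcript], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\texons\n")
        for t in sorted(transcripts, key=lambda t: (t.gene_id, t.id)):
            exons = ",".join(f"{e.start}-{e.end}" for e in t.exons)
            fh.write(f"{t.gene_id}\t{t.id}\t{exons}\n")


def write_fixture(fx: Fixture, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "truth": outdir / "truth.tsv",
        "virtual": outdir / "virtual_transcripts.tsv",
    }
    write_fasta(fx.genome, paths["fasta"], fx.spec.seed)
    write_gtf(fx.emitted, paths["gtf"], fx.spec.seed)
    write_truth(fx.reads, paths["truth"])
    write_virtual_list(fx.virtual_transcripts, paths["virtual"])
    if fx.spec.paired:
        paths["fastq1"] = outdir / "reads_1.fastq"
        paths["fastq2"] = outdir / "reads_2.fastq"
        write_fastq(fx.reads, paths["fastq1"], mate=1)
        write_fastq(fx.reads, paths["fastq2"], mate=2)
    else:
        paths["fastq"] = outdir / "reads.fastq"
        write_fastq(fx.reads, paths["fastq"])
    return paths
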