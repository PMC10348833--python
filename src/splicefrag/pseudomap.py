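"""k-mer pseudoalignment of reads to transcript fragments.

Reads are placed on fragments by offset voting: every k-mer of the read that
occurs in the fragment index casts a vote for an implied (fragment, offset,
orientation) placement; the placement with maximal support wins and the
read's mapping signature is recovered by a positional scan through the
fragment's subexon breakpoints.  Offset voting tolerates mismatches without
base-level alignment: a read is placed correctly as long as at least one
intact k-mer survives on one side of each mismatch.

Canonical k-mers are indexed so that libraries of either strandedness map;
the read orientation is recovered from the majority vote.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._util import revcomp
from .fragments import Fragment, FragmentSet

DEFAULT_K = 31


# ----------------------------------------------------------------------
# index
# ----------------------------------------------------------------------

@dataclass
class KmerIndex:
    k: int
    read_length: int
    fragments: list[Fragment]
    # canonical k-mer -> list of (fragment idx, offset, kmer-was-forward)
    postings: dict[str, list[tuple[int, int, bool]]] = field(default_factory=dict)


def default_k(l: int, k: int = DEFAULT_K) -> int:
    """k clamped to at most l-1 (a read must contain at least one k-mer)."""
    return min(k, l - 1)


def build_kmer_index(fragset: FragmentSet, k: int | None = None) -> KmerIndex:
    l = fragset.read_length
    if k is None:
        k = default_k(l)
    if k >= l:
        raise ValueError(f"k ({k}) must be smaller than the read length ({l})")
    if k < 1:
        raise ValueError("k must be positive")
    idx = KmerIndex(k, l, list(fragset.fragments))
    for fi, frag in enumerate(idx.fragments):
        seq = frag.seq
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            rc = revcomp(kmer)
            canon, fwd = (kmer, True) if kmer <= rc else (rc, False)
            idx.postings.setdefault(canon, []).append((fi, off, fwd))
    return idx


# ----------------------------------------------------------------------
# per-read mapping
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ReadHit:
    frag_idx: int
    frag_name: str
    offset: int
    orient: str  # "fwd" | "rc"  (orientation of the read on the fragment)
    support: int
    matchlen: int  # exact-matching bases at the placement


@dataclass(frozen=True)
class MapResult:
    status: str  # mapped | unmapped | ambiguous
    gene_id: str | None = None
    signature: tuple[int, ...] | None = None
    introns: tuple[tuple[int, int], ...] = ()
    hit: ReadHit | None = None


UNMAPPED = MapResult("unmapped")
AMBIGUOUS = MapResult("ambiguous")


def select_primary(hits: list[ReadHit]) -> ReadHit:
    """Deterministic primary hit: maximal k-mer support, then maximal exact-
    match length, then lowest fragment id."""
    if not hits:
        raise ValueError("select_primary requires at least one hit")
    return sorted(hits, key=lambda h: (-h.support, -h.matchlen, h.frag_name, h.offset))[0]


def _vote(read: str, index: KmerIndex) -> tuple[Counter, int]:
    """Offset votes plus the number of read k-mer positions found in the
    index at all (missing k-mers — mismatch- or novel-junction-affected —
    are skipped, as in pseudoalignment)."""
    k = index.k
    votes: Counter = Counter()
    lr = len(read)
    found = 0
    for pos in range(lr - k + 1):
        kmer = read[pos : pos + k]
        rc = revcomp(kmer)
        canon, read_fwd = (kmer, True) if kmer <= rc else (rc, False)
        palindromic = kmer == rc
        postings = index.postings.get(canon, ())
        if postings:
            found += 1
        for fi, off, frag_fwd in postings:
            same = frag_fwd == read_fwd
            if same or palindromic:
                votes[(fi, off - pos, "fwd")] += 1
            if (not same) or palindromic:
                votes[(fi, off - (lr - k - pos), "rc")] += 1
    return votes, found


def map_read(
    read: str,
    index: KmerIndex,
    max_n_frac: float = 0.5,
    verify_hamming: int | str | None = "auto",
) -> MapResult:
    """Map one read; returns its signature or an unmapped/ambiguous status.

    Reads shorter than the indexed read length are mapped if they contain at
    least one k-mer; longer reads are rejected (the fragment set is specific
    to the read length it was built for).  ``verify_hamming`` caps the
    mismatches tolerated at the winning placement: ``"auto"`` allows 5% of
    the read length, an integer sets the cap explicitly, ``None`` disables
    verification.
    """
    read = read.upper()
    lr = len(read)
    if lr > index.read_length:
        raise ValueError(
            f"read of length {lr} exceeds the indexed read length "
            f"{index.read_length}; rebuild the index with --read-length {lr}"
        )
    if lr < index.k:
        return UNMAPPED
    if read.count("N") > max_n_frac * lr:
        return UNMAPPED

    votes, _ = _vote(read, index)
    if not votes:
        return UNMAPPED

    # keep placements that fit inside the fragment
    valid = {
        key: n
        for key, n in votes.items()
        if 0 <= key[1] <= len(index.fragments[key[0]].seq) - lr
    }
    if not valid:
        return UNMAPPED
    best = max(valid.values())
    # one substitution moves at most k votes, so the true placement is never
    # more than k votes behind a spurious leader: keep all close candidates
    candidates = [(key, n) for key, n in valid.items() if n >= best - index.k]

    # placement verification: a candidate placement must explain the read up
    # to a small number of mismatches.  Reads whose every placement leaves a
    # long unexplained stretch — e.g. reads spanning a splice site absent
    # from the index — stay unmapped and are handed to the refine phase.
    if verify_hamming == "auto":
        max_mm = max(1, round(0.05 * lr))
    else:
        max_mm = verify_hamming  # explicit integer, or None to disable

    hits: list[ReadHit] = []
    for (fi, off, orient), n in candidates:
        frag = index.fragments[fi]
        oriented = read if orient == "fwd" else revcomp(read)
        window = frag.seq[off : off + lr]
        matchlen = sum(a == b for a, b in zip(oriented, window))
        if max_mm is not None and lr - matchlen > max_mm:
            continue
        hits.append(ReadHit(fi, frag.name, off, orient, n, matchlen))
    if not hits:
        return UNMAPPED

    top = max((h.support, h.matchlen) for h in hits)
    hits = [h for h in hits if (h.support, h.matchlen) == top]

    outcomes = set()
    for h in hits:
        frag = index.fragments[h.frag_idx]
        subs, introns = frag.scan(h.offset, lr)
        outcomes.add((frag.gene_id, subs, introns))
    if len(outcomes) > 1:
        return AMBIGUOUS
    gene_id, subs, introns = outcomes.pop()
    return MapResult("mapped", gene_id, subs, introns, select_primary(hits))


# ----------------------------------------------------------------------
# counting
# ----------------------------------------------------------------------

@dataclass
class SignatureCountTable:
    """Counts of reads per mapping signature per gene.

    ``counts`` holds exonic signatures; reads overlapping intron
    pseudo-segments (intron-retention evidence) are tallied separately in
    ``intron_cov`` keyed by (gene, intron interval).
    """

    counts: dict[tuple[str, tuple[int, ...]], int] = field(default_factory=dict)
    intron_cov: dict[tuple[str, tuple[int, int]], int] = field(default_factory=dict)
    pair_counts: dict = field(default_factory=dict)
    mapped: int = 0
    unmapped: int = 0
    ambiguous: int = 0

    def add_result(self, res: MapResult) -> None:
        if res.status == "unmapped":
            self.unmapped += 1
        elif res.status == "ambiguous":
            self.ambiguous += 1
        else:
            self.mapped += 1
            if res.introns:
                for iv in res.introns:
                    key = (res.gene_id, iv)
                    self.intron_cov[key] = self.intron_cov.get(key, 0) + 1
            elif res.signature:
                key = (res.gene_id, res.signature)
                self.counts[key] = self.counts.get(key, 0) + 1

    @property
    def total_reads(self) -> int:
        return self.mapped + self.unmapped + self.ambiguous

    @property
    def total_counts(self) -> int:
        return sum(self.counts.values())

    def merge(self, other: "SignatureCountTable") -> None:
        for k, n in other.counts.items():
            self.counts[k] = self.counts.get(k, 0) + n
        for k, n in other.intron_cov.items():
            self.intron_cov[k] = self.intron_cov.get(k, 0) + n
        for k, n in other.pair_counts.items():
            self.pair_counts[k] = self.pair_counts.get(k, 0) + n
        self.mapped += other.mapped
        self.unmapped += other.unmapped
        self.ambiguous += other.ambiguous

    def summary(self) -> dict:
        return {
            "mapped": self.mapped,
            "unmapped": self.unmapped,
            "ambiguous": self.ambiguous,
            "signature_classes": len(self.counts),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tsignature\tcount\n")
            for (gid, sig), n in sorted(self.counts.items()):
                fh.write(f"{gid}\t{','.join(map(str, sig))}\t{n}\n")
            for (gid, (a, b)), n in sorted(self.intron_cov.items()):
                fh.write(f"{gid}\t~{a}-{b}\t{n}\n")

    @classmethod
    def read(cls, path) -> "SignatureCountTable":
        t = cls()
        with open(path) as fh:
            fh.readline()
            for line in fh:
                gid, sig_s, n = line.rstrip("\n").split("\t")
                if sig_s.startswith("~"):
                    a, b = map(int, sig_s[1:].split("-"))
                    t.intron_cov[(gid, (a, b))] = int(n)
                else:
                    sig = tuple(int(x) for x in sig_s.split(","))
                    t.counts[(gid, sig)] = int(n)
        t.mapped = sum(t.counts.values()) + sum(t.intron_cov.values())
        return t


def _fastq_records(path):
    if isinstance(path, (list, tuple)):  # in-memory (name, seq) records
        yield from path
        return
    import pysam

    n = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                n += 1
                if rec.sequence is None:
                    raise ValueError(f"truncated FASTQ record {n} in {path}")
                yield rec.name, rec.sequence
    except OSError as exc:
        raise ValueError(f"error reading {path} near record {n + 1}: {exc}") from exc


def count_reads(
    fastq1,
    index: KmerIndex,
    fastq2=None,
    pair_signatures: bool = False,
    threads: int = 1,
    max_n_frac: float = 0.5,
    verify_hamming: int | str | None = "auto",
    unmapped_out: list | None = None,
) -> SignatureCountTable:
    """Count reads by mapping signature.

    Paired-end mates are mapped independently and each increments the table
    (sum-over-ends); with ``pair_signatures`` the ordered signature pair is
    additionally tallied.  ``threads`` is accepted for interface parity; read
    mapping is independent per read and results are merged in deterministic
    order, so output is identical for any thread count.  When
    ``unmapped_out`` is a list, (name, sequence) of unmapped reads are
    appended to it (input to the refine phase).
    """
    del threads  # per-read mapping is pure; serial evaluation is already deterministic
    table = SignatureCountTable()

    def one(name, seq):
        res = map_read(seq, index, max_n_frac=max_n_frac, verify_hamming=verify_hamming)
        table.add_result(res)
        if res.status == "unmapped" and unmapped_out is not None:
            unmapped_out.append((name, seq))
        return res

    if fastq2 is None:
        for name, seq in _fastq_records(fastq1):
            one(name, seq)
        return table

    it1, it2 = _fastq_records(fastq1), _fastq_records(fastq2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        if r1 is None or r2 is None:
            raise ValueError(f"paired FASTQ files desynchronized after {n} pairs")
        n += 1
        res1, res2 = one(*r1), one(*r2)
        if pair_signatures:
            key = (
                (res1.gene_id, res1.signature) if res1.status == "mapped" else None,
                (res2.gene_id, res2.signature) if res2.status == "mapped" else None,
            )
            table.pair_counts[key] = table.pair_counts.get(key, 0) + 1
    return table
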