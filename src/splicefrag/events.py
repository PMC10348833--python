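"""Classification of novel introns into alternative-splicing event types.

Each novel intron implied by a mapping signature is compared pairwise to
every annotated transcript of its gene and typed as one of:

* ``ES``  (multi-)exon skipping: >=1 complete exon of t lies inside the intron.
          *classical* when the intron endpoints equal the boundaries of the
          t-introns immediately flanking the skipped exon run.
* ``AD``  alternative donor: the acceptor matches an intron of t, the donor
          does not (and no complete exon of t is skipped).
* ``AA``  alternative acceptor: mirror of AD.
* ``AP``  alternative donor-acceptor pair: the intron overlaps an intron of t
          but matches neither of its endpoints.
* ``IE``  novel intron in exon (exitron): the intron lies strictly inside one
          exon of t.
* ``IR``  intron retention: unspliced coverage of a region intronic in every
          transcript, with no splicing observed inside it (gene-level call).
* ``UNK`` anything else.

The same intron can imply different types with respect to different
transcripts; one record is produced per (junction, transcript) pair.
Precedence when rules overlap is IE, then ES, then AD/AA, then AP.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gene_model import GeneModel, GenomicInterval, Transcript

EVENT_TYPES = ("ES", "AD", "AA", "AP", "IE", "IR", "UNK")


@dataclass(frozen=True)
class EventAnnotation:
    gene_id: str
    chrom: str
    donor: int
    acceptor: int
    strand: str
    transcript_id: str
    type: str
    classical: bool
    skipped_exons: int
    supporting_count: int

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type}")


def classify_intron(junction, t: Transcript) -> tuple[str, bool, int]:
    """Type a novel intron against one annotated transcript.

    ``junction`` needs ``start``/``end`` attributes (half-open genomic intron
    interval) and a strand consistent with ``t``.  Returns
    ``(type, classical, n_skipped_exons)``; ``classical`` is meaningful for
    ES only.  Raises if the intron is annotated in ``t``.
    """
    js, je = junction.start, junction.end
    introns = t.introns
    if any(i.start == js and i.end == je for i in introns):
        raise ValueError(f"intron {js}-{je} is annotated in transcript {t.id}")

    # IE: strictly inside one exon
    for e in t.exons:
        if e.start < js and je < e.end:
            return "IE", False, 0

    # ES: >=1 complete exon inside the intron
    skipped = [e for e in t.exons if js <= e.start and e.end <= je]
    if skipped:
        first, last = skipped[0], skipped[-1]
        prev = next((i for i in introns if i.end == first.start), None)
        nxt = next((i for i in introns if i.start == last.end), None)
        classical = (
            prev is not None and prev.start == js and nxt is not None and nxt.end == je
        )
        return "ES", classical, len(skipped)

    matches_left = any(i.start == js for i in introns)
    matches_right = any(i.end == je for i in introns)
    # donor is the left intron boundary on '+', the right one on '-'
    if t.strand == "-":
        donor_matches, acceptor_matches = matches_right, matches_left
    else:
        donor_matches, acceptor_matches = matches_left, matches_right
    if acceptor_matches and not donor_matches:
        return "AD", False, 0
    if donor_matches and not acceptor_matches:
        return "AA", False, 0

    if any(i.start < je and js < i.end for i in introns):
        return "AP", False, 0
    return "UNK", False, 0


def _observed_junction_counts(sig_counts, model: GeneModel) -> dict[tuple[int, int], int]:
    """Spliced-gap evidence: intron interval -> summed signature count."""
    out: dict[tuple[int, int], int] = {}
    for (gid, sig), n in sig_counts.items():
        if gid != model.gene_id:
            continue
        for a, b in zip(sig, sig[1:]):
            left = model.subexon(a).interval.end
            right = model.subexon(b).interval.start
            if left < right:  # non-adjacent: a spliced junction was crossed
                out[(left, right)] = out.get((left, right), 0) + n
    return out


def _ir_candidate_introns(model: GeneModel) -> list[GenomicInterval]:
    """Annotated introns that overlap no exon of any transcript of the gene."""
    exons = [e for t in model.transcripts for e in t.exons]
    cands = []
    seen = set()
    for t in model.transcripts:
        for i in t.introns:
            key = (i.start, i.end)
            if key in seen:
                continue
            seen.add(key)
            if not any(e.start < i.end and i.start < e.end for e in exons):
                cands.append(i)
    return sorted(cands, key=lambda i: i.start)


def detect_intron_retention(table, model: GeneModel, min_reads: int = 1) -> list[EventAnnotation]:
    """Conservative intron-retention calls for one gene.

    An intron I is reported IR iff (a) I is intronic in every transcript,
    (b) >= ``min_reads`` reads map contiguously across an exon-intron boundary
    of I or within I, and (c) no junction with an endpoint strictly inside I
    has nonzero count.
    """
    junc = _observed_junction_counts(table.counts, model)
    out = []
    for i in _ir_candidate_introns(model):
        cov = table.intron_cov.get((model.gene_id, (i.start, i.end)), 0)
        if cov < min_reads:
            continue
        spliced_inside = any(
            (i.start < a < i.end) or (i.start < b < i.end)
            for (a, b), n in junc.items()
            if n > 0
        )
        if spliced_inside:
            continue
        out.append(
            EventAnnotation(
                model.gene_id, model.chrom, i.start, i.end, model.strand,
                transcript_id="*", type="IR", classical=False,
                skipped_exons=0, supporting_count=cov,
            )
        )
    return out


def annotate_events(table, models: dict[str, GeneModel], min_reads: int = 1) -> list[EventAnnotation]:
    """Classify every novel junction observed in a signature-count table.

    Each signature containing a novel (unannotated) spliced gap contributes
    its count to that junction; one record is emitted per (junction,
    transcript) pair over all transcripts overlapping the junction span.
    Intron-retention calls are appended per gene.
    """
    out: list[EventAnnotation] = []
    for gid, model in models.items():
        annotated = model.annotated_introns
        junc = _observed_junction_counts(table.counts, model)
        for (a, b), n in sorted(junc.items()):
            if (a, b) in annotated or n < min_reads:
                continue
            overlapping = model.transcripts_overlapping(a, b)
            if not overlapping:
                continue
            jiv = GenomicInterval(model.chrom, a, b, model.strand)
            # donor is the left intron boundary on '+', the right one on '-'
            d, acc = (a, b) if model.strand != "-" else (b, a)
            for t in sorted(overlapping, key=lambda t: t.id):
                if any(i.start == a and i.end == b for i in t.introns):
                    continue  # annotated in t itself (possible for multi-gene input)
                typ, classical, nskip = classify_intron(jiv, t)
                out.append(
                    EventAnnotation(
                        gid, model.chrom, d, acc, model.strand, t.id,
                        typ, classical, nskip, n,
                    )
                )
        out.extend(detect_intron_retention(table, model, min_reads=min_reads))
    return out


def write_events(events: list[EventAnnotation], path) -> None:
    import pandas as pd

    rows = [e.__dict__ for e in events]
    cols = [
        "gene_id", "chrom", "donor", "acceptor", "strand", "transcript_id",
        "type", "classical", "skipped_exons", "supporting_count",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
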