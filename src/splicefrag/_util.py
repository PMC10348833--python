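"""Small shared helpers: sequence access and reverse complement."""

from __future__ import annotations

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_RC)[::-1]


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) as an uppercase string.

    ``genome`` may be a plain dict of strings, a ``pyfaidx.Fasta`` or any
    mapping whose values support slicing.  Raises ``KeyError`` naming the
    chromosome when it is absent.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} missing from genome sequence")
    piece = genome[chrom][start:end]
    seq = piece if isinstance(piece, str) else str(piece)
    if len(seq) < end - start:
        raise ValueError(
            f"requested {chrom}:{start}-{end} but sequence has only "
            f"{len(genome[chrom])} bases"
        )
    return seq.upper()
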