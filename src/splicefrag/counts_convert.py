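"""Conversions of signature counts to other counting schemes.

Signature counts are the most refined read summary over a gene's subexons;
every scheme below is a many-to-one aggregation of them, computed without
revisiting reads:

* transcript-compatibility counts (TCCs): the compatible-transcript set of a
  signature ı is  ∩_{i∈ı} t(s_i) ∖ ∪_{i∈ı̄} t(s_i),  where t(s) is the set of
  transcripts containing subexon s and ı̄ the indices strictly between
  min(ı) and max(ı) that are absent from ı.  Signatures with an empty result
  (novel splicing patterns) are kept under a reserved NOVEL key so that count
  totals are conserved.
* per-subexon counts (exon-bin style): every signature containing s adds its
  count to s.
* merged bins: signatures with overlapping genomic spans and identical
  compatible-transcript sets are merged (union-find closure).
* splicing-graph counts: per-subexon node counts plus edge counts for every
  adjacency or junction crossed by a signature.
"""

from __future__ import annotations

from .gene_model import GeneModel
from .pseudomap import SignatureCountTable

NOVEL = "<NOVEL>"


def compatible_transcripts(sig: tuple[int, ...], model: GeneModel) -> frozenset[str]:
    """TCC set expression for one signature."""
    for i in sig:
        if not 1 <= i <= model.n_subexons:
            raise KeyError(f"unknown subexon index {i} for gene {model.gene_id}")
    inter: frozenset[str] = model.t_of(sig[0])
    for i in sig[1:]:
        inter &= model.t_of(i)
    gaps = [i for i in range(sig[0] + 1, sig[-1]) if i not in set(sig)]
    excl: set[str] = set()
    for i in gaps:
        excl |= model.t_of(i)
    return frozenset(inter - excl)


def to_tcc(table: SignatureCountTable, models: dict[str, GeneModel]) -> dict:
    """Aggregate to transcript-compatibility counts.

    Returns ``{(gene_id, sorted transcript-id tuple or NOVEL): count}``.
    """
    out: dict[tuple[str, tuple | str], int] = {}
    for (gid, sig), n in table.counts.items():
        model = models[gid]
        ts = compatible_transcripts(sig, model)
        key = (gid, tuple(sorted(ts)) if ts else NOVEL)
        out[key] = out.get(key, 0) + n
    return out


def to_subexon_counts(table: SignatureCountTable) -> dict[tuple[str, int], int]:
    """count(s) = sum of counts of all signatures containing s."""
    out: dict[tuple[str, int], int] = {}
    for (gid, sig), n in table.counts.items():
        for i in sig:
            out[(gid, i)] = out.get((gid, i), 0) + n
    return out


def _span(sig: tuple[int, ...], model: GeneModel) -> tuple[int, int]:
    return (model.subexon(sig[0]).interval.start, model.subexon(sig[-1]).interval.end)


def to_merged_bins(table: SignatureCountTable, models: dict[str, GeneModel]) -> dict:
    """Merge overlapping signatures compatible with the same transcript set.

    Returns ``{(gene_id, tuple of member signatures): count}``; merging is the
    transitive closure of pairwise genomic-span overlap with equal TCC sets.
    """
    by_gene: dict[str, list[tuple[int, ...]]] = {}
    for gid, sig in table.counts:
        by_gene.setdefault(gid, []).append(sig)

    out: dict[tuple[str, tuple], int] = {}
    for gid, sigs in by_gene.items():
        model = models[gid]
        sigs = sorted(set(sigs))
        parent = list(range(len(sigs)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        spans = [_span(s, model) for s in sigs]
        tccs = [compatible_transcripts(s, model) for s in sigs]
        for a in range(len(sigs)):
            for b in range(a + 1, len(sigs)):
                if tccs[a] == tccs[b] and spans[a][0] < spans[b][1] and spans[b][0] < spans[a][1]:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
        groups: dict[int, list[int]] = {}
        for i in range(len(sigs)):
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            key = (gid, tuple(sigs[i] for i in sorted(members)))
            out[key] = sum(table.counts[(gid, sigs[i])] for i in members)
    return out


def to_graph_counts(table: SignatureCountTable, models: dict[str, GeneModel]) -> dict:
    """Splicing-graph node and edge counts.

    Returns ``{"nodes": {(gene, subexon): n}, "edges": {(gene, (i, j), kind): n}}``
    where kind is ``"adj"`` for read-through adjacencies and ``"jct"`` for
    spliced junctions.
    """
    nodes = to_subexon_counts(table)
    edges: dict[tuple[str, tuple[int, int], str], int] = {}
    for (gid, sig), n in table.counts.items():
        model = models[gid]
        for a, b in zip(sig, sig[1:]):
            adjacent = model.subexon(a).interval.end == model.subexon(b).interval.start
            kind = "adj" if adjacent else "jct"
            key = (gid, (a, b), kind)
            edges[key] = edges.get(key, 0) + n
    return {"nodes": nodes, "edges": edges}


# ----------------------------------------------------------------------
# TSV writers
# ----------------------------------------------------------------------

def write_tcc(tcc: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscripts\tcount\n")
        for (gid, key), n in sorted(tcc.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
            label = key if isinstance(key, str) else ",".join(key)
            fh.write(f"{gid}\t{label}\t{n}\n")


def write_dexseq_counts(sub: dict[tuple[str, int], int], path) -> None:
    """Flattened exon-bin counts: one ``gene:Exxx`` bin per subexon."""
    with open(path, "w") as fh:
        for (gid, i), n in sorted(sub.items()):
            fh.write(f"{gid}:E{i:03d}\t{n}\n")


def write_graph_counts(gc: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\telement\tkind\tcount\n")
        for (gid, i), n in sorted(gc["nodes"].items()):
            fh.write(f"{gid}\ts{i}\tnode\t{n}\n")
        for (gid, (a, b), kind), n in sorted(gc["edges"].items()):
            fh.write(f"{gid}\ts{a}-s{b}\t{kind}\t{n}\n")
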