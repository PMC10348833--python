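"""Partition a two-isoform gene into subexons and read off mapping signatures.

The smallest exonic units bounded by splice sites or transcript start/end
sites (subexons) are the atoms of all downstream counting: a read's mapping
signature is the increasing sequence of subexon indices it overlaps.
"""

from splicefrag.simulate import fixg1_model

model = fixg1_model()

print(f"gene {model.gene_id} ({model.strand} strand), "
      f"{len(model.transcripts)} transcripts -> {model.n_subexons} subexons\n")
for s in model.subexons:
    members = ",".join(sorted(s.containing_transcripts))
    print(f"  s{s.index}: {s.interval.start}-{s.interval.end} ({s.length} nt)  in {members}")

print("\ntranscript signatures (subexon index chains):")
for tid, sig in sorted(model.signatures.items()):
    print(f"  {tid}: {sig}")

print("""
Each subexon boundary is a splice site or a transcript start/end; a read
overlapping, say, the 3' half of s3 and the start of s4 has signature (3,4),
and two reads are equivalent exactly when their signatures agree.""")
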