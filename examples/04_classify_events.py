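"""Classify novel introns into alternative-splicing event types.

Every novel intron implied by a counted signature is compared pairwise to
each annotated transcript: exon skipping (classical or not), alternative
donor/acceptor/pair, intron-in-exon (exitron), intron retention, or unknown.
The same intron can imply different types against different transcripts.
"""

from splicefrag.events import classify_intron, detect_intron_retention
from splicefrag.gene_model import GenomicInterval
from splicefrag.pseudomap import SignatureCountTable
from splicefrag.simulate import fig3_model

model = fig3_model()
tx = {t.id.split(".")[-1]: t for t in model.transcripts}
print(f"{model.gene_id}: {model.n_subexons} subexons from 3 transcripts")


def j(a, b):
    return GenomicInterval(model.chrom, a, b, "+")


cases = [
    ("s1->s7 (skip)", 180, 740, ["t2", "t3"]),
    ("s3->s5", 340, 500, ["t2"]),
    ("s4->s6", 420, 580, ["t2"]),
    ("s5->s8", 580, 820, ["t2", "t3"]),
    ("s1->s3 (in-exon)", 180, 260, ["t2"]),
]
for label, a, b, others in cases:
    for o in others:
        typ, classical, nskip = classify_intron(j(a, b), tx[o])
        extra = " classical" if typ == "ES" and classical else ""
        extra += f" ({nskip} exon skipped)" if typ == "ES" else ""
        print(f"  {label:18s} vs {o}: {typ}{extra}")

table = SignatureCountTable()
table.intron_cov = {("FIG3G", (660, 740)): 12}  # unspliced coverage of the intron
for call in detect_intron_retention(table, model):
    print(f"  intron {call.donor}-{call.acceptor}: {call.type} "
          f"({call.supporting_count} supporting reads)")

print("""
The same novel intron 580-820 is an alternative donor-acceptor pair with
respect to one transcript but a plain alternative acceptor with respect to
another - event types are transcript-relative by construction.""")
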