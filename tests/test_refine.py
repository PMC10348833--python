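"""SJ parsing, subexon re-partition, count remapping, requantification."""

import random

import pytest

from splicefrag.fragments import build_fragment_set
from splicefrag.gene_model import GeneModel, Transcript
from splicefrag.pseudomap import build_kmer_index, count_reads
from splicefrag.refine import (
    JunctionRecord,
    incorporate_novel_sites,
    parse_sj,
    refine_counts,
    remap_counts,
    remap_signature,
    write_sj,
)
from splicefrag.virtual_splicing import build_splice_graph

from conftest import iv, random_genome


@pytest.fixture()
def novel_acceptor_setup():
    """One gene; a novel acceptor at 600 inside the middle exon creates the
    unannotated junction 300-600; deep-anchored reads across it."""
    rng = random.Random(7)
    t1 = Transcript("R.t1", "R", (iv(100, 300, "chrR"), iv(500, 800, "chrR"),
                                  iv(1000, 1200, "chrR")))
    model = GeneModel("R", [t1])
    genome = random_genome(77, {"chrR": 1400})
    l = 100
    novel, annotated = [], []
    for i in range(30):
        o = rng.randint(36, 64)
        seq = genome["chrR"][300 - o : 300] + genome["chrR"][600 : 600 + (l - o)]
        novel.append((f"n{i}", seq))
    for i in range(50):
        u = rng.randint(0, 99)
        annotated.append((f"a{i}", genome["chrR"][100 + u : 200 + u]))
    sj = [JunctionRecord("chrR", 300, 600, "+", 1, False, 30, 0, 20)]
    return model, genome, l, novel, annotated, sj


class TestParseSJ:
    def test_roundtrip(self, tmp_path):
        recs = [
            JunctionRecord("chr1", 299, 600, "+", 2, True, 12, 3, 25),
            JunctionRecord("chr2", 10, 50, ".", 0, False, 4, 0, 11),
        ]
        p = tmp_path / "sj.tab"
        write_sj(recs, p)
        assert parse_sj(p) == recs
        # 1-based inclusive on disk
        line = p.read_text().splitlines()[0].split("\t")
        assert line[1] == "300" and line[2] == "600"

    def test_strand_code_zero_kept_unstranded(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t100\t200\t0\t0\t0\t5\t0\t20\n")
        assert parse_sj(p)[0].strand == "."

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t100\t200\t1\t0\t0\t5\t0\t20\nchr1\t100\t200\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_sj(p)


class TestIncorporate:
    def test_no_novel_sites_no_change(self, novel_acceptor_setup):
        model, *_ = novel_acceptor_setup
        models = {"R": model}
        new, disc, remaps, skipped = incorporate_novel_sites(models, [])
        assert new["R"] is model
        assert remaps["R"] == {s.index: [s.index] for s in model.subexons}

    def test_split_and_remap(self, novel_acceptor_setup):
        model, _, _, _, _, sj = novel_acceptor_setup
        new, disc, remaps, skipped = incorporate_novel_sites({"R": model}, sj)
        assert [(s.interval.start, s.interval.end) for s in new["R"].subexons] == [
            (100, 300), (500, 600), (600, 800), (1000, 1200)
        ]
        assert remaps["R"] == {1: [1], 2: [2, 3], 3: [4]}
        assert {(j.start, j.end, j.status) for j in disc["R"]} == {(300, 600, "discovered")}

    def test_remap_expansion_policy(self):
        remap = {1: [1], 2: [2, 3], 3: [4]}
        assert remap_signature((1, 2, 3), remap) == (1, 2, 3, 4)  # internal: all pieces
        assert remap_signature((2, 3), remap) == (3, 4)  # first: rightmost piece
        assert remap_signature((1, 2), remap) == (1, 2)  # last: leftmost piece
        assert remap_signature((2,), remap) == (2, 3)  # singleton: all pieces

    def test_count_conservation_under_remap(self, novel_acceptor_setup):
        from splicefrag.pseudomap import SignatureCountTable

        model, _, _, _, _, sj = novel_acceptor_setup
        _, _, remaps, _ = incorporate_novel_sites({"R": model}, sj)
        t = SignatureCountTable()
        t.counts = {("R", (1, 2)): 10, ("R", (2,)): 5, ("R", (1, 2, 3)): 2}
        out = remap_counts(t, remaps)
        assert sum(out.counts.values()) == 17

    def test_filters_respected(self, novel_acceptor_setup):
        model, _, _, _, _, _ = novel_acceptor_setup
        weak = [JunctionRecord("chrR", 300, 600, "+", 1, False, 2, 0, 20)]
        new, disc, _, _ = incorporate_novel_sites({"R": model}, weak, min_unique=3)
        assert not disc["R"] and new["R"] is model

    def test_intergenic_site_skipped(self, novel_acceptor_setup):
        model, _, _, _, _, _ = novel_acceptor_setup
        off = [JunctionRecord("chrZ", 300, 600, "+", 1, False, 30, 0, 20)]
        _, disc, _, skipped = incorporate_novel_sites({"R": model}, off)
        assert skipped == off and not disc["R"]

    def test_intron_interior_site_needs_novel_exon_skipped(self, novel_acceptor_setup):
        model, _, _, _, _, _ = novel_acceptor_setup
        # acceptor at 900 falls in intronic territory (800-1000)
        rec = [JunctionRecord("chrR", 300, 900, "+", 1, False, 30, 0, 20)]
        _, disc, _, skipped = incorporate_novel_sites({"R": model}, rec)
        assert skipped == rec and not disc["R"]


class TestRefineEndToEnd:
    def _phase1(self, model, genome, l, reads):
        graphs = {"R": build_splice_graph(model, "as")}
        fs = build_fragment_set(graphs, genome, l, "F")
        idx = build_kmer_index(fs)
        unmapped = []
        table = count_reads(reads, idx, unmapped_out=unmapped)
        return table, unmapped

    def test_novel_junction_reads_recovered(self, novel_acceptor_setup):
        model, genome, l, novel, annotated, sj = novel_acceptor_setup
        table, unmapped = self._phase1(model, genome, l, novel + annotated)
        assert len(unmapped) == len(novel)  # all novel-site reads unmapped in phase 1
        new_table, new_models, disc, _ = refine_counts(
            table, {"R": model}, sj, unmapped, genome, l
        )
        assert new_table.unmapped == 0
        # every novel read now counted with the discovered junction signature
        assert new_table.counts[("R", (1, 3))] == len(novel)
        # events: junction between annotated donor and discovered acceptor
        from splicefrag.events import annotate_events

        evs = annotate_events(new_table, new_models)
        # annotated donor with a discovered (alternative) acceptor
        assert {(e.donor, e.acceptor, e.type) for e in evs} == {(300, 600, "AA")}

    def test_phase1_counts_never_decrease(self, novel_acceptor_setup):
        model, genome, l, novel, annotated, sj = novel_acceptor_setup
        table, unmapped = self._phase1(model, genome, l, novel + annotated)
        _, _, remaps, _ = incorporate_novel_sites({"R": model}, sj)
        new_table, *_ = refine_counts(table, {"R": model}, sj, unmapped, genome, l)
        for (gid, sig), n in table.counts.items():
            assert new_table.counts[(gid, remap_signature(sig, remaps[gid]))] >= n

    def test_idempotence(self, novel_acceptor_setup):
        model, genome, l, novel, annotated, sj = novel_acceptor_setup
        table, unmapped = self._phase1(model, genome, l, novel + annotated)
        t1, m1, d1, _ = refine_counts(table, {"R": model}, sj, unmapped, genome, l)
        residual = []
        t2, m2, d2, _ = refine_counts(
            t1, m1, sj, residual, genome, l
        )
        assert t2.counts == t1.counts
        assert [s.interval for s in m2["R"].subexons] == [s.interval for s in m1["R"].subexons]

    def test_zero_affected_genes_empty_delta(self, novel_acceptor_setup):
        from splicefrag.refine import requant_unmapped

        model, genome, l, *_ = novel_acceptor_setup
        delta = requant_unmapped([], {"R": model}, {"R": set()}, genome, l)
        assert delta.counts == {} and delta.total_reads == 0

    def test_end_to_end_truth_with_ten_percent_novel(self, novel_acceptor_setup):
        # (phase-1 mapped) + (refine delta) equals the truth histogram exactly
        model, genome, l, novel, annotated, sj = novel_acceptor_setup
        reads = annotated + novel[: len(annotated) // 9]
        table, unmapped = self._phase1(model, genome, l, reads)
        new_table, *_ = refine_counts(table, {"R": model}, sj, unmapped, genome, l)
        truth = {
            ("R", (1,)): len(annotated),
            ("R", (1, 3)): len(novel[: len(annotated) // 9]),
        }
        assert new_table.counts == truth
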