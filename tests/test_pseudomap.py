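"""k-mer index construction, read mapping, signature counting."""

import pytest

from splicefrag._util import revcomp
from splicefrag.fragments import build_fragment_set
from splicefrag.pseudomap import (
    ReadHit,
    build_kmer_index,
    count_reads,
    map_read,
    select_primary,
)
from splicefrag.simulate import FixtureSpec, make_fixture, write_fastq
from splicefrag.virtual_splicing import build_splice_graph


@pytest.fixture(scope="module")
def fx():
    return make_fixture(FixtureSpec(seed=5, n_genes=3, n_reads=1000, hold_out_events=True))


@pytest.fixture(scope="module")
def index(fx):
    graphs = {gid: build_splice_graph(m, "as") for gid, m in fx.models.items()}
    fs = build_fragment_set(graphs, fx.genome, 100, "F")
    return build_kmer_index(fs)


class TestIndex:
    def test_posting_count_per_fragment(self, index):
        k = index.k
        total = sum(len(v) for v in index.postings.values())
        assert total == sum(len(f.seq) - k + 1 for f in index.fragments)

    def test_exhaustive_self_lookup(self, index):
        k = index.k
        for f in index.fragments[:10]:
            fi = index.fragments.index(f)
            for off in range(0, len(f.seq) - k + 1, 7):
                kmer = f.seq[off : off + k]
                canon = min(kmer, revcomp(kmer))
                assert any(p[0] == fi and p[1] == off for p in index.postings[canon])

    def test_k_must_be_below_read_length(self, index):
        from splicefrag.fragments import FragmentSet

        fs = FragmentSet("F", "as", 100, list(index.fragments))
        with pytest.raises(ValueError):
            build_kmer_index(fs, k=100)


class TestMapRead:
    def test_error_free_reads_recover_truth(self, fx, index):
        for r in fx.reads[:300]:
            res = map_read(r.seq, index)
            assert res.status == "mapped"
            assert (res.gene_id, res.signature) == (r.gene_id, r.signature)

    def test_reverse_complement_maps_identically(self, fx, index):
        for r in fx.reads[:50]:
            res = map_read(revcomp(r.seq), index)
            assert res.status == "mapped"
            assert (res.gene_id, res.signature) == (r.gene_id, r.signature)

    def test_central_mismatch_keeps_signature(self, fx, index):
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for r in fx.reads[:50]:
            seq = list(r.seq)
            seq[50] = sub[seq[50]]
            res = map_read("".join(seq), index)
            assert res.status == "mapped" and res.signature == r.signature

    def test_systematic_mismatch_positions_away_from_ends(self, fx, index):
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        k = index.k
        for r in fx.reads[:10]:
            for p in range(k, 100 - k + 1):
                seq = list(r.seq)
                seq[p] = sub[seq[p]]
                res = map_read("".join(seq), index)
                assert res.status == "mapped" and res.signature == r.signature

    def test_one_nt_overhang_read_maps_via_junction_kmers(self, fx, index):
        # a read overlapping only the trimmed boundary of a junction fragment
        # but fully covered by the singleton subexon fragment gets the
        # singleton signature
        for f in index.fragments:
            if len(f.signature) == 1 and len(f.seq) >= 120:
                sub = f.signature[0]
                read = f.seq[5:105]
                res = map_read(read, index)
                assert res.status == "mapped" and res.signature == (sub,)
                break
        else:
            pytest.skip("no long singleton in fixture")

    def test_n_rich_read_unmapped(self, index):
        assert map_read("N" * 100, index).status == "unmapped"

    def test_read_longer_than_index_rejected(self, index):
        with pytest.raises(ValueError, match="rebuild"):
            map_read("A" * 101, index)

    def test_short_read_maps_if_at_least_k(self, fx, index):
        r = fx.reads[0]
        res = map_read(r.seq[:40], index)
        assert res.status == "mapped"
        assert map_read(r.seq[:20], index).status == "unmapped"  # < k

    def test_foreign_sequence_unmapped(self, index):
        import random

        rng = random.Random(999)
        seq = "".join(rng.choices("ACGT", k=100))
        assert map_read(seq, index).status == "unmapped"


class TestSelectPrimary:
    def test_single_hit(self):
        h = ReadHit(0, "f0", 3, "fwd", 10, 100)
        assert select_primary([h]) is h

    def test_support_dominates(self):
        h1 = ReadHit(0, "f0", 3, "fwd", 10, 90)
        h2 = ReadHit(1, "f1", 5, "fwd", 3, 100)
        assert select_primary([h1, h2]) is h1

    def test_tie_broken_by_matchlen_then_name(self):
        h1 = ReadHit(2, "b", 0, "fwd", 10, 100)
        h2 = ReadHit(1, "a", 0, "fwd", 10, 100)
        h3 = ReadHit(0, "c", 0, "fwd", 10, 99)
        assert select_primary([h1, h2, h3]) is h2
        assert select_primary([h1, h2, h3]) is select_primary([h3, h2, h1])


class TestCountReads:
    def test_class_of_seven(self, fx, index):
        # seven identical-signature reads form one equivalence class of size 7
        r = fx.reads[0]
        table = count_reads([(f"c{i}", r.seq) for i in range(7)], index)
        assert table.counts == {(r.gene_id, r.signature): 7}

    def test_empty_input(self, index, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        table = count_reads(p, index)
        assert table.counts == {} and table.mapped == 0

    def test_library_matches_truth_exactly(self, fx, index):
        table = count_reads([(r.id, r.seq) for r in fx.reads], index)
        assert table.counts == fx.truth_histogram()
        assert table.mapped == len(fx.reads)
        assert table.mapped + table.unmapped + table.ambiguous == len(fx.reads)

    def test_fastq_roundtrip_and_table_io(self, fx, index, tmp_path):
        fq = tmp_path / "reads.fastq"
        write_fastq(fx.reads[:200], fq)
        table = count_reads(fq, index)
        sub = {(r.gene_id, r.signature) for r in fx.reads[:200]}
        assert set(table.counts) == sub
        out = tmp_path / "counts.tsv"
        table.write(out)
        back = type(table).read(out)
        assert back.counts == table.counts

    def test_paired_sum_and_pair_signatures(self, tmp_path):
        fx = make_fixture(FixtureSpec(seed=9, n_genes=2, n_reads=400, paired=True))
        graphs = {gid: build_splice_graph(m, "as") for gid, m in fx.models.items()}
        fs = build_fragment_set(graphs, fx.genome, 100, "F")
        idx = build_kmer_index(fs)
        r1 = [(r.id, r.seq) for r in fx.reads if r.mate == 1]
        r2 = [(r.id, r.seq) for r in fx.reads if r.mate == 2]
        table = count_reads(r1, idx, fastq2=r2, pair_signatures=True)
        assert table.counts == fx.truth_histogram()  # sum over both ends
        assert sum(table.pair_counts.values()) == len(r1)

    def test_desynchronized_pairs_rejected(self, fx, index):
        with pytest.raises(ValueError, match="desynchronized"):
            count_reads([("a", fx.reads[0].seq)], index,
                        fastq2=[("a", fx.reads[0].seq), ("b", fx.reads[1].seq)])

    def test_thread_count_does_not_change_output(self, fx, index):
        reads = [(r.id, r.seq) for r in fx.reads[:300]]
        t1 = count_reads(reads, index, threads=1)
        t4 = count_reads(reads, index, threads=4)
        assert t1.counts == t4.counts and t1.summary() == t4.summary()


class TestTriSetEquivalence:
    @pytest.mark.parametrize("seed", [0, 4])
    def test_identical_tables_across_fragment_sets(self, seed):
        fx = make_fixture(FixtureSpec(seed=seed, n_genes=3, n_reads=1500, hold_out_events=True))
        graphs = {gid: build_splice_graph(m, "as") for gid, m in fx.models.items()}
        reads = [(r.id, r.seq) for r in fx.reads]
        tables = {}
        sizes = {}
        for var in ("F11", "Fmax", "F"):
            fs = build_fragment_set(graphs, fx.genome, 100, var)
            sizes[var] = (len(fs), fs.total_nt)
            tables[var] = count_reads(reads, build_kmer_index(fs))
        assert tables["F11"].counts == tables["Fmax"].counts == tables["F"].counts
        assert sizes["Fmax"][0] <= sizes["F11"][0]
        assert sizes["F"][0] <= sizes["F11"][0]
        assert sizes["F"][1] <= sizes["Fmax"][1]

    def test_trimming_soundness(self):
        # every mapped read overlapping a fragment's boundary subexon also
        # overlaps the neighbouring subexon of that fragment
        fx = make_fixture(FixtureSpec(seed=6, n_genes=2, n_reads=800))
        graphs = {gid: build_splice_graph(m, "as") for gid, m in fx.models.items()}
        fs = build_fragment_set(graphs, fx.genome, 100, "F")
        idx = build_kmer_index(fs)
        checked = 0
        for r in fx.reads:
            res = map_read(r.seq, idx)
            assert res.status == "mapped"
            frag = idx.fragments[res.hit.frag_idx]
            if len(frag.signature) < 2:
                continue
            subs, _ = frag.scan(res.hit.offset, len(r.seq))
            if frag.signature[0] in subs:
                assert frag.signature[1] in subs
                checked += 1
            if frag.signature[-1] in subs:
                assert frag.signature[-2] in subs
        assert checked > 0
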