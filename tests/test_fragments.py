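"""Feasible signatures, Eq.-1 fragments, the three fragment sets, theorem checks."""

import pytest

from splicefrag.fragments import (
    build_F,
    build_F11,
    build_Fmax,
    build_fragment_set,
    enumerate_feasible_signatures,
    fragment_sequence,
    maximal_signatures,
    parse_fragment_name,
    verify_theorem1,
    write_fragments,
)
from splicefrag.gene_model import GeneModel, Transcript
from splicefrag.simulate import FixtureSpec, make_fixture
from splicefrag.virtual_splicing import build_splice_graph

from conftest import iv, random_genome


def window_oracle(graph, l):
    """Independent sliding-window enumeration: walk every maximal explicit
    path, slide every length-l window, record the overlapped index tuples."""
    lens = {s.index: s.length for s in graph.gene.subexons}
    if graph.mode == "annotated":
        paths = sorted(set(graph.gene.signatures.values()))
    else:
        edges = graph.edges()
        has_pred = {b for _, b in edges}
        stack = [(n,) for n in graph.nodes if n not in has_pred]
        paths = []
        while stack:
            p = stack.pop()
            succ = [b for (a, b) in edges if a == p[-1]]
            if not succ:
                paths.append(p)
            for s in succ:
                stack.append(p + (s,))
    out = set()
    for p in paths:
        bounds = [0]
        for i in p:
            bounds.append(bounds[-1] + lens[i])
        total = bounds[-1]
        for off in range(total - l + 1):
            lo, hi = off, off + l
            sig = tuple(
                p[k] for k in range(len(p)) if bounds[k] < hi and lo < bounds[k + 1]
            )
            if graph.mode == "annotated" or graph.span_admissible(sig):
                out.add(sig)
    return out


class TestFeasibility:
    def test_single_long_subexon_is_feasible(self):
        t = Transcript("t", "g", (iv(0, 100),))
        g = build_splice_graph(GeneModel("g", [t]), "annotated")
        assert (1,) in enumerate_feasible_signatures(g, 50)
        assert (1,) not in enumerate_feasible_signatures(g, 101)

    def test_internal_length_boundary_of_f3(self):
        # internal subexon of length l-2 feasible, l-1 infeasible
        for mid_len, feasible in ((8, True), (9, False)):
            t1 = Transcript("t1", "g", (iv(0, 50), iv(100, 100 + mid_len), iv(200, 250)))
            t2 = Transcript("t2", "g", (iv(0, 50), iv(200, 250)))
            g = build_splice_graph(GeneModel("g", [t1, t2]), "annotated")
            sigs = enumerate_feasible_signatures(g, 10)
            assert ((1, 2, 3) in sigs) == feasible

    def test_read_length_below_two_rejected(self, fixg1):
        g = build_splice_graph(fixg1, "as")
        with pytest.raises(ValueError):
            enumerate_feasible_signatures(g, 1)

    @pytest.mark.parametrize("mode", ["annotated", "as", "ap"])
    @pytest.mark.parametrize("l", [8, 10, 15])
    def test_enumeration_matches_window_oracle(self, fixg1, mode, l):
        g = build_splice_graph(fixg1, mode)
        assert enumerate_feasible_signatures(g, l) == window_oracle(g, l)

    @pytest.mark.parametrize("seed", [7, 11])
    def test_enumeration_matches_oracle_on_random_genes(self, seed):
        fx = make_fixture(FixtureSpec(seed=seed, n_genes=2, n_reads=0, exons_per_gene=(3, 5)))
        for gid, m in fx.models.items():
            g = build_splice_graph(m, "as")
            assert enumerate_feasible_signatures(g, 10) == window_oracle(g, 10)


class TestFragmentSequence:
    def test_m1_fragment_is_whole_subexon(self, fixg1, fixg1_genome):
        f = fragment_sequence((1,), fixg1, fixg1_genome, 10)
        assert f.seq == fixg1_genome["chrFIXG1"][100:200]

    def test_m2_trimming_and_substring_coverage(self, fixg1, fixg1_genome):
        # junction s1 -> s3 (annotated in t2), b = l - 1 = 9
        f = fragment_sequence((1, 3), fixg1, fixg1_genome, 10)
        chrom = fixg1_genome["chrFIXG1"]
        assert f.seq == chrom[191:200] + chrom[500:509]
        assert len(f.seq) == 18
        # every junction-spanning read of length 10 occurs in the fragment
        for o in range(1, 10):
            read = chrom[200 - o : 200] + chrom[500 : 510 - o]
            assert read in f.seq

    def test_m3_short_internal_subexon(self):
        t = Transcript("t", "g", (iv(0, 50), iv(100, 104), iv(200, 250)))
        g = GeneModel("g", [t])
        genome = random_genome(5, {"chrT": 300})
        f = fragment_sequence((1, 2, 3), g, genome, 10)
        # b = 10 - 4 - 1 = 5: suffix-5 + middle-4 + prefix-5
        assert len(f.seq) == 14
        assert f.seq == genome["chrT"][45:50] + genome["chrT"][100:104] + genome["chrT"][200:205]
        # substring-coverage oracle: all window placements covering all three
        for o in (1, 2, 3, 4, 5):
            read = genome["chrT"][50 - o : 50] + genome["chrT"][100:104] + genome["chrT"][200 : 206 - o]
            assert read in f.seq

    def test_infeasible_signature_rejected(self):
        t = Transcript("t", "g", (iv(0, 50), iv(100, 150), iv(200, 250)))
        g = GeneModel("g", [t])
        genome = random_genome(5, {"chrT": 300})
        with pytest.raises(ValueError):
            fragment_sequence((1, 2, 3), g, genome, 10)  # internal 50 > l-2

    def test_name_roundtrip(self, fixg1, fixg1_genome):
        f = fragment_sequence((1, 3, 4), fixg1, fixg1_genome, 110)
        gene, sig, a, b = parse_fragment_name(f.name)
        assert gene == "FIXG1" and sig == (1, 3, 4)
        assert a == f.segments[0].frag_end - f.segments[0].frag_start
        assert b == f.segments[-1].frag_end - f.segments[-1].frag_start


class TestFragmentSets:
    def test_fmax_smaller_and_f_least_redundant(self, fixg1, fixg1_genome):
        g = build_splice_graph(fixg1, "as")
        sigs = enumerate_feasible_signatures(g, 10)
        f11 = build_F11(sigs, fixg1, fixg1_genome, 10)
        fmax = build_Fmax(sigs, fixg1, fixg1_genome, 10)
        f = build_F(sigs, fixg1, fixg1_genome, 10)
        assert len(fmax) <= len(f11)
        assert len(f) <= len(f11)
        assert sum(len(x.seq) for x in f) <= sum(len(x.seq) for x in fmax)

    def test_maximality_is_contiguous_containment(self):
        sigs = {(1,), (1, 2), (2, 3), (1, 2, 3), (5,)}
        assert maximal_signatures(sigs) == {(1, 2, 3), (5,)}

    def test_singleton_rule(self, fixg1, fixg1_genome):
        l = 10
        g = build_splice_graph(fixg1, "as")
        sigs = enumerate_feasible_signatures(g, l)
        f = build_F(sigs, fixg1, fixg1_genome, l)
        singles = {x.signature for x in f if len(x.signature) == 1}
        assert singles == {(i,) for i in range(1, 6)}  # all subexons are >= l long
        # no other F fragment contains more than l-1 bases of a long subexon
        for x in f:
            if len(x.signature) == 1:
                continue
            for seg in (x.segments[0], x.segments[-1]):
                assert seg.frag_end - seg.frag_start <= l - 1

    def test_fragment_fasta_deterministic(self, fixg1, fixg1_genome, tmp_path):
        g = build_splice_graph(fixg1, "as")
        out = []
        for i in (1, 2):
            fs = build_fragment_set({"FIXG1": g}, fixg1_genome, 10, "F")
            p = tmp_path / f"f{i}.fa"
            write_fragments(fs, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]


class TestTheorem:
    def test_annotated_single_transcript_complete(self):
        t = Transcript("t", "g", (iv(0, 60), iv(100, 160), iv(200, 260)))
        m = GeneModel("g", [t])
        genome = random_genome(9, {"chrT": 400})
        g = build_splice_graph(m, "annotated")
        fs = build_fragment_set({"g": g}, genome, 12, "F")
        assert verify_theorem1(fs, g, genome, 12)["ok"]

    @pytest.mark.parametrize("l", [8, 10, 15])
    @pytest.mark.parametrize("variant", ["F11", "Fmax", "F"])
    def test_fixg1_as_mode(self, fixg1, fixg1_genome, l, variant):
        g = build_splice_graph(fixg1, "as")
        fs = build_fragment_set({"FIXG1": g}, fixg1_genome, l, variant)
        rep = verify_theorem1(fs, g, fixg1_genome, l)
        assert rep["ok"], rep["violations"][:3]

    def test_adversarial_one_nt_subexon(self):
        # a 1-nt subexon created by two donors one base apart
        t1 = Transcript("t1", "g", (iv(0, 50), iv(100, 151), iv(200, 250)))
        t2 = Transcript("t2", "g", (iv(0, 50), iv(100, 150), iv(200, 250)))
        m = GeneModel("g", [t1, t2])
        assert 1 in [s.length for s in m.subexons]
        genome = random_genome(13, {"chrT": 300})
        g = build_splice_graph(m, "as")
        for l in (8, 10):
            fs = build_fragment_set({"g": g}, genome, l, "F")
            rep = verify_theorem1(fs, g, genome, l)
            assert rep["ok"], rep["violations"][:3]
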