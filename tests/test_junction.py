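"""TDT scoring and the cluster-level D / N-region refinement rules."""

import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdjlineage import (Member, TDTModel, build_forest,
                        find_consensus_mismatches, nscore, p_tdt,
                        refine_d_gene, refine_n_edges, unify_annotations)
from vdjlineage.annotate import Annotation, NRegion, Span, annotate_sequence
from vdjlineage.germline import GermlineDatabase, GermlineGene, \
    find_anchor_positions, make_inverted_d
from vdjlineage.junction import DEFAULT_TDT, RefineConfig, _edge_trim, \
    _objective
from vdjlineage.lineage import CloneCluster

COMP = str.maketrans("ACGT", "TGCA")


class TestPTdt:
    @pytest.mark.parametrize("seq,expected", [
        ("GGG", 0.93),       # trimming example: became the N_VD region
        ("TATC", 0.40),      # via element-wise complement ATAG; no trim
        ("GGGCCC", 0.31),    # unfavourable combination; no trim
        ("A", 0.50),         # P_A equals the uniform baseline
    ])
    def test_printed_values(self, seq, expected):
        assert round(p_tdt(seq), 2) == expected

    def test_empty_region_is_neutral(self):
        assert p_tdt("") == 0.5

    @given(st.text(alphabet="ACGT", min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_invariant_under_elementwise_complement(self, seq):
        comp = seq.translate(COMP)
        assert p_tdt(seq) == pytest.approx(p_tdt(comp))

    def test_poly_g_approaches_one_monotonically(self):
        vals = [p_tdt("G" * k) for k in range(1, 10)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.999

    def test_uniform_composition_stays_neutral(self):
        model = TDTModel(p_insert=(("A", 0.25), ("C", 0.25),
                                   ("G", 0.25), ("T", 0.25)))
        for seq in ("A", "ACGT", "GGGG"):
            assert p_tdt(seq, model) == pytest.approx(0.5)


class TestNscore:
    def test_worked_value(self):
        assert nscore("GGG") == pytest.approx((p_tdt("GGG") * 3) ** 2)
        assert round(nscore("GGG"), 2) == 7.83

    def test_empty_is_zero(self):
        assert nscore("") == 0.0

    def test_monotone_in_p_tdt_at_fixed_length(self):
        # p_tdt("GGG") > p_tdt("CCT") (via complement GGA) > p_tdt("GGT")
        assert nscore("GGG") > nscore("CCT") > nscore("GGT")


class TestEdgeTrimRules:
    """The four worked trimming scenarios, interior->tip slices."""

    def test_rule_b_creates_n_region(self):
        # V ends TGCA|gGG, g mismatched: P_TDT(gGG)=0.93>0.5 -> trim 3
        assert _edge_trim("TTTGCAGGG", {6}, "", True, DEFAULT_TDT,
                          RefineConfig()) == 3

    def test_rule_b_rejects_implausible_trim(self):
        # V ends CA|tATC: P_TDT(tATC)=0.40 -> no trim
        assert _edge_trim("TTTTTCATATC", {7}, "", True, DEFAULT_TDT,
                          RefineConfig()) == 0

    def test_rule_c_rejects_unfavourable_combination(self):
        # existing N_VD ccc: gggccc drops P_TDT 0.93 -> 0.31 -> no trim
        assert _edge_trim("TTTGCAGGG", {6}, "CCC", True, DEFAULT_TDT,
                          RefineConfig()) == 0

    def test_rule_c_accepts_favourable_combination(self):
        assert _edge_trim("TTTGCAGGG", {6}, "GGG", True, DEFAULT_TDT,
                          RefineConfig()) == 3

    def test_rule_a_moves_run_with_trailing_matches(self):
        # V ends TG|agg|GG: run of 3 plus the 2 matching tip nts move
        assert _edge_trim("TTTTGAGGGG", {5, 6, 7}, "", True, DEFAULT_TDT,
                          RefineConfig()) == 5

    def test_no_mismatch_no_trim(self):
        assert _edge_trim("TTTGCAGGG", set(), "", True, DEFAULT_TDT,
                          RefineConfig()) == 0


def _toy_db():
    """One V, two D (one dominant by chance), one J; junction controlled."""
    v = find_anchor_positions(GermlineGene(
        "IGHV1-1*01", "V",
        "ACG" * 36 + "TGT" + "GCTAGA"))          # anchor at 109
    truth_d = GermlineGene("IGHD1-1*01", "D", "ATCGATTACGAT")
    decoy_d = GermlineGene("IGHD2-1*01", "D", "TTTTTTTTT")
    j = find_anchor_positions(GermlineGene(
        "IGHJ1*01", "J", "CCACCC" + "TGG" + "ACTGTC"))
    return GermlineDatabase([v, truth_d, decoy_d, j] +
                            make_inverted_d([truth_d, decoy_d])[2:],
                            species="test")


def _cluster_from_reads(db, reads):
    members = [Member(id=f"m{i}",
                      annotation=annotate_sequence(f"m{i}", r, db))
               for i, r in enumerate(reads)]
    trees = build_forest(members)
    assert len(trees) == 1
    return unify_annotations(CloneCluster(tree=trees[0]), db)


class TestConsensusMismatches:
    def test_shared_substitution_is_consensus(self, db, small_sim):
        seqs, _ = small_sim
        # pick a clone with a roomy D segment and mutate its middle
        s = max((x for x in seqs if x.generation == 0),
                key=lambda x: x.d_end - x.d_start)
        read = s.sequence
        p = (s.d_start + s.d_end) // 2
        base = read[p - 1]
        sub = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
        mut = read[:p - 1] + sub + read[p:]
        cluster = _cluster_from_reads(db, [mut, mut])
        positions = {c.position for c in find_consensus_mismatches(cluster)}
        assert p in positions

    def test_member_specific_mutations_are_not_consensus(self, db, small_sim):
        seqs, _ = small_sim
        s = max((x for x in seqs if x.generation == 0),
                key=lambda x: x.d_end - x.d_start)
        read = s.sequence
        p = (s.d_start + s.d_end) // 2
        base = read[p - 1]
        sub = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
        mut = read[:p - 1] + sub + read[p:]
        cluster = _cluster_from_reads(db, [read, mut])
        assert find_consensus_mismatches(cluster) == []

    def test_vframe_labelling(self, db, small_sim):
        seqs, _ = small_sim
        s = [x for x in seqs if x.generation == 0][0]
        read = s.sequence
        p = 10                          # deep in the V framework
        sub = {"A": "G", "G": "A", "C": "T", "T": "C"}[read[p - 1]]
        mut = read[:p - 1] + sub + read[p:]
        cluster = _cluster_from_reads(db, [mut, mut])
        labelled = {c.position: c.region
                    for c in find_consensus_mismatches(cluster)}
        if p in labelled:
            assert labelled[p] == "Vframe"


class TestRefineDGene:
    def _masked_cluster(self):
        """Truth D present in the junction but the cluster carries a
        decoy call with a consensus mismatch."""
        db = _toy_db()
        v, truth_d, j = db["IGHV1-1*01"], db["IGHD1-1*01"], db["IGHJ1*01"]
        n_vd, n_dj = "GGA", "GG"
        read = v.sequence + n_vd + truth_d.sequence + n_dj + j.sequence[:9]
        cluster = _cluster_from_reads(db, [read, read])
        ann = cluster.annotation
        # overwrite with a decoy D call: off-target placement, 1 consensus mm
        v_end = ann.v_span.end
        j_start = ann.j_span.start
        ann.d_name = "IGHD2-1*01"
        ann.d_span = Span(v_end + 2, v_end + 10)
        ann.d_gene_span = (1, 9)
        ann.d_score = 1.0
        ann.nvd_span = Span(v_end + 1, v_end + 1)
        ann.ndj_span = Span(v_end + 11, j_start - 1)
        ann.n_vd = NRegion(ann.nvd_span.extract(read), "VD")
        ann.n_dj = NRegion(ann.ndj_span.extract(read), "DJ")
        return unify_annotations(cluster, db), db

    def test_truth_d_restored(self):
        cluster, db = self._masked_cluster()
        assert len(find_consensus_mismatches(cluster)) > 0
        before = _objective(cluster.annotation, DEFAULT_TDT)
        out = refine_d_gene(cluster, db)
        assert out.annotation.d_name == "IGHD1-1*01"
        assert _objective(out.annotation, DEFAULT_TDT) > before

    def test_vframe_consensus_gates_refinement(self):
        cluster, db = self._masked_cluster()
        # plant a Vframe consensus mismatch in every member
        for mid in cluster.ids:
            ann = cluster.member(mid).annotation
            seq = ann.sequence
            sub = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq[4]]
            ann.sequence = seq[:4] + sub + seq[5:]
        cluster = unify_annotations(cluster, db)
        before = cluster.annotation.d_name
        out = refine_d_gene(cluster, db)
        assert out.annotation.d_name == before

    def test_clean_cluster_untouched(self, db, small_sim):
        seqs, _ = small_sim
        clean = None
        for s in (x for x in seqs if x.generation == 0):
            cluster = _cluster_from_reads(db, [s.sequence, s.sequence])
            if not find_consensus_mismatches(cluster):
                clean = cluster
                break
        assert clean is not None, "no cleanly annotated germline read"
        before = clean.annotation.d_name
        out = refine_d_gene(clean, db)
        assert out.annotation.d_name == before


class TestRefineNEdges:
    def test_tiling_preserved(self, db, small_sim):
        seqs, _ = small_sim
        s = [x for x in seqs if x.generation == 0][0]
        read = s.sequence
        # plant a shared V 3' edge mismatch to provoke a trim decision
        cluster = _cluster_from_reads(db, [read, read])
        v_end = cluster.annotation.v_span.end
        sub = {"A": "G", "G": "A", "C": "T", "T": "C"}[read[v_end - 1]]
        for mid in cluster.ids:
            ann = cluster.member(mid).annotation
            ann.sequence = read[:v_end - 1] + sub + read[v_end:]
        cluster = unify_annotations(cluster, db)
        out = refine_n_edges(cluster, db=db)
        ann = out.annotation
        spans = [ann.v_span, ann.nvd_span, ann.d_span, ann.ndj_span,
                 ann.j_span]
        pos = 0
        for sp in spans:
            assert sp.start == pos + 1
            pos = max(pos, sp.end)
        assert pos == len(ann.sequence)
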