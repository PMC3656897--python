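"""Signature extraction, nearest-neighbor and placement substrate calling,
C-domain and TE typing."""

import numpy as np
import pytest

from nrpslip import classification as cl
from nrpslip import phylo
from nrpslip.simulate import (
    class_ancestor,
    make_reference_panel,
    mutate,
)


@pytest.fixture(scope="module")
def template():
    return cl.default_signature_template()


@pytest.fixture(scope="module")
def a_panel():
    return make_reference_panel("A", ["Leu", "Ser", "Glu"], 3, seed=41)


@pytest.fixture(scope="module")
def c_panel():
    return make_reference_panel(
        "C", ["starter", "dual", "conventional"], 3, seed=51
    )


@pytest.fixture(scope="module")
def te_panel():
    return make_reference_panel("TE", ["TE1", "TE2"], 3, seed=61)


def _sig_ref(rid, label, sig10):
    return cl.ReferenceDomain(
        id=rid, kind="A", label=label, sequence="", signature_10=sig10
    )


class TestExtractSignature:
    def test_template_identity(self, template):
        s34, s10 = cl.extract_signature(template.anchor_sequence, template)
        assert (s34, s10) == template.own_signature()

    def test_insertion_outside_pocket_leaves_signature_unchanged(
        self, template
    ):
        anchor = template.anchor_sequence
        # insert 5 residues well before the first signature column
        ins_at = min(template.positions_34) - 100
        query = anchor[:ins_at] + "WWWWW" + anchor[ins_at:]
        s34, s10 = cl.extract_signature(query, template)
        assert (s34, s10) == template.own_signature()

    def test_signature10_is_indexed_subset_of_34(self, template, a_panel):
        for ref in a_panel:
            s34, s10 = cl.extract_signature(ref.sequence, template)
            assert s10 == "".join(s34[i - 1] for i in template.positions_10)

    def test_short_sequence_rejected(self, template):
        with pytest.raises(ValueError, match="short"):
            cl.extract_signature("ACDEF" * 10, template)

    def test_unrelated_sequence_not_extractable(self, template):
        rng = np.random.default_rng(3)
        junk = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=30)
        ) * 10
        with pytest.raises(cl.SignatureNotExtractable):
            cl.extract_signature(junk, template, min_coverage=0.995)

    def test_alignment_recovers_column_signatures(self, template, a_panel):
        # substitution-only panel members: aligned extraction must equal the
        # direct column read-off recorded by the generator
        for ref in a_panel:
            _, s10 = cl.extract_signature(ref.sequence, template)
            assert s10 == ref.signature_10


class TestNearestNeighbor:
    def test_exact_match_is_confident_ten(self):
        refs = [_sig_ref("Leu.r0", "Leu", "ACDEFGHIKL"),
                _sig_ref("Ser.r0", "Ser", "WWWWWWWWWW"),
                _sig_ref("Glu.r0", "Glu", "YYYYYYYYYY")]
        call = cl.call_substrate_nn("ACDEFGHIKL", refs)
        assert (call.label, call.score, call.confidence) == ("Leu", 10, "confident")
        assert call.ties == ("Leu",)

    def test_equidistant_query_is_ambiguous_with_sorted_ties(self):
        refs = [_sig_ref("Leu.r0", "Leu", "AAAAAAAAAA"),
                _sig_ref("Ile.r0", "Ile", "CCAAAAAAAA"),
                _sig_ref("Ser.r0", "Ser", "WWWWWWWWWW")]
        call = cl.call_substrate_nn("ACAAAAAAAA", refs)
        assert call.confidence == "ambiguous"
        assert call.ties == ("Ile", "Leu")
        assert call.score == 9

    def test_below_floor_flags_none(self):
        refs = [_sig_ref("Leu.r0", "Leu", "AAAAAAAAAA"),
                _sig_ref("Ser.r0", "Ser", "CCCCCCCCCC")]
        call = cl.call_substrate_nn("AAADDDDDDD", refs, floor=6)
        assert call.confidence == "none"

    def test_invariant_to_panel_ordering(self, a_panel):
        rng = np.random.default_rng(0)
        query = mutate(class_ancestor("A", "Ser"), 0.1, rng)
        _, sig10 = cl.extract_signature(query)
        base = cl.call_substrate_nn(sig10, a_panel)
        for seed in range(5):
            shuffled = list(a_panel)
            np.random.default_rng(seed).shuffle(shuffled)
            assert cl.call_substrate_nn(sig10, shuffled) == base

    def test_score_monotone_under_matching_position_mutation(self):
        refs = [_sig_ref("Leu.r0", "Leu", "ACDEFGHIKL"),
                _sig_ref("Ser.r0", "Ser", "WWWWWWWWWW")]
        query = "ACDEFGHIKL"
        base = cl.call_substrate_nn(query, refs).score
        for pos in range(10):
            worse = query[:pos] + "M" + query[pos + 1:]
            assert cl.call_substrate_nn(worse, refs).score <= base

    def test_accuracy_on_three_class_panel(self):
        """>= 95% correct class over 200 seeded queries at 10% mutation."""
        labels = ["Leu", "Ser", "Glu"]
        panel = make_reference_panel("A", labels, 3, seed=41)
        rng = np.random.default_rng(17)
        correct = 0
        n = 200
        for k in range(n):
            truth = labels[k % 3]
            query = mutate(class_ancestor("A", truth), 0.10, rng)
            _, sig10 = cl.extract_signature(query)
            correct += cl.call_substrate_nn(sig10, panel).label == truth
        assert correct / n >= 0.95


class TestPlacement:
    def test_copy_of_reference_gets_its_label_at_near_zero_distance(
        self, a_panel
    ):
        ref = a_panel[0]
        call = cl.call_substrate_placement(ref.sequence, a_panel)
        assert call.label == ref.label
        assert call.score == pytest.approx(0.0, abs=1e-6)

    def test_agreement_with_nn_on_seeded_queries(self):
        """Placement agrees with NN on >= 90% of 200 queries at 10%."""
        labels = ["Leu", "Ser", "Glu"]
        panel = make_reference_panel("A", labels, 3, seed=41)
        rng = np.random.default_rng(23)
        agree = 0
        n = 200
        for k in range(n):
            truth = labels[k % 3]
            query = mutate(class_ancestor("A", truth), 0.10, rng)
            _, sig10 = cl.extract_signature(query)
            nn = cl.call_substrate_nn(sig10, panel)
            pl = cl.call_substrate_placement(query, panel)
            agree += nn.label == pl.label
        assert agree / n >= 0.90

    def test_imported_tree_equals_internal_tree(self, a_panel):
        rng = np.random.default_rng(4)
        query = mutate(class_ancestor("A", "Leu"), 0.05, rng)
        internal = cl.call_substrate_placement(query, a_panel)
        aln = phylo.MultipleAlignment.from_pairs(
            [("@query", query)] + [(r.id, r.sequence) for r in a_panel]
        )
        tree = phylo.nj_tree(phylo.pairwise_distances(aln))
        imported = phylo.PhyloTree.from_newick(tree.to_newick())
        external = cl.call_substrate_placement(query, a_panel, tree=imported)
        assert external.label == internal.label
        assert external.score == pytest.approx(internal.score, abs=1e-9)

    def test_unalignable_query_is_error(self, a_panel):
        with pytest.raises(ValueError, match="not alignable"):
            cl.call_substrate_placement("A" * 200, a_panel)

    def test_too_few_references_is_error(self, a_panel):
        with pytest.raises(ValueError, match=">= 3"):
            cl.call_substrate_placement(a_panel[0].sequence, a_panel[:2])


class TestCDomain:
    def test_copy_of_starter_reference_called_starter(self, c_panel):
        ref = next(r for r in c_panel if r.label == "starter")
        call = cl.classify_c_domain(ref.sequence, c_panel, position_in_line=1)
        assert call.subtype == "starter"
        assert call.starter_candidate

    def test_positional_starter_annotation_is_independent(self, c_panel):
        ref = next(r for r in c_panel if r.label == "dual")
        call = cl.classify_c_domain(ref.sequence, c_panel, position_in_line=5)
        assert call.subtype == "dual"
        assert not call.starter_candidate

    def test_accuracy_on_subtype_panels(self, c_panel):
        """>= 95% correct C subtype over 200 queries at 10% mutation."""
        labels = ["starter", "dual", "conventional"]
        rng = np.random.default_rng(31)
        correct = 0
        n = 200
        for k in range(n):
            truth = labels[k % 3]
            query = mutate(class_ancestor("C", truth), 0.10, rng)
            correct += (
                cl.classify_c_domain(query, c_panel, 2).subtype == truth
            )
        assert correct / n >= 0.95

    def test_missing_class_in_panel_is_error(self, c_panel):
        partial = [r for r in c_panel if r.label != "starter"]
        with pytest.raises(ValueError, match="starter"):
            cl.classify_c_domain(partial[0].sequence, partial, 1)


class TestTE:
    def test_copy_of_te2_reference(self, te_panel):
        ref = next(r for r in te_panel if r.label == "TE2")
        call = cl.classify_te(ref.sequence, te_panel, ordinal_in_tandem=1)
        assert call.subtype == "TE2"
        assert not call.ordinal_mismatch

    def test_ordinal_disagreement_is_flagged(self, te_panel):
        ref = next(r for r in te_panel if r.label == "TE2")
        call = cl.classify_te(ref.sequence, te_panel, ordinal_in_tandem=0)
        assert call.subtype == "TE2"
        assert call.ordinal_mismatch

    def test_accuracy_on_te_panels(self, te_panel):
        """>= 95% correct TE class over 200 queries at 10% mutation."""
        rng = np.random.default_rng(37)
        correct = 0
        n = 200
        for k in range(n):
            truth = "TE1" if k % 2 == 0 else "TE2"
            query = mutate(class_ancestor("TE", truth), 0.10, rng)
            correct += (
                cl.classify_te(query, te_panel, k % 2).subtype == truth
            )
        assert correct / n >= 0.95

    def test_tighter_te2_clustering_under_asymmetric_divergence(self):
        """Lower mean intra-class patristic distance detects the better
        conservation of the editing (TE2) domains."""
        te1 = make_reference_panel(
            "TE", ["TE1", "TE2"], 4, seed=71, ref_rate=0.15
        )
        refs = [r for r in te1 if r.label == "TE1"] + [
            r for r in make_reference_panel(
                "TE", ["TE1", "TE2"], 4, seed=72, ref_rate=0.03
            )
            if r.label == "TE2"
        ]
        aln = phylo.MultipleAlignment.from_pairs(
            [(r.id, r.sequence) for r in refs]
        )
        pat = phylo.patristic_distances(
            phylo.nj_tree(phylo.pairwise_distances(aln))
        )

        def mean_intra(label):
            ids = [r.id for r in refs if r.label == label]
            vals = [
                pat[(a, b)] for i, a in enumerate(ids) for b in ids[i + 1:]
            ]
            return float(np.mean(vals))

        assert mean_intra("TE2") < mean_intra("TE1")


class TestPanelIO:
    def test_round_trip(self, tmp_path, a_panel):
        tsv, fasta = tmp_path / "p.tsv", tmp_path / "p.fasta"
        cl.write_reference_panel(a_panel, tsv, fasta)
        back = cl.read_reference_panel(tsv, fasta)
        assert back == list(a_panel)

    def test_packaged_panel_is_complete(self, packaged_panel):
        kinds = {r.kind for r in packaged_panel}
        assert kinds == {"A", "C", "TE"}
        assert {r.label for r in packaged_panel if r.kind == "C"} == {
            "starter", "dual", "conventional"
        }
        assert all(
            r.signature_10 for r in packaged_panel if r.kind == "A"
        )
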