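import itertools

import numpy as np
import pytest

from denovopop.io_formats import FormatError, SequenceRecord
from denovopop.orf_evolution import (
    BranchEvent,
    EventKind,
    HomologyHit,
    OrthologAlignment,
    annotate_branch_events,
    count_events,
    filter_homology_hits,
    reconstruct_ancestor_parsimony,
    scan_tsd,
)


def aln(seqs: dict[str, str], ref="ref", frame_offset=0):
    return OrthologAlignment(
        [SequenceRecord(k, v) for k, v in seqs.items()], ref, frame_offset
    )


QUARTET_TREE = "((a,b)anc,out);"


class TestAlignmentValidation:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(FormatError):
            aln({"ref": "ATGAAA", "x": "ATG"})

    def test_fractional_reference_codons_rejected(self):
        with pytest.raises(FormatError):
            aln({"ref": "ATGA", "x": "ATGA"})

    def test_reference_codon_columns_skip_gaps(self):
        a = aln({"ref": "AT--GAAA", "x": "ATCCGAAA"})
        assert a.reference_codon_columns() == [[0, 1, 4], [5, 6, 7]]


class TestParsimonyAncestor:
    def test_identical_sequences(self):
        a = aln({"a": "ATG", "b": "ATG", "out": "ATG", "ref": "ATG"})
        anc = reconstruct_ancestor_parsimony(
            a, "((a,b)anc,(out,ref));", "out"
        )
        assert anc.seq == "ATG"

    def test_unanimous_ingroup_beats_outgroup(self):
        a = aln({"a": "AAA", "b": "AAA", "out": "GAA"}, ref="a")
        anc = reconstruct_ancestor_parsimony(a, QUARTET_TREE, "out")
        assert anc.seq[0] == "A"

    def test_outgroup_breaks_ingroup_tie(self):
        a = aln({"a": "AAA", "b": "GAA", "out": "GAA"}, ref="a")
        anc = reconstruct_ancestor_parsimony(a, QUARTET_TREE, "out")
        assert anc.seq[0] == "G"

    def test_reference_fallback_when_outgroup_not_parsimonious(self):
        a = aln({"a": "AAA", "b": "GAA", "out": "TAA"}, ref="a")
        anc = reconstruct_ancestor_parsimony(a, QUARTET_TREE, "out")
        assert anc.seq[0] == "A"  # reference state among {A, G}

    def test_missing_leaf_raises(self):
        a = aln({"a": "AAA", "b": "AAA"}, ref="a")
        with pytest.raises(ValueError):
            reconstruct_ancestor_parsimony(a, QUARTET_TREE, "out")

    def test_fewer_than_three_leaves_raises(self):
        a = aln({"a": "AAA", "out": "AAA"}, ref="a")
        with pytest.raises(ValueError):
            reconstruct_ancestor_parsimony(a, "(a,out);", "out")

    @pytest.mark.parametrize("tree,leaves", [
        (QUARTET_TREE, ["a", "b"]),
        ("((a,(b,c)),out);", ["a", "b", "c"]),
        ("(((a,b),c),out);", ["a", "b", "c"]),
    ])
    def test_matches_exhaustive_minimum_change_enumeration(self, tree, leaves):
        """Fitch root set equals the exhaustive MP enumeration on <=4 leaves."""
        rng = np.random.default_rng(17)
        states = "ACGT-"
        for _ in range(200):
            col = {leaf: states[rng.integers(5)] for leaf in leaves}
            out_state = states[rng.integers(5)]
            ref_state = col[leaves[0]]
            seqs = {leaf: col[leaf] * 3 for leaf in leaves}
            seqs["out"] = out_state * 3
            if set("".join(seqs.values())) == {"-"}:
                continue
            # guard: the reference needs a whole codon count after gap removal
            if ref_state == "-":
                continue
            a = aln(seqs, ref=leaves[0])
            got = reconstruct_ancestor_parsimony(a, tree, "out").seq[0]
            mp_states = _mp_root_states(tree, leaves, col)
            assert got in mp_states
            if out_state in mp_states:
                assert got == out_state
            elif ref_state in mp_states:
                assert got == ref_state


def _mp_root_states(tree, leaves, col):
    """Enumerate all internal labelings of the ingroup topology; return the
    set of root states achieving the minimum number of changes."""
    topologies = {
        QUARTET_TREE: [("root", ["a", "b"])],
        "((a,(b,c)),out);": [("root", ["a", "n1"]), ("n1", ["b", "c"])],
        "(((a,b),c),out);": [("root", ["n1", "c"]), ("n1", ["a", "b"])],
    }
    internals = [name for name, _ in topologies[tree]]
    children = dict(topologies[tree])
    best_cost, best_states = None, set()
    for assignment in itertools.product("ACGT-", repeat=len(internals)):
        state = dict(zip(internals, assignment))
        state.update(col)
        cost = 0
        for parent, kids in children.items():
            for kid in kids:
                cost += state[parent] != state[kid]
        if best_cost is None or cost < best_cost:
            best_cost, best_states = cost, {state["root"]}
        elif cost == best_cost:
            best_states.add(state["root"])
    return best_states


class TestBranchEvents:
    def pair(self, parent_seq, child_seq, ref_seq=None):
        ref_seq = ref_seq or parent_seq
        a = aln({"ref": ref_seq, "p": parent_seq, "c": child_seq})
        return a.get("p"), a.get("c"), a

    @pytest.mark.parametrize(
        "parent,child,kind",
        [
            ("AAA", "AAG", EventKind.SYN),
            ("AAA", "GAA", EventKind.NONSYN),
            ("TGG", "TGA", EventKind.STOP_GAIN),
            ("TGA", "TGG", EventKind.STOP_LOSS),
        ],
    )
    def test_single_codon_substitutions(self, parent, child, kind):
        p, c, a = self.pair("ATG" + parent + "TAA", "ATG" + child + "TAA")
        (event,) = annotate_branch_events(p, c, a)
        assert event.kind is kind and event.codon_index == 1

    def test_start_codon_destruction(self):
        p, c, a = self.pair("ATGAAATAA", "ATAAAATAA")
        (event,) = annotate_branch_events(p, c, a)
        assert event.kind is EventKind.START_LOST and event.codon_index == 0

    def test_identity_yields_no_events(self):
        p, c, a = self.pair("ATGAAATAA", "ATGAAATAA")
        assert annotate_branch_events(p, c, a) == []

    def test_insertion_run_grouped(self):
        p, c, a = self.pair("AAA---GGG", "AAACCCGGG", ref_seq="AAACCCGGG")
        (event,) = annotate_branch_events(p, c, a)
        assert event.kind is EventKind.INS and event.column_span == (3, 6)

    def test_deletion_run_grouped(self):
        p, c, a = self.pair("AAACCCGGG", "AAA---GGG", ref_seq="AAACCCGGG")
        (event,) = annotate_branch_events(p, c, a)
        assert event.kind is EventKind.DEL and event.column_span == (3, 6)

    def test_adjacent_ins_and_del_not_merged(self):
        p, c, a = self.pair("AAA---CCCGGG", "AAATTT---GGG", ref_seq="AAATTTCCCGGG")
        events = annotate_branch_events(p, c, a)
        assert [e.kind for e in events] == [EventKind.INS, EventKind.DEL]

    def test_reference_gap_column_has_na_codon(self):
        a = aln({"ref": "ATG---AAATAA", "p": "ATGCCCAAATAA", "c": "ATGCTCAAATAA"})
        (event,) = annotate_branch_events(a.get("p"), a.get("c"), a)
        assert event.codon_index is None and event.kind is EventKind.UNFRAMED

    def test_multi_hit_codon_flagged_per_site(self):
        p, c, a = self.pair("ATGAAATAA", "ATGGGATAA")
        events = annotate_branch_events(p, c, a)
        assert len(events) == 2 and all(e.multi_hit for e in events)

    def test_multi_hit_per_codon_mode_joint_classification(self):
        p, c, a = self.pair("ATGAAATAA", "ATGTAATAA"[:3] + "TGA" + "TAA")
        # parent codon AAA -> child TGA: joint change is a stop gain
        events = annotate_branch_events(p, c, a, multi_hit="per-codon")
        (event,) = events
        assert event.kind is EventKind.STOP_GAIN and event.multi_hit

    def test_syn_nonsyn_count_identity(self):
        """SYN+NONSYN events equal substituted in-frame columns minus
        stop-affecting and start-affecting ones."""
        rng = np.random.default_rng(23)
        from denovopop.synthetic_data import SAFE_CODONS

        for _ in range(50):
            n = 20
            parent = "ATG" + "".join(rng.choice(SAFE_CODONS, n)) + "TAA"
            child = list(parent)
            sub_cols = rng.choice(len(parent), size=5, replace=False)
            for col in sub_cols:
                child[col] = "ACGT"[rng.integers(4)]
            child = "".join(child)
            p, c, a = self.pair(parent, child)
            events = annotate_branch_events(p, c, a)
            counts = count_events(events)
            n_changed = sum(x != y for x, y in zip(parent, child))
            total = sum(
                counts[k] for k in
                ("SYN", "NONSYN", "STOP_GAIN", "STOP_LOSS", "START_LOST")
            )
            assert total == n_changed


class TestTsdScan:
    def test_planted_distance_167(self):
        rng = np.random.default_rng(1)
        motif = "CATGGC"
        upstream = "".join(rng.choice(list("ACGT"), 300))
        # plant so the motif 3' end sits 167 bp upstream of the ATG
        start = 300
        i = start - 167 + 1 - len(motif)
        flank = upstream[:i] + motif + upstream[i + len(motif):] + "ATGAAA"
        hits = [h for h in scan_tsd(SequenceRecord("f", flank), motif, start)
                if h.mismatches == 0]
        assert any(h.distance_upstream == 167 for h in hits)

    def test_motif_abutting_start_codon_is_1bp_upstream(self):
        flank = "TTTT" + "CATGGC" + "ATGAAA"
        (hit,) = scan_tsd(SequenceRecord("f", flank), "CATGGC", 10)
        assert hit.distance_upstream == 1

    def test_absent_motif_empty(self):
        assert scan_tsd(SequenceRecord("f", "AAAATTTTATG"), "CATGGC", 8) == []

    def test_two_hits_in_order(self):
        flank = "CATGGC" + "TT" + "CATGGC" + "TTTT" + "ATG"
        hits = scan_tsd(SequenceRecord("f", flank), "CATGGC", 18)
        assert [h.start for h in hits] == [0, 8]
        assert hits[0].distance_upstream > hits[1].distance_upstream

    def test_mismatch_tolerance(self):
        flank = "CATGAC" + "ATG"
        assert scan_tsd(SequenceRecord("f", flank), "CATGGC", 6) == []
        (hit,) = scan_tsd(SequenceRecord("f", flank), "CATGGC", 6, max_mismatches=1)
        assert hit.mismatches == 1


class TestHomologyFilter:
    def hit(self, identity, qcov, evalue):
        return HomologyHit("q", "s", identity, 100, evalue, qcov)

    @pytest.mark.parametrize(
        "identity,qcov,evalue,kept",
        [
            (59.9, 80.0, 1e-10, False),   # identity below 60
            (60.0, 70.0, 1e-5, True),     # all bounds inclusive
            (95.0, 90.0, 1e-4, False),    # e-value too large
            (95.0, 69.9, 1e-10, False),   # coverage below 70
            (80.0, 80.0, 0.0, True),
        ],
    )
    def test_thresholds(self, identity, qcov, evalue, kept):
        out = filter_homology_hits([self.hit(identity, qcov, evalue)])
        assert (len(out) == 1) is kept

    def test_malformed_hit_rejected(self):
        out = filter_homology_hits([self.hit(-5.0, 80.0, 1e-10)])
        assert out == []
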