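"""Pass rules, scores and ancestral states of the inapplicable-aware
algorithm."""

import itertools

import pytest

from inappfitch import (Alphabet, ancestral_states, column_from_tokens,
                        fitch_missing_length, random_tree, score_character,
                        score_matrix)
from inappfitch.baselines import fitch_sets, missing_masks
from inappfitch.datasets import two_region_example, worked_example
from inappfitch.errors import DataError, StructureError
from inappfitch.inapplicable_fitch import (down1, down2, first_downpass,
                                           first_uppass, resolve_tips,
                                           up2)
from inappfitch.statesets import Matrix, matrix_from_rows
from inappfitch.trees import all_rootings, parse_newick

ALPHA = Alphabet(("0", "1"))
INAPP = ALPHA.inapplicable_bit
FULL = ALPHA.full_applicable


def mask(*symbols):
    m = 0
    for s in symbols:
        m |= ALPHA.bit(s)
    return m


class TestFirstDownpass:
    """Node-local rules, one per published worked case."""

    @pytest.mark.parametrize("left,right,expected", [
        (mask("1", "-"), mask("0"), mask("0", "1")),   # both applicable
        (mask("-"), mask("0", "-"), mask("-")),        # inapplicable wins
        (mask("-"), mask("1"), mask("1", "-")),        # undecidable: union
        (mask("0", "-"), mask("1", "-"), mask("0", "1", "-")),
        (mask("0", "-"), mask("0"), mask("0")),        # shared: intersection
    ])
    def test_rules(self, left, right, expected):
        assert down1(left, right, INAPP, FULL) == expected

    def test_rules_are_total(self):
        """Every pair of nonempty child sets yields a nonempty set."""
        for l, r in itertools.product(range(1, 8), repeat=2):
            assert down1(l, r, INAPP, FULL) != 0


class TestFirstUppass:
    def test_mixed_node_with_applicable_ancestor(self):
        # (A,B) has prelim {0,-}; the root is applicable -> node applicable
        tree = parse_newick("((A,B),(C,D));")
        col = column_from_tokens(list("ABCD"), ["0", "-", "0", "0"])
        prelim = first_downpass(tree, col)
        upset, flag = first_uppass(tree, col, prelim)
        node = tree.root.children[0]
        assert flag[node] and upset[node] == mask("0")

    def test_inapplicable_singleton_stays_inapplicable(self):
        tree, col = two_region_example()
        prelim = first_downpass(tree, col)
        upset, flag = first_uppass(tree, col, prelim)
        for v in tree.preorder():
            if not v.is_leaf:
                assert not flag[v]  # every internal vertex lacks the feature

    def test_root_convention_prefers_presence(self):
        # root prelim {0,1,-}: phantom ancestor applicable -> {0,1}
        tree = parse_newick("((A,B),(C,D));")
        col = column_from_tokens(list("ABCD"), ["0", "-", "1", "-"])
        prelim = first_downpass(tree, col)
        assert prelim[tree.root] == mask("0", "1", "-")
        upset, flag = first_uppass(tree, col, prelim)
        assert flag[tree.root] and upset[tree.root] == mask("0", "1")


class TestResolveTips:
    def test_ambiguous_tip_follows_parent(self):
        tree = parse_newick("((A,B),(C,D));")
        col = column_from_tokens(list("ABCD"), ["01-", "0", "1", "0"])
        tip = tree.root.children[0].children[0]
        applicable = resolve_tips(tree, col, {tip.parent: True})
        assert applicable[tip] == mask("0", "1")
        inapplicable = resolve_tips(tree, col, {tip.parent: False})
        assert inapplicable[tip] == mask("-")

    def test_unambiguous_tip_unchanged(self):
        tree = parse_newick("((A,B),(C,D));")
        col = column_from_tokens(list("ABCD"), ["0", "0", "1", "0"])
        resolved = resolve_tips(tree, col, {})
        assert all(resolved[v] == col.mask(v.label) for v in tree.leaves())


class TestSecondDownpass:
    @pytest.mark.parametrize(
        "applicable,lw,rw,lt,rt,expected,dstep,dregion", [
            (True, mask("0"), mask("0", "1"), True, True, mask("0"), 0, 0),
            (True, mask("0"), mask("1"), True, True, mask("0", "1"), 1, 0),
            (False, mask("-"), mask("-"), True, True, mask("-"), 0, 1),
            (True, mask("0"), mask("-"), True, True, mask("0"), 0, 1),
            (True, mask("0"), mask("-"), True, False, mask("0"), 0, 0),
        ])
    def test_rules(self, applicable, lw, rw, lt, rt, expected, dstep,
                   dregion):
        got, step, region = down2(applicable, lw, rw, lt, rt, 0, INAPP, FULL)
        assert (got, step, region) == (expected, dstep, dregion)


class TestSecondUppass:
    def test_inapplicable_ancestor_keeps_working_set(self):
        # subtree root below an inapplicable vertex: state is final
        tree = parse_newick("(((A,B),C),((D,E),(F,G)));")
        col = column_from_tokens("ABCDEFG",
                                 ["0", "1", "-", "-", "-", "-", "-"])
        rec = ancestral_states(tree, col)
        node = tree.root.children[0].children[0]  # (A,B)
        assert rec.final[node] == mask("0", "1")
        assert rec.final[tree.root] == mask("-")

    def test_shared_states_are_kept(self):
        assert up2(mask("0", "1"), mask("0"), mask("0"), mask("1"),
                   INAPP, FULL) == mask("0")

    def test_ancestor_states_added_across_inapplicable_child(self):
        assert up2(mask("0"), mask("1"), mask("0"), mask("-"),
                   INAPP, FULL) == mask("0", "1")


class TestScoreCharacter:
    def test_plain_fitch_column(self):
        tree = parse_newick("((A,B),(C,D));")
        col = column_from_tokens(list("ABCD"), ["0", "1", "0", "1"])
        b = score_character(tree, col)
        assert (b.steps, b.extra_regions, b.total) == (2, 0, 2)

    def test_all_inapplicable_scores_zero(self):
        tree = parse_newick("((A,B),(C,D));")
        col = column_from_tokens(list("ABCD"), ["-"] * 4,
                                 Alphabet(("0",)))
        assert score_character(tree, col).total == 0

    def test_two_separated_regions(self):
        tree, col = two_region_example()
        b = score_character(tree, col)
        assert (b.steps, b.extra_regions) == (0, 1)

    def test_worked_example_contributes_two(self):
        tree, col = worked_example()
        b = score_character(tree, col)
        assert (b.steps, b.extra_regions, b.total) == (1, 1, 2)

    def test_polytomy_rejected(self):
        tree = parse_newick("(A,B,C,D);")
        col = column_from_tokens(list("ABCD"), ["0", "1", "-", "-"])
        with pytest.raises(StructureError):
            score_character(tree, col)

    def test_missing_taxon_rejected(self):
        tree = parse_newick("((A,B),(C,D));")
        col = column_from_tokens(list("ABCE"), ["0", "1", "0", "1"])
        with pytest.raises(DataError):
            score_character(tree, col)


class TestScoreMatrix:
    def test_additivity(self, rng):
        tree = parse_newick("((A,B),(C,D));")
        mat = matrix_from_rows(list("ABCD"), ["01", "10", "01", "11"])
        total, breakdowns = score_matrix(tree, mat)
        assert total == sum(b.total for b in breakdowns)
        doubled = Matrix(mat.taxa, mat.columns + mat.columns)
        assert score_matrix(tree, doubled)[0] == 2 * total

    def test_tail_matrix_additivity(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        rows = ["0--0", "0--0", "0--0", "1011", "1000", "1111", "1200",
                "1???"]
        mat = matrix_from_rows(taxa, rows)
        tree = random_tree(taxa, rng)
        total, breakdowns = score_matrix(tree, mat)
        assert total == sum(score_character(tree, c).total
                            for c in mat.columns)

    def test_weights(self):
        tree = parse_newick("((A,B),(C,D));")
        mat = matrix_from_rows(list("ABCD"), ["01", "10", "01", "11"])
        unweighted, _ = score_matrix(tree, mat)
        weighted, _ = score_matrix(tree, mat, weights=[2, 2])
        assert weighted == 2 * unweighted


class TestAncestralStates:
    def test_matches_plain_fitch_without_gaps(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 10))
            labels = [f"x{i}" for i in range(n)]
            tree = random_tree(labels, rng)
            toks = [str(rng.choice(["0", "1", "2"])) for _ in range(n)]
            col = column_from_tokens(labels, toks)
            rec = ancestral_states(tree, col)
            _, final, length = fitch_sets(tree, missing_masks(col))
            assert rec.breakdown.total == length
            assert all(rec.final[v] == final[v] for v in tree.postorder())

    def test_all_inapplicable(self):
        tree = parse_newick("((A,B),(C,D));")
        col = column_from_tokens(list("ABCD"), ["-"] * 4, Alphabet(("0",)))
        rec = ancestral_states(tree, col)
        # gaps are treated as missing below the inapplicable threshold:
        # reconstruction is the single applicable state everywhere
        assert rec.breakdown.total == 0

    def test_fourth_pass_never_changes_score(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 11))
            labels = [f"x{i}" for i in range(n)]
            tree = random_tree(labels, rng)
            toks = [str(rng.choice(["0", "1", "-", "-", "?"]))
                    for _ in range(n)]
            col = column_from_tokens(labels, toks)
            assert ancestral_states(tree, col).breakdown == \
                score_character(tree, col)

    def test_final_sets_pure(self, rng):
        tree, col = worked_example()
        rec = ancestral_states(tree, col)
        inapp = rec.column.alphabet.inapplicable_bit
        for v in tree.postorder():
            m = rec.final[v]
            assert m == inapp or not (m & inapp)


class TestProperties:
    def test_fitch_equivalence_without_inapplicable(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 15))
            labels = [f"x{i}" for i in range(n)]
            tree = random_tree(labels, rng)
            toks = [str(rng.choice(["0", "1", "2", "?"])) for _ in range(n)]
            col = column_from_tokens(labels, toks)
            assert score_character(tree, col).total == \
                fitch_missing_length(tree, col)

    def test_threshold_below_three_inapplicable(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 12))
            labels = [f"x{i}" for i in range(n)]
            tree = random_tree(labels, rng)
            toks = [str(rng.choice(["0", "1"])) for _ in range(n)]
            for i in rng.choice(n, size=int(rng.integers(0, 3)),
                                replace=False):
                toks[i] = "-"
            col = column_from_tokens(labels, toks)
            assert col.n_inapplicable <= 2
            assert score_character(tree, col).total == \
                fitch_missing_length(tree, col)

    def test_rooting_invariance(self, rng):
        checked = 0
        while checked < 30:
            n = int(rng.integers(6, 11))
            labels = [f"x{i}" for i in range(n)]
            tree = random_tree(labels, rng)
            toks = [str(rng.choice(["0", "1", "-", "-", "?"]))
                    for _ in range(n)]
            col = column_from_tokens(labels, toks)
            if col.n_inapplicable < 3:
                continue
            checked += 1
            totals = {score_character(r, col).total
                      for r in all_rootings(tree)}
            assert len(totals) == 1

    def test_invariant_character_with_regions_informs(self):
        """A single applicable state split into separated regions costs:
        an invariant character with inapplicability still informs search."""
        tree, col = two_region_example()
        b = score_character(tree, col)
        assert (b.steps, b.extra_regions) == (0, 1)
        # three single-tip regions separated by inapplicable clades
        tree3 = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        col3 = column_from_tokens(
            list("ABCDEFGH"), ["0", "-", "0", "-", "-", "-", "0", "-"])
        b3 = score_character(tree3, col3)
        assert (b3.steps, b3.extra_regions) == (0, 2)
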