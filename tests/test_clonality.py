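import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonomark import (
    ClonalityLabel,
    NoDominantPairError,
    admit_cells,
    assign_clonality,
    clonality_fractions,
    dominant_pair,
)

from .conftest import make_cell, random_repertoire
from .oracles import brute_force_clonality


class TestAdmitCells:
    def test_cd8_and_chainless_cells_are_dropped(self):
        cells = [
            make_cell("c1", alphas=["a1"], betas=["b1"], cd8=True),
            make_cell("c2"),  # no chains
            make_cell("c3", betas=["b2"]),
        ]
        kept = admit_cells(cells)
        assert [c.cell_id for c in kept] == ["c3"]
        assert len(cells) == 3  # input untouched

    def test_empty_input(self):
        assert admit_cells([]) == []

    def test_counts_on_mixed_fixture(self):
        cells = [make_cell(f"c{i}", alphas=[f"a{i}"]) for i in range(7)]
        cells += [make_cell("x1", alphas=["a9"], cd8=True),
                  make_cell("x2", betas=["b9"], cd8=True),
                  make_cell("x3")]
        assert len(admit_cells(cells)) == 7


class TestDominantPair:
    def test_majority_pair_wins(self):
        cells = [make_cell(f"c{i}", alphas=["a1"], betas=["b1"]) for i in range(6)]
        cells += [make_cell(f"d{i}", alphas=["a2"], betas=["b2"]) for i in range(2)]
        assert dominant_pair(cells) == ("a1", "b1")

    def test_single_cell(self):
        assert dominant_pair([make_cell("c", alphas=["a1"], betas=["b1"])]) == ("a1", "b1")

    def test_no_paired_cell_raises(self):
        with pytest.raises(NoDominantPairError):
            dominant_pair([make_cell("c", alphas=["a1"])])

    def test_tie_broken_by_single_chain_support_then_lexicographic(self):
        # 3 cells each for (a1,b1) and (a2,b2); one extra single-chain a2 cell
        cells = [make_cell(f"c{i}", alphas=["a1"], betas=["b1"]) for i in range(3)]
        cells += [make_cell(f"d{i}", alphas=["a2"], betas=["b2"]) for i in range(3)]
        cells += [make_cell("s", alphas=["a2"])]
        assert dominant_pair(cells) == ("a2", "b2")
        # pure tie falls back to the lexicographically smallest pair
        cells_tied = cells[:-1]
        assert dominant_pair(cells_tied) == ("a1", "b1")

    def test_multi_recombinant_cell_contributes_every_pair(self):
        cells = [
            make_cell("c1", alphas=["a1", "a2"], betas=["b1"]),
            make_cell("c2", alphas=["a2"], betas=["b1"]),
        ]
        # (a2,b1) occurs in both cells, (a1,b1) in one
        assert dominant_pair(cells) == ("a2", "b1")


class TestAssignClonality:
    def test_worked_pattern(self):
        """The canonical per-donor pattern: a1/b1 main clone, a2-via-b1
        related cell, one duplicated bystander pair, one singleton."""
        cells = (
            [make_cell(f"m{i}", alphas=["a1"], betas=["b1"]) for i in range(4)]
            + [make_cell("m4", alphas=["a1"], betas=["b2"]),
               make_cell("m5", alphas=["a2"], betas=["b1"]),
               make_cell("r0", alphas=["a2"], betas=["b3"]),
               make_cell("g0", alphas=["a5"], betas=["b9"]),
               make_cell("g1", alphas=["a5"], betas=["b9"]),
               make_cell("s0", alphas=["a7"], betas=["b8"])]
        )
        by_label = {}
        for a in assign_clonality(cells):
            by_label.setdefault(a.label, set()).add(a.cell_id)
        assert by_label[ClonalityLabel.MAIN_CLONE] == {"m0", "m1", "m2", "m3", "m4", "m5"}
        assert by_label[ClonalityLabel.RELATED_TO_MAIN_CLONE] == {"r0"}
        assert by_label[ClonalityLabel.BYSTANDER_GROUP] == {"g0", "g1"}
        assert by_label[ClonalityLabel.SINGLE_BYSTANDER] == {"s0"}
        for a in assign_clonality(cells):
            assert a.malignancy_target == int(
                a.label in (ClonalityLabel.MAIN_CLONE, ClonalityLabel.RELATED_TO_MAIN_CLONE)
            )
            assert (a.dominant_alpha, a.dominant_beta) == ("a1", "b1")

    def test_lone_cell_is_single_bystander(self):
        [a] = assign_clonality([make_cell("c", alphas=["a1"], betas=["b1"])])
        # a lone paired cell constitutes the main clone of its donor
        assert a.label is ClonalityLabel.MAIN_CLONE
        [b] = assign_clonality([make_cell("c", alphas=["a1"])])
        assert b.label is ClonalityLabel.SINGLE_BYSTANDER

    def test_no_dominant_pair_falls_back_to_bystander_rules(self):
        cells = [
            make_cell("c1", alphas=["a1"]),
            make_cell("c2", alphas=["a1"]),
            make_cell("c3", betas=["b7"]),
        ]
        labels = {a.cell_id: a.label for a in assign_clonality(cells)}
        assert labels["c1"] is ClonalityLabel.BYSTANDER_GROUP
        assert labels["c2"] is ClonalityLabel.BYSTANDER_GROUP
        assert labels["c3"] is ClonalityLabel.SINGLE_BYSTANDER

    def test_matches_brute_force_on_random_repertoires(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            cells = random_repertoire(rng, int(rng.integers(10, 31)))
            expected = brute_force_clonality(cells)
            got = {a.cell_id: a.label.value for a in assign_clonality(cells)}
            assert got == expected

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        cells = random_repertoire(rng, 25)
        ref = {a.cell_id: a.label for a in assign_clonality(cells)}
        for _ in range(5):
            perm = [cells[i] for i in rng.permutation(len(cells))]
            assert {a.cell_id: a.label for a in assign_clonality(perm)} == ref

    def test_one_step_association_is_narrower(self):
        # chain c links to the dominant component only through depth 2
        cells = (
            [make_cell(f"m{i}", alphas=["a1"], betas=["b1"]) for i in range(3)]
            + [make_cell("m3", alphas=["a2"], betas=["b1"]),
               make_cell("r1", alphas=["a2"], betas=["b5"]),
               make_cell("r2", alphas=["a9"], betas=["b5"])]
        )
        transitive = {a.cell_id: a.label for a in assign_clonality(cells)}
        assert transitive["r2"] is ClonalityLabel.RELATED_TO_MAIN_CLONE
        one_step = {
            a.cell_id: a.label
            for a in assign_clonality(cells, transitive_association=False)
        }
        assert one_step["r1"] is ClonalityLabel.RELATED_TO_MAIN_CLONE
        assert one_step["r2"] is not ClonalityLabel.RELATED_TO_MAIN_CLONE

    def test_donors_processed_independently(self):
        d1 = [make_cell(f"x{i}", donor="d1", alphas=["a1"], betas=["b1"]) for i in range(3)]
        d2 = [make_cell("y0", donor="d2", alphas=["a1"], betas=["b1"])]
        d2 += [make_cell(f"y{i}", donor="d2", alphas=["a9"], betas=["b9"]) for i in (1, 2)]
        labels = {a.cell_id: a.label for a in assign_clonality(d1 + d2)}
        # (a1,b1) is dominant in d1 but not in d2
        assert labels["x0"] is ClonalityLabel.MAIN_CLONE
        assert labels["y1"] is ClonalityLabel.MAIN_CLONE
        assert labels["y0"] is ClonalityLabel.SINGLE_BYSTANDER

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 30))
    def test_partition_property(self, seed, n_cells):
        """Every admitted cell gets exactly one non-excluded label and the
        main clone always carries a dominant chain."""
        rng = np.random.default_rng(seed)
        cells = random_repertoire(rng, n_cells)
        assignments = assign_clonality(cells)
        assert len(assignments) == len(cells)
        assert {a.cell_id for a in assignments} == {c.cell_id for c in cells}
        lookup = {c.cell_id: c for c in cells}
        for a in assignments:
            assert a.label is not ClonalityLabel.EXCLUDED
            if a.label is ClonalityLabel.MAIN_CLONE:
                c = lookup[a.cell_id]
                assert a.dominant_alpha in c.alpha_set or a.dominant_beta in c.beta_set


class TestClonalityFractions:
    def test_hand_counts(self):
        cells = (
            [make_cell(f"m{i}", alphas=["a1"], betas=["b1"]) for i in range(4)]
            + [make_cell("m4", alphas=["a2"], betas=["b1"]),
               make_cell("r0", alphas=["a2"], betas=["b9"]),
               make_cell("g0", alphas=["a5"], betas=["b5"]),
               make_cell("g1", alphas=["a5"], betas=["b5"]),
               make_cell("s0", alphas=["a6"], betas=["b6"])]
        )
        fracs = clonality_fractions(assign_clonality(cells))
        assert fracs[ClonalityLabel.MAIN_CLONE] == pytest.approx(5 / 9)
        assert fracs[ClonalityLabel.RELATED_TO_MAIN_CLONE] == pytest.approx(1 / 9)
        assert fracs[ClonalityLabel.BYSTANDER_GROUP] == pytest.approx(2 / 9)
        assert fracs[ClonalityLabel.SINGLE_BYSTANDER] == pytest.approx(1 / 9)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_main_clone(self):
        cells = [make_cell(f"m{i}", alphas=["a1"], betas=["b1"]) for i in range(5)]
        fracs = clonality_fractions(assign_clonality(cells))
        assert fracs[ClonalityLabel.MAIN_CLONE] == 1.0
        assert sum(fracs.values()) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            clonality_fractions([])
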