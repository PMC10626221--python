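"""Perfect-phylogeny checking, clone-tree inference, template mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemaseq.datasets import case_character_matrix
from hemaseq.lineage import (CharacterMatrix, check_perfect_phylogeny,
                             infer_clone_tree, load_template, map_to_template)


def matrix_from_rows(rows: dict[str, list[str]], chars: list[str],
                     cell_types=None) -> CharacterMatrix:
    df = pd.DataFrame([[1 if c in v else 0 for c in chars] for v in rows.values()],
                      index=list(rows), columns=chars)
    return CharacterMatrix(matrix=df, cell_types=cell_types or {})


def chain_oracle(df: pd.DataFrame) -> bool:
    """Independent laminarity oracle: for every population the supports of
    its carried characters must form a containment chain."""
    supports = {c: frozenset(df.index[df[c] == 1]) for c in df.columns}
    for pop in df.index:
        carried = [supports[c] for c in df.columns if df.loc[pop, c] == 1]
        for s1, s2 in itertools.combinations(carried, 2):
            if not (s1 <= s2 or s2 <= s1):
                return False
    return True


class TestCheckPerfectPhylogeny:
    def test_nested_and_disjoint_rows_compatible(self):
        rows = {"p1": list("ABC"), "p2": list("ABD"), "p3": list("AEF"),
                "p4": list("AE")}
        m = matrix_from_rows(rows, list("ABCDEF"))
        assert check_perfect_phylogeny(m) == "compatible"

    def test_crossing_supports_conflict(self):
        rows = {"p1": ["X"], "p2": ["Y"], "p3": ["X", "Y"]}
        m = matrix_from_rows(rows, ["X", "Y"])
        assert check_perfect_phylogeny(m) == [("X", "Y")]

    def test_single_row_compatible(self):
        m = matrix_from_rows({"p": ["A", "B"]}, ["A", "B"])
        assert check_perfect_phylogeny(m) == "compatible"


class TestInferCloneTree:
    def test_case_matrix_root_shared_edge_is_exactly_A(self):
        tree = infer_clone_tree(case_character_matrix())
        neoplastic = {"nPC_ABC1", "nPC_ABD2", "MB_AEF3", "MB_AE"}
        # the deepest edge ancestral to all four neoplastic populations
        shared = frozenset.intersection(
            *(tree.path_characters(p) for p in neoplastic))
        # A alone separates the neoplastic clade from the root
        node_a = next(n for n in tree.iter_nodes() if "A" in n.characters)
        assert node_a.characters == ("A",)
        assert "A" in shared
        b_or_e = {c for p in neoplastic for c in tree.path_characters(p)} - shared
        assert "B" in b_or_e and "E" in b_or_e

    def test_single_population_chain_merges_equal_supports(self):
        m = matrix_from_rows({"p": ["A", "B"]}, ["A", "B"])
        tree = infer_clone_tree(m)
        [child] = tree.root.children
        assert child.characters == ("A", "B")
        assert child.populations == ["p"]

    def test_row_reconstruction_on_random_laminar_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            # build a laminar family by random recursive splitting
            pops = [f"p{i}" for i in range(rng.integers(3, 8))]
            chars: dict[str, set] = {}

            def split(group, depth=0):
                label = f"c{len(chars)}"
                chars[label] = set(group)
                if len(group) > 1 and depth < 4 and rng.random() < 0.8:
                    cut = rng.integers(1, len(group))
                    split(group[:cut], depth + 1)
                    split(group[cut:], depth + 1)

            split(pops)
            df = pd.DataFrame(
                [[1 if p in members else 0 for c, members in chars.items()]
                 for p in pops], index=pops, columns=list(chars))
            m = CharacterMatrix(matrix=df)
            tree = infer_clone_tree(m)
            for p in pops:
                assert tree.path_characters(p) == m.row_set(p)

    def test_incompatible_matrix_raises_with_conflicts(self):
        m = matrix_from_rows({"p1": ["X"], "p2": ["Y"], "p3": ["X", "Y"]},
                             ["X", "Y"])
        with pytest.raises(ValueError, match="conflicting"):
            infer_clone_tree(m)

    def test_newick_is_parseable_and_has_all_populations(self):
        import skbio

        tree = infer_clone_tree(case_character_matrix())
        t = skbio.TreeNode.read([tree.to_newick()])
        tips = {tip.name for tip in t.tips()}
        assert set(case_character_matrix().matrix.index) <= tips


class TestOracleAgreement:
    def test_exhaustive_small_matrices(self):
        """Pairwise laminar test vs the per-row chain oracle vs tree building,
        on every 0/1 matrix with at most 9 cells (no empty characters)."""
        checked = 0
        for r, c in [(1, 1), (2, 2), (2, 3), (3, 2), (3, 3), (2, 4), (4, 2)]:
            pops = [f"p{i}" for i in range(r)]
            chars = [f"c{j}" for j in range(c)]
            for bits in itertools.product([0, 1], repeat=r * c):
                arr = np.array(bits).reshape(r, c)
                if (arr.sum(axis=0) == 0).any():
                    continue
                df = pd.DataFrame(arr, index=pops, columns=chars)
                m = CharacterMatrix(matrix=df)
                compat = check_perfect_phylogeny(m) == "compatible"
                assert compat == chain_oracle(df)
                if compat:
                    tree = infer_clone_tree(m)
                    for p in pops:
                        assert tree.path_characters(p) == m.row_set(p)
                checked += 1
        assert checked > 500


class TestTemplateMapping:
    def test_shared_pc_mb_character_maps_to_lmpp(self):
        tree = map_to_template(infer_clone_tree(case_character_matrix()),
                               load_template("classical"))
        node_a = next(n for n in tree.iter_nodes() if n.characters == ("A",))
        assert node_a.template_assignment == "LMPP"

    def test_erythrocyte_private_character_below_mep(self):
        tree = map_to_template(infer_clone_tree(case_character_matrix()),
                               load_template("classical"))
        node_i = next(n for n in tree.iter_nodes() if n.characters == ("I",))
        assert "below MEP" in node_i.template_assignment

    def test_characterless_population_in_normal_lineage(self):
        tree = map_to_template(infer_clone_tree(case_character_matrix()),
                               load_template("classical"))
        assert "megakaryocyte" in tree.root.populations
        assert tree.root.template_assignment == "normal lineage"

    def test_mapping_never_alters_topology(self):
        plain = infer_clone_tree(case_character_matrix())
        before = plain.to_newick()
        map_to_template(plain, load_template("composite"))
        assert plain.to_newick() == before

    def test_adding_population_moves_assignment_rootward(self):
        rows = {"e1": ["X"]}
        m = matrix_from_rows(rows, ["X"], cell_types={"e1": "erythrocyte"})
        t1 = map_to_template(infer_clone_tree(m), load_template("classical"))
        a1 = next(n for n in t1.iter_nodes() if n.characters).template_assignment
        rows2 = {"e1": ["X"], "n1": ["X"]}
        m2 = matrix_from_rows(rows2, ["X"],
                              cell_types={"e1": "erythrocyte", "n1": "neutrophil"})
        t2 = map_to_template(infer_clone_tree(m2), load_template("classical"))
        a2 = next(n for n in t2.iter_nodes() if n.characters).template_assignment
        assert "below MEP" in a1
        assert a2 == "MPP"  # LCA of MEP and GMP descendants in the classical tree

    def test_unknown_cell_type_slot_rejected(self):
        template = load_template("classical")
        object.__setattr__(template, "leaf_slots",
                           {k: v for k, v in template.leaf_slots.items() if k != "PC"})
        with pytest.raises(ValueError, match="PC"):
            map_to_template(infer_clone_tree(case_character_matrix()), template)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2**20))
def test_random_matrices_agree_with_chain_oracle(seed):
    rng = np.random.default_rng(seed)
    r, c = int(rng.integers(2, 7)), int(rng.integers(2, 7))
    arr = (rng.random((r, c)) < 0.4).astype(int)
    if (arr.sum(axis=0) == 0).any():
        arr[0, arr.sum(axis=0) == 0] = 1
    df = pd.DataFrame(arr, index=[f"p{i}" for i in range(r)],
                      columns=[f"c{j}" for j in range(c)])
    m = CharacterMatrix(matrix=df)
    assert (check_perfect_phylogeny(m) == "compatible") == chain_oracle(df)
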