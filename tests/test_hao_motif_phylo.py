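"""Anchor mapping, profile alignment, motif calls, NJ trees, clades."""
import numpy as np
import pandas as pd
import pytest

from matncycle import (
    ReferenceAlignment,
    SimConfig,
    align_query_to_reference,
    assign_clade,
    classify_hao,
    classify_hao_sequences,
    generate_hao_proteins,
    load_packaged_reference,
    map_anchor_column,
    nj_tree,
    pdistance_matrix,
)

CLASS_TO_CALL = {"AOB-HAO": "oxidative-HAO-like", "epsilonHao": "epsilonHao-like"}


def refaln_of(rows, anchor_ref, anchor_pos, labels=None):
    return ReferenceAlignment(
        rows=rows,
        anchor_ref=anchor_ref,
        anchor_pos=anchor_pos,
        class_labels=labels or {rid: "AOB-HAO" for rid, _ in rows},
    )


class TestAnchorMapping:
    def test_ungapped_reference_identity(self):
        ref = refaln_of([("r", "ACDEF")], "r", 3)
        assert map_anchor_column(ref) == 3

    def test_single_gap_shifts_column(self):
        ref = refaln_of([("r", "AC-DE")], "r", 3)
        assert map_anchor_column(ref) == 4

    def test_position_beyond_sequence_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            map_anchor_column(refaln_of([("r", "AC-DE")], "r", 9))

    def test_matches_scan_and_count_oracle(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        for _ in range(300):
            row = "".join(rng.choice(aas, size=40))
            n_res = len(row.replace("-", ""))
            if n_res == 0:
                continue
            pos = int(rng.integers(1, n_res + 1))
            ref = refaln_of([("r", row)], "r", pos)
            col = map_anchor_column(ref)
            # oracle: linear scan counting non-gaps
            count = 0
            for c, res in enumerate(row, start=1):
                if res != "-":
                    count += 1
                if count == pos and res != "-":
                    assert col == c
                    break

    def test_anchor_composes_with_gap_pattern(self):
        """The mapped column of the packaged reference holds its tyrosine."""
        ref = load_packaged_reference()
        col = map_anchor_column(ref)
        row = dict(ref.rows)[ref.anchor_ref]
        assert row[col - 1] == "Y"


class TestProfileAlignment:
    def test_self_alignment_reproduces_gap_pattern(self, tiny_refaln):
        ungapped = dict(tiny_refaln.rows)["refA"].replace("-", "")
        out = align_query_to_reference("q", ungapped, tiny_refaln)
        assert out.row == dict(tiny_refaln.rows)["refA"]
        assert out.insertions == {}

    def test_packaged_reference_rows_self_align(self):
        ref = load_packaged_reference()
        for rid, row in ref.rows[:3]:
            out = align_query_to_reference(rid, row.replace("-", ""), ref)
            assert out.row == row

    def test_single_deletion_preserves_columns(self, tiny_refaln):
        full = dict(tiny_refaln.rows)["refB"]  # ungapped row
        deleted = full[:4] + full[5:]  # drop the 'E'
        out = align_query_to_reference("q", deleted, tiny_refaln)
        assert out.row.count("-") == 1
        assert len(out.row) == len(full)

    def test_self_score_is_optimal(self, tiny_refaln):
        ungapped = dict(tiny_refaln.rows)["refB"]
        best = align_query_to_reference("q", ungapped, tiny_refaln).score
        shuffled = ungapped[::-1]
        assert align_query_to_reference("q", shuffled, tiny_refaln).score <= best

    def test_empty_query_rejected(self, tiny_refaln):
        with pytest.raises(ValueError, match="empty"):
            align_query_to_reference("q", "", tiny_refaln)


class TestMotifCall:
    def test_reference_row_classified_against_itself(self):
        ref = load_packaged_reference()
        col = map_anchor_column(ref)
        row = dict(ref.rows)[ref.anchor_ref].replace("-", "")
        out = classify_hao(align_query_to_reference("q", row, ref), col)
        assert out.call == "oxidative-HAO-like"
        assert out.anchor_column_residue == "Y"

    def test_tryptophan_with_met_minus8(self):
        ref = load_packaged_reference()
        col = map_anchor_column(ref)
        eps = next(
            rid for rid, _ in ref.rows if ref.class_labels[rid] == "epsilonHao"
        )
        row = dict(ref.rows)[eps].replace("-", "")
        out = classify_hao(align_query_to_reference("q", row, ref), col)
        assert out.call == "epsilonHao-like"
        assert out.met_minus8

    def test_gap_or_other_residue_is_ambiguous(self, tiny_refaln):
        col = map_anchor_column(tiny_refaln)
        full = dict(tiny_refaln.rows)["refB"]
        # replace the anchor residue with alanine
        mutated = full[: col - 1] + "A" + full[col:]
        out = classify_hao(align_query_to_reference("q", mutated, tiny_refaln), col)
        assert out.call == "ambiguous"

    def test_call_invariant_to_renaming_and_row_order(self):
        ref = load_packaged_reference()
        col = map_anchor_column(ref)
        reordered = ReferenceAlignment(
            rows=list(reversed(ref.rows)),
            anchor_ref=ref.anchor_ref,
            anchor_pos=ref.anchor_pos,
            class_labels=ref.class_labels,
        )
        row = dict(ref.rows)[ref.anchor_ref].replace("-", "")
        a = classify_hao(align_query_to_reference("x", row, ref), col)
        b = classify_hao(
            align_query_to_reference("y", row, reordered), map_anchor_column(reordered)
        )
        assert (a.call, a.anchor_column_residue) == (b.call, b.anchor_column_residue)


class TestPdistance:
    def test_identical_and_half_mismatch(self):
        d = pdistance_matrix([("a", "AAAA"), ("b", "AATT"), ("c", "AAAA")])
        assert d.loc["a", "c"] == 0.0
        assert d.loc["a", "b"] == pytest.approx(0.5)

    def test_gapped_columns_excluded(self):
        d = pdistance_matrix([("a", "A-CD"), ("b", "ABCD"), ("c", "ABCD")])
        # a vs b: 3 comparable columns, 0 mismatches
        assert d.loc["a", "b"] == 0.0

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            pdistance_matrix([("a", "A--"), ("b", "-B-"), ("c", "ABC")])


def random_additive_tree(rng, n_leaves):
    """Random binary topology with uniform branch lengths; returns
    (leaf-distance DataFrame, set of nontrivial splits)."""
    names = [f"L{i}" for i in range(n_leaves)]
    members = {i: [names[i]] for i in range(n_leaves)}
    depth = dict.fromkeys(names, 0.0)
    D = {x: dict.fromkeys(names, 0.0) for x in names}
    active = list(range(n_leaves))
    next_id = n_leaves
    clusters = []
    while len(active) > 1:
        idx = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(idx[0])], active[int(idx[1])]
        la, lb = rng.uniform(0.2, 1.0), rng.uniform(0.2, 1.0)
        for x in members[a]:
            for y in members[b]:
                D[x][y] = D[y][x] = depth[x] + la + depth[y] + lb
        for x in members[a]:
            depth[x] += la
        for y in members[b]:
            depth[y] += lb
        members[next_id] = members[a] + members[b]
        clusters.append(frozenset(members[a]))
        clusters.append(frozenset(members[b]))
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    splits = {s for s in clusters if 1 < len(s) < n_leaves - 1}
    mat = pd.DataFrame(
        [[D[x][y] for y in names] for x in names], index=names, columns=names
    )
    return mat, splits


def tree_splits(root, all_leaves):
    """Nontrivial splits of an (unrooted) tree, canonicalized."""
    universe = frozenset(all_leaves)
    out = set()

    def walk(node):
        names = frozenset(leaf.name for leaf in node.leaves())
        if 1 < len(names) < len(universe) - 1:
            out.add(names)
        for child, _ in node.children:
            walk(child)

    walk(root)
    return canon_splits(out, all_leaves)


def canon_splits(splits, all_leaves):
    universe = frozenset(all_leaves)
    canon = set()
    for s in splits:
        comp = universe - s
        canon.add(s if sorted(s) <= sorted(comp) else comp)
    return canon


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        tree = nj_tree(d)
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxa_recovers_split(self):
        # tree ((a,b),(c,d)) with internal branch 4
        d = pd.DataFrame(
            [
                [0, 2, 8, 9],
                [2, 0, 8, 9],
                [8, 8, 0, 3],
                [9, 9, 3, 0],
            ],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        tree = nj_tree(d)
        splits = tree_splits(tree.root, list("abcd"))
        assert frozenset("ab") in splits or frozenset("cd") in splits

    def test_recovers_random_additive_topologies(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 9))
            mat, true_splits = random_additive_tree(rng, n)
            tree = nj_tree(mat)
            names = list(mat.index)
            assert tree_splits(tree.root, names) == canon_splits(true_splits, names)

    def test_ultrametric_tie_break_is_deterministic(self):
        d = pd.DataFrame(
            1.0 - np.eye(4), index=list("abcd"), columns=list("abcd")
        )
        assert nj_tree(d).newick == nj_tree(d).newick

    def test_newick_is_parseable(self, rng):
        import io as _io

        import skbio

        mat, _ = random_additive_tree(rng, 6)
        tree = nj_tree(mat)
        parsed = skbio.TreeNode.read(_io.StringIO(tree.newick))
        assert {t.name for t in parsed.tips()} == set(mat.index)

    def test_too_few_taxa_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            nj_tree(d)


class TestAssignClade:
    def test_query_beside_single_class_references(self):
        # two well-separated class groups, query near the epsilon group
        d = np.array(
            [
                #  e1   e2    q   a1   a2
                [0.0, 0.2, 0.1, 2.0, 2.1],
                [0.2, 0.0, 0.15, 2.1, 2.2],
                [0.1, 0.15, 0.0, 2.0, 2.1],
                [2.0, 2.1, 2.0, 0.0, 0.2],
                [2.1, 2.2, 2.1, 0.2, 0.0],
            ]
        )
        names = ["e1", "e2", "q", "a1", "a2"]
        tree = nj_tree(pd.DataFrame(d, index=names, columns=names))
        labels = {"e1": "epsilonHao", "e2": "epsilonHao",
                  "a1": "AOB-HAO", "a2": "AOB-HAO"}
        out = assign_clade(tree, labels)
        assert out["q"] == "epsilonHao"
        assert out["a1"] == "AOB-HAO"  # references keep their own label

    def test_query_between_classes_unresolved(self):
        d = np.array(
            [
                [0.0, 0.2, 1.0, 2.0],
                [0.2, 0.0, 1.0, 2.0],
                [1.0, 1.0, 0.0, 1.0],
                [2.0, 2.0, 1.0, 0.0],
            ]
        )
        names = ["a1", "a2", "q", "e1"]
        tree = nj_tree(pd.DataFrame(d, index=names, columns=names))
        labels = {"a1": "AOB-HAO", "a2": "AOB-HAO", "e1": "epsilonHao"}
        out = assign_clade(tree, labels)
        assert out["q"] in ("unresolved", "AOB-HAO", "epsilonHao")

    def test_tree_without_references_rejected(self):
        d = pd.DataFrame(
            1.0 - np.eye(3), index=list("xyz"), columns=list("xyz")
        )
        tree = nj_tree(d)
        with pytest.raises(ValueError, match="reference"):
            assign_clade(tree, {"other": "AOB-HAO"})


class TestEndToEnd:
    def test_motif_recovery_perfect_at_low_mutation(self):
        cfg = SimConfig(seed=11, n_oxidative_hao=5, n_epsilon_hao=15)
        queries, truth = generate_hao_proteins(cfg)
        calls, _, _ = classify_hao_sequences(queries)
        got = calls.set_index("query_id")["call"].to_dict()
        assert all(got[q] == lab for q, lab in truth.hao_labels.items())

    def test_clade_recovery_across_seeds(self):
        hits = total = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_oxidative_hao=5, n_epsilon_hao=15)
            queries, truth = generate_hao_proteins(cfg)
            _, _, clades = classify_hao_sequences(queries)
            for q, lab in truth.hao_labels.items():
                total += 1
                hits += CLASS_TO_CALL.get(clades[q]) == lab
        assert hits / total >= 0.95
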