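from __future__ import annotations

import math

import numpy as np
import pytest

from famseq.phylo import (
    MultipleAlignment,
    SupportTree,
    TreeNode,
    bootstrap_support,
    neighbor_joining,
    parse_newick,
    pdistance,
)


class TestMultipleAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            MultipleAlignment(("a", "b"), ("MKV", "MK"))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            MultipleAlignment(("a", "a"), ("MKV", "MKV"))


class TestPdistance:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment.from_dict({"a": "MKVLL", "b": "MKVLL"})
        assert pdistance(aln)[0, 1] == 0.0

    def test_poisson_closed_form(self):
        aln = MultipleAlignment.from_dict({"a": "AAAA", "b": "AACC"})
        D = pdistance(aln, correction="poisson")
        assert D[0, 1] == pytest.approx(math.log(2))

    def test_pairwise_gap_deletion(self):
        aln = MultipleAlignment.from_dict({"a": "MK-V", "b": "MKAV", "c": "MCAV"})
        D = pdistance(aln)
        assert D[0, 1] == 0.0  # 3 compared columns, all equal
        assert D[0, 2] == pytest.approx(1 / 3)

    def test_zero_overlap_error_names_pair(self):
        aln = MultipleAlignment.from_dict({"a": "MK--", "b": "--AV"})
        with pytest.raises(ValueError, match="'a'.*'b'"):
            pdistance(aln)

    def test_counting_oracle_random(self, rng):
        ids = [f"s{i}" for i in range(6)]
        rows = {}
        for i in ids:
            rows[i] = "".join(rng.choice(list("ACDEFG-"), 40))
        aln = MultipleAlignment.from_dict(rows)
        D = pdistance(aln)
        for i in range(6):
            for j in range(6):
                compared = sum(
                    1 for a, b in zip(rows[ids[i]], rows[ids[j]]) if a != "-" and b != "-"
                )
                mism = sum(
                    1
                    for a, b in zip(rows[ids[i]], rows[ids[j]])
                    if a != "-" and b != "-" and a != b
                )
                assert D[i, j] == pytest.approx(0.0 if i == j else mism / compared)


def _random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree; returns (distance matrix, bipartitions)."""
    labels = [f"L{i}" for i in range(n_leaves)]
    # start from a 3-leaf star, attach remaining leaves to random edges
    nodes = {i: TreeNode(label=lab) for i, lab in enumerate(labels)}
    adj: dict[int, dict[int, float]] = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    center = n_leaves
    next_id = n_leaves + 1
    for i in range(3):
        connect(i, center, float(rng.uniform(0.05, 1.0)))
    edges = [(i, center) for i in range(3)]
    for leaf in range(3, n_leaves):
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        mid = next_id
        next_id += 1
        w1 = w * float(rng.uniform(0.2, 0.8))
        connect(a, mid, w1)
        connect(b, mid, w - w1)
        connect(leaf, mid, float(rng.uniform(0.05, 1.0)))
        edges.remove((a, b))
        edges.extend([(a, mid), (b, mid), (leaf, mid)])
    # all-pairs leaf distances by BFS
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    # true bipartitions: for each internal edge, leaves on one side
    bips = set()
    internal = [(u, v) for u in adj for v in adj[u] if u < v and u >= n_leaves and v >= n_leaves]
    for u, v in internal:
        side = set()
        stack = [(u, v)]
        seen = {v}
        stack2 = [u]
        seen2 = {u, v}
        while stack2:
            x = stack2.pop()
            if x < n_leaves:
                side.add(labels[x])
            for y in adj[x]:
                if y not in seen2:
                    seen2.add(y)
                    stack2.append(y)
        all_set = frozenset(labels)
        fs = frozenset(side)
        other = all_set - fs
        if 1 < len(fs) < n_leaves - 1:
            canon = fs if (len(fs), tuple(sorted(fs))) <= (len(other), tuple(sorted(other))) else other
            bips.add(min((fs, other), key=lambda s: (len(s), tuple(sorted(s)))))
    return labels, D, bips


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        lengths = {child.label: w for child, w in tree.root.children}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:1.5,d:0.5)) -> additive distances
        D = np.array(
            [
                [0.0, 3.0, 3.5, 2.5],
                [3.0, 0.0, 4.5, 3.5],
                [3.5, 4.5, 0.0, 2.0],
                [2.5, 3.5, 2.0, 0.0],
            ]
        )
        tree = neighbor_joining(D, ["a", "b", "c", "d"])
        assert tree.bipartitions() == {frozenset({"a", "b"})}
        # branch lengths exact for the additive input: check path distances
        assert _tree_distance(tree, "a", "b") == pytest.approx(3.0)
        assert _tree_distance(tree, "a", "c") == pytest.approx(3.5)
        assert _tree_distance(tree, "c", "d") == pytest.approx(2.0)

    def test_additive_matrices_up_to_8_taxa(self, rng):
        for n in (4, 5, 6, 7, 8):
            for _ in range(4):
                labels, D, true_bips = _random_additive_tree(rng, n)
                tree = neighbor_joining(D, labels)
                assert tree.bipartitions() == true_bips, (n, labels)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(D, ["a", "b", "c"])

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])

    def test_ultrametric_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(D, ["a", "b", "c", "d"])
        t2 = neighbor_joining(D, ["a", "b", "c", "d"])
        assert t1.to_newick() == t2.to_newick()

    def test_leaf_set_preserved(self, rng):
        labels, D, _ = _random_additive_tree(rng, 7)
        tree = neighbor_joining(D, labels)
        assert sorted(tree.leaves()) == sorted(labels)


def _tree_distance(tree: SupportTree, a: str, b: str) -> float:
    # path length between two leaves via shared parent traversal
    def paths(node, target, acc):
        if node.label == target:
            return acc
        for child, w in node.children:
            got = paths(child, target, acc + w)
            if got is not None:
                return got
        return None

    def lca_dist(node):
        pa = paths(node, a, 0.0)
        pb = paths(node, b, 0.0)
        best = None
        if pa is not None and pb is not None:
            best = pa + pb
            for child, _ in node.children:
                down = lca_dist(child)
                if down is not None and (best is None or down < best):
                    best = down
        return best

    return lca_dist(tree.root)


def _family_alignment(rng, n_families=4, n_members=5, length=60):
    from famseq.synthetic_data import AMINO_ACIDS, mutate_peptide

    seqs = {}
    for f in range(n_families):
        ancestor = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(length))
        for m in range(n_members):
            seqs[f"F{f}_m{m}"] = mutate_peptide(ancestor, 0.05, rng, keep_first=False)
    return MultipleAlignment.from_dict(seqs)


class TestBootstrap:
    def test_single_replicate_support_binary(self, rng):
        aln = _family_alignment(rng, n_families=3, n_members=3, length=40)
        tree = bootstrap_support(aln, n_replicates=1, seed=1)
        for node in _internal_supports(tree):
            assert node in (0.0, 100.0)

    def test_saturated_signal_full_support(self, rng):
        aln = _family_alignment(rng, n_families=3, n_members=4, length=120)
        tree = bootstrap_support(aln, n_replicates=25, seed=2)
        for f in range(3):
            clade = frozenset(f"F{f}_m{m}" for m in range(4))
            support = _clade_support(tree, clade)
            assert support == pytest.approx(100.0)

    def test_family_clades_above_70(self, rng):
        aln = _family_alignment(rng, n_families=4, n_members=5, length=80)
        tree = bootstrap_support(aln, n_replicates=100, seed=3)
        for f in range(4):
            clade = frozenset(f"F{f}_m{m}" for m in range(5))
            assert _clade_support(tree, clade) >= 70.0

    def test_invalid_replicates(self, rng):
        aln = _family_alignment(rng, 3, 3, 30)
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_replicates=0)

    def test_leafset_preserved_and_deterministic(self, rng):
        aln = _family_alignment(rng, 3, 3, 50)
        t1 = bootstrap_support(aln, n_replicates=20, seed=5)
        t2 = bootstrap_support(aln, n_replicates=20, seed=5)
        assert sorted(t1.leaves()) == sorted(aln.ids)
        assert t1.to_newick() == t2.to_newick()


def _internal_supports(tree: SupportTree) -> list[float]:
    out = []

    def walk(node, is_root):
        if node.children and not is_root and node.support is not None:
            out.append(node.support)
        for child, _ in node.children:
            walk(child, False)

    walk(tree.root, True)
    return out


def _clade_support(tree: SupportTree, clade: frozenset) -> float:
    universe = frozenset(tree.leaves())

    def walk(node):
        side = frozenset(node.leaves())
        if side == clade or universe - side == clade:
            return node.support
        for child, _ in node.children:
            got = walk(child)
            if got is not None:
                return got
        return None

    support = walk(tree.root)
    assert support is not None, f"clade {sorted(clade)} not in tree"
    return support


class TestNewick:
    def test_round_trip(self, rng):
        labels, D, _ = _random_additive_tree(rng, 6)
        tree = neighbor_joining(D, labels)
        text = tree.to_newick()
        parsed = parse_newick(text)
        assert sorted(parsed.leaves()) == sorted(labels)
        assert SupportTree(parsed).to_newick() == text

    def test_support_labels_survive(self, rng):
        aln = _family_alignment(rng, 3, 3, 60)
        tree = bootstrap_support(aln, n_replicates=10, seed=7)
        parsed = parse_newick(tree.to_newick())
        assert SupportTree(parsed).to_newick() == tree.to_newick()

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("(a,b")
        with pytest.raises(ValueError):
            parse_newick("(a,(b,c));extra")
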