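"""Distance-based family trees with bootstrap support.

A deterministic neighbor-joining implementation over p-distances (with
optional Poisson correction) stands in for maximum-likelihood inference:
topology and clade support, not branch lengths, are the supported
surface. Bootstrap support resamples alignment columns with replacement,
rebuilds the tree per replicate, and reports the percentage of replicates
containing each original bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultipleAlignment",
    "TreeNode",
    "SupportTree",
    "pdistance",
    "neighbor_joining",
    "bootstrap_support",
    "parse_newick",
]

GAP = "-"


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length aligned peptides."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "MultipleAlignment":
        return cls(tuple(seqs), tuple(seqs.values()))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "MultipleAlignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = tuple("".join(row[c] for c in cols) for row in self.rows)
        return MultipleAlignment(self.ids, rows)


def pdistance(alignment: MultipleAlignment, correction: str = "none") -> np.ndarray:
    """Pairwise distance matrix under pairwise gap deletion.

    ``d = mismatches / compared columns``; with ``correction="poisson"``,
    ``d = -ln(1 - p)``. A pair with zero ungapped overlap is an error.
    """
    if correction not in ("none", "poisson"):
        raise ValueError("correction must be 'none' or 'poisson'")
    n = len(alignment.ids)
    D = np.zeros((n, n))
    rows = alignment.rows
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatch = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                compared += 1
                if a != b:
                    mismatch += 1
            if compared == 0:
                raise ValueError(
                    f"no ungapped overlap between {alignment.ids[i]!r} and "
                    f"{alignment.ids[j]!r}"
                )
            p = mismatch / compared
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined at p >= 1")
                d = -math.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return D


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label is not None else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, *, support_threshold: float | None = None) -> str:
        return self._newick(support_threshold) + ";"

    def _newick(self, thresh: float | None) -> str:
        if not self.children:
            return self.label or ""
        parts = ",".join(
            f"{child._newick(thresh)}:{length:.6f}" for child, length in self.children
        )
        label = ""
        if self.support is not None and (thresh is None or self.support >= thresh):
            label = f"{self.support:g}"
        return f"({parts}){label}"


@dataclass
class SupportTree:
    """An (unrooted, stored with a trifurcating root) tree with optional
    per-internal-node bootstrap support in [0, 100]."""

    root: TreeNode
    display_threshold: float = 70.0
    warnings: list[str] = field(default_factory=list)

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the smaller side
        (ties broken lexicographically)."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset] = set()
        for node in _internal_nodes(self.root, include_root=False):
            side = frozenset(node.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(_canonical(side, all_leaves))
        return out

    def to_newick(self, show_all_support: bool = True) -> str:
        thresh = None if show_all_support else self.display_threshold
        return self.root.to_newick(support_threshold=thresh)


def _canonical(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def _internal_nodes(root: TreeNode, include_root: bool) -> list[TreeNode]:
    out: list[TreeNode] = []

    def walk(node: TreeNode, is_root: bool) -> None:
        if node.children and (include_root or not is_root):
            out.append(node)
        for child, _ in node.children:
            walk(child, False)

    walk(root, True)
    return out


def neighbor_joining(D: np.ndarray, labels: list[str]) -> SupportTree:
    """Standard neighbor joining with deterministic tie-breaking.

    The lowest-index pair wins Q-criterion ties; negative branch lengths
    are clamped to 0 and recorded in the tree's warnings.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape must match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    warnings: list[str] = []
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in labels]
    D = D.copy()
    active = list(range(n))

    def clamp(x: float, context: str) -> float:
        if x < 0:
            warnings.append(f"negative branch length {x:.6g} clamped to 0 ({context})")
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = math.inf
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        li = sub[a, b] / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = sub[a, b] - li
        li = clamp(li, f"join {a},{b}")
        lj = clamp(lj, f"join {a},{b}")
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # reuse slot i for the new node, retire j
        new_row = np.zeros(D.shape[0])
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = (D[i, c] + D[j, c] - D[i, j]) / 2
        D[i, :] = new_row
        D[:, i] = new_row
        nodes[i] = parent
        active.remove(j)
    # resolve the final three around a central node (closed form)
    i, j, k = active
    li = clamp((D[i, j] + D[i, k] - D[j, k]) / 2, "final star")
    lj = clamp((D[i, j] + D[j, k] - D[i, k]) / 2, "final star")
    lk = clamp((D[i, k] + D[j, k] - D[i, j]) / 2, "final star")
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return SupportTree(root, warnings=warnings)


def bootstrap_support(
    alignment: MultipleAlignment,
    n_replicates: int = 600,
    seed: int = 0,
    correction: str = "none",
) -> SupportTree:
    """NJ tree with column-resampled bootstrap support percentages."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = list(alignment.ids)
    tree = neighbor_joining(pdistance(alignment, correction), labels)
    universe = frozenset(labels)
    tally: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = alignment.resample_columns(rng)
        rep_tree = neighbor_joining(pdistance(rep, correction), labels)
        rep_bps = rep_tree.bipartitions()
        for bp in tally:
            if bp in rep_bps:
                tally[bp] += 1
    for node in _internal_nodes(tree.root, include_root=False):
        side = frozenset(node.leaves())
        if 1 < len(side) < len(universe) - 1:
            bp = _canonical(side, universe)
            node.support = 100.0 * tally[bp] / n_replicates
    return tree


def parse_newick(text: str) -> TreeNode:
    """Parse the Newick dialect emitted by :meth:`TreeNode.to_newick`
    (internal labels read as support values)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = parse_node()
                length = 0.0
                if pos < len(s) and s[pos] == ":":
                    pos += 1
                    start = pos
                    while pos < len(s) and s[pos] not in ",();:":
                        pos += 1
                    length = float(s[start:pos])
                node.children.append((child, length))
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                break
            if pos >= len(s) or s[pos] != ")":
                raise ValueError("unbalanced parentheses in Newick string")
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();:":
                pos += 1
            label = s[start:pos]
            if label:
                node.support = float(label)
        else:
            start = pos
            while pos < len(s) and s[pos] not in ",();:":
                pos += 1
            node.label = s[start:pos]
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick string: {s[pos:]!r}")
    return root
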