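"""Boolean logic trees over binary genotype-indicator columns.

A logic tree is a full binary tree whose internal nodes are AND/OR and
whose leaves reference columns of a binary indicator matrix, optionally
negated.  Trees are the predictors of logic regression: a gene-specific
tree (GST) is one such tree restricted to a single gene's indicator
columns, and pathway trees are trees over GST columns.

The module provides evaluation, the De Morgan complement, the simulated
annealing move set, canonicalisation, serialisation, and an exhaustive
enumeration oracle for small instances (used to verify the stochastic
search against the true optimum).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Leaf",
    "Node",
    "LogicTree",
    "MOVE_TYPES",
    "propose_move",
    "enumerate_trees",
    "trees_equivalent",
    "random_leaf_tree",
]


class TreeError(ValueError):
    """Structural error in a logic tree (bad reference, malformed node)."""


@dataclass(frozen=True)
class Leaf:
    """Leaf predicate: indicator column ``col``, negated when ``neg``."""

    col: int
    neg: bool = False


@dataclass(frozen=True)
class Node:
    """Internal AND/OR node with exactly two children."""

    op: str  # "and" | "or"
    left: "Leaf | Node"
    right: "Leaf | Node"

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise TreeError(f"unknown operator {self.op!r}")


def _eval(node, X: np.ndarray) -> np.ndarray:
    if isinstance(node, Leaf):
        if node.col < 0 or node.col >= X.shape[1]:
            raise TreeError(f"leaf references column {node.col}, matrix has {X.shape[1]}")
        v = X[:, node.col].astype(bool)
        return ~v if node.neg else v
    a = _eval(node.left, X)
    b = _eval(node.right, X)
    return (a & b) if node.op == "and" else (a | b)


def _complement(node):
    if isinstance(node, Leaf):
        return Leaf(node.col, not node.neg)
    op = "or" if node.op == "and" else "and"
    return Node(op, _complement(node.left), _complement(node.right))


def _leaves(node) -> Iterator[Leaf]:
    if isinstance(node, Leaf):
        yield node
    else:
        yield from _leaves(node.left)
        yield from _leaves(node.right)


def _key(node) -> tuple:
    if isinstance(node, Leaf):
        return (0, node.col, node.neg)
    return (1, node.op, _key(node.left), _key(node.right))


def _canon(node):
    """Sort children of commutative operators so printed trees are stable."""
    if isinstance(node, Leaf):
        return node
    a, b = _canon(node.left), _canon(node.right)
    if _key(a) > _key(b):
        a, b = b, a
    return Node(node.op, a, b)


class LogicTree:
    """A Boolean tree bound by column index to an indicator matrix."""

    __slots__ = ("root",)

    def __init__(self, root: Leaf | Node):
        if not isinstance(root, (Leaf, Node)):
            raise TreeError("root must be a Leaf or Node")
        self.root = root

    # -- evaluation ----------------------------------------------------
    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the tree row-wise over a subjects x columns 0/1 matrix."""
        X = np.asarray(X)
        return _eval(self.root, X).astype(np.uint8)

    def truth_table(self, n_columns: int) -> np.ndarray:
        """Evaluation over all 2**n_columns input rows (column 0 fastest)."""
        rows = np.array(
            [[(i >> j) & 1 for j in range(n_columns)] for i in range(2**n_columns)],
            dtype=np.uint8,
        )
        return self.evaluate(rows)

    # -- structure -----------------------------------------------------
    def complement(self) -> "LogicTree":
        """De Morgan complement: swap AND/OR, negate every leaf."""
        return LogicTree(_complement(self.root))

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in _leaves(self.root))

    def leaves(self) -> list[Leaf]:
        return list(_leaves(self.root))

    def columns(self) -> set[int]:
        return {lf.col for lf in _leaves(self.root)}

    def canonical(self) -> "LogicTree":
        return LogicTree(_canon(self.root))

    # -- serialisation -------------------------------------------------
    def to_text(self, names: Sequence[str] | None = None) -> str:
        """Parenthesised text form, e.g. ``(rs1:dom AND rs2:rec^c)``."""

        def fmt(node):
            if isinstance(node, Leaf):
                label = names[node.col] if names is not None else f"x{node.col}"
                return f"{label}^c" if node.neg else label
            return f"({fmt(node.left)} {node.op.upper()} {fmt(node.right)})"

        return fmt(self.root)

    def to_json(self) -> str:
        def enc(node):
            if isinstance(node, Leaf):
                return {"col": node.col, "neg": node.neg}
            return {"op": node.op, "left": enc(node.left), "right": enc(node.right)}

        return json.dumps(enc(self.root))

    @classmethod
    def from_json(cls, s: str) -> "LogicTree":
        def dec(d):
            if "col" in d:
                return Leaf(int(d["col"]), bool(d["neg"]))
            return Node(d["op"], dec(d["left"]), dec(d["right"]))

        return cls(dec(json.loads(s)))

    def __eq__(self, other):
        return isinstance(other, LogicTree) and _key(self.root) == _key(other.root)

    def __hash__(self):
        return hash(_key(self.root))

    def __repr__(self):
        return f"LogicTree({self.to_text()})"


def trees_equivalent(t1: LogicTree, t2: LogicTree, n_columns: int) -> bool:
    """Boolean equivalence by truth-table comparison."""
    return bool(np.array_equal(t1.truth_table(n_columns), t2.truth_table(n_columns)))


def random_leaf_tree(n_columns: int, rng: np.random.Generator) -> LogicTree:
    return LogicTree(Leaf(int(rng.integers(n_columns)), bool(rng.integers(2))))


# ---------------------------------------------------------------------------
# Annealing move set
# ---------------------------------------------------------------------------

MOVE_TYPES = (
    "alternate_leaf",
    "alternate_operator",
    "grow_branch",
    "prune_branch",
    "split_leaf",
    "delete_leaf",
)


def _paths(node, path=()):  # all subtree paths; path elements are "L"/"R"
    yield path, node
    if isinstance(node, Node):
        yield from _paths(node.left, path + ("L",))
        yield from _paths(node.right, path + ("R",))


def _replace(node, path, sub):
    if not path:
        return sub
    if path[0] == "L":
        return Node(node.op, _replace(node.left, path[1:], sub), node.right)
    return Node(node.op, node.left, _replace(node.right, path[1:], sub))


def propose_move(
    tree: LogicTree,
    n_columns: int,
    rng: np.random.Generator,
    max_leaves: int = 8,
    min_leaves: int = 1,
) -> tuple[LogicTree, str] | None:
    """Propose one random move from the logic-regression move set.

    Returns ``(new_tree, move_name)`` or ``None`` when no move is legal
    (stay-in-place signal).  Move type is uniform over legal types, then
    uniform over positions/values within the type.
    """
    root = tree.root
    all_paths = list(_paths(root))
    leaf_paths = [(p, n) for p, n in all_paths if isinstance(n, Leaf)]
    node_paths = [(p, n) for p, n in all_paths if isinstance(n, Node)]
    n_leaves = len(leaf_paths)

    legal = ["alternate_leaf"] if n_columns > 1 or n_leaves > 0 else []
    if node_paths:
        legal.append("alternate_operator")
        legal.append("prune_branch")
    if n_leaves < max_leaves:
        legal.append("split_leaf")
        if node_paths:
            legal.append("grow_branch")
    if n_leaves > min_leaves:
        legal.append("delete_leaf")
    if not legal:
        return None

    move = legal[int(rng.integers(len(legal)))]

    if move == "alternate_leaf":
        path, lf = leaf_paths[int(rng.integers(n_leaves))]
        choices = [
            Leaf(c, bool(neg))
            for c in range(n_columns)
            for neg in (False, True)
            if not (c == lf.col and bool(neg) == lf.neg)
        ]
        new = choices[int(rng.integers(len(choices)))]
        return LogicTree(_replace(root, path, new)), move

    if move == "alternate_operator":
        path, nd = node_paths[int(rng.integers(len(node_paths)))]
        flipped = Node("or" if nd.op == "and" else "and", nd.left, nd.right)
        return LogicTree(_replace(root, path, flipped)), move

    if move == "split_leaf":
        path, lf = leaf_paths[int(rng.integers(n_leaves))]
        op = "and" if rng.integers(2) else "or"
        new_leaf = Leaf(int(rng.integers(n_columns)), bool(rng.integers(2)))
        return LogicTree(_replace(root, path, Node(op, lf, new_leaf))), move

    if move == "grow_branch":
        path, nd = node_paths[int(rng.integers(len(node_paths)))]
        op = "and" if rng.integers(2) else "or"
        new_leaf = Leaf(int(rng.integers(n_columns)), bool(rng.integers(2)))
        return LogicTree(_replace(root, path, Node(op, nd, new_leaf))), move

    if move == "delete_leaf":
        # remove a leaf whose sibling replaces the parent
        candidates = [
            (p, n)
            for p, n in node_paths
            if isinstance(n.left, Leaf) or isinstance(n.right, Leaf)
        ]
        path, nd = candidates[int(rng.integers(len(candidates)))]
        if isinstance(nd.left, Leaf) and isinstance(nd.right, Leaf):
            keep = nd.right if rng.integers(2) else nd.left
        elif isinstance(nd.left, Leaf):
            keep = nd.right
        else:
            keep = nd.left
        return LogicTree(_replace(root, path, keep)), move

    # prune_branch: replace an internal node by one of its children
    path, nd = node_paths[int(rng.integers(len(node_paths)))]
    keep = nd.left if rng.integers(2) else nd.right
    new_tree = LogicTree(_replace(root, path, keep))
    if new_tree.n_leaves < min_leaves:
        return None
    return new_tree, "prune_branch"


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (test-scale only)
# ---------------------------------------------------------------------------

_ENUM_MAX_COLUMNS = 6
_ENUM_MAX_LEAVES = 3


def enumerate_trees(n_columns: int, max_leaves: int) -> list[LogicTree]:
    """All logic trees up to Boolean equivalence, one representative each.

    Trees with up to ``max_leaves`` leaves over ``n_columns`` columns are
    generated exhaustively and deduplicated by truth table over all
    ``2**n_columns`` input rows.  Refuses instances beyond the supported
    oracle scale (6 columns, 3 leaves): the enumeration is a verification
    device, not a search method.
    """
    if n_columns > _ENUM_MAX_COLUMNS or max_leaves > _ENUM_MAX_LEAVES:
        raise ValueError(
            f"enumeration bounded to <= {_ENUM_MAX_COLUMNS} columns and "
            f"<= {_ENUM_MAX_LEAVES} leaves"
        )
    if n_columns < 1 or max_leaves < 1:
        raise ValueError("need at least one column and one leaf")

    def gen(k: int):
        if k == 1:
            for c in range(n_columns):
                yield Leaf(c, False)
                yield Leaf(c, True)
            return
        for k_left in range(1, k):
            for left, right in itertools.product(gen(k_left), gen(k - k_left)):
                yield Node("and", left, right)
                yield Node("or", left, right)

    seen: dict[bytes, LogicTree] = {}
    for k in range(1, max_leaves + 1):
        for root in gen(k):
            t = LogicTree(root)
            tt = t.truth_table(n_columns).tobytes()
            if tt not in seen:
                seen[tt] = t.canonical()
    return list(seen.values())
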