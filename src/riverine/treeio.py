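"""Rooted phylogenetic trees: parsing, writing, and clade/age queries.

Trees are stored in flat parallel arrays indexed by node id (preorder,
root = 0).  Branch lengths are attached to the edge above each node; the
root's length slot is kept but never interpreted.  Two kinds of trees flow
through the pipeline: maximum-likelihood trees whose branch lengths are
expected substitutions per site, and dated ultrametric trees in Ma.  Units
are not validated here; each downstream stage declares which kind it needs.

Newick and NEXUS parsing are delegated to :mod:`dendropy`; this module only
adds the light-weight array representation, error wrapping, and the age /
MRCA / monophyly utilities the rest of the pipeline is built on.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Tree",
    "PosteriorTreeSet",
    "NewickParseError",
    "NexusParseError",
    "UltrametricityError",
    "parse_newick",
    "write_newick",
    "parse_nexus_trees",
    "write_nexus_trees",
    "mrca",
    "node_age",
    "node_ages",
    "is_monophyletic",
    "resolve_polytomies",
    "extract_subtree",
]

DEFAULT_ULTRAMETRIC_TOL = 1e-4


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class NexusParseError(ValueError):
    """Raised when a NEXUS trees file cannot be parsed or is inconsistent."""


class UltrametricityError(ValueError):
    """Raised when a tree expected to be ultrametric is not, within tolerance."""


class Tree:
    """A rooted tree with branch lengths, stored in parallel arrays.

    Attributes
    ----------
    parent : list[int]
        Parent id per node; -1 for the root.
    children : list[list[int]]
        Child ids per node; empty for tips.
    lengths : list[float]
        Length of the edge above each node (0.0 for the root).
    labels : list[str | None]
        Tip labels (always set for tips, unique); internal labels optional.
    root : int
        Node id of the root (always 0).
    """

    __slots__ = ("parent", "children", "lengths", "labels", "root")

    def __init__(
        self,
        parent: list[int],
        children: list[list[int]],
        lengths: list[float],
        labels: list[str | None],
        root: int = 0,
    ) -> None:
        self.parent = parent
        self.children = children
        self.lengths = lengths
        self.labels = labels
        self.root = root

    # -- construction ------------------------------------------------------

    @classmethod
    def from_nested(cls, spec) -> "Tree":
        """Build a tree from nested tuples ``(label, length, [children])``.

        ``label`` may be None for internal nodes; ``children`` is a list of
        specs (empty or absent for tips).  Mostly used by simulators and
        tests to write topologies down explicitly.
        """
        parent: list[int] = []
        children: list[list[int]] = []
        lengths: list[float] = []
        labels: list[str | None] = []

        def _add(node_spec, parent_id: int) -> int:
            label = node_spec[0]
            length = float(node_spec[1])
            kids = node_spec[2] if len(node_spec) > 2 else []
            nid = len(parent)
            parent.append(parent_id)
            children.append([])
            lengths.append(length)
            labels.append(label)
            if parent_id >= 0:
                children[parent_id].append(nid)
            for k in kids:
                _add(k, nid)
            return nid

        _add(spec, -1)
        tree = cls(parent, children, lengths, labels)
        tree._validate()
        return tree

    def _validate(self) -> None:
        tip_labels = [self.labels[i] for i in self.tip_ids()]
        if any(lab is None for lab in tip_labels):
            raise ValueError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if any(l < 0 for l in self.lengths):
            raise ValueError("negative branch length")

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids()]  # type: ignore[misc]

    def tip_label_set(self) -> frozenset[str]:
        return frozenset(self.tip_labels())

    def tip_id_map(self) -> dict[str, int]:
        return {self.labels[i]: i for i in self.tip_ids()}  # type: ignore[misc]

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children[v]))

    def postorder(self) -> Iterator[int]:
        out: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return reversed(out)

    def subtree_nodes(self, node: int) -> list[int]:
        """All nodes in the subtree rooted at ``node`` (inclusive)."""
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def subtree_tip_labels(self, node: int) -> frozenset[str]:
        return frozenset(
            self.labels[v] for v in self.subtree_nodes(node) if not self.children[v]
        )

    def depths(self) -> list[float]:
        """Path length from the root to every node (root edge excluded)."""
        d = [0.0] * self.n_nodes
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    def copy(self) -> "Tree":
        return Tree(
            list(self.parent),
            [list(c) for c in self.children],
            list(self.lengths),
            list(self.labels),
            self.root,
        )

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree {len(self.tip_ids())} tips, {self.n_nodes} nodes>"


@dataclass
class PosteriorTreeSet:
    """An ordered sample of dated trees sharing one tip-label set.

    ``translate_map`` records the NEXUS translate table (token -> label)
    when one was present; trees themselves always carry full labels.
    """

    trees: list[Tree]
    translate_map: dict[str, str] = field(default_factory=dict)
    burnin_fraction: float = 0.0

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Tree]:
        return iter(self.trees)


# ---------------------------------------------------------------------------
# parsing / writing


def _check_parentheses(text: str) -> None:
    depth = 0
    in_quote = False
    for offset, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError(
                        f"unbalanced ')' at character offset {offset}"
                    )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at character offset {len(text)}"
        )


def _from_dendropy(dtree: "dendropy.Tree") -> Tree:
    parent: list[int] = []
    children: list[list[int]] = []
    lengths: list[float] = []
    labels: list[str | None] = []
    index: dict = {}
    for nd in dtree.preorder_node_iter():
        nid = len(parent)
        index[nd] = nid
        pid = index[nd.parent_node] if nd.parent_node is not None else -1
        parent.append(pid)
        children.append([])
        lengths.append(float(nd.edge.length) if nd.edge.length is not None else 0.0)
        if nd.taxon is not None:
            labels.append(nd.taxon.label)
        else:
            labels.append(nd.label)
        if pid >= 0:
            children[pid].append(nid)
    tree = Tree(parent, children, lengths, labels)
    tree._validate()
    return tree


def parse_newick(text: str) -> Tree:
    """Parse a single Newick string into a :class:`Tree`.

    Branch lengths default to 0 when absent; polytomies are preserved.
    Raises :class:`NewickParseError` (naming a character offset for
    unbalanced parentheses) on malformed input.
    """
    _check_parentheses(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, precision: int = 10, label_fn=None) -> str:
    """Serialize a tree to Newick with ``precision`` significant digits.

    ``label_fn`` optionally maps a tip label to the token written (used for
    NEXUS translate tables).
    """
    fmt = f":%.{precision}g"

    def _node(v: int) -> str:
        if not tree.children[v]:
            lab = tree.labels[v] or ""
            tok = label_fn(lab) if label_fn else _quote_label(lab)
            return tok + (fmt % tree.lengths[v])
        inner = ",".join(_node(c) for c in tree.children[v])
        if v == tree.root:
            return f"({inner})"
        return f"({inner})" + (fmt % tree.lengths[v])

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, tree.n_nodes + 100))
    try:
        return _node(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


_TRANSLATE_RE = re.compile(r"\btranslate\b(.*?);", re.IGNORECASE | re.DOTALL)


def _parse_translate_map(text: str) -> dict[str, str]:
    m = _TRANSLATE_RE.search(text)
    if not m:
        return {}
    out: dict[str, str] = {}
    for entry in m.group(1).split(","):
        entry = entry.strip()
        if not entry:
            continue
        parts = entry.split(None, 1)
        if len(parts) == 2:
            token, label = parts
            out[token] = label.strip().strip("'").replace("''", "'")
    return out


def parse_nexus_trees(text: str, burnin_fraction: float = 0.0) -> PosteriorTreeSet:
    """Parse a NEXUS TREES block into a :class:`PosteriorTreeSet`.

    Translate tables, quoted labels, and square-bracket comments (including
    BEAST-style metadata) are tolerated; metadata comments are discarded.
    The first ``floor(burnin_fraction * N)`` trees are dropped; order is
    preserved.  Trees with mismatched tip sets raise
    :class:`NexusParseError` naming the offending tree index.
    """
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must be in [0, 1)")
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema="nexus",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise NexusParseError(f"invalid NEXUS: {exc}") from exc
    if len(tree_list) == 0:
        raise NexusParseError("NEXUS file contains no trees")
    trees = [_from_dendropy(t) for t in tree_list]
    ref = trees[0].tip_label_set()
    for i, t in enumerate(trees):
        if t.tip_label_set() != ref:
            raise NexusParseError(
                f"tree {i} has a different tip set from tree 0 "
                f"(difference: {sorted(ref ^ t.tip_label_set())})"
            )
    n_drop = math.floor(burnin_fraction * len(trees))
    return PosteriorTreeSet(
        trees=trees[n_drop:],
        translate_map=_parse_translate_map(text),
        burnin_fraction=burnin_fraction,
    )


def write_nexus_trees(trees: Sequence[Tree], precision: int = 10) -> str:
    """Write trees as a NEXUS TREES block with a translate table."""
    if not trees:
        raise ValueError("no trees to write")
    labels = sorted(trees[0].tip_label_set())
    token = {lab: str(i + 1) for i, lab in enumerate(labels)}
    lines = ["#NEXUS", "BEGIN TREES;", "\tTRANSLATE"]
    for i, lab in enumerate(labels):
        sep = "," if i < len(labels) - 1 else ""
        lines.append(f"\t\t{token[lab]} {_quote_label(lab)}{sep}")
    lines.append("\t;")
    for i, t in enumerate(trees):
        nwk = write_newick(t, precision=precision, label_fn=lambda l: token[l])
        lines.append(f"\tTREE STATE_{i} = [&R] {nwk}")
    lines.append("END;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# clade and age utilities


def _resolve_tip_ids(tree: Tree, tips: Iterable[str]) -> list[int]:
    tip_map = tree.tip_id_map()
    ids = []
    for label in tips:
        if label not in tip_map:
            raise KeyError(f"unknown tip label: {label!r}")
        ids.append(tip_map[label])
    if not ids:
        raise ValueError("tip set must be non-empty")
    return ids


def mrca(tree: Tree, tips: Iterable[str]) -> int:
    """Most recent common ancestor (node id) of a set of tip labels.

    The MRCA of a single tip is that tip itself.
    """
    ids = _resolve_tip_ids(tree, tips)
    # depth = number of edges from root, computed by walking parents
    depth = {}

    def _depth(v: int) -> int:
        d = 0
        u = v
        while tree.parent[u] >= 0:
            u = tree.parent[u]
            d += 1
        return d

    current = ids[0]
    cur_depth = _depth(current)
    for v in ids[1:]:
        d = _depth(v)
        a, b, da, db = current, v, cur_depth, d
        while da > db:
            a = tree.parent[a]
            da -= 1
        while db > da:
            b = tree.parent[b]
            db -= 1
        while a != b:
            a = tree.parent[a]
            b = tree.parent[b]
            da -= 1
        current, cur_depth = a, da
    return current


def _check_ultrametric(
    tree: Tree, depths: list[float], tolerance: float
) -> None:
    tip_depths = [depths[i] for i in tree.tip_ids()]
    max_path = max(tip_depths)
    if max_path <= 0:
        return
    deviation = (max_path - min(tip_depths)) / max_path
    if deviation > tolerance:
        raise UltrametricityError(
            f"tree is not ultrametric: max relative root-to-tip deviation "
            f"{deviation:.3e} exceeds tolerance {tolerance:.3e}"
        )


def node_age(
    tree: Tree, node: int, tolerance: float = DEFAULT_ULTRAMETRIC_TOL
) -> float:
    """Age of ``node`` in a dated (ultrametric) tree.

    Age is the mean path length from the node to its descendant tips, so
    tips have age 0 and sampler jitter averages out.  Raises
    :class:`UltrametricityError` when root-to-tip path sums deviate by more
    than ``tolerance`` (relative to the longest path).
    """
    depths = tree.depths()
    _check_ultrametric(tree, depths, tolerance)
    tip_depths = [
        depths[v] for v in tree.subtree_nodes(node) if not tree.children[v]
    ]
    return sum(tip_depths) / len(tip_depths) - depths[node]


def node_ages(
    tree: Tree, tolerance: float = DEFAULT_ULTRAMETRIC_TOL
) -> list[float]:
    """Ages of all nodes at once (same definition as :func:`node_age`)."""
    depths = tree.depths()
    _check_ultrametric(tree, depths, tolerance)
    n_tips = [0] * tree.n_nodes
    sum_depth = [0.0] * tree.n_nodes
    for v in tree.postorder():
        if not tree.children[v]:
            n_tips[v] = 1
            sum_depth[v] = depths[v]
        else:
            for c in tree.children[v]:
                n_tips[v] += n_tips[c]
                sum_depth[v] += sum_depth[c]
    return [sum_depth[v] / n_tips[v] - depths[v] for v in range(tree.n_nodes)]


def is_monophyletic(tree: Tree, tips: Iterable[str]) -> bool:
    """True iff the MRCA of ``tips`` has exactly ``tips`` as descendants."""
    tip_set = frozenset(tips)
    anc = mrca(tree, tip_set)
    return tree.subtree_tip_labels(anc) == tip_set


def resolve_polytomies(tree: Tree, seed: int = 0) -> tuple[Tree, int]:
    """Arbitrarily resolve polytomies with zero-length edges (seeded).

    Returns the resolved tree and the number of polytomies resolved.
    """
    import random

    rng = random.Random(seed)
    n_resolved = 0

    def _nested(v: int):
        kids = [_nested(c) for c in tree.children[v]]
        if not kids:
            return (tree.labels[v], tree.lengths[v], [])
        while len(kids) > 2:
            i = rng.randrange(len(kids))
            a = kids.pop(i)
            j = rng.randrange(len(kids))
            b = kids.pop(j)
            kids.append((None, 0.0, [a, b]))
        return (tree.labels[v], tree.lengths[v], kids)

    n_resolved = sum(1 for c in tree.children if len(c) > 2)
    return Tree.from_nested(_nested(tree.root)), n_resolved


def extract_subtree(tree: Tree, keep_tips: Iterable[str]) -> Tree:
    """Subtree induced on ``keep_tips``.

    Degree-2 nodes are suppressed with branch lengths summed; the new root
    is the surviving common ancestor of the kept tips and its root-edge
    length is dropped.
    """
    keep = frozenset(keep_tips)
    unknown = keep - tree.tip_label_set()
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least two tips to induce a subtree")

    def _reduce(v: int):
        if not tree.children[v]:
            if tree.labels[v] in keep:
                return (tree.labels[v], tree.lengths[v], [])
            return None
        kept = [r for r in (_reduce(c) for c in tree.children[v]) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            lab, length, kids = kept[0]
            return (lab, length + tree.lengths[v], kids)
        return (tree.labels[v], tree.lengths[v], kept)

    reduced = _reduce(tree.root)
    assert reduced is not None
    lab, _length, kids = reduced
    return Tree.from_nested((lab, 0.0, kids))
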