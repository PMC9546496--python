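"""Poisson Tree Processes lineage delimitation (single- and multi-rate).

Model: every edge of the tree belongs to exactly one class — the
between-lineage ("speciation") class, or a within-lineage ("coalescent")
class.  Edge lengths within a class are i.i.d. exponential; the profile
log-likelihood contribution of a class with ``n`` edges of total length
``S`` at its plug-in MLE rate ``lambda = n / S`` is ``n*ln(n/S) - n``.

A delimitation is encoded by its *transition nodes*: an antichain of nodes
covering every tip.  Tips below a transition node form one lineage; edges
strictly below transition nodes are coalescent, everything else (including
the transition nodes' own parent edges) is speciation.  Placing the single
transition at the root yields the one-lineage null model in which all
edges are pooled into one class.

Because the objective depends on the partition alone, small trees admit an
exhaustive oracle (:func:`delimit_exhaustive`); larger trees are searched
with a seeded multi-restart hill climb (:func:`delimit_search`).

An optional likelihood-ratio guard against the one-lineage null model
(chi-square, as in the mPTP family of tools) prevents spurious splitting
when edge lengths carry no rate signal; it is off in the oracle by default
so that oracle and search can be compared on the raw maximum-likelihood
objective.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .treeio import Tree, extract_subtree, is_monophyletic, mrca

__all__ = [
    "Delimitation",
    "DelimitationConfig",
    "crop_outgroup",
    "ptp_loglik",
    "delimit_exhaustive",
    "delimit_search",
    "auto_min_branch_length",
]

MAX_EXHAUSTIVE_TIPS = 12


@dataclass(frozen=True)
class Delimitation:
    """A partition of tips into lineages with its edge classification."""

    lineages: tuple[frozenset[str], ...]
    transition_nodes: tuple[int, ...]
    speciation_edges: frozenset[int]  # node ids whose parent edge is speciation
    coalescent_rates: tuple[float | None, ...]  # per lineage (multi) or (pooled,)
    speciation_rate: float | None
    log_likelihood: float
    mode: str
    degenerate: bool = False
    n_excluded_edges: int = 0

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def tip_to_lineage(self) -> dict[str, int]:
        """Map tip label -> lineage index (lineages sorted by smallest tip)."""
        out: dict[str, int] = {}
        for i, lin in enumerate(self.lineages):
            for tip in lin:
                out[tip] = i
        return out

    def partition_key(self) -> tuple[tuple[str, ...], ...]:
        return tuple(sorted(tuple(sorted(lin)) for lin in self.lineages))


@dataclass
class DelimitationConfig:
    mode: str = "multi"  # "single" | "multi"
    min_branch_length: float = 0.0
    outgroup: frozenset[str] = frozenset()
    search: str = "hillclimb"  # "exhaustive" | "hillclimb"
    seed: int = 0
    restarts: int = 8
    max_exhaustive_tips: int = MAX_EXHAUSTIVE_TIPS
    lrt_alpha: float | None = 0.001  # None disables the null-model guard

    def __post_init__(self) -> None:
        if self.mode not in ("single", "multi"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.min_branch_length < 0:
            raise ValueError("min_branch_length must be >= 0")


def auto_min_branch_length(alignment_length: int) -> float:
    """Noise floor for branch lengths: one substitution across the alignment."""
    if alignment_length <= 0:
        raise ValueError("alignment_length must be > 0")
    return 1.0 / alignment_length


def crop_outgroup(tree: Tree, outgroup: set[str]) -> Tree:
    """Remove outgroup tips and reroot at the surviving ingroup ancestor.

    Degree-2 nodes are suppressed with branch lengths summed.  A
    non-monophyletic outgroup triggers a warning but is cropped tip by tip
    all the same.
    """
    outgroup = set(outgroup)
    if not outgroup:
        return tree.copy()
    all_tips = tree.tip_label_set()
    unknown = outgroup - all_tips
    if unknown:
        raise KeyError(f"unknown outgroup tips: {sorted(unknown)}")
    remaining = all_tips - outgroup
    if len(remaining) < 3:
        raise ValueError("fewer than 3 tips would remain after cropping")
    if not is_monophyletic(tree, outgroup):
        warnings.warn(
            "outgroup is not monophyletic; cropping each outgroup tip "
            "individually",
            stacklevel=2,
        )
    return extract_subtree(tree, remaining)


# ---------------------------------------------------------------------------
# likelihood machinery


class _Workspace:
    """Per-tree precomputation making the objective O(k) per partition.

    Edges shorter than ``min_branch_length`` are excluded from every class
    (but retained in the topology).  For each node ``v`` the number and
    total length of *included* edges strictly below ``v`` are precomputed,
    so any class term is an O(1) lookup.
    """

    def __init__(self, tree: Tree, min_branch_length: float = 0.0) -> None:
        self.tree = tree
        self.minbr = min_branch_length
        n = tree.n_nodes
        include = [False] * n
        for v in range(n):
            if v != tree.root and tree.lengths[v] >= min_branch_length:
                include[v] = True
        ecnt = [0] * n
        esum = [0.0] * n
        for v in tree.postorder():
            for c in tree.children[v]:
                ecnt[v] += ecnt[c] + (1 if include[c] else 0)
                esum[v] += esum[c] + (tree.lengths[c] if include[c] else 0.0)
        self.include = include
        self.ecnt = ecnt
        self.esum = esum
        # Euler intervals for O(1) ancestor tests in compound search moves
        tin = [0] * n
        tout = [0] * n
        clock = 0
        stack: list[tuple[int, bool]] = [(tree.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                tout[v] = clock
                continue
            tin[v] = clock
            clock += 1
            stack.append((v, True))
            stack.extend((c, False) for c in tree.children[v])
        self.tin = tin
        self.tout = tout
        self.n_total = ecnt[tree.root]
        self.s_total = esum[tree.root]
        self.n_excluded = sum(
            1 for v in range(n) if v != tree.root and not include[v]
        )

    @staticmethod
    def class_term(n: int, s: float) -> tuple[float, bool]:
        """Profile log-likelihood of one exponential class; (term, degenerate)."""
        if n == 0:
            return 0.0, False
        if s <= 0.0:
            return 0.0, True  # positive count but zero length: flag
        return n * math.log(n / s) - n, False

    def loglik(self, transitions: tuple[int, ...], mode: str):
        """(logL, degenerate, n_classes_with_edges, rates) for a partition.

        ``transitions`` must be sorted so that float summation order — and
        hence the returned value — is identical no matter which search
        path produced the partition.
        """
        n_co = 0
        s_co = 0.0
        for t in transitions:
            n_co += self.ecnt[t]
            s_co += self.esum[t]
        n_sp = self.n_total - n_co
        s_sp = self.s_total - s_co
        logl, degenerate = self.class_term(n_sp, s_sp)
        n_classes = 1 if n_sp > 0 else 0
        sp_rate = (n_sp / s_sp) if n_sp > 0 and s_sp > 0 else None
        if mode == "single":
            term, deg = self.class_term(n_co, s_co)
            logl += term
            degenerate = degenerate or deg
            if n_co > 0:
                n_classes += 1
            rates = ((n_co / s_co) if n_co > 0 and s_co > 0 else None,)
        else:
            rate_list = []
            for t in transitions:
                term, deg = self.class_term(self.ecnt[t], self.esum[t])
                logl += term
                degenerate = degenerate or deg
                if self.ecnt[t] > 0:
                    n_classes += 1
                rate_list.append(
                    (self.ecnt[t] / self.esum[t])
                    if self.ecnt[t] > 0 and self.esum[t] > 0
                    else None
                )
            rates = tuple(rate_list)
        return logl, degenerate, n_classes, sp_rate, rates


def _lineage_sets(tree: Tree, transitions: tuple[int, ...]):
    return [tree.subtree_tip_labels(t) for t in transitions]


def _partition_key(tree: Tree, transitions: tuple[int, ...]):
    return tuple(sorted(tuple(sorted(s)) for s in _lineage_sets(tree, transitions)))


def _build_delimitation(
    tree: Tree,
    ws: _Workspace,
    transitions: tuple[int, ...],
    mode: str,
) -> Delimitation:
    transitions = tuple(sorted(transitions))
    logl, degenerate, _nc, sp_rate, rates = ws.loglik(transitions, mode)
    # order lineages (and multi-mode rates) by smallest tip label
    tip_sets = _lineage_sets(tree, transitions)
    order = sorted(range(len(transitions)), key=lambda i: min(tip_sets[i]))
    lineages = tuple(tip_sets[i] for i in order)
    if mode == "multi":
        rates = tuple(rates[i] for i in order)
    below: set[int] = set()
    for t in transitions:
        below.update(tree.subtree_nodes(t))
        below.discard(t)
    spec_edges = frozenset(
        v for v in range(tree.n_nodes) if v != tree.root and v not in below
    )
    return Delimitation(
        lineages=lineages,
        transition_nodes=tuple(transitions[i] for i in order),
        speciation_edges=spec_edges,
        coalescent_rates=rates,
        speciation_rate=sp_rate,
        log_likelihood=logl,
        mode=mode,
        degenerate=degenerate or ws.n_total == 0,
        n_excluded_edges=ws.n_excluded,
    )


def ptp_loglik(
    tree: Tree,
    transitions: tuple[int, ...] | list[int],
    mode: str = "multi",
    min_branch_length: float = 0.0,
) -> float:
    """Log-likelihood of the delimitation given by ``transitions``.

    ``transitions`` is an antichain of node ids covering all tips (checked).
    """
    _validate_transitions(tree, tuple(transitions))
    ws = _Workspace(tree, min_branch_length)
    logl, _deg, _nc, _sp, _rates = ws.loglik(tuple(sorted(transitions)), mode)
    return logl


def _validate_transitions(tree: Tree, transitions: tuple[int, ...]) -> None:
    covered: set[int] = set()
    trans = set(transitions)
    if len(trans) != len(transitions):
        raise ValueError("duplicate transition nodes")
    for t in transitions:
        sub = tree.subtree_nodes(t)
        if trans & set(sub) - {t}:
            raise ValueError("transition nodes must form an antichain")
        covered.update(v for v in sub if not tree.children[v])
    all_tips = set(tree.tip_ids())
    if covered != all_tips:
        raise ValueError("transition nodes must cover every tip exactly once")


# ---------------------------------------------------------------------------
# exhaustive oracle


def _enumerate_antichains(tree: Tree) -> list[tuple[int, ...]]:
    """All antichains covering the tips, i.e. all valid delimitations."""

    def _options(v: int) -> list[tuple[int, ...]]:
        opts = [(v,)]
        if tree.children[v]:
            child_opts = [_options(c) for c in tree.children[v]]
            for combo in itertools.product(*child_opts):
                opts.append(tuple(x for part in combo for x in part))
        return opts

    return _options(tree.root)


def _apply_lrt_guard(
    tree: Tree,
    ws: _Workspace,
    best: tuple[int, ...],
    mode: str,
    lrt_alpha: float | None,
) -> tuple[int, ...]:
    """Fall back to the one-lineage null unless the best delimitation is a
    significantly better fit (likelihood-ratio test, chi-square with df =
    extra rate parameters)."""
    if lrt_alpha is None:
        return best
    null = (tree.root,)
    if tuple(sorted(best)) == null:
        return best
    logl_best, _d, nc_best, _s, _r = ws.loglik(tuple(sorted(best)), mode)
    logl_null, _d, nc_null, _s, _r = ws.loglik(null, mode)
    df = max(1, nc_best - nc_null)
    stat = 2.0 * (logl_best - logl_null)
    if stat <= 0 or chi2.sf(stat, df) > lrt_alpha:
        return null
    return best


def delimit_exhaustive(
    tree: Tree,
    mode: str = "multi",
    min_branch_length: float = 0.0,
    max_exhaustive_tips: int = MAX_EXHAUSTIVE_TIPS,
    lrt_alpha: float | None = None,
) -> Delimitation:
    """Enumerate every valid delimitation and return the maximum-logL one.

    Ties are broken toward fewer lineages, then toward the
    lexicographically smallest lineage partition.  Only allowed on trees
    with at most ``max_exhaustive_tips`` tips; use :func:`delimit_search`
    beyond that.
    """
    n_tips = len(tree.tip_ids())
    if n_tips > max_exhaustive_tips:
        raise ValueError(
            f"tree has {n_tips} tips > max_exhaustive_tips="
            f"{max_exhaustive_tips}; use delimit_search"
        )
    ws = _Workspace(tree, min_branch_length)
    if ws.n_total == 0:
        return _build_delimitation(tree, ws, (tree.root,), mode)
    best = None
    best_score = None
    for trans in _enumerate_antichains(tree):
        trans = tuple(sorted(trans))
        logl, _deg, _nc, _sp, _rates = ws.loglik(trans, mode)
        score = (logl, -len(trans))
        if best_score is None or score > best_score:
            best, best_score = trans, score
        elif score == best_score and _partition_key(tree, trans) < _partition_key(
            tree, best
        ):
            best = trans
    best = _apply_lrt_guard(tree, ws, best, mode, lrt_alpha)
    return _build_delimitation(tree, ws, best, mode)


# ---------------------------------------------------------------------------
# hill-climbing search


def _random_antichain(tree: Tree, rng: np.random.Generator) -> tuple[int, ...]:
    stop_p = rng.uniform(0.2, 0.8)
    out: list[int] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if not tree.children[v] or rng.random() < stop_p:
            out.append(v)
        else:
            stack.extend(tree.children[v])
    return tuple(out)


def _depth_frontiers(tree: Tree) -> list[tuple[int, ...]]:
    """Antichain at each edge-depth level: nodes at depth d plus shallower
    tips.  Deterministic starts that approximate species-level frontiers."""
    depth = [0] * tree.n_nodes
    for v in tree.preorder():
        if v != tree.root:
            depth[v] = depth[tree.parent[v]] + 1
    max_depth = max(depth)
    frontiers = []
    for d in range(1, max_depth):
        frontier = tuple(
            v
            for v in range(tree.n_nodes)
            if depth[v] == d or (depth[v] < d and not tree.children[v])
        )
        if len(frontier) > 1:
            frontiers.append(frontier)
    return frontiers


def _hillclimb(
    tree: Tree, ws: _Workspace, start: tuple[int, ...], mode: str
):
    current = set(start)

    def evaluate(trans_set: set[int]):
        trans = tuple(sorted(trans_set))
        logl, *_ = ws.loglik(trans, mode)
        return logl

    cur_logl = evaluate(current)
    tin, tout = ws.tin, ws.tout
    while True:
        best_cand = None
        best_logl = cur_logl
        candidates: list[set[int]] = []
        # splits: push a transition down onto its children; atomize: push it
        # all the way down to its tips
        for t in current:
            if tree.children[t]:
                candidates.append((current - {t}) | set(tree.children[t]))
                tips_below = {
                    v for v in tree.subtree_nodes(t) if not tree.children[v]
                }
                if len(tips_below) > 2:
                    candidates.append((current - {t}) | tips_below)
        # merges: pull transitions up to any strict ancestor that dominates
        # two or more of them (one-level sibling merges are a special case)
        for v in range(tree.n_nodes):
            if not tree.children[v] or v in current:
                continue
            dominated = {
                t for t in current if tin[v] < tin[t] and tout[t] <= tout[v]
            }
            if len(dominated) >= 2:
                # the antichain property guarantees these cover all of v's
                # tips, so the replacement is always a valid delimitation
                candidates.append((current - dominated) | {v})
        for cand in candidates:
            logl = evaluate(cand)
            if _better(logl, cand, best_logl, best_cand, current, tree):
                best_cand, best_logl = cand, logl
        if best_cand is None:
            return tuple(sorted(current)), cur_logl
        current, cur_logl = best_cand, best_logl


def _better(logl, cand, ref_logl, ref_cand, current, tree) -> bool:
    """Ordering used for move acceptance: higher logL, then fewer lineages,
    then lexicographically smaller partition (guarantees termination)."""
    ref = ref_cand if ref_cand is not None else current
    if logl != ref_logl:
        return logl > ref_logl
    if len(cand) != len(ref):
        return len(cand) < len(ref)
    return _partition_key(tree, tuple(cand)) < _partition_key(tree, tuple(ref))


def delimit_search(tree: Tree, config: DelimitationConfig) -> Delimitation:
    """Seeded multi-restart hill climb over delimitations.

    Starts from the one-lineage null, the all-singleton delimitation, and
    ``config.restarts`` random antichains; each climb moves transition
    points one edge down (split) or up (merge) until no move improves the
    objective.  Deterministic given ``config.seed``.
    """
    if config.outgroup:
        tree = crop_outgroup(tree, set(config.outgroup))
    if not tree.is_binary():
        raise ValueError(
            "delimit_search requires a binary tree; resolve polytomies first"
        )
    n_tips = len(tree.tip_ids())
    if n_tips < 4:
        raise ValueError("delimit_search requires at least 4 tips")
    ws = _Workspace(tree, config.min_branch_length)
    if ws.n_total == 0:
        return _build_delimitation(tree, ws, (tree.root,), config.mode)
    if config.search == "exhaustive":
        return delimit_exhaustive(
            tree,
            config.mode,
            config.min_branch_length,
            config.max_exhaustive_tips,
            config.lrt_alpha,
        )
    rng = np.random.default_rng(config.seed)
    starts: list[tuple[int, ...]] = [
        (tree.root,),
        tuple(tree.tip_ids()),
    ]
    starts.extend(_depth_frontiers(tree))
    for _ in range(config.restarts):
        starts.append(_random_antichain(tree, rng))
    best = None
    best_logl = -math.inf
    n_reached_best = 0
    for start in starts:
        trans, logl = _hillclimb(tree, ws, start, config.mode)
        if best is None or logl > best_logl:
            best, best_logl, n_reached_best = trans, logl, 1
        elif logl == best_logl:
            n_reached_best += 1
            if len(trans) < len(best) or (
                len(trans) == len(best)
                and _partition_key(tree, trans) < _partition_key(tree, best)
            ):
                best = trans
    best = _apply_lrt_guard(tree, ws, best, config.mode, config.lrt_alpha)
    return _build_delimitation(tree, ws, best, config.mode)
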