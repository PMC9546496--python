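"""Spatial congruence of between-lineage divergences with river barriers.

Condition 1 of the barrier test: a divergence is congruent with a river
when its two child clades are distinct delimited lineages found only on
opposite banks.  Verdicts are computed from sampled tips only; tips with
indeterminate or missing bank assignments are treated as missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .geography import INDETERMINATE, LEFT, RIGHT, RiverBarrier
from .treeio import Tree, node_ages

__all__ = [
    "DivergenceRecord",
    "CongruenceSummary",
    "enumerate_lineage_divergences",
    "classify_spatial_congruence",
    "find_barrier_violations",
    "summarize",
]

logger = logging.getLogger(__name__)

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
UNEVALUABLE = "unevaluable"


@dataclass(frozen=True)
class DivergenceRecord:
    node_id: int
    child_a_tips: frozenset[str]
    child_b_tips: frozenset[str]
    lineages_a: frozenset[int]
    lineages_b: frozenset[int]
    river_name: str
    spatial_verdict: str
    n_determinate_a: int
    n_determinate_b: int

    @property
    def low_support(self) -> bool:
        """True when a congruent verdict rests on a single-sample side."""
        return self.spatial_verdict == CONGRUENT and (
            self.n_determinate_a == 1 or self.n_determinate_b == 1
        )


@dataclass
class CongruenceSummary:
    n_total_divergences: int
    per_river: dict[str, dict[str, int]] = field(default_factory=dict)
    low_support: list[tuple[int, str]] = field(default_factory=list)
    violations: dict[str, list[int]] = field(default_factory=dict)


def _scoped_lineage_sets(
    tree: Tree, tip_to_lineage: dict[str, int], scope: set[str] | None
):
    """Per-node sets of lineage ids among in-scope tips below the node."""
    tips = tree.tip_label_set()
    if scope is None:
        scope = set(tip_to_lineage)
    else:
        scope = set(scope)
        unknown = scope - tips
        if unknown:
            raise KeyError(f"scope tips not in tree: {sorted(unknown)}")
    uncovered = scope - set(tip_to_lineage)
    if uncovered:
        raise ValueError(
            f"delimitation does not cover scope tips: {sorted(uncovered)}"
        )
    lin_below: list[frozenset[int]] = [frozenset()] * tree.n_nodes
    for v in tree.postorder():
        if not tree.children[v]:
            lab = tree.labels[v]
            if lab in scope:
                lin_below[v] = frozenset({tip_to_lineage[lab]})
        else:
            acc: set[int] = set()
            for c in tree.children[v]:
                acc |= lin_below[c]
            lin_below[v] = frozenset(acc)
    return lin_below, scope


def enumerate_lineage_divergences(
    tree: Tree,
    tip_to_lineage: dict[str, int],
    scope: set[str] | None = None,
) -> list[int]:
    """Internal nodes whose two children carry disjoint lineage sets.

    Evaluated on the subtree induced by ``scope`` (nodes with in-scope
    tips in only one child are pass-throughs).  Ordered by node age,
    oldest first.
    """
    lin_below, scope = _scoped_lineage_sets(tree, tip_to_lineage, scope)
    out = []
    for v in range(tree.n_nodes):
        kids = [c for c in tree.children[v] if lin_below[c]]
        if len(kids) < 2:
            continue
        if len(kids) > 2:
            raise ValueError(
                f"node {v} has {len(kids)} in-scope children; resolve "
                "polytomies before enumerating divergences"
            )
        a, b = kids
        if lin_below[a] & lin_below[b]:
            continue
        out.append(v)
    if not out:
        logger.info("no between-lineage divergences found in scope")
        return out
    ages = _ordering_ages(tree)
    out.sort(key=lambda v: -ages[v])
    return out


def _ordering_ages(tree: Tree) -> list[float]:
    # mean node-to-tip path; used only for ordering, so no ultrametricity check
    n_tips = [0] * tree.n_nodes
    sum_below = [0.0] * tree.n_nodes
    for v in tree.postorder():
        if not tree.children[v]:
            n_tips[v] = 1
        else:
            for c in tree.children[v]:
                n_tips[v] += n_tips[c]
                sum_below[v] += sum_below[c] + n_tips[c] * tree.lengths[c]
    return [sum_below[v] / n_tips[v] for v in range(tree.n_nodes)]


def _bank_map(bank_table: pd.DataFrame, river_name: str) -> dict[str, str]:
    sub = bank_table[bank_table["river_name"] == river_name]
    return dict(zip(sub["sample_id"], sub["bank"]))


def classify_spatial_congruence(
    tree: Tree,
    node_id: int,
    bank_table: pd.DataFrame,
    river: RiverBarrier,
    tip_to_lineage: dict[str, int],
    scope: set[str] | None = None,
    min_determinate_per_side: int = 1,
) -> DivergenceRecord:
    """Classify one between-lineage divergence against one river.

    Congruent iff each child clade's determinate banks are unanimous, the
    two sides differ, and each side has at least
    ``min_determinate_per_side`` determinate tips; unevaluable when either
    side falls short of that count; incongruent otherwise.
    """
    lin_below, scope = _scoped_lineage_sets(tree, tip_to_lineage, scope)
    kids = [c for c in tree.children[node_id] if lin_below[c]]
    if len(kids) != 2:
        raise ValueError(f"node {node_id} is not a between-lineage divergence")
    a, b = kids
    tips_a = frozenset(l for l in tree.subtree_tip_labels(a) if l in scope)
    tips_b = frozenset(l for l in tree.subtree_tip_labels(b) if l in scope)
    banks = _bank_map(bank_table, river.name)
    det_a = [banks[t] for t in tips_a if banks.get(t) in (LEFT, RIGHT)]
    det_b = [banks[t] for t in tips_b if banks.get(t) in (LEFT, RIGHT)]

    if len(det_a) < min_determinate_per_side or len(det_b) < min_determinate_per_side:
        verdict = UNEVALUABLE
    elif (
        len(set(det_a)) == 1
        and len(set(det_b)) == 1
        and det_a[0] != det_b[0]
        and not (lin_below[a] & lin_below[b])
    ):
        verdict = CONGRUENT
    else:
        verdict = INCONGRUENT
    return DivergenceRecord(
        node_id=node_id,
        child_a_tips=tips_a,
        child_b_tips=tips_b,
        lineages_a=lin_below[a],
        lineages_b=lin_below[b],
        river_name=river.name,
        spatial_verdict=verdict,
        n_determinate_a=len(det_a),
        n_determinate_b=len(det_b),
    )


def find_barrier_violations(
    tip_to_lineage: dict[str, int],
    bank_table: pd.DataFrame,
    river: RiverBarrier,
) -> list[int]:
    """Lineages with determinate tips on both banks of ``river``."""
    banks = _bank_map(bank_table, river.name)
    sides: dict[int, set[str]] = {}
    for tip, lineage in tip_to_lineage.items():
        bank = banks.get(tip)
        if bank in (LEFT, RIGHT):
            sides.setdefault(lineage, set()).add(bank)
    return sorted(l for l, s in sides.items() if len(s) == 2)


def summarize(
    records: list[DivergenceRecord],
    rivers: list[RiverBarrier],
    violations: dict[str, list[int]] | None = None,
) -> CongruenceSummary:
    """Per-river and overall congruence counts.

    A divergence counts once overall (``n_total_divergences`` is the
    number of distinct nodes); per-river counts tally evaluable verdicts
    for that river.
    """
    n_total = len({r.node_id for r in records})
    per_river: dict[str, dict[str, int]] = {
        r.name: {
            "n_congruent": 0,
            "n_incongruent": 0,
            "n_unevaluable": 0,
            "n_evaluable": 0,
        }
        for r in rivers
    }
    low_support = []
    for rec in records:
        if rec.river_name not in per_river:
            per_river[rec.river_name] = {
                "n_congruent": 0,
                "n_incongruent": 0,
                "n_unevaluable": 0,
                "n_evaluable": 0,
            }
        counts = per_river[rec.river_name]
        if rec.spatial_verdict == CONGRUENT:
            counts["n_congruent"] += 1
            counts["n_evaluable"] += 1
        elif rec.spatial_verdict == INCONGRUENT:
            counts["n_incongruent"] += 1
            counts["n_evaluable"] += 1
        else:
            counts["n_unevaluable"] += 1
        if rec.low_support:
            low_support.append((rec.node_id, rec.river_name))
    return CongruenceSummary(
        n_total_divergences=n_total,
        per_river=per_river,
        low_support=low_support,
        violations=violations or {},
    )
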