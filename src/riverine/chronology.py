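"""Divergence chronology: node-age posteriors, HPDs, synchrony, river ages.

Condition 2 of the barrier test: a divergence is temporally congruent with
a river when it does not demonstrably postdate river formation, i.e. when
the upper bound of its 95% HPD reaches the river's geological minimum age.
Synchrony across a river is read from pairwise overlap of the HPDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .treeio import PosteriorTreeSet, mrca, node_age

__all__ = [
    "AgePosterior",
    "TemporalVerdict",
    "mrca_ages_posterior",
    "hpd",
    "intervals_overlap",
    "synchrony_groups",
    "temporal_congruence",
    "exp_calibration_mean",
]

RULE_NOT_POSTDATE = "hpd_high >= river.min_age_ma"
RULE_STRICT = "hpd_low >= river.min_age_ma or min_age_ma in hpd"


@dataclass(frozen=True)
class AgePosterior:
    """Posterior sample of a clade's MRCA age across dated trees."""

    clade_tips: frozenset[str]
    samples: tuple[float, ...]
    monophyly_fraction: float
    hpd_low: float
    hpd_high: float
    level: float = 0.95

    @property
    def interval(self) -> tuple[float, float]:
        return (self.hpd_low, self.hpd_high)


@dataclass(frozen=True)
class TemporalVerdict:
    river_name: str
    congruent: bool
    rule: str = RULE_NOT_POSTDATE


def mrca_ages_posterior(
    posterior: PosteriorTreeSet,
    clade_tips: set[str],
    level: float = 0.95,
    tolerance: float = 1e-4,
) -> AgePosterior:
    """Extract the MRCA age of ``clade_tips`` from every posterior tree.

    Ages are recorded whether or not the clade is monophyletic in a given
    tree (the MRCA may then be a deeper node); ``monophyly_fraction``
    exposes how often the clade held together.
    """
    if len(posterior.trees) == 0:
        raise ValueError("posterior tree set is empty")
    clade = frozenset(clade_tips)
    samples = []
    n_mono = 0
    for tree in posterior.trees:
        anc = mrca(tree, clade)
        samples.append(node_age(tree, anc, tolerance=tolerance))
        if tree.subtree_tip_labels(anc) == clade:
            n_mono += 1
    low, high = hpd(samples, level)
    return AgePosterior(
        clade_tips=clade,
        samples=tuple(samples),
        monophyly_fraction=n_mono / len(samples),
        hpd_low=low,
        hpd_high=high,
        level=level,
    )


def hpd(samples, level: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval of a sample.

    The shortest contiguous window over the sorted samples containing
    ``ceil(level * n)`` points; ties are broken toward the earliest
    (smallest lower bound) window.
    """
    s = sorted(samples)
    n = len(s)
    if n == 0:
        raise ValueError("samples must be non-empty")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    m = max(1, math.ceil(level * n))
    best = (s[m - 1] - s[0], 0)
    for i in range(1, n - m + 1):
        width = s[i + m - 1] - s[i]
        if width < best[0]:
            best = (width, i)
    i = best[1]
    return (s[i], s[i + m - 1])


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Closed-interval overlap; touching endpoints count."""
    return a[0] <= b[1] and b[0] <= a[1]


def synchrony_groups(intervals: dict[str, tuple[float, float]]):
    """Partition named intervals into synchrony groups.

    Groups are connected components of the pairwise-overlap graph; each is
    annotated with whether it is a clique (every pair overlapping — the
    strict sense of synchrony) or merely chained together.
    Returns a list of dicts ``{"members": [names...], "clique": bool}``,
    ordered by the smallest lower bound in the group.
    """
    if not intervals:
        raise ValueError("need at least one interval")
    g = nx.Graph()
    g.add_nodes_from(intervals)
    names = list(intervals)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if intervals_overlap(intervals[a], intervals[b]):
                g.add_edge(a, b)
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        clique = all(
            intervals_overlap(intervals[a], intervals[b])
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        groups.append({"members": members, "clique": clique})
    groups.sort(key=lambda grp: min(intervals[m][0] for m in grp["members"]))
    return groups


def temporal_congruence(
    interval: tuple[float, float], river, rule: str = "not-postdate"
) -> TemporalVerdict:
    """Temporal congruence of an HPD with a river's minimum formation age.

    ``not-postdate`` (default): congruent iff ``hpd_high >= min_age_ma`` —
    the divergence is not demonstrably younger than the river (boundary
    inclusive).  ``strict``: congruent iff the HPD contains or exceeds the
    minimum age; for valid intervals this coincides with the default and
    is kept as a named variant for reporting.
    """
    low, high = interval
    if river.min_age_ma is None:
        raise ValueError(f"river {river.name!r} has no min_age_ma")
    if rule == "not-postdate":
        return TemporalVerdict(river.name, high >= river.min_age_ma, RULE_NOT_POSTDATE)
    if rule == "strict":
        ok = low >= river.min_age_ma or (low <= river.min_age_ma <= high)
        return TemporalVerdict(river.name, ok, RULE_STRICT)
    raise ValueError(f"unknown temporal rule: {rule!r}")


def exp_calibration_mean(offset: float, max_age: float, quantile: float = 0.95) -> float:
    """Mean of an offset exponential prior placing ``max_age`` at ``quantile``.

    Used to construct node-age calibration priors where the fossil minimum
    is the offset and the soft maximum sits at the given quantile:
    ``mean = (max_age - offset) / -ln(1 - quantile)``.
    """
    if max_age <= offset:
        raise ValueError("max_age must exceed offset")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    return (max_age - offset) / (-math.log1p(-quantile))
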