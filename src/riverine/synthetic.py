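"""Synthetic inputs with planted truth for every pipeline stage.

Generates (a) dated birth-death species trees, (b) trees with two
exponential branch-length regimes and a known lineage partition, (c)
sample coordinates scattered on planned river banks with a controllable
violation rate, and (d) pseudo-posterior sets of dated trees with
multiplicative age noise.  All generators are deterministic per seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .geography import LEFT, RIGHT, RiverBarrier, haversine_km
from .treeio import PosteriorTreeSet, Tree, node_ages

__all__ = [
    "SimulationConfig",
    "simulate_species_tree",
    "graft_coalescent_samples",
    "graft_dated_samples",
    "simulate_river_geography",
    "perturb_posterior",
    "straight_river",
    "sine_river",
]

KM_PER_DEG_LAT = 111.32


@dataclass
class SimulationConfig:
    n_species: int = 20
    birth_rate: float = 1.0
    death_rate: float = 0.0
    samples_per_species: int = 5
    lambda_speciation: float = 1.0
    lambda_coalescent_mean: float = 20.0
    lambda_coalescent_spread: float = 0.0  # lognormal sigma of per-species rates
    violation_rate: float = 0.0
    age_noise_cv: float = 0.1
    n_posterior_draws: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for name in ("birth_rate", "lambda_speciation", "lambda_coalescent_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.violation_rate <= 1.0:
            raise ValueError("violation_rate must be in [0, 1]")
        if self.death_rate >= self.birth_rate:
            raise ValueError("death_rate must be < birth_rate")


def simulate_species_tree(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
) -> Tree:
    """Constant-rate birth-death tree conditioned on ``n_species`` extant
    tips, dated in Ma (ultrametric).  Tips are relabelled ``sp001``...
    deterministically; identical seeds give identical trees."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    # the general-sampling-approach (gsa_ntax) conditioning draws a uniform
    # time slice with exactly n extant lineages, so the youngest divergence
    # has a proper positive age instead of stopping at the n-th birth event
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_species,
        gsa_ntax=n_species + 3,
        rng=random.Random(seed),
        repeat_until_success=True,
    )

    def _nested(nd):
        kids = nd.child_nodes()
        length = float(nd.edge.length or 0.0)
        if not kids:
            return ("", length, [])
        return (None, length, [_nested(c) for c in kids])

    spec = _nested(dtree.seed_node)
    width = max(3, len(str(n_species)))
    counter = [0]

    def _relabel(node_spec):
        label, length, kids = node_spec
        if not kids:
            counter[0] += 1
            return (f"sp{counter[0]:0{width}d}", length, [])
        return (None, length, [_relabel(k) for k in kids])

    spec = _relabel(spec)
    tree = Tree.from_nested((None, 0.0, spec[2]) if spec[2] else spec)
    return tree


def _coalescent_join(
    labels: list[str], rate: float, rng: np.random.Generator
):
    """Random sequential pairwise joins with Exp(rate) edge lengths."""
    nodes = [(lab, float(rng.exponential(1.0 / rate)), []) for lab in labels]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append((None, float(rng.exponential(1.0 / rate)), [a, b]))
    return nodes[0]


def graft_coalescent_samples(
    species_tree: Tree,
    samples_per_species: int | dict[str, int],
    lambda_speciation: float,
    lambda_coalescent,
    seed: int = 0,
) -> tuple[Tree, dict[str, frozenset[str]]]:
    """Two-regime tree with a planted lineage partition.

    Internal (between-lineage) edges are redrawn Exp(lambda_speciation);
    each species tip is replaced by a coalescent-shaped subtree of its
    samples with edges Exp(lambda_coalescent_i).  ``lambda_coalescent``
    may be a scalar or a per-species dict.  Returns the branch-length tree
    and the true delimitation (species -> sample labels).
    """
    rng = np.random.default_rng(seed)
    species = sorted(species_tree.tip_label_set())

    def _n_samples(sp: str) -> int:
        if isinstance(samples_per_species, dict):
            return samples_per_species[sp]
        return int(samples_per_species)

    def _rate(sp: str) -> float:
        if isinstance(lambda_coalescent, dict):
            return lambda_coalescent[sp]
        return float(lambda_coalescent)

    truth: dict[str, frozenset[str]] = {}

    def _nested(v: int):
        if not species_tree.children[v]:
            sp = species_tree.labels[v]
            n = _n_samples(sp)
            labels = [f"{sp}_{j + 1:02d}" for j in range(n)]
            truth[sp] = frozenset(labels)
            if n == 1:
                return (labels[0], float(rng.exponential(1.0 / lambda_speciation)), [])
            sub = _coalescent_join(labels, _rate(sp), rng)
            # the species' own stem edge is a speciation edge
            return (
                sub[0],
                float(rng.exponential(1.0 / lambda_speciation)),
                sub[2],
            )
        kids = [_nested(c) for c in species_tree.children[v]]
        length = (
            0.0
            if v == species_tree.root
            else float(rng.exponential(1.0 / lambda_speciation))
        )
        return (None, length, kids)

    # draw in a fixed traversal order for reproducibility
    tree = Tree.from_nested(_nested(species_tree.root))
    return tree, truth


def graft_dated_samples(
    species_tree: Tree,
    samples: dict[str, frozenset[str]],
    seed: int = 0,
    depth_fraction: float = 0.3,
) -> Tree:
    """Ultrametric sample-level tree matching a dated species tree.

    Each species tip is replaced by a random binary subtree of its samples
    whose join ages are drawn below ``depth_fraction`` of the species'
    stem-parent age, so within-species coalescences are always younger
    than between-species divergences.  Tips sit at age 0.
    """
    rng = np.random.default_rng(seed)
    ages = node_ages(species_tree)

    def _join_with_ages(labels: list[str], max_age: float):
        """Sequential pairwise joins; returns (nested_spec, subtree_root_age)."""
        join_ages = np.sort(rng.uniform(0.0, max_age, size=len(labels) - 1))
        nodes: list[tuple[object, float]] = [((lab, 0.0, []), 0.0) for lab in labels]
        for age in join_ages:
            i = int(rng.integers(len(nodes)))
            a, age_a = nodes.pop(i)
            j = int(rng.integers(len(nodes)))
            b, age_b = nodes.pop(j)
            a = (a[0], age - age_a, a[2])
            b = (b[0], age - age_b, b[2])
            nodes.append(((None, 0.0, [a, b]), float(age)))
        return nodes[0]

    def _nested(v: int):
        if not species_tree.children[v]:
            sp = species_tree.labels[v]
            labs = sorted(samples[sp])
            parent_age = ages[species_tree.parent[v]]
            if len(labs) == 1:
                return (labs[0], parent_age, [])
            spec, root_age = _join_with_ages(labs, depth_fraction * parent_age)
            return (spec[0], parent_age - root_age, spec[2])
        kids = [_nested(c) for c in species_tree.children[v]]
        length = 0.0 if v == species_tree.root else species_tree.lengths[v]
        return (None, length, kids)

    return Tree.from_nested(_nested(species_tree.root))


def straight_river(
    name: str = "synthetic",
    lon: float = -60.0,
    lat_range: tuple[float, float] = (-6.0, 6.0),
    min_age_ma: float = 2.4,
    max_age_ma: float | None = None,
    n_vertices: int = 7,
) -> RiverBarrier:
    """A meridian polyline flowing south-to-north (left bank = west)."""
    lats = np.linspace(lat_range[0], lat_range[1], n_vertices)
    return RiverBarrier(
        name, tuple((lon, float(la)) for la in lats), min_age_ma, max_age_ma
    )


def sine_river(
    name: str = "meander",
    lon: float = -60.0,
    lat_range: tuple[float, float] = (-6.0, 6.0),
    amplitude_deg: float = 0.5,
    wavelength_deg: float = 4.0,
    min_age_ma: float = 2.4,
    n_vertices: int = 121,
) -> RiverBarrier:
    """A meandering (sine-wave) river for geometry edge-case tests."""
    lats = np.linspace(lat_range[0], lat_range[1], n_vertices)
    pts = tuple(
        (lon + amplitude_deg * math.sin(2 * math.pi * la / wavelength_deg), float(la))
        for la in lats
    )
    return RiverBarrier(name, pts, min_age_ma)


def simulate_river_geography(
    true_delimitation: dict[str, frozenset[str]],
    river: RiverBarrier,
    bank_plan: dict[str, str],
    spread_km: float = 10.0,
    violation_rate: float = 0.0,
    seed: int = 0,
    offset_km: float = 60.0,
) -> pd.DataFrame:
    """Coordinates for every sample, jittered around a lineage centroid on
    its planned bank; a ``violation_rate`` fraction of samples (seeded
    Bernoulli) is reflected to the opposite bank.

    Returns a metadata frame with columns sample_id, taxon, latitude,
    longitude, planted_bank (the realized side, for truth checks).
    """
    missing = set(true_delimitation) - set(bank_plan)
    if missing:
        raise ValueError(f"bank_plan does not cover lineages: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    verts = river.polyline
    # cumulative arc positions along the polyline, used to pick centroids
    # away from the termini so samples never fall beyond the mapped extent
    rows = []
    for lineage in sorted(true_delimitation):
        side = bank_plan[lineage]
        if side not in (LEFT, RIGHT):
            raise ValueError(f"bank_plan[{lineage!r}] must be left or right")
        t = rng.uniform(0.15, 0.85) * (len(verts) - 1)
        i = min(int(t), len(verts) - 2)
        frac = t - i
        ax, ay = verts[i]
        bx, by = verts[i + 1]
        cx, cy = ax + frac * (bx - ax), ay + frac * (by - ay)
        dx, dy = bx - ax, by - ay
        norm = math.hypot(dx, dy)
        # unit normal pointing to the LEFT of downstream direction
        nx_, ny_ = -dy / norm, dx / norm
        sign = 1.0 if side == LEFT else -1.0
        for sample in sorted(true_delimitation[lineage]):
            perp_km = offset_km + float(rng.normal(0.0, spread_km))
            perp_km = max(perp_km, 1.0)
            along_km = float(rng.normal(0.0, spread_km))
            if rng.random() < violation_rate:
                realized = RIGHT if side == LEFT else LEFT
                s = -sign
            else:
                realized = side
                s = sign
            # convert the km offsets expressed in the local frame to degrees
            klat = KM_PER_DEG_LAT
            klon = KM_PER_DEG_LAT * math.cos(math.radians(cy))
            lon_pt = cx + (s * perp_km * nx_ + along_km * dx / norm) / klon
            lat_pt = cy + (s * perp_km * ny_ + along_km * dy / norm) / klat
            rows.append((sample, lineage, lat_pt, lon_pt, realized))
    df = pd.DataFrame(
        rows, columns=["sample_id", "taxon", "latitude", "longitude", "planted_bank"]
    )
    return df.sort_values("sample_id", ignore_index=True)


def perturb_posterior(
    dated_tree: Tree,
    n_draws: int,
    age_noise_cv: float,
    seed: int = 0,
    tolerance: float = 1e-4,
) -> PosteriorTreeSet:
    """Pseudo-posterior: multiplicative lognormal age noise on a fixed
    topology.

    Each draw rescales every internal node age by an independent
    lognormal factor with mean 1 and coefficient of variation
    ``age_noise_cv``; parent-older-than-child order is preserved by
    clamping a child to just below its parent, and tips stay at age 0.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if age_noise_cv < 0:
        raise ValueError("age_noise_cv must be >= 0")
    ages = node_ages(dated_tree, tolerance=tolerance)
    rng = np.random.default_rng(seed)
    n = dated_tree.n_nodes
    internal = [v for v in range(n) if dated_tree.children[v]]
    preorder = list(dated_tree.preorder())
    root_age = ages[dated_tree.root]
    eps = 1e-9 * max(root_age, 1.0)
    if age_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + age_noise_cv**2))
        mu = -0.5 * sigma**2  # lognormal with mean exactly 1
        factors = rng.lognormal(mu, sigma, size=(n_draws, len(internal)))
    else:
        factors = np.ones((n_draws, len(internal)))
    internal_pos = {v: i for i, v in enumerate(internal)}
    trees = []
    for d in range(n_draws):
        new_age = [0.0] * n
        for v in preorder:
            if not dated_tree.children[v]:
                continue
            a = ages[v] * factors[d, internal_pos[v]]
            p = dated_tree.parent[v]
            if p >= 0:
                a = min(a, new_age[p] - eps)
            new_age[v] = max(a, 0.0)
        lengths = [0.0] * n
        for v in range(n):
            p = dated_tree.parent[v]
            if p >= 0:
                lengths[v] = new_age[p] - new_age[v]
        trees.append(
            Tree(
                list(dated_tree.parent),
                [list(c) for c in dated_tree.children],
                lengths,
                list(dated_tree.labels),
                dated_tree.root,
            )
        )
    return PosteriorTreeSet(trees=trees, translate_map={}, burnin_fraction=0.0)
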