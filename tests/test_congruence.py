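import pandas as pd
import pytest

from riverine import congruence as cg
from riverine import geography as geo
from riverine import synthetic as sy
from riverine import treeio as tio

RIVER = geo.RiverBarrier("R", ((0.0, -5.0), (0.0, 5.0)), min_age_ma=2.4)


def _banks(mapping, river_name="R"):
    return pd.DataFrame(
        [(sid, river_name, bank, 1.0) for sid, bank in mapping.items()],
        columns=["sample_id", "river_name", "bank", "distance_km"],
    )


def _brute_force_divergences(tree, tip_to_lineage, scope):
    """Independent oracle: apply the definition to every internal node."""
    out = []
    for v in range(tree.n_nodes):
        kids = [
            c
            for c in tree.children[v]
            if tree.subtree_tip_labels(c) & scope
        ]
        if len(kids) != 2:
            continue
        lin = [
            {tip_to_lineage[t] for t in tree.subtree_tip_labels(c) if t in scope}
            for c in kids
        ]
        if lin[0] and lin[1] and not (lin[0] & lin[1]):
            out.append(v)
    return set(out)


class TestEnumerate:
    def test_three_lineages_caterpillar(self):
        tree = tio.parse_newick("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(c1:1,c2:1):2);")
        t2l = {"a1": 0, "a2": 0, "b1": 1, "b2": 1, "c1": 2, "c2": 2}
        nodes = cg.enumerate_lineage_divergences(tree, t2l)
        assert len(nodes) == 2

    def test_single_lineage_no_divergences(self, four_tip_tree):
        t2l = {t: 0 for t in four_tip_tree.tip_label_set()}
        assert cg.enumerate_lineage_divergences(four_tip_tree, t2l) == []

    def test_ordered_oldest_first(self):
        tree = tio.parse_newick("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(c1:1,c2:1):2);")
        t2l = {"a1": 0, "a2": 0, "b1": 1, "b2": 1, "c1": 2, "c2": 2}
        nodes = cg.enumerate_lineage_divergences(tree, t2l)
        ages = tio.node_ages(tree)
        assert ages[nodes[0]] >= ages[nodes[1]]

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_matches_brute_force(self, seed):
        species = sy.simulate_species_tree(10, seed=seed)
        dated = sy.graft_dated_samples(
            species,
            {sp: frozenset({f"{sp}_1", f"{sp}_2"}) for sp in species.tip_label_set()},
            seed=seed,
        )
        t2l = {
            tip: i
            for i, sp in enumerate(sorted(species.tip_label_set()))
            for tip in (f"{sp}_1", f"{sp}_2")
        }
        scope = set(t2l)
        nodes = cg.enumerate_lineage_divergences(dated, t2l)
        assert len(nodes) == 9  # k lineages => k-1 between-lineage nodes
        assert set(nodes) == _brute_force_divergences(dated, t2l, scope)

    def test_lineage_spanning_node_excluded(self):
        # both lineages straddle the root, so the root is not a divergence;
        # the two mixed cherries still are
        tree = tio.parse_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        t2l = {"a1": 0, "a2": 0, "b1": 1, "b2": 1}
        nodes = cg.enumerate_lineage_divergences(tree, t2l)
        assert tree.root not in nodes
        assert len(nodes) == 2

    def test_scope_restricts(self):
        tree = tio.parse_newick("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(c1:1,c2:1):2);")
        t2l = {"a1": 0, "a2": 0, "b1": 1, "b2": 1, "c1": 2, "c2": 2}
        nodes = cg.enumerate_lineage_divergences(
            tree, t2l, scope={"a1", "a2", "b1", "b2"}
        )
        assert len(nodes) == 1


class TestClassify:
    TREE = tio.parse_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
    T2L = {"a1": 0, "a2": 0, "b1": 1, "b2": 1}

    def _classify(self, banks, **kwargs):
        node = cg.enumerate_lineage_divergences(self.TREE, self.T2L)[0]
        return cg.classify_spatial_congruence(
            self.TREE, node, _banks(banks), RIVER, self.T2L, **kwargs
        )

    def test_opposite_unanimous_congruent(self):
        rec = self._classify(
            {"a1": "left", "a2": "left", "b1": "right", "b2": "right"}
        )
        assert rec.spatial_verdict == cg.CONGRUENT
        assert not rec.low_support

    def test_one_defector_incongruent(self):
        rec = self._classify(
            {"a1": "left", "a2": "right", "b1": "right", "b2": "right"}
        )
        assert rec.spatial_verdict == cg.INCONGRUENT

    def test_same_side_incongruent(self):
        rec = self._classify(
            {"a1": "left", "a2": "left", "b1": "left", "b2": "left"}
        )
        assert rec.spatial_verdict == cg.INCONGRUENT

    def test_indeterminate_side_unevaluable(self):
        rec = self._classify(
            {"a1": "left", "a2": "left", "b1": "indeterminate", "b2": "indeterminate"}
        )
        assert rec.spatial_verdict == cg.UNEVALUABLE

    def test_min_determinate_threshold(self):
        banks = {"a1": "left", "a2": "left", "b1": "right", "b2": "indeterminate"}
        assert self._classify(banks).spatial_verdict == cg.CONGRUENT
        assert (
            self._classify(banks, min_determinate_per_side=2).spatial_verdict
            == cg.UNEVALUABLE
        )

    def test_single_sample_side_flagged_low_support(self):
        rec = self._classify(
            {"a1": "left", "a2": "left", "b1": "right", "b2": "indeterminate"}
        )
        assert rec.spatial_verdict == cg.CONGRUENT
        assert rec.low_support

    def test_adding_indeterminate_tip_never_flips_verdict(self):
        base = {"a1": "left", "a2": "left", "b1": "right", "b2": "right"}
        rec = self._classify(base)
        rec2 = self._classify({**base, "b2": "indeterminate"})
        assert rec.spatial_verdict == cg.CONGRUENT
        assert rec2.spatial_verdict == cg.CONGRUENT

    def test_missing_bank_rows_are_missing_data(self):
        rec = self._classify({"a1": "left", "b1": "right"})
        assert rec.spatial_verdict == cg.CONGRUENT
        assert rec.n_determinate_a == 1
        assert rec.n_determinate_b == 1


class TestViolations:
    def test_both_sides_flagged(self):
        t2l = {"x1": 0, "x2": 0, "x3": 0}
        banks = _banks({"x1": "left", "x2": "left", "x3": "right"})
        assert cg.find_barrier_violations(t2l, banks, RIVER) == [0]

    def test_indeterminate_not_flagged(self):
        t2l = {"x1": 0, "x2": 0}
        banks = _banks({"x1": "left", "x2": "indeterminate"})
        assert cg.find_barrier_violations(t2l, banks, RIVER) == []

    def test_planted_spanning_lineage_flagged(self):
        species = sy.simulate_species_tree(5, seed=3)
        truth = {sp: frozenset({f"{sp}_1", f"{sp}_2"}) for sp in species.tip_label_set()}
        plan = {sp: geo.LEFT for sp in truth}
        meta = sy.simulate_river_geography(truth, RIVER, plan, seed=1)
        # plant one lineage spanning the river: move one of its samples
        meta.loc[meta["sample_id"] == "sp001_1", "longitude"] = 0.5
        banks = geo.assign_banks_table(meta, [RIVER])
        t2l = {tip: i for i, sp in enumerate(sorted(truth)) for tip in truth[sp]}
        assert cg.find_barrier_violations(t2l, banks, RIVER) == [0]

    def test_violator_never_side_of_congruent_divergence(self):
        tree = tio.parse_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        t2l = {"a1": 0, "a2": 0, "b1": 1, "b2": 1}
        banks = _banks({"a1": "left", "a2": "right", "b1": "right", "b2": "right"})
        violations = cg.find_barrier_violations(t2l, banks, RIVER)
        node = cg.enumerate_lineage_divergences(tree, t2l)[0]
        rec = cg.classify_spatial_congruence(tree, node, banks, RIVER, t2l)
        assert violations == [0]
        assert rec.spatial_verdict != cg.CONGRUENT


class TestSummarize:
    def _records(self, verdicts):
        return [
            cg.DivergenceRecord(
                node_id=i,
                child_a_tips=frozenset({"a"}),
                child_b_tips=frozenset({"b"}),
                lineages_a=frozenset({0}),
                lineages_b=frozenset({1}),
                river_name="R",
                spatial_verdict=v,
                n_determinate_a=2,
                n_determinate_b=2,
            )
            for i, v in enumerate(verdicts)
        ]

    def test_counting(self):
        records = self._records(
            [cg.CONGRUENT, cg.CONGRUENT, cg.INCONGRUENT, cg.INCONGRUENT, cg.UNEVALUABLE]
        )
        summary = cg.summarize(records, [RIVER])
        assert summary.n_total_divergences == 5
        assert summary.per_river["R"]["n_congruent"] == 2
        assert summary.per_river["R"]["n_evaluable"] == 4

    def test_no_rivers(self):
        records = self._records([cg.CONGRUENT, cg.INCONGRUENT])
        summary = cg.summarize(records, [])
        assert summary.n_total_divergences == 2

    def test_counts_nodes_once_across_rivers(self):
        records = self._records([cg.CONGRUENT])
        other = cg.DivergenceRecord(
            node_id=0,
            child_a_tips=frozenset({"a"}),
            child_b_tips=frozenset({"b"}),
            lineages_a=frozenset({0}),
            lineages_b=frozenset({1}),
            river_name="R2",
            spatial_verdict=cg.INCONGRUENT,
            n_determinate_a=2,
            n_determinate_b=2,
        )
        summary = cg.summarize(records + [other], [RIVER])
        assert summary.n_total_divergences == 1

    def test_planted_congruent_count(self):
        species = sy.simulate_species_tree(6, seed=9)
        truth = {sp: frozenset({f"{sp}_1", f"{sp}_2"}) for sp in species.tip_label_set()}
        plan = {
            sp: (geo.LEFT if i % 2 == 0 else geo.RIGHT)
            for i, sp in enumerate(sorted(truth))
        }
        meta = sy.simulate_river_geography(truth, RIVER, plan, violation_rate=0.0, seed=5)
        banks = geo.assign_banks_table(meta, [RIVER])
        dated = sy.graft_dated_samples(species, truth, seed=9)
        t2l = {tip: i for i, sp in enumerate(sorted(truth)) for tip in truth[sp]}
        nodes = cg.enumerate_lineage_divergences(dated, t2l)
        records = [
            cg.classify_spatial_congruence(dated, n, banks, RIVER, t2l) for n in nodes
        ]
        # every cherry whose two species sit on opposite planned banks is
        # congruent; count those directly from the species tree as oracle
        expected = 0
        for v in range(species.n_nodes):
            kids = species.children[v]
            if len(kids) == 2 and all(not species.children[c] for c in kids):
                sides = {plan[species.labels[c]] for c in kids}
                expected += len(sides) == 2
        summary = cg.summarize(records, [RIVER])
        assert summary.per_river["R"]["n_congruent"] >= expected
        got_cherry_nodes = sum(
            1
            for rec in records
            if rec.spatial_verdict == cg.CONGRUENT
            and len(rec.lineages_a) == 1
            and len(rec.lineages_b) == 1
        )
        assert got_cherry_nodes == expected
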