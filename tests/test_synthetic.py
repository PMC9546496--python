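import math

import numpy as np
import pandas as pd
import pytest

from riverine import delimitation as dl
from riverine import geography as geo
from riverine import synthetic as sy
from riverine import treeio as tio


class TestSimulateSpeciesTree:
    def test_two_species_single_divergence(self):
        tree = sy.simulate_species_tree(2, seed=1)
        assert len(tree.tip_ids()) == 2
        assert tio.node_age(tree, tree.root) > 0

    def test_seed_determinism(self):
        a = sy.simulate_species_tree(15, seed=77)
        b = sy.simulate_species_tree(15, seed=77)
        assert tio.write_newick(a) == tio.write_newick(b)
        c = sy.simulate_species_tree(15, seed=78)
        assert tio.write_newick(c) != tio.write_newick(a)

    def test_ultrametric_and_binary(self):
        tree = sy.simulate_species_tree(25, death_rate=0.3, seed=5)
        assert tree.is_binary()
        tio.node_age(tree, tree.root)  # raises if not ultrametric

    def test_yule_lineage_growth_is_exponential(self):
        """Lineages-through-time on pure-birth trees: the mean log lineage
        count grows roughly linearly in time at rate ~ birth_rate."""
        birth = 1.0
        n_lineages_at = {0.25: [], 0.5: [], 0.75: []}
        for rep in range(200):
            tree = sy.simulate_species_tree(50, birth_rate=birth, seed=rep)
            ages = tio.node_ages(tree)
            root_age = ages[tree.root]
            for frac, acc in n_lineages_at.items():
                t = root_age * (1 - frac)  # age threshold, from the root
                count = 2 + sum(
                    1
                    for v in range(tree.n_nodes)
                    if tree.children[v] and v != tree.root and ages[v] > t
                )
                acc.append(count)
        # log-mean counts at the three times should be close to linear
        xs = np.array([0.25, 0.5, 0.75])
        ys = np.log([np.mean(n_lineages_at[f]) for f in xs])
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope > 0
        resid = ys - np.polyval(np.polyfit(xs, ys, 1), xs)
        assert np.max(np.abs(resid)) < 0.1

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            sy.simulate_species_tree(1)


class TestGraftCoalescentSamples:
    def test_one_sample_per_species_tip_lineages(self):
        species = sy.simulate_species_tree(5, seed=2)
        tree, truth = sy.graft_coalescent_samples(species, 1, 1.0, 20.0, seed=2)
        assert len(tree.tip_ids()) == 5
        assert all(len(v) == 1 for v in truth.values())

    def test_seed_determinism(self):
        species = sy.simulate_species_tree(6, seed=3)
        t1, _ = sy.graft_coalescent_samples(species, 3, 1.0, 20.0, seed=9)
        t2, _ = sy.graft_coalescent_samples(species, 3, 1.0, 20.0, seed=9)
        assert tio.write_newick(t1) == tio.write_newick(t2)

    def test_truth_partitions_tips(self):
        species = sy.simulate_species_tree(6, seed=4)
        tree, truth = sy.graft_coalescent_samples(species, 4, 1.0, 20.0, seed=4)
        all_tips = set()
        for tips in truth.values():
            assert not (all_tips & tips)
            all_tips |= tips
        assert all_tips == set(tree.tip_label_set())

    def test_per_species_rates_accepted(self):
        species = sy.simulate_species_tree(3, seed=5)
        rates = {sp: 10.0 + i for i, sp in enumerate(sorted(species.tip_label_set()))}
        tree, _ = sy.graft_coalescent_samples(species, 3, 1.0, rates, seed=5)
        assert len(tree.tip_ids()) == 9

    def test_no_signal_collapses_to_one_lineage(self):
        ones = 0
        for rep in range(15):
            species = sy.simulate_species_tree(8, seed=600 + rep)
            tree, _ = sy.graft_coalescent_samples(species, 4, 1.0, 1.0, seed=700 + rep)
            delim = dl.delimit_search(
                tree, dl.DelimitationConfig(mode="multi", seed=rep, restarts=2)
            )
            ones += delim.n_lineages == 1
        assert ones > 15 / 2


class TestGraftDatedSamples:
    def test_ultrametric_with_monophyletic_species(self, cherry_species_tree):
        truth = {
            sp: frozenset({f"{sp}_1", f"{sp}_2", f"{sp}_3"})
            for sp in cherry_species_tree.tip_label_set()
        }
        dated = sy.graft_dated_samples(cherry_species_tree, truth, seed=1)
        tio.node_age(dated, dated.root)  # ultrametric check
        for tips in truth.values():
            assert tio.is_monophyletic(dated, tips)

    def test_species_divergence_ages_preserved(self, cherry_species_tree):
        truth = {
            sp: frozenset({f"{sp}_1", f"{sp}_2"})
            for sp in cherry_species_tree.tip_label_set()
        }
        dated = sy.graft_dated_samples(cherry_species_tree, truth, seed=2)
        got = tio.node_age(dated, tio.mrca(dated, truth["sp_a"] | truth["sp_b"]))
        assert got == pytest.approx(1.0)
        got = tio.node_age(dated, tio.mrca(dated, truth["sp_e"] | truth["sp_f"]))
        assert got == pytest.approx(2.5)


class TestSimulateRiverGeography:
    RIVER = sy.straight_river(min_age_ma=2.4)

    def _truth(self, n=4, k=3):
        return {
            f"L{i}": frozenset(f"L{i}_s{j}" for j in range(k)) for i in range(n)
        }

    def test_violation_zero_reproduces_plan(self):
        truth = self._truth()
        plan = {l: (geo.LEFT if i % 2 else geo.RIGHT) for i, l in enumerate(sorted(truth))}
        meta = sy.simulate_river_geography(truth, self.RIVER, plan, seed=8)
        banks = geo.assign_banks_table(meta, [self.RIVER])
        merged = meta.merge(banks, on="sample_id")
        assert (merged["bank"] == merged["planted_bank"]).all()
        for _, row in merged.iterrows():
            assert row["bank"] == plan[row["taxon"]]

    def test_violation_one_reflects_everything(self):
        truth = self._truth()
        plan = {l: geo.LEFT for l in truth}
        meta = sy.simulate_river_geography(
            truth, self.RIVER, plan, violation_rate=1.0, seed=8
        )
        banks = geo.assign_banks_table(meta, [self.RIVER])
        assert (banks["bank"] == geo.RIGHT).all()

    def test_spread_zero_collapses_lineage_to_point(self):
        truth = self._truth()
        plan = {l: geo.LEFT for l in truth}
        meta = sy.simulate_river_geography(truth, self.RIVER, plan, spread_km=0.0, seed=8)
        for _, grp in meta.groupby("taxon"):
            assert grp["latitude"].nunique() == 1
            assert grp["longitude"].nunique() == 1

    def test_missing_plan_rejected(self):
        truth = self._truth()
        with pytest.raises(ValueError, match="cover"):
            sy.simulate_river_geography(truth, self.RIVER, {"L0": geo.LEFT}, seed=1)

    def test_seed_determinism(self):
        truth = self._truth()
        plan = {l: geo.LEFT for l in truth}
        m1 = sy.simulate_river_geography(truth, self.RIVER, plan, seed=4)
        m2 = sy.simulate_river_geography(truth, self.RIVER, plan, seed=4)
        pd.testing.assert_frame_equal(m1, m2)


class TestPerturbPosterior:
    def test_zero_noise_identity(self, cherry_species_tree):
        post = sy.perturb_posterior(cherry_species_tree, 5, 0.0, seed=1)
        ref = tio.write_newick(cherry_species_tree)
        assert all(tio.write_newick(t) == ref for t in post.trees)

    def test_draws_remain_ultrametric_and_ordered(self, cherry_species_tree):
        post = sy.perturb_posterior(cherry_species_tree, 50, 0.3, seed=2)
        for tree in post.trees:
            ages = tio.node_ages(tree, tolerance=1e-6)
            for v in range(tree.n_nodes):
                p = tree.parent[v]
                if p >= 0:
                    assert ages[v] <= ages[p] + 1e-12
            assert all(abs(ages[i]) < 1e-9 for i in tree.tip_ids())

    def test_bitwise_reproducible(self, cherry_species_tree):
        p1 = sy.perturb_posterior(cherry_species_tree, 10, 0.2, seed=3)
        p2 = sy.perturb_posterior(cherry_species_tree, 10, 0.2, seed=3)
        for a, b in zip(p1.trees, p2.trees):
            assert a.lengths == b.lengths

    def test_invalid_args_rejected(self, cherry_species_tree):
        with pytest.raises(ValueError):
            sy.perturb_posterior(cherry_species_tree, 0, 0.1)
        with pytest.raises(ValueError):
            sy.perturb_posterior(cherry_species_tree, 5, -0.1)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            sy.SimulationConfig(n_species=1)
        with pytest.raises(ValueError):
            sy.SimulationConfig(violation_rate=1.5)
        with pytest.raises(ValueError):
            sy.SimulationConfig(birth_rate=1.0, death_rate=1.0)
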