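"""Generators: coalescent trees, clock sequence evolution, damaged reads,
locality tables."""

import numpy as np
import pytest
import scipy.stats

from paleomt.simulate import (
    ClockModel,
    DamageProfile,
    SliceSpec,
    SpreadScenario,
    evolve_sequences,
    fragment_and_damage,
    mutated_copy,
    newick_string,
    random_genome,
    simulate_localities,
    simulate_tree,
    tip_ages,
)


class TestSimulateTree:
    def test_rejects_fewer_than_two_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(1, (0, 1000), seed=0)

    def test_two_tip_minimal_case(self):
        tree = simulate_tree(2, (0, 40_000), seed=3)
        ages = tip_ages(tree)
        assert len(ages) == 2
        root = tree.seed_node
        assert root.age > max(ages.values())
        for leaf in tree.leaf_node_iter():
            path = (leaf.edge.length or 0.0) + leaf.age
            assert path == pytest.approx(root.age)

    def test_same_seed_gives_identical_newick(self):
        a = newick_string(simulate_tree(15, (0, 50_000), seed=11))
        b = newick_string(simulate_tree(15, (0, 50_000), seed=11))
        c = newick_string(simulate_tree(15, (0, 50_000), seed=12))
        assert a == b
        assert a != c

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_binary_tree_internal_node_count(self, seed):
        tree = simulate_tree(50, (0, 30_000), seed=seed)
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        assert len(internal) == 49
        assert all(len(nd.child_nodes()) == 2 for nd in internal)

    def test_tip_ages_within_range_and_branch_lengths_positive(self):
        tree = simulate_tree(20, (10_000, 60_000), seed=5)
        for label, age in tip_ages(tree).items():
            assert 10_000 <= age <= 60_000
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.edge.length >= 0


class TestEvolveSequences:
    def test_zero_rate_gives_identical_sequences(self):
        tree = simulate_tree(6, (0, 20_000), seed=1)
        sim = evolve_sequences(tree, ClockModel(rate=0.0), 500, seed=2)
        seqs = set(sim.alignment.values())
        assert len(seqs) == 1
        assert sim.total_substitutions == 0

    def test_alignment_length_and_alphabet_conserved(self):
        tree = simulate_tree(8, (0, 40_000), seed=3)
        sim = evolve_sequences(
            tree, ClockModel(rate=1e-7, invariant_fraction=0.4), 700, seed=4
        )
        for seq in sim.alignment.values():
            assert len(seq) == 700
            assert set(seq) <= set("ACGT")

    def test_invariant_sites_never_substitute(self):
        tree = simulate_tree(8, (0, 40_000), seed=5)
        sim = evolve_sequences(
            tree, ClockModel(rate=5e-7, invariant_fraction=0.5), 600, seed=6
        )
        root = np.array(list(sim.node_sequences[tree.seed_node.label]))
        for seq in sim.alignment.values():
            arr = np.array(list(seq))
            assert (arr[sim.invariant_mask] == root[sim.invariant_mask]).all()

    def test_substitution_count_matches_poisson_expectation(self):
        # under JC69 the realized substitution count on the whole tree is
        # Poisson with mean rate * tree_length_years * L * (1 - p_inv)
        tree = simulate_tree(10, (0, 30_000), seed=7, pop_size=40_000)
        tree_len = sum(
            nd.edge.length for nd in tree.preorder_node_iter() if nd.parent_node
        )
        rate, L, pinv, reps = 2e-7, 1_000, 0.3, 60
        clock = ClockModel(rate=rate, model="JC69", invariant_fraction=pinv)
        total = sum(
            evolve_sequences(tree, clock, L, seed=100 + i).total_substitutions
            for i in range(reps)
        )
        expected = reps * rate * tree_len * L * (1 - pinv)
        assert abs(total - expected) <= 3 * np.sqrt(expected)

    def test_tn93_with_unit_kappas_collapses_to_jc69(self):
        # pairwise-distance distributions should be statistically
        # indistinguishable when TN93 degenerates to JC69
        tree = simulate_tree(6, (0, 30_000), seed=8)
        tn = ClockModel(rate=3e-7, model="TN93", kappa1=1, kappa2=1,
                        base_freqs=(0.25,) * 4)
        jc = ClockModel(rate=3e-7, model="JC69")

        def pair_dists(clock, seed):
            sim = evolve_sequences(tree, clock, 800, seed=seed)
            seqs = [np.array(list(s)) for s in sim.alignment.values()]
            return [
                (seqs[i] != seqs[j]).sum()
                for i in range(len(seqs))
                for j in range(i + 1, len(seqs))
            ]

        d_tn = np.concatenate([pair_dists(tn, 500 + i) for i in range(60)])
        d_jc = np.concatenate([pair_dists(jc, 9000 + i) for i in range(60)])
        assert scipy.stats.ks_2samp(d_tn, d_jc).pvalue > 0.01


class TestFragmentAndDamage:
    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            fragment_and_damage("", DamageProfile(), seed=0)

    def test_zero_damage_zero_contamination_gives_no_mismatches(self):
        g = random_genome(2_000, seed=1)
        res = fragment_and_damage(g, DamageProfile(p_ct_5p=0.0, coverage=10), seed=2)
        assert all(not f.mismatches for f in res.fragments)

    def test_terminal_damage_rate_within_binomial_band(self):
        g = random_genome(4_000, seed=3)
        p = 0.30
        res = fragment_and_damage(
            g, DamageProfile(p_ct_5p=p, coverage=300), seed=4
        )
        # qualifying ends: left-terminal C (C->T) and right-terminal G (G->A)
        hits = trials = 0
        for f in res.fragments:
            left = g[f.start - 1]
            if left in "C":
                trials += 1
                hits += f.bases[0] == "T"
            right_pos = (f.start - 1 + len(f) - 1) % len(g)
            if g[right_pos] == "G":
                trials += 1
                hits += f.bases[-1] == "A"
        assert trials > 5_000
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(hits / trials - p) <= 3 * se

    def test_damage_decays_into_the_read(self):
        g = random_genome(4_000, seed=5)
        res = fragment_and_damage(
            g, DamageProfile(p_ct_5p=0.6, decay=0.5, coverage=300), seed=6
        )
        hits = np.zeros(3)
        trials = np.zeros(3)
        for f in res.fragments:
            for k in range(3):
                if len(f) > k and g[(f.start - 1 + k) % len(g)] == "C":
                    trials[k] += 1
                    hits[k] += f.bases[k] == "T"
        rates = hits / trials
        for k, expected in enumerate([0.6, 0.3, 0.15]):
            se = np.sqrt(expected * (1 - expected) / trials[k])
            assert abs(rates[k] - expected) <= 4 * se

    def test_contaminant_fragments_are_faithful_substrings(self):
        g = random_genome(2_000, seed=7)
        contam = mutated_copy(g, 40, seed=8)
        res = fragment_and_damage(
            g,
            DamageProfile(p_ct_5p=0.4, coverage=30, contamination_frac=0.5),
            contam,
            seed=9,
        )
        n_contam = 0
        for f, origin in zip(res.fragments, res.truth["origin"]):
            idx = [(f.start - 1 + k) % len(g) for k in range(len(f))]
            if origin == "contaminant":
                n_contam += 1
                assert f.bases == "".join(contam[i] for i in idx)
            else:
                # endogenous mismatches are only the configured damage types
                for pos, ref, read in f.mismatches:
                    assert (ref, read) in {("C", "T"), ("G", "A")}
        frac = n_contam / len(res.fragments)
        se = np.sqrt(0.25 / len(res.fragments))
        assert abs(frac - 0.5) <= 3 * se

    def test_mean_coverage_near_target(self):
        g = random_genome(3_000, seed=10)
        res = fragment_and_damage(g, DamageProfile(coverage=25), seed=11)
        total = sum(len(f) for f in res.fragments)
        assert abs(total / len(g) - 25) / 25 < 0.10

    def test_determinism(self):
        g = random_genome(1_000, seed=12)
        a = fragment_and_damage(g, DamageProfile(coverage=5), seed=13)
        b = fragment_and_damage(g, DamageProfile(coverage=5), seed=13)
        assert [f.bases for f in a.fragments] == [f.bases for f in b.fragments]
        assert [f.start for f in a.fragments] == [f.start for f in b.fragments]


class TestSimulateLocalities:
    def scenario(self, widths=(40.0, 30.0), n=500):
        return SpreadScenario(
            slices=[
                SliceSpec(80, 70, n, lon_center=10, lon_width=widths[0]),
                SliceSpec(70, 60, n, lon_center=10, lon_width=widths[1]),
            ]
        )

    def test_counts_and_bounds_exact(self):
        df = simulate_localities(self.scenario(n=120), seed=1)
        assert len(df) == 240
        first = df[df.site_id.str.startswith("s0")]
        assert len(first) == 120
        assert first.longitude.between(-10, 30).all()
        assert (df.date_max_ka >= df.date_min_ka).all()

    def test_degenerate_width_gives_zero_spread(self):
        sc = SpreadScenario(slices=[SliceSpec(80, 70, 50, 5, 1e-4)])
        df = simulate_localities(sc, seed=2)
        spread = np.percentile(df.longitude, 97.5) - np.percentile(df.longitude, 2.5)
        assert spread < 1e-3

    def test_wider_slice_has_wider_sample_range(self):
        # order-statistics: with n=500 the sample range of a 40-degree
        # uniform exceeds that of a 30-degree uniform essentially always
        wins = 0
        for seed in range(50):
            df = simulate_localities(self.scenario(), seed=seed)
            r0 = np.ptp(df[df.site_id.str.startswith("s0")].longitude.to_numpy())
            r1 = np.ptp(df[df.site_id.str.startswith("s1")].longitude.to_numpy())
            wins += r0 > r1
        assert wins >= 50 * 0.99

    def test_fixed_seed_identical_csv(self):
        a = simulate_localities(self.scenario(n=40), seed=9).to_csv(index=False)
        b = simulate_localities(self.scenario(n=40), seed=9).to_csv(index=False)
        assert a == b


class TestValidation:
    def test_clock_model_invariants(self):
        with pytest.raises(ValueError):
            ClockModel(rate=-1)
        with pytest.raises(ValueError):
            ClockModel(invariant_fraction=1.0)
        with pytest.raises(ValueError):
            ClockModel(base_freqs=(0.5, 0.5, 0.5, 0.5))

    def test_damage_profile_invariants(self):
        with pytest.raises(ValueError):
            DamageProfile(p_ct_5p=1.5)
        with pytest.raises(ValueError):
            DamageProfile(decay=0.0)
        with pytest.raises(ValueError):
            DamageProfile(coverage=0.0)
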