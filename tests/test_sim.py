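import numpy as np
import pytest

from mtpopgen._hky import HKYModel
from mtpopgen.alignio import classify_sites
from mtpopgen.diversity import nucleotide_diversity, pairwise_differences
from mtpopgen.sim import (
    AT_RICH_FREQS,
    SimConfig,
    branch_mutation_counts,
    count_haplotypes_from_mutations,
    evolve_sequences,
    pairwise_diffs_from_mutations,
    simulate_dataset,
    simulate_genealogy,
)


class TestGenealogies:
    def test_pair_coalescence_time_constant(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(scenario="constant", n=2, theta=3.0)
        times = np.array([simulate_genealogy(cfg, rng).tmrca for _ in range(10_000)])
        se = times.std() / np.sqrt(len(times))
        assert abs(times.mean() - 3.0) < 3 * se

    def test_pair_coalescence_sudden_expansion_limit(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(scenario="sudden_expansion", n=2, theta0=1.0, theta1=1e12, tau=5.0)
        times = np.array([simulate_genealogy(cfg, rng).tmrca for _ in range(4000)])
        se = times.std() / np.sqrt(len(times))
        assert abs(times.mean() - 6.0) < 3 * se
        assert times.min() >= 5.0

    def test_im_split_without_migration_is_structured(self):
        rng = np.random.default_rng(2)
        cfg = SimConfig(scenario="im_split", n=[5, 5], theta1=2, theta2=2, thetaA=2,
                        t_split=4.0, m1=0.0, m2=0.0)
        for _ in range(30):
            tree = simulate_genealogy(cfg, rng)
            demes = np.array(tree.tip_demes)
            # cross-deme pairs must coalesce above the split
            ind = np.zeros((tree.n_nodes, tree.n_tips), bool)
            ind[np.arange(10), np.arange(10)] = True
            order = np.argsort(tree.time)
            for v in order:
                p = tree.parent[v]
                if p >= 0:
                    ind[p] |= ind[v]
            for v in range(10, tree.n_nodes):
                tips = np.flatnonzero(ind[v])
                if len(set(demes[tips])) > 1:
                    assert tree.time[v] >= 4.0

    def test_watterson_segregating_sites(self):
        rng = np.random.default_rng(3)
        n, theta = 93, 7.5
        cfg = SimConfig(scenario="constant", n=n, theta=theta)
        S = np.array(
            [branch_mutation_counts(simulate_genealogy(cfg, rng), rng).sum() for _ in range(200)]
        )
        a1 = (1.0 / np.arange(1, n)).sum()
        se = S.std() / np.sqrt(len(S))
        assert abs(S.mean() - theta * a1) < 3 * se


class TestSequences:
    def test_zero_length_tree_gives_identical_sequences(self):
        rng = np.random.default_rng(4)
        cfg = SimConfig(scenario="constant", n=4, theta=1e-9)
        tree = simulate_genealogy(cfg, rng)
        aln = evolve_sequences(tree, HKYModel(AT_RICH_FREQS, 20.0), 200, rng)
        assert len(set(aln.seqs)) == 1

    def test_pair_divergence_matches_matrix_exponential(self):
        # two tips separated by total branch length b: expected differences
        # from the HKY transition matrix directly
        rng = np.random.default_rng(5)
        model = HKYModel(AT_RICH_FREQS, 20.0)
        L, theta = 400, 4.0
        cfg = SimConfig(scenario="constant", n=2, theta=theta)
        obs, exp = [], []
        for _ in range(500):
            tree = simulate_genealogy(cfg, rng)
            aln = evolve_sequences(tree, model, L, rng)
            d, _ = pairwise_differences(aln)
            obs.append(d[0, 1])
            b = tree.branch_subs().sum() / L
            P = model.transition_matrices(np.array([b]))[0]
            pi = model.stationary()
            exp.append(L * (1.0 - (pi * np.diag(P)).sum()))
        obs, exp = np.array(obs), np.array(exp)
        se = obs.std() / np.sqrt(len(obs))
        assert abs(obs.mean() - exp.mean()) < 3 * se

    def test_jukes_cantor_special_case(self):
        # kappa=1, equal frequencies: observed difference proportion at
        # distance d follows p = 3/4 (1 - exp(-4 d / 3))
        rng = np.random.default_rng(6)
        model = HKYModel((0.25, 0.25, 0.25, 0.25), 1.0)
        L = 2000
        for d in (0.05, 0.2, 0.5):
            P = model.transition_matrices(np.array([d]))[0]
            jc = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            assert 1.0 - P[0, 0] == pytest.approx(jc, rel=1e-8)

    def test_base_composition_tracks_model(self):
        rng = np.random.default_rng(7)
        out = simulate_dataset(SimConfig(scenario="constant", n=20, L=993, theta=7.5, seed=77))
        comp = classify_sites(out.alignment).base_composition
        assert comp["A"] + comp["T"] > 0.75  # AT-rich, as configured


class TestDatasets:
    def test_same_seed_reproduces_everything(self):
        cfg = SimConfig(scenario="sudden_expansion", n=[6, 6], L=300, theta0=0.1,
                        theta1=40, tau=5, seed=123)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.alignment.seqs == b.alignment.seqs
        assert a.tree.newick() == b.tree.newick()

    def test_writes_all_artifacts(self, tmp_path):
        out = simulate_dataset(SimConfig(scenario="constant", n=4, L=50, theta=2, seed=5))
        paths = out.write(tmp_path)
        for key in ("fasta", "popmap", "newick", "truth"):
            assert paths[key].exists() and paths[key].stat().st_size > 0

    def test_expansion_regime_gives_high_haplotype_diversity(self):
        # the study regime: 5 demes painted on one expansion genealogy
        from mtpopgen.alignio import collapse_haplotypes
        from mtpopgen.diversity import haplotype_diversity

        rng = np.random.default_rng(8)
        hit = 0
        reps = 25
        for _ in range(reps):
            cfg = SimConfig(scenario="sudden_expansion", n=[17, 21, 17, 18, 20],
                            L=993, theta0=0.03, theta1=62.6, tau=8.1,
                            seed=int(rng.integers(2**31)))
            out = simulate_dataset(cfg)
            tbl = collapse_haplotypes(out.alignment, out.popmap)
            h, _ = haplotype_diversity(tbl.total_counts())
            hit += h >= 0.9
        assert hit >= 0.9 * reps

    def test_mean_pi_matches_theta(self):
        rng = np.random.default_rng(9)
        theta, L, n = 5.0, 993, 25
        cfg = SimConfig(scenario="constant", n=n, theta=theta)
        pis = []
        for _ in range(120):
            tree = simulate_genealogy(cfg, rng)
            muts = branch_mutation_counts(tree, rng)
            d = pairwise_diffs_from_mutations(tree, muts)
            iu = np.triu_indices(n, 1)
            pis.append(d[iu].mean() / L)
        pis = np.array(pis)
        se = pis.std() / np.sqrt(len(pis))
        assert abs(pis.mean() - theta / L) < 3 * se

    def test_haplotype_count_from_mutations(self):
        rng = np.random.default_rng(10)
        cfg = SimConfig(scenario="constant", n=6, theta=3.0)
        tree = simulate_genealogy(cfg, rng)
        muts = np.zeros(tree.n_nodes, int)
        assert count_haplotypes_from_mutations(tree, muts) == 1
        muts[:6] = 1  # every external branch mutated: all tips distinct
        assert count_haplotypes_from_mutations(tree, muts) == 6
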