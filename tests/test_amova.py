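import numpy as np
import pytest

from mtpopgen.amova import amova, pairwise_phist


def oracle_one_level(d2, labels):
    """Plain-loop variance components from the definitional mean squares."""
    labels = list(labels)
    n = len(labels)
    pops = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i, j]
    ss_total /= n
    ss_within = 0.0
    for p in pops:
        idx = [i for i, l in enumerate(labels) if l == p]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ss_within += d2[idx[a], idx[b]] / len(idx)
    ss_among = ss_total - ss_within
    P = len(pops)
    ms_among = ss_among / (P - 1)
    sigma_w = ss_within / (n - P)
    sizes = [labels.count(p) for p in pops]
    n_prime = (n - sum(s * s for s in sizes) / n) / (P - 1)
    sigma_a = (ms_among - sigma_w) / n_prime
    return sigma_a, sigma_w


class TestAmova:
    def test_complete_fixation(self):
        d2 = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float)
        res = amova(d2, ["A", "A", "B", "B"], n_perms=99, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.percent["among_populations"] == pytest.approx(100.0)

    def test_exhaustive_permutation_p_one_third(self):
        d2 = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float)
        res = amova(d2, ["A", "A", "B", "B"], n_perms="exhaustive")
        assert res.p_value == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 2
        res = amova(d2, labels, n_perms=10, seed=0)
        sa, sw = oracle_one_level(d2, labels)
        assert res.sigma2["among_populations"] == pytest.approx(sa, abs=1e-10)
        assert res.sigma2["within_populations"] == pytest.approx(sw, abs=1e-10)
        assert res.phi_st == pytest.approx(sa / (sa + sw), abs=1e-10)

    def test_null_split_of_panmictic_sample(self):
        rng = np.random.default_rng(3)
        phis, ps = [], []
        for rep in range(60):
            pts = rng.normal(size=(16, 2))
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            labels = ["A"] * 8 + ["B"] * 8
            res = amova(d2, labels, n_perms=60, seed=int(rng.integers(2**31)))
            phis.append(res.phi_st)
            ps.append(res.p_value)
        assert abs(np.mean(phis)) < 0.03
        assert 0.3 < np.mean(ps) < 0.7  # p roughly uniform under the null

    def test_degenerate_all_identical_flagged(self):
        d2 = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="undefined"):
            res = amova(d2, ["A", "A", "B", "B"], n_perms=9, seed=0)
        assert not res.defined and res.phi_st is None

    def test_two_level_percentages_and_df(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 2))
        pts[8:] += 3.0
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        res = amova(d2, labels, groups={"A": "g1", "B": "g1", "C": "g2"},
                    n_perms=60, seed=1)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=0.05)
        assert sum(res.df.values()) == 11
        assert res.phi_ct is not None and res.p_ct is not None

    def test_group_must_cover_all_populations(self):
        d2 = np.eye(4) * 0
        with pytest.raises(ValueError, match="cover"):
            amova(np.ones((4, 4)) - np.eye(4), ["A", "A", "B", "B"],
                  groups={"A": "g"}, n_perms=9)

    def test_permutation_p_in_unit_interval_with_correction(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        res = amova(d2, ["A"] * 5 + ["B"] * 5, n_perms=19, seed=2)
        assert 1 / 20 <= res.p_value <= 1.0


class TestPairwisePhist:
    def test_identical_pops_near_zero_and_fixed_pops_one(self):
        d2 = np.zeros((8, 8))
        d2[:4, 4:] = 1.0
        d2[4:, :4] = 1.0
        rng = np.random.default_rng(0)
        noise = rng.uniform(0, 1e-6, (8, 8))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        res = pairwise_phist(d2 + noise, ["A"] * 4 + ["B"] * 4, n_perms=99, seed=1)
        assert res.phi_st.loc["B", "A"] == pytest.approx(1.0, abs=1e-3)
        assert res.p_values.loc["B", "A"] == pytest.approx(1 / 100, abs=0.03)

    def test_negative_estimates_reported(self):
        rng = np.random.default_rng(9)
        found_negative = False
        for rep in range(10):
            pts = rng.normal(size=(12, 2))
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            res = pairwise_phist(d2, ["A"] * 6 + ["B"] * 6, n_perms=20,
                                 seed=int(rng.integers(2**31)))
            if res.phi_st.loc["B", "A"] < 0:
                found_negative = True
        assert found_negative

    def test_singleton_population_excluded(self):
        d2 = np.ones((5, 5)) - np.eye(5)
        with pytest.warns(UserWarning, match="single"):
            res = pairwise_phist(d2, ["A", "A", "B", "B", "C"], n_perms=10, seed=0)
        assert res.populations == ["A", "B"]

    def test_island_model_differentiation_matches_expectation(self):
        # symmetric two-deme equilibrium: with per-pair coalescence rate
        # 1/theta and per-lineage migration m, E[T_within] = 2 theta and
        # E[T_between] = 2 theta + 1/(2m), so Phi_ST ~ 1/(1 + 4 theta m).
        # theta*m = 2.25 targets ~0.1.
        from mtpopgen.diversity import pairwise_differences
        from mtpopgen.sim import SimConfig, simulate_dataset

        theta, m = 5.0, 0.45
        rng = np.random.default_rng(21)
        phis = []
        for rep in range(10):
            out = simulate_dataset(
                SimConfig(scenario="im_split", n=[12, 12], L=993, theta1=theta,
                          theta2=theta, thetaA=theta, t_split=2000.0, m1=m, m2=m,
                          seed=int(rng.integers(2**31)))
            )
            d, _ = pairwise_differences(out.alignment)
            labels = [out.popmap.of(s) for s in out.alignment.ids]
            res = pairwise_phist(d.astype(float) ** 2, labels, n_perms=5,
                                 seed=int(rng.integers(2**31)))
            phis.append(res.phi_st.iloc[1, 0])
        assert 0.05 < np.mean(phis) < 0.15
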