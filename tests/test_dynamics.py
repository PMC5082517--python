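"""Dynamic network model: fixed points, symmetry, monotonicity, determinism."""

import numpy as np
import pytest

from ictomark import (
    DynamicNetworkModel,
    NetworkConfig,
    biomarker_profile,
    build_network,
    default_K_grid,
    generate_segment,
    node_dynamics_step,
    seizure_likelihood_table,
)
from ictomark.dynamics import ModelConfigError
from ictomark.preprocess import band_filter, broadband_filter

from conftest import coupled_spec


def isolated_model(k, delta=0.5, **kw):
    n = 2
    A = np.zeros((n, n))
    return DynamicNetworkModel(
        A, A.copy(), sigma2=np.ones(n), K=k, g=0.0, delta=delta,
        t_burn=0.0, t_sim=30.0, **kw,
    )


def random_network(n=10, density=0.25, seed=0):
    rng = np.random.default_rng(seed)
    adj = np.triu((rng.random((n, n)) < density).astype(float), 1)
    adj = adj + adj.T
    lag = np.triu(rng.uniform(-1.0, 1.0, (n, n)), 1)
    lag = (lag - lag.T) * adj
    sigma2 = rng.lognormal(0.0, 0.5, n)
    return adj, lag, sigma2


class TestIsolatedNodeFixedPoint:
    @pytest.mark.parametrize("ratio", [1.5, 2.0, 4.0])
    def test_supercritical_steady_state_matches_closed_form(self, ratio):
        m = isolated_model(k=ratio * 1.0)  # k_c = 1 at delta = 0.5
        _, Z = m.simulate(t_max=30.0)
        expected = np.sqrt(1.0 - 2.0 * m.delta / m.k_local[0])
        assert abs(np.abs(Z[-1, 0]) - expected) < 1e-3

    @pytest.mark.parametrize("ratio", [0.3, 0.6])
    def test_subcritical_decays_to_incoherence(self, ratio):
        m = isolated_model(k=ratio * 1.0)
        _, Z = m.simulate(t_max=30.0)
        assert np.abs(Z[-1]).max() < 1e-3


class TestNodeDynamicsStep:
    def test_symmetric_pair_stays_symmetric(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = DynamicNetworkModel(A, np.zeros((2, 2)), np.ones(2), K=1.5, g=0.8,
                                t_burn=0.0, t_sim=10.0)
        z = np.array([0.1 + 0.05j, 0.1 + 0.05j])
        for _ in range(2000):
            z = node_dynamics_step(z, m)
        assert z[0] == z[1]  # exact: identical inputs, identical arithmetic

    def test_overshoot_state_rejected(self):
        m = isolated_model(k=3.0)
        with pytest.raises(ModelConfigError, match=r"\|z\| <= 1"):
            node_dynamics_step(np.array([1.5 + 0j, 0j]), m)

    def test_drive_below_critical_coupling_rejected(self):
        with pytest.raises(ModelConfigError, match="k_drive"):
            isolated_model(k=1.0, k_drive=0.5)


class TestSeizureLikelihood:
    def test_empty_network_cannot_propagate(self):
        A = np.zeros((5, 5))
        m = DynamicNetworkModel(A, A.copy(), np.ones(5), K=0.0, g=1.0,
                                t_burn=1.0, t_sim=5.0)
        res = m.fit()
        np.testing.assert_array_equal(res.s, 0.0)

    def test_complete_graph_symmetric_and_saturating(self):
        n = 6
        A = np.ones((n, n)) - np.eye(n)
        prev = -1.0
        for g in (0.5, 2.0, 8.0):
            m = DynamicNetworkModel(A, np.zeros((n, n)), np.ones(n), K=1.0, g=g,
                                    t_burn=2.0, t_sim=5.0, seed=3)
            s = m.fit().s
            # driven nodes are all equivalent up to initial-condition noise
            assert np.ptp(s) < 0.1 if g < 1 else np.ptp(s) < 0.02
            assert s.mean() >= prev
            prev = s.mean()
        assert prev == pytest.approx(1.0, abs=1e-6)

    def test_seizure_likelihood_nondecreasing_in_K(self):
        adj, lag, sigma2 = random_network(seed=4)
        K_grid = 1.0 / sigma2.mean() * np.array([0.5, 1.0, 2.0])
        tab = seizure_likelihood_table(adj, lag, sigma2, K_grid,
                                       t_burn=2.0, t_sim=5.0, seed=0)
        assert (np.diff(tab, axis=0) >= -1e-12).all()

    def test_single_and_batched_runs_agree(self):
        adj, lag, sigma2 = random_network(seed=5)
        m = DynamicNetworkModel(adj, lag, sigma2, K=0.8 / sigma2.mean(), g=0.3,
                                t_burn=1.0, t_sim=4.0, seed=2)
        res = m.fit()
        assert m.seizure_likelihood(3) == res.s[3]

    def test_deterministic_profile_reproducible(self):
        adj, lag, sigma2 = random_network(seed=6)
        kw = dict(K=1.0 / sigma2.mean(), g=0.3, t_burn=1.0, t_sim=4.0, seed=9)
        a = DynamicNetworkModel(adj, lag, sigma2, **kw).fit()
        b = DynamicNetworkModel(adj, lag, sigma2, **kw).fit()
        np.testing.assert_array_equal(a.s, b.s)

    def test_halving_dt_barely_changes_s(self):
        adj, lag, sigma2 = random_network(n=8, seed=7)
        kw = dict(g=0.5, t_burn=2.0, t_sim=5.0, seed=1)
        K = [1.0 / sigma2.mean()]
        a = seizure_likelihood_table(adj, lag, sigma2, K, dt=1e-3, **kw)
        b = seizure_likelihood_table(adj, lag, sigma2, K, dt=5e-4, **kw)
        assert np.abs(a - b).max() < 0.01

    def test_relabelling_leaves_s_profile_consistent(self):
        adj, lag, sigma2 = random_network(n=8, seed=8)
        kw = dict(g=0.4, t_burn=2.0, t_sim=6.0, seed=0)
        K = 1.0 / sigma2.mean()
        base = DynamicNetworkModel(adj, lag, sigma2, K, **kw).fit().s
        perm = np.random.default_rng(1).permutation(8)
        permuted = DynamicNetworkModel(
            adj[np.ix_(perm, perm)], lag[np.ix_(perm, perm)], sigma2[perm], K, **kw
        ).fit().s
        # initial conditions are node-indexed, so equality is approximate
        np.testing.assert_allclose(permuted, base[perm], atol=0.05)

    def test_stochastic_mode_runs_and_stays_bounded(self):
        adj, lag, sigma2 = random_network(n=6, seed=9)
        m = DynamicNetworkModel(adj, lag, sigma2, K=1.0 / sigma2.mean(), g=0.4,
                                noise_amp=0.05, t_burn=1.0, t_sim=4.0, seed=5)
        s = m.fit().s
        assert ((0.0 <= s) & (s <= 1.0)).all()

    def test_t_sim_must_cover_intrinsic_periods(self):
        with pytest.raises(ModelConfigError, match="intrinsic"):
            isolated_model(k=3.0).__class__(
                np.zeros((2, 2)), np.zeros((2, 2)), np.ones(2), K=3.0,
                t_sim=0.5,
            )


@pytest.fixture(scope="module")
def seg_and_net():
    seg = generate_segment(coupled_spec(n=6, seed=13))
    nb = band_filter(broadband_filter(seg), "low_alpha")
    return nb, build_network(nb, NetworkConfig(seed=13))


class TestBiomarkerProfile:

    def test_local_coupling_is_variance_times_K(self, seg_and_net):
        nb, net = seg_and_net
        m = DynamicNetworkModel.from_subject(nb, net, K=2.0, t_burn=1.0, t_sim=4.0)
        np.testing.assert_array_equal(m.k_local, 2.0 * nb.variances())
        doubled = nb.with_data(nb.data * np.where(np.arange(6) == 2, np.sqrt(2), 1.0)[:, None])
        m2 = DynamicNetworkModel.from_subject(doubled, net, K=2.0, t_burn=1.0, t_sim=4.0)
        assert m2.k_local[2] == pytest.approx(2.0 * m.k_local[2])
        np.testing.assert_allclose(np.delete(m2.k_local, 2), np.delete(m.k_local, 2))

    def test_zero_K_gives_baseline_profile(self, seg_and_net):
        nb, net = seg_and_net
        res0 = biomarker_profile(nb, net, K=0.0, t_burn=1.0, t_sim=4.0)
        res1 = biomarker_profile(nb, net, K=5.0 / nb.variances().mean(),
                                 t_burn=1.0, t_sim=4.0)
        assert (res0.s <= res1.s + 1e-12).all()
        np.testing.assert_array_equal(
            DynamicNetworkModel.from_subject(nb, net, K=0.0, t_burn=1.0, t_sim=4.0).k_local,
            0.0,
        )

    def test_label_mismatch_rejected(self, seg_and_net):
        nb, net = seg_and_net
        bad = nb.__class__(nb.data, nb.sample_rate,
                           tuple(f"X{i}" for i in range(6)), band=nb.band)
        with pytest.raises(ModelConfigError, match="labels"):
            DynamicNetworkModel.from_subject(bad, net, K=1.0)

    def test_biomarker_value_reads_profile_entry(self, seg_and_net):
        nb, net = seg_and_net
        res = biomarker_profile(nb, net, K=1.0, t_burn=1.0, t_sim=4.0)
        ch = res.labels[4]
        assert res.biomarker_value(ch) == res.s[4]
        with pytest.raises(KeyError):
            res.biomarker_value("FOO")

    def test_summary_table_layout(self, seg_and_net):
        nb, net = seg_and_net
        df = biomarker_profile(nb, net, K=1.0, t_burn=1.0, t_sim=4.0).summary()
        assert list(df.columns) == ["k_local", "degree", "seizure_likelihood"]
        assert len(df) == 6


def test_default_K_grid_spans_sub_to_supercritical():
    sigma2 = np.array([1.0, 2.0, 4.0])
    grid = default_K_grid(sigma2, k_c=1.0, n=20)
    assert len(grid) == 20
    assert grid[0] == pytest.approx(0.1 / 4.0)
    assert grid[-1] == pytest.approx(10.0 / sigma2.mean())
    assert (np.diff(np.log(grid)) > 0).all()
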