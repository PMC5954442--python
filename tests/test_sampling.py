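"""Toy prior, Langevin sampling, metadynamics, and reproducibility."""

import numpy as np
import pytest

from cryometa.fit import FitConfig, divide_and_conquer_fit
from cryometa.forward import ScatteringTable, model_gmm
from cryometa.benchmark import grid_for
from cryometa.gmm import rasterize
from cryometa.sampling import (
    HingeChainPrior,
    LangevinConfig,
    MetadynamicsBias,
    ReplicaEnsemble,
    Trajectory,
    hinge_chain_prior,
    run_metainference,
    wt_metadynamics_update,
)
from cryometa.scoring import KB, MetaInfParams
from cryometa.analysis import backbone_rmsd

KBT = KB * 300.0


class TestHingeChainPrior:
    def test_conformers_are_exact_minima(self):
        prior, open_m, closed_m = hinge_chain_prior(n_beads=20)
        assert prior.energy(open_m.positions) == pytest.approx(0.0, abs=1e-9)
        assert prior.energy(closed_m.positions) == pytest.approx(0.0, abs=1e-9)

    def test_conformers_well_separated(self):
        prior, open_m, closed_m = hinge_chain_prior(n_beads=30)
        assert backbone_rmsd(open_m.positions, closed_m.positions) > 0.3

    def test_gradient_finite_difference(self, rng):
        prior = HingeChainPrior(n_beads=12)
        x = prior.conformer("open") + 0.02 * rng.standard_normal((12, 3))
        _, f = prior.energy_forces(x)
        h = 1e-6
        for k in range(12):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[k, d] += h
                xm[k, d] -= h
                num = -(prior.energy(xp) - prior.energy(xm)) / (2 * h)
                assert f[k, d] == pytest.approx(num, rel=1e-6, abs=1e-6)

    def test_cv_gradients_finite_difference(self, rng):
        prior = HingeChainPrior(n_beads=10)
        x = prior.conformer("closed") + 0.02 * rng.standard_normal((10, 3))
        for fn in (prior.hinge_angle_and_grad, prior.arm_angle_and_grad):
            val, grad = fn(x)
            h = 1e-7
            for k in range(10):
                for d in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[k, d] += h
                    xm[k, d] -= h
                    num = (fn(xp)[0] - fn(xm)[0]) / (2 * h)
                    assert grad[k, d] == pytest.approx(num, abs=1e-5)

    def test_single_well_parameters_warn(self):
        with pytest.warns(UserWarning, match="single well"):
            HingeChainPrior(theta_open=1.6, theta_closed=1.58)

    def test_hinge_double_well_barrier_height(self):
        prior = HingeChainPrior(barrier=5.0)
        mid = 0.5 * (prior.theta_open + prior.theta_closed)
        u_mid, _ = prior._hinge_u_du(mid)
        assert u_mid == pytest.approx(5.0)
        assert prior._hinge_u_du(prior.theta_open)[0] == pytest.approx(0.0)


class TestMetadynamics:
    def test_first_hill_full_height_and_gamma_limit(self):
        bias = MetadynamicsBias(w0=3.0, gamma=1e9, width=0.5, pace=10)
        wt_metadynamics_update(bias, 0.0, 0)
        assert bias.heights[0] == pytest.approx(3.0)
        for step in (10, 20, 30):
            wt_metadynamics_update(bias, 0.0, step)
        # gamma -> infinity: standard metadynamics, constant hills
        np.testing.assert_allclose(bias.heights, 3.0, rtol=1e-6)

    def test_fixed_cv_heights_decay_geometrically(self):
        bias = MetadynamicsBias(w0=2.0, gamma=5.0, width=0.3, pace=1,
                                temperature=300.0)
        for step in range(6):
            wt_metadynamics_update(bias, 1.0, step)
        h = np.asarray(bias.heights)
        # V(s) grows by the full stack of previous hills at the same point,
        # so h_{k+1}/h_k = exp(-h_k / kB dT)
        for k in range(5):
            expected = h[k] * np.exp(-h[k] / bias.kb_delta_t)
            assert h[k + 1] == pytest.approx(expected, rel=1e-9)

    def test_off_pace_steps_do_not_deposit(self):
        bias = MetadynamicsBias(w0=1.0, gamma=10.0, pace=100)
        wt_metadynamics_update(bias, 0.0, 50)
        assert bias.n_hills == 0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MetadynamicsBias(w0=-1.0, gamma=10.0)
        with pytest.raises(ValueError):
            MetadynamicsBias(w0=1.0, gamma=0.5)


import functools


@functools.lru_cache(maxsize=4)
def _tiny_benchmark(n_beads=8, w=1.0, budget=24, seed=5):
    """Small single/two-state map + prior for sampler tests (cached)."""
    prior = HingeChainPrior(n_beads=n_beads, barrier=2.0)
    open_m, closed_m = prior.model("open"), prior.model("closed")
    table = ScatteringTable.beads_only(0.2, weight=1.0 / n_beads)
    tpl = grid_for([open_m.positions, closed_m.positions], 0.2, 0.15)
    mo = rasterize(model_gmm(open_m, table), tpl)
    mc = rasterize(model_gmm(closed_m, table), tpl)
    mix = tpl.like(w * mo.values + (1 - w) * mc.values)
    data = divide_and_conquer_fit(mix, FitConfig(budget=budget, seed=seed))
    return prior, open_m, closed_m, table, data


class TestRunMetainference:
    def test_same_seed_bit_identical(self):
        prior, open_m, _, table, data = _tiny_benchmark()
        ens = ReplicaEnsemble.from_model(open_m, 2, jitter=0.01, seed=3)
        kwargs = dict(
            params=MetaInfParams(alpha=0.1), steps=500, seed=42, table=table,
            config=LangevinConfig(save_stride=50),
        )
        t1 = run_metainference(ens, prior, data, **kwargs)
        t2 = run_metainference(ens, prior, data, **kwargs)
        np.testing.assert_array_equal(t1.frames, t2.frames)
        np.testing.assert_array_equal(t1.ov, t2.ov)

    def test_prior_only_hinge_distribution_matches_boltzmann(self):
        # the hinge-angle marginal of the ideal chain is analytic:
        # p(theta) ~ sin(theta) exp(-U_hinge(theta)/kBT); soft angles and a
        # high mobility give fast mixing at a stable step
        prior = HingeChainPrior(n_beads=8, barrier=2.0, k_angle=100.0)
        ens = ReplicaEnsemble.from_model(prior.model("open"), 4, jitter=0.01, seed=0)
        traj = run_metainference(
            ens, prior, None, MetaInfParams(), steps=150000, seed=7,
            config=LangevinConfig(diffusion=0.03, save_stride=250),
        )
        pooled = traj.pooled_frames(0.1)
        angles = np.array([prior.hinge_angle(f) for f in pooled])
        edges = np.linspace(0.5, 2.7, 23)
        hist, _ = np.histogram(angles, bins=edges, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        u = np.array([prior._hinge_u_du(t)[0] for t in centers])
        ref = np.sin(centers) * np.exp(-u / KBT)
        ref /= np.trapezoid(ref, centers)
        # chi-square on binned counts (subsampled frames are correlated; the
        # comparison uses total-variation distance instead of raw chi2)
        tv = 0.5 * np.sum(np.abs(hist - ref)) * (edges[1] - edges[0])
        assert tv < 0.08

    def test_symmetric_wells_visited_equally_without_barrier(self):
        with pytest.warns(UserWarning, match="single well"):
            prior = HingeChainPrior(n_beads=6, barrier=0.0, k_angle=100.0)
        ens = ReplicaEnsemble.from_model(prior.model("open"), 4, jitter=0.01, seed=1)
        traj = run_metainference(
            ens, prior, None, MetaInfParams(), steps=150000, seed=3,
            config=LangevinConfig(diffusion=0.03, save_stride=250),
        )
        angles = np.array([prior.hinge_angle(f) for f in traj.pooled_frames(0.2)])
        n_open = np.sum(angles > np.pi / 2)
        n_closed = np.sum(angles <= np.pi / 2)
        ratio = n_open / max(n_closed, 1)
        assert abs(ratio - 1.0) < 0.2

    def test_single_state_map_confines_ensemble(self):
        prior, open_m, closed_m, table, data = _tiny_benchmark(w=1.0)
        ens = ReplicaEnsemble.from_model(open_m, 1, jitter=0.01, seed=2)
        traj = run_metainference(
            ens, prior, data, MetaInfParams(alpha=0.01), steps=30000, seed=9,
            table=table,
        )
        frames = traj.pooled_frames(0.2)
        nearer_open = np.array(
            [
                backbone_rmsd(f, open_m.positions)
                < backbone_rmsd(f, closed_m.positions)
                for f in frames
            ]
        )
        assert nearer_open.mean() >= 0.95

    def test_multiple_time_step_strides_agree(self):
        prior, open_m, _, table, data = _tiny_benchmark(w=1.0)
        means = {}
        for stride in (1, 2):
            vals = []
            for seed in (1, 2, 3):
                ens = ReplicaEnsemble.from_model(open_m, 2, jitter=0.01, seed=seed)
                traj = run_metainference(
                    ens, prior, data, MetaInfParams(alpha=0.01, stride=stride),
                    steps=20000, seed=seed + 50, table=table,
                )
                angles = [prior.hinge_angle(f) for f in traj.pooled_frames(0.3)]
                vals.append(np.mean(angles))
            means[stride] = (np.mean(vals), np.std(vals))
        diff = abs(means[1][0] - means[2][0])
        spread = means[1][1] + means[2][1] + 0.02
        assert diff < 3 * spread

    def test_force_overflow_halves_then_aborts(self):
        class ExplodingPrior:
            def energy(self, x):
                return 0.0

            def forces(self, x):
                return np.full_like(x, 1e9)

        prior = ExplodingPrior()
        ens = ReplicaEnsemble(
            np.zeros((1, 4, 3)),
            model=__import__("cryometa").forward.AtomicModel(
                np.zeros((4, 3)), ["BEAD"] * 4
            ),
        )
        with pytest.warns(UserWarning, match="halving"):
            with pytest.raises(RuntimeError, match="force overflow"):
                run_metainference(
                    ens, prior, None, MetaInfParams(), steps=10, seed=0
                )

    def test_restraint_energy_cv_requires_data(self):
        prior = HingeChainPrior(n_beads=6)
        ens = ReplicaEnsemble.from_model(prior.model("open"), 1, seed=0)
        bias = MetadynamicsBias(w0=1.0, gamma=10.0)
        with pytest.raises(ValueError, match="bias_cv"):
            run_metainference(
                ens, prior, None, MetaInfParams(), steps=10, seed=0, bias=bias
            )


class TestBiasedFreeEnergy:
    def test_metadynamics_reweighting_preserves_well_free_energy_gap(self):
        # asymmetric wells: the sin(theta) volume element tilts the balance;
        # a biased + reweighted run must agree with the unbiased estimate
        prior = HingeChainPrior(n_beads=8, barrier=2.0, k_angle=100.0,
                                theta_open=2.0, theta_closed=1.1)
        ens = ReplicaEnsemble.from_model(prior.model("open"), 4, jitter=0.01, seed=0)

        def gap_from(angles, weights=None):
            w = np.ones_like(angles) if weights is None else weights
            p_open = w[angles > np.pi / 2].sum()
            p_closed = w[angles <= np.pi / 2].sum()
            return -np.log(p_open / p_closed)

        fast = LangevinConfig(diffusion=0.03, save_stride=250)
        plain = run_metainference(
            ens, prior, None, MetaInfParams(), steps=120000, seed=11, config=fast,
        )
        a_plain = np.array([prior.hinge_angle(f) for f in plain.pooled_frames(0.2)])

        bias = MetadynamicsBias(w0=0.5, gamma=6.0, width=0.10, pace=200)
        biased = run_metainference(
            ens, prior, None, MetaInfParams(), steps=120000, seed=12,
            bias=bias, bias_cv=prior.hinge_angle_and_grad, config=fast,
        )
        a_biased = np.array([prior.hinge_angle(f) for f in biased.pooled_frames(0.2)])
        # final-bias reweighting: w(s) = exp(+V_final(s)/kBT)
        v = np.array([bias.energy(s) for s in a_biased])
        w = np.exp((v - v.max()) / KBT)
        assert abs(gap_from(a_biased, w) - gap_from(a_plain)) < 0.5


class TestTrajectory:
    def test_save_load_round_trip(self, tmp_path):
        prior, open_m, _, table, data = _tiny_benchmark()
        ens = ReplicaEnsemble.from_model(open_m, 2, jitter=0.01, seed=3)
        traj = run_metainference(
            ens, prior, data, MetaInfParams(alpha=0.1), steps=300, seed=1,
            table=table, config=LangevinConfig(save_stride=50),
        )
        path = tmp_path / "t.npz"
        traj.save(path)
        back = Trajectory.load(path)
        np.testing.assert_array_equal(back.frames, traj.frames)
        np.testing.assert_array_equal(back.ov, traj.ov)
        np.testing.assert_allclose(back.ov_bar(), traj.ov.mean(axis=1))

    def test_pooled_frames_discard(self):
        frames = np.arange(10 * 2 * 3 * 3, dtype=float).reshape(10, 2, 3, 3)
        traj = Trajectory(frames=frames, steps=np.arange(10))
        pooled = traj.pooled_frames(0.2)
        assert pooled.shape == (16, 3, 3)
        np.testing.assert_array_equal(pooled[0], frames[2, 0])

    def test_write_pdb_format(self, tmp_path):
        frames = np.zeros((2, 1, 3, 3))
        traj = Trajectory(frames=frames, steps=np.arange(2))
        path = tmp_path / "t.pdb"
        traj.write_pdb(path)
        text = path.read_text()
        assert text.count("MODEL") == 2
        assert text.count("ENDMDL") == 2
        assert "ATOM " in text
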