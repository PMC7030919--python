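"""Binless reweighting: weights, 2D landscapes, basin occupancies."""

import numpy as np
import pytest
from scipy import integrate

import lipidpmf as lp
from lipidpmf.constants import rt
from lipidpmf.potential import XI1_DOMAIN


class TestFrameWeights:
    def test_single_unbiased_window_gives_equal_weights(self):
        rng = np.random.default_rng(2)
        n = 5000
        tr = lp.CVTrajectory(time=np.arange(n, dtype=float),
                             xi1=rng.uniform(0.4, 1.5, n), window_index=0)
        proto = lp.UmbrellaProtocol(centers=(0.9,), force_constant=1e-12,
                                    n_steps=n)
        cfg = lp.AnalysisConfig(xi1_bin_min=0.4, xi1_bin_max=1.5)
        pmf = lp.wham_1d([tr], proto, cfg)
        w = lp.frame_weights([tr], proto, pmf)
        assert np.allclose(w.weights, 1.0 / n, rtol=1e-9)
        assert w.ess == pytest.approx(n, rel=1e-9)

    def test_weights_match_direct_formula_on_two_window_toy(self):
        """Implementation agrees with a brute-force evaluation of the
        binless formula w_n = 1 / sum_j N_j exp(beta*(f_j - u_j(x_n)))."""
        rng = np.random.default_rng(4)
        proto = lp.UmbrellaProtocol(centers=(0.6, 0.9), force_constant=800.0,
                                    n_steps=300)
        trajs = [
            lp.CVTrajectory(time=np.arange(300.0),
                            xi1=np.clip(rng.normal(c, 0.08, 300), 0.31, 1.99),
                            window_index=i)
            for i, c in enumerate(proto.centers)
        ]
        cfg = lp.AnalysisConfig()
        pmf = lp.wham_1d(trajs, proto, cfg)
        w = lp.frame_weights(trajs, proto, pmf)

        kt = rt(proto.temperature)
        x = np.concatenate([t.xi1 for t in trajs])
        brute = np.empty(len(x))
        for n, xn in enumerate(x):
            denom = 0.0
            for j, c in enumerate(proto.centers):
                u = 0.5 * proto.force_constant * (xn - c) ** 2
                denom += 300 * np.exp((pmf.window_offsets[j] - u) / kt)
            brute[n] = 1.0 / denom
        brute /= brute.sum()
        assert np.allclose(w.weights, brute, rtol=1e-8)

    def test_reweighted_mean_matches_quadrature(self, weights, post_burn,
                                                pot1):
        """Unbiased <xi1> from reweighted frames agrees with quadrature on
        the ground-truth marginal within 3 standard errors (time-block SE,
        which accounts for chain autocorrelation)."""
        kt = rt(323.0)
        x = np.linspace(*XI1_DOMAIN, 4001)
        p = np.exp(-pot1.marginal_xi1(x) / kt)
        p /= integrate.trapezoid(p, x)
        mean_truth = integrate.trapezoid(x * p, x)
        est = float(np.sum(weights.weights * weights.xi1))

        # contiguous time blocks across all windows (frames are stored
        # window-major, equal length per window)
        L = len(post_burn[0])
        W = len(post_burn)
        tpos = np.tile(np.arange(L), W)
        nb = 10
        block_means = []
        for b in range(nb):
            m = (tpos * nb // L) == b
            wsum = weights.weights[m].sum()
            block_means.append(
                float(np.sum(weights.weights[m] * weights.xi1[m]) / wsum))
        se = np.std(block_means, ddof=1) / np.sqrt(nb)
        assert abs(est - mean_truth) < 3 * se

    def test_unconverged_offsets_refused_without_override(self, post_burn,
                                                          config,
                                                          pmf_aligned):
        bad = lp.PMFProfile(
            bin_centers=pmf_aligned.bin_centers,
            free_energy=pmf_aligned.free_energy,
            zero_convention=pmf_aligned.zero_convention,
            window_offsets=pmf_aligned.window_offsets,
            counts=pmf_aligned.counts, temperature=pmf_aligned.temperature,
            converged=False)
        with pytest.raises(ValueError, match="unconverged"):
            lp.frame_weights(post_burn, config.protocol, bad)
        with pytest.warns(UserWarning, match="override"):
            lp.frame_weights(post_burn, config.protocol, bad,
                             allow_unconverged=True)

    def test_weight_invariants(self, weights):
        assert np.all(weights.weights >= 0)
        assert weights.weights.sum() == pytest.approx(1.0)
        assert 1.0 <= weights.ess <= len(weights)


class TestFes2D:
    def test_gaussian_samples_give_quadratic_surface(self):
        """Equal-weight independent Gaussian (xi2, xi3) samples produce a
        quadratic free-energy surface whose curvatures match the declared
        variances within 10%."""
        rng = np.random.default_rng(9)
        n = 400_000
        s2, s3 = 0.30, 0.20
        tr = lp.CVTrajectory(
            time=np.arange(n, dtype=float),
            xi1=np.full(n, 0.9),
            xi2=rng.normal(4.5, s2, n),
            xi3=np.clip(rng.normal(0.0, s3, n), -0.999, 0.999),
            window_index=0)
        w = lp.FrameWeights(weights=np.ones(n), xi1=tr.xi1, xi2=tr.xi2,
                            xi3=tr.xi3)
        cfg = lp.AnalysisConfig(fes_bins=40)
        fes = lp.fes_2d([tr], w, ("xi2", "xi3"), cfg)
        kt = rt(323.0)
        # fit F(x) = a (x - mu)^2 + c along the xi2 axis through the min
        _, jmin = np.unravel_index(np.nanargmin(fes.free_energy),
                                   fes.free_energy.shape)
        xs = fes.x_centers
        Fx = fes.free_energy[:, jmin]
        m = np.isfinite(Fx) & (np.abs(xs - 4.5) < 2 * s2)
        a = np.polyfit(xs[m], Fx[m], 2)[0]
        assert a == pytest.approx(kt / (2 * s2 ** 2), rel=0.10)

    def test_degenerate_pair_is_diagonal_ridge(self):
        n = 2000
        rng = np.random.default_rng(1)
        xi1 = rng.uniform(0.4, 1.5, n)
        tr = lp.CVTrajectory(time=np.arange(n, dtype=float), xi1=xi1,
                             xi2=xi1.copy(), window_index=0)
        w = lp.FrameWeights(weights=np.ones(n), xi1=xi1, xi2=xi1.copy(),
                            xi3=None)
        cfg = lp.AnalysisConfig(fes_bins=30)
        with pytest.warns(UserWarning, match="empty"):
            fes = lp.fes_2d([tr], w, ("xi1", "xi2"), cfg)
        finite = np.argwhere(np.isfinite(fes.free_energy))
        assert np.all(np.abs(finite[:, 0] - finite[:, 1]) <= 1)

    def test_three_basin_geometry_recovered(self, post_burn, weights,
                                            config):
        """The reweighted landscapes show the encounter basin at
        (xi1, xi2) = (0.73, 4.3) nm and the split bound state at xi1 =
        0.48 nm with two orientation basins, within one grid cell."""
        fes12 = lp.fes_2d(post_burn, weights, ("xi1", "xi2"), config)
        cell1 = np.diff(fes12.x_edges).max()
        cell2 = np.diff(fes12.y_edges).max()
        # global minimum: bound state at 0.48 nm
        b1, _ = fes12.minimum_location()
        assert abs(b1 - 0.48) <= cell1
        # encounter basin: minimum within the xi1 slab [0.65, 0.81]
        sl = (fes12.x_centers >= 0.65) & (fes12.x_centers <= 0.81)
        sub = fes12.free_energy[sl]
        i, j = np.unravel_index(np.nanargmin(sub), sub.shape)
        assert abs(fes12.y_centers[j] - 4.3) <= 2 * cell2

        fes23 = lp.fes_2d(post_burn, weights, ("xi2", "xi3"), config)
        cx = np.diff(fes23.x_edges).max()
        cy = np.diff(fes23.y_edges).max()
        F = fes23.free_energy
        for mu2, mu3 in ((3.94, 0.41), (3.48, 0.94)):
            near = (np.abs(fes23.x_centers[:, None] - mu2) <= 3 * cx) \
                & (np.abs(fes23.y_centers[None, :] - mu3) <= 3 * cy)
            best = np.nanmin(np.where(near, F, np.nan))
            assert best <= np.nanmin(F) + 2.0  # both basins thermally low
            ij = np.argwhere((F == best) & near)[0]
            assert abs(fes23.x_centers[ij[0]] - mu2) <= 1.5 * cx
            assert abs(fes23.y_centers[ij[1]] - mu3) <= 1.5 * cy

    def test_marginal_consistency_with_wham(self, weights, pmf_aligned,
                                            config):
        """xi1 marginal of the reweighted ensemble equals the WHAM PMF
        within 0.5 kJ/mol on well-sampled bins."""
        prof = lp.reweighted_profile_xi1(weights, config.xi1_bin_edges,
                                         config.temperature)
        F = pmf_aligned.free_energy - np.nanmin(pmf_aligned.free_energy)
        m = pmf_aligned.finite_mask & (pmf_aligned.total_counts() >= 100) \
            & np.isfinite(prof)
        assert np.nanmax(np.abs(prof[m] - F[m])) < 0.5


class TestBasinOccupancy:
    def test_whole_domain_state_has_unit_probability(self, weights):
        whole = lp.StateDefinition("all")
        occ = lp.basin_occupancy(weights, [whole], 323.0)
        assert occ["all"]["probability"] == pytest.approx(1.0)
        assert occ["(unassigned)"]["probability"] == pytest.approx(0.0)

    def test_symmetric_wells_equally_occupied(self):
        """Two mirror-image wells in a symmetric landscape get equal
        probability within Monte Carlo error."""
        pot = lp.make_model_potential([0.7, 1.1], [-8.0, -8.0])
        proto = lp.UmbrellaProtocol(n_steps=60_000, seed=23,
                                    exchange_interval=200)
        cfg = lp.AnalysisConfig(protocol=proto)
        reus = lp.run_reus(pot, proto)
        post = [lp.apply_burn_in(t, cfg) for t in reus.trajectories]
        pmf = lp.align_pmf(lp.wham_1d(post, proto, cfg), cfg.plateau_region)
        w = lp.frame_weights(post, proto, pmf)
        states = [lp.StateDefinition("L", xi1=(0.60, 0.80)),
                  lp.StateDefinition("R", xi1=(1.00, 1.20))]
        occ = lp.basin_occupancy(w, states, 323.0)
        pl, pr = occ["L"]["probability"], occ["R"]["probability"]
        assert abs(pl - pr) / (pl + pr) < 0.10

    def test_twenty_kj_stabilization_recovered(self):
        """At five lipids the generator declares a 20 kJ/mol E-to-B
        stabilisation; the reweighted basin free-energy difference matches
        quadrature on the generator within 1 kJ/mol."""
        # a 20 kJ/mol basin gap needs long, well-exchanged chains: the
        # deep-well / encounter probability ratio spans 3 decades
        pot = lp.default_potential(5)
        proto = lp.UmbrellaProtocol(n_steps=400_000, seed=29,
                                    exchange_interval=100)
        cfg = lp.AnalysisConfig(protocol=proto, burn_in_fraction=0.25)
        reus = lp.run_reus(pot, proto)
        post = [lp.apply_burn_in(t, cfg) for t in reus.trajectories]
        pmf = lp.align_pmf(lp.wham_1d(post, proto, cfg), cfg.plateau_region)
        w = lp.frame_weights(post, proto, pmf)
        states = [lp.StateDefinition("B", xi1=(0.40, 0.60)),
                  lp.StateDefinition("E", xi1=(0.60, 0.90))]
        occ = lp.basin_occupancy(w, states, 323.0)
        kt = rt(323.0)
        est = -kt * np.log(occ["B"]["probability"] / occ["E"]["probability"])
        x = np.linspace(*XI1_DOMAIN, 8001)
        g = np.exp(-pot.marginal_xi1(x) / kt)
        zb = integrate.trapezoid(np.where((x >= 0.40) & (x <= 0.60), g, 0), x)
        ze = integrate.trapezoid(np.where((x >= 0.60) & (x <= 0.90), g, 0), x)
        truth = -kt * np.log(zb / ze)
        assert est == pytest.approx(truth, abs=1.0)

    def test_empty_state_has_zero_probability_nan_energy(self, weights):
        far = lp.StateDefinition("nowhere", xi1=(1.90, 1.99))
        occ = lp.basin_occupancy(weights, [far], 323.0)
        assert occ["nowhere"]["probability"] == 0.0
        assert np.isnan(occ["nowhere"]["free_energy"])
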