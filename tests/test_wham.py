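"""WHAM estimator: recovery of known ground truths, gauge behaviour,
convergence diagnostics, minima detection, and agreement with an
independent maximum-likelihood solution of the same equations."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import lipidpmf as lp
from lipidpmf.constants import rt
from lipidpmf.potential import DEFAULT_ORIENTATION_COMPONENTS


def reference_wham(counts, centers, k, temperature, bin_centers):
    """Independent WHAM solution: minimise the negative log-likelihood
    over the window offsets with BFGS instead of iterating the
    self-consistent equations.  Returns (bin free energies, offsets)."""
    kt = rt(temperature)
    N = counts.sum(axis=1)
    n_tot = counts.sum(axis=0)
    occ = n_tot > 0
    beta_w = 0.5 * k * (bin_centers[None, :]
                        - np.asarray(centers)[:, None]) ** 2 / kt

    def negloglik(bf_free):
        bf = np.concatenate([[0.0], bf_free])
        log_denom = logsumexp(np.log(N)[:, None] + bf[:, None] - beta_w,
                              axis=0)
        return (np.sum(n_tot[occ] * log_denom[occ]) - np.dot(N, bf))

    res = minimize(negloglik, np.zeros(len(N) - 1), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    bf = np.concatenate([[0.0], res.x])
    log_denom = logsumexp(np.log(N)[:, None] + bf[:, None] - beta_w, axis=0)
    with np.errstate(divide="ignore"):
        log_p = np.where(occ, np.log(n_tot) - log_denom, -np.inf)
    F = np.where(occ, -kt * log_p, np.nan)
    return F - np.nanmin(F), bf * kt


class HarmonicTruth:
    """Duck-typed ground truth with a harmonic xi1 marginal."""

    components = DEFAULT_ORIENTATION_COMPONENTS

    def __init__(self, k0=60.0, x0=0.9):
        self.k0, self.x0 = k0, x0

    def marginal_xi1(self, x):
        return 0.5 * self.k0 * (np.asarray(x, float) - self.x0) ** 2


@pytest.fixture(scope="module")
def quick_cfg():
    return lp.AnalysisConfig(
        protocol=lp.UmbrellaProtocol(n_steps=40_000, seed=7))


class TestWham1D:
    def test_uniform_unbiased_window_gives_flat_pmf(self):
        """A single effectively unbiased window sampling a uniform density
        yields a flat profile within bootstrap error."""
        rng = np.random.default_rng(12)
        n = 50_000
        tr = lp.CVTrajectory(time=np.arange(n, dtype=float),
                             xi1=rng.uniform(0.4, 1.5, n), window_index=0)
        proto = lp.UmbrellaProtocol(centers=(0.9,), force_constant=1e-12,
                                    n_steps=n)
        cfg = lp.AnalysisConfig(xi1_bin_min=0.4, xi1_bin_max=1.5)
        pmf = lp.wham_1d([tr], proto, cfg)
        # bootstrap of the flatness statistic under multinomial resampling
        counts = pmf.total_counts()
        kt = rt(proto.temperature)
        boots = []
        for _ in range(100):
            c = rng.multinomial(n, counts / counts.sum())
            F = -kt * np.log(np.maximum(c, 1))
            boots.append(F.max() - F.min())
        spread = pmf.free_energy[pmf.finite_mask]
        assert spread.max() - spread.min() < 3 * np.mean(boots)

    def test_recovers_harmonic_ground_truth(self, quick_cfg):
        """16-window ladder on a harmonic landscape: recovered PMF matches
        the parabola with RMSE < 0.3 kJ/mol on well-sampled bins."""
        truth = HarmonicTruth()
        proto = quick_cfg.protocol
        trajs = [lp.sample_window(truth, proto, i)
                 for i in range(proto.n_windows)]
        pmf = lp.wham_1d(trajs, proto, quick_cfg)
        expected = truth.marginal_xi1(pmf.bin_centers)
        m = pmf.finite_mask & (pmf.total_counts() >= 100)
        diff = pmf.free_energy[m] - expected[m]
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff ** 2)) < 0.3

    def test_recovers_double_well_basin_gap(self, pmf_aligned, pot1):
        """The bound-to-encounter free-energy difference of the recovered
        PMF matches the quadrature truth (-4 kJ/mol) within 0.5."""
        x = pmf_aligned.bin_centers
        F = pmf_aligned.free_energy
        fb = np.nanmin(np.where(np.abs(x - 0.48) < 0.06, F, np.nan))
        fe = np.nanmin(np.where(np.abs(x - 0.73) < 0.06, F, np.nan))
        truth_b = float(pot1.marginal_xi1(0.48))
        truth_e = float(pot1.marginal_xi1(0.73))
        assert (fb - fe) == pytest.approx(truth_b - truth_e, abs=0.5)

    def test_empty_window_raises_with_name(self, quick_cfg):
        tr = lp.CVTrajectory(time=[0.0, 1.0], xi1=[0.5, 0.51],
                             window_index=0)
        with pytest.raises(ValueError, match="window 1"):
            lp.wham_1d([tr], lp.UmbrellaProtocol(centers=(0.5, 1.0)),
                       quick_cfg)

    def test_disjoint_windows_warn_about_overlap(self, quick_cfg):
        rng = np.random.default_rng(5)
        t = np.arange(500, dtype=float)
        trajs = [
            lp.CVTrajectory(time=t, xi1=rng.normal(0.45, 0.005, 500),
                            window_index=0),
            lp.CVTrajectory(time=t, xi1=rng.normal(1.45, 0.005, 500),
                            window_index=1),
        ]
        proto = lp.UmbrellaProtocol(centers=(0.45, 1.45))
        with pytest.warns(UserWarning, match="overlap"):
            lp.wham_1d(trajs, proto, quick_cfg)

    def test_gauge_invariance_of_offsets(self, post_burn, config,
                                         pmf_aligned):
        """Adding a constant to all window offsets leaves the reweighted
        profile (after alignment) unchanged."""
        shifted = lp.PMFProfile(
            bin_centers=pmf_aligned.bin_centers,
            free_energy=pmf_aligned.free_energy,
            zero_convention=pmf_aligned.zero_convention,
            window_offsets=pmf_aligned.window_offsets + 7.3,
            counts=pmf_aligned.counts,
            temperature=pmf_aligned.temperature,
            converged=True)
        w0 = lp.frame_weights(post_burn, config.protocol, pmf_aligned)
        w1 = lp.frame_weights(post_burn, config.protocol, shifted)
        assert np.allclose(w0.weights, w1.weights, rtol=1e-10)

    def test_agrees_with_independent_mle_solution(self, quick_cfg, pot1):
        """Direct iteration and an independent BFGS maximum-likelihood
        solution of the same estimator agree to 0.1 kJ/mol per bin."""
        proto = lp.UmbrellaProtocol(n_steps=20_000, seed=31)
        reus = lp.run_reus(pot1, proto)
        post = [lp.apply_burn_in(t, quick_cfg) for t in reus.trajectories]
        pmf = lp.wham_1d(post, proto, quick_cfg)
        ref_F, ref_f = reference_wham(
            pmf.counts, proto.centers, proto.force_constant,
            proto.temperature, pmf.bin_centers)
        m = pmf.finite_mask
        assert np.allclose(pmf.free_energy[m], ref_F[m], atol=0.1)
        assert np.allclose(pmf.window_offsets, ref_f, atol=0.1)


class TestAlign:
    def test_alignment_is_idempotent(self, pmf_aligned, config):
        again = lp.align_pmf(pmf_aligned, config.plateau_region)
        assert np.allclose(again.free_energy, pmf_aligned.free_energy,
                           equal_nan=True)

    def test_constant_shift_recovered(self, pmf_aligned, config):
        shifted = lp.PMFProfile(
            bin_centers=pmf_aligned.bin_centers,
            free_energy=pmf_aligned.free_energy + 5.0,
            zero_convention="min-zero",
            window_offsets=pmf_aligned.window_offsets,
            counts=pmf_aligned.counts,
            temperature=pmf_aligned.temperature)
        back = lp.align_pmf(shifted, config.plateau_region)
        assert np.allclose(back.free_energy, pmf_aligned.free_energy,
                           equal_nan=True)

    def test_well_depth_matches_declared_truth(self, pmf_aligned):
        """Aligned well depth reproduces the declared -17 kJ/mol minimum."""
        assert pmf_aligned.well_depth() == pytest.approx(-17.0, abs=0.5)

    def test_empty_plateau_region_raises(self, pmf_aligned):
        with pytest.raises(ValueError, match="plateau"):
            lp.align_pmf(pmf_aligned, (5.0, 6.0))


class TestConvergence:
    def test_identical_blocks_have_zero_discrepancy(self, quick_cfg):
        rng = np.random.default_rng(3)
        seg = rng.uniform(0.85, 0.95, 400)
        tr = lp.CVTrajectory(time=np.arange(1200, dtype=float),
                             xi1=np.tile(seg, 3), window_index=0)
        proto = lp.UmbrellaProtocol(centers=(0.9,))
        cfg = lp.AnalysisConfig(xi1_bin_min=0.84, xi1_bin_max=0.96,
                                xi1_bin_width=0.02, burn_in_fraction=0.0)
        _, D = lp.pmf_convergence([tr], proto, cfg, n_blocks=3)
        assert D.shape == (3, 3)
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(D, D.T, equal_nan=True)
        assert np.nanmax(D) < 1e-9

    def test_unrelaxed_first_block_stands_out(self, pot1):
        """A deliberately non-stationary first block disagrees with the
        last block more than later blocks disagree among themselves."""
        proto = lp.UmbrellaProtocol(n_steps=30_000, seed=19)
        reus = lp.run_reus(pot1, proto)
        trajs = []
        for tr in reus.trajectories:
            x = tr.xi1.copy()
            n0 = len(x) // 3
            x[:n0] = np.clip(x[:n0] + 0.12, 0.31, 1.99)  # shifted start
            trajs.append(lp.CVTrajectory(time=tr.time, xi1=x,
                                         window_index=tr.window_index))
        cfg = lp.AnalysisConfig(burn_in_fraction=0.0)
        _, D = lp.pmf_convergence(trajs, proto, cfg, n_blocks=3)
        assert D[0, 2] > D[1, 2]

    def test_needs_two_blocks(self, post_burn, config):
        with pytest.raises(ValueError, match="2 blocks"):
            lp.pmf_convergence(post_burn, config.protocol, config, 1)


class TestFindMinima:
    def test_two_well_positions_recovered(self, pmf_aligned):
        """Minima detected at the bound (0.48 nm) and encounter (0.73 nm)
        distances within one bin width."""
        res = lp.find_minima(pmf_aligned)
        w = pmf_aligned.bin_width
        assert len(res.minima) == 2
        positions = sorted(p for p, _ in res.minima)
        assert abs(positions[0] - 0.48) <= w
        assert abs(positions[1] - 0.73) <= w
        assert len(res.barriers) == 1
        assert res.barriers[0] > 0

    def test_monotone_profile_flags_edge(self):
        from conftest import make_profile
        x = np.linspace(0.4, 1.5, 30)
        prof = make_profile(x, 10 * (x - 0.4))
        res = lp.find_minima(prof, smooth=False)
        assert res.minima == []
        assert len(res.edge_minima) == 1
        assert res.edge_minima[0][0] == pytest.approx(0.4)

    def test_parabola_vertex(self):
        from conftest import make_profile
        x = np.linspace(0.4, 1.4, 51)
        prof = make_profile(x, 30 * (x - 0.9) ** 2)
        res = lp.find_minima(prof, smooth=False)
        assert len(res.minima) == 1
        assert res.minima[0][0] == pytest.approx(0.9, abs=0.02)

    def test_flat_profile_has_no_minima(self):
        from conftest import make_profile
        prof = make_profile(np.linspace(0.4, 1.4, 20), np.zeros(20))
        res = lp.find_minima(prof, smooth=False)
        assert res.minima == []
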