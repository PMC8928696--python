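import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime, minimize

import cutdecon.gpdeconv as gd
from cutdecon.fragio import GenomeIndex, fragments_to_cuts
from cutdecon.lengthmodel import LengthPrior

from conftest import frags_df


def make_region(pos, fraglen, weight=None, span=None, padding=0, chrom="chrS"):
    pos = np.asarray(pos)
    if span is None:
        span = (0, int(pos.max()) + 1)
    return gd.DeconvRegion(
        chrom=chrom,
        start=span[0],
        end=span[1],
        pos=pos,
        fraglen=np.asarray(fraglen),
        weight=np.ones(pos.size) if weight is None else np.asarray(weight, float),
        padding=padding,
    )


class TestMatern32:
    def test_unit_variance_at_zero(self):
        assert gd.matern32(0.0, 500.0) == 1.0

    def test_value_at_one_lengthscale(self):
        expected = (1 + math.sqrt(3)) * math.exp(-math.sqrt(3))
        assert gd.matern32(500.0, 500.0) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.4834, abs=5e-4)

    def test_monotone_decreasing(self):
        d = np.linspace(0, 10_000, 500)
        v = gd.matern32(d, 2000.0)
        assert np.all(np.diff(v) < 0)

    def test_rejects_bad_lengthscale(self):
        with pytest.raises(ValueError):
            gd.matern32(1.0, 0.0)


class TestStateSpaceEquivalence:
    """The Markov representation must reproduce the dense Matérn-3/2 GP."""

    def test_marginal_covariance_matches_kernel(self):
        rng = np.random.default_rng(0)
        xs = np.sort(rng.choice(5000, 40, replace=False)).astype(float)
        for ell in (500.0, 2000.0):
            mp = gd._MarkovPrior(xs, ell)
            # build the joint precision from the factorisation and invert
            n = xs.size
            prec = np.zeros((2 * n, 2 * n))
            prec[:2, :2] += mp.pinf_inv
            for i in range(n - 1):
                A, Qi = mp.A[i], mp.Qinv[i]
                s, t = 2 * i, 2 * i + 2
                prec[t : t + 2, t : t + 2] += Qi
                prec[s : s + 2, s : s + 2] += A.T @ Qi @ A
                prec[t : t + 2, s : s + 2] += -Qi @ A
                prec[s : s + 2, t : t + 2] += -(Qi @ A).T
            cov = np.linalg.inv(prec)
            K_ssm = cov[::2, ::2]
            K = gd.matern32(np.abs(xs[:, None] - xs[None, :]), ell)
            assert np.abs(K_ssm - K).max() < 1e-5

    def test_whitening_reproduces_prior_quadratic_form(self):
        rng = np.random.default_rng(1)
        xs = np.sort(rng.choice(3000, 25, replace=False)).astype(float)
        mp = gd._MarkovPrior(xs, 500.0)
        eps = rng.normal(size=(25, 2))
        z = mp.states_from_innovations(eps)
        v, _ = mp.value_grad(z)
        assert v == pytest.approx(-0.5 * (eps**2).sum(), rel=1e-10)
        # and the inverse map round-trips
        assert np.allclose(mp.innovations_from_states(z), eps, atol=1e-8)

    def test_bridge_interpolation_equals_kernel_interpolation(self):
        rng = np.random.default_rng(2)
        xs = np.sort(rng.choice(4000, 30, replace=False)).astype(float)
        mp = gd._MarkovPrior(xs, 700.0)
        g = rng.normal(size=30)
        # profile the derivative coordinates to their conditional mean
        def negprior(gp):
            Z = np.stack([g, gp], axis=1)
            v, gr = mp.value_grad(Z)
            return -v, -gr[:, 1]

        res = minimize(negprior, np.zeros(30), jac=True, method="L-BFGS-B",
                       options=dict(gtol=1e-13, ftol=1e-16))
        Z = np.stack([g, res.x], axis=1)
        query = np.array([xs[0] - 400.0, xs[0], 0.5 * (xs[3] + xs[4]),
                          xs[17] + 1.0, xs[-1] + 250.0])
        got = mp.interpolate(xs, Z, query)
        K = gd.matern32(np.abs(xs[:, None] - xs[None, :]), 700.0)
        Kq = gd.matern32(np.abs(query[:, None] - xs[None, :]), 700.0)
        want = Kq @ np.linalg.solve(K, g)
        assert np.abs(got - want).max() < 1e-4


class TestRectangleRule:
    def test_equally_spaced_constant(self):
        pos = np.arange(0, 100, 10)
        val = np.full(10, 2.0)
        # widths: 10 at both ends and 10 interior -> 2 * 100
        assert gd.rectangle_integral(pos, val) == pytest.approx(200.0)

    def test_stated_toy_example(self):
        assert np.allclose(gd.rectangle_widths(np.array([0, 10, 30])), [10, 15, 20])

    def test_close_to_fine_quadrature_on_smooth_function(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.uniform(0, 1000, 200))
        f = lambda x: 2 + np.sin(x / 150.0)
        approx = gd.rectangle_integral(pos, f(pos))
        fine = np.trapezoid(f(np.linspace(pos[0], pos[-1], 20_000)),
                            np.linspace(pos[0], pos[-1], 20_000))
        assert approx == pytest.approx(fine, rel=0.2)

    def test_single_position_fallback(self):
        assert gd.rectangle_integral(np.array([5.0]), np.array([3.0])) == 3.0

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            gd.rectangle_integral(np.array([5.0, 1.0]), np.ones(2))


class TestSelectRegions:
    def test_no_cuts_no_regions(self):
        cuts = pd.DataFrame(columns=["chrom", "pos", "fraglen", "weight"])
        out = gd.select_regions(cuts, GenomeIndex.from_dict({"chrS": 10_000}))
        assert out.empty

    def test_uniform_dense_window_selected(self):
        """1,000 cuts uniform in a 10-kb window (0.1 cuts/bp) and nothing
        elsewhere select one region covering the window up to KDE edge
        effects (3 sigma)."""
        rng = np.random.default_rng(4)
        pos = np.sort(rng.integers(20_000, 30_000, 1000))
        cuts = pd.DataFrame(
            {"chrom": "chrS", "pos": pos, "fraglen": 100, "weight": 1.0}
        )
        out = gd.select_regions(cuts, GenomeIndex.from_dict({"chrS": 100_000}))
        assert len(out) == 1
        row = out.iloc[0]
        assert abs(row["start"] - 20_000) <= 600
        assert abs(row["end"] - 30_000) <= 600

    def test_nearby_clusters_merged(self):
        rng = np.random.default_rng(5)
        pos = np.concatenate(
            [rng.integers(10_000, 12_000, 500), rng.integers(17_000, 19_000, 500)]
        )
        cuts = pd.DataFrame(
            {"chrom": "chrS", "pos": np.sort(pos), "fraglen": 100, "weight": 1.0}
        )
        out = gd.select_regions(cuts, GenomeIndex.from_dict({"chrS": 50_000}))
        assert len(out) == 1  # 5-kb gap < 10-kb merge rule

    def test_sparse_background_not_selected(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.integers(0, 100_000, 500))  # 0.005 cuts/bp
        cuts = pd.DataFrame(
            {"chrom": "chrS", "pos": pos, "fraglen": 100, "weight": 1.0}
        )
        out = gd.select_regions(cuts, GenomeIndex.from_dict({"chrS": 100_000}))
        assert out.empty


class TestSplitIntervals:
    def _cuts(self, pos):
        return pd.DataFrame(
            {"chrom": "chrS", "pos": pos, "fraglen": 100, "weight": 1.0}
        )

    def test_boundary_chunk_counts(self):
        cfg = gd.GPConfig(max_cuts_per_chunk=10_000)
        pos = np.arange(9_999)
        assert len(gd.split_intervals("chrS", 0, 20_000, self._cuts(pos), cfg)) == 1
        pos = np.arange(10_001)
        assert len(gd.split_intervals("chrS", 0, 20_000, self._cuts(pos), cfg)) == 2

    def test_padding_cut_used_in_inference_not_output(self):
        cfg = gd.GPConfig()
        pos = np.array([500, 600, 700, 1_000 + 9_999])
        # region covers only the first three cuts; the fourth sits 9,999 bp
        # beyond the region end and must enter as padding context
        chunks = gd.split_intervals("chrS", 0, 1_000, self._cuts(pos), cfg)
        assert len(chunks) == 1
        assert 1_000 + 9_999 in chunks[0].pos
        track = gd.map_deconvolve(chunks[0], cfg)
        assert 1_000 + 9_999 not in track.cut_pos
        assert track.grid_pos.max() < 1_000


class TestObjectiveAndPosterior:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(2000, 15, replace=False))
        region = make_region(pos, rng.choice([70, 200, 400], 15))
        obj = gd._Objective(region, gd.GPConfig(), LengthPrior())
        theta = obj.initial()
        _, g = obj(theta)
        gn = approx_fprime(theta, lambda t: obj(t)[0], 1e-7)
        rel = np.abs(g - gn) / (1 + np.abs(gn))
        assert rel.max() < 1e-3  # forward-difference noise floor

    def test_one_cut_likelihood_term_matches_hand_computation(self):
        """With one cut and flat g chosen so each exp-density integrates
        to half a cut, the likelihood term is the log of a two-term
        mixture evaluated by hand."""
        prior = LengthPrior()
        cfg = gd.GPConfig()
        region = make_region(np.array([100]), np.array([70]))
        w_pol = prior.prior_mean_weights("pol")
        w_k27 = prior.prior_mean_weights("k27")
        g = math.log(0.5)  # single rectangle of width 1
        lp = gd.log_posterior(region, [g], [g], w_pol, w_k27, cfg, prior)
        h_pol = (prior.component_pdfs([70]) @ w_pol).item()
        h_k27 = (prior.component_pdfs([70]) @ w_k27).item()
        lik = math.log(0.5 * h_pol + 0.5 * h_k27)
        # remaining terms: two N(g; 0, 1+jitter) priors, two Dirichlet
        # log-densities, and the integral factor at I = W = 1
        from scipy.stats import norm
        from cutdecon.lengthmodel import dirichlet_log_prior

        rest = (
            2 * norm.logpdf(g, 0, math.sqrt(1 + cfg.jitter))
            + dirichlet_log_prior(w_pol, prior.dirichlet_pol)
            + dirichlet_log_prior(w_k27, prior.dirichlet_k27)
            - math.log(1.0 * cfg.integral_sd * math.sqrt(2 * math.pi))
        )
        assert lp == pytest.approx(lik + rest, abs=1e-9)

    def test_doubling_weights_doubles_likelihood_term(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(3000, 20, replace=False))
        lens = rng.choice([70, 200], 20)
        prior = LengthPrior()
        cfg = gd.GPConfig()
        g = rng.normal(scale=0.1, size=20)
        w_pol = prior.prior_mean_weights("pol")
        w_k27 = prior.prior_mean_weights("k27")

        def lik_only(weight):
            region = make_region(pos, lens, weight=np.full(20, weight))
            obj = gd._Objective(region, cfg, prior)
            h = obj.phi
            s = np.exp(g)[obj.idx] * (h @ w_pol) + np.exp(g)[obj.idx] * (h @ w_k27)
            return float(obj.w @ np.log(s))

        assert lik_only(2.0) == pytest.approx(2 * lik_only(1.0))

    def test_log_posterior_rejects_nonfinite(self):
        region = make_region(np.array([10, 20]), np.array([70, 200]))
        prior = LengthPrior()
        with pytest.raises(ValueError):
            gd.log_posterior(region, [np.nan, 0.0], [0.0, 0.0],
                             prior.prior_mean_weights("pol"),
                             prior.prior_mean_weights("k27"))


class TestMapDeconvolve:
    def test_symmetric_posterior_gives_equal_tracks(self):
        """With identical length priors and length scales the two targets
        are exchangeable and the MAP tracks must coincide."""
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(2000, 60, replace=False))
        region = make_region(pos, rng.choice([70, 200, 400], 60))
        prior = LengthPrior(dirichlet_pol=(100.0, 50.0, 10.0, 5.0),
                            dirichlet_k27=(100.0, 50.0, 10.0, 5.0))
        cfg = gd.GPConfig(lengthscale_pol=800.0, lengthscale_k27=800.0)
        track = gd.map_deconvolve(region, cfg, prior)
        assert np.abs(track.log_pol - track.log_k27).max() < 1e-2
        assert np.allclose(track.weights_pol, track.weights_k27, atol=1e-3)

    def test_short_fragment_cluster_assigned_to_pol(self):
        """Cuts drawn only from the short mode in a narrow cluster should
        be attributed to the short-fragment target."""
        rng = np.random.default_rng(10)
        pos = np.sort(rng.integers(900, 1100, 80))
        lens = np.clip(rng.lognormal(np.log(70) + 0.16, 0.4, 80), 30, 150).astype(int)
        region = make_region(pos, lens, span=(0, 2000))
        track = gd.map_deconvolve(region, gd.GPConfig(), LengthPrior())
        mass_pol = track.integral_pol
        assert mass_pol / (mass_pol + track.integral_k27) > 0.9

    def test_integral_matches_soft_constraint_equilibrium(self):
        """The MAP integral equals the cut weight inflated by the
        likelihood-scale equilibrium factor exp(sd^2 (W - 1))."""
        rng = np.random.default_rng(11)
        for n in (200, 800):
            pos = np.sort(rng.choice(20_000, n, replace=False))
            region = make_region(pos, rng.choice([70, 200, 400], n))
            track = gd.map_deconvolve(region, gd.GPConfig(), LengthPrior())
            ratio = track.constraint_integral / track.target_weight
            predicted = math.exp(1e-6 * (track.target_weight - 1))
            assert ratio == pytest.approx(predicted, abs=6e-3)

    def test_region_without_cuts_rejected(self):
        region = make_region(np.array([], dtype=int), np.array([], dtype=int),
                             span=(0, 100))
        with pytest.raises(ValueError):
            gd.fit_region(region)


class TestDeconvolveGenome:
    def test_two_far_regions_independent_and_deterministic(self):
        rng = np.random.default_rng(12)
        frags = frags_df(
            [("chrS", int(p), int(p) + 80) for p in rng.integers(5_000, 8_000, 400)]
            + [("chrS", int(p), int(p) + 300) for p in rng.integers(60_000, 65_000, 400)]
        )
        genome = GenomeIndex.from_dict({"chrS": 100_000})
        cuts = fragments_to_cuts(frags)
        r1 = gd.deconvolve_genome(cuts, genome)
        r2 = gd.deconvolve_genome(cuts, genome)
        assert len(r1.regions) == 2
        for t1, t2 in zip(r1.tracks, r2.tracks):
            assert np.array_equal(t1.log_pol, t2.log_pol)  # bitwise identical
            assert np.array_equal(t1.log_k27, t2.log_k27)
        starts = [t.start for t in r1.tracks]
        assert starts == sorted(starts)

    def test_chunk_boundary_continuity(self):
        """A feature straddling a forced chunk split is reconstructed
        consistently thanks to the padding: adjacent chunks agree at the
        boundary."""
        rng = np.random.default_rng(13)
        pos = np.sort(rng.normal(10_000, 2_000, 1200).astype(int))
        frags = frags_df([("chrS", int(p), int(p) + 150) for p in pos if p > 0])
        genome = GenomeIndex.from_dict({"chrS": 40_000})
        cuts = fragments_to_cuts(frags)
        cfg = gd.GPConfig(max_cuts_per_chunk=800)  # force a split
        res = gd.deconvolve_genome(cuts, genome, cfg)
        assert len(res.tracks) >= 2
        for a, b in zip(res.tracks, res.tracks[1:]):
            if a.end == b.start:
                da = math.exp(a.log_k27[-1])
                db = math.exp(b.log_k27[0])
                assert abs(da - db) / max(da, db) < 0.1

    def test_assign_cuts_falls_back_to_length_posterior(self, tiny_sim):
        cfg, truth, frags, table = tiny_sim
        cuts = fragments_to_cuts(frags)
        res = gd.deconvolve_genome(cuts, cfg.genome)
        p = gd.assign_cuts(res, "chrS", np.array([0]), np.array([70]))
        assert 0.0 < p[0] < 1.0  # outside all tracks: finite length-only value
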