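import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from retinacode.encoding_models import (
    CellFilters,
    PopulationEncoder,
    SpikeTrainSet,
    softplus,
)
from retinacode.priors import GaussianFourierPrior, OneOverFPrior, RhoSchedule
from retinacode.reconstruction import (
    ImageLikelihood,
    JointEMConfig,
    ParticleEnsemble,
    encoding_step,
    particle_filter_update,
    reconstruct_1f_exact,
    reconstruct_flashed_map,
    reconstruct_joint_em,
    reconstruct_known_em,
    reconstruct_noiseless_linear,
    systematic_resample,
)
from retinacode.reconstruction import _pnp_loop
from retinacode.retina_simulator import (
    build_mosaic,
    sample_ground_truth_params,
    simulate_spikes,
)
from retinacode.synthetic_stimulus import (
    generate_texture_image,
    render_flashed_trial,
    render_jittered_trial,
    simulate_drift_trajectory,
)

FRAME_PERIOD = 1000.0 / 120.0
SIZE = 16
FIELD = SIZE * 11.0


@pytest.fixture(scope="module")
def small_encoder():
    mosaic = build_mosaic((FIELD, FIELD), jitter_fraction=0.1, seed=3)
    return sample_ground_truth_params(mosaic, seed=4, image_shape=(SIZE, SIZE))


@pytest.fixture(scope="module")
def flash_spikes(small_encoder):
    img = generate_texture_image(21, SIZE, SIZE)
    movie = render_flashed_trial(img, 100.0, 100.0, FRAME_PERIOD)
    return img, simulate_spikes(small_encoder, movie, seed=5)


class QuadraticLikelihood:
    """Gaussian (linearized) likelihood 0.5 ||W y - d||^2 for oracle tests."""

    def __init__(self, W, d, image_shape):
        self.W = W
        self.d = d
        self.image_shape = image_shape

    def nll_and_grad(self, y):
        r = self.W @ y - self.d
        return 0.5 * float(r @ r), self.W.T @ r

    def nll(self, y):
        return self.nll_and_grad(y)[0]


class TestEncodingStep:
    def test_large_rho_pins_to_z(self, small_encoder, flash_spikes):
        _, spikes = flash_spikes
        lik = ImageLikelihood(small_encoder, spikes, (SIZE, SIZE), 24,
                              FRAME_PERIOD)
        z = np.full((SIZE, SIZE), 0.4)
        x = encoding_step(lik, z, rho=1e6)
        assert np.linalg.norm(x - z) < 1e-3

    def test_nonpositive_rho_rejected(self, small_encoder, flash_spikes):
        _, spikes = flash_spikes
        lik = ImageLikelihood(small_encoder, spikes, (SIZE, SIZE), 24,
                              FRAME_PERIOD)
        with pytest.raises(ValueError):
            encoding_step(lik, np.zeros((SIZE, SIZE)), rho=0.0)

    def test_objective_not_worse_than_start(self, small_encoder, flash_spikes):
        _, spikes = flash_spikes
        lik = ImageLikelihood(small_encoder, spikes, (SIZE, SIZE), 24,
                              FRAME_PERIOD)
        z = np.full((SIZE, SIZE), 0.5)
        rho = 1.0
        x = encoding_step(lik, z, rho)

        def obj(v):
            d = v.ravel() - z.ravel()
            return lik.nll(v.ravel()) + 0.5 * rho * (d @ d)

        assert obj(x) <= obj(z) + 1e-9

    def test_single_pixel_cell_scalar_oracle(self):
        # one cell reading one pixel through a 1-bin kernel: the encoding
        # sub-problem reduces to a 1D problem checked against a scalar solver
        cell = CellFilters(0, np.array([[1.0]]), (2, 2), np.array([1.0]),
                           np.zeros(1), {}, bias=-1.0)
        enc = PopulationEncoder(cells=[cell])
        rng = np.random.default_rng(0)
        spikes = SpikeTrainSet(binned=(rng.random((1, 50)) < 0.3).astype(np.uint8))
        lik = ImageLikelihood(enc, spikes, (8, 8), 6, FRAME_PERIOD)
        z = np.full((8, 8), 0.5)
        rho = 2.0
        x = encoding_step(lik, z, rho, grad_tol=1e-12)
        s = spikes.binned[0].astype(float)
        n1, n0 = s[1:].sum(), (1 - s[1:]).sum()  # bin 0 has no stimulus drive

        def scalar_obj(v):
            g = (v - 0.5) + cell.bias
            return (n1 * softplus(np.array([-g]))[0]
                    + n0 * softplus(np.array([g]))[0]
                    + 0.5 * rho * (v - 0.5) ** 2)

        v_star = minimize_scalar(scalar_obj, bounds=(-2, 3), method="bounded").x
        assert abs(x[2, 2] - v_star) < 1e-4
        # all other pixels stay at z
        mask = np.ones((8, 8), bool)
        mask[2, 2] = False
        assert np.allclose(x[mask], 0.5, atol=1e-8)


class TestPlugAndPlayOracle:
    def test_matches_closed_form_gaussian_map(self, rng):
        # exact Gaussian prior + quadratic likelihood: the 10-iteration
        # splitting loop must land on the closed-form MAP solution.  The
        # instance is well-posed (overdetermined likelihood, weak prior): the
        # splitting fixed-point bias scales like lam/rho while the per-
        # iteration contraction scales like rho/(rho + likelihood curvature),
        # so both are small only in this regime.
        n = 12 * 12
        W = rng.normal(size=(600, n)) / np.sqrt(n)
        y_true = rng.random(n)
        d = W @ y_true + 0.05 * rng.normal(size=600)
        weights = 0.5 + np.abs(rng.random((12, 12)))
        lam = 0.002
        prior = GaussianFourierPrior(spectral_weights=weights, lambda_weight=lam)
        lik = QuadraticLikelihood(W, d, (12, 12))
        sched = RhoSchedule(0.3, 40.0, 10)
        z, _ = _pnp_loop(lik, prior, sched, np.full((12, 12), 0.5), max_iter=400)
        # closed form in Fourier domain: (W^T W + 2 lam D) y = W^T d
        F = np.fft.fft2(np.eye(n).reshape(n, 12, 12), norm="ortho").reshape(n, n).T
        Dmat = np.conj(F).T @ np.diag(weights.ravel()) @ F
        A = W.T @ W + 2 * lam * np.real(Dmat)
        y_map = np.linalg.solve(A, W.T @ d)
        rmse = np.sqrt(np.mean((z.ravel() - y_map) ** 2))
        assert rmse < 1e-3

    def test_default_schedule_has_ten_iterations(self):
        assert RhoSchedule().n_iters == 10
        assert len(RhoSchedule().values) == 10


class TestFlashedReconstruction:
    def test_runs_and_improves_over_ablated(self, small_encoder, flash_spikes):
        from retinacode.evaluation import ms_ssim

        img, spikes = flash_spikes
        prior = OneOverFPrior(shape=(SIZE, SIZE), lambda_weight=2.0)
        res = reconstruct_flashed_map(spikes, small_encoder, prior,
                                      image_shape=(SIZE, SIZE))
        assert res.image.shape == (SIZE, SIZE)
        assert len(res.trace) == 10
        assert np.all(np.isfinite(res.image))
        # ablation: spikes from an encoder with zeroed stimulus filters carry
        # no image information
        ablated_enc = PopulationEncoder(cells=[
            CellFilters(c.cell_id, 0.0 * c.spatial_map, c.crop_origin,
                        c.temporal_kernel, c.feedback_kernel,
                        c.coupling_kernels, c.bias)
            for c in small_encoder.cells
        ], mosaic=small_encoder.mosaic)
        movie = render_flashed_trial(img, 100.0, 100.0, FRAME_PERIOD)
        blank_spikes = simulate_spikes(ablated_enc, movie, seed=5)
        res0 = reconstruct_flashed_map(blank_spikes, small_encoder, prior,
                                       image_shape=(SIZE, SIZE))
        s1 = ms_ssim(res.image_clipped, img.pixels)
        s0 = ms_ssim(res0.image_clipped, img.pixels)
        assert s1 > s0


class TestExact1F:
    def test_trace_nonincreasing(self, small_encoder, flash_spikes):
        _, spikes = flash_spikes
        prior = OneOverFPrior(shape=(SIZE, SIZE), lambda_weight=1.0)
        res = reconstruct_1f_exact(spikes, small_encoder, prior,
                                   image_shape=(SIZE, SIZE))
        trace = np.asarray(res.trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_agrees_with_splitting_exact_prox(self, rng):
        # algorithm equivalence on a well-posed instance: gradient descent on
        # NLL + 1/F prior vs the splitting loop with the exact 1/F prox must
        # find the same optimum.  (On a spike likelihood the splitting's
        # fixed-point bias in near-null directions prevents 1e-3 agreement;
        # see the looser spike-likelihood check below.)
        from retinacode.reconstruction import gradient_descent_map

        n = 12 * 12
        W = rng.normal(size=(600, n)) / np.sqrt(n)
        y_true = rng.random(n)
        d = W @ y_true + 0.05 * rng.normal(size=600)
        prior = OneOverFPrior(shape=(12, 12), lambda_weight=0.02)
        lik = QuadraticLikelihood(W, d, (12, 12))
        gd_img, gd_trace = gradient_descent_map(lik, prior, (12, 12),
                                                max_iter=20000, grad_tol=1e-9)
        sched = RhoSchedule(0.3, 40.0, 10)
        z, _ = _pnp_loop(lik, prior, sched, np.full((12, 12), 0.5),
                         max_iter=400)
        rmse = np.sqrt(np.mean((gd_img - z) ** 2))
        assert rmse < 1e-3
        assert np.all(np.diff(gd_trace) <= 1e-9)

    def test_spike_likelihood_agreement_loose(self, small_encoder, flash_spikes):
        # on the real Bernoulli likelihood the two algorithms must agree where
        # the posterior is well determined (weak modes differ by the HQS bias)
        _, spikes = flash_spikes
        prior = OneOverFPrior(shape=(SIZE, SIZE), lambda_weight=1.0)
        exact = reconstruct_1f_exact(spikes, small_encoder, prior,
                                     image_shape=(SIZE, SIZE), grad_tol=1e-7,
                                     max_iter=4000)
        sched = RhoSchedule(0.5, 2000.0, 40)
        split = reconstruct_flashed_map(spikes, small_encoder, prior, sched,
                                        image_shape=(SIZE, SIZE),
                                        encoding_max_iter=300)
        rmse = np.sqrt(np.mean((exact.image - split.image) ** 2))
        assert rmse < 0.1
        corr = np.corrcoef(exact.image.ravel(), split.image.ravel())[0, 1]
        assert corr > 0.95

    def test_huge_lambda_flattens_image(self, small_encoder, flash_spikes):
        _, spikes = flash_spikes
        prior = OneOverFPrior(shape=(SIZE, SIZE), lambda_weight=1e7)
        res = reconstruct_1f_exact(spikes, small_encoder, prior,
                                   image_shape=(SIZE, SIZE))
        assert np.std(res.image) < 0.01


class TestKnownEyeMovements:
    def test_zero_trajectory_reduces_to_static(self, small_encoder):
        img = generate_texture_image(31, SIZE, SIZE)
        traj = simulate_drift_trajectory(24, 0.0, seed=0)
        movie = render_jittered_trial(img, traj)
        spikes = simulate_spikes(small_encoder, movie, seed=6)
        prior = OneOverFPrior(shape=(SIZE, SIZE), lambda_weight=1.0)
        r1 = reconstruct_known_em(spikes, small_encoder, prior,
                                  traj, image_shape=(SIZE, SIZE))
        r2 = reconstruct_known_em(spikes, small_encoder, prior,
                                  np.zeros((24, 2), dtype=int),
                                  image_shape=(SIZE, SIZE))
        assert np.allclose(r1.image, r2.image, atol=1e-10)

    def test_length_mismatch_rejected(self, small_encoder, flash_spikes):
        _, spikes = flash_spikes
        prior = OneOverFPrior(shape=(SIZE, SIZE))
        with pytest.raises(ValueError):
            reconstruct_known_em(spikes, small_encoder, prior,
                                 np.zeros((99, 2), dtype=int),
                                 image_shape=(SIZE, SIZE))

    def test_translation_gauge_of_likelihood(self, small_encoder):
        # shifting both the image hypothesis and the trajectory leaves the
        # likelihood unchanged (content away from borders)
        img = generate_texture_image(33, SIZE, SIZE)
        traj = simulate_drift_trajectory(24, 10.0, seed=1)
        movie = render_jittered_trial(img, traj)
        spikes = simulate_spikes(small_encoder, movie, seed=8)
        shifts = traj.displacements_px
        rng = np.random.default_rng(0)
        y = np.full((SIZE, SIZE), 0.5)
        y[6:10, 6:10] = rng.random((4, 4))  # interior content only
        offset = np.array([2, -1])
        lik1 = ImageLikelihood(small_encoder, spikes, (SIZE, SIZE), 24,
                               FRAME_PERIOD, frame_shifts=shifts)
        from retinacode.synthetic_stimulus import shift_image
        y_shifted = shift_image(y, -offset[0], -offset[1], 0.5)
        lik2 = ImageLikelihood(small_encoder, spikes, (SIZE, SIZE), 24,
                               FRAME_PERIOD, frame_shifts=shifts + offset)
        assert np.isclose(lik1.nll(y.ravel()), lik2.nll(y_shifted.ravel()),
                          rtol=1e-10)


class TestParticleFilter:
    def test_weights_uniform_when_uninformative(self, rng):
        ens = ParticleEnsemble(paths_um=np.zeros((8, 1, 2)),
                               weights=np.full(8, 1 / 8))
        out = particle_filter_update(ens, lambda p: 0.0, transition_sd_um=0.0,
                                     rng=rng)
        assert np.allclose(out.weights, 1 / 8)
        assert np.all(out.paths_um == 0.0)

    def test_weights_always_normalized(self, rng):
        ens = ParticleEnsemble(paths_um=np.zeros((16, 1, 2)),
                               weights=np.full(16, 1 / 16))
        for k in range(30):
            ens = particle_filter_update(
                ens, lambda p: float(-0.5 * np.sum(p[-1] ** 2) / 100.0),
                transition_sd_um=3.0, rng=rng,
            )
            assert np.isclose(ens.weights.sum(), 1.0, atol=1e-12)
            assert np.all(ens.weights >= 0)

    def test_default_n_particles_is_ten(self):
        assert JointEMConfig().n_particles == 10

    def test_all_underflow_raises(self, rng):
        ens = ParticleEnsemble(paths_um=np.zeros((4, 1, 2)),
                               weights=np.full(4, 0.25))
        with pytest.raises(RuntimeError):
            particle_filter_update(ens, lambda p: float("-inf"),
                                   transition_sd_um=1.0, rng=rng)

    def test_systematic_resample_unbiased(self, rng):
        w = np.array([0.5, 0.3, 0.1, 0.1])
        counts = np.zeros(4)
        for _ in range(500):
            idx = systematic_resample(w, rng)
            counts += np.bincount(idx, minlength=4)
        freq = counts / counts.sum()
        assert np.allclose(freq, w, atol=0.02)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ParticleEnsemble(paths_um=np.zeros((2, 1, 2)),
                             weights=np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            ParticleEnsemble(paths_um=np.zeros((2, 1, 2)),
                             weights=np.array([1.5, -0.5]))

    def test_tracks_kalman_filter_1d(self):
        # linear-Gaussian surrogate: Brownian position observed with Gaussian
        # noise; the PF posterior mean must match the Kalman filter
        q, r = 4.0, 9.0
        n_steps = 25
        rng = np.random.default_rng(11)
        x_true = np.cumsum(rng.normal(scale=np.sqrt(q), size=n_steps))
        obs = x_true + rng.normal(scale=np.sqrt(r), size=n_steps)
        # Kalman oracle
        m, P = 0.0, 0.0
        kalman_means = []
        for t in range(n_steps):
            P = P + q
            K = P / (P + r)
            m = m + K * (obs[t] - m)
            P = (1 - K) * P
            kalman_means.append(m)
        # particle filter (2D machinery, y-axis unused)
        n_p = 1000
        ens = ParticleEnsemble(paths_um=np.zeros((n_p, 1, 2)),
                               weights=np.full(n_p, 1 / n_p))
        pf_rng = np.random.default_rng(12)
        for t in range(n_steps):
            obs_t = obs[t]
            ens = particle_filter_update(
                ens,
                lambda p, o=obs_t: float(-0.5 * (o - p[-1, 0]) ** 2 / r),
                transition_sd_um=np.sqrt(q), rng=pf_rng,
            )
            pf_mean = float(np.sum(ens.weights * ens.paths_um[:, -1, 0]))
            # Monte-Carlo standard error of the weighted mean
            ess = ens.effective_sample_size()
            spread = np.sqrt(np.sum(
                ens.weights * (ens.paths_um[:, -1, 0] - pf_mean) ** 2
            ))
            se = spread / np.sqrt(ess)
            assert abs(pf_mean - kalman_means[t]) < 3 * max(se, 0.15)


class TestJointEM:
    def test_smoke_and_invariants(self, small_encoder):
        img = generate_texture_image(44, SIZE, SIZE)
        traj = simulate_drift_trajectory(24, 10.0, seed=7)
        movie = render_jittered_trial(img, traj)
        spikes = simulate_spikes(small_encoder, movie, seed=9)
        prior = OneOverFPrior(shape=(SIZE, SIZE), lambda_weight=1.0)
        cfg = JointEMConfig(n_particles=4, init_iters=4, encoding_max_iter=20,
                            seed=0)
        res = reconstruct_joint_em(spikes, small_encoder, prior,
                                   RhoSchedule(0.1, 10.0, 4), cfg,
                                   image_shape=(SIZE, SIZE), n_frames=24)
        assert res.image.shape == (SIZE, SIZE)
        assert np.all(np.isfinite(res.image))
        assert res.ensemble.n_particles == 4
        assert np.isclose(res.ensemble.weights.sum(), 1.0, atol=1e-12)
        assert res.trajectory_um.shape == (24, 2)
        assert np.all(res.trajectory_um[0] == 0.0)


class TestNoiselessLinear:
    def _setup(self, rng, n_cells=30, size=12):
        # random localized unit-norm projection filters
        M = np.zeros((size * size, n_cells))
        for j in range(n_cells):
            m = np.zeros((size, size))
            r, c = rng.integers(1, size - 1, size=2)
            m[r - 1 : r + 2, c - 1 : c + 2] = rng.normal(size=(3, 3))
            M[:, j] = m.ravel() / np.linalg.norm(m)
        return M

    def test_projection_identity_and_exact_solution(self, rng):
        M = self._setup(rng)
        size = 12
        # truth inside span(M): the prior-free loop must reproduce it exactly
        coef = rng.normal(size=M.shape[1])
        y_true = M @ np.linalg.solve(M.T @ M, coef)
        s = M.T @ y_true
        prior = OneOverFPrior(shape=(size, size), lambda_weight=0.0)
        res = reconstruct_noiseless_linear(s, M, prior,
                                           image_shape=(size, size))
        assert np.linalg.norm(M.T @ res.image.ravel() - s, np.inf) < 1e-8
        # in-span components recovered exactly
        proj = M @ np.linalg.solve(M.T @ M, M.T @ res.image.ravel())
        assert np.allclose(proj, y_true, atol=1e-8)

    def test_projection_idempotent(self, rng):
        M = self._setup(rng)
        gram_chol = np.linalg.cholesky(M.T @ M)

        def project(z, s):
            rhs = np.linalg.solve(gram_chol.T, np.linalg.solve(gram_chol,
                                                               M.T @ z - s))
            return z - M @ rhs

        z = rng.random(144)
        s = rng.normal(size=M.shape[1])
        p1 = project(z, s)
        p2 = project(p1, s)
        assert np.allclose(p1, p2, atol=1e-10)

    def test_matches_kkt_oracle(self, rng):
        M = self._setup(rng)
        s = rng.normal(size=M.shape[1])
        z = rng.random(144)
        # KKT oracle: solve [[I, M], [M^T, 0]] [x; nu] = [z; s]
        n, k = M.shape
        kkt = np.block([[np.eye(n), M], [M.T, np.zeros((k, k))]])
        sol = np.linalg.solve(kkt, np.concatenate([z, s]))
        x_oracle = sol[:n]
        x = z - M @ np.linalg.solve(M.T @ M, M.T @ z - s)
        assert np.max(np.abs(x - x_oracle)) < 1e-8

    def test_singular_gram_rejected(self, rng):
        M = np.zeros((64, 3))
        M[:, 0] = rng.random(64)
        M[:, 1] = M[:, 0]  # duplicate cell -> singular Gram matrix
        M[:, 2] = rng.random(64)
        prior = OneOverFPrior(shape=(8, 8), lambda_weight=0.0)
        with pytest.raises(np.linalg.LinAlgError):
            reconstruct_noiseless_linear(rng.normal(size=3), M, prior,
                                         image_shape=(8, 8))

    def test_final_constraint_residual_with_prior(self, rng):
        M = self._setup(rng)
        size = 12
        y_true = rng.random(size * size)
        s = M.T @ y_true
        prior = OneOverFPrior(shape=(size, size), lambda_weight=1.0)
        res = reconstruct_noiseless_linear(s, M, prior,
                                           image_shape=(size, size))
        assert np.linalg.norm(M.T @ res.image.ravel() - s, np.inf) < 1e-8
        assert not np.any(np.isnan(res.image))
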