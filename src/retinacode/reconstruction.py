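"""MAP image reconstruction from RGC spike trains.

Implements the four estimators:

* plug-and-play half-quadratic splitting for flashed images (alternating an
  encoding sub-problem with a prior/denoiser step along an increasing rho
  schedule),
* exact MAP under the 1/F Gaussian prior by first-order descent,
* the known-eye-movement variant (same loop, likelihood composed with the
  per-frame shifts), and
* joint image / eye-trajectory estimation by particle-filter EM, plus
* the noiseless linear-constrained reconstruction with its closed-form
  projection step.

The Bernoulli likelihood is linear in the image given the frame timing and
trajectory, which makes every encoding sub-problem an unconstrained convex
minimization solved here with L-BFGS and an analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.signal import fftconvolve

from .encoding_models import (
    PopulationEncoder,
    SpikeTrainSet,
    frame_of_bin,
    sigmoid,
    softplus,
    temporal_mixing_matrix,
)
from .priors import RhoSchedule, prior_step
from .synthetic_stimulus import shift_image

__all__ = [
    "ReconstructionResult",
    "ParticleEnsemble",
    "JointEMConfig",
    "ImageLikelihood",
    "MixtureLikelihood",
    "encoding_step",
    "reconstruct_flashed_map",
    "reconstruct_1f_exact",
    "gradient_descent_map",
    "reconstruct_known_em",
    "reconstruct_joint_em",
    "reconstruct_noiseless_linear",
    "particle_filter_update",
    "systematic_resample",
]


@dataclass
class ReconstructionResult:
    """Estimated image plus per-iteration diagnostics."""

    image: np.ndarray
    trace: list[float] = field(default_factory=list)
    trajectory_um: np.ndarray | None = None
    ensemble: "ParticleEnsemble | None" = None
    config: dict = field(default_factory=dict)

    @property
    def image_clipped(self) -> np.ndarray:
        return np.clip(self.image, 0.0, 1.0)


# --------------------------------------------------------------------------
# likelihood operator

class LikelihoodContext:
    """Trajectory-independent caches shared across likelihood operators.

    The history drive (feedback + coupling + bias) and the temporal mixing
    matrices depend only on the encoder and the recorded spikes, so the joint
    EM loop — which builds one likelihood per particle per image update —
    computes them once here.
    """

    def __init__(self, encoder: PopulationEncoder, spikes: SpikeTrainSet,
                 n_frames: int, frame_period_ms: float):
        n_bins = spikes.n_bins
        ncells = encoder.n_cells
        self.offset_full = np.empty((n_bins, ncells))
        for i, cell in enumerate(encoder.cells):
            self.offset_full[:, i] = (
                _history_drive_full(cell, spikes, encoder) + cell.bias
            )
        self.fob = frame_of_bin(n_bins, frame_period_ms, n_frames)
        self.groups = _kernel_groups(encoder)
        self.B_full = {
            key: temporal_mixing_matrix(kernel, self.fob, n_frames).tocsr()
            for key, (_idx, kernel) in self.groups.items()
        }
        self.cell_entries = _entry_arrays(encoder)


class ImageLikelihood:
    """Bernoulli spike NLL as a function of the (flattened) image.

    ``frame_shifts`` gives the integer (dy, dx) image translation shown on
    each display frame; entries may be masked off with ``frame_shows_image``
    (False = uniform background frame, e.g. the gray period after a flash).
    The likelihood is evaluated over bins ``bin_window = (t0, t1)``.
    """

    def __init__(
        self,
        encoder: PopulationEncoder,
        spikes: SpikeTrainSet,
        image_shape: tuple[int, int],
        n_frames: int,
        frame_period_ms: float,
        frame_shifts: np.ndarray | None = None,
        frame_shows_image: np.ndarray | None = None,
        background: float = 0.5,
        bin_window: tuple[int, int] | None = None,
        context: LikelihoodContext | None = None,
    ):
        self.encoder = encoder
        self.spikes = spikes
        self.image_shape = tuple(image_shape)
        self.frame_period_ms = frame_period_ms
        self.background = background
        n_bins = spikes.n_bins
        self.bin_window = bin_window or (0, n_bins)
        t0, t1 = self.bin_window
        if not (0 <= t0 < t1 <= n_bins):
            raise ValueError("bin_window outside the recorded spikes")
        if context is None:
            context = LikelihoodContext(encoder, spikes, n_frames, frame_period_ms)
        else:
            n_frames = max(n_frames, len(context.fob) and int(context.fob[-1]) + 1)
        self.n_frames = n_frames
        if frame_shifts is None:
            frame_shifts = np.zeros((n_frames, 2), dtype=int)
        frame_shifts = np.asarray(frame_shifts, dtype=int)
        if frame_shows_image is None:
            frame_shows_image = np.ones(len(frame_shifts), dtype=bool)
        frame_shows_image = np.asarray(frame_shows_image, dtype=bool)
        # trajectory prefixes shorter than the trial: later frames carry no
        # information about the window's bins and are treated as background
        if len(frame_shifts) < n_frames:
            pad = n_frames - len(frame_shifts)
            frame_shifts = np.vstack([frame_shifts, np.zeros((pad, 2), dtype=int)])
            frame_shows_image = np.concatenate(
                [frame_shows_image, np.zeros(pad, dtype=bool)]
            )
        elif len(frame_shifts) > n_frames:
            raise ValueError("frame_shifts longer than the frame count")
        self.frame_shifts = frame_shifts
        self.frame_shows_image = frame_shows_image

        self.s = spikes.binned[:, t0:t1].T.astype(float)  # (Twin, N)
        self.fob = context.fob
        self.offset = context.offset_full[t0:t1]

        # stacked shifted-filter matrix A: row (f * N + i) -> pixels
        self.A = _stacked_filter_matrix(
            encoder, image_shape, frame_shifts, frame_shows_image,
            cell_entries=context.cell_entries,
        )

        # temporal mixing per cell group, restricted to the bin window
        self.groups = context.groups
        self.B = {key: Bf[t0:t1] for key, Bf in context.B_full.items()}

    # -- internals ---------------------------------------------------------

    def _projections(self, y: np.ndarray) -> np.ndarray:
        """P[f, i] = <shifted filter, y - bg>; background frames give 0."""
        yc = (y.reshape(self.image_shape) - self.background).ravel()
        ncells = self.encoder.n_cells
        return (self.A @ yc).reshape(self.n_frames, ncells)

    def _drive(self, P: np.ndarray) -> np.ndarray:
        g = np.empty_like(self.offset)
        for key, (idx, _k) in self.groups.items():
            g[:, idx] = self.B[key] @ P[:, idx]
        return g + self.offset

    def nll_and_grad(self, y: np.ndarray) -> tuple[float, np.ndarray]:
        P = self._projections(y)
        g = self._drive(P)
        val = float(np.sum(softplus(g) - self.s * g))
        r = sigmoid(g) - self.s  # (Twin, N)
        Q = np.empty_like(P)
        for key, (idx, _k) in self.groups.items():
            Q[:, idx] = self.B[key].T @ r[:, idx]
        grad = self.A.T @ Q.ravel()
        return val, grad

    def nll(self, y: np.ndarray) -> float:
        return self.nll_and_grad(y)[0]


def _history_drive_full(cell, spikes, encoder) -> np.ndarray:
    n_bins = spikes.n_bins
    kern = np.concatenate([[0.0], cell.feedback_kernel])
    h = fftconvolve(spikes.binned[encoder.index_of(cell.cell_id)].astype(float),
                    kern)[:n_bins]
    for j, ck in cell.coupling_kernels.items():
        kern = np.concatenate([[0.0], ck])
        h += fftconvolve(spikes.binned[encoder.index_of(j)].astype(float),
                         kern)[:n_bins]
    return h


def _kernel_groups(encoder: PopulationEncoder) -> dict:
    groups: dict = {}
    for i, cell in enumerate(encoder.cells):
        key = cell.temporal_kernel.tobytes()
        groups.setdefault(key, ([], cell.temporal_kernel))[0].append(i)
    return {k: (np.array(idx), kern) for k, (idx, kern) in groups.items()}


def _entry_arrays(encoder) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All cells' filter entries stacked: (row pix, col pix, value, cell index).

    Entries below 5e-4 of each filter's peak are dropped (the DoG tails are
    numerically irrelevant but inflate the sparse operators).
    """
    rr_all, cc_all, vv_all, ci_all = [], [], [], []
    for i, cell in enumerate(encoder.cells):
        r0, c0 = cell.crop_origin
        h, w = cell.spatial_map.shape
        rr, cc = np.meshgrid(np.arange(r0, r0 + h), np.arange(c0, c0 + w),
                             indexing="ij")
        vv = cell.spatial_map.ravel()
        keep = np.abs(vv) > 5e-4 * np.abs(vv).max()
        rr_all.append(rr.ravel()[keep])
        cc_all.append(cc.ravel()[keep])
        vv_all.append(vv[keep])
        ci_all.append(np.full(keep.sum(), i, dtype=np.int64))
    return (np.concatenate(rr_all), np.concatenate(cc_all),
            np.concatenate(vv_all), np.concatenate(ci_all))


def _stacked_filter_matrix(encoder, image_shape, frame_shifts, shows_image,
                           cell_entries=None):
    """Sparse (F * N, H * W): row f*N+i holds cell i's filter shifted by
    -frame_shift[f], rows empty for background frames or out-of-bounds pixels."""
    H, W = image_shape
    N = encoder.n_cells
    F = len(frame_shifts)
    if cell_entries is None:
        cell_entries = _entry_arrays(encoder)
    rr, cc, vv, ci = cell_entries
    shown = np.nonzero(np.asarray(shows_image, dtype=bool))[0]
    if len(shown) == 0:
        return sp.csr_matrix((F * N, H * W))
    dy = frame_shifts[shown, 0][:, None]
    dx = frame_shifts[shown, 1][:, None]
    r = rr[None, :] - dy
    c = cc[None, :] - dx
    ok = (r >= 0) & (r < H) & (c >= 0) & (c < W)
    rows = (shown[:, None] * N + ci[None, :])[ok]
    cols = (r * W + c)[ok]
    vals = np.broadcast_to(vv, ok.shape)[ok]
    return sp.coo_matrix((vals, (rows, cols)), shape=(F * N, H * W)).tocsr()


class MixtureLikelihood:
    """Weighted sum of likelihood operators (expectation over trajectories)."""

    def __init__(self, components: list[tuple[float, ImageLikelihood]]):
        if not components:
            raise ValueError("mixture needs at least one component")
        self.components = components
        self.image_shape = components[0][1].image_shape

    def nll_and_grad(self, y: np.ndarray) -> tuple[float, np.ndarray]:
        val = 0.0
        grad = np.zeros(int(np.prod(self.image_shape)))
        for w, lik in self.components:
            if w <= 0:
                continue
            v, g = lik.nll_and_grad(y)
            val += w * v
            grad += w * g
        return val, grad

    def nll(self, y: np.ndarray) -> float:
        return self.nll_and_grad(y)[0]


# --------------------------------------------------------------------------
# encoding sub-problem

def encoding_step(
    likelihood,
    z: np.ndarray,
    rho: float,
    x0: np.ndarray | None = None,
    max_iter: int = 200,
    grad_tol: float = 1e-6,
) -> np.ndarray:
    """x = argmin  NLL(x) + rho/2 ||x - z||^2  (L-BFGS, analytic gradient)."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    z_flat = np.asarray(z, dtype=float).ravel()
    x_start = z_flat if x0 is None else np.asarray(x0, dtype=float).ravel()

    def fun(x):
        v, g = likelihood.nll_and_grad(x)
        d = x - z_flat
        return v + 0.5 * rho * (d @ d), g + rho * d

    res = minimize(fun, x_start, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": grad_tol,
                            "ftol": 1e-14})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(
            f"encoding step diverged (final gradient norm "
            f"{np.linalg.norm(res.jac):.3g})"
        )
    # the solver starts at z (or x0); keep whichever is better
    if fun(res.x)[0] <= fun(x_start)[0]:
        out = res.x
    else:  # pragma: no cover - L-BFGS safeguard
        out = x_start
    return out.reshape(np.shape(z))


# --------------------------------------------------------------------------
# plug-and-play loops

def _pnp_loop(likelihood, prior, schedule: RhoSchedule, z0: np.ndarray,
              max_iter: int = 200) -> tuple[np.ndarray, list[float]]:
    z = np.asarray(z0, dtype=float)
    trace = []
    for rho in schedule.values:
        x = encoding_step(likelihood, z, rho, max_iter=max_iter)
        z = np.asarray(prior_step(prior, x, rho))
        trace.append(likelihood.nll(z.ravel()))
    return z, trace


def reconstruct_flashed_map(
    spikes: SpikeTrainSet,
    encoder: PopulationEncoder,
    prior,
    schedule: RhoSchedule | None = None,
    image_shape: tuple[int, int] = (32, 32),
    flash_ms: float = 100.0,
    frame_period_ms: float = 1000.0 / 120.0,
    window_ms: float = 150.0,
    background: float = 0.5,
    init: np.ndarray | None = None,
    encoding_max_iter: int = 100,
) -> ReconstructionResult:
    """Plug-and-play MAP reconstruction of a flashed image.

    The likelihood covers ``window_ms`` from flash onset; display frames after
    the flash are modeled as the uniform gray screen.
    """
    schedule = schedule or RhoSchedule()
    n_bins = spikes.n_bins
    t1 = min(int(round(window_ms)), n_bins)
    n_frames = int(np.ceil(n_bins / frame_period_ms))
    n_flash = int(round(flash_ms / frame_period_ms))
    shows = np.arange(n_frames) < n_flash
    lik = ImageLikelihood(
        encoder, spikes, image_shape, n_frames, frame_period_ms,
        frame_shows_image=shows, background=background, bin_window=(0, t1),
    )
    z0 = np.full(image_shape, background) if init is None else init
    z, trace = _pnp_loop(lik, prior, schedule, z0, max_iter=encoding_max_iter)
    return ReconstructionResult(image=z, trace=trace,
                                config={"mode": "flash", "window_ms": window_ms})


def reconstruct_known_em(
    spikes: SpikeTrainSet,
    encoder: PopulationEncoder,
    prior,
    trajectory,
    schedule: RhoSchedule | None = None,
    image_shape: tuple[int, int] = (32, 32),
    frame_period_ms: float = 1000.0 / 120.0,
    background: float = 0.5,
    init: np.ndarray | None = None,
    encoding_max_iter: int = 100,
) -> ReconstructionResult:
    """Plug-and-play MAP with the eye trajectory known a priori.

    ``trajectory`` is an EyeTrajectory or an (F, 2) integer pixel-shift array.
    A zero trajectory reduces exactly to the flashed-style reconstruction.
    """
    schedule = schedule or RhoSchedule()
    shifts = getattr(trajectory, "displacements_px", trajectory)
    shifts = np.asarray(shifts, dtype=int)
    n_frames = shifts.shape[0]
    n_bins = spikes.n_bins
    expected = int(round(n_frames * frame_period_ms))
    if abs(expected - n_bins) > frame_period_ms:
        raise ValueError(
            f"trajectory ({n_frames} frames ~ {expected} ms) does not match "
            f"the spike train length ({n_bins} ms)"
        )
    lik = ImageLikelihood(
        encoder, spikes, image_shape, n_frames, frame_period_ms,
        frame_shifts=shifts, background=background,
        bin_window=(0, min(expected, n_bins)),
    )
    z0 = np.full(image_shape, background) if init is None else init
    z, trace = _pnp_loop(lik, prior, schedule, z0, max_iter=encoding_max_iter)
    return ReconstructionResult(image=z, trace=trace, config={"mode": "known"})


def reconstruct_1f_exact(
    spikes: SpikeTrainSet,
    encoder: PopulationEncoder,
    prior,
    trajectory=None,
    image_shape: tuple[int, int] = (32, 32),
    frame_period_ms: float = 1000.0 / 120.0,
    flash_ms: float | None = 100.0,
    window_ms: float | None = 150.0,
    background: float = 0.5,
    max_iter: int = 500,
    grad_tol: float = 1e-5,
) -> ReconstructionResult:
    """Exact MAP under a smooth Gaussian (e.g. 1/F) prior by gradient descent.

    The objective NLL(y) + prior(y) is smooth and convex; plain descent with
    Armijo backtracking gives a strictly nonincreasing objective trace.
    """
    n_bins = spikes.n_bins
    if trajectory is not None:
        shifts = np.asarray(getattr(trajectory, "displacements_px", trajectory),
                            dtype=int)
        n_frames = shifts.shape[0]
        lik = ImageLikelihood(encoder, spikes, image_shape, n_frames,
                              frame_period_ms, frame_shifts=shifts,
                              background=background)
    else:
        t1 = n_bins if window_ms is None else min(int(round(window_ms)), n_bins)
        n_frames = int(np.ceil(n_bins / frame_period_ms))
        n_flash = n_frames if flash_ms is None else int(round(flash_ms / frame_period_ms))
        shows = np.arange(n_frames) < n_flash
        lik = ImageLikelihood(encoder, spikes, image_shape, n_frames,
                              frame_period_ms, frame_shows_image=shows,
                              background=background, bin_window=(0, t1))

    y, trace = gradient_descent_map(lik, prior, image_shape,
                                    init=np.full(image_shape, background),
                                    max_iter=max_iter, grad_tol=grad_tol)
    return ReconstructionResult(image=y, trace=trace,
                                config={"mode": "1f_exact"})


def gradient_descent_map(
    likelihood,
    prior,
    image_shape: tuple[int, int],
    init: np.ndarray | None = None,
    max_iter: int = 500,
    grad_tol: float = 1e-5,
) -> tuple[np.ndarray, list[float]]:
    """First-order descent on NLL + prior with Armijo backtracking.

    Works for any smooth likelihood exposing ``nll_and_grad``; the objective
    trace is strictly nonincreasing.
    """
    y = (np.full(int(np.prod(image_shape)), 0.5) if init is None
         else np.asarray(init, dtype=float).ravel().copy())

    def f_and_g(yv):
        v1, g1 = likelihood.nll_and_grad(yv)
        v2, g2 = prior.value_and_grad(yv.reshape(image_shape))
        return v1 + v2, g1 + g2.ravel()

    val, grad = f_and_g(y)
    trace = [val]
    step = 1.0
    for _ in range(max_iter):
        gnorm = np.linalg.norm(grad)
        if gnorm < grad_tol:
            break
        # Armijo backtracking
        for _bt in range(60):
            y_new = y - step * grad
            v_new, g_new = f_and_g(y_new)
            if np.isfinite(v_new) and v_new <= val - 1e-4 * step * gnorm**2:
                break
            step *= 0.5
        else:  # pragma: no cover
            break
        y, val, grad = y_new, v_new, g_new
        trace.append(val)
        step *= 1.5
    return y.reshape(image_shape), trace


# --------------------------------------------------------------------------
# particle filter

@dataclass
class ParticleEnsemble:
    """Weighted trajectory prefixes representing q(w | s, y)."""

    paths_um: np.ndarray  # (N, F_so_far, 2)
    weights: np.ndarray  # (N,), nonnegative, sums to 1

    def __post_init__(self) -> None:
        self.paths_um = np.asarray(self.paths_um, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("particle weights must be nonnegative")
        s = self.weights.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError("particle weights must sum to 1")

    @property
    def n_particles(self) -> int:
        return self.paths_um.shape[0]

    @property
    def n_frames(self) -> int:
        return self.paths_um.shape[1]

    def posterior_mean_um(self) -> np.ndarray:
        return np.einsum("p,pfd->fd", self.weights, self.paths_um)

    def effective_sample_size(self) -> float:
        return 1.0 / float(np.sum(self.weights**2))


def systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Systematic resampling: indices drawn with a single uniform offset."""
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def particle_filter_update(
    ensemble: ParticleEnsemble,
    log_likelihood,
    transition_sd_um: float,
    rng: np.random.Generator,
    resample_threshold: float = 0.5,
) -> ParticleEnsemble:
    """One sequential-importance-resampling step.

    Each particle is extended by a draw from the 2D Gaussian Brownian
    transition (per-axis sd ``transition_sd_um``), reweighted by
    ``log_likelihood(extended_path) `` (log-domain, max-subtracted), and the
    ensemble is resampled systematically when the effective sample size drops
    below ``resample_threshold * N``.
    """
    n, f, _ = ensemble.paths_um.shape
    steps = rng.normal(scale=transition_sd_um, size=(n, 1, 2))
    new_paths = np.concatenate([ensemble.paths_um,
                                ensemble.paths_um[:, -1:, :] + steps], axis=1)
    loglik = np.array([log_likelihood(new_paths[p]) for p in range(n)])
    if np.all(~np.isfinite(loglik)):
        raise RuntimeError("particle filter: all particle likelihoods underflowed")
    logw = np.log(np.maximum(ensemble.weights, 1e-300)) + loglik
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    ens = ParticleEnsemble(paths_um=new_paths, weights=w)
    if ens.effective_sample_size() < resample_threshold * n:
        idx = systematic_resample(w, rng)
        ens = ParticleEnsemble(paths_um=new_paths[idx],
                               weights=np.full(n, 1.0 / n))
    return ens


# --------------------------------------------------------------------------
# joint EM

@dataclass
class JointEMConfig:
    n_particles: int = 10
    image_update_every: int = 5  # display frame transitions per image update
    init_iters: int = 10
    resample_threshold: float = 0.5
    encoding_max_iter: int = 40
    seed: int = 0


class _FrameLikelihood:
    """Incremental per-frame spike likelihood used by the particle filter."""

    def __init__(self, encoder, spikes, image_shape, n_frames, frame_period_ms,
                 background, context: LikelihoodContext | None = None):
        self.encoder = encoder
        self.spikes = spikes
        self.image_shape = image_shape
        self.n_frames = n_frames
        self.frame_period_ms = frame_period_ms
        self.background = background
        if context is None:
            context = LikelihoodContext(encoder, spikes, n_frames, frame_period_ms)
        self.fob = context.fob
        self.offset = context.offset_full
        self.s = spikes.binned.T.astype(float)
        # static (unshifted) filter matrix; image is shifted instead
        self.M = _stacked_filter_matrix(
            encoder, image_shape, np.zeros((1, 2), dtype=int),
            np.ones(1, dtype=bool), cell_entries=context.cell_entries,
        )
        self.groups = context.groups
        self.max_lag = max(len(k) for _, k in self.groups.values())
        self._y_contrast = None

    def set_image(self, y: np.ndarray) -> None:
        self._y = np.asarray(y, dtype=float).reshape(self.image_shape)

    def projections_for(self, shift_px: np.ndarray) -> np.ndarray:
        """P[i] = <filter_i, shift(y, w) - bg> for one frame shift."""
        ys = shift_image(self._y, int(shift_px[0]), int(shift_px[1]),
                         self.background)
        return self.M @ (ys - self.background).ravel()

    def frame_bins(self, f: int) -> np.ndarray:
        return np.nonzero(self.fob == f)[0]

    def loglik_bins(self, P_hist: np.ndarray, bins: np.ndarray) -> float:
        """log p(spikes in `bins`) given per-frame projections so far."""
        lags = np.arange(1, self.max_lag + 1)
        tb = bins[:, None] - lags[None, :]
        valid = tb >= 0
        fidx = self.fob[np.clip(tb, 0, None)]
        g = self.offset[bins].copy()
        for _key, (idx, kernel) in self.groups.items():
            k = np.zeros(self.max_lag)
            k[: len(kernel)] = kernel
            pv = P_hist[fidx][:, :, idx] * valid[:, :, None]
            g[:, idx] += np.einsum("l,bli->bi", k, pv)
        s = self.s[bins]
        return -float(np.sum(softplus(g) - s * g))


def reconstruct_joint_em(
    spikes: SpikeTrainSet,
    encoder: PopulationEncoder,
    prior,
    schedule: RhoSchedule | None = None,
    em_config: JointEMConfig | None = None,
    image_shape: tuple[int, int] = (32, 32),
    n_frames: int = 60,
    frame_period_ms: float = 1000.0 / 120.0,
    diffusion_um2_per_frame: float = 10.0,
    pixel_pitch_um: float = 11.0,
    background: float = 0.5,
) -> ReconstructionResult:
    """Joint MAP estimation of the image and the unknown drift trajectory.

    The image is initialized by ten plug-and-play iterations assuming a fixed
    eye position at the origin; a sequential-importance-resampling particle
    filter then tracks the trajectory posterior, and the image is re-estimated
    (one encoding step on the particle-weighted expected NLL, one prior step)
    once every ``image_update_every`` display frame transitions.
    """
    schedule = schedule or RhoSchedule()
    cfg = em_config or JointEMConfig()
    rng = np.random.default_rng(cfg.seed)
    transition_sd_um = float(np.sqrt(2.0 * diffusion_um2_per_frame))

    # ---- initialization at zero trajectory
    context = LikelihoodContext(encoder, spikes, n_frames, frame_period_ms)
    init_sched = RhoSchedule(schedule.rho_start, schedule.rho_end, cfg.init_iters)
    zero_lik = ImageLikelihood(
        encoder, spikes, image_shape, n_frames, frame_period_ms,
        background=background, context=context,
    )
    y, init_trace = _pnp_loop(zero_lik, prior, init_sched,
                              np.full(image_shape, background),
                              max_iter=cfg.encoding_max_iter)

    fl = _FrameLikelihood(encoder, spikes, image_shape, n_frames,
                          frame_period_ms, background, context=context)
    fl.set_image(y)

    n_p = cfg.n_particles
    ensemble = ParticleEnsemble(paths_um=np.zeros((n_p, 1, 2)),
                                weights=np.full(n_p, 1.0 / n_p))
    P_hist = np.repeat(fl.projections_for(np.zeros(2))[None, None, :], n_p, axis=0)

    n_updates = max(1, (n_frames - 1) // cfg.image_update_every)
    rho_values = np.geomspace(schedule.rho_start, schedule.rho_end, n_updates)
    trace = list(init_trace)
    update_count = 0

    def _paths_to_px(paths):
        return np.sign(paths) * np.ceil(np.abs(paths) / pixel_pitch_um - 0.5)

    for f in range(1, n_frames):
        bins = fl.frame_bins(f)
        # SIR update with incremental per-particle projection history
        steps = rng.normal(scale=transition_sd_um, size=(n_p, 2))
        new_paths = np.concatenate(
            [ensemble.paths_um, ensemble.paths_um[:, -1:, :] + steps[:, None, :]],
            axis=1,
        )
        P_new = np.stack([
            fl.projections_for(_paths_to_px(new_paths[p, -1]))
            for p in range(n_p)
        ])
        P_hist = np.concatenate([P_hist, P_new[:, None, :]], axis=1)
        loglik_vals = np.array([
            fl.loglik_bins(P_hist[p], bins) for p in range(n_p)
        ])
        logw = np.log(np.maximum(ensemble.weights, 1e-300)) + loglik_vals
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        ensemble = ParticleEnsemble(paths_um=new_paths, weights=w)
        if ensemble.effective_sample_size() < cfg.resample_threshold * n_p:
            idx = systematic_resample(w, rng)
            ensemble = ParticleEnsemble(paths_um=new_paths[idx],
                                        weights=np.full(n_p, 1.0 / n_p))
            P_hist = P_hist[idx]

        if f % cfg.image_update_every == 0 or f == n_frames - 1:
            rho = rho_values[min(update_count, n_updates - 1)]
            update_count += 1
            t_end = int(min(round((f + 1) * frame_period_ms), spikes.n_bins))
            # merge particles whose rounded-pixel paths coincide (common
            # after resampling) so the expectation has fewer components
            merged: dict[bytes, list] = {}
            for p in range(n_p):
                if ensemble.weights[p] <= 1e-6:
                    continue
                shifts = _paths_to_px(ensemble.paths_um[p]).astype(int)
                key = shifts.tobytes()
                if key in merged:
                    merged[key][0] += float(ensemble.weights[p])
                else:
                    merged[key] = [float(ensemble.weights[p]), shifts]
            comps = [
                (wt, ImageLikelihood(
                    encoder, spikes, image_shape, f + 1, frame_period_ms,
                    frame_shifts=shifts, background=background,
                    bin_window=(0, t_end), context=context,
                ))
                for wt, shifts in merged.values()
            ]
            mix = MixtureLikelihood(comps)
            x = encoding_step(mix, y, rho, max_iter=cfg.encoding_max_iter)
            y = np.asarray(prior_step(prior, x, rho))
            fl.set_image(y)
            # projections depend on the image: refresh particle histories
            for p in range(n_p):
                px = _paths_to_px(ensemble.paths_um[p])
                P_hist[p] = np.stack([
                    fl.projections_for(px[ff]) for ff in range(f + 1)
                ])
            trace.append(mix.nll(y.ravel()))

    return ReconstructionResult(
        image=y,
        trace=trace,
        trajectory_um=ensemble.posterior_mean_um(),
        ensemble=ensemble,
        config={"mode": "joint", "n_particles": n_p,
                "image_update_every": cfg.image_update_every},
    )


# --------------------------------------------------------------------------
# noiseless linear reconstruction

def reconstruct_noiseless_linear(
    s: np.ndarray,
    M: np.ndarray,
    prior,
    schedule: RhoSchedule | None = None,
    image_shape: tuple[int, int] | None = None,
) -> ReconstructionResult:
    """Reconstruction from noiseless linear measurements s = M^T y.

    Alternates the closed-form equality-constrained projection
    ``x = z - M (M^T M)^{-1} (M^T z - s)`` with the prior step; a final
    projection enforces the constraint exactly.
    """
    schedule = schedule or RhoSchedule()
    M = np.asarray(M, dtype=float)
    s = np.asarray(s, dtype=float)
    gram = M.T @ M
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e8:
        deficient = np.nonzero(np.abs(np.linalg.eigvalsh(gram)) < 1e-10)[0]
        raise np.linalg.LinAlgError(
            f"M^T M is singular/ill-conditioned (cond={cond:.3g}); "
            f"deficient directions involve cells {deficient.tolist()}"
        )
    chol = cho_factor(gram)
    if image_shape is None:
        n = int(np.sqrt(M.shape[0]))
        image_shape = (n, n)

    def project(z):
        return z - M @ cho_solve(chol, M.T @ z - s)

    z = np.full(M.shape[0], 0.5)
    trace = []
    for rho in schedule.values:
        x = project(z)
        z = np.asarray(prior_step(prior, x.reshape(image_shape), rho)).ravel()
        trace.append(float(np.linalg.norm(M.T @ z - s, np.inf)))
    y = project(z)
    return ReconstructionResult(image=y.reshape(image_shape), trace=trace,
                                config={"mode": "noiseless"})
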