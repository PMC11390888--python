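"""Bernoulli GLM encoding models of RGC spiking and their fitting machinery.

The coupled model drives each cell's 1 ms Bernoulli spike probability through
a generator signal

    g_i[t] = m_i^T (v[t-1] - bg) + (s_i * f_i)[t-1]
             + sum_j (s_j * c_i^(j))[t-1] + b_i

with a rank-1 (space x time separable) stimulus filter, a spike-history
feedback filter, coupling filters to nearby cells and a bias.  All temporal
filters are strictly causal (support at lags >= 1 ms).  The uncoupled variant
drops the coupling sum; the Poisson benchmark operates on per-frame spike
counts with an exponential nonlinearity.

Fitting alternates two convex sub-problems (spatial side / temporal side),
each solved with FISTA using backtracking, an L1 penalty on the spatial
weights and an L2,1 group penalty on each neighbor's coupling weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.signal import fftconvolve

from .synthetic_stimulus import StimulusMovie

__all__ = [
    "SpikeTrainSet",
    "RaisedCosineBasis",
    "SpatialSplineBasis",
    "BasisSet",
    "LNBRCParams",
    "CellFilters",
    "PopulationEncoder",
    "FitConfig",
    "FitData",
    "raised_cosine_basis",
    "spatial_spline_basis",
    "default_basis_set",
    "fit_cell",
    "select_coupled_neighbors",
    "generator_signal",
    "lnbrc_nll",
    "lnbr_nll",
    "lnp_nll",
    "fit_encoder",
    "grid_search_hyperparams",
    "fraction_psth_variance_explained",
    "sigmoid",
    "softplus",
    "frame_of_bin",
    "bin_count",
    "temporal_mixing_matrix",
]

BIN_MS = 1.0


# --------------------------------------------------------------------------
# numerics

def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)), stable for large |x|."""
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """exp(x) / (1 + exp(x)), computed branchlessly and stably."""
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# --------------------------------------------------------------------------
# spike trains

@dataclass
class SpikeTrainSet:
    """Binary spike indicators, cells x 1 ms time bins."""

    binned: np.ndarray  # (n_cells, n_bins) in {0, 1}
    cell_ids: np.ndarray | None = None
    bin_ms: float = BIN_MS

    def __post_init__(self) -> None:
        arr = np.asarray(self.binned)
        if arr.ndim != 2:
            raise ValueError("binned spikes must be (cells, bins)")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("spike trains must be binary")
        self.binned = arr.astype(np.uint8)
        if self.cell_ids is None:
            self.cell_ids = np.arange(arr.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.binned.shape[0]

    @property
    def n_bins(self) -> int:
        return self.binned.shape[1]

    def to_events(self) -> np.ndarray:
        """Sparse event table: rows of (cell_id, time_ms)."""
        ci, t = np.nonzero(self.binned)
        return np.column_stack([self.cell_ids[ci], t.astype(float) * self.bin_ms])

    @classmethod
    def from_events(
        cls, events: np.ndarray, cell_ids: Sequence[int], n_bins: int
    ) -> "SpikeTrainSet":
        cell_ids = np.asarray(cell_ids)
        binned = np.zeros((len(cell_ids), n_bins), dtype=np.uint8)
        index = {int(c): i for i, c in enumerate(cell_ids)}
        for cid, t_ms in np.asarray(events, dtype=float):
            b = int(t_ms // BIN_MS)
            if 0 <= b < n_bins:
                binned[index[int(cid)], b] = 1
        return cls(binned=binned, cell_ids=cell_ids)


def bin_count(movie: StimulusMovie) -> int:
    """Number of 1 ms bins spanned by a movie."""
    return int(round(movie.n_frames * movie.frame_period_ms / BIN_MS))


def frame_of_bin(n_bins: int, frame_period_ms: float, n_frames: int) -> np.ndarray:
    """Display frame index shown during each 1 ms bin.

    A bin starting exactly on a frame transition belongs to the new frame
    (epsilon guards the floating-point boundary).
    """
    f = np.floor(np.arange(n_bins) * (BIN_MS / frame_period_ms) + 1e-9).astype(int)
    return np.minimum(f, n_frames - 1)


# --------------------------------------------------------------------------
# bases

@dataclass(frozen=True)
class RaisedCosineBasis:
    """Log-time raised cosine bumps over integer lags 1..n_lags (ms)."""

    funcs: np.ndarray  # (n_funcs, n_lags); funcs[k, j] = basis_k(lag j+1)
    t_min_ms: float
    t_max_ms: float
    log_stretch: float

    @property
    def n_funcs(self) -> int:
        return self.funcs.shape[0]

    @property
    def n_lags(self) -> int:
        return self.funcs.shape[1]

    def realize(self, weights: np.ndarray) -> np.ndarray:
        """Kernel over lags 1..n_lags from basis coefficients."""
        return np.asarray(weights, dtype=float) @ self.funcs


def raised_cosine_basis(
    n_funcs: int, t_min_ms: float, t_max_ms: float, log_stretch: float = 10.0
) -> RaisedCosineBasis:
    """Half-overlapping cosine bumps in phi(t) = log(t + log_stretch).

    The bumps form a partition of unity on the interior of [t_min, t_max]
    (exactly 1 wherever two neighboring bumps overlap fully).
    """
    if n_funcs < 1:
        raise ValueError("n_funcs must be >= 1")
    if not (1 <= t_min_ms < t_max_ms):
        raise ValueError("need 1 <= t_min_ms < t_max_ms")
    phi = lambda t: np.log(t + log_stretch)  # noqa: E731
    lags = np.arange(1, int(np.ceil(t_max_ms)) + 1, dtype=float)
    centers = np.linspace(phi(t_min_ms), phi(t_max_ms), n_funcs)
    width = (centers[1] - centers[0]) if n_funcs > 1 else (
        (phi(t_max_ms) - phi(t_min_ms)) or 1.0
    )
    x = phi(lags)[None, :] - centers[:, None]
    funcs = 0.5 * (1.0 + np.cos(np.clip(x * (np.pi / width), -np.pi, np.pi)))
    funcs[np.abs(x) >= width] = 0.0
    return RaisedCosineBasis(
        funcs=funcs, t_min_ms=t_min_ms, t_max_ms=t_max_ms, log_stretch=log_stretch
    )


@dataclass(frozen=True)
class SpatialSplineBasis:
    """Tensor-product cubic B-spline basis over a rectangular crop window."""

    design: np.ndarray  # (crop_h * crop_w, n_basis)
    crop_shape: tuple[int, int]
    knot_spacing: float

    @property
    def n_basis(self) -> int:
        return self.design.shape[1]

    def realize(self, weights: np.ndarray) -> np.ndarray:
        """Spatial map (crop_h, crop_w) from spline coefficients."""
        return (self.design @ np.asarray(weights, dtype=float)).reshape(self.crop_shape)


def _bspline_1d_design(n: int, spacing: float) -> np.ndarray:
    x = np.arange(n, dtype=float)
    inner = np.arange(0.0, n - 1 + 1e-9, spacing)
    if inner[-1] < n - 1:
        inner = np.append(inner, float(n - 1))
    knots = np.concatenate([[inner[0]] * 3, inner, [inner[-1]] * 3])
    return BSpline.design_matrix(x, knots, 3).toarray()


def spatial_spline_basis(
    crop_shape: tuple[int, int], knot_spacing: float = 2.0
) -> SpatialSplineBasis:
    dh = _bspline_1d_design(crop_shape[0], knot_spacing)
    dw = _bspline_1d_design(crop_shape[1], knot_spacing)
    design = np.einsum("ik,jl->ijkl", dh, dw).reshape(
        crop_shape[0] * crop_shape[1], dh.shape[1] * dw.shape[1]
    )
    return SpatialSplineBasis(
        design=design, crop_shape=crop_shape, knot_spacing=knot_spacing
    )


@dataclass(frozen=True)
class BasisSet:
    """Default temporal/spatial function families used by the models."""

    temporal_stim: RaisedCosineBasis
    feedback: RaisedCosineBasis
    coupling: RaisedCosineBasis
    spline_knot_spacing: float = 2.0
    crop_factor: float = 3.0  # crop half-size = crop_factor * rf radius


def default_basis_set(
    n_temporal: int = 10,
    temporal_span_ms: float = 250.0,
    n_feedback: int = 8,
    feedback_span_ms: float = 100.0,
    n_coupling: int = 4,
    coupling_span_ms: float = 50.0,
    log_stretch: float = 10.0,
    spline_knot_spacing: float = 2.0,
    crop_factor: float = 3.0,
) -> BasisSet:
    return BasisSet(
        temporal_stim=raised_cosine_basis(n_temporal, 1.0, temporal_span_ms, log_stretch),
        feedback=raised_cosine_basis(n_feedback, 1.0, feedback_span_ms, log_stretch),
        coupling=raised_cosine_basis(n_coupling, 1.0, coupling_span_ms, log_stretch),
        spline_knot_spacing=spline_knot_spacing,
        crop_factor=crop_factor,
    )


# --------------------------------------------------------------------------
# parameters

@dataclass
class CellFilters:
    """Realized (pixel / 1 ms) filters for one cell.

    ``spatial_map`` lives on a crop window whose top-left corner in the full
    image is ``crop_origin``; temporal kernels are indexed by lag 1..L ms.
    The stimulus drive uses image contrast (pixel value minus the background
    level), so a uniform gray screen contributes nothing.
    """

    cell_id: int
    spatial_map: np.ndarray  # (crop_h, crop_w)
    crop_origin: tuple[int, int]
    temporal_kernel: np.ndarray  # (L_stim,)
    feedback_kernel: np.ndarray  # (L_fb,)
    coupling_kernels: dict[int, np.ndarray] = field(default_factory=dict)
    bias: float = 0.0

    def spatial_full(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Spatial map embedded in the full image frame (zeros elsewhere)."""
        out = np.zeros(image_shape)
        r0, c0 = self.crop_origin
        h, w = self.spatial_map.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.spatial_map
        return out


@dataclass
class LNBRCParams:
    """Basis-coefficient parameterization of one cell's filters."""

    cell_id: int
    spatial_weights: np.ndarray
    temporal_weights: np.ndarray
    feedback_weights: np.ndarray
    coupling_weights: dict[int, np.ndarray]
    bias: float
    crop_origin: tuple[int, int]
    spatial_basis: SpatialSplineBasis

    def realize(self, bases: BasisSet) -> CellFilters:
        return CellFilters(
            cell_id=self.cell_id,
            spatial_map=self.spatial_basis.realize(self.spatial_weights),
            crop_origin=self.crop_origin,
            temporal_kernel=bases.temporal_stim.realize(self.temporal_weights),
            feedback_kernel=bases.feedback.realize(self.feedback_weights),
            coupling_kernels={
                j: bases.coupling.realize(w) for j, w in self.coupling_weights.items()
            },
            bias=self.bias,
        )


@dataclass
class PopulationEncoder:
    """A mosaic together with per-cell realized filters."""

    cells: list[CellFilters]
    mosaic: object = None  # RGCMosaic; duck-typed to avoid a cyclic import

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.array([c.cell_id for c in self.cells])

    def index_of(self, cell_id: int) -> int:
        return int(np.nonzero(self.cell_ids == cell_id)[0][0])


# --------------------------------------------------------------------------
# neighbor selection

_PARASOL_FACTOR = 2.0
_MIDGET_FACTOR = 2.5


def _median_nn_distance(points: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(points).query(points, k=2)
    return float(np.median(d[:, 1]))


def select_coupled_neighbors(mosaic, cell_index: int) -> np.ndarray:
    """Indices of cells coupled to ``cell_index``.

    A candidate of type T is included when its RF center lies within
    factor(T) x (median nearest-neighbor distance among type-T cells), with
    factor 2 for parasol types and 2.5 for midget types.
    """
    types = np.asarray(mosaic.cell_types)
    centers = np.asarray(mosaic.centers_um, dtype=float)
    me = centers[cell_index]
    keep: list[int] = []
    for t in np.unique(types):
        idx = np.nonzero(types == t)[0]
        if len(idx) < 2:
            warnings.warn(f"cell type {t} has < 2 cells; no coupling to it")
            continue
        factor = _MIDGET_FACTOR if "midget" in str(t) else _PARASOL_FACTOR
        thresh = factor * _median_nn_distance(centers[idx])
        d = np.linalg.norm(centers[idx] - me, axis=1)
        keep.extend(int(j) for j, dj in zip(idx, d) if dj <= thresh and j != cell_index)
    return np.array(sorted(keep), dtype=int)


# --------------------------------------------------------------------------
# generator signal and likelihoods

def _causal_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """(x * k)[t-1]: sum_{tau>=1} k[tau] x[t - tau], same length as x."""
    padded = np.concatenate([[0.0], np.asarray(kernel, dtype=float)])
    return fftconvolve(x.astype(float), padded)[: len(x)]


def stimulus_projections(
    cell: CellFilters, movie: StimulusMovie
) -> np.ndarray:
    """Per-frame inner products of the cell's spatial map with frame contrast."""
    r0, c0 = cell.crop_origin
    h, w = cell.spatial_map.shape
    crops = movie.frames[:, r0 : r0 + h, c0 : c0 + w] - movie.background_level
    return crops.reshape(movie.n_frames, -1) @ cell.spatial_map.ravel()


def stimulus_drive(cell: CellFilters, movie: StimulusMovie, n_bins: int) -> np.ndarray:
    """Strictly causal stimulus contribution to g over 1 ms bins."""
    proj = stimulus_projections(cell, movie)
    fob = frame_of_bin(n_bins, movie.frame_period_ms, movie.n_frames)
    return _causal_convolve(proj[fob], cell.temporal_kernel)


def temporal_mixing_matrix(
    kernel: np.ndarray, frame_index: np.ndarray, n_frames: int
) -> sp.csr_matrix:
    """Sparse B with B[t, f] = sum_{tau>=1, frame_index[t-tau]=f} kernel[tau].

    Maps per-frame stimulus projections to the per-bin causal stimulus drive.
    """
    n_bins = len(frame_index)
    rows, cols, vals = [], [], []
    for tau, k in enumerate(np.asarray(kernel, dtype=float), start=1):
        if k == 0.0 or tau >= n_bins:
            continue
        t = np.arange(tau, n_bins)
        rows.append(t)
        cols.append(frame_index[t - tau])
        vals.append(np.full(len(t), k))
    if not rows:
        return sp.csr_matrix((n_bins, n_frames))
    m = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_bins, n_frames),
    )
    return m.tocsr()


def _history_drive(
    cell: CellFilters, spikes: SpikeTrainSet, encoder: PopulationEncoder,
    include_coupling: bool = True,
) -> np.ndarray:
    g = _causal_convolve(
        spikes.binned[encoder.index_of(cell.cell_id)], cell.feedback_kernel
    )
    if include_coupling:
        for j, ck in cell.coupling_kernels.items():
            g += _causal_convolve(spikes.binned[encoder.index_of(j)], ck)
    return g


def generator_signal(
    encoder: PopulationEncoder,
    movie: StimulusMovie,
    spikes: SpikeTrainSet,
    cell_id: int,
    t_range: tuple[int, int] | None = None,
    include_coupling: bool = True,
) -> np.ndarray:
    """g_i[t] over ``t_range`` (default: the whole trial), strictly causal."""
    n_bins = spikes.n_bins
    cell = encoder.cells[encoder.index_of(cell_id)]
    if t_range is None:
        t_range = (0, n_bins)
    t0, t1 = t_range
    if t0 < 0 or t1 > n_bins:
        raise ValueError("t_range extends outside the available spike history")
    g = stimulus_drive(cell, movie, n_bins)
    g += _history_drive(cell, spikes, encoder, include_coupling)
    g += cell.bias
    return g[t0:t1]


def _bernoulli_nll_series(g: np.ndarray, s: np.ndarray) -> np.ndarray:
    return softplus(g) - s * g


def lnbrc_nll(
    encoder: PopulationEncoder,
    movie: StimulusMovie,
    spikes: SpikeTrainSet,
    cell_id: int,
    t_range: tuple[int, int] | None = None,
) -> float:
    """Coupled-model Bernoulli negative log-likelihood for one cell."""
    g = generator_signal(encoder, movie, spikes, cell_id, t_range)
    t0 = 0 if t_range is None else t_range[0]
    s = spikes.binned[encoder.index_of(cell_id), t0 : t0 + len(g)].astype(float)
    return float(_bernoulli_nll_series(g, s).sum())


def lnbr_nll(
    encoder: PopulationEncoder,
    movie: StimulusMovie,
    spikes: SpikeTrainSet,
    cell_id: int,
    t_range: tuple[int, int] | None = None,
) -> float:
    """Uncoupled-model NLL: identical to the coupled model with no coupling."""
    g = generator_signal(
        encoder, movie, spikes, cell_id, t_range, include_coupling=False
    )
    t0 = 0 if t_range is None else t_range[0]
    s = spikes.binned[encoder.index_of(cell_id), t0 : t0 + len(g)].astype(float)
    return float(_bernoulli_nll_series(g, s).sum())


def lnp_nll(
    cell: CellFilters, movie: StimulusMovie, frame_counts: np.ndarray
) -> float:
    """Poisson benchmark NLL on per-frame counts with exponential nonlinearity.

    g[t] = m^T (v[t] - bg) + b uses the current frame (no temporal filtering).
    """
    counts = np.asarray(frame_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("spike counts must be nonnegative")
    g = stimulus_projections(cell, movie) + cell.bias
    return float(np.sum(np.exp(g) - g * counts))


# --------------------------------------------------------------------------
# fitting

@dataclass
class FitConfig:
    l1_weight: float = 1e-4
    group_l21_weight: float = 1e-3
    alternation_rounds: int = 2
    max_fista_iters: int = 400
    grad_tol: float = 1e-6
    obj_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.l1_weight < 0 or self.group_l21_weight < 0:
            raise ValueError("regularization weights must be >= 0")


@dataclass
class FitData:
    """Everything a fit needs: the movie, the binned spikes and the mosaic."""

    movie: StimulusMovie
    spikes: SpikeTrainSet
    mosaic: object
    bases: BasisSet


def _fista(objective, x0, prox, max_iter=400, grad_tol=1e-6, obj_tol=1e-9):
    """FISTA with backtracking and restart-on-increase.

    ``objective(x)`` returns (smooth value, gradient); ``prox(x, step)``
    applies the proximal map of the nonsmooth part (and returns its value).
    Returns (x, trace of composite objective values).
    """
    x = np.asarray(x0, dtype=float).copy()
    y = x.copy()
    t_mom = 1.0
    L = 1.0
    f_x, _ = objective(x)
    _, pen_x = prox(x, 0.0)
    best = f_x + pen_x
    trace = [best]
    for _ in range(max_iter):
        f_y, g_y = objective(y)
        # backtracking line search on the majorizer at y
        for _bt in range(60):
            x_new, pen_new = prox(y - g_y / L, 1.0 / L)
            d = x_new - y
            f_new, _ = objective(x_new)
            if np.isfinite(f_new) and f_new <= f_y + g_y @ d + 0.5 * L * (d @ d) + 1e-12:
                break
            L *= 2.0
        F_new = f_new + pen_new
        if F_new > best + 1e-12:  # restart momentum
            y = x.copy()
            t_mom = 1.0
            L *= 2.0
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        y = x_new + ((t_mom - 1.0) / t_next) * (x_new - x)
        step = np.linalg.norm(x_new - x)
        x, t_mom = x_new, t_next
        converged = abs(best - F_new) <= obj_tol * max(1.0, abs(best)) and step <= grad_tol * max(
            1.0, np.linalg.norm(x)
        )
        best = min(best, F_new)
        trace.append(F_new)
        L = max(L * 0.7, 1e-8)
        if converged:
            break
    if not np.isfinite(best):
        raise RuntimeError(f"FISTA diverged (objective NaN/inf, step size 1/L={1.0/L:g})")
    return x, trace


def _make_prox(slices_l1, slices_groups, l1_w, group_w):
    def prox(v, step):
        out = v.copy()
        pen = 0.0
        for sl in slices_l1:
            out[sl] = np.sign(v[sl]) * np.maximum(np.abs(v[sl]) - step * l1_w, 0.0)
            pen += l1_w * np.abs(out[sl]).sum()
        for sl in slices_groups:
            nrm = np.linalg.norm(v[sl])
            scale = max(0.0, 1.0 - step * group_w / nrm) if nrm > 0 else 0.0
            out[sl] = v[sl] * scale
            pen += group_w * np.linalg.norm(out[sl])
        return out, pen

    return prox


class _CellDesign:
    """Precomputed per-cell design pieces shared by both alternation sides."""

    def __init__(self, data: FitData, cell_index: int, neighbors: np.ndarray,
                 model_kind: str):
        movie, spikes, mosaic, bases = data.movie, data.spikes, data.mosaic, data.bases
        self.model_kind = model_kind
        self.n_bins = spikes.n_bins
        self.s = spikes.binned[cell_index].astype(float)
        h_img, w_img = movie.image_shape
        center = np.asarray(mosaic.centers_um[cell_index]) / movie.pixel_pitch_um
        half = max(3, int(round(bases.crop_factor * mosaic.radii_um[cell_index]
                                / movie.pixel_pitch_um)))
        r0 = int(np.clip(round(center[0]) - half, 0, max(h_img - 2 * half - 1, 0)))
        c0 = int(np.clip(round(center[1]) - half, 0, max(w_img - 2 * half - 1, 0)))
        ch = min(2 * half + 1, h_img)
        cw = min(2 * half + 1, w_img)
        self.crop_origin = (r0, c0)
        self.spatial_basis = spatial_spline_basis((ch, cw), bases.spline_knot_spacing)
        crops = movie.frames[:, r0 : r0 + ch, c0 : c0 + cw] - movie.background_level
        self.FS = crops.reshape(movie.n_frames, -1) @ self.spatial_basis.design
        self.fob = frame_of_bin(self.n_bins, movie.frame_period_ms, movie.n_frames)
        self.bases = bases
        self.D_fb = self._conv_design(self.s, bases.feedback.funcs)
        self.neighbors = neighbors
        cols = []
        for j in neighbors:
            cols.append(self._conv_design(spikes.binned[j].astype(float),
                                          bases.coupling.funcs))
        self.D_cp = np.hstack(cols) if cols else np.zeros((self.n_bins, 0))
        self.n_sp = self.spatial_basis.n_basis
        self.n_tc = bases.temporal_stim.n_funcs
        self.n_fb = bases.feedback.n_funcs
        self.n_cp = bases.coupling.n_funcs

    @staticmethod
    def _conv_design(s: np.ndarray, funcs: np.ndarray) -> np.ndarray:
        padded = np.concatenate([np.zeros((funcs.shape[0], 1)), funcs], axis=1)
        return fftconvolve(s[:, None], padded.T)[: len(s)]

    def sta_spatial_init(self, lag_window_ms=(15, 60)) -> np.ndarray:
        """Spline weights of the spike-triggered average (standard GLM init)."""
        lo, hi = lag_window_ms
        sta = np.zeros(self.FS.shape[1])
        count = max(self.s.sum(), 1.0)
        for lag in range(lo, hi + 1):
            idx = np.nonzero(self.s[lag:])[0]
            if len(idx):
                sta += self.FS[self.fob[idx]].sum(axis=0)
        # FS already contains the spline projection of the frame contrast, so
        # solve the basis gram system to express the STA in spline weights
        gram = self.spatial_basis.design.T @ self.spatial_basis.design
        rhs = sta / count
        w = np.linalg.lstsq(gram + 1e-8 * np.eye(len(gram)), rhs, rcond=None)[0]
        nrm = np.linalg.norm(self.spatial_basis.design @ w)
        return w / nrm if nrm > 1e-12 else w

    def stim_design_spatial(self, w_t: np.ndarray) -> np.ndarray:
        """T x n_spline design: spatial weights -> per-bin stimulus drive,
        with the temporal factor fixed (causal convolution of the per-bin
        frame-basis projections with the realized temporal kernel)."""
        kernel = self.bases.temporal_stim.realize(w_t)
        padded = np.concatenate([[0.0], kernel])
        pb = self.FS[self.fob]  # (T, n_sp)
        return fftconvolve(pb, padded[:, None], axes=0)[: self.n_bins]

    def stim_design_temporal(self, w_s: np.ndarray) -> np.ndarray:
        """T x n_cosine design: temporal weights -> per-bin stimulus drive,
        with the spatial factor fixed."""
        p = (self.FS @ w_s)[self.fob]
        return self._conv_design(p, self.bases.temporal_stim.funcs)


def _fista_standardized(X, s, theta0, l1_slices, group_slices, l1_w, l21_w,
                        max_iter, grad_tol, obj_tol):
    """FISTA on a column-standardized design (first-order conditioning).

    Columns are scaled to unit RMS before the solve and the solution is
    mapped back; the sparsity penalties act in the scaled coordinates, i.e.
    they are column-RMS-weighted penalties in the original coordinates.
    """
    scale = np.sqrt(np.mean(X**2, axis=0))
    scale[scale < 1e-12] = 1.0
    # float32 design: halves the matvec cost; the objective/gradient are
    # accumulated in float64
    Xs = (X / scale).astype(np.float32)
    prox = _make_prox(l1_slices, group_slices, l1_w, l21_w)
    theta_sc, trace = _fista(
        _bernoulli_obj(Xs, s, 0.0), np.asarray(theta0) * scale, prox,
        max_iter, grad_tol, obj_tol,
    )
    return theta_sc / scale, trace


def _bernoulli_obj(X, s, offset):
    x_dtype = X.dtype

    def objective(theta):
        g = (X @ theta.astype(x_dtype)).astype(float) + offset
        val = float(np.sum(softplus(g) - s * g))
        grad = (X.T @ (sigmoid(g) - s).astype(x_dtype)).astype(float)
        return val, grad

    return objective


def fit_cell(
    data: FitData,
    cell_index: int,
    model_kind: str = "LNBRC",
    config: FitConfig | None = None,
) -> tuple[LNBRCParams, dict]:
    """Fit one cell's filters by alternating spatial/temporal convex solves."""
    config = config or FitConfig()
    kind = model_kind.upper()
    if kind not in ("LNBRC", "LNBR", "LNP"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    neighbors = (
        select_coupled_neighbors(data.mosaic, cell_index) if kind == "LNBRC"
        else np.array([], dtype=int)
    )
    des = _CellDesign(data, cell_index, neighbors, kind)

    if kind == "LNP":
        return _fit_lnp(data, des, cell_index, config)

    n_sp, n_tc, n_fb = des.n_sp, des.n_tc, des.n_fb
    n_cp_tot = des.D_cp.shape[1]
    s = des.s
    rate = max(s.mean(), 1.0 / len(s))
    # init: STA spatial factor, flat temporal factor, bias at the mean rate
    w_s = des.sta_spatial_init()
    w_t = np.ones(n_tc) / n_tc
    w_fb = np.zeros(n_fb)
    w_cp = np.zeros(n_cp_tot)
    bias = float(np.log(rate / (1.0 - rate)))
    trace_rounds = []
    group_slices_rel = lambda off: [  # noqa: E731
        slice(off + k * des.n_cp, off + (k + 1) * des.n_cp)
        for k in range(len(des.neighbors))
    ]

    def solve(X, theta0, l1_slices, group_slices, l1_w):
        return _fista_standardized(
            X, s, theta0, l1_slices, group_slices, l1_w,
            config.group_l21_weight, config.max_fista_iters,
            config.grad_tol, config.obj_tol,
        )

    for _round in range(config.alternation_rounds):
        # ---- temporal side: (w_t, w_fb, w_cp, bias) with w_s fixed
        Xt = des.stim_design_temporal(w_s)
        X = np.column_stack([Xt, des.D_fb, des.D_cp, np.ones(des.n_bins)])
        theta0 = np.concatenate([w_t, w_fb, w_cp, [bias]])
        theta, tr1 = solve(X, theta0, [], group_slices_rel(n_tc + n_fb), 0.0)
        w_t, w_fb = theta[:n_tc], theta[n_tc : n_tc + n_fb]
        w_cp, bias = theta[n_tc + n_fb : -1], float(theta[-1])
        # ---- spatial side: (w_s, w_fb, w_cp, bias) with w_t fixed
        Xs = des.stim_design_spatial(w_t)
        X = np.column_stack([Xs, des.D_fb, des.D_cp, np.ones(des.n_bins)])
        theta0 = np.concatenate([w_s, w_fb, w_cp, [bias]])
        theta, tr2 = solve(X, theta0, [slice(0, n_sp)],
                           group_slices_rel(n_sp + n_fb), config.l1_weight)
        w_s, w_fb = theta[:n_sp], theta[n_sp : n_sp + n_fb]
        w_cp, bias = theta[n_sp + n_fb : -1], float(theta[-1])
        # resolve the rank-1 scale ambiguity: unit-L2 spatial map
        scale = np.linalg.norm(des.spatial_basis.design @ w_s)
        if scale > 1e-12:
            w_s = w_s / scale
            w_t = w_t * scale
        trace_rounds.append((tr1[-1], tr2[-1]))

    params = LNBRCParams(
        cell_id=int(data.spikes.cell_ids[cell_index]),
        spatial_weights=w_s,
        temporal_weights=w_t,
        feedback_weights=w_fb,
        coupling_weights={
            int(data.spikes.cell_ids[j]): w_cp[k * des.n_cp : (k + 1) * des.n_cp]
            for k, j in enumerate(des.neighbors)
        },
        bias=bias,
        crop_origin=des.crop_origin,
        spatial_basis=des.spatial_basis,
    )
    report = {
        "model": kind,
        "objective_per_round": trace_rounds,
        "final_objective": trace_rounds[-1][-1],
        "n_neighbors": int(len(des.neighbors)),
    }
    return params, report


def _fit_lnp(data: FitData, des: _CellDesign, cell_index: int, config: FitConfig):
    """Poisson benchmark: spatial filter + bias on per-frame counts."""
    movie = data.movie
    counts = np.zeros(movie.n_frames)
    np.add.at(counts, des.fob, des.s)
    X = np.column_stack([des.FS, np.ones(movie.n_frames)])

    def objective(theta):
        g = X @ theta
        eg = np.exp(np.minimum(g, 60.0))
        val = float(np.sum(eg - g * counts))
        grad = X.T @ (eg - counts)
        return val, grad

    theta0 = np.zeros(X.shape[1])
    theta0[-1] = np.log(max(counts.mean(), 1e-6))
    prox = _make_prox([slice(0, des.n_sp)], [], config.l1_weight, 0.0)
    theta, tr = _fista(objective, theta0, prox, config.max_fista_iters,
                       config.grad_tol, config.obj_tol)
    params = LNBRCParams(
        cell_id=int(data.spikes.cell_ids[cell_index]),
        spatial_weights=theta[:-1],
        temporal_weights=np.array([1.0]),
        feedback_weights=np.zeros(0),
        coupling_weights={},
        bias=float(theta[-1]),
        crop_origin=des.crop_origin,
        spatial_basis=des.spatial_basis,
    )
    return params, {"model": "LNP", "objective_per_round": [(tr[-1],)],
                    "final_objective": tr[-1], "n_neighbors": 0}


def fit_encoder(
    data: FitData,
    model_kind: str = "LNBRC",
    config: FitConfig | None = None,
    cell_indices: Sequence[int] | None = None,
) -> tuple[PopulationEncoder, dict]:
    """Fit every cell (or a subset) and assemble a population encoder."""
    config = config or FitConfig()
    idx = range(data.spikes.n_cells) if cell_indices is None else cell_indices
    cells, reports = [], {}
    for i in idx:
        params, rep = fit_cell(data, i, model_kind, config)
        cells.append(_realize_fitted(params, data.bases, model_kind))
        reports[int(data.spikes.cell_ids[i])] = rep
    return PopulationEncoder(cells=cells, mosaic=data.mosaic), {
        "model": model_kind, "per_cell": reports,
    }


def _realize_fitted(params: LNBRCParams, bases: BasisSet, kind: str) -> CellFilters:
    if kind.upper() == "LNP":
        return CellFilters(
            cell_id=params.cell_id,
            spatial_map=params.spatial_basis.realize(params.spatial_weights),
            crop_origin=params.crop_origin,
            temporal_kernel=np.array([1.0]),
            feedback_kernel=np.zeros(1),
            coupling_kernels={},
            bias=params.bias,
        )
    return params.realize(bases)


def grid_search_hyperparams(
    data: FitData,
    grid: Sequence[tuple[float, float]],
    model_kind: str = "LNBRC",
    n_cells_per_type: int = 4,
    train_fraction: float = 0.75,
    seed: int = 0,
    config: FitConfig | None = None,
) -> tuple[float, float]:
    """Pick (l1, group_l21) minimizing mean held-out NLL on sample cells.

    ``n_cells_per_type`` cells of each type are drawn at random; the data is
    split in time into train/test segments.
    """
    if len(grid) == 0:
        raise ValueError("hyperparameter grid must be non-empty")
    rng = np.random.default_rng(seed)
    types = np.asarray(data.mosaic.cell_types)
    chosen: list[int] = []
    for t in np.unique(types):
        idx = np.nonzero(types == t)[0]
        take = min(n_cells_per_type, len(idx))
        chosen.extend(rng.choice(idx, size=take, replace=False).tolist())
    n_train = int(data.spikes.n_bins * train_fraction)
    train = _slice_fit_data(data, 0, n_train)
    base = config or FitConfig()
    best, best_nll = None, np.inf
    for l1, l21 in grid:
        cfg = FitConfig(l1_weight=l1, group_l21_weight=l21,
                        alternation_rounds=base.alternation_rounds,
                        max_fista_iters=base.max_fista_iters,
                        grad_tol=base.grad_tol, obj_tol=base.obj_tol)
        enc, _ = fit_encoder(train, model_kind, cfg, cell_indices=chosen)
        # held-out NLL evaluated on the time segment past the training cut
        full = _embed_population(enc, data)
        nlls = [
            lnbrc_nll(full, data.movie, data.spikes,
                      int(data.spikes.cell_ids[i]),
                      t_range=(n_train, data.spikes.n_bins))
            / (data.spikes.n_bins - n_train)
            for i in chosen
        ]
        mean_nll = float(np.mean(nlls))
        if mean_nll < best_nll:
            best, best_nll = (l1, l21), mean_nll
    return best


def _embed_population(enc: PopulationEncoder, data: FitData) -> PopulationEncoder:
    """Population with fitted cells available plus identity spike indexing."""
    id_to_cell = {c.cell_id: c for c in enc.cells}
    cells = []
    for cid in data.spikes.cell_ids:
        if int(cid) in id_to_cell:
            cells.append(id_to_cell[int(cid)])
        else:  # placeholder silent cell (never evaluated)
            cells.append(CellFilters(int(cid), np.zeros((1, 1)), (0, 0),
                                     np.zeros(1), np.zeros(1), {}, -10.0))
    return PopulationEncoder(cells=cells, mosaic=data.mosaic)


def _slice_fit_data(data: FitData, t0: int, t1: int) -> FitData:
    movie = data.movie
    f0 = int(t0 / movie.frame_period_ms)
    f1 = int(np.ceil(t1 / movie.frame_period_ms))
    sub_movie = StimulusMovie(
        frames=movie.frames[f0:f1],
        frame_period_ms=movie.frame_period_ms,
        pixel_pitch_um=movie.pixel_pitch_um,
        background_level=movie.background_level,
    )
    spikes = SpikeTrainSet(binned=data.spikes.binned[:, t0:t1],
                           cell_ids=data.spikes.cell_ids)
    return FitData(movie=sub_movie, spikes=spikes, mosaic=data.mosaic,
                   bases=data.bases)


def fraction_psth_variance_explained(
    encoder: PopulationEncoder,
    movie: StimulusMovie,
    repeat_spikes: list[SpikeTrainSet],
    cell_id: int,
    n_model_repeats: int | None = None,
    seed: int = 0,
    kernel_sd_ms: float = 2.0,
) -> float:
    """1 - MSE(model PSTH, data PSTH) / Var(data PSTH) for one cell.

    The model PSTH is computed from spike trains simulated by the encoder in
    conditioned mode (coupling reads the recorded neighbor spikes), one
    simulated train per recorded repeat by default.
    """
    from .evaluation import psth
    from .retina_simulator import simulate_spikes

    if len(repeat_spikes) < 2:
        raise ValueError("need >= 2 repeats")
    n_model = n_model_repeats or len(repeat_spikes)
    rng = np.random.default_rng(seed)
    sims = [
        simulate_spikes(encoder, movie, mode="conditioned",
                        seed=rng.integers(2**31), conditioning_spikes=rep)
        for rep in repeat_spikes[:n_model]
    ]
    ci = encoder.index_of(cell_id)
    data_psth = psth(repeat_spikes, kernel_sd_ms)[ci]
    model_psth = psth(sims, kernel_sd_ms)[ci]
    var = float(np.var(data_psth))
    if var < 1e-20:
        warnings.warn("zero-variance PSTH; fraction undefined")
        return float("nan")
    return 1.0 - float(np.mean((model_psth - data_psth) ** 2)) / var
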