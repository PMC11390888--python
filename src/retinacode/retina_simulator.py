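"""Synthetic RGC mosaics with ground-truth encoder parameters and spiking.

Mosaics are jittered hexagonal lattices per cell type (ON/OFF parasol and
midget), receptive-field radii set so neighboring fields abut (spacing about
twice the radius).  Ground-truth filters are difference-of-Gaussians spatial
maps, biphasic temporal kernels, refractory feedback and small homotypic
coupling.  Spike trains are sampled per 1 ms bin from the Bernoulli
generator-signal model, either with all cells simulated jointly ("network"
mode, coupling reads the simulated spikes) or conditioned on provided spike
trains ("conditioned" mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .encoding_models import (
    CellFilters,
    PopulationEncoder,
    SpikeTrainSet,
    bin_count,
    frame_of_bin,
    select_coupled_neighbors,
    sigmoid,
    stimulus_projections,
)
from .synthetic_stimulus import StimulusMovie

__all__ = [
    "RGCMosaic",
    "CELL_TYPES",
    "DEFAULT_SPACINGS_UM",
    "build_mosaic",
    "density_for_spacing",
    "sample_ground_truth_params",
    "simulate_spikes",
]

CELL_TYPES = ("ON_parasol", "OFF_parasol", "ON_midget", "OFF_midget")

#: Hexagonal lattice spacings (um) giving midget mosaics denser than parasol.
DEFAULT_SPACINGS_UM = {
    "ON_parasol": 130.0,
    "OFF_parasol": 120.0,
    "ON_midget": 75.0,
    "OFF_midget": 70.0,
}


@dataclass
class RGCMosaic:
    """Cell locations, types and receptive-field radii over a planar field."""

    cell_ids: np.ndarray  # (N,)
    cell_types: np.ndarray  # (N,) str
    centers_um: np.ndarray  # (N, 2) as (y, x)
    radii_um: np.ndarray  # (N,)
    field_size_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        self.cell_types = np.asarray(self.cell_types)
        self.centers_um = np.asarray(self.centers_um, dtype=float)
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        if np.any(self.radii_um <= 0):
            raise ValueError("receptive-field radii must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def of_type(self, cell_type: str) -> np.ndarray:
        return np.nonzero(self.cell_types == cell_type)[0]


def density_for_spacing(spacing_um: float) -> float:
    """Cells per um^2 of a hexagonal lattice with the given spacing."""
    return 1.0 / (np.sqrt(3.0) / 2.0 * spacing_um**2)


def _hex_lattice(field: tuple[float, float], spacing: float) -> np.ndarray:
    h, w = field
    row_pitch = spacing * np.sqrt(3.0) / 2.0
    pts = []
    y = spacing / 2.0
    row = 0
    while y < h:
        x0 = spacing / 2.0 + (spacing / 2.0 if row % 2 else 0.0)
        xs = np.arange(x0, w, spacing)
        pts.extend((y, x) for x in xs)
        y += row_pitch
        row += 1
    return np.array(pts, dtype=float).reshape(-1, 2)


def build_mosaic(
    field_size_um: tuple[float, float] = (352.0, 352.0),
    densities_per_type: dict[str, float] | None = None,
    jitter_fraction: float = 0.1,
    seed: int = 0,
) -> RGCMosaic:
    """Jittered hexagonal lattice per type, radii = spacing / 2 (abutting RFs).

    ``densities_per_type`` maps type name -> cells/um^2 (see
    :func:`density_for_spacing`); defaults come from ``DEFAULT_SPACINGS_UM``.
    """
    if not (0.0 <= jitter_fraction < 1.0):
        raise ValueError("jitter_fraction must be in [0, 1)")
    if densities_per_type is None:
        densities_per_type = {
            t: density_for_spacing(s) for t, s in DEFAULT_SPACINGS_UM.items()
        }
    if any(d <= 0 for d in densities_per_type.values()):
        raise ValueError("densities must be positive")
    rng = np.random.default_rng(seed)
    types, centers, radii = [], [], []
    for cell_type, density in densities_per_type.items():
        spacing = np.sqrt(2.0 / (np.sqrt(3.0) * density))
        pts = _hex_lattice(field_size_um, spacing)
        if len(pts) == 0:
            raise ValueError(
                f"field {field_size_um} um too small for one {cell_type} cell "
                f"(spacing {spacing:.1f} um)"
            )
        jitter = rng.uniform(-0.5, 0.5, size=pts.shape) * jitter_fraction * spacing
        pts = pts + jitter
        pts[:, 0] = np.clip(pts[:, 0], 0.0, field_size_um[0])
        pts[:, 1] = np.clip(pts[:, 1], 0.0, field_size_um[1])
        types.extend([cell_type] * len(pts))
        centers.append(pts)
        radii.extend([spacing / 2.0] * len(pts))
    centers = np.concatenate(centers, axis=0)
    return RGCMosaic(
        cell_ids=np.arange(len(types)),
        cell_types=np.array(types),
        centers_um=centers,
        radii_um=np.array(radii),
        field_size_um=tuple(field_size_um),
    )


# --------------------------------------------------------------------------
# ground-truth parameters

def _dog_map(shape, center, sigma_c, surround_scale=2.0, surround_weight=0.5):
    yy, xx = np.indices(shape, dtype=float)
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    m = np.exp(-r2 / (2 * sigma_c**2)) - surround_weight * np.exp(
        -r2 / (2 * (surround_scale * sigma_c) ** 2)
    ) / surround_scale**2 * 1.0
    return m


def _biphasic_kernel(n_lags: int, peak_ms: float, trough_scale: float = 1.6,
                     trough_weight: float = 0.5) -> np.ndarray:
    """Difference of gamma-shaped lobes; near-balanced so sustained input decays.

    With ``trough_weight = 1 / trough_scale`` the areas cancel exactly (pure
    transient response); the default leaves a modest sustained component.
    Normalized so the kernel sums of absolute values are 1, which makes the
    stimulus gain directly comparable across peak latencies.
    """
    t = np.arange(1, n_lags + 1, dtype=float)
    n = 4.0
    lobe = lambda tp: (t / tp) ** n * np.exp(n * (1 - t / tp))  # noqa: E731
    k = lobe(peak_ms) - trough_weight * lobe(peak_ms * trough_scale)
    return k / np.abs(k).sum()


def _refractory_kernel(n_lags: int, strength: float = 8.0, tau: float = 4.0,
                       rebound_area: float = 1.0, tau2: float = 25.0) -> np.ndarray:
    t = np.arange(1, n_lags + 1, dtype=float)
    rb = np.exp(-t / tau2) * (t / tau2)
    return -strength * np.exp(-t / tau) + rebound_area * rb / rb.sum()


def _coupling_kernel(n_lags: int, area: float, tau: float = 5.0) -> np.ndarray:
    """Excitatory bump at short lag whose integrated drive equals ``area``."""
    t = np.arange(1, n_lags + 1, dtype=float)
    shape = (t / tau) * np.exp(1 - t / tau)
    return area * shape / shape.sum()


def _renewal_rate(bias: float, fb_kernel: np.ndarray, horizon: int = 5000) -> float:
    """Stationary rate of a Bernoulli process with self-feedback, treating the
    interspike interval as a renewal driven by the last spike only."""
    hazard = sigmoid(bias + np.concatenate([fb_kernel,
                                            np.zeros(horizon - len(fb_kernel))]))
    survival = np.cumprod(1.0 - hazard)
    mean_isi = 1.0 + survival.sum()
    return 1.0 / mean_isi


def _bias_for_target_rate(p_target: float, fb_kernel: np.ndarray) -> float:
    """Bias giving an unstimulated rate of ``p_target`` per bin (bisection)."""
    lo, hi = -15.0, 5.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _renewal_rate(mid, fb_kernel) < p_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# per-type (temporal peak ms, stimulus gain, coupling strength)
_TYPE_PROFILES = {
    "ON_parasol": (28.0, 1.0, 0.35),
    "OFF_parasol": (28.0, -1.0, 0.35),
    "ON_midget": (42.0, 1.0, 0.30),
    "OFF_midget": (42.0, -1.0, 0.30),
}


def sample_ground_truth_params(
    mosaic: RGCMosaic,
    seed: int = 0,
    pixel_pitch_um: float = 11.0,
    image_shape: tuple[int, int] | None = None,
    target_rate_hz: float = 20.0,
    stimulus_gain: float = 8.0,
    coupling_scale: float = 1.0,
    n_stim_lags: int = 150,
    n_feedback_lags: int = 100,
    n_coupling_lags: int = 50,
) -> PopulationEncoder:
    """Plausible ground-truth filters for every cell in the mosaic.

    Spatial filters are unit-norm difference-of-Gaussians centered on the RF
    (positive center for ON, negative for OFF); temporal kernels are biphasic
    with a type-specific peak latency; feedback is strongly negative at short
    lags (refractoriness); coupling is excitatory and strongest between
    homotypic neighbors.  The bias sets the unstimulated firing rate.
    """
    rng = np.random.default_rng(seed)
    p = target_rate_hz / 1000.0  # per 1 ms bin
    fb = _refractory_kernel(n_feedback_lags)
    bias = _bias_for_target_rate(p, fb)
    if image_shape is None:
        image_shape = (
            int(round(mosaic.field_size_um[0] / pixel_pitch_um)),
            int(round(mosaic.field_size_um[1] / pixel_pitch_um)),
        )
    # symmetrized neighbor graph: the distance rule keys off the candidate's
    # type, which is asymmetric across types; ground truth uses the union so
    # coupling sets are symmetric
    neighbor_sets = [set(select_coupled_neighbors(mosaic, i))
                     for i in range(mosaic.n_cells)]
    for i in range(mosaic.n_cells):
        for j in list(neighbor_sets[i]):
            neighbor_sets[j].add(i)

    cells: list[CellFilters] = []
    for i in range(mosaic.n_cells):
        ctype = str(mosaic.cell_types[i])
        peak_ms, polarity, cpl_strength = _TYPE_PROFILES[ctype]
        center_px = mosaic.centers_um[i] / pixel_pitch_um
        radius_px = mosaic.radii_um[i] / pixel_pitch_um
        half = max(2, int(np.ceil(2.5 * radius_px)))
        r0 = int(np.clip(round(center_px[0]) - half, 0, max(image_shape[0] - 2 * half - 1, 0)))
        c0 = int(np.clip(round(center_px[1]) - half, 0, max(image_shape[1] - 2 * half - 1, 0)))
        ch = min(2 * half + 1, image_shape[0])
        cw = min(2 * half + 1, image_shape[1])
        local_center = (center_px[0] - r0, center_px[1] - c0)
        sigma = max(radius_px / 1.8, 0.8) * rng.uniform(0.9, 1.1)
        m = _dog_map((ch, cw), local_center, sigma)
        m = polarity * m / np.linalg.norm(m)
        coupling = {}
        for j in sorted(neighbor_sets[i]):
            same = mosaic.cell_types[j] == mosaic.cell_types[i]
            strength = cpl_strength * (1.0 if same else 0.35) * coupling_scale
            strength *= rng.uniform(0.7, 1.3)
            coupling[int(mosaic.cell_ids[j])] = _coupling_kernel(
                n_coupling_lags, strength
            )
        cells.append(
            CellFilters(
                cell_id=int(mosaic.cell_ids[i]),
                spatial_map=m,
                crop_origin=(r0, c0),
                temporal_kernel=stimulus_gain
                * _biphasic_kernel(n_stim_lags, peak_ms),
                feedback_kernel=_refractory_kernel(n_feedback_lags),
                coupling_kernels=coupling,
                bias=bias,
            )
        )
    return PopulationEncoder(cells=cells, mosaic=mosaic)


# --------------------------------------------------------------------------
# spike generation

def simulate_spikes(
    encoder: PopulationEncoder,
    movie: StimulusMovie,
    mode: str = "network",
    seed: int = 0,
    conditioning_spikes: SpikeTrainSet | None = None,
) -> SpikeTrainSet:
    """Sample Bernoulli spikes per 1 ms bin from the generator-signal model.

    ``network``: all cells simulated jointly; coupling reads the simulated
    spikes of the previous bins.  ``conditioned``: coupling reads the provided
    ``conditioning_spikes`` instead (feedback still reads the simulated own
    train).  Strictly causal: the spike at bin t depends only on frames and
    spikes at bins <= t-1.  Reproducible given ``seed``.
    """
    if mode not in ("network", "conditioned"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    if mode == "conditioned" and conditioning_spikes is None:
        raise ValueError("conditioned mode requires conditioning_spikes")
    n_cells = encoder.n_cells
    n_bins = bin_count(movie)
    rng = np.random.default_rng(seed)
    uniforms = rng.random((n_bins, n_cells))

    # stimulus + bias drive, fully precomputable (strictly causal via lag >= 1)
    fob = frame_of_bin(n_bins, movie.frame_period_ms, movie.n_frames)
    base = np.empty((n_bins, n_cells))
    for i, cell in enumerate(encoder.cells):
        proj = stimulus_projections(cell, movie)[fob]
        kern = np.concatenate([[0.0], cell.temporal_kernel])
        base[:, i] = fftconvolve(proj, kern)[:n_bins] + cell.bias

    id_to_index = {c.cell_id: k for k, c in enumerate(encoder.cells)}
    max_lag = max(
        max((len(c.feedback_kernel) for c in encoder.cells), default=1),
        max(
            (len(k) for c in encoder.cells for k in c.coupling_kernels.values()),
            default=1,
        ),
    )
    # conditioned mode: coupling drive is a fixed convolution of the data
    if mode == "conditioned":
        for i, cell in enumerate(encoder.cells):
            for j, ck in cell.coupling_kernels.items():
                s_j = conditioning_spikes.binned[id_to_index[j]].astype(float)
                kern = np.concatenate([[0.0], ck])
                base[:, i] += fftconvolve(s_j, kern)[:n_bins]

    # incoming-coupling table in flat CSR-like form: for spiking cell k, the
    # coupled targets are inc_targets[inc_ptr[k]:inc_ptr[k+1]] with kernels in
    # the matching rows of inc_kernels
    inc_ptr = np.zeros(n_cells + 1, dtype=np.int64)
    inc_targets_list: list[int] = []
    inc_kernel_rows: list[np.ndarray] = []
    if mode == "network":
        for k, src in enumerate(encoder.cells):
            for i, cell in enumerate(encoder.cells):
                ck = cell.coupling_kernels.get(src.cell_id)
                if ck is not None:
                    inc_targets_list.append(i)
                    kk = np.zeros(max_lag)
                    kk[: len(ck)] = ck
                    inc_kernel_rows.append(kk)
            inc_ptr[k + 1] = len(inc_targets_list)
    inc_targets = np.array(inc_targets_list, dtype=np.int64)
    inc_kernels = (
        np.array(inc_kernel_rows) if inc_kernel_rows else np.zeros((0, max_lag))
    )

    fb_kernels = np.zeros((n_cells, max_lag))
    for i, cell in enumerate(encoder.cells):
        fb_kernels[i, : len(cell.feedback_kernel)] = cell.feedback_kernel

    pending = np.zeros((n_cells, n_bins + max_lag))
    spikes = np.zeros((n_cells, n_bins), dtype=np.uint8)
    _sim_loop(base, uniforms, fb_kernels, inc_ptr, inc_targets, inc_kernels,
              pending, spikes)
    return SpikeTrainSet(binned=spikes, cell_ids=encoder.cell_ids)


def _sim_loop_py(base, uniforms, fb_kernels, inc_ptr, inc_targets, inc_kernels,
                 pending, spikes):
    """Sequential Bernoulli sampling; compiled with numba when available."""
    n_bins, n_cells = base.shape
    max_lag = fb_kernels.shape[1]
    for t in range(n_bins):
        for i in range(n_cells):
            g = base[t, i] + pending[i, t]
            p = 0.5 * (1.0 + np.tanh(0.5 * g))
            if uniforms[t, i] < p:
                spikes[i, t] = 1
                for lag in range(max_lag):
                    pending[i, t + 1 + lag] += fb_kernels[i, lag]
                for e in range(inc_ptr[i], inc_ptr[i + 1]):
                    j = inc_targets[e]
                    for lag in range(max_lag):
                        pending[j, t + 1 + lag] += inc_kernels[e, lag]


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _sim_loop = njit(cache=True)(_sim_loop_py)
except Exception:  # pragma: no cover
    _sim_loop = _sim_loop_py
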