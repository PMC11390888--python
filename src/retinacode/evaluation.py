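"""Analysis procedures: masked MS-SSIM, PSTHs, correlograms, perturbations.

The image-quality score is multi-scale SSIM restricted to a valid region
(the convex hull of the receptive fields), optionally maximized over integer
shifts of the reconstruction (the absolute position of a jointly estimated
image is a gauge freedom).  Spike-train analyses include the kernel-smoothed
PSTH, shift-predictor-corrected cross-correlograms, Gaussian spike-time
perturbation and across-repeat shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter
from scipy.spatial import ConvexHull
from skimage.draw import polygon

from .encoding_models import SpikeTrainSet
from .synthetic_stimulus import shift_image

__all__ = [
    "ValidRegionMask",
    "valid_region",
    "ms_ssim",
    "ms_ssim_masked",
    "psth",
    "cross_correlogram",
    "perturb_spike_times",
    "shuffle_repeats",
    "realized_drift_magnitude",
    "eye_position_error",
]


@dataclass
class ValidRegionMask:
    mask: np.ndarray  # (H, W) bool
    provenance: str = ""

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def valid_region(mosaic, image_shape: tuple[int, int],
                 pixel_pitch_um: float = 11.0) -> ValidRegionMask:
    """Convex hull of the union of RF disks, rasterized onto the image grid."""
    centers = np.asarray(mosaic.centers_um, dtype=float) / pixel_pitch_um
    radii = np.asarray(mosaic.radii_um, dtype=float) / pixel_pitch_um
    if len(centers) < 3:
        raise ValueError("need at least 3 cells for a valid region")
    ang = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    ring = np.stack([np.sin(ang), np.cos(ang)], axis=1)  # (32, 2) as (y, x)
    pts = (centers[:, None, :] + radii[:, None, None] * ring[None, :, :]).reshape(-1, 2)
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # collinear / degenerate
        raise ValueError(f"degenerate receptive-field hull: {exc}") from exc
    verts = pts[hull.vertices]
    rr, cc = polygon(verts[:, 0], verts[:, 1], shape=image_shape)
    mask = np.zeros(image_shape, dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("valid region does not intersect the image")
    return ValidRegionMask(mask=mask, provenance=f"mosaic[{mosaic.n_cells}]")


# --------------------------------------------------------------------------
# MS-SSIM

_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
_WIN = 8  # uniform filter window


def _ssim_maps(a: np.ndarray, b: np.ndarray, data_range: float = 1.0):
    """Mean/contrast/structure SSIM component maps with a uniform window."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_a = uniform_filter(a, _WIN)
    mu_b = uniform_filter(b, _WIN)
    var_a = uniform_filter(a * a, _WIN) - mu_a**2
    var_b = uniform_filter(b * b, _WIN) - mu_b**2
    cov = uniform_filter(a * b, _WIN) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return lum, cs


def _downsample(x: np.ndarray) -> np.ndarray:
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def ms_ssim(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | None = None,
    data_range: float = 1.0,
) -> float:
    """Multi-scale SSIM, optionally averaged over a pixel mask.

    The number of scales is reduced automatically so the smallest scale is at
    least the filter window; the canonical five weights are truncated and
    renormalized accordingly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_scales = 1
    dim = min(a.shape)
    while n_scales < len(_MSSSIM_WEIGHTS) and dim // 2 >= _WIN:
        n_scales += 1
        dim //= 2
    weights = _MSSSIM_WEIGHTS[:n_scales] / _MSSSIM_WEIGHTS[:n_scales].sum()
    m = mask.astype(float)
    vals = []
    for level in range(n_scales):
        lum, cs = _ssim_maps(a, b, data_range)
        sel = m > 0.5
        if not sel.any():
            raise ValueError("mask vanished during multi-scale downsampling")
        if level == n_scales - 1:
            vals.append(float(np.mean((lum * cs)[sel])))
        else:
            vals.append(float(np.mean(cs[sel])))
            a, b, m = _downsample(a), _downsample(b), _downsample(m)
    vals = np.clip(vals, 1e-6, None)  # negative cs at coarse scales is rare
    return float(np.prod(vals ** weights))


def ms_ssim_masked(
    recon: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | ValidRegionMask | None = None,
    max_shift_px: int = 0,
    fill: float = 0.5,
) -> tuple[float, tuple[int, int]]:
    """Best masked MS-SSIM over integer shifts in [-max_shift, max_shift]^2.

    Returns (score, best (dy, dx) shift of the reconstruction).
    """
    if isinstance(mask, ValidRegionMask):
        mask = mask.mask
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be >= 0")
    if mask is not None and mask.sum() < _WIN**2:
        raise ValueError("mask smaller than the SSIM window")
    best, best_shift = -np.inf, (0, 0)
    for dy in range(-max_shift_px, max_shift_px + 1):
        for dx in range(-max_shift_px, max_shift_px + 1):
            shifted = shift_image(np.asarray(recon, dtype=float), dy, dx, fill)
            score = ms_ssim(shifted, truth, mask)
            if score > best:
                best, best_shift = score, (dy, dx)
    return best, best_shift


# --------------------------------------------------------------------------
# spike-train analyses

def psth(
    repeat_spikes: list[SpikeTrainSet], kernel_sd_ms: float = 2.0
) -> np.ndarray:
    """Trial-averaged smoothed firing rate (spikes/bin), cells x bins.

    Counts in 1 ms bins are smoothed with a Gaussian kernel (sd 2 ms default,
    zero-padded borders) and averaged over repeats.
    """
    if len(repeat_spikes) < 1:
        raise ValueError("need at least one repeat")
    stack = np.stack([r.binned.astype(float) for r in repeat_spikes])
    mean = stack.mean(axis=0)
    if kernel_sd_ms <= 0:
        return mean
    return gaussian_filter1d(mean, kernel_sd_ms, axis=-1, mode="constant",
                             truncate=6.0)


def cross_correlogram(
    repeat_spikes_a: list[np.ndarray],
    repeat_spikes_b: list[np.ndarray],
    max_lag_ms: int,
    shift_correct: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlogram of spike-time differences, averaged over repeats.

    Inputs are per-repeat binary trains (1 ms bins).  The value at lag L is
    the mean count of pairs with ``t_b - t_a = L``.  With ``shift_correct``
    the same histogram computed after reassigning cell b's trials to the next
    repeat (responses to a different stimulus presentation) is subtracted,
    removing structure predictable from the trial timing alone.
    Returns (lags_ms, corrected histogram).
    """
    n_rep = len(repeat_spikes_a)
    if n_rep != len(repeat_spikes_b) or n_rep < 1:
        raise ValueError("need matching, nonempty repeat lists")
    T = len(repeat_spikes_a[0])
    if max_lag_ms >= T:
        raise ValueError("max_lag exceeds the trial length")
    if shift_correct and n_rep < 2:
        raise ValueError("shift predictor requires >= 2 repeats")
    lags = np.arange(-max_lag_ms, max_lag_ms + 1)

    def _ccg(pairs):
        acc = np.zeros(len(lags))
        for sa, sb in pairs:
            full = np.correlate(sb.astype(float), sa.astype(float), mode="full")
            center = len(sa) - 1
            acc += full[center - max_lag_ms : center + max_lag_ms + 1]
        return acc / len(pairs)

    raw = _ccg(list(zip(repeat_spikes_a, repeat_spikes_b)))
    if not shift_correct:
        return lags, raw
    shifted_b = repeat_spikes_b[1:] + repeat_spikes_b[:1]
    predictor = _ccg(list(zip(repeat_spikes_a, shifted_b)))
    return lags, raw - predictor


def perturb_spike_times(
    spikes: SpikeTrainSet, sigma_ms: float, seed: int = 0
) -> SpikeTrainSet:
    """Shift each spike independently by N(0, sigma^2) ms and re-bin.

    Spikes moved outside the trial are clipped to the trial bounds; multiple
    spikes landing in one 1 ms bin collapse to a single spike (binary trains);
    the number of collapsed spikes is recorded on the returned object as
    ``n_collisions``.
    """
    if sigma_ms < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n_bins = spikes.n_bins
    out = np.zeros_like(spikes.binned)
    n_coll = 0
    for i in range(spikes.n_cells):
        t = np.nonzero(spikes.binned[i])[0].astype(float) + 0.5
        if sigma_ms > 0:
            t = t + rng.normal(scale=sigma_ms, size=len(t))
        t = np.clip(t, 0.0, n_bins - 1e-9)
        b = np.floor(t).astype(int)
        uniq = np.unique(b)
        n_coll += len(b) - len(uniq)
        out[i, uniq] = 1
    perturbed = SpikeTrainSet(binned=out, cell_ids=spikes.cell_ids)
    perturbed.n_collisions = n_coll
    return perturbed


def shuffle_repeats(
    repeat_spikes: list[SpikeTrainSet], seed: int = 0
) -> list[SpikeTrainSet]:
    """Independently permute trial labels per cell across repeated trials.

    Per-cell marginal statistics are preserved exactly; same-trial pairing
    across cells (noise correlations) is destroyed.
    """
    if len(repeat_spikes) < 2:
        raise ValueError("need >= 2 repeats to shuffle")
    rng = np.random.default_rng(seed)
    n_rep = len(repeat_spikes)
    n_cells = repeat_spikes[0].n_cells
    stack = np.stack([r.binned for r in repeat_spikes])  # (R, N, T)
    out = stack.copy()
    for i in range(n_cells):
        out[:, i, :] = stack[rng.permutation(n_rep), i, :]
    return [
        SpikeTrainSet(binned=out[r], cell_ids=repeat_spikes[0].cell_ids)
        for r in range(n_rep)
    ]


def realized_drift_magnitude(trajectory, how: str = "pooled") -> float:
    """Std of the within-trial eye position, in um.

    ``pooled`` (default) returns sqrt(var_y + var_x); ``mean_axis`` averages
    the per-axis standard deviations instead.
    """
    um = np.asarray(getattr(trajectory, "displacements_um", trajectory),
                    dtype=float)
    if um.size == 0:
        raise ValueError("empty trajectory")
    v = um.var(axis=0)
    if how == "pooled":
        return float(np.sqrt(v.sum()))
    if how == "mean_axis":
        return float(np.mean(np.sqrt(v)))
    raise ValueError(f"unknown mode {how!r}")


def eye_position_error(
    true_trajectory,
    estimated,
    align: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-frame Euclidean error (um) between true and estimated eye paths.

    The global translation is a gauge freedom of joint estimation, so (by
    default) each path's mean is subtracted before differencing.  Returns
    (per-frame error series, trial mean).
    """
    t = np.asarray(getattr(true_trajectory, "displacements_um", true_trajectory),
                   dtype=float)
    e = np.asarray(getattr(estimated, "posterior_mean_um", lambda: estimated)()
                   if hasattr(estimated, "posterior_mean_um") else estimated,
                   dtype=float)
    if t.shape != e.shape:
        raise ValueError("trajectory lengths differ")
    if align:
        t = t - t.mean(axis=0)
        e = e - e.mean(axis=0)
    err = np.linalg.norm(t - e, axis=1)
    return err, float(err.mean())
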