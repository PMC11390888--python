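"""Synthetic stimuli: textured images, fixational drift paths, rendered trials.

Grayscale images stand in for natural photographs; they are random textures
with a power-law (``1/f**alpha``) radially averaged power spectrum.  Drift is
discretized 2D Brownian motion at the display frame rate, and trials are
rendered either as a flash followed by a gray screen or as a per-frame
jittered presentation of a single image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Image",
    "EyeTrajectory",
    "StimulusMovie",
    "DEFAULT_FRAME_PERIOD_MS",
    "DEFAULT_PIXEL_PITCH_UM",
    "generate_texture_image",
    "simulate_drift_trajectory",
    "render_flashed_trial",
    "render_jittered_trial",
    "shift_image",
]

#: 120 Hz display refresh.
DEFAULT_FRAME_PERIOD_MS = 1000.0 / 120.0
#: Microns per pixel on the retina.
DEFAULT_PIXEL_PITCH_UM = 11.0
BACKGROUND_LEVEL = 0.5


@dataclass(frozen=True)
class Image:
    """A grayscale image with physical pixel size.

    Attributes
    ----------
    pixels : ndarray, shape (H, W)
        Luminance values in [0, 1].
    pixel_pitch_um : float
        Physical size of one pixel in microns.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 16:
            raise ValueError("image must be 2D with both dimensions >= 16")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ValueError("image values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class EyeTrajectory:
    """Per-frame 2D eye displacement relative to frame 0.

    ``displacements_um`` is the continuous Brownian path; ``displacements_px``
    is the same path divided by the pixel pitch and rounded to integers
    (ties toward zero).  Row order is (dy, dx) = (row shift, column shift).
    """

    displacements_px: np.ndarray  # (F, 2) int
    displacements_um: np.ndarray  # (F, 2) float
    frame_period_ms: float = DEFAULT_FRAME_PERIOD_MS

    def __post_init__(self) -> None:
        self.displacements_px = np.asarray(self.displacements_px, dtype=int)
        self.displacements_um = np.asarray(self.displacements_um, dtype=float)
        if self.displacements_px.shape != self.displacements_um.shape:
            raise ValueError("pixel and micron paths must have the same shape")
        if np.any(self.displacements_px[0] != 0) or np.any(self.displacements_um[0] != 0):
            raise ValueError("frame 0 displacement must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.displacements_px.shape[0]


@dataclass
class StimulusMovie:
    """A stack of display frames with timing and geometry metadata."""

    frames: np.ndarray  # (F, H, W) in [0, 1]
    frame_period_ms: float = DEFAULT_FRAME_PERIOD_MS
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    background_level: float = BACKGROUND_LEVEL
    trajectory: EyeTrajectory | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) stack")
        if self.frames.min() < -1e-12 or self.frames.max() > 1 + 1e-12:
            raise ValueError("frame values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_period_ms

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _round_half_toward_zero(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with exact .5 ties rounded toward zero."""
    return np.sign(x) * np.ceil(np.abs(x) - 0.5)


def shift_image(pixels: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Translate image content by integer (dy, dx); exposed borders get `fill`.

    A positive ``dy`` moves content down, positive ``dx`` moves it right:
    ``out[r, c] = pixels[r - dy, c - dx]`` where defined.
    """
    h, w = pixels.shape
    out = np.full((h, w), fill, dtype=float)
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = pixels[ys_src, xs_src]
    return out


def shift_adjoint(pixels: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Adjoint of :func:`shift_image` with zero fill (i.e. shift by -dy, -dx)."""
    return shift_image(pixels, -dy, -dx, 0.0)


def generate_texture_image(
    seed: int,
    height: int = 64,
    width: int = 64,
    spectral_exponent: float = 2.0,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> Image:
    """Random texture whose radial power spectrum follows 1/f**spectral_exponent.

    White Gaussian noise is shaped in the Fourier domain by
    ``f ** (-spectral_exponent / 2)`` (amplitude), then linearly rescaled to
    span [0, 1].  Deterministic given ``seed``.
    """
    if height < 16 or width < 16:
        raise ValueError("height and width must both be >= 16")
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    spec = np.fft.fft2(noise)
    fy = np.fft.fftfreq(height)[:, None] * height
    fx = np.fft.fftfreq(width)[None, :] * width
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # DC handled below
    amp = f ** (-spectral_exponent / 2.0)
    amp[0, 0] = 0.0
    img = np.real(np.fft.ifft2(spec * amp))
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-15:  # exponent huge / degenerate: flat gray
        img = np.full_like(img, BACKGROUND_LEVEL)
    else:
        img = (img - lo) / (hi - lo)
    return Image(pixels=img, pixel_pitch_um=pixel_pitch_um)


def simulate_drift_trajectory(
    n_frames: int,
    diffusion_um2_per_frame: float = 10.0,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
    seed: int | np.random.Generator = 0,
    frame_period_ms: float = DEFAULT_FRAME_PERIOD_MS,
    msd_convention: str = "msd4dt",
) -> EyeTrajectory:
    """Discretized 2D Brownian drift.

    With the default ``msd_convention='msd4dt'`` the per-axis increment
    variance per frame is ``2 * D`` so the mean squared 2D displacement is
    ``4 * D * t`` after ``t`` frames.  The alternative ``'per_axis'`` treats
    D as the per-axis variance directly (MSD = 2 D t).  The micron path is
    cumulative; the pixel path is the micron path divided by the pixel pitch
    and rounded per frame (ties toward zero), so rounding error never
    accumulates.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if diffusion_um2_per_frame < 0:
        raise ValueError("diffusion constant must be >= 0")
    if msd_convention == "msd4dt":
        axis_var = 2.0 * diffusion_um2_per_frame
    elif msd_convention == "per_axis":
        axis_var = diffusion_um2_per_frame
    else:
        raise ValueError(f"unknown msd_convention: {msd_convention!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.normal(scale=np.sqrt(axis_var), size=(n_frames, 2))
    steps[0] = 0.0
    um = np.cumsum(steps, axis=0)
    with np.errstate(invalid="ignore"):
        px = _round_half_toward_zero(np.divide(um, pixel_pitch_um))
    px = np.nan_to_num(px).astype(int)
    return EyeTrajectory(
        displacements_px=px, displacements_um=um, frame_period_ms=frame_period_ms
    )


def _n_frames_for(duration_ms: float, frame_period_ms: float, what: str) -> int:
    n = duration_ms / frame_period_ms
    if duration_ms < 0 or abs(n - round(n)) > 1e-6 * max(1.0, n):
        raise ValueError(
            f"{what}={duration_ms} ms is not a nonnegative multiple of the "
            f"frame period {frame_period_ms} ms"
        )
    return int(round(n))


def render_flashed_trial(
    image: Image,
    flash_ms: float = 100.0,
    gray_ms: float = 400.0,
    frame_period_ms: float = DEFAULT_FRAME_PERIOD_MS,
    background_level: float = BACKGROUND_LEVEL,
) -> StimulusMovie:
    """Image shown for ``flash_ms`` then a uniform gray screen for ``gray_ms``."""
    n_flash = _n_frames_for(flash_ms, frame_period_ms, "flash_ms")
    n_gray = _n_frames_for(gray_ms, frame_period_ms, "gray_ms")
    if n_flash + n_gray == 0:
        raise ValueError("trial must contain at least one frame")
    h, w = image.shape
    frames = np.empty((n_flash + n_gray, h, w))
    frames[:n_flash] = image.pixels
    frames[n_flash:] = background_level
    return StimulusMovie(
        frames=frames,
        frame_period_ms=frame_period_ms,
        pixel_pitch_um=image.pixel_pitch_um,
        background_level=background_level,
    )


def render_jittered_trial(
    image: Image,
    trajectory: EyeTrajectory,
    background_level: float = BACKGROUND_LEVEL,
) -> StimulusMovie:
    """Present one image for the whole trial, shifted per frame by the drift path."""
    h, w = image.shape
    px = trajectory.displacements_px
    if np.any(np.abs(px[:, 0]) >= h) or np.any(np.abs(px[:, 1]) >= w):
        raise ValueError("trajectory shift exceeds the image extent")
    frames = np.stack(
        [shift_image(image.pixels, dy, dx, background_level) for dy, dx in px]
    )
    return StimulusMovie(
        frames=frames,
        frame_period_ms=trajectory.frame_period_ms,
        pixel_pitch_um=image.pixel_pitch_um,
        background_level=background_level,
        trajectory=trajectory,
    )
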