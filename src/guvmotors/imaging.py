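"""Synthetic microscopy rendering and z-stack fluorescence quantification.

Two modalities are emulated with a Gaussian point-spread stand-in: single
bright-field-like frames for particle tracking, and 45-plane confocal-like
z-stacks whose summed fluorescence serves as a relative readout of the
coacervate concentration inside each GUV. Only relative intensities
matter downstream, so no optics model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameStack",
    "render_frame",
    "render_zstack",
    "total_fluorescence",
    "classify_concentration",
]

#: Default number of confocal planes per stack
N_PLANES_DEFAULT = 45

#: Concentration group thresholds, arbitrary units
LOW_CUT_DEFAULT = 100.0
HIGH_CUT_DEFAULT = 175.0


@dataclass
class FrameStack:
    """Pixel data (planes x height x width, arbitrary units) with
    physical pixel size and, for z-stacks, plane spacing."""

    pixels: np.ndarray
    pixel_size: float          # um/px
    z_spacing: float = 0.0     # um between planes (0 for single frames)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None, :, :]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (planes, height, width)")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]


def _gaussian_spots_2d(shape: tuple[int, int], xy_px: np.ndarray,
                       sigma_px: float, amplitude: float) -> np.ndarray:
    """Sum of unit-integral 2D Gaussians (times ``amplitude``) at
    sub-pixel centres ``xy_px`` (x, y in pixel units)."""
    h, w = shape
    img = np.zeros((h, w))
    half = int(np.ceil(5 * sigma_px))
    ys = np.arange(h)
    xs = np.arange(w)
    for x0, y0 in xy_px:
        x_lo, x_hi = max(0, int(x0) - half), min(w, int(x0) + half + 1)
        y_lo, y_hi = max(0, int(y0) - half), min(h, int(y0) + half + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        gx = np.exp(-0.5 * ((xs[x_lo:x_hi] - x0) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((ys[y_lo:y_hi] - y0) / sigma_px) ** 2)
        img[y_lo:y_hi, x_lo:x_hi] += (
            amplitude / (2 * np.pi * sigma_px**2)) * np.outer(gy, gx)
    return img


def render_frame(xy_positions: np.ndarray, psf_sigma: float = 0.4,
                 pixel_size: float = 0.2, noise_sd: float = 0.0,
                 fov: float = 40.0, intensity: float = 1.0,
                 rng: np.random.Generator | None = None) -> FrameStack:
    """Render one 2D frame of point particles.

    Each particle contributes an isotropic Gaussian spot of integrated
    intensity ``intensity`` (a.u.) and width ``psf_sigma`` (um); optional
    additive Gaussian background noise of SD ``noise_sd``. Positions are
    um relative to the field-of-view corner; the field is ``fov`` um
    square.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    xy = np.atleast_2d(np.asarray(xy_positions, dtype=float)) if np.size(xy_positions) else np.empty((0, 2))
    n_px = int(round(fov / pixel_size))
    sigma_px = psf_sigma / pixel_size
    # intensity is per-um^2 integral; convert to per-pixel-area integral
    amp_px = intensity
    img = _gaussian_spots_2d((n_px, n_px), xy / pixel_size, sigma_px, amp_px)
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
    return FrameStack(pixels=img, pixel_size=pixel_size)


def render_zstack(positions_3d: np.ndarray, n_planes: int = N_PLANES_DEFAULT,
                  psf_sigma_xy: float = 0.4, psf_sigma_z: float = 0.8,
                  pixel_size: float = 0.2, z_spacing: float = 0.5,
                  fov: float = 40.0, intensity: float = 1.0,
                  noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None) -> FrameStack:
    """Render a confocal-like z-stack (default 45 planes).

    Each particle is a separable 3D Gaussian sampled on the plane grid;
    its total stack-integrated intensity is ``intensity`` a.u. per unit
    z-spacing coverage, so summed fluorescence scales with particle count
    away from the stack edges. The z grid is centred on z = 0.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    if psf_sigma_xy <= 0 or psf_sigma_z <= 0:
        raise ValueError("PSF widths must be positive")
    pos = np.atleast_2d(np.asarray(positions_3d, dtype=float)) if np.size(positions_3d) else np.empty((0, 3))
    n_px = int(round(fov / pixel_size))
    z_grid = (np.arange(n_planes) - (n_planes - 1) / 2.0) * z_spacing
    stack = np.zeros((n_planes, n_px, n_px))
    sigma_px = psf_sigma_xy / pixel_size
    for x, y, z in pos:
        # z weight normalised so the plane-summed intensity integrates to 1
        wz = np.exp(-0.5 * ((z_grid - z) / psf_sigma_z) ** 2)
        wz *= z_spacing / (psf_sigma_z * np.sqrt(2 * np.pi))
        for p in np.nonzero(wz > 1e-8)[0]:
            stack[p] += _gaussian_spots_2d(
                (n_px, n_px), np.array([[x, y]]) / pixel_size, sigma_px,
                intensity * wz[p])
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        stack = np.clip(stack + rng.normal(0.0, noise_sd, stack.shape), 0.0, None)
    return FrameStack(pixels=stack, pixel_size=pixel_size, z_spacing=z_spacing)


def total_fluorescence(stack: FrameStack, background: float = 0.0) -> float:
    """Summed fluorescence over all planes and pixels (a.u.) after
    per-pixel background subtraction clamped at zero — the relative
    coacervate-concentration readout for one GUV."""
    px = stack.pixels - background
    return float(np.clip(px, 0.0, None).sum())


def classify_concentration(f: float, low_cut: float = LOW_CUT_DEFAULT,
                           high_cut: float = HIGH_CUT_DEFAULT) -> str:
    """Concentration group from total fluorescence: below ``low_cut`` is
    low, between the cuts (inclusive) medium, above ``high_cut`` high."""
    if f < 0:
        raise ValueError("fluorescence must be non-negative")
    if f < low_cut:
        return "low"
    if f <= high_cut:
        return "medium"
    return "high"
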