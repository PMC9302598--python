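"""Synthetic fluorescence movie rendering and TIFF I/O.

Renders tracked loci as pixel-integrated 2D Gaussian point-spread profiles
with Poisson photon statistics, constant background and Gaussian read
noise, emulating streamed EMCCD acquisition of punctate nuclear loci.
Movies are written as multi-page unsigned 16-bit TIFF with a JSON sidecar
holding the frame interval and pixel size; the ground-truth spot registry
travels as CSV.

Coordinate convention: pixel (row i, col j) has its center at
((j + 0.5)·pixel_size, (i + 0.5)·pixel_size) µm; x maps to columns, y to
rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.special import ndtr

from .tracks import Track

__all__ = ["ImagingParams", "MovieStack", "render_movie", "write_movie", "read_movie"]


@dataclass(frozen=True)
class ImagingParams:
    """Camera and optics model for rendering.

    pixel_size : µm per pixel
    frame_shape : (rows, cols) in pixels
    psf_sigma : Gaussian PSF s.d. in µm
    photons_per_spot : expected photon count per locus per frame
    background : mean background counts per pixel
    gaussian_read_noise : read-noise s.d. in counts
    """

    pixel_size: float = 0.16
    frame_shape: tuple[int, int] = (512, 512)
    psf_sigma: float = 0.12
    photons_per_spot: float = 1000.0
    background: float = 10.0
    gaussian_read_noise: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.psf_sigma, self.background, self.gaussian_read_noise) < 0 or (
            self.pixel_size <= 0 or self.psf_sigma <= 0
        ):
            raise ValueError("imaging parameters must be positive")
        if self.photons_per_spot < 0:
            raise ValueError("photons_per_spot must be non-negative")
        if self.psf_sigma < self.pixel_size / 4:
            raise ValueError("psf_sigma must be at least pixel_size/4 to be renderable")
        if min(self.frame_shape) < 1:
            raise ValueError("frame_shape must be positive")


@dataclass
class MovieStack:
    """Frame stack with acquisition metadata and optional truth registry."""

    frames: np.ndarray  # (T, rows, cols) uint16
    dt: float
    pixel_size: float
    truth: pd.DataFrame | None = None  # columns: frame, track_id, x_um, y_um

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _spot_profile(center_px: float, n: int, lo: int, hi: int, psf_px: float) -> np.ndarray:
    """Flux fraction of a pixel-integrated 1D Gaussian over pixels lo..hi-1."""
    edges = np.arange(lo, hi + 1, dtype=float)
    cdf = ndtr((edges - center_px) / psf_px)
    return cdf[1:] - cdf[:-1]


def render_movie(
    tracks: list[Track],
    imaging: ImagingParams,
    seed: int,
    n_frames: int | None = None,
    use_true_positions: bool = True,
) -> MovieStack:
    """Render trajectories into a noisy movie with a truth registry.

    Each locus present in a frame contributes a pixel-integrated symmetric
    Gaussian of s.d. ``psf_sigma`` centred at its (true, when available)
    position; per-pixel counts are Poisson around signal + background, plus
    Gaussian read noise. Identical inputs and seed give a bit-identical
    stack.
    """
    if not tracks:
        raise ValueError("render_movie requires at least one track")
    rng = np.random.default_rng(seed)
    rows, cols = imaging.frame_shape
    ps = imaging.pixel_size
    fov_x, fov_y = cols * ps, rows * ps
    if n_frames is None:
        n_frames = int(max(tr.frames[-1] for tr in tracks)) + 1

    # validate coordinates before touching the RNG
    for tr in tracks:
        x = tr.x_true if (use_true_positions and tr.x_true is not None) else tr.x
        y = tr.y_true if (use_true_positions and tr.y_true is not None) else tr.y
        bad = (x < 0) | (x >= fov_x) | (y < 0) | (y >= fov_y)
        if np.any(bad):
            f = int(tr.frames[np.argmax(bad)])
            raise ValueError(
                f"track {tr.track_id} leaves the field of view at frame {f}"
            )

    psf_px = imaging.psf_sigma / ps
    half = int(np.ceil(5 * psf_px)) + 1
    expected = np.full((n_frames, rows, cols), float(imaging.background))
    truth_rows = []
    for tr in tracks:
        x = tr.x_true if (use_true_positions and tr.x_true is not None) else tr.x
        y = tr.y_true if (use_true_positions and tr.y_true is not None) else tr.y
        for k, f in enumerate(tr.frames):
            if f >= n_frames:
                continue
            cx, cy = x[k] / ps, y[k] / ps  # continuous pixel coordinates
            c0, c1 = max(0, int(cx) - half), min(cols, int(cx) + half + 1)
            r0, r1 = max(0, int(cy) - half), min(rows, int(cy) + half + 1)
            if c0 >= c1 or r0 >= r1:
                continue
            px = _spot_profile(cx, cols, c0, c1, psf_px)
            py = _spot_profile(cy, rows, r0, r1, psf_px)
            expected[f, r0:r1, c0:c1] += imaging.photons_per_spot * np.outer(py, px)
            truth_rows.append((int(f), tr.track_id, float(x[k]), float(y[k])))

    counts = rng.poisson(expected).astype(float)
    if imaging.gaussian_read_noise > 0:
        counts += rng.normal(0.0, imaging.gaussian_read_noise, size=counts.shape)
    frames = np.clip(np.rint(counts), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    truth = pd.DataFrame(truth_rows, columns=["frame", "track_id", "x_um", "y_um"])
    truth = truth.sort_values(["frame", "track_id"]).reset_index(drop=True)
    return MovieStack(frames=frames, dt=tracks[0].dt, pixel_size=ps, truth=truth)


def write_movie(stack: MovieStack, path) -> None:
    """Write multi-page TIFF + JSON sidecar (+ truth CSV when present)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"dt_s": stack.dt, "pixel_size_um": stack.pixel_size}, indent=2)
    )
    if stack.truth is not None:
        stack.truth.to_csv(path.with_suffix(".truth.csv"), index=False)


def read_movie(path) -> MovieStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    truth_path = path.with_suffix(".truth.csv")
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return MovieStack(
        frames=frames,
        dt=float(meta["dt_s"]),
        pixel_size=float(meta["pixel_size_um"]),
        truth=truth,
    )
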