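"""LoG spot detection, subpixel refinement and trajectory linking.

Detection follows the standard Laplacian-of-Gaussian recipe for
diffraction-limited puncta: the image is filtered with a scale-normalized
negated LoG kernel matched to the expected spot radius and local maxima
above a quality threshold are kept, with duplicates inside one spot radius
suppressed. Positions are refined by least-squares 2D Gaussian fits (with
an intensity-weighted centroid fallback). Linking solves, per frame pair,
an optimal bipartite assignment (linear assignment problem with birth and
death slots) on squared displacement, with gap closing up to ``max_gap``
missed frames and the search radius scaled by sqrt(gap+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .movie import MovieStack
from .tracks import Track

__all__ = [
    "SpotDetection",
    "detect_spots",
    "refine_subpixel",
    "link_tracks",
    "filter_tracks",
    "track_movie",
]


@dataclass
class SpotDetection:
    """One detected locus: continuous µm coordinates, pixel-center convention."""

    frame: int
    x: float
    y: float
    intensity: float
    quality: float


def log_response(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized negated LoG response (bright blobs -> positive peaks)."""
    return -(sigma_px**2) * ndimage.gaussian_laplace(image.astype(float), sigma_px)


def detect_spots(
    image: np.ndarray,
    pixel_size: float,
    expected_radius: float,
    quality_threshold: float,
    frame_index: int = 0,
) -> list[SpotDetection]:
    """Detect punctate loci in one frame.

    The LoG scale is ``expected_radius / sqrt(2)`` (the radius at which the
    LoG response of a Gaussian blob peaks); maxima closer than one expected
    radius are suppressed, keeping the higher-quality one.

    Parameters
    ----------
    image : 2D array
    pixel_size : µm per pixel
    expected_radius : expected spot radius, µm
    quality_threshold : minimum filter response at the maximum
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty frame")
    if not np.all(np.isfinite(image)):
        raise ValueError("frame contains non-finite pixels")
    if expected_radius <= 0:
        raise ValueError("expected_radius must be positive")
    radius_px = expected_radius / pixel_size
    sigma_px = radius_px / np.sqrt(2.0)
    resp = log_response(image, sigma_px)
    peaks = peak_local_max(
        resp,
        min_distance=max(1, int(round(radius_px))),
        threshold_abs=quality_threshold,
        exclude_border=False,
    )
    out = []
    for r, c in peaks:
        out.append(
            SpotDetection(
                frame=frame_index,
                x=(c + 0.5) * pixel_size,
                y=(r + 0.5) * pixel_size,
                intensity=float(image[r, c]),
                quality=float(resp[r, c]),
            )
        )
    out.sort(key=lambda s: -s.quality)
    return out


def _gauss2d(coords, amp, x0, y0, sd, offset):
    xv, yv = coords
    return (amp * np.exp(-((xv - x0) ** 2 + (yv - y0) ** 2) / (2 * sd**2)) + offset).ravel()


def refine_subpixel(
    image: np.ndarray,
    spots: list[SpotDetection],
    pixel_size: float,
    window: int = 7,
) -> list[SpotDetection]:
    """Refine detections to subpixel precision by 2D Gaussian fitting.

    Each spot's position is replaced by the centre of a least-squares
    symmetric 2D Gaussian fitted in a ``window``×``window`` patch; if the
    fit does not converge an intensity-weighted centroid (background = patch
    minimum) is used. Spots whose window overlaps the image border are kept
    at their original position with a warning.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    image = np.asarray(image, dtype=float)
    half = window // 2
    rows, cols = image.shape
    out = []
    for s in spots:
        c = int(s.x / pixel_size)
        r = int(s.y / pixel_size)
        if r - half < 0 or r + half >= rows or c - half < 0 or c + half >= cols:
            warnings.warn(
                f"spot at frame {s.frame} ({s.x:.2f}, {s.y:.2f}) µm too close to the "
                "border for refinement; keeping detector position",
                stacklevel=2,
            )
            out.append(s)
            continue
        patch = image[r - half : r + half + 1, c - half : c + half + 1]
        # continuous pixel coordinates of the patch (pixel centers at k+0.5)
        yy, xx = np.mgrid[r - half : r + half + 1, c - half : c + half + 1]
        xx = xx + 0.5
        yy = yy + 0.5
        lo = float(patch.min())
        amp0 = float(patch.max() - lo)
        p0 = [max(amp0, 1e-6), c + 0.5, r + 0.5, 1.5, lo]
        x0 = y0 = None
        try:
            # unconstrained Levenberg-Marquardt is much faster than a
            # bounded solver; containment is checked afterwards instead
            popt, _ = optimize.curve_fit(
                _gauss2d, (xx, yy), patch.ravel(), p0=p0, method="lm", maxfev=800
            )
            if (
                abs(popt[1] - (c + 0.5)) <= half
                and abs(popt[2] - (r + 0.5)) <= half
                and popt[0] > 0
            ):
                x0, y0, amp = popt[1], popt[2], popt[0]
        except RuntimeError:
            pass
        if x0 is None:  # non-convergence or escape: intensity-weighted centroid
            w = np.clip(patch - lo, 0, None)
            tot = w.sum()
            if tot <= 0:
                out.append(s)
                continue
            x0 = float((w * xx).sum() / tot)
            y0 = float((w * yy).sum() / tot)
            amp = amp0
        out.append(
            SpotDetection(
                frame=s.frame,
                x=float(x0 * pixel_size),
                y=float(y0 * pixel_size),
                intensity=float(amp),
                quality=s.quality,
            )
        )
    return out


def _assign(cost: np.ndarray, track_thresh2: np.ndarray, det_thresh2: float):
    """Jaqaman-style LAP with birth/death slots.

    cost is (n_tracks, n_dets) squared distances with np.inf where the link
    exceeds its radius. Returns list of (track_idx, det_idx) accepted links.
    """
    nt, nd = cost.shape
    if nt == 0 or nd == 0:
        return []
    big = 1e12
    block = np.full((nt + nd, nt + nd), big)
    finite = np.isfinite(cost)
    block[:nt, :nd][finite] = cost[finite]
    for i in range(nt):  # death slot: leave track unlinked at its radius cost
        block[i, nd + i] = track_thresh2[i]
    for j in range(nd):  # birth slot: start a new track at base radius cost
        block[nt + j, j] = det_thresh2
    block[nt:, nd:] = 0.0
    rows, cols = optimize.linear_sum_assignment(block)
    links = []
    for i, j in zip(rows, cols):
        if i < nt and j < nd and finite[i, j]:
            links.append((i, j))
    return links


def link_tracks(
    detections: list[list[SpotDetection]],
    max_disp: float,
    max_gap: int = 2,
    dt: float = 0.1,
) -> list[Track]:
    """Link per-frame detections into trajectories.

    Per frame pair, the assignment between open track ends and new
    detections minimizes total squared displacement among links shorter
    than ``max_disp`` (scaled by sqrt(gap+1) when bridging up to ``max_gap``
    missed frames). Unlinked detections start new tracks; tracks with more
    than ``max_gap`` consecutive missed frames are closed. Tracks shorter
    than 2 detections are dropped.

    Parameters
    ----------
    detections : list of per-frame detection lists, sorted by frame; the
        ``frame`` attribute of each detection is authoritative.
    max_disp : µm per frame search radius.
    max_gap : maximum bridged gap, frames.
    dt : frame interval, s, stamped on the output tracks.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    open_tracks: list[dict] = []
    done: list[dict] = []
    for frame_dets in detections:
        if not frame_dets:
            continue
        f = frame_dets[0].frame
        # close tracks that can no longer be bridged
        still_open = []
        for trk in open_tracks:
            if f - trk["last_frame"] - 1 > max_gap:
                done.append(trk)
            else:
                still_open.append(trk)
        open_tracks = still_open

        nt, nd = len(open_tracks), len(frame_dets)
        if nt:
            cost = np.full((nt, nd), np.inf)
            thresh2 = np.empty(nt)
            for i, trk in enumerate(open_tracks):
                gap = f - trk["last_frame"] - 1
                radius = max_disp * np.sqrt(gap + 1.0)
                thresh2[i] = radius**2
                lx, ly = trk["dets"][-1].x, trk["dets"][-1].y
                for j, d in enumerate(frame_dets):
                    d2 = (d.x - lx) ** 2 + (d.y - ly) ** 2
                    if d2 <= radius**2:
                        cost[i, j] = d2
            links = _assign(cost, thresh2, max_disp**2)
        else:
            links = []
        linked_dets = set()
        for i, j in links:
            open_tracks[i]["dets"].append(frame_dets[j])
            open_tracks[i]["last_frame"] = f
            linked_dets.add(j)
        for j, d in enumerate(frame_dets):
            if j not in linked_dets:
                open_tracks.append({"dets": [d], "last_frame": f})
    done.extend(open_tracks)

    tracks = []
    tid = 0
    for trk in done:
        dets = trk["dets"]
        if len(dets) < 2:
            continue
        tracks.append(
            Track(
                track_id=tid,
                frames=np.array([d.frame for d in dets]),
                x=np.array([d.x for d in dets]),
                y=np.array([d.y for d in dets]),
                dt=dt,
            )
        )
        tid += 1
    return tracks


def filter_tracks(tracks: list[Track], min_duration: float = 20.0) -> list[Track]:
    """Keep tracks whose time span is at least ``min_duration`` seconds.

    The boundary is inclusive: a 201-frame track at Δt = 0.1 s (span exactly
    20 s) is retained.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be non-negative")
    return [tr for tr in tracks if tr.duration >= min_duration]


def track_movie(
    stack: MovieStack,
    expected_radius: float = 0.3,
    quality_threshold: float = 5.0,
    max_disp: float = 0.5,
    max_gap: int = 2,
    min_duration: float = 20.0,
    refine_window: int = 7,
) -> list[Track]:
    """Detect, refine and link a whole movie; returns duration-filtered tracks."""
    per_frame = []
    for f in range(stack.n_frames):
        spots = detect_spots(
            stack.frames[f],
            pixel_size=stack.pixel_size,
            expected_radius=expected_radius,
            quality_threshold=quality_threshold,
            frame_index=f,
        )
        spots = refine_subpixel(stack.frames[f], spots, stack.pixel_size, window=refine_window)
        per_frame.append(spots)
    tracks = link_tracks(per_frame, max_disp=max_disp, max_gap=max_gap, dt=stack.dt)
    return filter_tracks(tracks, min_duration=min_duration)
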