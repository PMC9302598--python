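"""Scoring recovered tracks against a ground-truth registry.

Used to validate the detection/linking stage on rendered synthetic movies:
each recovered detection is attributed to the nearest truth spot in its
frame (within a match radius), and per-truth-track statistics — coverage,
identity purity, positional RMSE — are aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Track

__all__ = ["TrackRecovery", "match_tracks"]


@dataclass
class TrackRecovery:
    """Recovery metrics for one collection of truth tracks.

    recovered_single : fraction of truth tracks covered (>= min_coverage of
        their frames) by exactly one recovered track whose detections all
        attribute to that truth id.
    rmse_px : positional RMSE per coordinate over all matched detections,
        in pixels.
    n_swaps : matched detections whose recovered track attributes to more
        than one truth id (identity switches).
    """

    recovered_single: float
    rmse_px: float
    n_swaps: int
    n_truth: int
    per_truth: pd.DataFrame


def match_tracks(
    truth: pd.DataFrame,
    tracks: list[Track],
    pixel_size: float,
    match_radius: float = 0.3,
    min_coverage: float = 0.9,
) -> TrackRecovery:
    """Attribute recovered detections to truth spots and score recovery.

    Parameters
    ----------
    truth : DataFrame with columns frame, track_id, x_um, y_um.
    tracks : recovered tracks.
    pixel_size : µm per pixel, for reporting RMSE in pixels.
    match_radius : µm; a detection farther than this from every truth spot
        in its frame is unmatched.
    min_coverage : fraction of a truth track's frames that must be covered
        by a single pure recovered track to count as recovered.
    """
    by_frame = {f: g for f, g in truth.groupby("frame")}
    rows = []
    sq_err = []
    for tr in tracks:
        for k, f in enumerate(tr.frames):
            g = by_frame.get(int(f))
            if g is None:
                continue
            d2 = (g["x_um"].to_numpy() - tr.x[k]) ** 2 + (g["y_um"].to_numpy() - tr.y[k]) ** 2
            j = int(np.argmin(d2))
            if d2[j] <= match_radius**2:
                tid = int(g["track_id"].iloc[j])
                rows.append((tr.track_id, int(f), tid))
                sq_err.append(
                    ((tr.x[k] - g["x_um"].iloc[j]) ** 2 + (tr.y[k] - g["y_um"].iloc[j]) ** 2) / 2
                )
    matched = pd.DataFrame(rows, columns=["rec_id", "frame", "truth_id"])
    rmse_px = float(np.sqrt(np.mean(sq_err))) / pixel_size if sq_err else np.inf

    # identity swaps: recovered tracks attributing to >1 truth id
    n_swaps = 0
    impure = set()
    if len(matched):
        for rec_id, g in matched.groupby("rec_id"):
            ids = g["truth_id"].to_numpy()
            switches = int(np.sum(ids[1:] != ids[:-1]))
            if switches:
                n_swaps += switches
                impure.add(rec_id)

    per_truth_rows = []
    truth_ids = sorted(truth["track_id"].unique())
    for tid in truth_ids:
        n_frames = int((truth["track_id"] == tid).sum())
        sub = matched[matched["truth_id"] == tid] if len(matched) else matched
        ok = False
        if len(sub):
            best_rec, best_cov = None, 0
            for rec_id, g in sub.groupby("rec_id"):
                if len(g) > best_cov:
                    best_rec, best_cov = rec_id, len(g)
            ok = best_cov >= min_coverage * n_frames and best_rec not in impure
        per_truth_rows.append({"truth_id": tid, "n_frames": n_frames, "recovered_single": ok})
    per_truth = pd.DataFrame(per_truth_rows)
    frac = float(per_truth["recovered_single"].mean()) if len(per_truth) else 0.0
    return TrackRecovery(
        recovered_single=frac,
        rmse_px=rmse_px,
        n_swaps=n_swaps,
        n_truth=len(truth_ids),
        per_truth=per_truth,
    )
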