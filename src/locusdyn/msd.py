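"""Time-averaged MSD computation and anomalous-diffusion fitting.

The per-trajectory time-averaged mean squared displacement at lag nΔt is

    MSD(nΔt) = (1 / (N−n)) Σ_{i=1}^{N−n} [x(i+n)−x(i)]² + [y(i+n)−y(i)]²

for a gapless track of N samples; for gapped tracks the average runs over
the index pairs that are both present. Ensemble curves are unweighted means
of per-track TA-MSD values. The 2D anomalous-diffusion law MSD = 4·D·t^α is
fitted by linear regression of log MSD on log t, which gives closed-form
standard errors for both α (the slope) and D (from the intercept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import Track

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "compute_tamsd",
    "ensemble_msd",
    "fit_anomalous",
    "fit_ensemble",
    "static_offset_from_tracks",
    "estimate_dapp",
    "dapp_table",
]


@dataclass
class MSDCurve:
    """Lag-time → MSD pairs with per-lag sample counts.

    lags are in seconds (n·Δt), msd in µm², counts is the number of averaged
    squared displacements (per-track curve) or contributing tracks
    (ensemble curve) at each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "msd_um2": self.msd, "count": self.counts})


@dataclass
class DiffusionFit:
    """Result of the 4Dt^α fit.

    D is the generalized diffusion coefficient (µm²/s^α), alpha the
    anomalous exponent. Standard errors come from the log-log regression.
    """

    D: float
    alpha: float
    se_D: float
    se_alpha: float
    n_points_fit: int
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "alpha": self.alpha,
            "se_D": self.se_D,
            "se_alpha": self.se_alpha,
            "n_points_fit": self.n_points_fit,
            "r_squared": self.r_squared,
        }


def compute_tamsd(track: Track, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one track.

    Parameters
    ----------
    track : Track
    max_lag : int, optional
        Largest lag in frames; defaults to the track's frame span minus one.
        Lags with no present index pair (possible with gaps) are omitted.
    """
    n = len(track)
    if n < 2:
        raise ValueError("track must have at least 2 samples")
    span = int(track.frames[-1] - track.frames[0])
    if max_lag is None:
        max_lag = span
    max_lag = min(int(max_lag), span)
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")

    x, y, frames = track.x, track.y, track.frames
    lags, msds, counts = [], [], []
    gapless = track.is_gapless
    for lag in range(1, max_lag + 1):
        if gapless:
            dx = x[lag:] - x[:-lag]
            dy = y[lag:] - y[:-lag]
        else:
            # pair index i with the index holding frame[i] + lag, if present
            target = frames + lag
            j = np.searchsorted(frames, target)
            ok = (j < n) & (frames[np.minimum(j, n - 1)] == target)
            if not np.any(ok):
                continue
            i = np.nonzero(ok)[0]
            dx = x[j[i]] - x[i]
            dy = y[j[i]] - y[i]
        lags.append(lag * track.dt)
        msds.append(np.mean(dx * dx + dy * dy))
        counts.append(len(dx))
    return MSDCurve(np.array(lags), np.array(msds), np.array(counts))


def ensemble_msd(tracks: list[Track], max_lag: int) -> MSDCurve:
    """Unweighted average of per-track TA-MSD curves.

    At each lag the mean runs over all tracks long enough to contribute that
    lag; counts records the number of contributing tracks.
    """
    if len(tracks) == 0:
        raise ValueError("ensemble_msd requires at least one track")
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    dt = tracks[0].dt
    for tr in tracks:
        if abs(tr.dt - dt) > 1e-12:
            raise ValueError("all tracks must share one frame interval")
        span = int(tr.frames[-1] - tr.frames[0])
        curve = compute_tamsd(tr, max_lag=min(max_lag, span))
        idx = np.rint(curve.lags / dt).astype(int) - 1
        sums[idx] += curve.msd
        counts[idx] += 1
    present = counts > 0
    lags = (np.arange(1, max_lag + 1) * dt)[present]
    return MSDCurve(lags, sums[present] / counts[present], counts[present])


def fit_anomalous(
    curve: MSDCurve,
    fit_fraction: float = 0.25,
    static_offset: float = 0.0,
) -> DiffusionFit:
    """Fit MSD = 4·D·t^α by log-log linear regression.

    The regression uses the first ``fit_fraction`` of available lags
    (at least 4), where TA-MSD estimates are best determined. α is the
    slope and D = exp(intercept)/4; standard errors propagate from the
    regression coefficients.

    ``static_offset`` (µm²) is subtracted from the curve before fitting;
    pass ``4·σ_loc²`` from a fixed-cell calibration to correct the constant
    localization-noise floor that otherwise flattens the short-lag slope.
    Non-positive corrected values are dropped; fewer than 4 surviving points
    is an error.
    """
    if not (0 < fit_fraction <= 1):
        raise ValueError("fit_fraction must lie in (0, 1]")
    n_fit = max(4, int(np.ceil(fit_fraction * len(curve.lags))))
    t = curve.lags[:n_fit]
    m = curve.msd[:n_fit] - static_offset
    keep = m > 0
    t, m = t[keep], m[keep]
    if len(t) < 4:
        raise ValueError("fewer than 4 positive MSD values in the fit range")
    res = stats.linregress(np.log(t), np.log(m))
    alpha = float(res.slope)
    D = float(np.exp(res.intercept) / 4.0)
    return DiffusionFit(
        D=D,
        alpha=alpha,
        se_D=float(D * res.intercept_stderr),
        se_alpha=float(res.stderr),
        n_points_fit=len(t),
        r_squared=float(res.rvalue**2),
    )


def static_offset_from_tracks(tracks: list[Track], max_lag: int = 20) -> float:
    """Static localization-noise floor (µm²) from fixed-cell tracks.

    For immobile loci the observed TA-MSD is flat at 4σ² where σ is the
    per-coordinate localization noise; the mean over the first ``max_lag``
    ensemble lags estimates that floor. Use the result as ``static_offset``
    in :func:`fit_anomalous` for live-cell curves acquired under the same
    imaging configuration.
    """
    curve = ensemble_msd(tracks, max_lag=max_lag)
    return float(np.mean(curve.msd))


def fit_ensemble(
    tracks: list[Track],
    max_lag: int,
    fit_fraction: float = 0.25,
    static_offset: float = 0.0,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[MSDCurve, DiffusionFit]:
    """Ensemble TA-MSD and 4Dt^α fit, with optional bootstrap errors.

    The regression standard errors of :func:`fit_anomalous` describe scatter
    about the fitted line, which understates the trajectory-sampling
    uncertainty of an ensemble curve (neighbouring lags are strongly
    correlated). With ``n_boot`` > 0, tracks are resampled with replacement
    and the fit repeated; the resulting standard deviations replace the
    regression standard errors in the returned fit.
    """
    curve = ensemble_msd(tracks, max_lag=max_lag)
    fit = fit_anomalous(curve, fit_fraction=fit_fraction, static_offset=static_offset)
    if n_boot > 0:
        # cache per-track curves once; resampled ensembles are weighted means
        rng = np.random.default_rng(seed)
        dt = tracks[0].dt
        sums = np.zeros((len(tracks), max_lag))
        present = np.zeros((len(tracks), max_lag), dtype=bool)
        for i, tr in enumerate(tracks):
            span = int(tr.frames[-1] - tr.frames[0])
            c = compute_tamsd(tr, max_lag=min(max_lag, span))
            idx = np.rint(c.lags / dt).astype(int) - 1
            sums[i, idx] = c.msd
            present[i, idx] = True
        alphas, ds = [], []
        for _ in range(n_boot):
            pick = rng.integers(0, len(tracks), size=len(tracks))
            cnt = present[pick].sum(axis=0)
            ok = cnt > 0
            msd_b = sums[pick].sum(axis=0)[ok] / cnt[ok]
            lags_b = (np.arange(1, max_lag + 1) * dt)[ok]
            try:
                fb = fit_anomalous(
                    MSDCurve(lags_b, msd_b, cnt[ok]),
                    fit_fraction=fit_fraction,
                    static_offset=static_offset,
                )
            except ValueError:
                continue
            alphas.append(fb.alpha)
            ds.append(fb.D)
        if len(alphas) >= 10:
            fit = DiffusionFit(
                D=fit.D,
                alpha=fit.alpha,
                se_D=float(np.std(ds, ddof=1)),
                se_alpha=float(np.std(alphas, ddof=1)),
                n_points_fit=fit.n_points_fit,
                r_squared=fit.r_squared,
            )
    return curve, fit


def estimate_dapp(track: Track, n_lags: int = 4) -> float:
    """Per-trajectory apparent diffusion constant, µm²/s.

    Ordinary least squares of TA-MSD over lags 1..n_lags against time with a
    free intercept; the intercept absorbs the constant localization-noise
    offset so D_app = slope/4 estimates the short-lag diffusivity. The value
    may be negative for effectively static loci (slope noise); callers that
    work on a log axis exclude and count those.
    """
    if len(track) < n_lags + 1:
        raise ValueError(f"track needs at least {n_lags + 1} samples for {n_lags} lags")
    curve = compute_tamsd(track, max_lag=n_lags)
    if len(curve.lags) < 2:
        raise ValueError("too few usable lags for the short-lag fit")
    slope = stats.linregress(curve.lags, curve.msd).slope
    return float(slope / 4.0)


def dapp_table(tracks: list[Track], n_lags: int = 4) -> pd.DataFrame:
    """Apparent diffusion constants for a track collection.

    Returns a DataFrame with track_id, d_app (µm²/s) and the ground-truth
    label when present. Tracks too short for the fit are skipped.
    """
    rows = []
    for tr in tracks:
        if len(tr) < n_lags + 1:
            continue
        rows.append(
            {
                "track_id": tr.track_id,
                "d_app": estimate_dapp(tr, n_lags=n_lags),
                "label": tr.label if tr.label is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=["track_id", "d_app", "label"])
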