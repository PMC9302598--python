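"""Synthetic trajectory generator for chromatin-locus motion.

Generates seeded 2D trajectories with the statistical structure the
downstream analysis assumes: mixtures of subdiffusive (fractional Brownian
motion), confined (reflected Brownian) and immobile loci, each observed
through additive Gaussian localization noise. Units are µm and seconds
throughout; the generalized diffusion coefficient ``D`` carries units
µm²/s^α so that the 2D ensemble law is ``MSD(t) = 4 D t^α``.

fBm paths are sampled exactly by Cholesky factorization of the
fractional-Gaussian-noise covariance; the analytic covariance
(:func:`fgn_covariance`) doubles as the oracle against which any faster
generator must be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import cholesky, toeplitz

from .tracks import Track

__all__ = [
    "MotionParams",
    "Component",
    "PopulationSpec",
    "fgn_covariance",
    "simulate_fbm",
    "simulate_confined",
    "simulate_immobile",
    "simulate_tracks",
    "sample_population",
    "sample_dapp_values",
]

MODELS = ("brownian", "fbm", "confined", "immobile")


@dataclass(frozen=True)
class MotionParams:
    """Parameters of one motion model.

    D : generalized diffusion coefficient, µm²/s^α (per the 2D law 4Dt^α)
    alpha : anomalous exponent in (0, 2]; 1 for Brownian; ignored for immobile
    box_side : confinement square side in µm (confined model only)
    sigma_loc : localization noise s.d. per coordinate, µm
    dt : frame interval, s
    n_steps : frames per trajectory
    d_log10_sd : trajectory-to-trajectory dispersion of D, in log10 units.
        0 gives a homogeneous population; positive values draw each track's
        diffusivity from a log-normal centred (in log10) on D, emulating
        the cell-to-cell and locus-to-locus heterogeneity that gives real
        D_app population peaks their width.
    """

    model: str
    D: float = 0.0
    alpha: float = 1.0
    box_side: float | None = None
    sigma_loc: float = 0.0
    dt: float = 0.1
    n_steps: int = 1200
    d_log10_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown motion model {self.model!r}")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.model != "immobile" and not (0 < self.alpha <= 2):
            raise ValueError("alpha must lie in (0, 2]")
        if self.model == "brownian" and self.alpha != 1:
            raise ValueError("brownian model requires alpha = 1")
        if self.model == "confined":
            if self.box_side is None or self.box_side <= 0:
                raise ValueError("confined model requires box_side > 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.d_log10_sd < 0:
            raise ValueError("d_log10_sd must be non-negative")


def fgn_covariance(n: int, hurst: float) -> np.ndarray:
    """Covariance matrix of n unit-variance fractional-Gaussian-noise steps.

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must lie in (0, 1)")
    k = np.arange(n, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    return toeplitz(gamma)


@lru_cache(maxsize=8)
def _fgn_cholesky(n: int, hurst_key: float) -> np.ndarray:
    # lower-triangular factor of the unit fGn covariance; cached because the
    # pipeline reuses one (n_steps, alpha) pair for hundreds of tracks
    return cholesky(fgn_covariance(n, hurst_key), lower=True)


def _track_diffusivities(
    params: MotionParams, n_tracks: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-track D values: constant, or log-normal around log10(D)."""
    if params.d_log10_sd == 0 or params.D == 0:
        return np.full(n_tracks, params.D)
    return 10.0 ** rng.normal(np.log10(params.D), params.d_log10_sd, size=n_tracks)


def _add_noise(pos: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return pos.copy()
    return pos + rng.normal(0.0, sigma, size=pos.shape)


def _build_tracks(
    x_true: np.ndarray,
    y_true: np.ndarray,
    params: MotionParams,
    rng: np.random.Generator,
    label: str | None,
    id_offset: int,
) -> list[Track]:
    """Wrap (n_tracks, n_steps) coordinate arrays into Track objects."""
    x_obs = _add_noise(x_true, params.sigma_loc, rng)
    y_obs = _add_noise(y_true, params.sigma_loc, rng)
    frames = np.arange(x_true.shape[1])
    return [
        Track(
            track_id=id_offset + i,
            frames=frames,
            x=x_obs[i],
            y=y_obs[i],
            dt=params.dt,
            label=label,
            x_true=x_true[i],
            y_true=y_true[i],
        )
        for i in range(x_true.shape[0])
    ]


def simulate_fbm(
    params: MotionParams,
    n_tracks: int,
    seed: int | np.random.Generator,
    label: str | None = None,
    id_offset: int = 0,
) -> list[Track]:
    """Simulate fBm trajectories with Hurst index H = alpha/2.

    Each coordinate is an independent fractional Brownian path scaled so the
    2D ensemble mean squared displacement is ``4 D t^alpha``. Per-coordinate
    increments over one frame have variance ``2 D dt^alpha`` with the exact
    long-range fGn correlation structure.
    """
    if params.model not in ("fbm", "brownian"):
        raise ValueError("simulate_fbm requires model 'fbm' or 'brownian'")
    if not (0 < params.alpha < 2):
        raise ValueError("fbm requires alpha in (0, 2)")
    if params.n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hurst = params.alpha / 2.0
    n_inc = params.n_steps - 1
    d_per_track = _track_diffusivities(params, n_tracks, rng)
    scale = (np.sqrt(2.0 * d_per_track) * params.dt**hurst)[:, None]
    if hurst == 0.5:
        # Brownian shortcut: independent increments, no factorization needed
        inc_x = scale * rng.standard_normal(size=(n_tracks, n_inc))
        inc_y = scale * rng.standard_normal(size=(n_tracks, n_inc))
    else:
        L = _fgn_cholesky(n_inc, round(hurst, 12))
        z = rng.standard_normal(size=(2, n_inc, n_tracks))
        inc_x = scale * (L @ z[0]).T
        inc_y = scale * (L @ z[1]).T
    x = np.concatenate([np.zeros((n_tracks, 1)), np.cumsum(inc_x, axis=1)], axis=1)
    y = np.concatenate([np.zeros((n_tracks, 1)), np.cumsum(inc_y, axis=1)], axis=1)
    return _build_tracks(x, y, params, rng, label, id_offset)


def _fold_reflecting(pos: np.ndarray, side: float) -> np.ndarray:
    """Map a free path onto [0, side] with reflecting boundaries."""
    m = np.mod(pos, 2.0 * side)
    return side - np.abs(m - side)


def simulate_confined(
    params: MotionParams,
    n_tracks: int,
    seed: int | np.random.Generator,
    label: str | None = None,
    id_offset: int = 0,
) -> list[Track]:
    """Brownian stepping inside a reflecting square of side ``box_side``.

    Initial positions are uniform in the square; per-step displacement s.d.
    is sqrt(2 D dt) per coordinate. The long-lag TA-MSD plateau is
    ``box_side²/3`` (mean squared separation of two uniform points in 2D).
    """
    if params.model != "confined":
        raise ValueError("simulate_confined requires model 'confined'")
    if params.box_side is None or params.box_side <= 0:
        raise ValueError("box_side must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    side = params.box_side
    step_sd = np.sqrt(2.0 * _track_diffusivities(params, n_tracks, rng) * params.dt)[:, None]
    x0 = rng.uniform(0.0, side, size=(n_tracks, 1))
    y0 = rng.uniform(0.0, side, size=(n_tracks, 1))
    n_inc = params.n_steps - 1
    if params.D == 0:
        x = np.repeat(x0, params.n_steps, axis=1)
        y = np.repeat(y0, params.n_steps, axis=1)
    else:
        dx = step_sd * rng.standard_normal(size=(n_tracks, n_inc))
        dy = step_sd * rng.standard_normal(size=(n_tracks, n_inc))
        x = _fold_reflecting(np.cumsum(np.concatenate([x0, dx], axis=1), axis=1), side)
        y = _fold_reflecting(np.cumsum(np.concatenate([y0, dy], axis=1), axis=1), side)
    return _build_tracks(x, y, params, rng, label, id_offset)


def simulate_immobile(
    params: MotionParams,
    n_tracks: int,
    seed: int | np.random.Generator,
    label: str | None = None,
    id_offset: int = 0,
) -> list[Track]:
    """Static loci observed through localization noise only.

    Emulates fixed-cell imaging: the true position never moves; the observed
    TA-MSD is flat at ``4 sigma_loc²`` for all lags ≥ 1.
    """
    if params.model != "immobile":
        raise ValueError("simulate_immobile requires model 'immobile'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = np.zeros((n_tracks, params.n_steps))
    y = np.zeros((n_tracks, params.n_steps))
    return _build_tracks(x, y, params, rng, label, id_offset)


def simulate_tracks(
    params: MotionParams,
    n_tracks: int,
    seed: int | np.random.Generator,
    label: str | None = None,
    id_offset: int = 0,
) -> list[Track]:
    """Dispatch to the simulator matching ``params.model``."""
    if params.model in ("fbm", "brownian"):
        return simulate_fbm(params, n_tracks, seed, label, id_offset)
    if params.model == "confined":
        return simulate_confined(params, n_tracks, seed, label, id_offset)
    return simulate_immobile(params, n_tracks, seed, label, id_offset)


@dataclass(frozen=True)
class Component:
    """One mixture component: a labelled motion model with a weight."""

    label: str
    params: MotionParams
    weight: float


@dataclass(frozen=True)
class PopulationSpec:
    """A weighted mixture of motion components defining one condition."""

    components: tuple[Component, ...]
    n_tracks: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be at least 1")
        w = np.array([c.weight for c in self.components], dtype=float)
        if len(w) == 0 or np.any(w <= 0):
            raise ValueError("component weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1 (tolerance 1e-9)")


def sample_population(spec: PopulationSpec) -> list[Track]:
    """Draw a labelled trajectory mixture.

    Component membership is multinomial in the weights; each track keeps its
    generating component's label so downstream recovery can be scored
    against truth. Localization noise is applied per component.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components], dtype=float)
    assignment = rng.choice(len(spec.components), size=spec.n_tracks, p=weights)
    tracks: list[Track] = []
    for ci, comp in enumerate(spec.components):
        n_c = int(np.sum(assignment == ci))
        if n_c == 0:
            continue
        child_seed = rng.integers(0, 2**31 - 1)
        tracks.extend(
            simulate_tracks(comp.params, n_c, int(child_seed), label=comp.label, id_offset=len(tracks))
        )
    # shuffle deterministically so component blocks are interleaved
    order = rng.permutation(len(tracks))
    out = []
    for new_id, idx in enumerate(order):
        tr = tracks[idx]
        tr.track_id = new_id
        out.append(tr)
    return out


def sample_dapp_values(
    weights, log10_means, log10_sds, n: int, seed: int
) -> np.ndarray:
    """Draw apparent diffusion constants from a log10-Gaussian mixture.

    Convenience sampler for testing the mixture decomposition directly
    against known component parameters, without simulating trajectories.
    Returns D values in µm²/s.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    logs = rng.normal(np.asarray(log10_means)[comp], np.asarray(log10_sds)[comp])
    return 10.0**logs
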