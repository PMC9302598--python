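"""Anchored Gaussian decomposition of apparent diffusion constants.

Per-trajectory D_app values from a cell population spread over orders of
magnitude and are multimodal: a fast population (global chromatin
movement), a slow population (local locus motion) and a fixed population
whose apparent diffusivity reflects only thermal/localization fluctuation.
The distribution is therefore analysed on the log10(D_app) axis: a
histogram density is fitted with a sum of up to three Gaussian peaks, the
fixed peak's location anchored at the fixed-cell calibration value D_fix.
When a peak cannot be supported by the data the fit falls back to fewer
components (3 → 2 → 1), mirroring how such distributions are reduced when a
population is absent under a perturbation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "DappDistribution",
    "FixedCellCalibration",
    "MixtureComponent",
    "MixtureFit",
    "MixtureError",
    "calibrate_dfix",
    "fit_mixture",
    "fit_with_fallback",
    "component_fractions",
]

COMPONENT_ORDER = ("fixed", "slow", "fast")


class MixtureError(RuntimeError):
    """All mixture fits failed; carries diagnostics."""


@dataclass
class DappDistribution:
    """Distribution of per-trajectory apparent diffusion constants.

    Holds the raw values (µm²/s), the log10 of the positive values, the
    count of excluded non-positive values, and a normalized histogram on the
    log10 axis (Freedman–Diaconis bins by default).
    """

    values: np.ndarray
    bins: int | str = "fd"
    min_bins: int = 30
    log_values: np.ndarray = field(init=False)
    n_excluded_nonpositive: int = field(init=False)
    bin_edges: np.ndarray = field(init=False)
    density: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        pos = self.values[self.values > 0]
        self.n_excluded_nonpositive = int(len(self.values) - len(pos))
        if len(pos) == 0:
            raise ValueError("no positive D_app values")
        self.log_values = np.log10(pos)
        edges = np.histogram_bin_edges(self.log_values, bins=self.bins)
        if len(edges) - 1 < self.min_bins:
            # multimodal log distributions have a large IQR, which makes
            # rule-based widths (fd, sturges, ...) too coarse to resolve
            # individual peaks; floor the resolution instead
            edges = np.histogram_bin_edges(self.log_values, bins=self.min_bins)
        self.density, self.bin_edges = np.histogram(
            self.log_values, bins=edges, density=True
        )

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_positive(self) -> int:
        return len(self.log_values)

    @classmethod
    def from_table(cls, table: pd.DataFrame, bins: int | str = "fd") -> "DappDistribution":
        return cls(table["d_app"].to_numpy(), bins=bins)


@dataclass
class FixedCellCalibration:
    """Fixed-cell anchor for the immobile component.

    d_fix is the mode of the fixed-cell D_app distribution (µm²/s),
    back-transformed from a single-Gaussian fit on the log10 axis;
    log10_sd is that fit's width, reused to bound the anchored component's
    width in population fits made under the same imaging configuration.
    """

    d_fix: float
    se: float
    n_tracks: int
    log10_sd: float

    def __post_init__(self) -> None:
        if self.d_fix <= 0:
            raise ValueError("d_fix must be positive")
        if self.n_tracks < 30:
            raise ValueError("calibration requires at least 30 tracks")

    def to_dict(self) -> dict:
        return {
            "d_fix": self.d_fix,
            "se": self.se,
            "n_tracks": self.n_tracks,
            "log10_sd": self.log10_sd,
        }


@dataclass
class MixtureComponent:
    label: str
    mean: float  # log10 µm²/s
    sd: float  # log10 units
    weight: float
    se_weight: float


@dataclass
class MixtureFit:
    """Gaussian components on the log10(D_app) axis with fractions."""

    components: list[MixtureComponent]
    anchored: bool
    fallback_applied: list[str]
    converged: bool
    rss: float
    dof: int
    n_excluded_nonpositive: int
    bin_edges: np.ndarray = field(repr=False, default=None)

    @property
    def fractions(self) -> dict[str, float]:
        """Percentages per label; absent labels are 0."""
        out = {label: 0.0 for label in COMPONENT_ORDER}
        for c in self.components:
            out[c.label] = 100.0 * c.weight
        return out

    def component(self, label: str) -> MixtureComponent | None:
        for c in self.components:
            if c.label == label:
                return c
        return None

    def to_dict(self) -> dict:
        return {
            "components": [
                {
                    "label": c.label,
                    "mean_log10": c.mean,
                    "sd_log10": c.sd,
                    "weight": c.weight,
                    "se_weight": c.se_weight,
                }
                for c in self.components
            ],
            "anchored": self.anchored,
            "fallback_applied": self.fallback_applied,
            "converged": self.converged,
            "rss": self.rss,
            "dof": self.dof,
            "fractions": self.fractions,
            "n_excluded_nonpositive": self.n_excluded_nonpositive,
            "bin_edges": None if self.bin_edges is None else list(self.bin_edges),
        }


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def calibrate_dfix(fixed_dapps: DappDistribution) -> FixedCellCalibration:
    """Fit a single Gaussian to the fixed-cell log10 histogram.

    The back-transformed peak location is D_fix, the anchor used by all
    subsequent population fits acquired under the same imaging
    configuration.
    """
    if fixed_dapps.n_positive < 30:
        raise ValueError("calibration requires at least 30 positive D_app values")
    x = fixed_dapps.bin_centers
    y = fixed_dapps.density
    mu0 = float(np.median(fixed_dapps.log_values))
    sd0 = float(np.std(fixed_dapps.log_values))
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, w, mu, sd: w * _gauss(x, mu, sd),
            x,
            y,
            p0=[1.0, mu0, max(sd0, 0.05)],
            bounds=([0.0, x.min() - 1.0, 0.01], [10.0, x.max() + 1.0, 5.0]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - degenerate histograms
        raise ValueError(f"fixed-cell calibration fit failed: {exc}") from exc
    _, mu, sd = popt
    se_mu = float(np.sqrt(max(pcov[1, 1], 0.0)))
    d_fix = float(10.0**mu)
    return FixedCellCalibration(
        d_fix=d_fix,
        se=float(np.log(10.0) * d_fix * se_mu),
        n_tracks=fixed_dapps.n_positive,
        log10_sd=float(sd),
    )


def _pick_initial_means(dist: DappDistribution, k: int, anchor: float | None) -> list[float]:
    """Deterministic initialization: well-separated histogram maxima.

    Peaks are taken from a lightly smoothed histogram, greedily by height
    with a minimum separation; shortfall is filled from quantiles of the
    log values so initialization never fails.
    """
    y = gaussian_filter1d(dist.density.astype(float), sigma=1.0)
    x = dist.bin_centers
    is_max = np.r_[False, (y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:]), False]
    cand = x[is_max][np.argsort(y[is_max])[::-1]]
    chosen: list[float] = [] if anchor is None else [anchor]
    for c in cand:
        if all(abs(c - m) > 0.4 for m in chosen):
            chosen.append(float(c))
        if len(chosen) >= k + (0 if anchor is None else 1):
            break
    free = [m for m in chosen if anchor is None or m != anchor]
    need = k - len(free)
    if need > 0:
        qs = np.quantile(dist.log_values, np.linspace(0.25, 0.85, need))
        free.extend(float(q) for q in np.atleast_1d(qs))
    return sorted(free)[:k]


def _fit_gaussian_sum(
    dist: DappDistribution,
    labels: list[str],
    calib: FixedCellCalibration | None,
    anchor: bool,
    sd_bounds_factor: tuple[float, float] = (0.5, 2.0),
):
    """Least-squares fit of a Gaussian sum to the log10 histogram density.

    The 'fixed' component's mean is held at log10(d_fix) when anchored and
    its width bounded to sd_bounds_factor × the calibration width. Free
    component widths are floored at one histogram bin width: a narrower
    feature cannot be a resolved population peak. Residuals are weighted by
    the Poisson standard deviation of each bin count. Returns
    (components, converged, rss, dof).
    """
    x = dist.bin_centers
    y = dist.density
    bin_w = float(np.mean(np.diff(dist.bin_edges)))
    n_obs = dist.n_positive
    counts = y * n_obs * bin_w
    sigma = np.sqrt(np.maximum(counts, 1.0)) / (n_obs * bin_w)
    has_fixed = anchor and "fixed" in labels and calib is not None
    anchor_mu = np.log10(calib.d_fix) if has_fixed else None
    free_labels = [lab for lab in labels if not (has_fixed and lab == "fixed")]
    init_means = _pick_initial_means(dist, len(free_labels), anchor_mu)
    if has_fixed:
        # free means should initialize above the anchor where possible
        init_means = [max(m, anchor_mu + 0.2) for m in init_means]
        init_means = sorted(init_means)

    sd0 = max(float(np.std(dist.log_values)) / max(len(labels), 1), 0.1)
    p0, lo, hi = [], [], []
    spread = float(x.max() - x.min() + 2.0)
    for lab in labels:
        w0 = 1.0 / len(labels)
        p0.append(w0), lo.append(0.0), hi.append(1.5)
        if has_fixed and lab == "fixed":
            p0.append(max(calib.log10_sd, 0.05))
            lo.append(sd_bounds_factor[0] * calib.log10_sd)
            hi.append(sd_bounds_factor[1] * calib.log10_sd)
        else:
            mu0 = init_means.pop(0)
            p0.append(mu0), lo.append(x.min() - 1.0), hi.append(x.max() + 1.0)
            p0.append(max(sd0, bin_w)), lo.append(bin_w), hi.append(spread)

    def model(xv, *theta):
        out = np.zeros_like(xv)
        i = 0
        for lab in labels:
            if has_fixed and lab == "fixed":
                w, sd = theta[i], theta[i + 1]
                out += w * _gauss(xv, anchor_mu, sd)
                i += 2
            else:
                w, mu, sd = theta[i], theta[i + 1], theta[i + 2]
                out += w * _gauss(xv, mu, sd)
                i += 3
        return out

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=p0, bounds=(lo, hi), sigma=sigma,
                absolute_sigma=False, maxfev=20000
            )
    except (RuntimeError, ValueError):
        return None, False, np.inf, max(len(x) - len(p0), 1)

    resid = (y - model(x, *popt)) / sigma
    rss = float(np.sum(resid**2))
    dof = max(len(x) - len(popt), 1)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))

    comps: list[MixtureComponent] = []
    i = 0
    for lab in labels:
        if has_fixed and lab == "fixed":
            comps.append(
                MixtureComponent(lab, float(anchor_mu), float(popt[i + 1]), float(popt[i]), float(perr[i]))
            )
            i += 2
        else:
            comps.append(
                MixtureComponent(lab, float(popt[i + 1]), float(popt[i + 2]), float(popt[i]), float(perr[i]))
            )
            i += 3

    # relabel free components by mean so slow < fast (fixed stays anchored)
    free = sorted((c for c in comps if not (has_fixed and c.label == "fixed")), key=lambda c: c.mean)
    free_names = [lab for lab in COMPONENT_ORDER if lab in labels and not (has_fixed and lab == "fixed")]
    for c, name in zip(free, free_names):
        c.label = name
    comps.sort(key=lambda c: COMPONENT_ORDER.index(c.label))

    # ordering must hold among present components
    means = [c.mean for c in comps]
    if any(m2 <= m1 for m1, m2 in zip(means, means[1:])):
        converged = False

    # normalize weights (density integrates to 1); keep se on the same scale
    wsum = sum(c.weight for c in comps)
    if wsum <= 0:
        return None, False, rss, dof
    for c in comps:
        c.weight /= wsum
        c.se_weight /= wsum
    return comps, converged, rss, dof


def _refine_weights(fit: MixtureFit, dapps: DappDistribution, max_iter: int = 200) -> MixtureFit:
    """Re-estimate component weights from sample responsibilities.

    Peak locations and widths stay as fitted on the histogram; only the
    weights are updated by iterating the mixture responsibility average
    over the individual log10 values. This uses every sample rather than
    the binned density, which tightens the weight estimates towards the
    multinomial sampling floor without touching component selection.
    """
    if len(fit.components) < 2 or not fit.converged:
        return fit
    logv = dapps.log_values
    pdf = np.stack([_gauss(logv, c.mean, c.sd) for c in fit.components], axis=1)
    w = np.array([c.weight for c in fit.components])
    for _ in range(max_iter):
        r = pdf * w
        tot = r.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        w_new = (r / tot).mean(axis=0)
        if np.max(np.abs(w_new - w)) < 1e-10:
            w = w_new
            break
        w = w_new
    w = w / w.sum()
    for c, wi in zip(fit.components, w):
        c.weight = float(wi)
    return fit


def fit_mixture(
    dapps: DappDistribution,
    calib: FixedCellCalibration,
    n_components: int = 3,
    anchor: bool = True,
    refine: bool = True,
) -> MixtureFit:
    """Anchored Gaussian-sum fit of the log10(D_app) histogram.

    Fits ``n_components`` Gaussian peaks by nonlinear least squares on the
    histogram density; the fixed peak's mean is held at log10(d_fix). A
    non-convergent fit is returned with ``converged=False`` rather than
    raising, so callers can fall back to fewer components. With ``refine``
    the final weights are re-estimated from per-sample responsibilities
    under the fitted peak shapes.
    """
    if dapps.n_positive < 100:
        warnings.warn(
            f"only {dapps.n_positive} positive D_app values; mixture fit may be unstable",
            stacklevel=2,
        )
    labels = list(COMPONENT_ORDER[:n_components]) if n_components < 3 else list(COMPONENT_ORDER)
    fit = _make_fit(dapps, labels, calib, anchor)
    fit.fallback_applied = []
    return _refine_weights(fit, dapps) if refine else fit


def _failing_components(
    comps: list[MixtureComponent],
    min_weight: float,
    converged: bool,
    sep_factor: float = 1.25,
) -> list[str]:
    """Labels of components the data cannot support.

    A component fails on vanishing weight, on a weight standard error
    exceeding the weight, or on overlap: two peaks whose means are closer
    than ``sep_factor`` times their combined widths describe one population,
    so the lighter of the pair is flagged as unresolved.
    """
    if not comps:
        return []
    bad = {c.label for c in comps if c.weight < min_weight or c.se_weight > c.weight}
    by_mean = sorted(comps, key=lambda c: c.mean)
    for a, b in zip(by_mean, by_mean[1:]):
        if abs(b.mean - a.mean) < sep_factor * (a.sd + b.sd):
            bad.add(min(a, b, key=lambda c: c.weight).label)
    if not bad and not converged:
        bad = {min(comps, key=lambda c: c.weight).label}
    return [c.label for c in comps if c.label in bad]


def _n_params(labels: list[str], anchored: bool) -> int:
    return sum(2 if (anchored and lab == "fixed") else 3 for lab in labels)


def _make_fit(dapps, labels, calib, anchored) -> MixtureFit:
    comps, conv, rss, dof = _fit_gaussian_sum(dapps, labels, calib, anchored)
    return MixtureFit(
        components=comps or [],
        anchored=anchored and "fixed" in labels,
        fallback_applied=[lab for lab in COMPONENT_ORDER if lab not in labels],
        converged=conv,
        rss=rss,
        dof=dof,
        n_excluded_nonpositive=dapps.n_excluded_nonpositive,
        bin_edges=dapps.bin_edges,
    )


def _supported_over(full: MixtureFit, reduced: MixtureFit, alpha_level: float) -> bool:
    """Does the fuller model improve the histogram fit significantly (F-test)?"""
    if not full.converged:
        return False
    if not reduced.converged:
        return True
    d_par = reduced.dof - full.dof
    if d_par <= 0 or full.dof <= 0 or full.rss <= 0:
        return True
    f_stat = ((reduced.rss - full.rss) / d_par) / (full.rss / full.dof)
    return f_stat > stats.f.ppf(1.0 - alpha_level, d_par, full.dof)


def fit_with_fallback(
    dapps: DappDistribution,
    calib: FixedCellCalibration,
    anchor: bool = True,
    min_weight: float = 0.02,
    support_alpha: float = 0.05,
) -> MixtureFit:
    """Triple-Gaussian fit with fallback to fewer peaks (3 → 2 → 1).

    A component fails if the fit does not converge, its weight falls below
    ``min_weight``, its weight's standard error exceeds the weight, or its
    presence does not improve the histogram fit significantly (partial
    F-test at ``support_alpha`` against the best reduced model). On failure
    the model is refitted with one fewer peak — the anchor preserved
    whenever the fixed component survives — and surviving free peaks are
    renamed contiguously, so a lone free peak beside a surviving fixed peak
    is "slow" while two free peaks are slow + fast. At most one further
    reduction to a single Gaussian is made.
    """
    fit3 = fit_mixture(dapps, calib, n_components=3, anchor=anchor, refine=False)
    failed3 = _failing_components(fit3.components, min_weight, fit3.converged)

    # Two-peak shapes: anchored fixed + slow, or slow + fast alone. The
    # shape is decided by identity, not raw residuals (a free mean always
    # fits at least as well as the anchored one): when the unanchored fit's
    # lower peak sits within 2 of its own s.d. of log10(d_fix), that peak
    # is the fixed population and the anchored shape is used.
    fit2a = _make_fit(dapps, ["fixed", "slow"], calib, anchor)
    fit2b = _make_fit(dapps, ["slow", "fast"], calib, False)
    best2 = None
    if fit2b.converged and fit2b.components and anchor:
        low = min(fit2b.components, key=lambda c: c.mean)
        low_is_fixed = abs(low.mean - np.log10(calib.d_fix)) <= 2.0 * low.sd
        if low_is_fixed and fit2a.converged and fit2a.components:
            best2 = fit2a
        else:
            best2 = fit2b
    for cand in (fit2a, fit2b):
        if best2 is None and cand.converged and cand.components:
            best2 = cand

    if fit3.converged and not failed3:
        if best2 is None or _supported_over(fit3, best2, support_alpha):
            return _refine_weights(fit3, dapps)
    if best2 is None:
        raise MixtureError(
            f"triple fit failed ({failed3 or 'non-convergence'}) and no "
            f"two-component fit converged (rss={fit3.rss:.3g})"
        )

    failed2 = _failing_components(best2.components, min_weight, best2.converged)
    fit1 = _make_fit(
        dapps, ["fixed"] if best2.anchored else ["slow"], calib, best2.anchored
    )
    if not failed2:
        if not fit1.converged or _supported_over(best2, fit1, support_alpha):
            return _refine_weights(best2, dapps)
    if fit1.converged and fit1.components:
        return fit1
    raise MixtureError(
        f"mixture fitting failed at every level (3-comp rss={fit3.rss:.3g}, "
        f"2-comp rss={best2.rss:.3g}, 1-comp rss={fit1.rss:.3g})"
    )


def component_fractions(fit: MixtureFit) -> pd.DataFrame:
    """Percentage table per component label; absent labels report 0."""
    fr = fit.fractions
    return pd.DataFrame(
        {"component": list(COMPONENT_ORDER), "percent": [fr[lab] for lab in COMPONENT_ORDER]}
    )
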