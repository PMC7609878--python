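"""GP population analysis: histograms, Gaussian-mixture decomposition into
cytosolic (low-GP) and plasma-membrane (high-GP) fractions, per-region
statistics, well-level plate GP, and condition comparison (one-way ANOVA
with Tukey HSD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from sklearn.mixture import GaussianMixture

from .errors import (
    BandCoverageError,
    EmptyDataError,
    EmptyRegionError,
    FitFailureError,
    InvalidParameterError,
)
from .gp import BAND_440, BAND_490, GPMap, GPValue, gp_from_spectrum
from .spectra import EmissionSpectrum
from .spectral_io import PlateRecord

__all__ = [
    "GPHistogram",
    "GaussianComponent",
    "MixtureFit",
    "RegionStats",
    "ConditionSummary",
    "ComparisonResult",
    "gp_histogram",
    "fit_gaussian_mixture",
    "select_component_count",
    "region_gp_stats",
    "well_gp",
    "compare_conditions",
]

COMPONENT_LABELS = {0: "cytosolic (low-GP)", 1: "plasma membrane (high-GP)"}


@dataclass(frozen=True)
class GPHistogram:
    """Normalized frequency histogram of GP values on uniform bins."""

    bin_centers: np.ndarray
    frequencies: np.ndarray
    n_values: int
    bin_width: float
    n_clipped: int = 0

    def __post_init__(self) -> None:
        assert abs(float(self.frequencies.sum()) - 1.0) < 1e-9

    @property
    def mean(self) -> float:
        """Histogram mean (first moment over bin centers)."""
        return float(np.sum(self.bin_centers * self.frequencies))


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    weight: float

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return self.weight * stats.norm.pdf(x, self.mean, self.sd)


@dataclass
class MixtureFit:
    """Gaussian components fitted to a GP distribution.

    Components are sorted ascending by mean; with ``k=2`` component 0 is the
    cytosolic (low-GP) population and component 1 the plasma-membrane
    (high-GP) population. ``selection_score`` is the information criterion
    used for model comparison (lower is better).
    """

    components: list[GaussianComponent]
    k: int
    rss: float
    log_likelihood: float | None
    selection_score: float
    fit_method: str
    converged: bool = True

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def component_label(self, index: int) -> str:
        if self.k == 2:
            return COMPONENT_LABELS[index]
        return f"component {index}"

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return sum(c.pdf(np.asarray(x, dtype=float)) for c in self.components)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [self.component_label(i) for i in range(self.k)],
                "mean": self.means,
                "sd": [c.sd for c in self.components],
                "weight": self.weights,
                "rss": self.rss,
                "method": self.fit_method,
            }
        )


def gp_histogram(
    values: np.ndarray,
    bin_width: float = 0.02,
    value_range: tuple[float, float] = (-1.0, 1.0),
) -> GPHistogram:
    """Normalized frequency histogram of GP values.

    Values outside ``value_range`` are clipped into the edge bins and
    counted in ``n_clipped``. Frequencies sum to exactly 1.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyDataError("no valid GP values to histogram")
    lo, hi = value_range
    if not (lo < hi):
        raise InvalidParameterError("value_range must satisfy lo < hi")
    if bin_width <= 0 or bin_width > hi - lo:
        raise InvalidParameterError(f"bad bin_width {bin_width} for range {value_range}")
    n_clipped = int(np.count_nonzero((values < lo) | (values > hi)))
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} GP values into the edge bins", stacklevel=2)
        values = np.clip(values, lo, hi)
    n_bins = max(int(np.ceil((hi - lo) / bin_width - 1e-12)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # last bin absorbs rounding remainder
    counts, _ = np.histogram(values, bins=edges)
    freqs = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return GPHistogram(
        bin_centers=centers,
        frequencies=freqs,
        n_values=int(values.size),
        bin_width=float(bin_width),
        n_clipped=n_clipped,
    )


# ---------------------------------------------------------------------------
# Gaussian mixture fitting


def _as_values_and_hist(data, bin_width: float) -> tuple[np.ndarray | None, GPHistogram]:
    if isinstance(data, GPHistogram):
        return None, data
    values = np.asarray(data, dtype=float).ravel()
    values = values[np.isfinite(values)]
    return values, gp_histogram(values, bin_width=bin_width)


def _histogram_ls_fit(
    hist: GPHistogram, k: int, seed: int | None, n_starts: int
) -> MixtureFit:
    """Nonlinear least squares of a k-Gaussian curve to the normalized
    histogram. Bin frequencies are modeled as bin_width * mixture pdf."""
    x = hist.bin_centers
    y = hist.frequencies
    rng = np.random.default_rng(seed)
    # seed means from the histogram's coarse quantiles
    cdf = np.cumsum(y)
    base_means = np.interp((np.arange(k) + 0.5) / k, cdf, x)
    spread = float(np.sqrt(max(np.sum(y * (x - hist.mean) ** 2), hist.bin_width**2)))

    def model(params):
        amps = params[:k]
        means = params[k : 2 * k]
        sds = params[2 * k :]
        return sum(
            a * np.exp(-0.5 * ((x - m) / s) ** 2) for a, m, s in zip(amps, means, sds)
        )

    lo = np.concatenate([np.zeros(k), np.full(k, x[0] - 1), np.full(k, hist.bin_width / 4)])
    hi = np.concatenate(
        [np.full(k, 10.0), np.full(k, x[-1] + 1), np.full(k, (x[-1] - x[0]))]
    )
    best = None
    for start in range(n_starts):
        if start == 0:
            means0 = base_means.copy()
        else:
            means0 = base_means + rng.normal(0, spread / 2, size=k)
        means0 = np.clip(means0, x[0], x[-1])
        sds0 = np.full(k, max(spread / max(k, 1), hist.bin_width))
        amps0 = np.full(k, y.max() / max(k, 1) + 1e-12)
        p0 = np.clip(np.concatenate([amps0, means0, sds0]), lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                lambda p: model(p) - y, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res.x)
    if best is None:
        return MixtureFit([], k, np.inf, None, np.inf, "histogram_ls", converged=False)
    rss, p = best
    amps, means, sds = p[:k], p[k : 2 * k], p[2 * k :]
    # integrated area of each Gaussian -> weight
    areas = amps * sds * np.sqrt(2 * np.pi)
    total = areas.sum()
    weights = areas / total if total > 0 else np.full(k, 1.0 / k)
    order = np.argsort(means, kind="stable")
    comps = [
        GaussianComponent(float(means[i]), float(sds[i]), float(weights[i])) for i in order
    ]
    n_b = x.size
    n_params = 3 * k
    score = n_b * np.log(max(rss, 1e-300) / n_b) + n_params * np.log(n_b)
    return MixtureFit(comps, k, rss, None, float(score), "histogram_ls")


def _em_fit(values: np.ndarray, k: int, seed: int | None) -> MixtureFit:
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=5,
        random_state=None if seed is None else int(seed),
        max_iter=500,
    )
    gm.fit(values.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    weights = gm.weights_
    order = np.argsort(means, kind="stable")
    comps = [
        GaussianComponent(float(means[i]), float(sds[i]), float(weights[i])) for i in order
    ]
    loglik = float(gm.score(values.reshape(-1, 1)) * values.size)
    bic = float(gm.bic(values.reshape(-1, 1)))
    return MixtureFit(
        comps, k, np.nan, loglik, bic, "em", converged=bool(gm.converged_)
    )


def fit_gaussian_mixture(
    data,
    k: int = 2,
    method: str = "histogram_ls",
    seed: int | None = 0,
    bin_width: float = 0.02,
    n_starts: int = 5,
) -> MixtureFit:
    """Fit a k-component Gaussian mixture to GP values.

    ``histogram_ls`` (default, mirroring a curve fit to the normalized
    frequency histogram) accepts raw values or a ready
    :class:`GPHistogram`; ``em`` runs expectation-maximization on raw
    values. Both are multi-start with a fixed seed, return components sorted
    ascending by mean, and flag (never silence) non-convergence.
    """
    if k not in (1, 2, 3):
        raise InvalidParameterError(f"k must be 1, 2 or 3, got {k}")
    values, hist = _as_values_and_hist(data, bin_width)
    n = hist.n_values if values is None else values.size
    if n < 10 * k:
        raise EmptyDataError(f"need at least {10 * k} values for k={k}, got {n}")
    if method == "histogram_ls":
        fit = _histogram_ls_fit(hist, k, seed, n_starts)
    elif method == "em":
        if values is None:
            raise InvalidParameterError("method='em' requires raw values, not a histogram")
        fit = _em_fit(values, k, seed)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    if not fit.converged and not fit.components:
        raise FitFailureError(f"all {n_starts} restarts of the k={k} fit failed")
    return fit


def select_component_count(
    data,
    k_candidates: tuple[int, ...] = (1, 2, 3),
    method: str = "em",
    seed: int | None = 0,
    bin_width: float = 0.02,
) -> MixtureFit:
    """Fit each candidate component count and return the fit minimizing the
    information criterion (``selection_score``), ties broken toward smaller k.
    """
    if not k_candidates:
        raise InvalidParameterError("k_candidates must be non-empty")
    fits: list[MixtureFit] = []
    for k in sorted(k_candidates):
        try:
            fits.append(fit_gaussian_mixture(data, k=k, method=method, seed=seed,
                                             bin_width=bin_width))
        except (EmptyDataError, FitFailureError):
            continue
    fits = [f for f in fits if f.converged]
    if not fits:
        raise FitFailureError("no candidate component count produced a converged fit")
    # stable min: earlier (smaller k) wins ties
    return min(fits, key=lambda f: (f.selection_score, f.k))


# ---------------------------------------------------------------------------
# Regions, wells, conditions


@dataclass(frozen=True)
class RegionStats:
    mean: float
    sd: float
    n: int
    fit: MixtureFit | None = None


def region_gp_stats(gp_map: GPMap, region_mask: np.ndarray, fit_gaussian: bool = False) -> RegionStats:
    """Mean/sd GP over the valid pixels inside a region mask.

    Supports the whole-cell vs compartment comparison: run once with the
    cytosol mask and once with the membrane mask, then compare against the
    k=2 mixture means of the whole-cell distribution.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != gp_map.gp.shape:
        raise InvalidParameterError(
            f"mask shape {region_mask.shape} != map shape {gp_map.gp.shape}"
        )
    sel = region_mask & gp_map.valid_mask
    vals = gp_map.gp[sel]
    if vals.size == 0:
        raise EmptyRegionError("region overlaps no valid pixels")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    fit = None
    if fit_gaussian and vals.size >= 10:
        fit = fit_gaussian_mixture(vals, k=1, method="em")
    return RegionStats(mean=float(vals.mean()), sd=sd, n=int(vals.size), fit=fit)


def well_gp(
    records: list[PlateRecord],
    band440: tuple[float, float] = BAND_440,
    band490: tuple[float, float] = BAND_490,
) -> GPValue:
    """Ensemble GP of one well: flash spectra are averaged wavelength-wise
    and GP is computed on the mean spectrum.

    Warns when fewer than the recommended minimum of 25 flashes are present.
    """
    if not records:
        raise EmptyDataError("no flash records for well")
    wells = {r.well for r in records}
    if len(wells) > 1:
        raise InvalidParameterError(f"records span multiple wells: {sorted(wells)}")
    if len(records) < 25:
        warnings.warn(
            f"well {records[0].well!r}: only {len(records)} flashes "
            "(recommended minimum is 25)",
            stacklevel=2,
        )
    grid = records[0].spectrum.wavelengths
    for r in records[1:]:
        if not np.array_equal(r.spectrum.wavelengths, grid):
            raise BandCoverageError("flash spectra are on different wavelength grids")
    mean_intensity = np.mean([r.spectrum.intensities for r in records], axis=0)
    return gp_from_spectrum(EmissionSpectrum(grid, mean_intensity), band440, band490)


def mean_of_flash_gps(
    records: list[PlateRecord],
    band440: tuple[float, float] = BAND_440,
    band490: tuple[float, float] = BAND_490,
) -> float:
    """Alternative well statistic: mean of per-flash GP values."""
    if not records:
        raise EmptyDataError("no flash records for well")
    return float(
        np.mean([gp_from_spectrum(r.spectrum, band440, band490).gp for r in records])
    )


@dataclass(frozen=True)
class ConditionSummary:
    """Box-plot summary of one condition's GP replicates."""

    condition: float
    n: int
    mean: float
    sd: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _summarize(condition: float, values: np.ndarray) -> ConditionSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return ConditionSummary(
        condition=float(condition),
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )


@dataclass
class ComparisonResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    summaries: list[ConditionSummary]
    excluded: list[float]


def compare_conditions(groups: dict[float, np.ndarray]) -> ComparisonResult:
    """One-way ANOVA across conditions plus Tukey HSD pairwise comparisons.

    ``groups`` maps condition (calcium mM) to its GP replicate values.
    Conditions with fewer than 2 replicates are excluded with a warning.
    """
    cleaned: dict[float, np.ndarray] = {}
    excluded: list[float] = []
    for cond, vals in groups.items():
        vals = np.asarray(vals, dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            excluded.append(float(cond))
            warnings.warn(
                f"condition {cond} excluded: {vals.size} replicate(s) < 2", stacklevel=2
            )
            continue
        cleaned[float(cond)] = vals
    if len(cleaned) < 2:
        raise EmptyDataError("need at least 2 conditions with >= 2 replicates")
    conds = sorted(cleaned)
    samples = [cleaned[c] for c in conds]
    grand = np.concatenate(samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p_val = stats.f_oneway(*samples)
    f_stat, p_val = float(f_stat), float(p_val)
    if not np.isfinite(f_stat):
        # scipy yields NaN when the within-group variance is zero; resolve by
        # the group means: identical means -> F = 0, else infinite separation
        means = np.array([s.mean() for s in samples])
        scale = max(abs(grand.mean()), float(np.abs(means).max()), 1e-30)
        if np.ptp(means) <= 1e-12 * scale:
            f_stat, p_val = 0.0, 1.0
        else:
            f_stat, p_val = np.inf, 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        hsd = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            ci = hsd.confidence_interval()
            rows.append(
                {
                    "condition_a": conds[i],
                    "condition_b": conds[j],
                    "mean_difference": float(samples[i].mean() - samples[j].mean()),
                    "p_value": float(hsd.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                }
            )
    tukey = pd.DataFrame(rows)
    summaries = [_summarize(c, cleaned[c]) for c in conds]
    return ComparisonResult(
        f_statistic=f_stat, p_value=p_val, tukey=tukey, summaries=summaries,
        excluded=sorted(excluded),
    )
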