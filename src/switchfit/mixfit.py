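"""Gaussian mixture fits to trait distributions.

The primary method mirrors how bimodal trait histograms are analysed in the
phenotyping literature: nonlinear least squares of one or two Gaussian
curves to binned frequency counts, with the coefficient of determination R²
as the goodness-of-fit statistic.  A raw-sample maximum-likelihood EM fit
serves as an independent cross-check (and supplies log-likelihood, AIC and
BIC for model comparison on the sample level).

Amplitude-parameterized curve components are converted to mixing fractions
through their areas (A·σ·√(2π), normalized to the total), so the heavy
component's fraction is directly the penetrance ("on-rate") of the heavy
state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "BinnedDistribution",
    "GaussianComponent",
    "MixtureFit",
    "BootstrapResult",
    "bin_trait",
    "fit_single_gaussian",
    "fit_double_gaussian",
    "fit_mixture_ml",
    "r_squared",
    "bootstrap_fit",
    "posterior_heavy",
    "DegenerateFitError",
    "InputError",
    "ConvergenceError",
    "UndefinedStatisticError",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


class InputError(ValueError):
    """Invalid input data (empty, non-finite, bad weights)."""


class DegenerateFitError(ValueError):
    """Data cannot identify the requested model (too few occupied bins,
    point mass, variance collapse)."""


class ConvergenceError(RuntimeError):
    """A downstream operation refused a non-converged fit."""


class UndefinedStatisticError(ValueError):
    """Statistic undefined for this input (e.g. R² of a flat histogram)."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class BinnedDistribution:
    """Histogram with explicit edges and (possibly weighted) counts."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)
        if len(counts) != len(edges) - 1:
            raise InputError("len(counts) must equal len(edges) - 1")
        if not np.all(np.diff(edges) > 0):
            raise InputError("edges must be strictly increasing")
        if np.any(counts < 0):
            raise InputError("counts must be non-negative")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def bin_width(self) -> float:
        """Scalar width if uniform, else the mean width."""
        return float(np.mean(self.widths))

    @property
    def n_effective(self) -> float:
        return float(self.counts.sum())

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian component: mean, SD and mixing fraction."""

    mu: float
    sigma: float
    weight: float
    amplitude: Optional[float] = None  # curve amplitude, when from a binned fit

    def density(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mu) / self.sigma
        return np.exp(-0.5 * z * z) / (self.sigma * SQRT_2PI)


@dataclass
class MixtureFit:
    """A fitted 1- or 2-component Gaussian model.

    ``components`` are sorted by mean ascending; for k=2 the second
    component is the heavy one and its ``weight`` is the on-rate estimate.
    """

    k: int
    components: list[GaussianComponent]
    method: str  # "binned-nls" | "ml-em"
    converged: bool
    r2: Optional[float] = None
    loglik: Optional[float] = None
    aic: Optional[float] = None
    bic: Optional[float] = None
    n_restarts_used: int = 1
    effectively_unimodal: bool = False
    n_samples: Optional[float] = None
    bin_width: Optional[float] = None
    loglik_path: Optional[np.ndarray] = None

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def heavy_fraction(self) -> float:
        if self.k == 1:
            raise ValueError("heavy fraction is defined only for k=2 fits")
        return self.components[-1].weight

    def predict_counts(self, binned: BinnedDistribution) -> np.ndarray:
        """Expected bin counts of this fit on a given binning."""
        x = binned.midpoints
        total = binned.n_effective
        dens = sum(c.weight * c.density(x) for c in self.components)
        return total * binned.widths * dens

    def mixture_density(self, x: np.ndarray) -> np.ndarray:
        return sum(c.weight * c.density(x) for c in self.components)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "method": self.method,
            "converged": self.converged,
            "effectively_unimodal": self.effectively_unimodal,
            "r2": self.r2,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_restarts_used": self.n_restarts_used,
            "components": [
                {"mu": c.mu, "sigma": c.sigma, "weight": c.weight}
                for c in self.components
            ],
        }


# ---------------------------------------------------------------------------
# binning


def bin_trait(
    values: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    bin_width: Optional[float] = None,
    edges: Optional[Sequence[float]] = None,
) -> BinnedDistribution:
    """Histogram trait values into half-open bins [edge_i, edge_{i+1}).

    Exactly one of ``bin_width`` / ``edges`` must be given.  With a scalar
    width the first edge sits at the data minimum and the last edge strictly
    exceeds the data maximum, so all mass is covered.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("values must be non-empty")
    if not np.all(np.isfinite(values)):
        raise InputError("values must all be finite")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != values.shape:
            raise InputError("weights must match values in length")
        if np.any(weights < 0) or not np.all(np.isfinite(weights)):
            raise InputError("weights must be finite and non-negative")
        if weights.sum() == 0:
            raise InputError("weights sum to zero")
    if (bin_width is None) == (edges is None):
        raise InputError("give exactly one of bin_width or edges")

    if edges is None:
        lo, hi = float(values.min()), float(values.max())
        n_bins = max(1, int(np.floor((hi - lo) / bin_width)) + 1)
        edges = lo + bin_width * np.arange(n_bins + 1)
    edges = np.asarray(edges, dtype=float)

    counts, _ = np.histogram(values, bins=edges, weights=weights)
    return BinnedDistribution(edges=edges, counts=counts.astype(float))


# ---------------------------------------------------------------------------
# binned nonlinear least squares


def _gauss_curve(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _double_curve(x, a1, m1, s1, a2, m2, s2):
    return _gauss_curve(x, a1, m1, s1) + _gauss_curve(x, a2, m2, s2)


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw, x[order]))


def fit_single_gaussian(binned: BinnedDistribution) -> MixtureFit:
    """Least-squares fit of a single Gaussian curve to bin counts."""
    if binned.n_occupied < 3:
        raise DegenerateFitError(
            f"single-Gaussian fit needs >= 3 occupied bins, got {binned.n_occupied}"
        )
    x, y = binned.midpoints, binned.counts
    w = y / y.sum()
    mu0 = float(np.sum(w * x))
    sd0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2)))
    sigma_floor = binned.bin_width / 2.0
    sd0 = max(sd0, sigma_floor)
    p0 = [float(y.max()), mu0, sd0]
    lo = [0.0, x.min() - sd0, sigma_floor]
    hi = [np.inf, x.max() + sd0, np.inf]
    try:
        popt, _ = optimize.curve_fit(
            _gauss_curve, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    amp, mu, sigma = map(float, popt)
    comp = GaussianComponent(mu=mu, sigma=sigma, weight=1.0, amplitude=amp)
    fit = MixtureFit(
        k=1, components=[comp], method="binned-nls", converged=converged,
        n_samples=binned.n_effective, bin_width=binned.bin_width,
    )
    fit.r2 = _r2(binned.counts, _curve_counts(fit, binned))
    return fit


def _curve_counts(fit: MixtureFit, binned: BinnedDistribution) -> np.ndarray:
    """Evaluate the fitted curve (amplitude form) at bin midpoints."""
    x = binned.midpoints
    out = np.zeros_like(x)
    for c in fit.components:
        if c.amplitude is not None:
            out += _gauss_curve(x, c.amplitude, c.mu, c.sigma)
        else:
            out += binned.n_effective * binned.widths * c.weight * c.density(x)
    return out


def fit_double_gaussian(
    binned: BinnedDistribution,
    n_restarts: int = 8,
    seed: int = 0,
    constraints: Optional[dict] = None,
) -> MixtureFit:
    """Least-squares fit of the sum of two Gaussian curves to bin counts.

    The first start places the component means at the 25th and 90th
    percentiles of the binned mass with fractions 0.8/0.2 (a dominant-lean
    prior); the remaining ``n_restarts - 1`` starts draw means uniformly
    over the data range.  The best fit by residual sum of squares wins.
    Curve amplitudes are converted to mixing fractions via component areas.
    A fit whose means land within one bin width of each other is flagged
    ``effectively_unimodal``.

    ``constraints`` may carry ``mu_bounds``: ((lo1, hi1), (lo2, hi2)).
    """
    if binned.n_occupied < 6:
        raise DegenerateFitError(
            f"double-Gaussian fit needs >= 6 occupied bins, got {binned.n_occupied}"
        )
    x, y = binned.midpoints, binned.counts
    total_area = float(np.sum(y * binned.widths))
    w = y / y.sum()
    sd_pooled = float(np.sqrt(np.sum(w * (x - np.sum(w * x)) ** 2)))
    sigma_floor = binned.bin_width / 2.0
    s0 = max(sd_pooled / 2.0, sigma_floor)
    span = float(x.max() - x.min())

    def amp(frac, sigma):
        return frac * total_area / (sigma * SQRT_2PI)

    starts = [(
        amp(0.8, s0), _weighted_quantile(x, w, 0.25), s0,
        amp(0.2, s0), _weighted_quantile(x, w, 0.90), s0,
    )]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        m1, m2 = np.sort(x.min() + span * rng.random(2))
        f1 = 0.5 + 0.45 * rng.random()
        s1 = s0 * (0.5 + rng.random())
        s2 = s0 * (0.5 + rng.random())
        starts.append((amp(f1, s1), m1, s1, amp(1 - f1, s2), m2, s2))

    mu_lo1 = mu_lo2 = float(x.min())
    mu_hi1 = mu_hi2 = float(x.max())
    if constraints and "mu_bounds" in constraints:
        (mu_lo1, mu_hi1), (mu_lo2, mu_hi2) = constraints["mu_bounds"]
    amp_hi = 10.0 * float(y.max())
    lo = [0.0, mu_lo1, sigma_floor, 0.0, mu_lo2, sigma_floor]
    hi = [amp_hi, mu_hi1, 2.0 * span, amp_hi, mu_hi2, 2.0 * span]

    best, best_ssr, used = None, np.inf, 0
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        used += 1
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _double_curve, x, y, p0=p0, bounds=(lo, hi), maxfev=5000
                )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _double_curve(x, *popt)) ** 2))
        if ssr < best_ssr:
            best, best_ssr = popt, ssr

    if best is None:
        comps = [
            GaussianComponent(mu=float(starts[0][1]), sigma=s0, weight=0.8),
            GaussianComponent(mu=float(starts[0][4]), sigma=s0, weight=0.2),
        ]
        return MixtureFit(
            k=2, components=comps, method="binned-nls", converged=False,
            n_restarts_used=used, n_samples=binned.n_effective,
            bin_width=binned.bin_width,
        )

    a1, m1, s1, a2, m2, s2 = map(float, best)
    areas = np.array([a1 * s1, a2 * s2]) * SQRT_2PI
    fracs = areas / areas.sum() if areas.sum() > 0 else np.array([0.5, 0.5])
    comps = [
        GaussianComponent(mu=m1, sigma=s1, weight=float(fracs[0]), amplitude=a1),
        GaussianComponent(mu=m2, sigma=s2, weight=float(fracs[1]), amplitude=a2),
    ]
    comps.sort(key=lambda c: c.mu)
    fit = MixtureFit(
        k=2, components=comps, method="binned-nls", converged=True,
        n_restarts_used=used,
        effectively_unimodal=abs(comps[1].mu - comps[0].mu) < binned.bin_width,
        n_samples=binned.n_effective, bin_width=binned.bin_width,
    )
    fit.r2 = _r2(y, _curve_counts(fit, binned))
    return fit


# ---------------------------------------------------------------------------
# R²


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("R² undefined for a flat histogram")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def r_squared(binned: BinnedDistribution, fit: MixtureFit) -> float:
    """Coefficient of determination of a fit on a binned distribution.

    1 − SS_res/SS_tot with SS_tot about the mean bin count; invariant to
    uniform rescaling of the counts.
    """
    return _r2(binned.counts, _curve_counts(fit, binned))


# ---------------------------------------------------------------------------
# maximum-likelihood EM


def _gauss_logpdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma * SQRT_2PI)


def fit_mixture_ml(
    values: Sequence[float],
    k: int,
    n_restarts: int = 4,
    seed: int = 0,
    weights: Optional[Sequence[float]] = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture fit on raw samples (EM for k=2).

    k=1 uses the closed-form solution (weighted mean and ML SD).  k=2 runs
    expectation-maximization with case weights, a σ floor of 1e-3 of the
    data range, and the stated number of restarts (first start: quantile
    split at the 80th percentile; remaining starts random).  The
    log-likelihood trace of the winning run is kept and is non-decreasing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10 * k:
        raise DegenerateFitError(f"need at least {10 * k} samples for k={k}")
    if not np.all(np.isfinite(x)):
        raise InputError("values must all be finite")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise InputError("weights must be non-negative with positive sum")
    n_eff = float(w.sum())
    sigma_floor = max(float(np.ptp(x)) * 1e-3, 1e-12)

    if k == 1:
        mu = float(np.average(x, weights=w))
        sigma = float(np.sqrt(np.average((x - mu) ** 2, weights=w)))
        if sigma < sigma_floor:
            raise DegenerateFitError(
                "variance collapse (point mass); add a σ floor or jitter the data"
            )
        ll = float(np.sum(w * _gauss_logpdf(x, mu, sigma)))
        comps = [GaussianComponent(mu=mu, sigma=sigma, weight=1.0)]
        n_par = 2
        return MixtureFit(
            k=1, components=comps, method="ml-em", converged=True,
            loglik=ll, aic=2 * n_par - 2 * ll, bic=n_par * np.log(n_eff) - 2 * ll,
            n_samples=n_eff, loglik_path=np.array([ll]),
        )

    if k != 2:
        raise ValueError("only k in {1, 2} is supported")

    rng = np.random.default_rng(seed)
    q80 = _weighted_quantile(x, w, 0.8)
    sd_all = float(np.sqrt(np.average((x - np.average(x, weights=w)) ** 2, weights=w)))
    starts = [(
        np.array([_weighted_quantile(x, w, 0.4), _weighted_quantile(x, w, 0.95)]),
        np.array([max(sd_all / 2, sigma_floor)] * 2),
        np.array([0.8, 0.2]),
    )]
    for _ in range(max(0, n_restarts - 1)):
        mus = np.sort(rng.uniform(x.min(), x.max(), 2))
        f = rng.uniform(0.3, 0.9)
        starts.append((mus, np.array([max(sd_all, sigma_floor)] * 2),
                       np.array([f, 1 - f])))

    best = None
    for mus, sds, pis in starts:
        mus, sds, pis = mus.copy(), sds.copy(), pis.copy()
        path = []
        ok = True
        for _ in range(max_iter):
            logp = np.stack([
                np.log(pis[j]) + _gauss_logpdf(x, mus[j], sds[j]) for j in range(2)
            ])
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            ll = float(np.sum(w * lse))
            path.append(ll)
            resp = np.exp(logp - lse)  # 2 x n
            wr = resp * w
            nk = wr.sum(axis=1)
            if np.any(nk <= 0):
                ok = False
                break
            pis = nk / n_eff
            mus = (wr @ x) / nk
            sds = np.sqrt(np.array([
                np.sum(wr[j] * (x - mus[j]) ** 2) / nk[j] for j in range(2)
            ]))
            sds = np.maximum(sds, sigma_floor)
            if len(path) > 1 and abs(path[-1] - path[-2]) < tol * (1 + abs(path[-1])):
                break
        if not ok or not path:
            continue
        if best is None or path[-1] > best[0]:
            best = (path[-1], mus, sds, pis, np.array(path))

    if best is None:
        raise DegenerateFitError("EM failed from every start (variance collapse)")

    ll, mus, sds, pis, path = best
    order = np.argsort(mus)
    comps = [
        GaussianComponent(mu=float(mus[j]), sigma=float(sds[j]), weight=float(pis[j]))
        for j in order
    ]
    n_par = 5  # 2 means + 2 SDs + 1 free fraction
    return MixtureFit(
        k=2, components=comps, method="ml-em", converged=True,
        loglik=float(ll), aic=2 * n_par - 2 * ll,
        bic=n_par * np.log(n_eff) - 2 * ll,
        n_restarts_used=len(starts), n_samples=n_eff, loglik_path=path,
    )


def posterior_heavy(fit: MixtureFit, values: Sequence[float]) -> np.ndarray:
    """Posterior responsibility of the heavy (higher-mean) component."""
    if fit.k != 2:
        raise ValueError("posterior responsibilities require a k=2 fit")
    x = np.asarray(values, dtype=float)
    lean, heavy = fit.components
    num = heavy.weight * heavy.density(x)
    den = num + lean.weight * lean.density(x)
    with np.errstate(invalid="ignore"):
        post = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
    return post


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals for mixture-fit parameters."""

    point: dict
    intervals: dict  # param -> (lo, hi)
    level: float
    B: int
    n_nonconverged: int
    warning: Optional[str] = None

    def width(self, param: str) -> float:
        lo, hi = self.intervals[param]
        return hi - lo


def bootstrap_fit(
    values: Sequence[float],
    k: int = 2,
    B: int = 200,
    seed: int = 0,
    level: float = 0.95,
    bin_width: Optional[float] = None,
    method: str = "binned-nls",
    n_restarts: int = 4,
) -> BootstrapResult:
    """Nonparametric bootstrap intervals for all fit parameters.

    Each of the ``B`` resamples is re-fit with the same restart policy;
    label switching is resolved by mean-ordering before aggregation.  More
    than 20% non-converged replicates records a warning; more than 50% is a
    failure.
    """
    if B < 100:
        raise InputError("B must be >= 100")
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)

    if method == "binned-nls" and bin_width is None:
        bin_width = float(np.ptp(x)) / 30.0

    def one_fit(sample):
        if method == "binned-nls":
            b = bin_trait(sample, bin_width=bin_width)
            if k == 2:
                return fit_double_gaussian(b, n_restarts=n_restarts)
            return fit_single_gaussian(b)
        return fit_mixture_ml(sample, k=k, n_restarts=n_restarts)

    full = one_fit(x)
    point = _params_of(full)

    draws = {p: [] for p in point}
    bad = 0
    for _ in range(B):
        sample = x[rng.integers(0, x.size, x.size)]
        try:
            f = one_fit(sample)
        except (DegenerateFitError, UndefinedStatisticError):
            bad += 1
            continue
        if not f.converged:
            bad += 1
            continue
        for p, v in _params_of(f).items():
            draws[p].append(v)

    if bad > 0.5 * B:
        raise ConvergenceError(
            f"{bad}/{B} bootstrap replicates failed to converge"
        )
    warning = (
        f"{bad}/{B} bootstrap replicates did not converge" if bad > 0.2 * B else None
    )
    alpha = (1 - level) / 2
    intervals = {
        p: (float(np.quantile(v, alpha)), float(np.quantile(v, 1 - alpha)))
        for p, v in draws.items()
    }
    return BootstrapResult(
        point=point, intervals=intervals, level=level, B=B,
        n_nonconverged=bad, warning=warning,
    )


def _params_of(fit: MixtureFit) -> dict:
    out = {}
    for i, c in enumerate(fit.components):
        out[f"mu{i + 1}"] = c.mu
        out[f"sigma{i + 1}"] = c.sigma
        out[f"weight{i + 1}"] = c.weight
    if fit.k == 2:
        out["heavy_fraction"] = fit.heavy_fraction
        lean, heavy = fit.components
        if lean.mu != 0:
            out["effect_size_pct"] = 100.0 * (heavy.mu - lean.mu) / lean.mu
    return out
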