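"""smFRET trajectory analysis: histograms, double-Gaussian fits,
autocorrelations, decay fits, and two-state rate estimation.

The analysis chain turns pooled single-molecule FRET trajectories into the
parameters of a two-state telegraph model:

1.  FRET efficiency per frame is ``I_A / (I_A + I_D)``.
2.  The pooled FRET histogram (area-normalized, sqrt-count errors, bin width
    at least ``1/sqrt(N)``) is fitted with a sum of two Gaussians
    ``a1*exp(-(x-b1)^2/c1^2) + a2*exp(-(x-b2)^2/c2^2)``; the centers ``b1 <
    b2`` are the two states S1 and S2 and the analytic component areas are
    ``a*c*sqrt(pi)``.
3.  The mean-subtracted autocorrelation (windowed means inside both factors,
    averaged over trajectories, normalized by the lag-0 value) is fitted over
    a lag range with both a boundary-respecting power law
    ``(a*tau + 1)^-b`` and an exponential ``d*exp(-e*tau) + f``.
4.  For a two-state process, area(S2)/area(S1) = k1/k2 and the exponential
    decay rate equals (k1 + k2), which identifies both rates.

:class:`TwoStateEstimator` packages the chain as a scikit-learn style
estimator; the module-level functions are the individual steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .telegraph import FretTrajectory

__all__ = [
    "IntensityTrace",
    "NormalizedHistogram",
    "DoubleGaussianFit",
    "CorrelationCurve",
    "DecayFits",
    "TwoStateEstimate",
    "LinearFit",
    "compute_fret",
    "build_histogram",
    "fit_double_gaussian",
    "autocorrelation",
    "fit_decays",
    "estimate_two_state",
    "linear_fit",
    "TwoStateEstimator",
]


# --------------------------------------------------------------------------
# containers


@dataclass
class IntensityTrace:
    """Anticorrelated donor/acceptor emission series (arbitrary units)."""

    I_D: np.ndarray
    I_A: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.I_D = np.asarray(self.I_D, dtype=float)
        self.I_A = np.asarray(self.I_A, dtype=float)
        if self.I_D.shape != self.I_A.shape or self.I_D.ndim != 1:
            raise ValueError("I_D and I_A must be 1-D arrays of equal length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.I_D.size


@dataclass
class NormalizedHistogram:
    """Area-normalized histogram with sqrt-count errors."""

    bin_edges: np.ndarray
    density: np.ndarray
    density_err: np.ndarray
    n_values: int
    counts: np.ndarray
    warning: str | None = None

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def area(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


@dataclass
class DoubleGaussianFit:
    """Parameters of the two-Gaussian histogram model, relabeled so b1 < b2."""

    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float
    residual_norm: float
    n_starts: int
    degenerate: bool = False

    @property
    def area1(self) -> float:
        return self.a1 * self.c1 * math.sqrt(math.pi)

    @property
    def area2(self) -> float:
        return self.a2 * self.c2 * math.sqrt(math.pi)

    @property
    def area_ratio(self) -> float:
        """area(S2)/area(S1) = k1/k2 for a two-state process."""
        if self.area1 == 0:
            raise ZeroDivisionError("area of the S1 component is zero")
        return self.area2 / self.area1

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _double_gaussian(np.asarray(x, dtype=float),
                                self.a1, self.b1, self.c1,
                                self.a2, self.b2, self.c2)


@dataclass
class CorrelationCurve:
    """Trajectory-averaged correlation versus lag index."""

    lags: np.ndarray
    C: np.ndarray
    sem: np.ndarray
    normalized: bool
    n_trajectories: int
    flat: bool = False  # all trajectories constant; normalization impossible


@dataclass
class DecayFits:
    """Power-law and exponential fits of a normalized correlation curve.

    Both models are fitted on the same lag points by unweighted least
    squares; ``preferred`` names the model with the smaller residual sum.
    """

    power_a: float
    power_b: float
    exp_d: float
    exp_e: float
    exp_f: float
    ss_power: float
    ss_exp: float
    lag_range: tuple[int, int]
    ss_total: float = float("nan")
    unreliable: bool = False

    @property
    def preferred(self) -> str:
        return "exponential" if self.ss_exp <= self.ss_power else "power_law"

    @property
    def r2_exp(self) -> float:
        """Fraction of the curve's variation explained by the exponential."""
        return 1.0 - self.ss_exp / self.ss_total

    @property
    def r2_power(self) -> float:
        """Fraction of the curve's variation explained by the power law."""
        return 1.0 - self.ss_power / self.ss_total

    def power_law(self, tau: np.ndarray) -> np.ndarray:
        return _pareto(np.asarray(tau, dtype=float), self.power_a, self.power_b)

    def exponential(self, tau: np.ndarray) -> np.ndarray:
        return _exp_decay(np.asarray(tau, dtype=float),
                          self.exp_d, self.exp_e, self.exp_f)


@dataclass
class TwoStateEstimate:
    """Two-state parameters inferred from histogram areas and decay rate."""

    S1: float
    S2: float
    rate_ratio: float       # k1/k2 = area(S2)/area(S1)
    rate_sum: float         # k1 + k2 in 1/s
    rate_sum_per_lag: float  # exponential decay rate in lag units
    k1: float
    k2: float
    provenance: dict = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class LinearFit:
    """OLS line with a pointwise 95% confidence band for the mean response."""

    b0: float
    b1: float
    x: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    rsquared: float


# --------------------------------------------------------------------------
# operations


def compute_fret(trace: IntensityTrace) -> FretTrajectory:
    """FRET efficiency ``I_A / (I_A + I_D)`` frame by frame."""
    total = trace.I_A + trace.I_D
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        raise ValueError(
            f"I_A + I_D is non-positive at frame {bad[0]}; cannot form FRET"
        )
    return FretTrajectory(values=trace.I_A / total, dt=trace.dt,
                          meta=dict(trace.meta))


def build_histogram(
    values: np.ndarray,
    bin_width: float | None = None,
    min_bin_width: float = 0.005,
) -> NormalizedHistogram:
    """Area-normalized histogram with sqrt-count per-bin errors.

    When ``bin_width`` is None (auto), the width is ``max(min_bin_width,
    1/sqrt(N))`` so that it is at least the inverse square root of the
    sample size.  Both the counts and the sqrt-count errors are divided by
    the histogram area, so the density integrates to one.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 2:
        raise ValueError("need at least two values to build a histogram")
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    if bin_width is None:
        bin_width = max(min_bin_width, 1.0 / math.sqrt(n))
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    lo, hi = float(values.min()), float(values.max())
    warning = None
    if hi == lo:
        warning = "all values identical; single-bin histogram"
        edges = np.array([lo - bin_width / 2, lo + bin_width / 2])
    else:
        n_bins = int(math.ceil((hi - lo) / bin_width))
        # extend the top edge so the maximum falls inside the last bin
        edges = lo + bin_width * np.arange(n_bins + 1)
        if edges[-1] <= hi:
            edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(values, bins=edges)
    area = counts.sum() * bin_width
    density = counts / area
    density_err = np.sqrt(counts) / area
    return NormalizedHistogram(
        bin_edges=edges, density=density, density_err=density_err,
        n_values=n, counts=counts, warning=warning,
    )


def _double_gaussian(x, a1, b1, c1, a2, b2, c2):
    return (a1 * np.exp(-((x - b1) ** 2) / c1**2)
            + a2 * np.exp(-((x - b2) ** 2) / c2**2))


def fit_double_gaussian(
    hist: NormalizedHistogram,
    init: tuple[float, float, float, float, float, float] | None = None,
    weighted: bool = False,
    n_restarts: int = 8,
) -> DoubleGaussianFit:
    """Least-squares fit of the two-Gaussian model to a normalized histogram.

    Initialization is multi-start and deterministic: centers are seeded at
    the two highest well-separated density peaks (falling back to symmetric
    offsets around the main peak when the mixture is not visibly bimodal),
    widths at five bin widths and at the sample SD, plus ``n_restarts``
    jittered restarts from a fixed-seed generator.  Components are relabeled
    so that ``b1 < b2``; ties in peak seeding break toward lower FRET.

    Fits are unweighted by default (``weighted=True`` uses the sqrt-count
    errors as sigma).
    """
    x = hist.bin_centers
    y = hist.density
    populated = np.count_nonzero(y > 0)
    if populated < 6:
        raise ValueError(
            f"need at least 6 populated bins to fit two Gaussians, got {populated}"
        )
    bw = hist.bin_width
    amax = float(y.max())
    spread = float(np.sqrt(np.sum(y * bw * x**2) - np.sum(y * bw * x) ** 2))
    peak = float(x[np.argmax(y)])  # argmax takes the first (lowest-FRET) tie

    starts: list[tuple[float, ...]] = []
    if init is not None:
        starts.append(tuple(init))
    # two-peak seeding: local maxima separated by at least 3 bins
    order = np.argsort(y)[::-1]
    second = None
    for idx in order[1:]:
        if abs(x[idx] - peak) >= 3 * bw and y[idx] > 0:
            second = float(x[idx])
            break
    width_seeds = [5 * bw, max(spread, 5 * bw)]
    if second is not None:
        lo, hi2 = sorted((peak, second))
        for w in width_seeds:
            starts.append((amax / 2, lo, w, amax / 2, hi2, w))
    for delta in (2 * bw, 0.01, 0.02, 0.03, 0.05):
        for b1, b2 in ((peak - delta, peak + delta),
                       (peak, peak + 2 * delta),
                       (peak - 2 * delta, peak)):
            starts.append((amax / 2, b1, 5 * bw, amax / 2, b2, 5 * bw))
    jitter_rng = np.random.default_rng(0)  # fixed seed: deterministic restarts
    base = starts[0] if init is not None else (amax / 2, peak - 0.02, 5 * bw,
                                               amax / 2, peak + 0.02, 5 * bw)
    for _ in range(n_restarts):
        jit = jitter_rng.normal(0.0, [amax / 4, 0.02, bw, amax / 4, 0.02, bw])
        starts.append(tuple(np.asarray(base) + jit))

    sigma = None
    if weighted:
        sigma = np.where(hist.density_err > 0, hist.density_err,
                         hist.density_err[hist.density_err > 0].min()
                         if np.any(hist.density_err > 0) else 1.0)

    lower = [0.0, x.min() - 10 * bw, 1e-9, 0.0, x.min() - 10 * bw, 1e-9]
    upper = [np.inf, x.max() + 10 * bw, np.inf, np.inf, x.max() + 10 * bw, np.inf]
    best: tuple[float, np.ndarray] | None = None
    n_tried = 0
    for p0 in starts:
        p0c = np.clip(p0, lower, upper)
        n_tried += 1
        try:
            popt, _ = curve_fit(_double_gaussian, x, y, p0=p0c, sigma=sigma,
                                bounds=(lower, upper), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((_double_gaussian(x, *popt) - y) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt)
    if best is None:
        raise RuntimeError(
            f"double-Gaussian fit failed to converge from {n_tried} starts"
        )
    ss, p = best
    a1, b1, c1, a2, b2, c2 = (float(v) for v in p)
    c1, c2 = abs(c1), abs(c2)
    if b1 > b2:
        a1, b1, c1, a2, b2, c2 = a2, b2, c2, a1, b1, c1
    fit = DoubleGaussianFit(a1=a1, b1=b1, c1=c1, a2=a2, b2=b2, c2=c2,
                            residual_norm=math.sqrt(ss), n_starts=n_tried)
    ratio = (fit.area2 / fit.area1) if fit.area1 > 0 else math.inf
    fit.degenerate = not (0.02 <= ratio <= 50.0)
    return fit


def correlation_single(x: np.ndarray, max_lag: int,
                       y: np.ndarray | None = None) -> np.ndarray:
    """Correlation of a single series at lags 0..max_lag.

    At lag tau the estimate is the average over t of
    ``{x(t) - mean(x[1..N-tau])} * {y(t+tau) - mean(y[1+tau..N])}`` --
    the windowed means are recomputed inside both factors at every lag.
    ``y`` defaults to ``x`` (autocorrelation); passing a second series gives
    the cross form used for residue-pair correlations.
    """
    x = np.asarray(x, dtype=float)
    y = x if y is None else np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = x.size
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} must be < series length {n}")
    out = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        a = x[: n - tau]
        b = y[tau:]
        out[tau] = np.dot(a - a.mean(), b - b.mean()) / (n - tau)
    return out


def autocorrelation(
    trajs: list[FretTrajectory] | list[np.ndarray] | np.ndarray,
    max_lag: int,
    normalize: bool = True,
) -> CorrelationCurve:
    """Trajectory-averaged autocorrelation with per-lag SEM.

    Each trajectory is mean-subtracted inside the lag-dependent windows (see
    :func:`correlation_single`), the curves are averaged, and the average is
    optionally normalized by its lag-0 value.  The SEM is the standard error
    over trajectories (scaled consistently when normalizing).
    """
    series = [t.values if isinstance(t, FretTrajectory) else np.asarray(t, float)
              for t in trajs]
    if len(series) == 0:
        raise ValueError("need at least one trajectory")
    curves = np.array([correlation_single(s, max_lag) for s in series])
    C = curves.mean(axis=0)
    if len(series) > 1:
        sem = curves.std(axis=0, ddof=1) / math.sqrt(len(series))
    else:
        sem = np.zeros_like(C)
    flat = bool(C[0] == 0.0)
    if normalize:
        if flat:
            warnings.warn("constant trajectories: zero correlation, "
                          "normalization impossible", RuntimeWarning,
                          stacklevel=2)
        else:
            sem = sem / C[0]
            C = C / C[0]
    return CorrelationCurve(lags=np.arange(max_lag + 1), C=C, sem=sem,
                            normalized=normalize and not flat,
                            n_trajectories=len(series), flat=flat)


def _pareto(tau, a, b):
    return (a * tau + 1.0) ** (-b)


def _exp_decay(tau, d, e, f):
    return d * np.exp(-e * tau) + f


def fit_decays(
    curve: CorrelationCurve,
    lag_range: tuple[int, int] = (1, 1000),
) -> DecayFits:
    """Fit the normalized correlation with a power law and an exponential.

    Both models are fitted by unweighted least squares on exactly the same
    lag points.  The power-law form ``(a*tau + 1)^-b`` satisfies C(0) = 1 by
    construction; the exponential is ``d*exp(-e*tau) + f`` with e >= 0.
    Initialization is a deterministic multi-start grid.
    """
    lo, hi = int(lag_range[0]), int(lag_range[1])
    if lo >= hi:
        raise ValueError("lag_range must satisfy min < max")
    if hi > curve.lags[-1]:
        raise ValueError(
            f"lag_range {lag_range} exceeds available lags (max {curve.lags[-1]})"
        )
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    tau = curve.lags[mask].astype(float)
    C = curve.C[mask]
    unreliable = bool(np.all(C <= 0))

    c1 = float(C[0])
    # exponential multi-start over decay-rate guesses
    best_exp = None
    for e0 in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):
        try:
            p, _ = curve_fit(_exp_decay, tau, C,
                             p0=[max(c1, 1e-3), e0, 0.0],
                             bounds=([0.0, 0.0, -1.0], [np.inf, np.inf, 1.0]),
                             maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((_exp_decay(tau, *p) - C) ** 2))
        if best_exp is None or ss < best_exp[0]:
            best_exp = (ss, p)
    # power law: seed a from (a*lo+1)^-b = C[lo] at several exponents
    best_pow = None
    for b0 in (0.5, 1.0, 2.0, 10.0, 100.0, 1000.0):
        if 0 < c1 < 1:
            a0 = max((c1 ** (-1.0 / b0) - 1.0) / max(lo, 1), 1e-12)
        else:
            a0 = 1e-3
        try:
            p, _ = curve_fit(_pareto, tau, C, p0=[a0, b0],
                             bounds=([1e-15, 1e-9], [np.inf, np.inf]),
                             maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((_pareto(tau, *p) - C) ** 2))
        if best_pow is None or ss < best_pow[0]:
            best_pow = (ss, p)
    if best_exp is None or best_pow is None:
        raise RuntimeError("decay fitting failed to converge")
    ss_exp, p_exp = best_exp
    ss_pow, p_pow = best_pow
    return DecayFits(
        power_a=float(p_pow[0]), power_b=float(p_pow[1]),
        exp_d=float(p_exp[0]), exp_e=float(p_exp[1]), exp_f=float(p_exp[2]),
        ss_power=ss_pow, ss_exp=ss_exp, lag_range=(lo, hi),
        ss_total=float(np.sum((C - C.mean()) ** 2)),
        unreliable=unreliable,
    )


def estimate_two_state(fit: DoubleGaussianFit, decays: DecayFits,
                       dt: float) -> TwoStateEstimate:
    """Combine histogram areas and the correlation decay into k1 and k2.

    ``k1/k2 = area(S2)/area(S1)`` and ``k1 + k2`` equals the exponential
    decay rate of the autocorrelation; the per-lag rate ``e`` converts to
    1/s as ``e/dt`` here and nowhere else.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if decays.exp_e <= 0:
        raise ValueError("exponential decay rate must be positive for a "
                         "two-state estimate")
    if fit.area1 == 0:
        raise ZeroDivisionError("area of the S1 Gaussian is zero; rate ratio "
                                "undefined")
    ratio = fit.area_ratio
    rate_sum = decays.exp_e / dt
    k1 = rate_sum * ratio / (1.0 + ratio)
    k2 = rate_sum / (1.0 + ratio)
    degenerate = fit.degenerate
    return TwoStateEstimate(
        S1=fit.b1, S2=fit.b2, rate_ratio=ratio, rate_sum=rate_sum,
        rate_sum_per_lag=decays.exp_e, k1=k1, k2=k2,
        provenance={
            "S1": "double-Gaussian center b1",
            "S2": "double-Gaussian center b2",
            "rate_ratio": "Gaussian area(S2)/area(S1)",
            "rate_sum": "exponential decay rate / dt",
        },
        degenerate=degenerate,
    )


def linear_fit(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> LinearFit:
    """Simple linear regression with a pointwise confidence band.

    Ordinary least squares ``y = b0 + b1*x`` with the (1-alpha) confidence
    interval of the mean response at each predictor value, via the
    t-distribution (statsmodels ``get_prediction``).
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    ci = res.get_prediction(X).conf_int(alpha=alpha)
    return LinearFit(b0=float(res.params[0]), b1=float(res.params[1]),
                     x=x, ci_lower=ci[:, 0], ci_upper=ci[:, 1],
                     rsquared=float(res.rsquared))


# --------------------------------------------------------------------------
# estimator


class TwoStateEstimator(BaseEstimator):
    """Fit a two-state telegraph model to an ensemble of FRET trajectories.

    Parameters
    ----------
    dt : float
        Frame interval in seconds (overridden by trajectory metadata when
        the input carries it).
    bin_width : float or None
        Histogram bin width; None selects ``max(min_bin_width, 1/sqrt(N))``.
    min_bin_width : float
        Floor for the automatic bin width.
    max_lag : int
        Longest lag of the autocorrelation curve.
    fit_min_lag, fit_max_lag : int
        Lag range of the decay fits.
    weighted : bool
        Weight the histogram fit by sqrt-count errors.

    Attributes
    ----------
    histogram_ : NormalizedHistogram
    gaussian_fit_ : DoubleGaussianFit
    correlation_ : CorrelationCurve
    decay_fits_ : DecayFits
    estimate_ : TwoStateEstimate
    S1_, S2_, k1_, k2_, rate_sum_, rate_ratio_ : float
    """

    def __init__(self, dt: float = 0.1, bin_width: float | None = None,
                 min_bin_width: float = 0.005, max_lag: int = 1000,
                 fit_min_lag: int = 1, fit_max_lag: int = 1000,
                 weighted: bool = False):
        self.dt = dt
        self.bin_width = bin_width
        self.min_bin_width = min_bin_width
        self.max_lag = max_lag
        self.fit_min_lag = fit_min_lag
        self.fit_max_lag = fit_max_lag
        self.weighted = weighted

    def fit(self, X, y=None):
        """Fit on a list of trajectories (FretTrajectory, 1-D arrays, or a
        2-D array of shape (n_trajectories, n_frames))."""
        if isinstance(X, np.ndarray) and X.ndim == 2:
            trajs: list = list(X)
        elif isinstance(X, (list, tuple)):
            trajs = list(X)
        else:
            raise TypeError("X must be a 2-D array or a list of trajectories")
        if len(trajs) == 0:
            raise ValueError("need at least one trajectory")
        dt = self.dt
        dts = {t.dt for t in trajs if isinstance(t, FretTrajectory)}
        if dts:
            if len(dts) > 1:
                raise ValueError(f"trajectories disagree on dt: {sorted(dts)}")
            dt = dts.pop()

        pooled = np.concatenate(
            [t.values if isinstance(t, FretTrajectory) else np.asarray(t, float)
             for t in trajs])
        self.dt_ = float(dt)
        self.histogram_ = build_histogram(pooled, bin_width=self.bin_width,
                                          min_bin_width=self.min_bin_width)
        self.gaussian_fit_ = fit_double_gaussian(self.histogram_,
                                                 weighted=self.weighted)
        self.correlation_ = autocorrelation(trajs, max_lag=self.max_lag,
                                            normalize=True)
        self.decay_fits_ = fit_decays(self.correlation_,
                                      (self.fit_min_lag, self.fit_max_lag))
        self.estimate_ = estimate_two_state(self.gaussian_fit_,
                                            self.decay_fits_, dt=self.dt_)
        est = self.estimate_
        self.S1_, self.S2_ = est.S1, est.S2
        self.k1_, self.k2_ = est.k1, est.k2
        self.rate_sum_, self.rate_ratio_ = est.rate_sum, est.rate_ratio
        self.n_values_ = pooled.size
        return self

    def summary_row(self, condition: str = "") -> dict:
        """One summary row: condition, states, widths, ratio, and rates."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "estimate_")
        g = self.gaussian_fit_
        e = self.estimate_
        return {
            "condition": condition,
            "S1": e.S1, "S2": e.S2,
            "c1": g.c1, "c2": g.c2,
            "rate_ratio": e.rate_ratio,
            "rate_sum_per_s": e.rate_sum,
            "rate_sum_per_lag": e.rate_sum_per_lag,
            "k1": e.k1, "k2": e.k2,
            "n_values": self.n_values_,
            "degenerate": e.degenerate,
        }
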