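"""Native implementations of the canonical 22-feature univariate set.

Each function takes a z-scored 1-D series and returns a scalar. The set spans
distributional shape (histogram modes, outlier timing), linear and nonlinear
autocorrelation (ACF timescales, automutual information, time reversibility),
symbolic dynamics (motif entropy, transition-matrix statistics), spectral
summaries, forecasting error, and scaling/fluctuation analysis.

The algorithms follow the published definitions of the canonical set; where a
numerical convention is open (histogram bin counts, quantile interpolation,
spectral estimator details) the choice made here is fixed and documented in
the project methods note. All features are invariant to positive affine
transforms of the raw series because the input is z-scored first.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import LSQUnivariateSpline


# ---------------------------------------------------------------- helpers

def _acf(y: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased-normalization autocorrelation function, acf[0] = 1, via FFT."""
    n = y.size
    if max_lag is None:
        max_lag = n - 1
    y0 = y - y.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    f = np.fft.rfft(y0, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1] / n
    if acov[0] <= 0:
        raise ValueError("zero-variance series has no autocorrelation function")
    return acov / acov[0]


def _first_zero_ac(y: np.ndarray) -> int:
    """First lag at which the ACF drops below zero (series length if never)."""
    ac = _acf(y)
    below = np.nonzero(ac[1:] < 0)[0]
    return int(below[0] + 1) if below.size else y.size


def _histogram_counts(y: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = y.min(), y.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(y, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def _quantile_symbols(y: np.ndarray, n_symbols: int = 3) -> np.ndarray:
    qs = np.quantile(y, np.linspace(0, 1, n_symbols + 1)[1:-1])
    return np.searchsorted(qs, y, side="left")


def _periodogram(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram on an angular-frequency grid (rad/sample)."""
    n = y.size
    nfft = int(2 ** np.ceil(np.log2(n)))
    spec = np.abs(np.fft.rfft(y - y.mean(), nfft)) ** 2 / (2 * np.pi * n)
    w = np.linspace(0, np.pi, spec.size)
    return w, spec


# --------------------------------------------------- distributional shape

def mode_5(y: np.ndarray) -> float:
    counts, centers = _histogram_counts(y, 5)
    return float(centers[counts == counts.max()].mean())


def mode_10(y: np.ndarray) -> float:
    counts, centers = _histogram_counts(y, 10)
    return float(centers[counts == counts.max()].mean())


def _outlier_timing(y: np.ndarray, sign: int) -> float:
    """Median (over inclusion thresholds) of the median relative timing of
    threshold-exceeding events; > 0 means exceedances concentrate late."""
    z = sign * y
    n = z.size
    if z.max() <= 0:
        return 0.0
    thresholds = np.arange(0, z.max(), 0.01)
    med_rel = []
    for th in thresholds:
        (idx,) = np.nonzero(z >= th)
        if idx.size < max(2, int(0.02 * n)):
            break
        med_rel.append(np.median(idx + 1) / (n / 2) - 1.0)
    if not med_rel:
        return 0.0
    return float(np.median(med_rel))


def outlier_timing_pos(y: np.ndarray) -> float:
    return _outlier_timing(y, +1)


def outlier_timing_neg(y: np.ndarray) -> float:
    return _outlier_timing(y, -1)


# ----------------------------------------------------- linear correlation

def acf_timescale(y: np.ndarray) -> float:
    """First 1/e crossing of the ACF, linearly interpolated between lags."""
    ac = _acf(y)
    thresh = 1.0 / np.e
    for i in range(1, ac.size):
        if ac[i] < thresh:
            if ac[i] == ac[i - 1]:
                return float(i)
            return float(i - 1 + (ac[i - 1] - thresh) / (ac[i - 1] - ac[i]))
    return float(y.size)


def acf_first_min(y: np.ndarray) -> float:
    ac = _acf(y)
    for i in range(1, ac.size - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            return float(i)
    return float(y.size)


def ami_timescale(y: np.ndarray) -> float:
    """First minimum of the Gaussian automutual information over lags 1..40."""
    max_lag = min(40, y.size // 2)
    ac = _acf(y, max_lag)
    rho2 = np.clip(ac[1:] ** 2, 0, 1 - 1e-12)
    ami = -0.5 * np.log1p(-rho2)
    for i in range(1, ami.size - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            return float(i + 1)
    return float(max_lag)


def whiten_timescale(y: np.ndarray) -> float:
    """Ratio of the first-zero ACF crossing after first differencing to the
    original series' crossing: how much incremental whitening shortens the
    correlation timescale."""
    resid = np.diff(y)
    return float(_first_zero_ac(resid) / _first_zero_ac(y))


# ------------------------------------------------------ information theory

def ami2(y: np.ndarray) -> float:
    """Histogram automutual information, lag 2, 5 equal-width bins (nats)."""
    lag, n_bins = 2, 5
    a, b = y[:-lag], y[lag:]
    lo, hi = y.min(), y.max() + 1e-10
    edges = np.linspace(lo, hi, n_bins + 1)
    joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))


def entropy_pairs(y: np.ndarray) -> float:
    """Shannon entropy (nats) of adjacent symbol pairs after tercile coding."""
    s = _quantile_symbols(y, 3)
    pair_codes = s[:-1] * 3 + s[1:]
    counts = np.bincount(pair_codes, minlength=9).astype(float)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ----------------------------------------------------- symbolic / binary

def stretch_high(y: np.ndarray) -> float:
    """Longest run of consecutive above-mean values."""
    above = y > y.mean()
    best = run = 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    return float(best)


def stretch_decreasing(y: np.ndarray) -> float:
    """Longest run of consecutive decreasing increments."""
    dec = np.diff(y) < 0
    best = run = 0
    for flag in dec:
        run = run + 1 if flag else 0
        best = max(best, run)
    return float(best)


def transition_variance(y: np.ndarray) -> float:
    """Sum of column variances of the 3-symbol transition matrix computed on
    the series coarse-grained at the ACF first-zero-crossing stride."""
    tau = max(1, _first_zero_ac(y))
    z = y[::tau]
    if z.size < 4:
        return np.nan
    s = _quantile_symbols(z, 3)
    T = np.zeros((3, 3))
    for a, b in zip(s[:-1], s[1:]):
        T[a, b] += 1
    T /= T.sum()
    cov = np.cov(T.T)
    return float(np.trace(cov))


# ---------------------------------------------------------- fluctuations

def trev(y: np.ndarray) -> float:
    """Time-reversal asymmetry: mean cubed successive difference."""
    return float(np.mean(np.diff(y) ** 3))


def high_fluctuation(y: np.ndarray) -> float:
    """Proportion of successive increments exceeding 0.04 in magnitude."""
    return float(np.mean(np.abs(np.diff(y)) > 0.04))


def _fluctuation_scaling(y: np.ndarray, kind: str) -> float:
    """Two-regime scaling split of log fluctuation vs log window size.

    The series is coarse-grained at lag 2, cumulatively summed, and the
    fluctuation function F(tau) is computed over 50 log-spaced window sizes
    as either the RMS linear-detrending residual ("dfa") or the RMS range of
    the detrended windows ("rsrange"). Two straight lines are fit to the
    log-log plot over every admissible split point; returns the proportion
    of window sizes falling in the first (small-scale) regime of the
    best-fitting split.
    """
    cs = np.cumsum(y[::2])
    n = cs.size
    taus = np.unique(
        np.round(np.exp(np.linspace(np.log(5), np.log(n / 2), 50))).astype(int)
    )
    taus = taus[(taus >= 5) & (taus <= n // 2)]
    if taus.size < 8:
        return np.nan
    F = np.empty(taus.size)
    for k, tau in enumerate(taus):
        n_win = n // tau
        segs = cs[: n_win * tau].reshape(n_win, tau)
        t = np.arange(tau)
        t_c = t - t.mean()
        denom = (t_c**2).sum()
        slopes = segs @ t_c / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * t_c
        if kind == "dfa":
            F[k] = np.sqrt(np.mean(resid**2))
        else:
            rng = resid.max(axis=1) - resid.min(axis=1)
            F[k] = np.sqrt(np.mean(rng**2))
    logt, logF = np.log(taus), np.log(F)
    min_pts = 6 if taus.size >= 12 else 3  # keep the split feasible at short T
    best_sse, best_split = np.inf, min_pts
    for split in range(min_pts, taus.size - min_pts + 1):
        sse = 0.0
        for sl in (slice(0, split), slice(split, taus.size)):
            x, f = logt[sl], logF[sl]
            coef = np.polyfit(x, f, 1)
            sse += float(np.sum((f - np.polyval(coef, x)) ** 2))
        if sse < best_sse:
            best_sse, best_split = sse, split
    return float(best_split / taus.size)


def dfa(y: np.ndarray) -> float:
    return _fluctuation_scaling(y, "dfa")


def rs_range(y: np.ndarray) -> float:
    return _fluctuation_scaling(y, "rsrange")


# -------------------------------------------------------------- spectral

def centroid_freq(y: np.ndarray) -> float:
    """Angular frequency splitting the power spectrum into equal halves."""
    w, S = _periodogram(y)
    csum = np.cumsum(S)
    half = csum[-1] / 2
    i = int(np.searchsorted(csum, half))
    return float(w[min(i, w.size - 1)])


def low_freq_power(y: np.ndarray) -> float:
    """Integrated spectral power over the lowest fifth of frequencies."""
    w, S = _periodogram(y)
    n_low = S.size // 5
    dw = w[1] - w[0]
    return float(S[:n_low].sum() * dw)


# ------------------------------------------------- forecasting / embedding

def forecast_error(y: np.ndarray) -> float:
    """SD of residuals from a trailing 3-point moving-average forecast."""
    w = 3
    if y.size <= w + 1:
        return np.nan
    pred = np.convolve(y, np.ones(w) / w, mode="valid")[:-1]
    resid = y[w:] - pred
    return float(np.std(resid, ddof=1))


def embedding_dist(y: np.ndarray) -> float:
    """Mean absolute deviation between the distribution of successive
    distances in a 2-D time-delay embedding and its exponential fit."""
    tau = min(_first_zero_ac(y), max(1, y.size // 10))
    pts = np.column_stack([y[:-tau], y[tau:]])
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if d.size < 10 or d.mean() == 0:
        return np.nan
    rate = 1.0 / d.mean()
    n_bins = max(5, int(np.ceil(np.sqrt(d.size))))
    counts, edges = np.histogram(d, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(np.mean(np.abs(counts - rate * np.exp(-rate * centers))))


def periodicity(y: np.ndarray) -> float:
    """Wang's periodicity: first ACF peak rising at least 0.01 above the
    preceding trough (with positive height), after cubic-spline detrending.
    Returns 0 when no such peak exists."""
    n = y.size
    t = np.arange(n, dtype=float)
    knots = [n / 3, 2 * n / 3]
    try:
        spline = LSQUnivariateSpline(t, y, knots, k=3)
        resid = y - spline(t)
    except Exception:
        resid = y - np.polyval(np.polyfit(t, y, 3), t)
    max_lag = max(3, int(np.ceil(n / 3)))
    ac = _acf(resid, max_lag)
    th = 0.01
    trough = None
    for i in range(1, ac.size - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            trough = i
        elif trough is not None and ac[i] > ac[i - 1] and ac[i] > ac[i + 1]:
            if ac[i] > 0 and ac[i] - ac[trough] >= th:
                return float(i)
    return 0.0


# ------------------------------------------------------------ public API

CATCH22_FEATURES = {
    "ACF_first_min": acf_first_min,
    "ACF_timescale": acf_timescale,
    "AMI_timescale": ami_timescale,
    "AMI2": ami2,
    "centroid_freq": centroid_freq,
    "DFA": dfa,
    "embedding_dist": embedding_dist,
    "entropy_pairs": entropy_pairs,
    "forecast_error": forecast_error,
    "high_fluctuation": high_fluctuation,
    "low_freq_power": low_freq_power,
    "mode_10": mode_10,
    "mode_5": mode_5,
    "outlier_timing_neg": outlier_timing_neg,
    "outlier_timing_pos": outlier_timing_pos,
    "periodicity": periodicity,
    "rs_range": rs_range,
    "stretch_decreasing": stretch_decreasing,
    "stretch_high": stretch_high,
    "transition_variance": transition_variance,
    "trev": trev,
    "whiten_timescale": whiten_timescale,
}
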