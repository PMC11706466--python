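"""Statistics of pairwise interactions (SPIs) between region time series.

Fourteen scalar dependence measures are computed between every pair of
regions: Pearson correlation, dynamic time warping and its barycenter
summary, spectral measures (coherence magnitude, phase lag index, phase
slope index in frequency and time-frequency form, power-envelope
correlation), Gaussian information-theoretic measures (transfer entropy,
directed information, integrated-information proxy phi-star), and
model-based measures (nonparametric spectral Granger causality via Wilson
factorization, Engle-Granger cointegration, additive-noise-model causal
score). All SPIs operate on z-scored series.

Directed SPIs are evaluated over all ordered pairs (i, j), i != j;
undirected SPIs over unordered pairs i < j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy import signal
from scipy.optimize import minimize_scalar

from .cohort import CohortDataset

__all__ = [
    "PairIndex",
    "CouplingTensor",
    "build_pair_index",
    "SPI_NAMES",
    "DIRECTED_SPIS",
    "UNDIRECTED_SPIS",
    "spi_pearson",
    "dtw_distance",
    "dtw_barycenter",
    "spi_distance",
    "spi_spectral",
    "spi_infotheory",
    "spi_model",
    "compute_spi",
    "compute_coupling_tensor",
]

DIRECTED_SPIS = (
    "ANM",
    "DI",
    "transfer_entropy",
    "spectral_GC",
    "PSI_frequency",
    "PSI_time_frequency",
)
UNDIRECTED_SPIS = (
    "phi_star",
    "PLI",
    "barycenter_DTW",
    "DTW",
    "power_envelope_corr",
    "coherence_magnitude",
    "cointegration",
    "Pearson",
)
SPI_NAMES = DIRECTED_SPIS + UNDIRECTED_SPIS


# ------------------------------------------------------------- pair index

@dataclass(frozen=True)
class PairIndex:
    """Deterministic row-major enumeration of region pairs."""

    n_regions: int
    directed: bool
    pairs: tuple[tuple[int, int], ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_pair_index(n_regions: int, directed: bool) -> PairIndex:
    if n_regions < 2:
        raise ValueError("pair enumeration requires at least 2 regions")
    if directed:
        pairs = tuple(
            (i, j) for i in range(n_regions) for j in range(n_regions) if i != j
        )
    else:
        pairs = tuple(
            (i, j) for i in range(n_regions) for j in range(i + 1, n_regions)
        )
    return PairIndex(n_regions=n_regions, directed=directed, pairs=pairs)


# ---------------------------------------------------------------- helpers

def _zscore(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    sd = y.std()
    if sd == 0:
        raise ValueError("constant series cannot be z-scored")
    return (y - y.mean()) / sd


def _check_pair(x: np.ndarray, y: np.ndarray, min_len: int = 3) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < min_len:
        raise ValueError(f"series too short: need length >= {min_len}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input series")


def _welch_nperseg(T: int) -> int:
    # capped so the Welch estimate always averages >= 2 segments
    return min(128, max(8, (2 * T) // 3))


def _welch_csd(x: np.ndarray, y: np.ndarray):
    """Welch auto- and cross-spectra with one shared convention.

    Hann window, 50% overlap, segment length min(128, 2T/3) so at least two
    segments are averaged (a single segment gives a rank-one cross-spectral
    matrix, which breaks coherence and spectral factorization).
    """
    nperseg = _welch_nperseg(x.size)
    kw = dict(fs=1.0, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    f, sxx = signal.welch(x, **kw)
    _, syy = signal.welch(y, **kw)
    _, sxy = signal.csd(x, y, **kw)
    return f, sxx, syy, sxy


# ---------------------------------------------------------------- Pearson

def spi_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Empirical covariance of the z-scored pair (= Pearson correlation)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_pair(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(np.mean(_zscore(x) * _zscore(y)))


# ------------------------------------------------------ dynamic time warp

def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Unconstrained DTW alignment cost, squared local cost, square-rooted."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = x.size, y.size
    cost = (x[:, None] - y[None, :]) ** 2
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = acc[i]
        prev = acc[i - 1]
        c = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = c[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(np.sqrt(acc[n, m]))


def _dtw_path(x: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    n, m = x.size, y.size
    cost = (x[:, None] - y[None, :]) ** 2
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(
                acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1]
            )
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        step = int(np.argmin([acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]]))
        if step == 0:
            i, j = i - 1, j - 1
        elif step == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    return path


def dtw_barycenter(
    series: list[np.ndarray], max_iter: int = 10, tol: float = 1e-8
) -> np.ndarray:
    """DTW barycenter averaging: mean initialization, <= ``max_iter`` updates."""
    stack = np.vstack(series)
    bary = stack.mean(axis=0)
    for _ in range(max_iter):
        sums = np.zeros_like(bary)
        counts = np.zeros_like(bary)
        for s in stack:
            for bi, si in _dtw_path(bary, s):
                sums[bi] += s[si]
                counts[bi] += 1
        new = np.where(counts > 0, sums / np.maximum(counts, 1), bary)
        if np.max(np.abs(new - bary)) < tol:
            bary = new
            break
        bary = new
    return bary


def spi_distance(x: np.ndarray, y: np.ndarray, which: str = "DTW") -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_pair(x, y)
    zx, zy = _zscore(x), _zscore(y)
    if which == "DTW":
        return dtw_distance(zx, zy)
    if which == "barycenter_DTW":
        return float(dtw_barycenter([zx, zy]).mean())
    raise ValueError(f"unknown distance SPI {which!r}")


# ---------------------------------------------------------------- spectral

def _psi_from_welch(x: np.ndarray, y: np.ndarray) -> float:
    _, sxx, syy, sxy = _welch_csd(x, y)
    # scipy's csd is conj(X)*Y; the phase-slope convention uses X*conj(Y),
    # so that a positive slope (positive PSI) means x leads y
    C = np.conj(sxy) / np.sqrt(sxx * syy)
    return float(np.sum(np.imag(np.conj(C[:-1]) * C[1:])))


def spi_spectral(
    x: np.ndarray, y: np.ndarray, which: str, tr_seconds: float = 1.0
) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_pair(x, y, min_len=30)
    zx, zy = _zscore(x), _zscore(y)

    if which == "coherence_magnitude":
        f, sxx, syy, sxy = _welch_csd(zx, zy)
        coh = np.abs(sxy) / np.sqrt(sxx * syy)
        return float(coh[f > 0].mean())

    if which == "PLI":
        phx = np.angle(signal.hilbert(zx))
        phy = np.angle(signal.hilbert(zy))
        return float(np.abs(np.mean(np.sign(np.sin(phx - phy)))))

    if which == "power_envelope_corr":
        ex = np.abs(signal.hilbert(zx))
        ey = np.abs(signal.hilbert(zy))
        return spi_pearson(ex, ey)

    if which == "PSI_frequency":
        return _psi_from_welch(zx, zy)

    if which == "PSI_time_frequency":
        win = int(np.ceil(x.size / 4))
        if win < 16:
            raise ValueError(
                f"series too short for windowed PSI: need T >= 64, got {x.size}"
            )
        step = max(1, win // 2)
        vals = []
        for start in range(0, x.size - win + 1, step):
            vals.append(_psi_from_welch(zx[start : start + win], zy[start : start + win]))
        return float(np.mean(vals))

    raise ValueError(f"unknown spectral SPI {which!r}")


# ------------------------------------------------------- information theory

def _lagged_cov(*cols: np.ndarray) -> np.ndarray:
    return np.cov(np.vstack(cols))


def _cond_var(cov: np.ndarray, target: int, given: list[int]) -> float:
    """Schur-complement conditional variance of one variable given others."""
    g = np.asarray(given)
    S_tt = cov[target, target]
    S_tg = cov[target, g]
    S_gg = cov[np.ix_(g, g)]
    try:
        sol = np.linalg.solve(S_gg, S_tg)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular conditioning covariance") from exc
    return float(S_tt - S_tg @ sol)


def _gaussian_te(x: np.ndarray, y: np.ndarray, contemporaneous: bool) -> float:
    """Gaussian information flow x -> y with target history length 1."""
    x_src = x[1:] if contemporaneous else x[:-1]
    cov = _lagged_cov(y[1:], y[:-1], x_src)
    v_hist = _cond_var(cov, 0, [1])
    v_full = _cond_var(cov, 0, [1, 2])
    if v_full <= 0 or v_hist <= 0:
        raise ValueError("singular conditioning covariance in Gaussian estimator")
    return float(0.5 * np.log(v_hist / v_full))


def _phi_star(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian mismatched-decoding integrated information, bipartition
    {x},{y}, lag 1, scalar decoding parameter optimized numerically.

    phi* = I(present; past) - I*, where I* is the maximal information
    extractable by a decoder that models each part's present from its own
    past only. Zero for independent parts; positive when disconnecting the
    parts loses predictive information.
    """
    Z = np.vstack([x[:-1], y[:-1]])  # past
    Y = np.vstack([x[1:], y[1:]])  # present
    full = np.cov(np.vstack([Y, Z]))
    S_Y, S_Z = full[:2, :2], full[2:, 2:]
    S_YZ = full[:2, 2:]
    try:
        S_cond = S_Y - S_YZ @ np.linalg.solve(S_Z, S_YZ.T)
        I_full = 0.5 * (np.log(np.linalg.det(S_Y)) - np.log(np.linalg.det(S_cond)))
    except (np.linalg.LinAlgError, FloatingPointError) as exc:
        raise ValueError("singular covariance in phi-star") from exc

    # per-part (mismatched) decoders: each present from its own past
    a = np.array([S_YZ[0, 0] / S_Z[0, 0], S_YZ[1, 1] / S_Z[1, 1]])
    A_D = np.diag(a)
    sig = np.array(
        [
            S_Y[0, 0] - S_YZ[0, 0] ** 2 / S_Z[0, 0],
            S_Y[1, 1] - S_YZ[1, 1] ** 2 / S_Z[1, 1],
        ]
    )
    if np.any(sig <= 0):
        raise ValueError("degenerate per-part conditional variance in phi-star")
    S_D_inv = np.diag(1.0 / sig)
    # residual covariance of the mismatched predictor under the true joint
    R = S_Y - A_D @ S_YZ.T - S_YZ @ A_D + A_D @ S_Z @ A_D

    def neg_mismatched_info(beta: float) -> float:
        M = beta * S_D_inv
        G = A_D @ M @ A_D  # A_D' M A_D (A_D diagonal)
        inner = np.linalg.inv(np.linalg.inv(S_Z) + G)
        W = M - M @ A_D @ inner @ A_D @ M
        val = (
            -0.5 * beta * np.trace(S_D_inv @ R)
            + 0.5 * np.log(np.linalg.det(np.eye(2) + G @ S_Z))
            + 0.5 * np.trace(W @ S_Y)
        )
        return -val

    res = minimize_scalar(neg_mismatched_info, bounds=(1e-8, 1.0), method="bounded")
    I_star = -res.fun
    return float(I_full - I_star)


def spi_infotheory(x: np.ndarray, y: np.ndarray, which: str) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_pair(x, y, min_len=30)
    zx, zy = _zscore(x), _zscore(y)
    if which == "transfer_entropy":
        return _gaussian_te(zx, zy, contemporaneous=False)
    if which == "DI":
        return _gaussian_te(zx, zy, contemporaneous=True)
    if which == "phi_star":
        return _phi_star(zx, zy)
    raise ValueError(f"unknown information-theoretic SPI {which!r}")


# ------------------------------------------------------------ model-based

def _wilson_factorize(
    S: np.ndarray, max_iter: int = 300, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson's matricial spectral factorization S(f) = psi(f) psi(f)^H.

    ``S``: (nfft, 2, 2) Hermitian cross-spectral matrices over the full
    frequency circle, with S(-f) = conj(S(f)). Returns (H, Sigma): the
    transfer function on the one-sided grid (nfft//2 + 1 points) and the
    innovation covariance. Initialized from the Cholesky factor of the
    zero-lag autocovariance; iterates until the relative update drops below
    ``tol`` or ``max_iter`` sweeps, then accepts only if the factorization
    residual is small.
    """
    nfft = S.shape[0]
    m = nfft // 2 + 1
    gam0 = np.real(np.fft.ifft(S, axis=0)[0])
    try:
        h0 = np.linalg.cholesky(gam0).T
    except np.linalg.LinAlgError:
        h0 = np.eye(2)
    psi = np.tile(h0.astype(complex), (nfft, 1, 1))
    eye = np.eye(2)
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ S @ np.conj(np.transpose(psi_inv, (0, 2, 1))) + eye
        gam = np.real(np.fft.ifft(g, axis=0))
        gp = np.zeros_like(gam)
        gp[0] = np.triu(0.5 * gam[0])
        gp[1:m] = gam[1:m]
        psi_new = psi @ np.fft.fft(gp, axis=0)
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-30)
        psi = psi_new
        if delta < tol:
            break
    resid = np.max(
        np.abs(psi @ np.conj(np.transpose(psi, (0, 2, 1))) - S)
    ) / max(np.max(np.abs(S)), 1e-30)
    if resid > 1e-2:
        raise ValueError(
            f"Wilson spectral factorization failed: relative residual "
            f"{resid:.2e} after {max_iter} iterations (update tolerance {tol:g})"
        )
    psi0 = np.real(np.mean(psi, axis=0))  # zero-lag coefficient
    Sigma = psi0 @ psi0.T
    H = psi[:m] @ np.linalg.inv(psi0)
    return H, Sigma


def _spectral_gc(x: np.ndarray, y: np.ndarray) -> float:
    """Mean nonparametric Granger causality x -> y over frequencies."""
    nperseg = _welch_nperseg(x.size)
    kw = dict(
        fs=1.0,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        return_onesided=False,
        # zero-pad to a fine grid: the factorization's causal projection
        # needs the implied autocovariance to decay well inside nfft/2 lags
        nfft=512,
    )
    # scipy's csd is conj(X)*Y; the factorization needs S_xy = X*conj(Y)
    f, sxy_conj = signal.csd(x, y, **kw)
    _, sxx = signal.welch(x, **kw)
    _, syy = signal.welch(y, **kw)
    nfft = f.size
    m = nfft // 2 + 1
    S = np.empty((nfft, 2, 2), dtype=complex)
    S[:, 0, 0], S[:, 1, 1] = sxx, syy
    S[:, 0, 1] = np.conj(sxy_conj)
    S[:, 1, 0] = sxy_conj
    # small diagonal loading for numerical positive-definiteness
    S += 1e-12 * np.eye(2)
    H, Sigma = _wilson_factorize(S)
    s_yy = np.real(S[:m, 1, 1])
    h_yx = np.abs(H[:, 1, 0]) ** 2
    sigma_x_cond = Sigma[0, 0] - Sigma[1, 0] ** 2 / Sigma[1, 1]
    denom = s_yy - sigma_x_cond * h_yx
    denom = np.maximum(denom, 1e-30)
    gc = np.log(np.maximum(s_yy, 1e-30) / denom)
    return float(np.mean(gc[1:]))  # all non-DC frequencies up to Nyquist


def _engle_granger_stat(x: np.ndarray, y: np.ndarray) -> float:
    """ADF statistic (constant, one lagged difference) on y-on-x residuals."""
    from statsmodels.tsa.stattools import adfuller

    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    stat = adfuller(resid, maxlag=1, regression="c", autolag=None)[0]
    return float(stat)


def _rbf_kernel(a: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = (a[:, None] - a[None, :]) ** 2
    return np.exp(-d2 / (2.0 * bandwidth**2))


def _median_bandwidth(a: np.ndarray) -> float:
    d = np.abs(a[:, None] - a[None, :])
    med = np.median(d[np.triu_indices_from(d, k=1)])
    return float(med) if med > 0 else 1.0


def _hsic(a: np.ndarray, b: np.ndarray) -> float:
    """Biased HSIC V-statistic with RBF kernels, median-heuristic bandwidth."""
    n = a.size
    K = _rbf_kernel(a, _median_bandwidth(a))
    L = _rbf_kernel(b, _median_bandwidth(b))
    H = np.eye(n) - np.ones((n, n)) / n
    return float(np.trace(H @ K @ H @ L) / n**2)


def _anm_score(x: np.ndarray, y: np.ndarray, ridge: float = 0.1) -> float:
    """Residual dependence after kernel-ridge regression of y on x.

    Lower score = residuals more independent of the cause = more consistent
    with the causal direction x -> y.
    """
    n = x.size
    if n > 500:  # HSIC and kernel ridge are O(n^2); thin long series evenly
        idx = np.linspace(0, n - 1, 500).astype(int)
        x, y = x[idx], y[idx]
        n = 500
    K = _rbf_kernel(x, _median_bandwidth(x))
    alpha = np.linalg.solve(K + ridge * np.eye(n), y)
    resid = y - K @ alpha
    return _hsic(resid, x)


def spi_model(x: np.ndarray, y: np.ndarray, which: str) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_pair(x, y, min_len=30)
    if which == "cointegration":
        # symmetrized: mean of the two regression directions, raw (non z-scored
        # levels carry the stochastic trend, but z-scoring is linear so either is fine)
        zx, zy = _zscore(x), _zscore(y)
        return float(
            0.5 * (_engle_granger_stat(zx, zy) + _engle_granger_stat(zy, zx))
        )
    zx, zy = _zscore(x), _zscore(y)
    if which == "spectral_GC":
        return _spectral_gc(zx, zy)
    if which == "ANM":
        return _anm_score(zx, zy)
    raise ValueError(f"unknown model-based SPI {which!r}")


# ---------------------------------------------------------------- dispatch

def compute_spi(x: np.ndarray, y: np.ndarray, name: str) -> float:
    """Compute a single named SPI between two series (z-scored internally)."""
    if name == "Pearson":
        return spi_pearson(x, y)
    if name in ("DTW", "barycenter_DTW"):
        return spi_distance(x, y, name)
    if name in (
        "coherence_magnitude",
        "PLI",
        "power_envelope_corr",
        "PSI_frequency",
        "PSI_time_frequency",
    ):
        return spi_spectral(x, y, name)
    if name in ("transfer_entropy", "DI", "phi_star"):
        return spi_infotheory(x, y, name)
    if name in ("spectral_GC", "cointegration", "ANM"):
        return spi_model(x, y, name)
    raise ValueError(f"unknown SPI {name!r}; valid names: {', '.join(SPI_NAMES)}")


@dataclass
class CouplingTensor:
    """N x P array of pairwise statistics for one SPI."""

    spi_name: str
    values: np.ndarray
    pair_index: PairIndex
    subjects: list[str]

    @property
    def directed(self) -> bool:
        return self.pair_index.directed

    def to_long_frame(self):
        import pandas as pd

        rows = []
        for si, sid in enumerate(self.subjects):
            for pi, (i, j) in enumerate(self.pair_index.pairs):
                rows.append((sid, i, j, self.spi_name, self.values[si, pi]))
        return pd.DataFrame(
            rows, columns=["subject_id", "region_i", "region_j", "spi", "value"]
        )


def _subject_spi_row(mat: np.ndarray, name: str, pair_index: PairIndex) -> np.ndarray:
    out = np.empty(pair_index.n_pairs)
    cache: dict[tuple[int, int], float] = {}
    for pi, (i, j) in enumerate(pair_index.pairs):
        key = (i, j)
        if key not in cache:
            cache[key] = compute_spi(mat[i], mat[j], name)
        out[pi] = cache[key]
    return out


def compute_coupling_tensor(
    dataset: CohortDataset, spi_names: list[str] | str = "all", n_jobs: int = 1
) -> list[CouplingTensor]:
    """One coupling tensor per requested SPI, parallelizable over subjects.

    Results are independent of scheduling: subject rows are assembled in
    participants-table order regardless of worker completion order.
    """
    if spi_names == "all":
        names = list(SPI_NAMES)
    else:
        names = list(spi_names)
    unknown = [n for n in names if n not in SPI_NAMES]
    if unknown:
        raise ValueError(
            f"unknown SPI name(s) {unknown}; valid names: {', '.join(SPI_NAMES)}"
        )
    tensors = []
    for name in names:
        directed = name in DIRECTED_SPIS
        pidx = build_pair_index(dataset.n_regions, directed)
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_subject_spi_row)(dataset.series[sid], name, pidx)
            for sid in dataset.subjects
        )
        tensors.append(
            CouplingTensor(
                spi_name=name,
                values=np.vstack(rows),
                pair_index=pidx,
                subjects=list(dataset.subjects),
            )
        )
    return tensors
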