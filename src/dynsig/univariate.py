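"""Per-region univariate time-series features.

25 features per region: the canonical 22-feature set computed on the z-scored
series, the mean and sample SD of the raw series, and fALFF (fractional
amplitude of low-frequency fluctuations, the share of non-DC spectral power
in the 0.01-0.08 Hz band).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._catch22 import CATCH22_FEATURES
from .cohort import CohortDataset

log = logging.getLogger(__name__)

FALFF_BAND_HZ = (0.01, 0.08)

FEATURE_NAMES: tuple[str, ...] = tuple(sorted(CATCH22_FEATURES)) + (
    "mean",
    "SD",
    "fALFF",
)
N_FEATURES = len(FEATURE_NAMES)  # 25


class UndefinedFeatureError(ValueError):
    """A feature has no defined value for this input (e.g. constant series)."""


def raw_moments(series: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD (denominator T-1) of the raw series."""
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("raw_moments requires length >= 2")
    return float(y.mean()), float(y.std(ddof=1))


def falff(
    series: np.ndarray,
    tr_seconds: float,
    band_hz: tuple[float, float] = FALFF_BAND_HZ,
) -> float:
    """Fraction of non-DC periodogram power inside ``band_hz`` (inclusive).

    Uses the plain one-sided periodogram of the mean-removed series with no
    taper; the DC bin is excluded from both numerator and denominator.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 30:
        raise ValueError("falff requires length >= 30")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    nyquist = 0.5 / tr_seconds
    lo, hi = band_hz
    if hi > nyquist + 1e-12:
        raise ValueError(
            f"band upper edge {hi} Hz exceeds Nyquist {nyquist:.4f} Hz at TR={tr_seconds}s"
        )
    freqs = np.fft.rfftfreq(y.size, d=tr_seconds)
    power = np.abs(np.fft.rfft(y - y.mean())) ** 2
    nondc = freqs > 0
    total = power[nondc].sum()
    if total == 0:
        raise UndefinedFeatureError("constant series has no non-DC spectral power")
    in_band = nondc & (freqs >= lo) & (freqs <= hi)
    return float(power[in_band].sum() / total)


def catch22_features(series: np.ndarray) -> dict[str, float]:
    """The 22 canonical features of the z-scored series, keyed by name."""
    y = np.asarray(series, dtype=float)
    if y.size < 30:
        raise ValueError("catch22_features requires length >= 30")
    sd = y.std(ddof=1)
    if sd == 0:
        raise UndefinedFeatureError("constant series cannot be z-scored")
    z = (y - y.mean()) / sd
    return {name: float(fn(z)) for name, fn in sorted(CATCH22_FEATURES.items())}


@dataclass
class UnivariateFeatureTensor:
    """N x R x F array of per-region feature values.

    ``values`` may contain NaN where a feature was undefined; such cells are
    listed in ``missing_log`` and are imputed downstream inside each
    cross-validation training fold.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    subjects: list[str]
    region_labels: list[str]
    missing_log: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        n, r, f = self.values.shape
        assert f == len(self.feature_names)
        assert n == len(self.subjects) and r == len(self.region_labels)

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def to_long_frame(self):
        import pandas as pd

        n, r, f = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, self.region_labels, self.feature_names],
            names=["subject_id", "region", "feature"],
        )
        return pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()


def compute_feature_tensor(dataset: CohortDataset) -> UnivariateFeatureTensor:
    """Compute all 25 features for every subject and region.

    A feature that is undefined for a particular series is stored as NaN and
    logged; a region whose series is constant for some subject (so that every
    z-score-based feature fails) raises, matching the quality-control
    contract — drop the region at QC time instead if that is intended.
    """
    values = np.full(
        (dataset.n_subjects, dataset.n_regions, N_FEATURES), np.nan, dtype=float
    )
    missing: list[tuple[str, str, str]] = []
    for si, sid in enumerate(dataset.subjects):
        mat = dataset.series[sid]
        for ri, rlabel in enumerate(dataset.region_labels):
            y = mat[ri]
            if np.ptp(y) == 0:
                raise UndefinedFeatureError(
                    f"region {rlabel!r} is constant for subject {sid!r}; "
                    "re-run quality control with drop_constant_regions=True "
                    "to drop it cohort-wide"
                )
            mean, sd = raw_moments(y)
            row = dict.fromkeys(FEATURE_NAMES, np.nan)
            row["mean"], row["SD"] = mean, sd
            try:
                row["fALFF"] = falff(y, dataset.tr_seconds)
            except (UndefinedFeatureError, ValueError) as exc:
                missing.append((sid, rlabel, f"fALFF: {exc}"))
            feats = catch22_features(y)
            for name, val in feats.items():
                if np.isfinite(val):
                    row[name] = val
                else:
                    missing.append((sid, rlabel, f"{name}: non-finite"))
            values[si, ri] = [row[name] for name in FEATURE_NAMES]
    for sid, rlabel, msg in missing:
        log.warning("missing feature for %s/%s: %s", sid, rlabel, msg)
    return UnivariateFeatureTensor(
        values=values,
        feature_names=FEATURE_NAMES,
        subjects=list(dataset.subjects),
        region_labels=list(dataset.region_labels),
        missing_log=missing,
    )
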