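"""Classifier input designs assembled from feature and coupling tensors.

Five families are supported, named by what each represents:

- ``A_region(r)``     : all F univariate features of one region (D = F)
- ``A_feature(f)``    : one feature across all regions (D = R)
- ``A_uni_combo``     : all features x all regions (D = R*F, region-major)
- ``A_FC(spi)``       : all pair couplings for one SPI (D = P)
- ``A_FC_combo(spi)`` : the SPI's couplings plus the full univariate block
                        (D = P + R*F)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spis import CouplingTensor
from .univariate import UnivariateFeatureTensor

FAMILIES = ("A_region", "A_feature", "A_uni_combo", "A_FC", "A_FC_combo")


@dataclass
class RepresentationMatrix:
    """N x D design matrix with labels and per-column provenance.

    ``column_provenance`` holds one (source, location, measure) triple per
    column, where source is "univariate" or "coupling", location is a region
    label or an (i, j) pair, and measure is a feature or SPI name.
    """

    tag: str
    X: np.ndarray
    y: np.ndarray
    column_provenance: list[tuple[str, object, str]]
    subjects: list[str]

    def __post_init__(self) -> None:
        assert self.X.shape == (len(self.subjects), len(self.column_provenance))
        assert self.y.shape == (self.X.shape[0],)
        if self.X.shape[1] and np.isnan(self.X).all(axis=0).any():
            raise ValueError(f"representation {self.tag} has an all-missing column")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _labels(subjects: list[str], groups) -> np.ndarray:
    """Binary labels: 1 for the case group (lexicographically first label is
    taken as control unless labels are 'case'/'control')."""
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    case = "case" if "case" in uniq else uniq[1]
    return np.array([1 if g == case else 0 for g in groups], dtype=int)


def _univariate_block(
    feats: UnivariateFeatureTensor,
) -> tuple[np.ndarray, list[tuple[str, object, str]]]:
    n, r, f = feats.values.shape
    X = feats.values.reshape(n, r * f)  # region-major, feature-minor
    prov = [
        ("univariate", region, feat)
        for region in feats.region_labels
        for feat in feats.feature_names
    ]
    return X, prov


def build_representation(
    tag: str,
    feature_tensor: UnivariateFeatureTensor | None = None,
    coupling_tensor: CouplingTensor | None = None,
    groups=None,
    region: str | None = None,
    feature: str | None = None,
) -> RepresentationMatrix:
    """Assemble one representation matrix.

    ``groups`` is the per-subject group label sequence in subject order
    (e.g. ``dataset.group_labels()``).
    """
    if groups is None:
        raise ValueError("groups (per-subject labels) are required")

    if tag == "A_region":
        if feature_tensor is None or region is None:
            raise ValueError("A_region requires feature_tensor and region")
        ri = feature_tensor.region_labels.index(region)
        X = feature_tensor.values[:, ri, :]
        prov = [("univariate", region, f) for f in feature_tensor.feature_names]
        subjects = feature_tensor.subjects
        full_tag = f"A_region({region})"
    elif tag == "A_feature":
        if feature_tensor is None or feature is None:
            raise ValueError("A_feature requires feature_tensor and feature")
        fi = feature_tensor.feature_index(feature)
        X = feature_tensor.values[:, :, fi]
        prov = [("univariate", r, feature) for r in feature_tensor.region_labels]
        subjects = feature_tensor.subjects
        full_tag = f"A_feature({feature})"
    elif tag == "A_uni_combo":
        if feature_tensor is None:
            raise ValueError("A_uni_combo requires feature_tensor")
        X, prov = _univariate_block(feature_tensor)
        subjects = feature_tensor.subjects
        full_tag = "A_uni_combo"
    elif tag == "A_FC":
        if coupling_tensor is None:
            raise ValueError("A_FC requires coupling_tensor")
        X = coupling_tensor.values
        prov = [
            ("coupling", pair, coupling_tensor.spi_name)
            for pair in coupling_tensor.pair_index.pairs
        ]
        subjects = coupling_tensor.subjects
        full_tag = f"A_FC({coupling_tensor.spi_name})"
    elif tag == "A_FC_combo":
        if coupling_tensor is None or feature_tensor is None:
            raise ValueError("A_FC_combo requires both tensors")
        if coupling_tensor.subjects != feature_tensor.subjects:
            raise ValueError("tensor subject orderings disagree")
        Xu, pu = _univariate_block(feature_tensor)
        Xc = coupling_tensor.values
        pc = [
            ("coupling", pair, coupling_tensor.spi_name)
            for pair in coupling_tensor.pair_index.pairs
        ]
        X = np.hstack([Xc, Xu])
        prov = pc + pu
        subjects = coupling_tensor.subjects
        full_tag = f"A_FC_combo({coupling_tensor.spi_name})"
    else:
        raise ValueError(f"unknown representation family {tag!r}")

    y = _labels(subjects, groups)
    return RepresentationMatrix(
        tag=full_tag,
        X=np.asarray(X, dtype=float).copy(),
        y=y,
        column_provenance=prov,
        subjects=list(subjects),
    )


def enumerate_models(
    family: str,
    n_regions: int | None = None,
    feature_names: tuple[str, ...] | None = None,
    region_labels: list[str] | None = None,
    spi_names: tuple[str, ...] | None = None,
) -> list[str]:
    """List the model tags fit within one representation family."""
    if family == "A_region":
        labels = region_labels or [f"region_{i}" for i in range(n_regions or 0)]
        return [f"A_region({r})" for r in labels]
    if family == "A_feature":
        if feature_names is None:
            raise ValueError("A_feature enumeration needs feature_names")
        return [f"A_feature({f})" for f in feature_names]
    if family == "A_uni_combo":
        return ["A_uni_combo"]
    if family in ("A_FC", "A_FC_combo"):
        if spi_names is None:
            raise ValueError(f"{family} enumeration needs spi_names")
        return [f"{family}({s})" for s in spi_names]
    raise ValueError(f"unknown representation family {family!r}")
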