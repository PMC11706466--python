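"""Cohort data model, file I/O, and quality control.

A cohort is a set of subjects, each contributing one region x time matrix of
real-valued signals sampled on a uniform grid with spacing ``tr_seconds``,
together with a participants table holding the binary group label and optional
covariates (site, age, sex, mean framewise displacement).

Text dialect: one tab-separated file per subject, regions as rows, a leading
row-name column of region labels and a header row of timepoint indices.
HDF5 dialect: a single store with one dataset per subject under ``/series``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

MIN_TIMEPOINTS = 30
FD_THRESHOLD_MM = 0.55
HEAD_RADIUS_MM = 50.0

REQUIRED_PARTICIPANT_COLUMNS = ("subject_id", "group")


class CohortError(ValueError):
    """Structural or validation problem with cohort inputs."""


@dataclass
class MotionParams:
    """Six rigid-body head-motion parameters for one subject.

    ``params`` is a T x 6 array: columns 0-2 are translations in mm, columns
    3-5 are rotations in radians.
    """

    subject_id: str
    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise CohortError(
                f"motion parameters for {self.subject_id!r} must be T x 6, "
                f"got shape {self.params.shape}"
            )
        if not np.all(np.isfinite(self.params)):
            raise CohortError(f"non-finite motion parameters for {self.subject_id!r}")


@dataclass
class CohortDataset:
    """Multi-subject collection of region x time series plus metadata.

    Subject order follows the participants table everywhere; all downstream
    tensors index subjects identically.
    """

    subjects: list[str]
    series: dict[str, np.ndarray]
    region_labels: list[str]
    tr_seconds: float
    participants: pd.DataFrame
    qc_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def group_labels(self) -> pd.Series:
        tab = self.participants.set_index("subject_id")
        return tab.loc[self.subjects, "group"]

    def validate(self) -> None:
        if self.tr_seconds <= 0:
            raise CohortError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if "subject_id" not in self.participants or "group" not in self.participants:
            raise CohortError(
                "participants table must contain 'subject_id' and 'group' columns"
            )
        table_ids = list(self.participants["subject_id"].astype(str))
        if len(set(table_ids)) != len(table_ids):
            raise CohortError("duplicate subject_id in participants table")
        for sid in self.subjects:
            if sid not in self.series:
                raise CohortError(f"subject {sid!r} has no series")
            if sid not in table_ids:
                raise CohortError(f"subject {sid!r} missing from participants table")
        R = len(self.region_labels)
        for sid in self.subjects:
            mat = np.asarray(self.series[sid], dtype=float)
            if mat.ndim != 2:
                raise CohortError(f"series for {sid!r} is not a matrix")
            if mat.shape[0] != R:
                raise CohortError(
                    f"subject {sid!r} has {mat.shape[0]} regions, expected {R}"
                )
            if mat.shape[1] < MIN_TIMEPOINTS:
                raise CohortError(
                    f"subject {sid!r} has T={mat.shape[1]} < {MIN_TIMEPOINTS} timepoints"
                )
            self.series[sid] = mat
        groups = set(self.group_labels())
        if self.subjects and len(groups) != 2:
            raise CohortError(
                f"expected exactly two group labels among retained subjects, got {sorted(groups)}"
            )


def _read_series_file(path: Path) -> tuple[list[str], np.ndarray]:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    mat = frame.to_numpy()
    if mat.dtype == object or not np.issubdtype(mat.dtype, np.number):
        for i, row in enumerate(frame.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise CohortError(
                        f"non-numeric cell in {path.name} at row {frame.index[i]!r}, "
                        f"column {frame.columns[j]!r}: {v!r}"
                    ) from None
    return [str(r) for r in frame.index], mat.astype(float)


def load_cohort(
    series_paths: Mapping[str, str | Path] | Iterable[str | Path],
    participants_path: str | Path,
    tr_seconds: float,
) -> CohortDataset:
    """Load per-subject series files plus a participants table.

    ``series_paths`` maps subject id -> file path, or is an iterable of paths
    whose stems are taken as subject ids. Subject ordering follows the
    participants table.
    """
    participants = pd.read_csv(participants_path, sep=None, engine="python")
    for col in REQUIRED_PARTICIPANT_COLUMNS:
        if col not in participants.columns:
            raise CohortError(f"participants table missing required column {col!r}")
    participants["subject_id"] = participants["subject_id"].astype(str)

    if isinstance(series_paths, Mapping):
        path_map = {str(k): Path(v) for k, v in series_paths.items()}
    else:
        path_map = {Path(p).stem: Path(p) for p in series_paths}

    subjects = list(participants["subject_id"])
    series: dict[str, np.ndarray] = {}
    region_labels: list[str] | None = None
    for sid in subjects:
        if sid not in path_map:
            raise CohortError(f"participants row {sid!r} has no matching series file")
        labels, mat = _read_series_file(path_map[sid])
        if region_labels is None:
            region_labels = labels
        elif mat.shape[0] != len(region_labels):
            raise CohortError(
                f"subject {sid!r} has {mat.shape[0]} regions; "
                f"expected {len(region_labels)} as in first subject"
            )
        series[sid] = mat
    if region_labels is None:
        raise CohortError("no subjects found")
    return CohortDataset(
        subjects=subjects,
        series=series,
        region_labels=region_labels,
        tr_seconds=float(tr_seconds),
        participants=participants,
    )


def save_cohort_text(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write one TSV per subject plus a participants.tsv; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid in dataset.subjects:
        mat = dataset.series[sid]
        frame = pd.DataFrame(
            mat, index=dataset.region_labels, columns=np.arange(mat.shape[1])
        )
        frame.to_csv(out / f"{sid}.tsv", sep="\t", float_format="%.15g")
    dataset.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    return out


def save_cohort_hdf5(dataset: CohortDataset, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["tr_seconds"] = dataset.tr_seconds
        h5.create_dataset(
            "region_labels",
            data=np.array(dataset.region_labels, dtype=h5py.string_dtype()),
        )
        grp = h5.create_group("series")
        for sid in dataset.subjects:
            grp.create_dataset(sid, data=dataset.series[sid])
        h5.create_dataset(
            "participants_csv",
            data=dataset.participants.to_csv(index=False),
        )
    return path


def load_cohort_hdf5(path: str | Path) -> CohortDataset:
    import io

    with h5py.File(path, "r") as h5:
        tr = float(h5.attrs["tr_seconds"])
        region_labels = [s.decode() for s in h5["region_labels"][()]]
        participants = pd.read_csv(io.StringIO(h5["participants_csv"][()].decode()))
        participants["subject_id"] = participants["subject_id"].astype(str)
        series = {sid: h5["series"][sid][()] for sid in h5["series"]}
    subjects = [s for s in participants["subject_id"] if s in series]
    return CohortDataset(
        subjects=subjects,
        series=series,
        region_labels=region_labels,
        tr_seconds=tr,
        participants=participants,
    )


def framewise_displacement(
    motion: MotionParams, head_radius_mm: float = HEAD_RADIUS_MM
) -> tuple[np.ndarray, float]:
    """Per-frame framewise displacement and its mean.

    FD_t = sum_i |d translation_i| + sum_i |d rotation_i| * r, the Power
    convention with rotations converted to arc length on a sphere of radius
    ``head_radius_mm``. The first frame has FD 0 by definition.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise CohortError("framewise displacement requires T >= 2 frames")
    deltas = np.abs(np.diff(p, axis=0))
    fd = deltas[:, :3].sum(axis=1) + head_radius_mm * deltas[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    return fd, float(fd.mean())


def qc_filter(
    dataset: CohortDataset,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    drop_constant_regions: bool = False,
) -> CohortDataset:
    """Apply motion- and degeneracy-based subject exclusions.

    Subjects with mean FD strictly greater than ``fd_threshold_mm`` are
    excluded, as are subjects whose every regional series is constant.
    A region that is constant in some retained subject (but not in all
    regions of that subject) is dropped cohort-wide only when
    ``drop_constant_regions`` is set; otherwise it is left in place and
    feature extraction will raise on it. Exclusions are recorded in
    ``qc_log``. Filtering an already-filtered dataset removes nothing.
    """
    qc_log = list(dataset.qc_log)
    keep: list[str] = []
    tab = dataset.participants.set_index("subject_id")
    has_fd = "mean_fd" in dataset.participants.columns
    if not has_fd:
        qc_log.append(("*", "mean_fd missing; motion screening skipped"))
    for sid in dataset.subjects:
        mat = dataset.series[sid]
        if np.all(np.ptp(mat, axis=1) == 0):
            qc_log.append((sid, "constant_series"))
            continue
        if has_fd:
            fd = tab.loc[sid, "mean_fd"]
            if np.isfinite(fd) and fd > fd_threshold_mm:
                qc_log.append((sid, f"mean_fd>{fd_threshold_mm}"))
                continue
        keep.append(sid)

    region_mask = np.ones(dataset.n_regions, dtype=bool)
    if drop_constant_regions:
        for sid in keep:
            constant = np.ptp(dataset.series[sid], axis=1) == 0
            for r in np.nonzero(constant & region_mask)[0]:
                qc_log.append((sid, f"constant_region:{dataset.region_labels[r]}"))
            region_mask &= ~constant

    labels = [l for l, m in zip(dataset.region_labels, region_mask) if m]
    series = {sid: dataset.series[sid][region_mask] for sid in keep}
    participants = dataset.participants[
        dataset.participants["subject_id"].isin(keep)
    ].reset_index(drop=True)
    groups = participants["group"].value_counts()
    if len(groups) < 2 or groups.min() < 2:
        raise CohortError(
            "quality control left fewer than 2 subjects in some group; "
            f"counts: {groups.to_dict()}"
        )
    return CohortDataset(
        subjects=keep,
        series=series,
        region_labels=labels,
        tr_seconds=dataset.tr_seconds,
        participants=participants,
        qc_log=qc_log,
    )
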