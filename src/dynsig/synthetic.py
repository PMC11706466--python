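"""Synthetic multi-subject cohorts from first-order vector autoregressions.

Each subject's region x time matrix is an independent realization of

    x_t = A x_{t-1} + eps_t,   eps_t ~ N(0, diag(noise_sd^2)),

with a burn-in discarded. Group effects are injected into the case group
only, in three ways that mirror the effect classes detectable downstream:
a multiplicative change to regional noise SD, an additive shift of the
diagonal AR coefficient (autocorrelation timescale), and an additive shift
of off-diagonal coupling entries. An optional motion-like confound adds a
shared global AR(1) component scaled per subject by a synthetic mean-FD
value drawn with an optional group offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortDataset

BURN_IN = 100

CASE_LABEL = "case"
CONTROL_LABEL = "control"


@dataclass
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    ``base_coupling`` is either an R x R off-diagonal matrix, or one of the
    templates ``"none"``, ``"chain"`` (each region driven by its predecessor
    with weight 0.2), or ``"dense(rho)"`` (all off-diagonal entries rho).
    Effects apply to case-group subjects only.
    """

    n_per_group: tuple[int, int] = (20, 20)
    n_regions: int = 6
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    base_ar: float = 0.3
    base_coupling: str | np.ndarray = "none"
    noise_sd: float | np.ndarray = 1.0
    sd_scale: tuple[tuple[int, ...], float] | None = None
    ar_shift: tuple[tuple[int, ...], float] | None = None
    coupling_shift: tuple[tuple[tuple[int, int], ...], float] | None = None
    motion_confound: tuple[float, float] | None = None  # (strength, group offset)
    seed: int = 0

    def transition_matrix(self, case: bool) -> np.ndarray:
        R = self.n_regions
        A = np.zeros((R, R))
        if isinstance(self.base_coupling, str):
            name = self.base_coupling
            if name == "none":
                pass
            elif name == "chain":
                for i in range(1, R):
                    A[i, i - 1] = 0.2
            elif name.startswith("dense(") and name.endswith(")"):
                rho = float(name[len("dense(") : -1])
                A[:] = rho
                np.fill_diagonal(A, 0.0)
            else:
                raise ValueError(f"unknown coupling template {name!r}")
        else:
            A = np.array(self.base_coupling, dtype=float)
            if A.shape != (R, R):
                raise ValueError("base_coupling matrix must be R x R")
            np.fill_diagonal(A, 0.0)
        np.fill_diagonal(A, self.base_ar)
        if case:
            if self.ar_shift is not None:
                regions, delta = self.ar_shift
                for r in regions:
                    A[r, r] += delta
            if self.coupling_shift is not None:
                pairs, delta = self.coupling_shift
                for i, j in pairs:
                    A[i, j] += delta
        return A

    def noise_vector(self, case: bool) -> np.ndarray:
        sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_regions,)
        ).copy()
        if case and self.sd_scale is not None:
            regions, mult = self.sd_scale
            if mult <= 0:
                raise ValueError("sd_scale multiplier must be positive")
            for r in regions:
                sd[r] *= mult
        return sd

    def validate(self) -> None:
        if self.n_timepoints < 30:
            raise ValueError("n_timepoints must be >= 30")
        if min(self.n_per_group) < 1:
            raise ValueError("n_per_group entries must be positive")
        for case in (False, True):
            A = self.transition_matrix(case)
            radius = np.max(np.abs(np.linalg.eigvals(A)))
            if radius >= 1.0:
                raise ValueError(
                    f"VAR(1) transition matrix has spectral radius {radius:.3f} >= 1 "
                    f"({'case' if case else 'control'} group); process not stationary"
                )


def _simulate_var(
    A: np.ndarray, noise_sd: np.ndarray, T: int, rng: np.random.Generator
) -> np.ndarray:
    R = A.shape[0]
    total = T + BURN_IN
    eps = rng.standard_normal((total, R)) * noise_sd
    x = np.zeros((total, R))
    for t in range(1, total):
        x[t] = A @ x[t - 1] + eps[t]
    return x[BURN_IN:].T  # R x T


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate a two-group cohort; deterministic under (spec, spec.seed).

    Per-subject noise streams are derived from the master seed via
    ``numpy``'s ``SeedSequence.spawn`` so subject order does not perturb
    other subjects' realizations.
    """
    spec.validate()
    n_control, n_case = spec.n_per_group
    n_total = n_control + n_case
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(n_total + 1)
    meta_rng = np.random.default_rng(children[-1])

    subjects, series, rows = [], {}, []
    region_labels = [f"region_{r}" for r in range(spec.n_regions)]
    for i in range(n_total):
        case = i >= n_control
        sid = f"sub-{i:03d}"
        rng = np.random.default_rng(children[i])
        A = spec.transition_matrix(case)
        sd = spec.noise_vector(case)
        mat = _simulate_var(A, sd, spec.n_timepoints, rng)
        mean_fd = 0.0
        if spec.motion_confound is not None:
            strength, offset = spec.motion_confound
            mean_fd = abs(meta_rng.normal(0.2 + (offset if case else 0.0), 0.05))
            # global AR(1) nuisance component shared across regions
            u = _simulate_var(
                np.array([[0.5]]), np.array([1.0]), spec.n_timepoints, rng
            )[0]
            mat = mat + strength * mean_fd * u[None, :]
        subjects.append(sid)
        series[sid] = mat
        rows.append(
            {
                "subject_id": sid,
                "group": CASE_LABEL if case else CONTROL_LABEL,
                "mean_fd": mean_fd,
            }
        )
    return CohortDataset(
        subjects=subjects,
        series=series,
        region_labels=region_labels,
        tr_seconds=spec.tr_seconds,
        participants=pd.DataFrame(rows),
    )


def generate_null_cohort(spec: CohortSpec) -> CohortDataset:
    """Same generative process for both groups: all group effects removed."""
    from dataclasses import replace

    null_spec = replace(spec, sd_scale=None, ar_shift=None, coupling_shift=None)
    if null_spec.motion_confound is not None:
        strength, _ = null_spec.motion_confound
        null_spec = replace(null_spec, motion_confound=(strength, 0.0))
    return generate_cohort(null_spec)
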