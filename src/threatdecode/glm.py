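"""Trial-block GLM: design construction and AR(1)-prewhitened estimation.

Each (trial-block x CS type) cell gets one HRF-convolved boxcar regressor;
shock events get their own 0.5 s regressor so CS betas are shock-adjusted.
Nuisance terms: 6 motion parameters, a discrete-cosine high-pass set with a
128 s cutoff, polynomial drift (constant/linear/quadratic), and one-hot
spike regressors for volumes with framewise displacement above 0.9 mm
(equivalent to row deletion under ordinary least squares). Temporal noise
structure is handled by estimating a single lag-1 autocorrelation pooled
over voxels and refitting after the AR(1) (Cochrane-Orcutt) transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .conditions import Condition
from .datasets import BetaMapSet
from .events import SHOCK_DURATION_S, EventSchedule

HEAD_RADIUS_MM = 50.0
FD_CENSOR_THRESHOLD_MM = 0.9
HIGHPASS_CUTOFF_S = 128.0


@dataclass
class BoldRun:
    """Preprocessed BOLD series: T volumes x V voxels."""

    data: np.ndarray
    tr: float
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be (volumes, voxels)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_vols(self) -> int:
        return self.data.shape[0]


def compute_framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Power framewise displacement: sum |d translation| + 50 mm * sum |d rotation|.

    ``motion`` is (T, 6): three translations (mm) then three rotations
    (radians). The first volume has no predecessor, so fd[0] = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must have 6 columns (3 translations, 3 rotations)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


@dataclass
class ConfoundSet:
    """Per-volume motion parameters, framewise displacement, censor flags."""

    motion: np.ndarray
    fd: np.ndarray
    censor: np.ndarray
    threshold_mm: float = FD_CENSOR_THRESHOLD_MM

    @classmethod
    def from_motion(cls, motion: np.ndarray,
                    threshold_mm: float = FD_CENSOR_THRESHOLD_MM) -> "ConfoundSet":
        fd = compute_framewise_displacement(motion)
        return cls(np.asarray(motion, float), fd, fd > threshold_mm, threshold_mm)

    def to_frame(self) -> pd.DataFrame:
        cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        frame = pd.DataFrame(self.motion, columns=cols)
        frame["framewise_displacement"] = self.fd
        return frame

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path, threshold_mm: float = FD_CENSOR_THRESHOLD_MM) -> "ConfoundSet":
        frame = pd.read_csv(path, sep="\t")
        motion = frame.iloc[:, :6].to_numpy()
        return cls.from_motion(motion, threshold_mm)


def double_gamma_hrf(dt: float, time_length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` s, peak normalized to 1.

    Response gamma peaks at 6 s, the undershoot gamma at 16 s, with an
    undershoot-to-peak ratio of 1/6.
    """
    t = np.arange(0, time_length_s, dt)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.max()


def _cosine_basis(n_vols: int, tr: float, cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """DCT-II high-pass basis: frequencies below 1/cutoff."""
    n_basis = int(np.floor(2.0 * n_vols * tr / cutoff_s))
    t = np.arange(n_vols)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_vols)) for k in range(1, n_basis + 1)]
    return np.column_stack(cols) if cols else np.empty((n_vols, 0))


@dataclass
class DesignMatrix:
    """T x K design with labeled columns; task columns listed separately."""

    matrix: np.ndarray
    names: list[str]
    task_names: list[str]
    censored_volumes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("column names do not match design width")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")

    @property
    def n_vols(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def build_design_matrix(
    schedule: EventSchedule,
    confounds: ConfoundSet | None,
    tr: float,
    n_vols: int,
    pool_csplus: bool = True,
    oversample: int = 16,
    poly_order: int = 2,
) -> DesignMatrix:
    """Assemble task, shock, and nuisance regressors for one run.

    Task regressors are 6 s boxcars at the CS onsets of each trial-block
    condition, convolved with the canonical HRF on an ``oversample``-fold
    finer grid and sampled at the volume times.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    run_len = n_vols * tr
    last_event_end = max(
        (
            (t.shock_onset_s + SHOCK_DURATION_S) if t.reinforced
            else (t.cs_onset_s + t.cs_duration_s)
        )
        for t in schedule.trials
    ) if schedule.trials else 0.0
    if last_event_end > run_len:
        raise ValueError(
            f"events extend to {last_event_end:.1f} s but the run ends at {run_len:.1f} s"
        )

    dt = tr / oversample
    n_fine = n_vols * oversample
    hrf = double_gamma_hrf(dt)

    def convolved(onsets, durations) -> np.ndarray:
        box = np.zeros(n_fine)
        for onset, dur in zip(onsets, durations):
            i0 = int(np.round(onset / dt))
            i1 = int(np.round((onset + dur) / dt))
            box[i0:min(i1, n_fine)] = 1.0
        return np.convolve(box, hrf)[:n_fine][::oversample]

    cols, names, task_names = [], [], []
    trial_by_index = {t.index: t for t in schedule.trials}
    for condition, trial_idx in schedule.block_assignments(pool_csplus=pool_csplus):
        trials = [trial_by_index[i] for i in trial_idx]
        cols.append(convolved([t.cs_onset_s for t in trials],
                              [t.cs_duration_s for t in trials]))
        name = condition.label if isinstance(condition, Condition) else str(condition)
        names.append(name)
        task_names.append(name)

    shock_onsets = [t.shock_onset_s for t in schedule.trials if t.reinforced]
    if shock_onsets:
        cols.append(convolved(shock_onsets, [SHOCK_DURATION_S] * len(shock_onsets)))
        names.append("shock")

    if confounds is not None:
        if confounds.motion.shape[0] != n_vols:
            raise ValueError("confounds do not match the run length")
        for j, nm in enumerate(["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]):
            cols.append(confounds.motion[:, j])
            names.append(nm)

    cosine = _cosine_basis(n_vols, tr)
    for j in range(cosine.shape[1]):
        cols.append(cosine[:, j])
        names.append(f"cosine{j + 1:02d}")

    t_scaled = np.linspace(-1.0, 1.0, n_vols)
    for order in range(poly_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(order)(t_scaled))
        names.append(f"poly{order}")

    censored = np.array([], dtype=int)
    if confounds is not None:
        censored = np.flatnonzero(confounds.censor)
        for v in censored:
            onehot = np.zeros(n_vols)
            onehot[v] = 1.0
            cols.append(onehot)
            names.append(f"censor{v:04d}")

    return DesignMatrix(np.column_stack(cols), names, task_names, censored)


@dataclass
class GlmResult:
    """Per-run GLM estimates: one beta map per task column plus diagnostics."""

    betas: np.ndarray            # (K, V) all columns
    names: list[str]
    task_names: list[str]
    rho: float
    residual_sd: np.ndarray

    def beta_map(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]

    def task_betas(self) -> dict[str, np.ndarray]:
        return {nm: self.beta_map(nm) for nm in self.task_names}


def _ar1_transform(A: np.ndarray, rho: float) -> np.ndarray:
    """Prewhitening transform: rows become x_t - rho x_{t-1} (first row scaled)."""
    out = np.empty_like(A)
    out[0] = np.sqrt(1.0 - rho**2) * A[0]
    out[1:] = A[1:] - rho * A[:-1]
    return out


def fit_glm_ar1(bold: BoldRun, design: DesignMatrix, rho: float | None = None) -> GlmResult:
    """Generalized least squares with a pooled AR(1) noise model.

    Ordinary least squares first; the lag-1 autocorrelation of its residuals
    (pooled across voxels, skipping volume pairs that touch a censored
    volume) gives rho; both sides are then prewhitened and refit. Passing
    ``rho`` explicitly (e.g. 0) skips estimation.
    """
    X = design.matrix
    Y = bold.data
    T, K = X.shape
    if Y.shape[0] != T:
        raise ValueError("design and BOLD run have different lengths")
    if T <= K:
        raise ValueError(f"underdetermined fit: {T} volumes for {K} regressors")
    if np.linalg.matrix_rank(X) < K:
        raise ValueError("design matrix is rank deficient after censoring")

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    if rho is None:
        resid = Y - X @ beta
        valid = np.ones(T, dtype=bool)
        valid[design.censored_volumes] = False
        pair = valid[1:] & valid[:-1]
        num = float((resid[1:][pair] * resid[:-1][pair]).sum())
        den = float((resid[:-1][pair] ** 2).sum())
        rho = num / den if den > 0 else 0.0
        rho = float(np.clip(rho, -0.99, 0.99))
    if rho != 0.0:
        Xw = _ar1_transform(X, rho)
        Yw = _ar1_transform(Y, rho)
        beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        resid_w = Yw - Xw @ beta
    else:
        resid_w = Y - X @ beta
    dof = max(T - K, 1)
    return GlmResult(beta, list(design.names), list(design.task_names),
                     float(rho), np.sqrt((resid_w**2).sum(axis=0) / dof))


def results_to_mapset(
    results: dict[str, GlmResult],
    grid_shape: tuple[int, int, int] | None = None,
    affine: np.ndarray | None = None,
    site: np.ndarray | None = None,
) -> BetaMapSet:
    """Assemble per-participant GLM results into one BetaMapSet.

    ``results`` maps participant id -> GlmResult; every result must share the
    same task-condition labels, which become the dataset's condition grid.
    """
    participants = list(results)
    first = results[participants[0]]
    conditions = [Condition.from_label(nm) for nm in first.task_names]
    values = np.stack(
        [np.stack([results[p].beta_map(c.label) for c in conditions]) for p in participants]
    )
    return BetaMapSet(values, participants, conditions, grid_shape, affine, site)
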