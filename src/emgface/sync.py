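"""Temporal alignment of simulated and measured marker trajectories.

Repetitions are performed at different speeds and the model output has
its own timing, so before computing correlations both trajectory sets are
(1) resampled onto a common uniform grid (default 160 frames, the model's
step count), (2) reduced to one dimension by projecting the stacked
30 x T coordinate matrix onto its first principal component (via SVD),
and (3) aligned by the integer frame shift that maximises the
cross-correlation of the two coefficient vectors.  The shift found in the
PCA domain is then applied to the resampled trajectories and the
overlapping region is cropped to equal length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .fem import TrajectorySet


@dataclass
class PCACoefficients:
    """First-principal-component reduction of a 30 x T marker matrix."""

    b: np.ndarray          # coefficient vector, length T
    u1: np.ndarray         # first principal direction, length 30, unit norm
    variances: np.ndarray  # squared singular values, nonincreasing


@dataclass
class SyncResult:
    """Aligned trajectory pair plus the diagnostics that produced it."""

    sim: TrajectorySet
    meas: TrajectorySet
    shift: int
    b_sim: np.ndarray
    b_meas: np.ndarray

    def __iter__(self):
        return iter((self.sim, self.meas))


def resample_trajectories(traj: TrajectorySet, frames: int = 160
                          ) -> TrajectorySet:
    """Linear-interpolation resampling onto ``frames`` uniform frames.

    The output spans the same duration as the input, so the frame rate is
    rescaled accordingly.
    """
    if frames < 2:
        raise ValueError("need at least 2 output frames")
    n = traj.n_frames
    if n < 2:
        raise ValueError("need at least 2 input frames to resample")
    t_old = np.linspace(0.0, 1.0, n)
    t_new = np.linspace(0.0, 1.0, frames)
    pos = np.empty((traj.n_markers, frames, 3))
    for m in range(traj.n_markers):
        for k in range(3):
            pos[m, :, k] = np.interp(t_new, t_old, traj.positions[m, :, k])
    duration = (n - 1) / traj.frame_rate
    rate = (frames - 1) / duration if duration > 0 else traj.frame_rate
    return replace(traj, positions=pos, frame_rate=rate)


def stack_matrix(traj: TrajectorySet) -> np.ndarray:
    """Stack marker coordinates into the (3*M) x T matrix X."""
    # rows: marker 0 x, y, z, marker 1 x, y, z, ...
    return traj.positions.transpose(0, 2, 1).reshape(
        3 * traj.n_markers, traj.n_frames
    )


def pca_first_component(X: np.ndarray, center: bool = True
                        ) -> PCACoefficients:
    """First principal component of X via SVD.

    Rows are centred by default (the coefficient vector of uncentred data
    is dominated by the mean offset, which defeats the later
    cross-correlation).  Sign convention: the largest-magnitude entry of
    ``b`` is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 time columns")
    Xc = X - X.mean(axis=1, keepdims=True) if center else X
    if not np.any(Xc):
        raise ValueError("constant trajectory matrix has no principal "
                         "direction")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    u1 = U[:, 0]
    b = u1 @ Xc
    if b[np.argmax(np.abs(b))] < 0:
        u1 = -u1
        b = -b
    return PCACoefficients(b=b, u1=u1, variances=s**2)


def align_by_crosscorr(b_est: np.ndarray, b_meas: np.ndarray,
                       min_overlap: int | None = None) -> int:
    """Integer shift d maximising the normalised cross-correlation.

    Both vectors are mean-removed; at every candidate lag the
    correlation of the overlapping segments is normalised by the
    segment norms, so the score is a true correlation in [-1, 1] and a
    pure delay is recovered without bias.  Lags leaving fewer than
    ``min_overlap`` samples (default T/4) are not considered.  The
    returned d satisfies, for a pure delay, ``b_meas(t) = b_est(t - d)``.
    Ties prefer the smallest ``|d|``.  A constant input yields shift 0
    with a warning.
    """
    e = np.asarray(b_est, dtype=float)
    m = np.asarray(b_meas, dtype=float)
    if e.shape != m.shape or e.ndim != 1:
        raise ValueError("coefficient vectors must be 1-D of equal length")
    T = e.size
    if min_overlap is None:
        min_overlap = max(2, T // 4)
    e = e - e.mean()
    m = m - m.mean()
    if np.linalg.norm(e) == 0.0 or np.linalg.norm(m) == 0.0:
        warnings.warn("constant coefficient vector: returning shift 0",
                      stacklevel=2)
        return 0
    # numerator(d) = sum_t e[t] m[t + d]
    num = np.correlate(m, e, mode="full")   # index k <-> d = k - (T - 1)
    lags = np.arange(-(T - 1), T)
    ce = np.concatenate([[0.0], np.cumsum(e * e)])
    cm = np.concatenate([[0.0], np.cumsum(m * m)])
    pos = lags >= 0
    d = lags
    ne = np.where(pos, ce[np.clip(T - d, 0, T)], ce[T] - ce[np.clip(-d, 0, T)])
    nm = np.where(pos, cm[T] - cm[np.clip(d, 0, T)],
                  cm[np.clip(T + d, 0, T)])
    denom = np.sqrt(ne * nm)
    score = np.where(denom > 0, num / np.maximum(denom, 1e-300), -np.inf)
    score[T - np.abs(lags) < min_overlap] = -np.inf
    order = np.lexsort((-lags, np.abs(lags), -score))
    return int(lags[order[0]])


def synchronise(
    sim: TrajectorySet,
    meas: TrajectorySet,
    frames: int = 160,
    min_overlap: int = 16,
) -> SyncResult:
    """Resample both sets, find the PCA-domain shift, crop to overlap."""
    if sim.n_markers != meas.n_markers:
        raise ValueError("trajectory sets must share the same marker set")
    sim_r = resample_trajectories(sim, frames)
    meas_r = resample_trajectories(meas, frames)
    b_sim = pca_first_component(stack_matrix(sim_r)).b
    b_meas = pca_first_component(stack_matrix(meas_r)).b
    # the PC sign convention can disagree between the two reductions;
    # resolve the relative sign by the peak cross-correlation magnitude
    e = b_sim - b_sim.mean()
    m = b_meas - b_meas.mean()
    if np.linalg.norm(e) > 0 and np.linalg.norm(m) > 0:
        full = np.correlate(m, e, mode="full")
        if np.abs(full.min()) > np.abs(full.max()):
            b_meas = -b_meas
    d = align_by_crosscorr(b_sim, b_meas,
                           min_overlap=max(min_overlap, frames // 4))
    if d >= 0:
        sim_c = sim_r.positions[:, : frames - d, :]
        meas_c = meas_r.positions[:, d:, :]
    else:
        sim_c = sim_r.positions[:, -d:, :]
        meas_c = meas_r.positions[:, : frames + d, :]
    if sim_c.shape[1] < min_overlap:
        raise ValueError(
            f"only {sim_c.shape[1]} overlapping frames after shift {d}; "
            f"need at least {min_overlap}"
        )
    return SyncResult(
        sim=replace(sim_r, positions=sim_c),
        meas=replace(meas_r, positions=meas_c),
        shift=d,
        b_sim=b_sim,
        b_meas=b_meas,
    )
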