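"""Single-trial ("beta series") GLM estimation.

Every trial is estimated in its own GLM: one convolved regressor for the
trial of interest, convolved categorical regressors for all other onsets
split by condition (HR/HF/LR/LF), one convolved regressor for button
presses, seven non-convolved confound columns (six rigid motion
parameters plus framewise displacement, consumed as supplied), and one
constant per concatenated run. Beta maps are converted to t maps with
OLS residual degrees of freedom; t maps are then minimally smoothed
before pattern extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .design import TrialTable

log = logging.getLogger(__name__)

#: full width at half maximum -> Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

CONDITIONS = ("HR", "HF", "LR", "LF")


class RankDeficientDesign(ValueError):
    """Design matrix is rank deficient; message names collinear columns."""


def hrf_kernel(dt: float, duration: float = 32.0, peak_delay: float = 6.0,
               undershoot_delay: float = 16.0, peak_disp: float = 1.0,
               undershoot_disp: float = 1.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at ``dt``.

    Difference of two gamma densities (peak ~5 s, undershoot ~15 s) with
    the widely used parameterization (delays 6/16 s, dispersions 1/1,
    peak:undershoot ratio 6), normalized to unit sum so convolution
    preserves the scale of a sustained response.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration + dt, dt)
    h = (gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - gamma_dist.pdf(t, undershoot_delay / undershoot_disp,
                          scale=undershoot_disp) / ratio)
    return h / h.sum()


def convolved_regressor(onsets: np.ndarray, durations: np.ndarray,
                        n_scans: int, tr: float,
                        oversample: int = 16) -> np.ndarray:
    """Boxcar events convolved with the canonical HRF, sampled at scan times.

    Built on an oversampled grid (``tr / oversample``) so that onsets
    between scans are handled exactly; the same routine drives both BOLD
    simulation and design construction, making noiseless recovery exact.
    """
    onsets = np.atleast_1d(np.asarray(onsets, float))
    durations = np.broadcast_to(np.asarray(durations, float), onsets.shape)
    dt = tr / oversample
    n_fine = n_scans * oversample + 1
    box = np.zeros(n_fine)
    for on, du in zip(onsets, durations):
        i0 = int(round(on / dt))
        i1 = int(round((on + max(du, dt)) / dt))
        if i0 >= n_fine:
            continue
        box[i0:min(i1, n_fine)] = 1.0
    h = hrf_kernel(dt)
    conv = np.convolve(box, h)[:n_fine]
    return conv[::oversample][:n_scans]


@dataclass
class DesignMatrix:
    """Design for a single-trial GLM over concatenated runs."""

    matrix: np.ndarray           # scans x regressors
    names: list[str]
    trial_column: int            # index of the trial-of-interest column

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]


def trial_conditions(table: TrialTable, retrieval: TrialTable) -> np.ndarray:
    """Condition label (HR/HF/LR/LF) per trial of ``table``.

    The memory factor of an encoding trial is the next-day recall outcome
    of its object, looked up in the retrieval table.
    """
    if retrieval.remembered is None:
        raise ValueError("retrieval table has no 'remembered' field")
    rem_of = np.zeros(int(retrieval.object_id.max()) + 1, bool)
    rem_of[retrieval.object_id] = retrieval.remembered
    rem = rem_of[table.object_id]
    labels = np.where(table.reward_high,
                      np.where(rem, "HR", "HF"),
                      np.where(rem, "LR", "LF"))
    return labels


def build_design(trial_index: int, events: TrialTable,
                 conditions: np.ndarray, run_lengths: list[int], tr: float,
                 confounds: np.ndarray | None = None,
                 oversample: int = 16) -> DesignMatrix:
    """Design matrix for the GLM of a single trial.

    ``conditions`` gives the HR/HF/LR/LF label of every trial in
    ``events`` (see :func:`trial_conditions`). ``confounds`` is a
    scans x k array of non-convolved noise regressors (the study used
    seven: six motion parameters plus framewise displacement). Empty
    condition groups are omitted with a logged notice rather than kept
    as all-zero columns.
    """
    n_trials = len(events)
    if not 0 <= trial_index < n_trials:
        raise IndexError(f"trial_index {trial_index} out of range 0..{n_trials - 1}")
    n_runs = len(run_lengths)
    n_scans = int(sum(run_lengths))
    run_ids = sorted(np.unique(events.run))
    if len(run_ids) != n_runs:
        raise ValueError("run_lengths length does not match runs in events")
    run_start = dict(zip(run_ids,
                         np.concatenate([[0], np.cumsum(run_lengths)[:-1]]) * tr))

    # onsets on the concatenated time axis
    global_onsets = events.onset + np.array([run_start[r] for r in events.run])

    cols: list[np.ndarray] = []
    names: list[str] = []

    cols.append(convolved_regressor(global_onsets[trial_index],
                                    events.duration[trial_index],
                                    n_scans, tr, oversample))
    names.append(f"trial_{trial_index:04d}")

    others = np.ones(n_trials, bool)
    others[trial_index] = False
    for cond in CONDITIONS:
        sel = others & (conditions == cond)
        if not sel.any():
            log.info("condition %s has no other onsets for trial %d; "
                     "column omitted", cond, trial_index)
            continue
        cols.append(convolved_regressor(global_onsets[sel], events.duration[sel],
                                        n_scans, tr, oversample))
        names.append(f"others_{cond}")

    if events.rt is not None:
        press = np.isfinite(events.rt)
        if press.any():
            cols.append(convolved_regressor(
                global_onsets[press] + events.rt[press], 0.0,
                n_scans, tr, oversample))
            names.append("button_press")
        else:
            log.info("no button presses; column omitted")

    if confounds is not None:
        confounds = np.asarray(confounds, float)
        if confounds.shape[0] != n_scans:
            raise ValueError("confounds rows must equal total scans")
        for j in range(confounds.shape[1]):
            cols.append(confounds[:, j])
            names.append(f"confound_{j}")

    offset = 0
    for r, length in zip(run_ids, run_lengths):
        const = np.zeros(n_scans)
        const[offset:offset + length] = 1.0
        cols.append(const)
        names.append(f"run_{r}_constant")
        offset += length

    return DesignMatrix(np.column_stack(cols), names, trial_column=0)


def fit_trial(ts: np.ndarray, design: DesignMatrix
              ) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit; returns (beta, t) of the trial-of-interest column per voxel.

    ``ts`` is scans x voxels. t = beta / SE(beta) with residual degrees
    of freedom ``scans - rank(X)``. Raises :class:`RankDeficientDesign`
    naming the collinear columns if X is not full column rank.
    """
    X = design.matrix
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name columns whose removal restores full rank among the rest
        bad = []
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(design.names[j])
        raise RankDeficientDesign(
            f"design matrix is rank deficient (rank {rank} < {p} columns); "
            f"collinear columns: {bad}")
    ts = np.asarray(ts, float)
    squeeze = ts.ndim == 1
    Y = ts[:, None] if squeeze else ts

    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta_all
    df = n - rank
    sigma2 = (resid ** 2).sum(axis=0) / df
    j = design.trial_column
    beta = beta_all[j]
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    if squeeze:
        return beta[0], t[0]
    return beta, t


def beta_series(ts: np.ndarray, events: TrialTable, conditions: np.ndarray,
                run_lengths: list[int], tr: float,
                confounds: np.ndarray | None = None,
                oversample: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """One GLM per trial; returns (betas, ts) of shape trials x voxels."""
    betas, tvals = [], []
    for i in range(len(events)):
        design = build_design(i, events, conditions, run_lengths, tr,
                              confounds, oversample)
        b, t = fit_trial(ts, design)
        betas.append(b)
        tvals.append(t)
    return np.asarray(betas), np.asarray(tvals)


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float,
                    voxel_size_mm: float | tuple[float, float, float] = 2.0
                    ) -> np.ndarray:
    """Separable Gaussian smoothing of a 3D volume (or 4D stack of volumes).

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, in voxel units. Uses
    zero padding at the edges ('constant' mode), so the image sum is
    conserved for impulses whose kernel support stays inside the volume.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return np.asarray(volume, float).copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    sigma = [fwhm_mm * FWHM_TO_SIGMA / v for v in vs]
    vol = np.asarray(volume, float)
    if vol.ndim == 4:
        sigma = sigma + [0.0]
    elif vol.ndim != 3:
        raise ValueError("expected a 3D volume or 4D stack")
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="constant")
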