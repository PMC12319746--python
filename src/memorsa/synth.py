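"""Synthetic cohorts with planted reinstatement and convergence structure.

The generative model plants, per region profile, the representational
effects the analysis pipeline is built to detect:

* encoding pattern of trial with object *o*, scene *s*::

      x_enc = encoding_scene_gain * P[s] + object_gain * O[o] + noise

* retrieval pattern of the trial cueing object *o* (scene *s*)::

      x_ret = g_reinst(remembered) * P[s] + g_conv(reward) * Q[s]
              + object_gain * O[o] + noise

``P`` are scene prototypes active during encoding; reinstatement during
retrieval re-expresses them, producing encoding-retrieval similarity for
same-scene pairs. ``Q`` are *retrieval-phase* scene prototypes drawn
orthogonal to all ``P``, so that retrieval-retrieval convergence is
dissociable from reinstatement by construction. Noise is i.i.d.
Gaussian per voxel (``noise_sd``).

Note one structural consequence: any model in which remembered retrieval
trials carry ``P[s]`` (required for encoding-retrieval similarity)
also gives two same-scene remembered retrieval trials a shared component
of squared magnitude ``g_reinst**2``. The default reinstatement gain is
therefore small relative to the encoding scene gain, keeping this
second-order retrieval-retrieval covariance near the detection floor
(see docs/methods.md for the calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (DONT_KNOW, TrialTable, make_design)


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters (and realized prototypes)."""

    # structural gains
    reinstatement_gain_remembered: float = 0.0
    reinstatement_gain_forgotten: float = 0.0
    convergence_gain_high: float = 0.0
    convergence_gain_low: float = 0.0
    encoding_scene_gain: float = 0.7
    object_gain: float = 0.5
    # per-voxel sd; 0.08 makes the total noise magnitude ~1 at the
    # default 150 voxels, on the order of the structured components
    noise_sd: float = 0.08
    # behavior
    p_remember_high: float = 0.537
    p_remember_low: float = 0.513
    p_encoding_correct: float = 0.97
    p_dont_know: float = 0.5       # error split: don't-know vs wrong scene
    seed: int | None = None
    # realized prototypes, filled by simulate_patterns
    scene_encoding_prototypes: np.ndarray | None = None   # P, scenes x voxels
    scene_retrieval_prototypes: np.ndarray | None = None  # Q, scenes x voxels
    object_components: np.ndarray | None = None           # O, objects x voxels

    def __post_init__(self) -> None:
        for name in ("reinstatement_gain_remembered",
                     "reinstatement_gain_forgotten", "convergence_gain_high",
                     "convergence_gain_low", "encoding_scene_gain",
                     "object_gain", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("p_remember_high", "p_remember_low",
                     "p_encoding_correct", "p_dont_know"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


#: Gain presets per region profile, mirroring the result patterns the
#: pipeline should recover: a memory-gated reinstatement region
#: (phc_like), a reward-independent convergence region (mpfc_like), a
#: reward-gated convergence region (ahc_like), and a structureless
#: control (null). Calibrated once for >=90% detection at n=40 subjects
#: and 150 voxels; frozen.
REGION_PROFILES: dict[str, dict[str, float]] = {
    "phc_like": dict(reinstatement_gain_remembered=0.02,
                     reinstatement_gain_forgotten=0.0,
                     convergence_gain_high=0.0, convergence_gain_low=0.0),
    "mpfc_like": dict(reinstatement_gain_remembered=0.0,
                      reinstatement_gain_forgotten=0.0,
                      convergence_gain_high=0.15, convergence_gain_low=0.15),
    "ahc_like": dict(reinstatement_gain_remembered=0.0,
                     reinstatement_gain_forgotten=0.0,
                     convergence_gain_high=0.15, convergence_gain_low=0.0),
    "null": dict(reinstatement_gain_remembered=0.0,
                 reinstatement_gain_forgotten=0.0,
                 convergence_gain_high=0.0, convergence_gain_low=0.0),
}


def truth_for_profile(profile: str, **overrides) -> SyntheticTruth:
    if profile not in REGION_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(REGION_PROFILES)}")
    kw = dict(REGION_PROFILES[profile])
    kw.update(overrides)
    return SyntheticTruth(**kw)


def simulate_behavior(enc: TrialTable, ret: TrialTable, truth: SyntheticTruth,
                      seed: int | None = None
                      ) -> tuple[TrialTable, TrialTable]:
    """Fill behavioral outcome fields on copies of the two tables.

    Each encoding repetition is answered correctly with probability
    ``p_encoding_correct``. Each object's scene is remembered with
    probability ``p_remember_high`` / ``p_remember_low`` depending on
    its reward. Non-remembered responses split between "don't know"
    (probability ``p_dont_know``) and a uniformly random wrong scene.
    """
    rng = np.random.default_rng(seed)
    enc = enc.copy()
    ret = ret.copy()

    enc.correct = rng.random(len(enc)) < truth.p_encoding_correct
    # correct encoding responses get a response time; incorrect/missed none
    enc.rt = np.where(enc.correct, rng.lognormal(-0.3, 0.25, len(enc)), np.nan)

    p = np.where(ret.reward_high, truth.p_remember_high, truth.p_remember_low)
    ret.remembered = rng.random(len(ret)) < p

    n_scenes = int(enc.scene_id.max())
    resp = ret.scene_id.copy()
    forgotten = np.flatnonzero(~ret.remembered)
    dk = rng.random(forgotten.size) < truth.p_dont_know
    resp[forgotten[dk]] = DONT_KNOW
    wrong = forgotten[~dk]
    # uniformly among the n_scenes - 1 wrong scenes
    shift = rng.integers(1, n_scenes, wrong.size)
    resp[wrong] = (ret.scene_id[wrong] - 1 + shift) % n_scenes + 1
    ret.recall_response = resp

    conf = np.full(len(ret), np.nan)
    scene_resp = resp != DONT_KNOW
    conf[scene_resp] = rng.integers(1, 5, int(scene_resp.sum()))
    ret.confidence = conf
    ret.rt = rng.lognormal(0.0, 0.25, len(ret))
    return enc, ret


def _unit_rows(rng: np.random.Generator, n: int, v: int) -> np.ndarray:
    m = rng.standard_normal((n, v))
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def simulate_patterns(enc: TrialTable, ret: TrialTable, truth: SyntheticTruth,
                      n_voxels: int = 150, seed: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Trial x voxel pattern matrices for both phases, plus realized truth.

    Rows are aligned with table row order. Retrieval prototypes Q are
    orthogonalized against all encoding prototypes P before scaling, so
    planted convergence shares no variance with planted reinstatement.
    """
    if n_voxels < 10:
        raise ValueError("n_voxels must be >= 10")
    if ret.remembered is None:
        raise ValueError("behavior must be simulated before patterns")
    rng = np.random.default_rng(seed)
    n_scenes = int(enc.scene_id.max())
    n_objects = int(enc.object_id.max())

    P = _unit_rows(rng, n_scenes, n_voxels)
    Q = rng.standard_normal((n_scenes, n_voxels))
    Q -= Q @ np.linalg.pinv(P) @ P          # project out span(P)
    Q /= np.linalg.norm(Q, axis=1, keepdims=True)
    O = _unit_rows(rng, n_objects, n_voxels)

    enc_pat = (truth.encoding_scene_gain * P[enc.scene_id - 1]
               + truth.object_gain * O[enc.object_id - 1]
               + truth.noise_sd * rng.standard_normal((len(enc), n_voxels)))

    g_reinst = np.where(ret.remembered, truth.reinstatement_gain_remembered,
                        truth.reinstatement_gain_forgotten)[:, None]
    g_conv = np.where(ret.reward_high, truth.convergence_gain_high,
                      truth.convergence_gain_low)[:, None]
    ret_pat = (g_reinst * P[ret.scene_id - 1]
               + g_conv * Q[ret.scene_id - 1]
               + truth.object_gain * O[ret.object_id - 1]
               + truth.noise_sd * rng.standard_normal((len(ret), n_voxels)))

    realized = replace(truth, scene_encoding_prototypes=P,
                       scene_retrieval_prototypes=Q, object_components=O)
    return enc_pat, ret_pat, realized


@dataclass
class Subject:
    """One simulated participant: design, behavior, and patterns."""

    encoding: TrialTable
    retrieval: TrialTable
    enc_patterns: np.ndarray
    ret_patterns: np.ndarray
    truth: SyntheticTruth


def simulate_subject(truth: SyntheticTruth, n_voxels: int = 150,
                     seed: int | None = None, n_objects: int = 160,
                     n_scenes: int = 4, n_runs: int = 4, n_reps: int = 2
                     ) -> Subject:
    ss = np.random.SeedSequence(seed)
    s_design, s_behav, s_pat = (int(c.generate_state(1)[0] % (2 ** 31))
                                for c in ss.spawn(3))
    enc, ret = make_design(n_objects, n_scenes, n_runs, n_reps, seed=s_design)
    enc, ret = simulate_behavior(enc, ret, truth, seed=s_behav)
    enc_pat, ret_pat, realized = simulate_patterns(enc, ret, truth, n_voxels,
                                                   seed=s_pat)
    return Subject(enc, ret, enc_pat, ret_pat, realized)


def simulate_cohort(profile: str | SyntheticTruth, n_subjects: int = 40,
                    n_voxels: int = 150, seed: int | None = None,
                    n_objects: int = 160, n_scenes: int = 4, n_runs: int = 4,
                    n_reps: int = 2) -> list[Subject]:
    """A cohort of independently simulated subjects (default n=40)."""
    truth = (truth_for_profile(profile) if isinstance(profile, str)
             else profile)
    ss = np.random.SeedSequence(seed)
    return [simulate_subject(truth, n_voxels,
                             seed=int(c.generate_state(1)[0] % (2 ** 31)),
                             n_objects=n_objects, n_scenes=n_scenes,
                             n_runs=n_runs, n_reps=n_reps)
            for c in ss.spawn(n_subjects)]


def simulate_bold(events: TrialTable, amplitudes: np.ndarray, tr: float = 2.0,
                  volume_shape: tuple[int, int, int] = (4, 4, 4),
                  seed: int | None = None, noise_sd: float = 0.0,
                  drift_sd: float = 0.0, rest_s: float = 16.0,
                  oversample: int = 16
                  ) -> tuple[np.ndarray, pd.DataFrame, list[int]]:
    """Synthesize a 4D BOLD series whose per-trial response amplitudes
    equal the supplied pattern rows.

    ``amplitudes`` is trials x voxels (voxels = prod(volume_shape)); each
    trial's boxcar (its tabled duration) is convolved with the canonical
    HRF — via the same routine the GLM stage uses — and scaled by its
    amplitude row. White noise (``noise_sd``) and a per-run random-walk
    drift (``drift_sd``) are added on top. Returns the 4D array
    (x, y, z, scans), a 7-column confound table (six motion-like series
    plus framewise displacement), and the per-run scan counts.

    Raises if two trials in a run share an onset (unidentifiable design).
    """
    from .glm import convolved_regressor

    if tr <= 0:
        raise ValueError("tr must be positive")
    n_vox = int(np.prod(volume_shape))
    amplitudes = np.asarray(amplitudes, float)
    if amplitudes.shape != (len(events), n_vox):
        raise ValueError("amplitudes must be trials x prod(volume_shape)")
    rng = np.random.default_rng(seed)

    run_ids = sorted(np.unique(events.run))
    run_lengths = []
    rows = []
    for r in run_ids:
        m = events.run == r
        on, du = events.onset[m], events.duration[m]
        if np.unique(on).size != on.size:
            raise ValueError(f"run {r} contains trials with identical onsets")
        n_scans = int(np.ceil((on.max() + du.max() + rest_s) / tr))
        run_lengths.append(n_scans)
        sig = np.zeros((n_scans, n_vox))
        idx = np.flatnonzero(m)
        for i, trial in enumerate(idx):
            x = convolved_regressor(on[i], du[i], n_scans, tr, oversample)
            sig += np.outer(x, amplitudes[trial])
        if drift_sd > 0:
            sig += np.cumsum(rng.standard_normal((n_scans, n_vox)), axis=0) \
                * drift_sd
        if noise_sd > 0:
            sig += rng.standard_normal((n_scans, n_vox)) * noise_sd
        rows.append(sig)
    Y = np.concatenate(rows, axis=0)                       # scans x voxels
    total = Y.shape[0]
    motion = np.cumsum(rng.standard_normal((total, 6)) * 0.01, axis=0)
    fd = np.abs(np.diff(motion, axis=0, prepend=motion[:1])).sum(axis=1)
    confounds = pd.DataFrame(
        motion, columns=["trans_x", "trans_y", "trans_z",
                         "rot_x", "rot_y", "rot_z"])
    confounds["framewise_displacement"] = fd
    vol4d = Y.T.reshape(*volume_shape, total)
    return vol4d, confounds, run_lengths
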