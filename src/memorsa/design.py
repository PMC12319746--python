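"""Trial tables and the balanced object-scene study design.

The experimental design emulated here: participants encode ``n_objects``
unique objects, each paired with one of ``n_scenes`` recurring scenes.
Half of the scenes yield high reward, half low reward. Every object-scene
pair is shown ``n_reps`` times within a single run; the next day each
object is cued once for scene recall. Both phases are split into
``n_runs`` scanner runs with scene-balanced run composition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENCODING = "encoding"
RETRIEVAL = "retrieval"

#: recall_response code for an explicit "don't know" answer
DONT_KNOW = 0

# default event timing (seconds)
ENC_DURATION = 3.75
RET_DURATION = 3.0
ITI_RANGE = (1.75, 5.75)

_REQUIRED_COLUMNS = {
    ENCODING: ["onset", "duration", "object_id", "scene_id", "reward", "run",
               "repetition"],
    RETRIEVAL: ["onset", "duration", "object_id", "scene_id", "reward", "run"],
}


class DesignError(ValueError):
    """Raised when a requested design violates its balance constraints."""


@dataclass
class TrialTable:
    """One phase of one subject's trial sequence, column-oriented.

    Rows are in presentation order. ``reward_high`` is a pure function of
    ``scene_id``. Behavioral fields (``correct``, ``remembered``, ...) are
    ``None`` until filled by :func:`memorsa.synth.simulate_behavior`.
    """

    phase: str
    object_id: np.ndarray
    scene_id: np.ndarray
    reward_high: np.ndarray
    run: np.ndarray
    onset: np.ndarray
    duration: np.ndarray
    repetition: np.ndarray | None = None          # encoding only, 1..n_reps
    correct: np.ndarray | None = None             # encoding, per repetition
    recall_response: np.ndarray | None = None     # retrieval, 0=don't know
    remembered: np.ndarray | None = None          # retrieval
    confidence: np.ndarray | None = None
    rt: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.object_id.shape[0])

    @property
    def n_trials(self) -> int:
        return len(self)

    @property
    def n_objects(self) -> int:
        return int(np.unique(self.object_id).size)

    @property
    def n_scenes(self) -> int:
        return int(np.unique(self.scene_id).size)

    @property
    def n_runs(self) -> int:
        return int(np.unique(self.run).size)

    def copy(self) -> "TrialTable":
        kw = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return TrialTable(**kw)

    def to_frame(self) -> pd.DataFrame:
        """BIDS-events-style DataFrame (tab-separated on disk)."""
        cols: dict[str, object] = {
            "onset": self.onset,
            "duration": self.duration,
            "phase": self.phase,
            "object_id": self.object_id,
            "scene_id": self.scene_id,
            "reward": np.where(self.reward_high, "high", "low"),
            "run": self.run,
        }
        if self.repetition is not None:
            cols["repetition"] = self.repetition
        if self.correct is not None:
            cols["correct"] = self.correct.astype(int)
        if self.recall_response is not None:
            resp = np.where(self.recall_response == DONT_KNOW, "dont_know",
                            np.char.add("scene", self.recall_response.astype(str)))
            cols["recall_response"] = resp
        if self.remembered is not None:
            cols["remembered"] = self.remembered.astype(int)
        if self.confidence is not None:
            cols["confidence"] = self.confidence
        if self.rt is not None:
            cols["rt"] = self.rt
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        phases = df["phase"].unique() if "phase" in df else []
        if len(phases) != 1 or phases[0] not in (ENCODING, RETRIEVAL):
            raise ValueError(
                "events table must contain a 'phase' column with a single "
                f"value 'encoding' or 'retrieval'; got {list(phases)}")
        phase = phases[0]
        for col in _REQUIRED_COLUMNS[phase]:
            if col not in df.columns:
                raise ValueError(f"events table is missing required column {col!r}")
        kw: dict[str, object] = dict(
            phase=phase,
            object_id=df["object_id"].to_numpy(np.int64),
            scene_id=df["scene_id"].to_numpy(np.int64),
            reward_high=(df["reward"].to_numpy() == "high"),
            run=df["run"].to_numpy(np.int64),
            onset=df["onset"].to_numpy(np.float64),
            duration=df["duration"].to_numpy(np.float64),
        )
        if "repetition" in df:
            kw["repetition"] = df["repetition"].to_numpy(np.int64)
        if "correct" in df:
            kw["correct"] = df["correct"].to_numpy().astype(bool)
        if "recall_response" in df:
            raw = df["recall_response"].astype(str).to_numpy(dtype="U16")
            resp = np.zeros(len(raw), np.int64)
            mask = raw != "dont_know"
            resp[mask] = np.char.replace(raw[mask], "scene", "").astype(np.int64)
            kw["recall_response"] = resp
        if "remembered" in df:
            kw["remembered"] = df["remembered"].to_numpy().astype(bool)
        if "confidence" in df:
            kw["confidence"] = df["confidence"].to_numpy(np.float64)
        if "rt" in df:
            kw["rt"] = df["rt"].to_numpy(np.float64)
        return cls(**kw)


def _onsets(n_trials: int, duration: float, rng: np.random.Generator,
            iti_range: tuple[float, float]) -> np.ndarray:
    itis = rng.uniform(iti_range[0], iti_range[1], n_trials)
    starts = np.cumsum(itis) + np.arange(n_trials) * duration
    return starts


def make_design(n_objects: int = 160, n_scenes: int = 4, n_runs: int = 4,
                n_reps: int = 2, seed: int | None = None, *,
                enc_duration: float = ENC_DURATION,
                ret_duration: float = RET_DURATION,
                iti_range: tuple[float, float] = ITI_RANGE,
                ) -> tuple[TrialTable, TrialTable]:
    """Generate a balanced encoding and retrieval design.

    Balance constraints, asserted by construction:

    * each scene occurs equally often in each run (both phases);
    * within an encoding run, every object-scene pair appears once
      before any repetition;
    * half the scenes are high-reward (assignment randomized per design).

    Raises :class:`DesignError` if ``n_objects`` is not divisible by
    ``n_scenes * n_runs`` or ``n_scenes`` is odd.
    """
    if n_objects % (n_scenes * n_runs) != 0:
        raise DesignError(
            f"n_objects={n_objects} must be divisible by n_scenes*n_runs="
            f"{n_scenes * n_runs} so that each scene occurs equally often "
            "in each run")
    if n_scenes % 2 != 0:
        raise DesignError(
            f"n_scenes={n_scenes} must be even so that half the scenes can "
            "carry high reward")
    rng = np.random.default_rng(seed)

    high_scenes = rng.choice(np.arange(1, n_scenes + 1), n_scenes // 2,
                             replace=False)
    per_scene = n_objects // n_scenes
    per_scene_run = per_scene // n_runs

    # object -> scene, balanced, uniformly random
    scene_of = np.repeat(np.arange(1, n_scenes + 1), per_scene)
    scene_of = scene_of[rng.permutation(n_objects)]        # index: object-1

    def _run_alloc() -> np.ndarray:
        """object -> run, scene-balanced within every run."""
        run_of = np.empty(n_objects, np.int64)
        for s in range(1, n_scenes + 1):
            objs = np.flatnonzero(scene_of == s) + 1
            objs = rng.permutation(objs)
            for r in range(n_runs):
                run_of[objs[r * per_scene_run:(r + 1) * per_scene_run] - 1] = r + 1
        return run_of

    # --- encoding ---------------------------------------------------------
    enc_run_of = _run_alloc()
    obj_seq, rep_seq, run_seq = [], [], []
    for r in range(1, n_runs + 1):
        run_objs = np.flatnonzero(enc_run_of == r) + 1
        for rep in range(1, n_reps + 1):
            obj_seq.append(rng.permutation(run_objs))
            rep_seq.append(np.full(run_objs.size, rep))
            run_seq.append(np.full(run_objs.size, r))
    enc_obj = np.concatenate(obj_seq)
    enc = TrialTable(
        phase=ENCODING,
        object_id=enc_obj,
        scene_id=scene_of[enc_obj - 1],
        reward_high=np.isin(scene_of[enc_obj - 1], high_scenes),
        run=np.concatenate(run_seq),
        onset=_onsets(len(enc_obj), enc_duration, rng, iti_range),
        duration=np.full(len(enc_obj), enc_duration),
        repetition=np.concatenate(rep_seq),
    )
    # onsets restart per run
    for r in range(1, n_runs + 1):
        m = enc.run == r
        enc.onset[m] = _onsets(int(m.sum()), enc_duration, rng, iti_range)

    # --- retrieval --------------------------------------------------------
    ret_run_of = _run_alloc()
    obj_seq, run_seq, onset_seq = [], [], []
    for r in range(1, n_runs + 1):
        run_objs = rng.permutation(np.flatnonzero(ret_run_of == r) + 1)
        obj_seq.append(run_objs)
        run_seq.append(np.full(run_objs.size, r))
        onset_seq.append(_onsets(run_objs.size, ret_duration, rng, iti_range))
    ret_obj = np.concatenate(obj_seq)
    ret = TrialTable(
        phase=RETRIEVAL,
        object_id=ret_obj,
        scene_id=scene_of[ret_obj - 1],
        reward_high=np.isin(scene_of[ret_obj - 1], high_scenes),
        run=np.concatenate(run_seq),
        onset=np.concatenate(onset_seq),
        duration=np.full(len(ret_obj), ret_duration),
    )
    return enc, ret


def encoding_all_correct(enc: TrialTable) -> np.ndarray:
    """Per-object flag: every encoding repetition answered correctly.

    Returned array is indexed by ``object_id`` (length ``max(object_id)+1``;
    index 0 unused). Objects with any incorrect repetition are excluded
    from all similarity analyses.
    """
    if enc.correct is None:
        raise ValueError("encoding table has no 'correct' field; run "
                         "simulate_behavior or supply behavioral data")
    ok = np.ones(int(enc.object_id.max()) + 1, bool)
    np.logical_and.at(ok, enc.object_id, enc.correct)
    return ok
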