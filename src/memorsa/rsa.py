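"""Encoding-retrieval and retrieval-retrieval pattern similarity.

Similarity between two trials is the Fisher-z-transformed Pearson
correlation of their voxel patterns (single-trial t values). Pairs are
binned into eight condition cells crossing reward (high/low), subsequent
memory (remembered/forgotten), and scene overlap (same/different scene);
both members of a pair must share the reward x memory condition.

Pair inclusion rules:

* ERS (one encoding trial x one retrieval trial): same-object pairs are
  excluded (perceptual identity would inflate same-scene similarity),
  as are all pairs touching an object with any incorrect encoding
  repetition.
* RRS (two retrieval trials): pairs from the same scanner run are
  excluded, as are pairs touching an incorrectly encoded object. Pairs
  are unordered and counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialTable, encoding_all_correct

#: fixed cell order used by every contrast and results table
CELLS = ("HR-same", "HR-diff", "HF-same", "HF-diff",
         "LR-same", "LR-diff", "LF-same", "LF-diff")

#: first-level contrast weight vectors over the 8 cells
CONTRASTS: dict[str, np.ndarray] = {
    "overlap": np.array([1, -1, 1, -1, 1, -1, 1, -1], float),
    "memory_by_overlap": np.array([1, -1, -1, 1, 1, -1, -1, 1], float),
    "reward_by_overlap": np.array([1, -1, 1, -1, -1, 1, -1, 1], float),
}


class DegeneratePairError(ValueError):
    """A pattern correlation is (numerically) +/-1 or a row is constant.

    With noisy data this indicates duplicated or constant patterns,
    i.e. a data bug; values are never clipped into range.
    """


def fisher_z(r):
    """Fisher z transform, ``z = atanh(r)``.

    Rejects correlations with ``|r| >= 1 - 1e-7`` rather than clipping.
    """
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) >= 1.0 - 1e-7):
        raise DegeneratePairError(
            "correlation of +/-1 encountered; duplicated or degenerate "
            "patterns in the input")
    return np.arctanh(r)


def _condition_index(reward_high: np.ndarray, remembered: np.ndarray
                     ) -> np.ndarray:
    """0=HR, 1=HF, 2=LR, 3=LF."""
    return np.where(reward_high, 0, 2) + np.where(remembered, 0, 1)


@dataclass
class PairSet:
    """Retained trial pairs of one analysis, with their cell assignment.

    ``a_idx``/``b_idx`` are row indices into the pattern matrices: for
    ERS, ``a`` indexes encoding and ``b`` retrieval trials; for RRS both
    index retrieval trials (a < b). ``cell`` indexes :data:`CELLS`.
    ``z`` holds Fisher-z similarities once computed.
    """

    analysis: str                 # "ERS" | "RRS"
    a_idx: np.ndarray
    b_idx: np.ndarray
    cell: np.ndarray
    z: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.a_idx.shape[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"analysis": self.analysis, "trial_a": self.a_idx,
                           "trial_b": self.b_idx,
                           "cell": np.asarray(CELLS)[self.cell]})
        if self.z is not None:
            df["z"] = self.z
        return df


def _memory_of_object(ret: TrialTable) -> np.ndarray:
    if ret.remembered is None:
        raise ValueError("retrieval table has no 'remembered' field; "
                         "behavioral outcomes are required")
    rem = np.zeros(int(ret.object_id.max()) + 1, bool)
    rem[ret.object_id] = ret.remembered
    return rem


def enumerate_ers_pairs(enc: TrialTable, ret: TrialTable) -> PairSet:
    """All retained encoding-retrieval pairs with cell assignments."""
    ok = encoding_all_correct(enc)
    rem_of = _memory_of_object(ret)

    cond_e = _condition_index(enc.reward_high, rem_of[enc.object_id])
    cond_r = _condition_index(ret.reward_high, ret.remembered)

    keep = (enc.object_id[:, None] != ret.object_id[None, :])
    keep &= ok[enc.object_id][:, None] & ok[ret.object_id][None, :]
    keep &= cond_e[:, None] == cond_r[None, :]
    a, b = np.nonzero(keep)
    same = enc.scene_id[a] == ret.scene_id[b]
    cell = cond_r[b] * 2 + np.where(same, 0, 1)
    return PairSet("ERS", a, b, cell)


def enumerate_rrs_pairs(ret: TrialTable, enc: TrialTable) -> PairSet:
    """All retained retrieval-retrieval pairs (unordered, a < b).

    Requires the encoding table for the correctness filter: both
    objects of a pair must have been encoded correctly on every
    repetition.
    """
    ok = encoding_all_correct(enc)[ret.object_id]
    cond = _condition_index(ret.reward_high, ret.remembered)

    n = len(ret)
    upper = np.triu(np.ones((n, n), bool), k=1)
    keep = upper & (ret.run[:, None] != ret.run[None, :])
    keep &= ok[:, None] & ok[None, :]
    keep &= cond[:, None] == cond[None, :]
    a, b = np.nonzero(keep)
    same = ret.scene_id[a] == ret.scene_id[b]
    cell = cond[a] * 2 + np.where(same, 0, 1)
    return PairSet("RRS", a, b, cell)


def _standardize_rows(pat: np.ndarray) -> np.ndarray:
    pat = np.asarray(pat, float)
    centered = pat - pat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1, keepdims=True)
    flat = np.flatnonzero(norm.ravel() == 0)
    if flat.size:
        raise DegeneratePairError(
            f"constant pattern rows (no voxel variance): {flat.tolist()}")
    return centered / norm


def pair_similarities(pairs: PairSet, patterns_a: np.ndarray,
                      patterns_b: np.ndarray | None = None) -> PairSet:
    """Fill ``pairs.z`` with Fisher-z Pearson correlations.

    ``patterns_a`` indexes ``a_idx`` rows, ``patterns_b`` the ``b_idx``
    rows (defaults to ``patterns_a`` for RRS).
    """
    if patterns_b is None:
        patterns_b = patterns_a
    za = _standardize_rows(patterns_a)
    zb = (_standardize_rows(patterns_b) if patterns_b is not patterns_a
          else za)
    r = np.einsum("ij,ij->i", za[pairs.a_idx], zb[pairs.b_idx])
    r = np.clip(r, -1.0, 1.0)  # guard rounding beyond +/-1 only
    pairs.z = fisher_z(r)
    return pairs


def cell_means(pairs: PairSet) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-cell mean of pair z values and pair counts.

    Returns (means, counts), both length 8 in :data:`CELLS` order; empty
    cells yield NaN means and count 0.
    """
    if pairs.z is None:
        raise ValueError("pair similarities not computed; call "
                         "pair_similarities first")
    counts = np.bincount(pairs.cell, minlength=8).astype(int)
    sums = np.bincount(pairs.cell, weights=pairs.z, minlength=8)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def bilateral_means(means_left: np.ndarray, means_right: np.ndarray
                    ) -> np.ndarray:
    """Average per-hemisphere cell means (computed on cell means, not
    pooled pairs)."""
    return (np.asarray(means_left) + np.asarray(means_right)) / 2.0


def similarity_table(subject_results: list[tuple[np.ndarray, np.ndarray]],
                     analysis: str, roi: str = "roi") -> pd.DataFrame:
    """Tidy per-subject similarity table.

    ``subject_results`` is a list of (means, counts) per subject.
    Columns: subject, analysis, roi, cell, mean_z, n_pairs.
    """
    rows = []
    for s, (means, counts) in enumerate(subject_results):
        for c, cell in enumerate(CELLS):
            rows.append((s, analysis, roi, cell, means[c], int(counts[c])))
    return pd.DataFrame(rows, columns=["subject", "analysis", "roi", "cell",
                                       "mean_z", "n_pairs"])


def cells_matrix(table: pd.DataFrame, analysis: str | None = None,
                 roi: str | None = None) -> pd.DataFrame:
    """Pivot a tidy similarity table into subjects x 8 cells."""
    df = table
    if analysis is not None:
        df = df[df["analysis"] == analysis]
    if roi is not None:
        df = df[df["roi"] == roi]
    wide = df.pivot(index="subject", columns="cell", values="mean_z")
    return wide.reindex(columns=list(CELLS))


def single_trial_reinstatement(pairs: PairSet, n_retrieval: int,
                               min_pairs: int = 1) -> np.ndarray:
    """Per-retrieval-trial reinstatement index from ERS pairs.

    mean z(same-scene) - mean z(different-scene), using only the trial's
    retained same-condition encoding partners. Trials lacking at least
    ``min_pairs`` pairs on either side are NaN (dropped downstream).
    """
    if pairs.analysis != "ERS":
        raise ValueError("expected an ERS pair set")
    return _single_trial_diff(pairs.b_idx[:, None], pairs, n_retrieval,
                              min_pairs)


def single_trial_overlap(pairs: PairSet, n_retrieval: int,
                         min_pairs: int = 1) -> np.ndarray:
    """Per-retrieval-trial overlap index from RRS pairs (each unordered
    pair contributes to both of its members)."""
    if pairs.analysis != "RRS":
        raise ValueError("expected an RRS pair set")
    members = np.stack([pairs.a_idx, pairs.b_idx], axis=1)
    return _single_trial_diff(members, pairs, n_retrieval, min_pairs)


def _single_trial_diff(members: np.ndarray, pairs: PairSet, n_trials: int,
                       min_pairs: int) -> np.ndarray:
    if pairs.z is None:
        raise ValueError("pair similarities not computed")
    same = (pairs.cell % 2 == 0)
    sums = np.zeros((n_trials, 2))
    counts = np.zeros((n_trials, 2), int)
    for col in range(members.shape[1]):
        idx = members[:, col]
        sel = same.astype(int) ^ 1          # 0 for same, 1 for diff
        np.add.at(sums, (idx, sel), pairs.z)
        np.add.at(counts, (idx, sel), 1)
    valid = (counts >= min_pairs).all(axis=1)
    out = np.full(n_trials, np.nan)
    with np.errstate(invalid="ignore"):
        diff = sums[:, 0] / np.maximum(counts[:, 0], 1) \
            - sums[:, 1] / np.maximum(counts[:, 1], 1)
    out[valid] = diff[valid]
    return out


def roi_similarity(enc: TrialTable, ret: TrialTable,
                   enc_patterns: np.ndarray, ret_patterns: np.ndarray
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Convenience: ERS and RRS cell means/counts for one subject/ROI."""
    ers = pair_similarities(enumerate_ers_pairs(enc, ret),
                            enc_patterns, ret_patterns)
    rrs = pair_similarities(enumerate_rrs_pairs(ret, enc), ret_patterns)
    return {"ERS": cell_means(ers), "RRS": cell_means(rrs)}
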