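"""Group-level inference on condition-cell similarity tables.

The central model is a 2 x 2 x 2 repeated-measures ANOVA with the
within-subject factors reward (high/low), memory (remembered/forgotten),
and scene overlap (same/different scene). For two-level within factors
every effect reduces exactly to a paired t test on per-subject contrast
scores, with F = t**2 on (1, n-1) degrees of freedom; the ANOVA is
implemented that way, which keeps the per-subject effect scores around
for follow-up contrasts, across-subject correlations, and permutation
tests.

Permutation control: within each subject, condition labels are permuted
across all included pair similarities (preserving per-cell pair counts),
the contrast is recomputed on permuted cell means, and the true effect
is z-scored against the null distribution, z = (true - mean) / sd. The
group test on the z scores is one-sample and one-sided (greater than 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .rsa import CELLS, PairSet

# factor sign codes per cell, CELLS order (HR-same .. LF-diff)
_REWARD = np.array([1, 1, 1, 1, -1, -1, -1, -1], float)
_MEMORY = np.array([1, 1, -1, -1, 1, 1, -1, -1], float)
_OVERLAP = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)

#: the seven within-subject effects of the 2x2x2 design, as contrast
#: weight vectors over the 8 cells
EFFECT_WEIGHTS: dict[str, np.ndarray] = {
    "reward": _REWARD,
    "memory": _MEMORY,
    "overlap": _OVERLAP,
    "reward:memory": _REWARD * _MEMORY,
    "reward:overlap": _REWARD * _OVERLAP,
    "memory:overlap": _MEMORY * _OVERLAP,
    "reward:memory:overlap": _REWARD * _MEMORY * _OVERLAP,
}


class DegenerateNullError(ValueError):
    """Permutation null distribution has zero spread."""


def contrast_scores(cells: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-subject effect score: difference of means of the +1 and -1
    cells (i.e. ``cells @ w / (len(w)/2)``)."""
    cells = np.asarray(cells, float)
    weights = np.asarray(weights, float)
    if weights.sum() != 0:
        raise ValueError("contrast weights must sum to zero")
    return cells @ weights / (np.abs(weights).sum() / 2.0)


def one_sample_t(x, popmean: float = 0.0, alternative: str = "two-sided"
                 ) -> tuple[float, int, float]:
    """One-sample t test; returns (t, df, p).

    Zero-variance input: t = 0, p = 1 when the mean equals ``popmean``
    (no evidence either way), otherwise +/-inf with p = 0 — degenerate
    data are reported, not hidden.
    """
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 finite observations")
    df = n - 1
    d = x.mean() - popmean
    s = x.std(ddof=1)
    if s == 0:
        if d == 0:
            return 0.0, df, 1.0
        return float(np.sign(d) * np.inf), df, 0.0
    t = d / (s / np.sqrt(n))
    if alternative == "two-sided":
        p = 2 * sp_stats.t.sf(abs(t), df)
    elif alternative == "greater":
        p = sp_stats.t.sf(t, df)
    elif alternative == "less":
        p = sp_stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), df, float(p)


def paired_t(a, b, alternative: str = "two-sided") -> tuple[float, int, float]:
    """Paired t test on matched samples; returns (t, df, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, alternative)


# --------------------------------------------------------------------------
# repeated-measures ANOVA as a model/results pair

@dataclass
class RMAnovaResults:
    """Fitted 2x2x2 repeated-measures ANOVA.

    ``table`` has one row per effect (F, df1, df2, p); ``scores`` holds
    the per-subject contrast scores each F was computed from, for use in
    follow-ups.
    """

    table: pd.DataFrame
    scores: dict[str, np.ndarray]
    n_subjects: int
    n_dropped: int = 0

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def summary(self) -> str:
        lines = [f"Repeated-measures ANOVA (2x2x2 within), "
                 f"n = {self.n_subjects} subjects"
                 + (f" ({self.n_dropped} dropped: incomplete cells)"
                    if self.n_dropped else ""),
                 f"{'effect':<24}{'F':>10}{'df':>10}{'p':>10}"]
        for name, row in self.table.iterrows():
            lines.append(f"{name:<24}{row.F:>10.3f}"
                         f"{f'(1,{int(row.df2)})':>10}{row.p:>10.4f}")
        return "\n".join(lines)


class RMAnova:
    """2x2x2 within-subject ANOVA on a subjects x 8-cell table.

    ``cells`` is an (n_subjects, 8) array or DataFrame in
    :data:`memorsa.rsa.CELLS` column order. Subjects with any missing
    cell are dropped (and counted) before fitting; fewer than 3 complete
    subjects is an error.
    """

    def __init__(self, cells: np.ndarray | pd.DataFrame):
        if isinstance(cells, pd.DataFrame):
            missing = [c for c in CELLS if c not in cells.columns]
            if missing:
                raise ValueError(f"cell table is missing columns {missing}")
            cells = cells[list(CELLS)].to_numpy(float)
        cells = np.asarray(cells, float)
        if cells.ndim != 2 or cells.shape[1] != 8:
            raise ValueError("expected a subjects x 8 cell table")
        complete = np.isfinite(cells).all(axis=1)
        self.n_dropped = int((~complete).sum())
        self.cells = cells[complete]
        if self.cells.shape[0] < 3:
            raise ValueError("need at least 3 subjects with complete cells")

    def fit(self) -> RMAnovaResults:
        n = self.cells.shape[0]
        rows = []
        scores: dict[str, np.ndarray] = {}
        for name, w in EFFECT_WEIGHTS.items():
            s = contrast_scores(self.cells, w)
            scores[name] = s
            t, df, p = one_sample_t(s)
            rows.append((name, t * t, 1, df, p))
        table = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"]
                             ).set_index("effect")
        return RMAnovaResults(table, scores, n, self.n_dropped)


def rm_anova_2x2x2(cells) -> RMAnovaResults:
    """Functional wrapper around :class:`RMAnova`."""
    return RMAnova(cells).fit()


# --------------------------------------------------------------------------
# control analyses

def rrs_vs_ers_contrast(rrs_cells: np.ndarray, ers_cells: np.ndarray,
                        weights: np.ndarray) -> tuple[float, int, float]:
    """Paired t: is the RRS effect larger than the matching ERS effect?

    Per subject, the same contrast is scored in both analyses; the two
    score vectors are compared with a (two-sided) paired t test.
    """
    s_rrs = contrast_scores(rrs_cells, weights)
    s_ers = contrast_scores(ers_cells, weights)
    return paired_t(s_rrs, s_ers)


def across_subject_corr(effect_a, effect_b) -> tuple[float, float]:
    """Pearson correlation of two per-subject effect vectors."""
    a = np.asarray(effect_a, float)
    b = np.asarray(effect_b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    r, p = sp_stats.pearsonr(a[ok], b[ok])
    return float(r), float(p)


def slope_regression(x_per_subject: list[np.ndarray],
                     y_per_subject: list[np.ndarray], min_trials: int = 3
                     ) -> tuple[np.ndarray, tuple[float, int, float]]:
    """Within-subject OLS slopes of y on x, then a group t test vs 0.

    NaN trials are dropped pairwise; a subject needs ``min_trials``
    usable trials (with x variance) for a slope, otherwise their slope
    is NaN and they drop out of the group test.
    """
    slopes = []
    for x, y in zip(x_per_subject, y_per_subject):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < min_trials or np.ptp(x) == 0:
            slopes.append(np.nan)
            continue
        xc = x - x.mean()
        slopes.append(float((xc @ (y - y.mean())) / (xc @ xc)))
    slopes = np.asarray(slopes)
    return slopes, one_sample_t(slopes)


# --------------------------------------------------------------------------
# label-permutation control

@dataclass
class PermutationResults:
    """Per-subject label-permutation z scores and their group test."""

    z: np.ndarray
    true_effect: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    group_t: float
    group_df: int
    group_p: float                # one-sided, greater than 0
    n_perm: int
    seed: int | None

    def summary(self) -> str:
        return (f"Label-permutation test, {self.n_perm} permutations/subject\n"
                f"n = {self.z.size} subjects, mean z = {self.z.mean():.3f}\n"
                f"group one-sample t (one-sided > 0): "
                f"t({self.group_df}) = {self.group_t:.3f}, "
                f"p = {self.group_p:.4f}")


def _subject_permutation_z(z: np.ndarray, cell: np.ndarray,
                           weights: np.ndarray, n_perm: int,
                           rng: np.random.Generator
                           ) -> tuple[float, float, float]:
    """(true effect, null mean, null sd) for one subject.

    The 8-cell label vector is shuffled as a whole across all included
    pairs, preserving per-cell counts; the contrast on cell means is
    recomputed per permutation.
    """
    counts = np.bincount(cell, minlength=8)
    touched = np.abs(weights) > 0
    if (counts[touched] == 0).any():
        raise ValueError("contrast touches empty cells; subject unusable")
    if np.count_nonzero(counts[touched]) < 2:
        raise ValueError("need >= 2 nonempty cells touched by the contrast")
    # per-pair coefficient: w_c / n_c of the pair's (permuted) cell
    coef = np.where(counts > 0, weights / np.maximum(counts, 1), 0.0)
    true = float(coef[cell] @ z)
    perm_labels = rng.permuted(
        np.broadcast_to(cell, (n_perm, cell.size)), axis=1)
    null = coef[perm_labels] @ z
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    scale = max(1.0, float(np.abs(z).max()))
    if sd <= 1e-10 * scale:
        raise DegenerateNullError(
            "permutation null has zero spread (all pair values equal "
            "under the contrast)")
    return true, mu, sd


def permutation_z(subject_pairs: list[PairSet] | list[tuple[np.ndarray, np.ndarray]],
                  weights: np.ndarray, n_perm: int = 10_000,
                  seed: int | None = None, skip_invalid: bool = False
                  ) -> PermutationResults:
    """Within-subject label-permutation z scores and the group t test.

    ``subject_pairs``: per subject, either a :class:`PairSet` with
    computed ``z`` or a raw ``(z_values, cell_labels)`` tuple. With
    ``skip_invalid`` subjects whose pairs cannot support the contrast
    (empty touched cells) are dropped with a logged notice instead of
    raising.
    """
    import logging

    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    weights = np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    true, mu, sd = [], [], []
    for i, item in enumerate(subject_pairs):
        if isinstance(item, PairSet):
            zv, cl = item.z, item.cell
        else:
            zv, cl = item
        try:
            t0, m0, s0 = _subject_permutation_z(np.asarray(zv, float),
                                                np.asarray(cl), weights,
                                                n_perm, rng)
        except DegenerateNullError:
            raise
        except ValueError:
            if not skip_invalid:
                raise
            logging.getLogger(__name__).info(
                "subject %d dropped from permutation test (contrast "
                "touches empty cells)", i)
            continue
        true.append(t0)
        mu.append(m0)
        sd.append(s0)
    true = np.asarray(true)
    mu = np.asarray(mu)
    sd = np.asarray(sd)
    zscores = (true - mu) / sd
    t, df, p = one_sample_t(zscores, alternative="greater")
    return PermutationResults(zscores, true, mu, sd, t, df, p, n_perm, seed)


# --------------------------------------------------------------------------
# behavior

def behavior_stats(subjects: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject behavioral measures and reward paired t tests.

    For each subject: encoding accuracy and median correct-response RT
    by reward, and scene-recall accuracy by reward. Recall denominators
    include only objects with both encoding repetitions correct.
    Returns (per-subject measures, paired-t table).
    """
    from .design import encoding_all_correct

    rows = []
    for i, s in enumerate(subjects):
        enc, ret = s.encoding, s.retrieval
        ok = encoding_all_correct(enc)[ret.object_id]
        for high in (True, False):
            m_enc = enc.reward_high == high
            m_ret = (ret.reward_high == high) & ok
            corr = enc.correct[m_enc]
            rt = enc.rt[m_enc][corr]
            rows.append({
                "subject": i, "reward": "high" if high else "low",
                "enc_accuracy": float(corr.mean()),
                "enc_median_rt": float(np.nanmedian(rt)) if corr.any() else np.nan,
                "recall_accuracy": (float(ret.remembered[m_ret].mean())
                                    if m_ret.any() else np.nan),
            })
    measures = pd.DataFrame(rows)
    wide = measures.pivot(index="subject", columns="reward")
    tests = []
    for var in ("enc_accuracy", "enc_median_rt", "recall_accuracy"):
        hi = wide[(var, "high")].to_numpy()
        lo = wide[(var, "low")].to_numpy()
        if np.allclose(np.nanstd(hi - lo), 0):
            t, df, p = (0.0, len(hi) - 1, 1.0) if np.allclose(hi, lo) \
                else (np.nan, len(hi) - 1, np.nan)
        else:
            t, df, p = paired_t(hi, lo)
        tests.append((var, t, df, p))
    ttable = pd.DataFrame(tests, columns=["measure", "t", "df", "p"]
                          ).set_index("measure")
    return measures, ttable
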