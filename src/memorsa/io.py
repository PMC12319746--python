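"""File formats, run configuration, and the pipeline orchestrator.

Event tables travel as BIDS-events-style tab-separated files (dot
decimal; required columns ``onset, duration, phase, object_id,
scene_id, reward, run`` plus phase-specific fields). Volumes are
NIfTI-1 via nibabel; voxel indices are 0-based internally, with world
coordinates given by the affine. Configurations round-trip through
YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TrialTable
from .rsa import (CONTRASTS, cells_matrix, roi_similarity, similarity_table)
from .stats import RMAnova, permutation_z
from .synth import simulate_cohort

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# events

def write_events(table: TrialTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path: str | Path) -> TrialTable:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return TrialTable.from_frame(df)


# --------------------------------------------------------------------------
# volumes

def write_volume(data: np.ndarray, path: str | Path,
                 voxel_size_mm: float = 2.0,
                 affine: np.ndarray | None = None) -> None:
    import nibabel as nib

    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))


def read_volume(path: str | Path, n_trials: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Returns (data, affine); checks the trial axis length if given."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if n_trials is not None:
        if data.ndim != 4 or data.shape[3] != n_trials:
            raise ValueError(
                f"expected a 4D volume with {n_trials} trials on the last "
                f"axis, got shape {data.shape}")
    return data, np.asarray(img.affine)


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary mask; non-binary input is binarized (>0) with a
    warning."""
    data, affine = read_volume(path)
    uniq = np.unique(data)
    if not np.isin(uniq, [0.0, 1.0]).all():
        log.warning("mask %s is not binary (values %s); binarizing at > 0",
                    path, uniq[:5])
    return data > 0, affine


# --------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    out_dir: str = "memorsa_out"
    profile: str = "null"
    n_subjects: int = 40
    n_voxels: int = 150
    n_objects: int = 160
    n_scenes: int = 4
    n_runs: int = 4
    n_reps: int = 2
    n_perm_roi: int = 10_000
    n_perm_searchlight: int = 1000
    radius: int = 3
    smooth_fwhm_mm: float = 2.0
    searchlight_fwhm_mm: float = 6.0
    rois: list[str] = field(default_factory=lambda: ["roi"])
    seed_simulate: int = 0
    seed_permutation: int = 0

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# --------------------------------------------------------------------------
# pipeline

HEADLINE_TESTS = {
    # analysis, ANOVA effect — the three planted result patterns
    "ers_memory_by_overlap": ("ERS", "memory:overlap"),
    "rrs_overlap": ("RRS", "overlap"),
    "rrs_reward_by_overlap": ("RRS", "reward:overlap"),
}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Simulate a cohort, run the ROI RSA and group statistics, write
    the result bundle (similarity CSV, stats CSV, permutation CSV, log),
    and return the output paths. Deterministic under a fixed config."""
    from .rsa import enumerate_ers_pairs, enumerate_rrs_pairs, \
        pair_similarities
    from .stats import behavior_stats

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("memorsa")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        import memorsa

        log.info("memorsa %s | numpy %s | pandas %s", memorsa.__version__,
                 np.__version__, pd.__version__)
        log.info("config: %s", dataclasses.asdict(config))
        cohort = simulate_cohort(config.profile, config.n_subjects,
                                 config.n_voxels, seed=config.seed_simulate,
                                 n_objects=config.n_objects,
                                 n_scenes=config.n_scenes,
                                 n_runs=config.n_runs, n_reps=config.n_reps)
        log.info("simulated %d subjects, profile %s, seed %d",
                 config.n_subjects, config.profile, config.seed_simulate)

        sim_rows = []
        subject_pairs = {"ERS": [], "RRS": []}
        for s in cohort:
            ers = pair_similarities(enumerate_ers_pairs(s.encoding,
                                                        s.retrieval),
                                    s.enc_patterns, s.ret_patterns)
            rrs = pair_similarities(enumerate_rrs_pairs(s.retrieval,
                                                        s.encoding),
                                    s.ret_patterns)
            subject_pairs["ERS"].append(ers)
            subject_pairs["RRS"].append(rrs)
        from .rsa import cell_means

        n_enc = config.n_objects * config.n_reps
        possible = {"ERS": n_enc * config.n_objects,
                    "RRS": config.n_objects * (config.n_objects - 1) // 2}
        for analysis in ("ERS", "RRS"):
            results = [cell_means(p) for p in subject_pairs[analysis]]
            sim_rows.append(similarity_table(results, analysis,
                                             roi=config.rois[0]))
            counts = np.array([c for _, c in results])
            retained = counts.sum(axis=1).mean()
            log.info("%s retained pairs per condition cell: mean %s "
                     "(retained %.1f, excluded %.1f of %d candidate pairs "
                     "per subject)",
                     analysis, np.round(counts.mean(axis=0), 1).tolist(),
                     retained, possible[analysis] - retained,
                     possible[analysis])
        similarity = pd.concat(sim_rows, ignore_index=True)
        sim_path = out / "similarity.csv"
        similarity.to_csv(sim_path, index=False, float_format="%.10g")

        stats_rows = []
        for analysis in ("ERS", "RRS"):
            cells = cells_matrix(similarity, analysis=analysis)
            res = RMAnova(cells).fit()
            for name, row in res.table.iterrows():
                stats_rows.append((config.rois[0], analysis, name, row.F,
                                   int(row.df1), int(row.df2), row.p))
        stats = pd.DataFrame(stats_rows, columns=["roi", "analysis", "effect",
                                                  "F", "df1", "df2", "p"])
        stats_path = out / "stats.csv"
        stats.to_csv(stats_path, index=False, float_format="%.10g")

        perm_rows = []
        for test, (analysis, effect) in HEADLINE_TESTS.items():
            from .stats import EFFECT_WEIGHTS

            res = permutation_z(subject_pairs[analysis],
                                EFFECT_WEIGHTS[effect],
                                n_perm=config.n_perm_roi,
                                seed=config.seed_permutation,
                                skip_invalid=True)
            perm_rows.append((test, res.z.mean(), res.group_t, res.group_df,
                              res.group_p, res.n_perm))
            log.info("permutation %s: %s", test, res.summary().replace("\n",
                                                                       " | "))
        perm = pd.DataFrame(perm_rows, columns=["test", "mean_z", "t", "df",
                                                "p_one_sided", "n_perm"])
        perm_path = out / "permutation.csv"
        perm.to_csv(perm_path, index=False, float_format="%.10g")

        measures, ttable = behavior_stats(cohort)
        behav_path = out / "behavior.csv"
        measures.to_csv(behav_path, index=False, float_format="%.10g")
        ttable.to_csv(out / "behavior_tests.csv", float_format="%.10g")
        log.info("pipeline complete")
    finally:
        root.removeHandler(handler)
        handler.close()
    return {"similarity": sim_path, "stats": stats_path,
            "permutation": perm_path, "behavior": behav_path,
            "log": log_path}
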