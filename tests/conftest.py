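import numpy as np
import pytest

import memorsa as m


@pytest.fixture(scope="session")
def toy_subject():
    """Small fully simulated subject (32 objects, 4 scenes, 2 runs)."""
    truth = m.truth_for_profile("mpfc_like")
    return m.simulate_subject(truth, n_voxels=40, seed=11, n_objects=32,
                              n_scenes=4, n_runs=2, n_reps=2)


@pytest.fixture(scope="session")
def default_design():
    return m.make_design(160, 4, 4, 2, seed=7)


def brute_force_ers(enc, ret):
    """Exhaustive double loop applying the ERS inclusion rules."""
    ok = {}
    for o in np.unique(enc.object_id):
        reps = enc.correct[enc.object_id == o]
        ok[o] = bool(reps.all())
    rem = {o: bool(r) for o, r in zip(ret.object_id, ret.remembered)}
    pairs = set()
    for i in range(len(enc)):
        for j in range(len(ret)):
            oe, orr = enc.object_id[i], ret.object_id[j]
            if oe == orr:
                continue
            if not (ok[oe] and ok[orr]):
                continue
            cond_e = (bool(enc.reward_high[i]), rem[oe])
            cond_j = (bool(ret.reward_high[j]), bool(ret.remembered[j]))
            if cond_e != cond_j:
                continue
            same = enc.scene_id[i] == ret.scene_id[j]
            cond = {(True, True): 0, (True, False): 1,
                    (False, True): 2, (False, False): 3}[cond_j]
            pairs.add((i, j, cond * 2 + (0 if same else 1)))
    return pairs


def brute_force_rrs(ret, enc):
    """Exhaustive double loop applying the RRS inclusion rules."""
    ok = {}
    for o in np.unique(enc.object_id):
        ok[o] = bool(enc.correct[enc.object_id == o].all())
    pairs = set()
    for i in range(len(ret)):
        for j in range(i + 1, len(ret)):
            if ret.run[i] == ret.run[j]:
                continue
            if not (ok[ret.object_id[i]] and ok[ret.object_id[j]]):
                continue
            ci = (bool(ret.reward_high[i]), bool(ret.remembered[i]))
            cj = (bool(ret.reward_high[j]), bool(ret.remembered[j]))
            if ci != cj:
                continue
            same = ret.scene_id[i] == ret.scene_id[j]
            cond = {(True, True): 0, (True, False): 1,
                    (False, True): 2, (False, False): 3}[ci]
            pairs.add((i, j, cond * 2 + (0 if same else 1)))
    return pairs


def random_toy_design(rng):
    """Small random design with random behavior, for oracle comparisons."""
    n_scenes = int(rng.choice([2, 4]))
    n_runs = int(rng.choice([1, 2]))
    per = int(rng.choice([1, 2]))
    n_objects = n_scenes * n_runs * per * 2
    enc, ret = m.make_design(n_objects, n_scenes, n_runs, 2,
                             seed=int(rng.integers(2 ** 31)))
    truth = m.truth_for_profile(
        "null", p_encoding_correct=float(rng.uniform(0.5, 1.0)),
        p_remember_high=float(rng.uniform(0.2, 0.9)),
        p_remember_low=float(rng.uniform(0.2, 0.9)))
    return m.simulate_behavior(enc, ret, truth,
                               seed=int(rng.integers(2 ** 31)))


def subject_pairsets(subject):
    """(ERS, RRS) pair sets with similarities for one subject."""
    ers = m.pair_similarities(
        m.enumerate_ers_pairs(subject.encoding, subject.retrieval),
        subject.enc_patterns, subject.ret_patterns)
    rrs = m.pair_similarities(
        m.enumerate_rrs_pairs(subject.retrieval, subject.encoding),
        subject.ret_patterns)
    return ers, rrs


def cohort_cell_tables(cohort):
    """(ERS cells, RRS cells) as subjects x 8 arrays for a cohort."""
    ers, rrs = [], []
    for s in cohort:
        pe, pr = subject_pairsets(s)
        ers.append(m.cell_means(pe)[0])
        rrs.append(m.cell_means(pr)[0])
    return np.asarray(ers), np.asarray(rrs)
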