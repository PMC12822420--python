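import numpy as np
import pandas as pd
import pytest

from lipidcross import (
    Intervention,
    LipidMatrix,
    SampleMeta,
    Timepoint,
    TrialConfig,
    generate_trial,
    parse_species,
)


def make_matrix(data: dict[str, list], sample_meta: list[tuple[str, str, str, str]]):
    """Build a LipidMatrix from {species_name: amounts} and metadata tuples."""
    samples = [
        SampleMeta(sid, subj, Intervention(iv), Timepoint(tp))
        for sid, subj, iv, tp in sample_meta
    ]
    frame = pd.DataFrame.from_dict(
        data, orient="index", columns=[s.sample_id for s in samples], dtype=float
    )
    frame.index.name = "species"
    species = [parse_species(n) for n in frame.index]
    return LipidMatrix(species=species, samples=samples, amounts=frame)


@pytest.fixture
def four_sample_meta():
    """One subject, both interventions, before/after."""
    return [
        ("A_e_b", "A", "eTRE", "before"),
        ("A_e_a", "A", "eTRE", "after"),
        ("A_l_b", "A", "lTRE", "before"),
        ("A_l_a", "A", "lTRE", "after"),
    ]


@pytest.fixture(scope="session")
def default_trial():
    """A full-size synthetic trial (300 species, 30 subjects), no effects."""
    return generate_trial(TrialConfig(seed=20250923))


@pytest.fixture(scope="session")
def small_trial():
    """A fast trial for pipeline-level tests."""
    return generate_trial(TrialConfig(n_subjects=8, n_species=60, seed=7))


def brute_force_wilcoxon_p(diffs: np.ndarray) -> float:
    """Exhaustive 2^n sign-flip null for the two-sided signed-rank test.

    Independent oracle: ranks |d|, enumerates every sign assignment, and
    returns the two-sided tail probability of W = min(W+, W-).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)
    wp = signs @ ranks
    return float(np.mean(np.minimum(wp, total - wp) <= w_obs + 1e-12))


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Direct step-up BH: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
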