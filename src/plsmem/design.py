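"""Synthetic recognition-memory experiment design and behavioral simulation.

Emulates the word-list structure of a two-phase recognition study: a pool of
512 synthetic word tokens split into 8 lists of 64 (4 concrete, 4 abstract),
a 256-word study phase in which half the words are shown once (1x) and half
three times (3x), and a scanned test phase of 8 runs of 64 words each
(16 1x + 16 3x + 32 new) plus 4 null events per run, with jittered
inter-trial intervals. Half the runs reward "old" responses more
(incentivize-old), half reward "new" responses more (incentivize-new),
shifting the response criterion.

Responses are simulated either from per-cell response probabilities or from
an equal-variance Gaussian signal-detection model with subject-level
heterogeneity in sensitivity and criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ITEM_TYPES = ("1x", "3x", "new")
RUN_TYPES = ("incentivize-old", "incentivize-new")

#: The six modeled trial types: correct responses per item type x run type.
MODELED_CONDITIONS = tuple(
    f"{rt}:{it}" for rt in RUN_TYPES for it in ITEM_TYPES
)


class ConfigurationError(ValueError):
    """Raised when design or simulation parameters are inconsistent."""


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the study/test design.

    Defaults reproduce the reference design: a 512-word pool in 8 lists of
    64, 8 test runs of 64 words (16 once-studied, 16 thrice-studied, 32 new)
    with 4 null events each, and ITIs jittered uniformly in 2-6 s.
    """

    n_subjects: int = 14
    pool_size: int = 512
    n_lists: int = 8
    n_runs: int = 8
    n_1x_per_run: int = 16
    n_3x_per_run: int = 16
    n_new_per_run: int = 32
    n_null_per_run: int = 4
    study_word_ms: int = 2800
    study_fix_ms: int = 200
    test_fix_ms: int = 500
    test_word_ms: int = 3000
    iti_range_ms: tuple[int, int] = (2000, 6000)
    payoff_high: int = 5
    payoff_low: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size % self.n_lists:
            raise ConfigurationError(
                f"pool_size {self.pool_size} not divisible by "
                f"n_lists {self.n_lists}"
            )
        if self.n_runs % 2:
            raise ConfigurationError("n_runs must be even (two run types)")
        if self.iti_range_ms[0] >= self.iti_range_ms[1]:
            raise ConfigurationError("iti_range_ms must satisfy min < max")

    @property
    def list_size(self) -> int:
        return self.pool_size // self.n_lists

    @property
    def words_per_run(self) -> int:
        return self.n_1x_per_run + self.n_3x_per_run + self.n_new_per_run

    @property
    def n_old_per_run(self) -> int:
        return self.n_1x_per_run + self.n_3x_per_run


@dataclass(frozen=True)
class WordPool:
    """A pool of synthetic word tokens in equal-size disjoint lists.

    Half the lists are labeled concrete, half abstract; only the list
    structure matters downstream.
    """

    words: tuple[str, ...]
    list_id: tuple[int, ...]     # 1-based list per word
    category: tuple[str, ...]    # "concrete" | "abstract" per word

    @property
    def n_lists(self) -> int:
        return len(set(self.list_id))

    def words_in_list(self, lid: int) -> list[str]:
        return [w for w, l in zip(self.words, self.list_id) if l == lid]


def generate_word_pool(params: DesignParams, rng=None) -> WordPool:
    """Build the word pool: ``n_lists`` disjoint lists of equal size.

    Words are synthetic tokens (w0001, w0002, ...). Lists alternate between
    the concrete and abstract halves so each category contributes
    ``n_lists / 2`` lists. Deterministic for a fixed ``params.rng_seed``.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    n, ls = params.pool_size, params.list_size
    words = [f"w{i + 1:04d}" for i in range(n)]
    # shuffle word->list assignment so list membership is seed-dependent
    order = rng.permutation(n)
    list_id = np.empty(n, dtype=int)
    category = np.empty(n, dtype=object)
    half = params.n_lists // 2
    for lid in range(params.n_lists):
        idx = order[lid * ls:(lid + 1) * ls]
        list_id[idx] = lid + 1
        category[idx] = "concrete" if lid < half else "abstract"
    return WordPool(tuple(words), tuple(list_id), tuple(category))


@dataclass(frozen=True)
class TestRun:
    """One test run: ordered trials with onsets, incl. null events."""

    run_type: str                 # incentivize-old | incentivize-new
    trials: pd.DataFrame          # onset_ms, duration_ms, item_type, word

    def __post_init__(self) -> None:
        if self.run_type not in RUN_TYPES:
            raise ConfigurationError(f"unknown run_type {self.run_type!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """A full study + test design for one participant slot."""

    study_list: dict[str, int]    # word -> repetitions (1 or 3)
    runs: tuple[TestRun, ...]
    counterbalance_id: int
    params: DesignParams


def generate_design(
    pool: WordPool,
    params: DesignParams,
    counterbalance_id: int = 0,
    rng: np.random.Generator | None = None,
) -> ExperimentDesign:
    """Assemble the counterbalanced study/test design.

    The counterbalance id selects which half of the lists is studied (its
    parity flips the studied/unstudied halves, so over ids 0 and 1 every
    list is studied exactly once). Within the studied half, half the words
    are assigned 1 repetition and half 3. Words are allocated to runs
    uniformly at random respecting the per-run cell counts, run types are
    ordered randomly with ``n_runs/2`` of each, and ITIs are drawn uniformly
    from ``iti_range_ms``.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    p = params
    n_lists = pool.n_lists
    half = n_lists // 2
    lids = np.arange(1, n_lists + 1)
    studied_lists = lids[:half] if counterbalance_id % 2 == 0 else lids[half:]

    studied = [w for lid in studied_lists for w in pool.words_in_list(lid)]
    unstudied = [w for w in pool.words if w not in set(studied)]
    need_old = p.n_runs * p.n_old_per_run
    need_new = p.n_runs * p.n_new_per_run
    if len(studied) < need_old or len(unstudied) < need_new:
        raise ConfigurationError(
            f"pool too small: need {need_old} studied / {need_new} new words"
        )

    studied = list(rng.permutation(studied))
    unstudied = list(rng.permutation(unstudied))
    n_1x_total = p.n_runs * p.n_1x_per_run
    words_1x = studied[:n_1x_total]
    words_3x = studied[n_1x_total:need_old]
    words_new = unstudied[:need_new]
    study_list = {w: 1 for w in words_1x}
    study_list.update({w: 3 for w in words_3x})

    run_types = np.array(
        [RUN_TYPES[0]] * (p.n_runs // 2) + [RUN_TYPES[1]] * (p.n_runs // 2)
    )
    rng.shuffle(run_types)

    runs = []
    for r in range(p.n_runs):
        w1 = words_1x[r * p.n_1x_per_run:(r + 1) * p.n_1x_per_run]
        w3 = words_3x[r * p.n_3x_per_run:(r + 1) * p.n_3x_per_run]
        wn = words_new[r * p.n_new_per_run:(r + 1) * p.n_new_per_run]
        items = (
            [("1x", w) for w in w1]
            + [("3x", w) for w in w3]
            + [("new", w) for w in wn]
            + [("null", "xxxxxxx")] * p.n_null_per_run
        )
        order = rng.permutation(len(items))
        itis = rng.integers(p.iti_range_ms[0], p.iti_range_ms[1],
                            endpoint=True, size=len(items))
        rows = []
        t = 0
        for k, oi in enumerate(order):
            item_type, word = items[oi]
            onset = t + p.test_fix_ms          # word onset follows fixation
            rows.append((onset, p.test_word_ms, item_type, word))
            t = onset + p.test_word_ms + int(itis[k])
        trials = pd.DataFrame(
            rows, columns=["onset_ms", "duration_ms", "item_type", "word"]
        )
        runs.append(TestRun(run_type=str(run_types[r]), trials=trials))

    return ExperimentDesign(
        study_list=study_list,
        runs=tuple(runs),
        counterbalance_id=counterbalance_id,
        params=p,
    )


# ---------------------------------------------------------------------------
# Behavioral simulation
# ---------------------------------------------------------------------------

#: Group-mean probability of an "old" response per (run_type, item_type),
#: the cohort-level operating point the generator is calibrated to
#: (hit rates for old items; 1 - CR rate for new items).
DEFAULT_P_OLD = {
    ("incentivize-old", "1x"): 0.74,
    ("incentivize-old", "3x"): 0.93,
    ("incentivize-old", "new"): 0.29,
    ("incentivize-new", "1x"): 0.63,
    ("incentivize-new", "3x"): 0.86,
    ("incentivize-new", "new"): 0.17,
}

#: Mean correct-response RT (ms) per (run_type, item_type).
DEFAULT_RT_MEAN_MS = {
    ("incentivize-old", "1x"): 1271.0,
    ("incentivize-old", "3x"): 1089.0,
    ("incentivize-old", "new"): 1424.0,
    ("incentivize-new", "1x"): 1383.0,
    ("incentivize-new", "3x"): 1165.0,
    ("incentivize-new", "new"): 1371.0,
}


@dataclass(frozen=True)
class SdtParams:
    """Generative model of the recognition decision.

    Two parameterizations:

    * ``mode="rate"``: each (run_type, item_type) cell has a probability of
      an "old" response; subject-level probabilities are drawn from a
      mean-preserving Beta distribution around the cell probability
      (concentration ``subject_concentration``; larger = more homogeneous,
      ``inf`` disables heterogeneity), and each trial is a Bernoulli draw.
    * ``mode="sdt"``: equal-variance Gaussian model. Old-item strength is
      N(d', 1), new-item strength N(0, 1); the subject responds "old" when
      strength exceeds lambda = d'_ref / 2 + c, where d'_ref is the
      run-type's reference sensitivity (mean of the old-item d' values), so
      c = 0 is the unbiased point. Subject-level d' and c are Normal around
      the condition means.

    RTs are lognormal with a condition-specific location calibrated so the
    mean matches ``rt_mean_ms``.
    """

    mode: str = "rate"
    p_old: dict = field(default_factory=lambda: dict(DEFAULT_P_OLD))
    d_prime: dict = field(default_factory=lambda: {
        ("incentivize-old", "1x"): 1.2, ("incentivize-old", "3x"): 2.1,
        ("incentivize-new", "1x"): 1.2, ("incentivize-new", "3x"): 2.1,
    })
    c: dict = field(default_factory=lambda: {
        "incentivize-old": -0.22, "incentivize-new": 0.16,
    })
    subject_concentration: float = 32.0
    subject_dprime_sd: float = 0.30
    subject_c_sd: float = 0.15
    rt_mean_ms: dict = field(default_factory=lambda: dict(DEFAULT_RT_MEAN_MS))
    rt_sigma: float = 0.30

    def __post_init__(self) -> None:
        if self.mode not in ("rate", "sdt"):
            raise ConfigurationError(f"unknown SDT mode {self.mode!r}")
        if self.mode == "rate":
            missing = [
                (rt, it) for rt in RUN_TYPES for it in ITEM_TYPES
                if (rt, it) not in self.p_old
            ]
            if missing:
                raise ConfigurationError(f"p_old missing cells: {missing}")
            bad = [k for k, v in self.p_old.items() if not 0.0 <= v <= 1.0]
            if bad:
                raise ConfigurationError(f"p_old outside [0,1] for {bad}")
        else:
            missing = [
                (rt, it) for rt in RUN_TYPES for it in ("1x", "3x")
                if (rt, it) not in self.d_prime
            ]
            if missing or set(self.c) != set(RUN_TYPES):
                raise ConfigurationError("d_prime/c missing cells")
        if self.rt_sigma <= 0:
            raise ConfigurationError("rt_sigma must be > 0")

    def with_criterion(self, c_old: float, c_new: float) -> "SdtParams":
        return replace(self, c={"incentivize-old": c_old,
                                "incentivize-new": c_new})


def simulate_responses(
    design: ExperimentDesign,
    sdt: SdtParams,
    rng_seed: int = 0,
    subject: int = 1,
) -> pd.DataFrame:
    """Simulate one subject's test-phase responses.

    Returns one row per non-null trial with columns
    ``subject, run, run_type, trial, item_type, word, response, correct,
    rt_ms``. Null events require a key press but carry no memory decision,
    so they are excluded from the response table.
    """
    rng = np.random.default_rng(rng_seed)

    # subject-level parameters
    if sdt.mode == "rate":
        conc = sdt.subject_concentration
        if not np.isfinite(conc):
            subj_p = dict(sdt.p_old)
        else:
            subj_p = {
                cell: float(rng.beta(max(p, 1e-6) * conc,
                                     max(1.0 - p, 1e-6) * conc))
                for cell, p in sdt.p_old.items()
            }
    else:
        subj_d = {cell: rng.normal(d, sdt.subject_dprime_sd)
                  for cell, d in sdt.d_prime.items()}
        subj_c = {rt: rng.normal(c, sdt.subject_c_sd)
                  for rt, c in sdt.c.items()}

    rows = []
    for run_idx, run in enumerate(design.runs, start=1):
        rt_type = run.run_type
        for trial_idx, tr in enumerate(run.trials.itertuples(), start=1):
            if tr.item_type == "null":
                continue
            cell = (rt_type, tr.item_type)
            if sdt.mode == "rate":
                respond_old = rng.random() < subj_p[cell]
            else:
                if tr.item_type == "new":
                    strength = rng.normal(0.0, 1.0)
                else:
                    strength = rng.normal(subj_d[cell], 1.0)
                d_ref = np.mean([subj_d[(rt_type, "1x")],
                                 subj_d[(rt_type, "3x")]])
                lam = d_ref / 2.0 + subj_c[rt_type]
                respond_old = strength > lam
            response = "old" if respond_old else "new"
            correct = response == ("new" if tr.item_type == "new" else "old")
            mu = np.log(sdt.rt_mean_ms[cell]) - sdt.rt_sigma ** 2 / 2.0
            rt_ms = float(rng.lognormal(mu, sdt.rt_sigma))
            rows.append((subject, run_idx, rt_type, trial_idx, tr.item_type,
                         tr.word, response, correct, rt_ms))

    return pd.DataFrame(rows, columns=[
        "subject", "run", "run_type", "trial", "item_type", "word",
        "response", "correct", "rt_ms",
    ])


def simulate_cohort(
    params: DesignParams,
    sdt: SdtParams,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full cohort: one design + response table per subject.

    Designs alternate counterbalance ids across subjects. The per-subject
    RNG streams are split deterministically from ``rng_seed``.
    """
    frames = []
    for s in range(1, params.n_subjects + 1):
        seed_s = (rng_seed * 100003 + s) % (2 ** 31)
        pool = generate_word_pool(replace(params, rng_seed=seed_s))
        design = generate_design(
            pool, params, counterbalance_id=(s - 1) % 2,
            rng=np.random.default_rng(seed_s),
        )
        frames.append(
            simulate_responses(design, sdt, rng_seed=seed_s, subject=s)
        )
    return pd.concat(frames, ignore_index=True)


def write_events_tsv(design: ExperimentDesign, path) -> None:
    """Write the test-phase design as one events table (TSV, all runs)."""
    frames = []
    for run_idx, run in enumerate(design.runs, start=1):
        df = run.trials.rename(columns={"item_type": "trial_type"}).copy()
        df.insert(0, "run", run_idx)
        df["run_type"] = run.run_type
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
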