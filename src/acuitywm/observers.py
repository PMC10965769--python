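"""Synthetic observers and trial schedules for the two psychophysical tasks.

The change-detection task probes visual working memory: an observer memorizes
a brief array of N colored squares and, after a blank retention interval,
judges whether a whole-display test array is identical or differs in one
color.  The dot-comparison task probes the approximate number system: two dot
arrays are shown left and right of fixation and the observer picks the more
numerous side.

This module generates balanced trial schedules for both designs and simulates
responses from parameterized observers, so that every estimator downstream
can be validated by parameter recovery against known ground truth.

Generative models
-----------------
Change detection follows a slots-plus-guessing account: an observer with
capacity ``k`` stores ``s = min(k_realized, N)`` of the N items (non-integer
``k`` is realized per trial as ``floor(k)`` items plus one more with
probability ``k - floor(k)``).  A change is detected iff the changed item is
among the stored ones; otherwise, and on no-change trials, the observer says
"different" with guess rate ``g``.  This yields the closed-form expectations

    E[hit rate]        = s/N + (1 - s/N) * g
    E[false-alarm rate] = g

which invert exactly to Pashler's capacity formula.

Dot comparison follows a Gaussian-noise-on-log-numerosity model: the
probability of calling the comparison array (numerosity N, reference Nref)
larger is ``p_larger(N, Nref, omega)`` with Weber fraction ``omega`` (see
:mod:`acuitywm.acuity`).  A lapse parameter mixes in uniform responding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .acuity import p_larger

CHANGE_CSV_COLUMNS = ["subject", "block", "set_size", "is_change", "response", "correct"]
DOT_CSV_COLUMNS = [
    "subject", "block", "ref_num", "ref_side", "n_left", "n_right",
    "ratio", "control", "response", "correct",
]

#: comparison numerosities for each reference; equal-numerosity pairs are
#: excluded (a "larger" response would be undefined).  Reference 32 steps by
#: two, which is the only spacing reproducing the 8 tested ratios.
DOT_COMPARISONS = {
    16: tuple(n for n in range(12, 21) if n != 16),
    32: tuple(n for n in range(24, 41, 2) if n != 32),
}


@dataclass(frozen=True)
class ChangeObserver:
    """Ground-truth observer for the change-detection task."""

    subject_id: str
    k_true: float
    guess_rate: float = 0.5
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.k_true < 0:
            raise ValueError("k_true must be >= 0")
        for name in ("guess_rate", "lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class AcuityObserver:
    """Ground-truth observer for the dot-comparison task."""

    subject_id: str
    omega_true: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_true <= 0:
            raise ValueError("omega_true must be > 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort.

    ``k_omega_correlation`` is the correlation of the underlying bivariate
    normal from which per-subject (capacity, Weber fraction) pairs are drawn
    before truncation to the stated bounds; 0 gives the null scenario
    (capacity and acuity functionally independent).
    """

    n_subjects: int = 41
    k_mean: float = 3.25
    k_sd: float = 0.9
    k_bounds: tuple[float, float] = (1.5, 5.0)
    omega_mean: float = 0.20
    omega_sd: float = 0.07
    omega_bounds: tuple[float, float] = (0.05, 0.50)
    k_omega_correlation: float = 0.0
    guess_rate: float = 0.5
    #: small attentional-lapse default: without it every simulated observer
    #: with k >= 2 sits at a hard ceiling at set-size 2, producing a
    #: zero-variance K column no real cohort shows
    lapse: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.k_sd <= 0 or self.omega_sd <= 0:
            raise ValueError("distribution SDs must be > 0")
        if not -1.0 < self.k_omega_correlation < 1.0:
            raise ValueError("k_omega_correlation must be in (-1, 1)")
        for lo, hi in (self.k_bounds, self.omega_bounds):
            if not lo < hi:
                raise ValueError("bounds must satisfy low < high")


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def make_change_schedule(
    n_blocks: int = 27,
    trials_per_block: int = 30,
    set_sizes: Sequence[int] = (2, 3, 5),
    p_change: float = 0.5,
    seed: int | None = None,
    n_practice: int = 0,
) -> pd.DataFrame:
    """Build a change-detection schedule balanced within blocks.

    Every block crosses set-size with change/no-change.  When
    ``trials_per_block`` is divisible by ``2 * len(set_sizes)`` (and
    ``p_change == 0.5``) the allocation is exactly balanced; otherwise the
    nearest balanced allocation is used, distributing remainder trials over
    cells in a seed-shuffled round robin.  ``n_practice`` extra trials are
    prepended with ``practice=True`` and ``block=-1``; analyses drop them.
    """
    if n_blocks <= 0 or trials_per_block <= 0:
        raise ValueError("counts must be positive")
    set_sizes = list(set_sizes)
    if not set_sizes:
        raise ValueError("set_sizes must be non-empty")
    if not 0.0 < p_change < 1.0:
        raise ValueError("p_change must be in (0, 1)")
    rng = np.random.default_rng(seed)

    def block_cells(n_trials: int) -> list[tuple[int, bool]]:
        per_ss = n_trials // len(set_sizes)
        ss_counts = {s: per_ss for s in set_sizes}
        leftover = n_trials - per_ss * len(set_sizes)
        for s in rng.permutation(set_sizes)[:leftover]:
            ss_counts[int(s)] += 1
        cells: list[tuple[int, bool]] = []
        for s, cnt in ss_counts.items():
            n_change = int(round(p_change * cnt))
            # keep at least the nearest balanced split
            cells += [(s, True)] * n_change + [(s, False)] * (cnt - n_change)
        return cells

    rows = []
    for b in range(-1 if n_practice else 0, n_blocks):
        cells = block_cells(n_practice if b == -1 else trials_per_block)
        order = rng.permutation(len(cells))
        for i in order:
            s, chg = cells[i]
            rows.append(
                {
                    "block": b,
                    "set_size": s,
                    "is_change": chg,
                    "changed_item": int(rng.integers(s)) if chg else -1,
                    "practice": b == -1,
                }
            )
    df = pd.DataFrame(rows)
    df["response"] = pd.NA
    df["correct"] = pd.NA
    return df


def make_dot_schedule(
    pool_size: int = 1280,
    n_trials: int = 192,
    refs: Sequence[int] = (16, 32),
    seed: int | None = None,
    n_practice: int = 0,
    block_size: int = 16,
) -> pd.DataFrame:
    """Sample a dot-comparison schedule from a balanced design pool.

    The pool enumerates every design cell — reference numerosity x comparison
    numerosity x feature-control condition x reference side — replicated up to
    ``pool_size``, from which ``n_trials`` are drawn without replacement,
    stratified so the density-matched and area-matched halves are exactly
    equal.  With the defaults (pool 1280, 192 trials) this reproduces the
    12-blocks-of-16 design.
    """
    if pool_size <= 0 or n_trials <= 0:
        raise ValueError("counts must be positive")
    if n_trials > pool_size:
        raise ValueError("n_trials cannot exceed pool_size")
    refs = list(refs)
    for r in refs:
        if r not in DOT_COMPARISONS:
            raise ValueError(f"unsupported reference numerosity {r}")
    rng = np.random.default_rng(seed)

    cells = [
        (ref, comp, control)
        for ref in refs
        for comp in DOT_COMPARISONS[ref]
        for control in ("density", "area")
    ]
    reps = int(np.ceil(pool_size / len(cells)))
    pool = (cells * reps)[:pool_size]
    pool_df = pd.DataFrame(pool, columns=["ref_num", "n_comp", "control"])
    # reference side is counterbalanced within each cell's replications
    pool_df["ref_side"] = ""
    for _, idx in pool_df.groupby(["ref_num", "n_comp", "control"]).groups.items():
        sides = np.array(["left", "right"] * ((len(idx) + 1) // 2))[: len(idx)]
        pool_df.loc[idx, "ref_side"] = rng.permutation(sides)

    def draw(n_draw: int) -> pd.DataFrame:
        # stratified by control so the 50/50 split is exact
        picked = []
        for j, ctrl in enumerate(("density", "area")):
            idx = pool_df.index[pool_df["control"] == ctrl].to_numpy()
            n_ctrl = n_draw // 2 + (n_draw % 2 if j == 0 else 0)
            if n_ctrl > idx.size:
                raise ValueError("pool too small for requested control split")
            picked.append(rng.choice(idx, size=n_ctrl, replace=False))
        sel = pool_df.loc[np.concatenate(picked)].sample(frac=1.0, random_state=rng).reset_index(drop=True)
        return sel

    frames = []
    if n_practice:
        prac = draw(n_practice).assign(practice=True, block=-1)
        frames.append(prac)
    main = draw(n_trials).assign(practice=False)
    main["block"] = np.arange(len(main)) // block_size
    frames.append(main)
    df = pd.concat(frames, ignore_index=True)

    df["n_left"] = np.where(df["ref_side"] == "left", df["ref_num"], df["n_comp"])
    df["n_right"] = np.where(df["ref_side"] == "right", df["ref_num"], df["n_comp"])
    big = df[["n_left", "n_right"]].max(axis=1)
    small = df[["n_left", "n_right"]].min(axis=1)
    df["ratio"] = big / small
    df["response"] = pd.NA
    df["correct"] = pd.NA
    return df.drop(columns=["n_comp"])


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------

def simulate_change_responses(
    observer: ChangeObserver, schedule: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Fill in responses of a slots+guessing observer (vectorized)."""
    rng = np.random.default_rng(seed)
    df = schedule.copy()
    n = len(df)
    set_size = df["set_size"].to_numpy(int)
    is_change = df["is_change"].to_numpy(bool)

    base = int(np.floor(observer.k_true))
    frac = observer.k_true - base
    stored = np.minimum(base + (rng.random(n) < frac), set_size)

    p_store_changed = stored / set_size
    detected = is_change & (rng.random(n) < p_store_changed)
    says_diff = detected | (rng.random(n) < observer.guess_rate)
    if observer.lapse > 0:
        lapse_mask = rng.random(n) < observer.lapse
        says_diff = np.where(lapse_mask, rng.random(n) < 0.5, says_diff)

    df["response"] = np.where(says_diff, "different", "same")
    df["correct"] = says_diff == is_change
    df["subject"] = observer.subject_id
    return df


def simulate_dot_responses(
    observer: AcuityObserver, schedule: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Fill in responses of a Weber-fraction observer (vectorized)."""
    rng = np.random.default_rng(seed)
    df = schedule.copy()
    ref = df["ref_num"].to_numpy(float)
    comp = np.where(df["ref_side"] == "left", df["n_right"], df["n_left"]).astype(float)
    p_comp = p_larger(comp, ref, observer.omega_true)
    p_comp = (1.0 - observer.lapse) * p_comp + observer.lapse / 2.0

    chose_comp = rng.random(len(df)) < p_comp
    comp_side = np.where(df["ref_side"] == "left", "right", "left")
    df["response"] = np.where(chose_comp, comp_side, df["ref_side"])
    larger_side = np.where(df["n_left"] > df["n_right"], "left", "right")
    df["correct"] = df["response"].to_numpy() == larger_side
    df["subject"] = observer.subject_id
    return df


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def make_cohort(spec: CohortSpec) -> tuple[list[ChangeObserver], list[AcuityObserver]]:
    """Draw per-subject (k, omega) from a truncated bivariate normal.

    Pairs are sampled jointly and rejected outside the rectangular bounds, so
    the realized correlation approaches ``spec.k_omega_correlation`` up to
    truncation attenuation.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.k_omega_correlation
    cov = [
        [spec.k_sd**2, rho * spec.k_sd * spec.omega_sd],
        [rho * spec.k_sd * spec.omega_sd, spec.omega_sd**2],
    ]
    mean = [spec.k_mean, spec.omega_mean]
    kept = np.empty((0, 2))
    attempts = 0
    while len(kept) < spec.n_subjects:
        attempts += 1
        if attempts > 1000:
            raise ValueError("bounds reject nearly all probability mass")
        draw = rng.multivariate_normal(mean, cov, size=4 * spec.n_subjects)
        ok = (
            (draw[:, 0] >= spec.k_bounds[0]) & (draw[:, 0] <= spec.k_bounds[1])
            & (draw[:, 1] >= spec.omega_bounds[0]) & (draw[:, 1] <= spec.omega_bounds[1])
        )
        kept = np.vstack([kept, draw[ok]])
    kept = kept[: spec.n_subjects]
    ids = [f"s{i + 1:03d}" for i in range(spec.n_subjects)]
    change = [
        ChangeObserver(sid, float(k), spec.guess_rate, spec.lapse)
        for sid, k in zip(ids, kept[:, 0])
    ]
    acuity = [AcuityObserver(sid, float(w), spec.lapse) for sid, w in zip(ids, kept[:, 1])]
    return change, acuity


def simulate_cohort_trials(
    spec: CohortSpec,
    change_schedule_kwargs: dict | None = None,
    dot_schedule_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ChangeObserver], list[AcuityObserver]]:
    """Simulate full trial logs for a cohort (fresh schedule per subject)."""
    change_obs, acuity_obs = make_cohort(spec)
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(2 * spec.n_subjects)
    chg_frames, dot_frames = [], []
    ckw = change_schedule_kwargs or {}
    dkw = dot_schedule_kwargs or {}
    for i, (co, ao) in enumerate(zip(change_obs, acuity_obs)):
        s1 = np.random.default_rng(child[2 * i])
        s2 = np.random.default_rng(child[2 * i + 1])
        sched_c = make_change_schedule(seed=s1.integers(2**31), **ckw)
        chg_frames.append(simulate_change_responses(co, sched_c, seed=s1.integers(2**31)))
        sched_d = make_dot_schedule(seed=s2.integers(2**31), **dkw)
        dot_frames.append(simulate_dot_responses(ao, sched_d, seed=s2.integers(2**31)))
    return (
        pd.concat(chg_frames, ignore_index=True),
        pd.concat(dot_frames, ignore_index=True),
        change_obs,
        acuity_obs,
    )


# ---------------------------------------------------------------------------
# trial-log I/O (fixed CSV dialects)
# ---------------------------------------------------------------------------

def drop_practice(trials: pd.DataFrame) -> pd.DataFrame:
    """Return experimental trials only (practice rows are flagged metadata)."""
    if "practice" in trials.columns:
        return trials.loc[~trials["practice"].astype(bool)]
    return trials


def write_change_csv(trials: pd.DataFrame, path) -> None:
    drop_practice(trials)[CHANGE_CSV_COLUMNS].to_csv(path, index=False)


def read_change_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CHANGE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"change-task CSV missing columns: {sorted(missing)}")
    return df


def write_dot_csv(trials: pd.DataFrame, path) -> None:
    drop_practice(trials)[DOT_CSV_COLUMNS].to_csv(path, index=False)


def read_dot_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DOT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dot-task CSV missing columns: {sorted(missing)}")
    return df
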