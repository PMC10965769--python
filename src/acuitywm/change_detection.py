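"""Capacity (Pashler K) and discriminability (d') from change detection.

For a whole-display change-detection task with set-size N, observed hit rate
h (P("different" | change)) and false-alarm rate f (P("different" | no
change)), working-memory capacity is estimated with Pashler's correction

    K = N * (h - f) / (1 - f)

which is the appropriate inversion when the test re-displays the whole array
(a single-probe design would instead call for Cowan's formula, out of scope
here).  Discriminability is the signal-detection index d' = Z(h) - Z(f).

K uses the raw rates (K is reported clamped to [0, N], with the raw value
retained for moment computations); d' applies the standard 1/(2n) correction
to rates of exactly 0 or 1, since Z is unbounded there.  The log-linear
correction would be a reasonable alternative; the 1/(2n) rule is used because
it leaves non-extreme cells untouched.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .observers import drop_practice


class RateTally(NamedTuple):
    hit_rate: float
    fa_rate: float
    accuracy: float
    n_change: int
    n_nochange: int


def tally_rates(trials: pd.DataFrame, subject=None, set_size: int | None = None) -> RateTally:
    """Hit/false-alarm/accuracy tally for one (subject, set-size) cell."""
    df = drop_practice(trials)
    if subject is not None:
        df = df[df["subject"] == subject]
    if set_size is not None:
        df = df[df["set_size"] == set_size]
    is_change = df["is_change"].astype(bool).to_numpy()
    says_diff = (df["response"] == "different").to_numpy()
    n_change = int(is_change.sum())
    n_nochange = int((~is_change).sum())
    if n_change == 0 or n_nochange == 0:
        raise ValueError("cell needs at least one change and one no-change trial")
    h = float(says_diff[is_change].mean())
    f = float(says_diff[~is_change].mean())
    acc = float((says_diff == is_change).mean())
    return RateTally(h, f, acc, n_change, n_nochange)


def pashler_k(set_size: int, hit_rate: float, fa_rate: float, clamp: bool = True) -> float:
    """Pashler's whole-display capacity estimate; NaN when fa_rate = 1."""
    if fa_rate >= 1.0:
        return float("nan")
    k = set_size * (hit_rate - fa_rate) / (1.0 - fa_rate)
    if clamp:
        k = min(max(k, 0.0), float(set_size))
    return float(k)


def dprime(hit_rate: float, fa_rate: float, n_change: int, n_nochange: int) -> float:
    """d' = Z(h) - Z(f), with extreme rates pulled in by 1/(2n)."""

    def corrected(rate: float, n: int) -> float:
        if n <= 0:
            raise ValueError("need positive trial counts for d'")
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        return min(max(rate, lo), hi)

    h = corrected(hit_rate, n_change)
    f = corrected(fa_rate, n_nochange)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def estimate_capacity(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-set-size capacity table (h, f, accuracy, K, d')."""
    df = drop_practice(trials)
    rows = []
    for (sid, n), _ in df.groupby(["subject", "set_size"]):
        t = tally_rates(df, subject=sid, set_size=int(n))
        rows.append(
            {
                "subject": sid,
                "set_size": int(n),
                "hit_rate": t.hit_rate,
                "fa_rate": t.fa_rate,
                "accuracy": t.accuracy,
                "n_change": t.n_change,
                "n_nochange": t.n_nochange,
                "k": pashler_k(int(n), t.hit_rate, t.fa_rate),
                "k_raw": pashler_k(int(n), t.hit_rate, t.fa_rate, clamp=False),
                "dprime": dprime(t.hit_rate, t.fa_rate, t.n_change, t.n_nochange),
            }
        )
    return pd.DataFrame(rows).sort_values(["subject", "set_size"]).reset_index(drop=True)


def max_k(estimates: pd.DataFrame) -> pd.DataFrame:
    """K at the largest tested set-size, flagging earlier-peaking subjects.

    The capacity ceiling should be probed at the supra-capacity set-size, so
    ``k_max`` is K at the largest set-size; ``peaked_before_largest`` marks
    subjects whose K at any smaller set-size exceeded it (a warning that the
    largest set-size did not capture their plateau).
    """
    rows = []
    for sid, sub in estimates.groupby("subject"):
        if sub["set_size"].nunique() < 2:
            raise ValueError(f"subject {sid}: need estimates at >= 2 set-sizes")
        sub = sub.sort_values("set_size")
        largest = sub.iloc[-1]
        k_at_largest = float(largest["k"])
        peaked = bool((sub["k"].iloc[:-1] > k_at_largest).any())
        rows.append(
            {
                "subject": sid,
                "k_max": k_at_largest,
                "set_size_at_max": int(largest["set_size"]),
                "peaked_before_largest": peaked,
            }
        )
    return pd.DataFrame(rows)


def exclude_low_accuracy(
    trials: pd.DataFrame, threshold: float = 0.60
) -> tuple[list, pd.DataFrame]:
    """Exclude subjects with overall change-detection accuracy < threshold.

    The rule is strict "less than": a subject at exactly the threshold is
    retained.  Returns (retained subject ids, exclusion log).
    """
    df = drop_practice(trials)
    acc = df.groupby("subject")["correct"].mean()
    excluded = acc[acc < threshold]
    log = pd.DataFrame(
        {
            "subject": excluded.index,
            "accuracy": excluded.to_numpy(float),
            "reason": f"accuracy < {threshold}",
        }
    )
    return [s for s in acc.index if s not in set(excluded.index)], log


def validity_matrix(estimates: pd.DataFrame, measure: str = "k") -> pd.DataFrame:
    """Pairwise Pearson r between per-subject K across set-sizes.

    A construct-validity check: if K at each set-size measures the same
    stable capacity, the columns must inter-correlate.
    """
    wide = estimates.pivot(index="subject", columns="set_size", values=measure)
    if len(wide) < 3:
        raise ValueError("need at least 3 subjects")
    if (wide.std() == 0).any():
        raise ValueError("zero-variance column in estimates")
    return wide.corr(method="pearson")


def _rm_anova(wide: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA (uncorrected df) by SS decomposition."""
    n, k = wide.shape
    grand = wide.mean()
    ss_cond = n * np.sum((wide.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((wide.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((wide - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ss_cond <= 1e-300:
        f = 0.0
    elif ms_err == 0:
        f = float("inf")
    else:
        f = ms_cond / ms_err
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    np2 = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return {"F": float(f), "df1": df1, "df2": df2, "p": p, "partial_eta_sq": float(np2)}


def setsize_contrasts(estimates: pd.DataFrame, measure: str = "accuracy") -> dict:
    """Within-subject set-size effect: RM-ANOVA plus BH-FDR paired t-tests.

    No sphericity correction is applied (uncorrected degrees of freedom are
    reported); this is noted in the output.
    """
    wide = estimates.pivot(index="subject", columns="set_size", values=measure)
    if wide.isna().any().any():
        raise ValueError("incomplete within-subject design")
    anova = _rm_anova(wide.to_numpy(float))
    anova["sphericity_correction"] = "none"

    cols = list(wide.columns)
    pairs, tvals, pvals = [], [], []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            t, p = stats.ttest_rel(wide[cols[i]], wide[cols[j]])
            pairs.append((int(cols[i]), int(cols[j])))
            tvals.append(float(t))
            pvals.append(float(p))
    p_adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    pairwise = pd.DataFrame(
        {
            "set_size_a": [a for a, _ in pairs],
            "set_size_b": [b for _, b in pairs],
            "t": tvals,
            "df": len(wide) - 1,
            "p": pvals,
            "p_fdr": p_adj,
        }
    )
    return {"measure": measure, "anova": anova, "pairwise": pairwise}
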