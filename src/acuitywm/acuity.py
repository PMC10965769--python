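"""Weber-fraction estimation from dot-comparison data.

The approximate number system represents numerosity with Gaussian noise on a
log scale, so the probability of judging a comparison array of numerosity N
larger than a reference of numerosity Nref is

    P_larger(N, Nref) = 1/2 * (1 + erf( ln(N / Nref) / (sqrt(2) * omega) ))

where omega is the Weber fraction: the SD of the internal noise in log-ratio
units.  Smaller omega means finer discrimination; acuity is reported as
1 - omega.  Natural log is the fixed convention (another base would only
rescale omega).

Fitting minimizes squared error between observed per-cell proportions of
"comparison larger" responses and the model curve (a variance-explained
criterion, reported as R^2); binomial maximum likelihood is available as an
alternative objective and agrees closely on well-behaved data.  The model is
deliberately one-parameter — no lapse term — matching common practice for
this design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

OMEGA_BOUNDS = (0.01, 2.0)


def p_larger(n, n_ref, omega):
    """Probability of calling the comparison array (numerosity ``n``) larger.

    Vectorized over ``n`` and ``n_ref``.  Satisfies P(n, n, w) = 0.5 and
    P(a, b, w) + P(b, a, w) = 1.
    """
    n = np.asarray(n, float)
    n_ref = np.asarray(n_ref, float)
    if np.any(n <= 0) or np.any(n_ref <= 0):
        raise ValueError("numerosities must be positive")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    out = 0.5 * (1.0 + special.erf(np.log(n / n_ref) / (np.sqrt(2.0) * omega)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class WeberFit:
    """Result of a psychometric fit."""

    subject_id: str
    omega: float
    r_squared: float
    n_cells: int
    n_trials: int
    subset: str = "all"

    @property
    def acuity(self) -> float:
        return 1.0 - self.omega


def aggregate_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse a dot-task trial log into (ref, comparison) psychometric cells.

    Returns one row per (ref_num, n_comp) with trial counts and the count of
    trials on which the comparison side was chosen as larger.  Omitted trials
    (missing response) are dropped.
    """
    df = trials.dropna(subset=["response"]).copy()
    comp_side = np.where(df["ref_side"] == "left", "right", "left")
    df["n_comp"] = np.where(df["ref_side"] == "left", df["n_right"], df["n_left"])
    df["chose_comp"] = df["response"].to_numpy() == comp_side
    g = df.groupby(["ref_num", "n_comp"], as_index=False).agg(
        n_trials=("chose_comp", "size"), n_chose_comp=("chose_comp", "sum")
    )
    return g


def _ls_objective(cells: pd.DataFrame):
    obs = cells["n_chose_comp"].to_numpy(float) / cells["n_trials"].to_numpy(float)
    n = cells["n_comp"].to_numpy(float)
    ref = cells["ref_num"].to_numpy(float)

    def sse(omega: float) -> float:
        return float(np.sum((obs - p_larger(n, ref, omega)) ** 2))

    return obs, sse


def _ml_objective(cells: pd.DataFrame):
    k = cells["n_chose_comp"].to_numpy(float)
    m = cells["n_trials"].to_numpy(float)
    n = cells["n_comp"].to_numpy(float)
    ref = cells["ref_num"].to_numpy(float)

    def nll(omega: float) -> float:
        p = np.clip(p_larger(n, ref, omega), 1e-12, 1 - 1e-12)
        return float(-np.sum(k * np.log(p) + (m - k) * np.log1p(-p)))

    return k / m, nll


def fit_weber(
    cells: pd.DataFrame,
    subject_id: str = "",
    objective: str = "ls",
    bounds: tuple[float, float] = OMEGA_BOUNDS,
    subset: str = "all",
    per_ratio: bool = False,
) -> WeberFit:
    """Fit the Weber fraction to psychometric cells.

    A coarse multi-start (log-spaced grid over ``bounds``) seeds a bounded
    scalar refinement, which makes the fit robust to the objective's flat
    shoulders at extreme omega.  ``per_ratio=True`` pools cells sharing the
    same large/small ratio before fitting (proportion-correct formulation);
    the default fits the 16 (ref, comparison) cells directly.
    """
    if per_ratio:
        c = cells.copy()
        big = np.maximum(c["n_comp"], c["ref_num"])
        small = np.minimum(c["n_comp"], c["ref_num"])
        c["ratio"] = (big / small).round(6)
        # correct response == "comparison larger" iff comparison is the bigger
        comp_bigger = c["n_comp"] > c["ref_num"]
        c["n_correct"] = np.where(
            comp_bigger, c["n_chose_comp"], c["n_trials"] - c["n_chose_comp"]
        )
        g = c.groupby("ratio", as_index=False).agg(
            n_trials=("n_trials", "sum"), n_chose_comp=("n_correct", "sum")
        )
        g["n_comp"] = g["ratio"]
        g["ref_num"] = 1.0
        cells = g
    if len(cells) < 4:
        raise ValueError("need at least 4 distinct psychometric cells")
    if (cells["n_trials"] <= 0).any():
        raise ValueError("cells must contain trials")

    obs, fun = {"ls": _ls_objective, "ml": _ml_objective}[objective](cells)
    if np.allclose(obs, obs[0]):
        raise ValueError("degenerate data: all cell proportions identical")

    grid = np.geomspace(bounds[0], bounds[1], 64)
    vals = [fun(w) for w in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(fun, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    if not res.success:
        raise RuntimeError("Weber fit failed to converge")
    omega = float(res.x)

    pred = p_larger(cells["n_comp"].to_numpy(float), cells["ref_num"].to_numpy(float), omega)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    sse = float(np.sum((obs - pred) ** 2))
    r2 = 1.0 - sse / sst
    return WeberFit(subject_id, omega, r2, len(cells), int(cells["n_trials"].sum()), subset)


def split_by_reference(cells: pd.DataFrame, subject_id: str = "", **kwargs) -> tuple[WeberFit, WeberFit]:
    """Independent fits for reference-16 and reference-32 trials."""
    fits = []
    for ref in (16, 32):
        sub = cells[cells["ref_num"] == ref]
        if sub.empty:
            raise ValueError(f"no trials with reference numerosity {ref}")
        fits.append(fit_weber(sub, subject_id, subset=f"ref{ref}", **kwargs))
    return fits[0], fits[1]


def fit_cohort(trials: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-subject fits (all trials plus split-by-reference sub-fits)."""
    rows = []
    for sid, sub in trials.groupby("subject"):
        cells = aggregate_cells(sub)
        fit = fit_weber(cells, str(sid), **kwargs)
        f16, f32 = split_by_reference(cells, str(sid), **kwargs)
        rows.append(
            {
                "subject": sid,
                "omega": fit.omega,
                "acuity": fit.acuity,
                "r_squared": fit.r_squared,
                "omega_ref16": f16.omega,
                "r_squared_ref16": f16.r_squared,
                "omega_ref32": f32.omega,
                "r_squared_ref32": f32.r_squared,
                "accuracy": float(sub["correct"].mean()),
            }
        )
    return pd.DataFrame(rows)


def reliability(fits: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (with two-sided p) between omega at reference 16 and 32."""
    if len(fits) < 3:
        raise ValueError("need at least 3 subjects")
    x = fits["omega_ref16"].to_numpy(float)
    y = fits["omega_ref32"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in omega estimates")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def exclude_outliers(
    summary: pd.DataFrame, measure: str = "accuracy", z_thresh: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass exclusion of subjects beyond ``z_thresh`` SDs of the mean.

    Applied to mean dot-task performance by default.  Returns
    (retained, excluded-log); the log records the offending value and its
    z-score.  The rule is strict (``> z_thresh``), so a value at exactly the
    threshold is retained.
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 subjects")
    v = summary[measure].to_numpy(float)
    mu, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        return summary.copy(), summary.iloc[0:0].copy()
    z = (v - mu) / sd
    bad = np.abs(z) > z_thresh
    excluded = summary.loc[bad].assign(z_score=z[bad], reason=f"|{measure} z| > {z_thresh}")
    return summary.loc[~bad].copy(), excluded
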