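"""End-to-end orchestration: simulate or ingest, exclude, estimate, infer.

One call runs the whole analysis in the order the stages depend on each
other: cohort simulation (or CSV ingest) -> accuracy and outlier exclusions
-> per-subject capacity and Weber-fraction estimation -> construct-validity
checks and set-size contrasts -> moment extrapolation and the Pearson-system
capacity simulation -> the frequentist + Bayesian correlation between maximum
K and acuity.  Every stage draws from its own RNG stream spawned from the
master seed, so reports reproduce bit-for-bit (timestamps aside) from a
config file.

Three input modes:

* ``simulate``                  — generate a synthetic cohort from a
  :class:`~acuitywm.observers.CohortSpec`;
* ``ingest``                    — read change-task and dot-task trial CSVs;
* ``replicate-paper-moments``   — skip trial-level analysis and run only the
  moment-extrapolation simulation from a literal moments table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib import metadata, resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acuity, change_detection, extrapolation, inference, observers

logger = logging.getLogger("acuitywm")

MODES = ("simulate", "ingest", "replicate-paper-moments")


@dataclasses.dataclass
class RunConfig:
    mode: str = "simulate"
    seed: int = 0
    outdir: str | None = None
    cohort: dict = dataclasses.field(default_factory=dict)
    change_csv: str | None = None
    dot_csv: str | None = None
    moments: dict = dataclasses.field(default_factory=dict)  # set_size -> [mean, sd, skew, kurt]
    target_set_size: int = 6
    reps: int = 10_000
    n_per_rep: int = 41
    bounds: tuple[float, float] = (0.0, 6.0)
    truncation: str = "reject"
    kappa: float = 1.0 / 3.0
    accuracy_threshold: float = 0.60
    outlier_z: float = 3.0
    run_extrapolation: bool = True
    run_correlation: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "ingest" and not (self.change_csv and self.dot_csv):
            raise ValueError("ingest mode requires change_csv and dot_csv paths")
        if self.mode == "replicate-paper-moments" and not self.moments:
            raise ValueError("replicate-paper-moments mode requires a moments table")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bounds" in raw:
            raw["bounds"] = tuple(raw["bounds"])
        return cls(**raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Structural validation against the shipped report schema.

    Checks the subset of JSON Schema this project uses: ``type``,
    ``required`` and nested ``properties``.  Raises ``ValueError`` on the
    first violation.
    """
    if schema is None:
        schema = load_report_schema()
    _validate_node(report, schema, path="$")


def load_report_schema() -> dict:
    with resources.files("acuitywm.schemas").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": (int, np.integer),
    "number": (int, float, np.integer, np.floating),
    "boolean": bool,
}


def _validate_node(value, schema: dict, path: str) -> None:
    expected = schema.get("type")
    if expected and not isinstance(value, _TYPES[expected]):
        raise ValueError(f"{path}: expected {expected}, got {type(value).__name__}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate_node(value[key], sub, f"{path}.{key}")


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and optionally write) a report."""
    seeds = _stage_seeds(config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    try:
        version = metadata.version("acuitywm")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    report: dict = {
        "mode": config.mode,
        "provenance": {
            "config_hash": hashlib.sha256(config.canonical().encode()).hexdigest(),
            "seed": config.seed,
            "package_version": version,
        },
        "exclusions": {"low_accuracy": [], "dot_outliers": [], "n_retained": 0},
    }

    if config.mode == "replicate-paper-moments":
        report["extrapolation"] = _extrapolate_from_moments(config, seeds[5], outdir)
        _finish(report, outdir)
        return report

    # --- stage: obtain trials ------------------------------------------------
    if config.mode == "simulate":
        spec = observers.CohortSpec(**{**config.cohort, "seed": seeds[0]})
        change_trials, dot_trials, *_ = observers.simulate_cohort_trials(spec)
        logger.info("simulated cohort of %d subjects", spec.n_subjects)
    else:
        change_trials = observers.read_change_csv(config.change_csv)
        dot_trials = observers.read_dot_csv(config.dot_csv)
        logger.info("ingested %d change / %d dot trials", len(change_trials), len(dot_trials))
    if outdir:
        observers.write_change_csv(change_trials, outdir / "change_trials.csv")
        observers.write_dot_csv(dot_trials, outdir / "dot_trials.csv")

    # --- stage: exclusions ---------------------------------------------------
    retained, low_log = change_detection.exclude_low_accuracy(
        change_trials, config.accuracy_threshold
    )
    change_trials = change_trials[change_trials["subject"].isin(retained)]
    dot_trials = dot_trials[dot_trials["subject"].isin(retained)]
    report["exclusions"]["low_accuracy"] = low_log.to_dict("records")

    dot_acc = (
        observers.drop_practice(dot_trials)
        .groupby("subject", as_index=False)["correct"]
        .mean()
        .rename(columns={"correct": "accuracy"})
    )
    kept_summary, out_log = acuity.exclude_outliers(dot_acc, "accuracy", config.outlier_z)
    retained = list(kept_summary["subject"])
    change_trials = change_trials[change_trials["subject"].isin(retained)]
    dot_trials = dot_trials[dot_trials["subject"].isin(retained)]
    report["exclusions"]["dot_outliers"] = out_log.to_dict("records")
    report["exclusions"]["n_retained"] = len(retained)
    logger.info("%d subjects retained after exclusions", len(retained))

    # --- stage: estimation ---------------------------------------------------
    estimates = change_detection.estimate_capacity(change_trials)
    kmax = change_detection.max_k(estimates)
    fits = acuity.fit_cohort(dot_trials)
    if outdir:
        estimates.to_csv(outdir / "capacity_estimates.csv", index=False)
        kmax.to_csv(outdir / "k_max.csv", index=False)
        fits.to_csv(outdir / "weber_fits.csv", index=False)

    # --- stage: validity + contrasts -----------------------------------------
    validity = change_detection.validity_matrix(estimates)
    rel_r, rel_p = acuity.reliability(fits)
    report["validity"] = {
        "k_between_set_sizes": {
            f"{a}v{b}": float(validity.loc[a, b])
            for i, a in enumerate(validity.index)
            for b in validity.index[i + 1:]
        },
        "omega_reliability_r": rel_r,
        "omega_reliability_p": rel_p,
    }
    contrasts = {}
    for measure in ("accuracy", "k"):
        c = change_detection.setsize_contrasts(estimates, measure)
        contrasts[measure] = {
            "anova": c["anova"],
            "pairwise": c["pairwise"].to_dict("records"),
        }
    report["contrasts"] = contrasts
    report["acuity"] = {
        "mean_omega": float(fits["omega"].mean()),
        "sd_omega": float(fits["omega"].std(ddof=1)),
        "mean_r_squared": float(fits["r_squared"].mean()),
        "mean_omega_ref16": float(fits["omega_ref16"].mean()),
        "mean_omega_ref32": float(fits["omega_ref32"].mean()),
    }

    # --- stage: extrapolation ------------------------------------------------
    if config.run_extrapolation:
        moments = {
            int(n): extrapolation.sample_moments(sub["k"].to_numpy())
            for n, sub in estimates.groupby("set_size")
        }
        fit = extrapolation.extrapolate_moments(moments, config.target_set_size)
        if fit.feasible:
            sim = extrapolation.simulate_k6(
                fit,
                n_per_rep=config.n_per_rep,
                reps=config.reps,
                bounds=config.bounds,
                seed=seeds[5],
                truncation=config.truncation,
            )
            report["extrapolation"] = _extrapolation_summary(fit, sim, outdir)
        else:
            report["extrapolation"] = {
                "predicted_moments": dataclasses.asdict(fit.predicted),
                "feasible": False,
                "pooled_median": float("nan"),
                "pooled_mean": float("nan"),
            }

    # --- stage: correlation --------------------------------------------------
    if config.run_correlation:
        merged = kmax.merge(fits[["subject", "acuity"]], on="subject")
        rep = inference.correlation_report(
            merged["k_max"].to_numpy(), merged["acuity"].to_numpy(), config.kappa
        )
        report["correlation"] = {
            "n": rep.n,
            "r": rep.r,
            "t_stat": rep.t_stat,
            "p_two_sided": rep.p_two_sided,
            "bf01": rep.bf01,
            "prior_scale": rep.prior_scale,
            "evidence": rep.evidence,
        }

    _finish(report, outdir)
    return report


def _extrapolate_from_moments(config: RunConfig, seed: int, outdir: Path | None) -> dict:
    moments = {
        int(n): extrapolation.MomentVector(*[float(v) for v in vals])
        for n, vals in config.moments.items()
    }
    fit = extrapolation.extrapolate_moments(moments, config.target_set_size)
    sim = extrapolation.simulate_k6(
        fit,
        n_per_rep=config.n_per_rep,
        reps=config.reps,
        bounds=config.bounds,
        seed=seed,
        truncation=config.truncation,
    )
    return _extrapolation_summary(fit, sim, outdir)


def _extrapolation_summary(fit, sim, outdir: Path | None) -> dict:
    centers, dens = sim.density()
    if outdir:
        pd.DataFrame({"k": centers, "density": dens}).to_csv(
            outdir / "k_target_density.csv", index=False
        )
    return {
        "target_set_size": fit.target,
        "lines": {k: {"slope": s, "intercept": i} for k, (s, i) in fit.lines.items()},
        "predicted_moments": dataclasses.asdict(fit.predicted),
        "feasible": fit.feasible,
        "reps": sim.reps,
        "n_per_rep": sim.n_per_rep,
        "bounds": list(sim.bounds),
        "truncation": sim.truncation,
        "acceptance_rate": sim.acceptance_rate,
        "pooled_median": sim.pooled_median,
        "pooled_mean": sim.pooled_mean,
        "per_rep_median_mean": float(sim.per_rep_medians.mean()),
    }


def _finish(report: dict, outdir: Path | None) -> None:
    validate_report(report)
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
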