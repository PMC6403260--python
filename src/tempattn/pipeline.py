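"""End-to-end analysis chains and the reproducible run orchestrator.

``analyze_narrow_range`` reproduces the narrow-range chain: per-subject
shared-slope thresholds (9 levels), a per-subject permutation fluctuation
test on the raw profiles, window-3 smoothing (9 -> 7 points), subject
centering, repeated-measures ANOVA with Fisher-LSD pairwise comparisons,
and the group mean curve.  ``analyze_wide_range`` mirrors the wide-range
chain: per-subject correction rates (centered, ANOVA'd on all 11 levels)
plus group-level pooled thresholds.  ``run_pipeline`` wires simulation,
threshold fitting, statistics, model fitting and model comparison together
from a JSON-serialisable :class:`RunConfig`, writing per-stage artifacts.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .duration import HierarchicalDurationModel
from .fitting import AttentionModelRegression, ThresholdCurve, compare_models
from .hazard import QuadratureSpec
from .psychometric import (
    SharedSlopePsychometric,
    ThresholdProfile,
    correction_rates,
    fit_group_thresholds_bootstrap,
)
from .simulate import ObserverPopulation, design, simulate_study
from .stats import (
    center_profiles,
    fisher_lsd,
    permutation_fluctuation_test,
    rm_anova,
    smooth_profile,
)

__all__ = [
    "RunConfig",
    "StageError",
    "analyze_narrow_range",
    "analyze_wide_range",
    "run_pipeline",
]


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def analyze_narrow_range(
    trials: pd.DataFrame, n_perm: int = 10000, seed: int | None = None
) -> dict:
    """Per-subject thresholds -> permutation test -> smooth -> center -> ANOVA."""
    profiles, slopes, perms = [], {}, {}
    for sid, g in trials.groupby("subject_id"):
        est = SharedSlopePsychometric().fit(g)
        prof = est.profile(str(sid))
        profiles.append(prof)
        slopes[str(sid)] = est.slope_
        perms[str(sid)] = permutation_fluctuation_test(prof, n_perm=n_perm, seed=seed)
    smoothed = [smooth_profile(p) for p in profiles]
    centered = center_profiles(smoothed)
    anova = rm_anova(centered)
    mat = np.vstack([p.thresholds for p in centered])
    n_lev = mat.shape[1]
    lsd = [
        {"level_a": a, "level_b": b, **fisher_lsd(centered, a, b)}
        for a in range(n_lev)
        for b in range(a + 1, n_lev)
    ]
    return {
        "profiles": profiles,
        "slopes": slopes,
        "permutation": perms,
        "smoothed": smoothed,
        "centered": centered,
        "anova": anova,
        "lsd": pd.DataFrame(lsd),
        "mean_curve": ThresholdProfile(
            "group", centered[0].intervals, mat.mean(axis=0), "centered"
        ),
    }


def analyze_wide_range(
    trials: pd.DataFrame, n_boot: int = 10000, seed: int | None = None
) -> dict:
    """Centered per-subject correction rates + group pooled thresholds."""
    rates = correction_rates(trials, per="subject")
    wide = rates.pivot(index="subject_id", columns="interval_s", values="prop_correct")
    centered = center_profiles(wide)
    anova = rm_anova(centered)
    thresholds = fit_group_thresholds_bootstrap(trials, n_boot=n_boot, seed=seed)
    return {
        "correction_rates": rates,
        "centered_rates": centered,
        "anova": anova,
        "group_thresholds": thresholds,
    }


@dataclass
class RunConfig:
    """JSON-round-trippable configuration for ``run_pipeline``.

    Stages run only when enabled; every stochastic stage has its own seed.
    """

    out_dir: str = "runs/demo"
    simulate: bool = True
    experiments: list = field(default_factory=lambda: ["1", "3"])
    n_subjects: int = 15
    seed: int = 0
    trials_csv: dict = field(default_factory=dict)  # experiment -> path
    fit_thresholds: bool = True
    stats: bool = True
    n_perm: int = 10000
    n_boot: int = 0
    fit_model: bool = True
    variant_full: str = "predictive"
    compare: bool = True
    n_starts: int = 10
    quad_n_grid: int = 128
    quad_trunc_sd: float = 8.0

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages, writing artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    for sub in ("inputs", "fits", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log = {"version": __version__, "python": platform.python_version(),
           "seed": config.seed, "stages": {}}
    quad = QuadratureSpec(config.quad_n_grid, config.quad_trunc_sd)
    trials = {}
    stage = "simulate"
    try:
        for i, exp in enumerate(config.experiments):
            t0 = time.perf_counter()
            if config.simulate:
                tr, truth = simulate_study(
                    design(exp), ObserverPopulation(), config.n_subjects,
                    config.seed + i,
                )
                tr.to_csv(out / "inputs" / f"trials_exp{exp}.csv", index=False)
                _write_json(out / "inputs" / f"truth_exp{exp}.json", truth)
            else:
                tr = pd.read_csv(config.trials_csv[exp])
            trials[exp] = tr
            log["stages"][f"simulate_exp{exp}"] = time.perf_counter() - t0

        results = {}
        stage = "fit_thresholds/stats"
        curves = []
        for exp in config.experiments:
            t0 = time.perf_counter()
            if exp in ("1", "2A", "2B") and design(exp).duration_task:
                continue
            if not (config.fit_thresholds or config.stats):
                continue
            if exp == "3":
                res = analyze_wide_range(
                    trials[exp], n_boot=config.n_boot, seed=config.seed
                )
                res["correction_rates"].to_csv(
                    out / "stats" / "correction_rates_exp3.csv", index=False
                )
                res["group_thresholds"].to_csv(
                    out / "fits" / "group_thresholds_exp3.csv", index=False
                )
                _write_json(out / "stats" / "anova_exp3.json", res["anova"])
                thr = res["group_thresholds"]
                curves.append(
                    ThresholdCurve(
                        thr["interval_s"].to_numpy(),
                        thr["threshold"].to_numpy(),
                        design(exp).dist,
                        label=f"exp{exp}",
                    )
                )
            else:
                res = analyze_narrow_range(
                    trials[exp], n_perm=config.n_perm, seed=config.seed
                )
                pd.DataFrame(
                    {
                        "subject_id": [p.subject_id for p in res["profiles"]],
                        "slope": [res["slopes"][p.subject_id] for p in res["profiles"]],
                        "perm_p": [
                            res["permutation"][p.subject_id].p_one_sided
                            for p in res["profiles"]
                        ],
                    }
                ).to_csv(out / "stats" / f"per_subject_exp{exp}.csv", index=False)
                _write_json(out / "stats" / f"anova_exp{exp}.json", res["anova"])
                res["lsd"].to_csv(out / "stats" / f"lsd_exp{exp}.csv", index=False)
                mc = res["mean_curve"]
                pd.DataFrame(
                    {"interval_s": mc.intervals, "threshold": mc.thresholds}
                ).to_csv(out / "fits" / f"mean_curve_exp{exp}.csv", index=False)
                curves.append(
                    ThresholdCurve(
                        mc.intervals, mc.thresholds, design(exp).dist,
                        label=f"exp{exp}",
                    )
                )
            results[exp] = res
            log["stages"][f"analyze_exp{exp}"] = time.perf_counter() - t0

        for exp in config.experiments:
            if design(exp).duration_task:
                stage = "fit_duration"
                t0 = time.perf_counter()
                model = HierarchicalDurationModel(seed=config.seed).fit(trials[exp])
                _write_json(
                    out / "fits" / f"duration_exp{exp}.json",
                    {
                        "pse_mode": model.pse_mode_,
                        "pse_ci95": list(model.pse_ci95_),
                        "acceptance_rate": model.posterior_.acceptance_rate,
                    },
                )
                log["stages"][f"fit_duration_exp{exp}"] = time.perf_counter() - t0

        if config.fit_model and len(curves) == 2:
            stage = "fit_model"
            t0 = time.perf_counter()
            fits = {}
            for variant in ("classical", config.variant_full):
                fit = AttentionModelRegression(
                    variant=variant, quad=quad, n_starts=config.n_starts,
                    seed=config.seed,
                ).fit(curves)
                fits[variant] = fit
                _write_json(
                    out / "fits" / f"model_{variant}.json",
                    {
                        "w": fit.w_, "mu": fit.mu_, "rss": fit.rss_,
                        "df_resid": fit.df_resid_,
                        "beta": [vars(b) for b in fit.beta_],
                        "starts": fit.starts_,
                    },
                )
            log["stages"]["fit_model"] = time.perf_counter() - t0
            if config.compare:
                stage = "compare"
                cmp_ = compare_models(fits["classical"], fits[config.variant_full])
                _write_json(out / "fits" / "comparison.json", cmp_)
    except Exception as e:  # noqa: BLE001 - halt with stage name, keep artifacts
        _write_json(out / "log.json", log)
        raise StageError(stage, e) from e
    _write_json(out / "log.json", log)
    return out
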