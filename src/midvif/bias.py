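"""Omitted-regressor bias simulation for MID first-level models.

Synthetic voxel time series are generated from the Saturated model,
``Y = X beta + eps`` with iid Gaussian noise (Eq.-style mixed-effects
framework): per subject, the nonzero "true signal" parameters are drawn
from a Gaussian around the scenario means with between-subject SD sigma_b,
the within-subject noise has SD sigma_w, and each subject's design is two
concatenated synthetic MID runs at TR 0.8 s.  Each replicate dataset fits
every subject by OLS under one or both of the Saturated and CueFeedback
models, then runs a group one-sample two-sided t-test per contrast.

For contrasts that are null under a scenario the result is bias and type-I
error rate (with an exact-binomial inflation flag); for non-null contrasts
it is power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import task as mid_task
from .design import (
    Contrast,
    DesignMatrix,
    HRFSpec,
    build_cuefeedback_design,
    build_saturated_design,
    concatenate_runs,
    make_contrasts,
    DEFAULT_TR,
    TABLE_CONTRASTS,
)

__all__ = [
    "SimulationScenario",
    "ScenarioResult",
    "table1_scenarios",
    "SubjectDesign",
    "build_subject_designs",
    "draw_subject_truth",
    "simulate_timeseries",
    "fit_ols",
    "OLSFit",
    "mixed_variance",
    "run_scenario",
]

#: Simulation settings: scenario name -> nonzero Saturated-model means.
#: The two compound settings set every non-Cue (resp. non-Feedback)
#: parameter to its single-event value.
_SINGLE_EVENT_MEANS: dict[str, dict[str, float]] = {
    "null": {},
    "cue_win": {"cue_LargeWin": 0.22, "cue_SmallWin": 0.22},
    "fixation_win": {"fixation_LargeWin": 0.22, "fixation_SmallWin": 0.22},
    "probe_win": {"probe_win": 0.85},
    "response_time": {"rt": 0.35},
    "feedback": {"feedback_LargeWin_Hit": 0.25, "feedback_LargeWin_Miss": 0.25},
}

DEFAULT_SIGMA_WITHIN = 1.0
DEFAULT_SIGMA_BETWEEN = 1.5


@dataclass(frozen=True)
class SimulationScenario:
    """True parameter means plus variance components and simulation sizes."""

    name: str
    true_means: dict[str, float] = field(default_factory=dict)
    sigma_within: float = DEFAULT_SIGMA_WITHIN
    sigma_between: float = DEFAULT_SIGMA_BETWEEN
    n_subjects: int = 100
    n_reps: int = 200
    alpha: float = 0.05
    seed: int = 0
    #: if True, zero-mean parameters also receive between-subject variability
    vary_zero_means: bool = False

    def __post_init__(self) -> None:
        if self.sigma_within <= 0:
            raise ValueError("sigma_within must be positive")
        if self.sigma_between < 0:
            raise ValueError("sigma_between must be nonnegative")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")


def table1_scenarios(**overrides) -> dict[str, SimulationScenario]:
    """The standard simulation settings (single-event rows plus the two
    compound rows), as SimulationScenario objects."""
    means = dict(_SINGLE_EVENT_MEANS)
    all_but_cue: dict[str, float] = {}
    for name in ("fixation_win", "probe_win", "response_time", "feedback"):
        all_but_cue.update(means[name])
    all_but_feedback: dict[str, float] = {}
    for name in ("cue_win", "fixation_win", "probe_win", "response_time"):
        all_but_feedback.update(means[name])
    means["all_but_cue"] = all_but_cue
    means["all_but_feedback"] = all_but_feedback
    return {
        name: SimulationScenario(name=name, true_means=m, **overrides)
        for name, m in means.items()
    }


@dataclass
class SubjectDesign:
    """Concatenated two-run designs for one synthetic subject."""

    subject_id: int
    saturated: DesignMatrix
    cuefeedback: DesignMatrix | None = None

    def design_for(self, model: str) -> DesignMatrix:
        if model == "saturated":
            return self.saturated
        if model == "cuefeedback":
            if self.cuefeedback is None:
                raise ValueError("CueFeedback design was not built for this subject")
            return self.cuefeedback
        raise ValueError(f"unknown model {model!r}")


def _complete(design: DesignMatrix, expected_task: int) -> bool:
    return len(design.task_columns) == expected_task and not design.dropped


def build_subject_designs(
    n_subjects: int,
    seed: int = 0,
    tr: float = DEFAULT_TR,
    hrf: HRFSpec = HRFSpec(),
    params: mid_task.BehaviorModelParams = mid_task.BehaviorModelParams(),
    n_runs: int = 2,
    models: tuple[str, ...] = ("saturated", "cuefeedback"),
) -> list[SubjectDesign]:
    """Simulate per-subject MID sessions and build concatenated designs.

    Subjects whose session leaves any design cell empty (e.g. a condition
    with no Miss trials across both runs, or no recorded RTs) are redrawn so
    every subject has the full 24-column Saturated (and 30-task-column
    CueFeedback) design; this mirrors analyses restricted to subjects with
    complete designs and keeps contrasts aligned across subjects.
    """
    out: list[SubjectDesign] = []
    ss = np.random.SeedSequence(seed)
    attempt = 0
    while len(out) < n_subjects:
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(attempt,))
        attempt += 1
        runs = mid_task.simulate_runs(params, n_runs, seed=child)  # type: ignore[arg-type]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sat = concatenate_runs(
                [build_saturated_design(r, tr=tr, hrf=hrf) for r in runs]
            )
            if not _complete(sat, expected_task=24):
                continue
            cf = None
            if "cuefeedback" in models:
                cf = concatenate_runs(
                    [build_cuefeedback_design(r, tr=tr, hrf=hrf) for r in runs]
                )
                if not _complete(cf, expected_task=30):
                    continue
        out.append(SubjectDesign(subject_id=len(out), saturated=sat, cuefeedback=cf))
    return out


def _truth_mean_vector(scenario: SimulationScenario, design_sat: DesignMatrix) -> np.ndarray:
    names = design_sat.task_columns
    unknown = set(scenario.true_means) - set(names)
    if unknown:
        raise ValueError(f"scenario means refer to unknown columns: {sorted(unknown)}")
    return np.array([scenario.true_means.get(n, 0.0) for n in names])


def draw_subject_truth(
    scenario: SimulationScenario,
    design_sat: DesignMatrix,
    rng: np.random.Generator,
) -> np.ndarray:
    """One subject's true Saturated-model betas.

    Parameters with nonzero scenario mean are drawn N(mean, sigma_between^2);
    zero-mean parameters stay exactly zero unless ``vary_zero_means``.
    """
    mean = _truth_mean_vector(scenario, design_sat)
    noise = rng.normal(0.0, scenario.sigma_between, size=mean.shape)
    if scenario.vary_zero_means:
        return mean + noise
    return np.where(mean != 0.0, mean + noise, 0.0)


def simulate_timeseries(
    design_sat: DesignMatrix,
    true_beta: np.ndarray,
    sigma_within: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Y = X_task beta + iid Gaussian noise at the design's frame times."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = design_sat.task_values()
    true_beta = np.asarray(true_beta, dtype=float)
    if true_beta.shape != (x.shape[1],):
        raise ValueError(
            f"true_beta has length {true_beta.shape}, expected {x.shape[1]} task columns"
        )
    return x @ true_beta + rng.normal(0.0, sigma_within, size=x.shape[0])


@dataclass
class OLSFit:
    """Ordinary least squares fit of a design to one time series."""

    design: DesignMatrix
    beta: np.ndarray
    sigma2: float
    df_resid: int
    _gram_inv: np.ndarray

    def contrast_estimate(self, contrast: Contrast) -> tuple[float, float]:
        """(estimate, variance) for c beta-hat; variance = c (X'X)^-1 c' s2."""
        c = np.asarray(contrast.weights, dtype=float)
        est = float(c @ self.beta)
        var = float(c @ self._gram_inv @ c * self.sigma2)
        return est, var

    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.design.column_names)


def fit_ols(design: DesignMatrix, y: np.ndarray) -> OLSFit:
    """OLS fit; errors on rank-deficient designs."""
    from .collinearity import _check_rank

    y = np.asarray(y, dtype=float)
    x = design.values
    if y.shape != (x.shape[0],):
        raise ValueError("data length does not match design frames")
    _check_rank(x, design.column_names)
    gram_inv = np.linalg.inv(x.T @ x)
    beta = gram_inv @ (x.T @ y)
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    sigma2 = float(resid @ resid / df)
    return OLSFit(design=design, beta=beta, sigma2=sigma2, df_resid=df,
                  _gram_inv=gram_inv)


def mixed_variance(
    design: DesignMatrix,
    contrast: Contrast,
    sigma_within: float = DEFAULT_SIGMA_WITHIN,
    sigma_between: float = DEFAULT_SIGMA_BETWEEN,
) -> tuple[float, float]:
    """Total mixed-effects contrast variance and the total/within SD ratio.

    sigma_mfx^2 = c (X'X)^-1 c' sigma_w^2 + c c' sigma_b^2;
    the ratio is sqrt(sigma_mfx^2 / within part).
    """
    from .collinearity import _gram_inverse

    c = np.asarray(contrast.weights, dtype=float)
    within = float(c @ _gram_inverse(design) @ c) * sigma_within ** 2
    total = within + float(c @ c) * sigma_between ** 2
    return total, float(np.sqrt(total / within))


@dataclass
class ScenarioResult:
    """Per model x contrast bias / error-rate / power table for one scenario."""

    scenario: SimulationScenario
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def row(self, model: str, contrast: str) -> pd.Series:
        sel = (self.table["model"] == model) & (self.table["contrast"] == contrast)
        if not sel.any():
            raise KeyError(f"no result row for ({model}, {contrast})")
        return self.table[sel].iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _contrast_is_null(weights: dict[str, float], means: dict[str, float]) -> bool:
    truth = sum(w * means.get(col, 0.0) for col, w in weights.items())
    return truth == 0.0 and all(means.get(col, 0.0) == 0.0 for col in weights)


def run_scenario(
    scenario: SimulationScenario,
    fit_models: tuple[str, ...] = ("saturated", "cuefeedback"),
    design_pool: list[SubjectDesign] | None = None,
    tr: float = DEFAULT_TR,
    hrf: HRFSpec = HRFSpec(),
    extra_contrasts: dict[str, dict[str, float]] | None = None,
) -> ScenarioResult:
    """Run one simulation scenario.

    For each replicate: draw per-subject truths, simulate each subject's
    voxel time series from the Saturated design, fit each requested model by
    OLS, form the standard contrasts, and run a group one-sample two-sided
    t-test at ``scenario.alpha``.  Reports per contrast the mean group
    estimate, bias (null contrasts), rejection rate (type-I error or power),
    its Monte-Carlo SE, and an exact-binomial inflation flag for null
    contrasts.

    ``design_pool`` allows reusing subject designs across scenarios; each
    subject's design is fixed across replicates (as when real per-subject
    timings are reused).
    """
    if scenario.n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if design_pool is None:
        design_pool = build_subject_designs(
            scenario.n_subjects, seed=scenario.seed, tr=tr, hrf=hrf, models=fit_models
        )
    if len(design_pool) < scenario.n_subjects:
        raise ValueError("design pool smaller than n_subjects")
    pool = design_pool[: scenario.n_subjects]

    contrast_defs = dict(TABLE_CONTRASTS)
    if extra_contrasts:
        contrast_defs.update(extra_contrasts)
    contrast_names = list(contrast_defs)

    # per subject and model, precompute the map from a data vector to the
    # vector of OLS contrast estimates: A = C (X'X)^-1 X'
    proj: dict[str, list[np.ndarray]] = {m: [] for m in fit_models}
    x_task: list[np.ndarray] = []
    truth_mean = _truth_mean_vector(scenario, pool[0].saturated)
    for subj in pool:
        if pool[0].saturated.task_columns != subj.saturated.task_columns:
            raise ValueError("subject designs have inconsistent task columns")
        x_task.append(subj.saturated.task_values())
        for model in fit_models:
            dm = subj.design_for(model)
            cmat = np.vstack(
                [Contrast.from_dict(n, contrast_defs[n], dm).weights for n in contrast_names]
            )
            a = cmat @ np.linalg.solve(dm.values.T @ dm.values, dm.values.T)
            proj[model].append(a)

    rng = np.random.default_rng(scenario.seed)
    n_c = len(contrast_names)
    tcrit = stats.t.ppf(1 - scenario.alpha / 2, df=scenario.n_subjects - 1)
    group_means = {m: np.empty((scenario.n_reps, n_c)) for m in fit_models}
    rejections = {m: np.zeros((scenario.n_reps, n_c), dtype=bool) for m in fit_models}

    ests = {m: np.empty((scenario.n_subjects, n_c)) for m in fit_models}
    for rep in range(scenario.n_reps):
        for s, subj in enumerate(pool):
            beta = draw_subject_truth(scenario, subj.saturated, rng)
            y = x_task[s] @ beta + rng.normal(
                0.0, scenario.sigma_within, size=x_task[s].shape[0]
            )
            for model in fit_models:
                ests[model][s] = proj[model][s] @ y
        for model in fit_models:
            e = ests[model]
            m = e.mean(axis=0)
            sd = e.std(axis=0, ddof=1)
            tstat = m / (sd / np.sqrt(scenario.n_subjects))
            group_means[model][rep] = m
            rejections[model][rep] = np.abs(tstat) > tcrit

    rows = []
    for model in fit_models:
        for j, cname in enumerate(contrast_names):
            is_null = _contrast_is_null(contrast_defs[cname], scenario.true_means)
            gm = group_means[model][:, j]
            mean_est = float(gm.mean())
            mc_se = float(gm.std(ddof=1) / np.sqrt(scenario.n_reps))
            rate = float(rejections[model][:, j].mean())
            k = int(rejections[model][:, j].sum())
            inflated = False
            if is_null:
                p = stats.binomtest(
                    k, scenario.n_reps, scenario.alpha, alternative="greater"
                ).pvalue
                inflated = bool(p < 0.05)
            rows.append(
                {
                    "model": model,
                    "contrast": cname,
                    "is_null": is_null,
                    "mean_estimate": mean_est,
                    "bias": mean_est if is_null else np.nan,
                    "rejection_rate": rate,
                    "mc_se": mc_se,
                    "inflated": inflated,
                }
            )
    table = pd.DataFrame(rows)
    meta = {
        "inflation_rule": "one-sided exact binomial test of rejection_rate > alpha at 0.05",
        "alpha": scenario.alpha,
        "n_subjects": scenario.n_subjects,
        "n_reps": scenario.n_reps,
        "truth_mean_columns": dict(zip(pool[0].saturated.task_columns, truth_mean)),
    }
    return ScenarioResult(scenario=scenario, table=table, metadata=meta)
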