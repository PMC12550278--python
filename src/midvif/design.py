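"""HRF-convolved design matrices for MID first-level GLMs.

Two standard models are built from a run's event table:

* **CueFeedback** — impulse regressors at Cue onsets (5 conditions) and
  Feedback onsets (5 conditions x Hit/Miss), each paired with its temporal
  derivative: 30 task columns.
* **Saturated** — boxcar regressors for every trial component: 5 Cue,
  5 Fixation, 3 Probe (win/loss/neutral), 1 RT (probe onset, RT as
  duration), 10 Feedback: 24 task columns, no derivatives.

Conventions: the double-gamma kernel is normalized to unit discrete sum on
the microtime grid (oversampling tr/50); an impulse occupies a single
microtime sample of height equal to its amplitude; regressors are sampled
at frame onsets (offset 0).  Column names are snake_case
``component_condition[_outcome][_derivative]``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .task import CONDITIONS, RunEvents

__all__ = [
    "HRFSpec",
    "RegressorSpec",
    "DesignMatrix",
    "Contrast",
    "hrf_kernel",
    "convolve_regressor",
    "build_cuefeedback_design",
    "build_saturated_design",
    "cosine_drift",
    "concatenate_runs",
    "make_contrasts",
    "TABLE_CONTRASTS",
    "STARRED_CONTRASTS",
]

DEFAULT_TR = 0.8

#: Feedback cells: condition x outcome group (Miss pools TooSoon and TooSlow).
FEEDBACK_OUTCOMES = ("Hit", "Miss")
PROBE_GROUPS = {"LargeWin": "win", "SmallWin": "win",
                "LargeLoss": "loss", "SmallLoss": "loss",
                "Neutral": "neutral"}


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF parameters (SPM parameterization)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0
    microtime_dt: float = DEFAULT_TR / 50.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "undershoot_ratio",
                     "kernel_length", "microtime_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def hrf_kernel(spec: HRFSpec = HRFSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Double-gamma kernel and its analytic time derivative.

    Both are sampled at ``microtime_dt`` over ``kernel_length`` seconds.  The
    main kernel is normalized to unit discrete sum; the derivative kernel is
    scaled by the same constant so the pair stays mutually consistent.
    """
    dt = spec.microtime_dt
    t = np.arange(0.0, spec.kernel_length, dt)
    a1 = spec.peak_delay / spec.peak_dispersion
    a2 = spec.undershoot_delay / spec.undershoot_dispersion
    g1 = stats.gamma.pdf(t, a1, scale=spec.peak_dispersion)
    g2 = stats.gamma.pdf(t, a2, scale=spec.undershoot_dispersion)
    kernel = g1 - spec.undershoot_ratio * g2
    norm = kernel.sum()
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError("HRF kernel does not integrate to a positive value")

    # d/dt gamma.pdf(t; a, s) = pdf * ((a-1)/t - 1/s); 0 at t=0 for a > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = np.where(t > 0, g1 * ((a1 - 1) / t - 1 / spec.peak_dispersion), 0.0)
        d2 = np.where(t > 0, g2 * ((a2 - 1) / t - 1 / spec.undershoot_dispersion), 0.0)
    derivative = d1 - spec.undershoot_ratio * d2
    return kernel / norm, derivative / norm


@dataclass(frozen=True)
class RegressorSpec:
    """Events of one regressor: onsets, durations (0 = impulse), amplitudes."""

    name: str
    onsets: tuple[float, ...]
    durations: tuple[float, ...]
    amplitudes: tuple[float, ...] | None = None
    add_derivative: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "onsets", tuple(float(o) for o in self.onsets))
        object.__setattr__(self, "durations", tuple(float(d) for d in self.durations))
        amps = self.amplitudes
        if amps is None:
            amps = (1.0,) * len(self.onsets)
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in amps))
        if not (len(self.onsets) == len(self.durations) == len(self.amplitudes)):
            raise ValueError("onsets, durations, amplitudes must have equal length")
        if any(o < 0 for o in self.onsets):
            raise ValueError("onsets must be nonnegative")


class EmptyRegressorError(ValueError):
    """A regressor with no events or an all-zero convolved column."""


def convolve_regressor(
    spec: RegressorSpec,
    frame_times: np.ndarray,
    hrf: HRFSpec = HRFSpec(),
) -> np.ndarray:
    """Convolve one regressor's neural indicator with the HRF.

    Returns an array of shape (n_frames, 1) or (n_frames, 2) when a
    derivative column is requested.  The neural indicator lives on the
    microtime grid: boxcars cover [onset, onset + duration) with the given
    amplitude; zero-duration events occupy a single microtime sample.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if len(spec.onsets) == 0:
        raise EmptyRegressorError(f"regressor {spec.name!r} has no events")
    t_max = frame_times[-1]
    if any(o > t_max for o in spec.onsets):
        raise ValueError(f"regressor {spec.name!r} has onsets beyond the run end")
    dt = hrf.microtime_dt
    n_hi = int(np.round(t_max / dt)) + 1
    neural = np.zeros(n_hi)
    for onset, dur, amp in zip(spec.onsets, spec.durations, spec.amplitudes):
        start = int(np.round(onset / dt))
        stop = max(start + 1, int(np.round((onset + dur) / dt)))
        neural[start:min(stop, n_hi)] += amp
    kernel, dkernel = hrf_kernel(hrf)
    idx = np.round(frame_times / dt).astype(int)
    cols = [signal.fftconvolve(neural, kernel)[:n_hi][idx]]
    if spec.add_derivative:
        cols.append(signal.fftconvolve(neural, dkernel)[:n_hi][idx])
    out = np.column_stack(cols)
    if np.allclose(out[:, 0], 0.0):
        raise EmptyRegressorError(f"regressor {spec.name!r} convolves to an all-zero column")
    return out


@dataclass
class DesignMatrix:
    """Frame-times x named-regressor matrix with per-column role tags.

    Roles are ``task``, ``derivative``, ``nuisance``, or ``intercept``.
    ``dropped`` records task cells that had no events and were omitted.
    """

    values: np.ndarray
    frame_times: np.ndarray
    column_names: list[str]
    column_roles: list[str]
    tr: float
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != (len(self.frame_times), len(self.column_names)):
            raise ValueError("design shape does not match frame_times/column_names")
        if len(self.column_roles) != len(self.column_names):
            raise ValueError("column_roles must align with column_names")
        diffs = np.diff(self.frame_times)
        if len(diffs) and not np.allclose(diffs, self.tr):
            raise ValueError("frame_times must be evenly spaced at tr")
        for j, role in enumerate(self.column_roles):
            if role in ("task", "derivative") and np.allclose(self.values[:, j], 0):
                raise ValueError(f"all-zero task column {self.column_names[j]!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def task_columns(self) -> list[str]:
        return [n for n, r in zip(self.column_names, self.column_roles)
                if r in ("task", "derivative")]

    @property
    def nuisance_columns(self) -> list[str]:
        return [n for n, r in zip(self.column_names, self.column_roles)
                if r in ("nuisance", "intercept")]

    def index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index(name)]

    def role(self, name: str) -> str:
        return self.column_roles[self.index(name)]

    def task_values(self) -> np.ndarray:
        sel = [i for i, r in enumerate(self.column_roles) if r in ("task", "derivative")]
        return self.values[:, sel]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.frame_times, name="frame_time"),
                            columns=self.column_names)

    def to_csv(self, path, sidecar_path=None) -> None:
        """CSV of frame_times + columns, with a JSON sidecar of roles/drops."""
        self.to_dataframe().to_csv(path)
        if sidecar_path is not None:
            meta = {"tr": self.tr,
                    "column_roles": dict(zip(self.column_names, self.column_roles)),
                    "dropped": self.dropped}
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "DesignMatrix":
        frame = pd.read_csv(path, index_col=0)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        names = list(frame.columns)
        return cls(
            values=frame.to_numpy(),
            frame_times=frame.index.to_numpy(dtype=float),
            column_names=names,
            column_roles=[meta["column_roles"][n] for n in names],
            tr=float(meta["tr"]),
            dropped=list(meta.get("dropped", [])),
        )


@dataclass(frozen=True)
class Contrast:
    """Named weight vector over design columns (zeros on nuisance)."""

    name: str
    weights: np.ndarray
    starred: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if not np.any(w != 0):
            raise ValueError("contrast must have at least one nonzero weight")

    @classmethod
    def from_dict(cls, name: str, weights: Mapping[str, float],
                  design: DesignMatrix, starred: bool = False) -> "Contrast":
        w = np.zeros(len(design.column_names))
        for col, val in weights.items():
            w[design.index(col)] = val
        return cls(name=name, weights=w, starred=starred)

    def as_dict(self, design: DesignMatrix) -> dict[str, float]:
        return {n: float(w) for n, w in zip(design.column_names, self.weights) if w != 0}


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def _frame_times(run: RunEvents, tr: float) -> np.ndarray:
    # acquisition covers the full run: every event onset falls on or before
    # the final frame
    n = int(np.ceil(run.total_duration / tr))
    return np.arange(n) * tr


def _assemble(
    specs: list[RegressorSpec],
    frame_times: np.ndarray,
    tr: float,
    hrf: HRFSpec,
    dropped: list[str],
    drift_cutoff: float | None,
) -> DesignMatrix:
    cols, names, roles = [], [], []
    for spec in specs:
        conv = convolve_regressor(spec, frame_times, hrf)
        cols.append(conv[:, 0])
        names.append(spec.name)
        roles.append("task")
        if spec.add_derivative:
            cols.append(conv[:, 1])
            names.append(spec.name + "_derivative")
            roles.append("derivative")
    if drift_cutoff is not None:
        drift = cosine_drift(frame_times, cutoff=drift_cutoff)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            names.append(f"drift_{k + 1}")
            roles.append("nuisance")
    cols.append(np.ones(len(frame_times)))
    names.append("intercept")
    roles.append("intercept")
    return DesignMatrix(
        values=np.column_stack(cols),
        frame_times=frame_times,
        column_names=names,
        column_roles=roles,
        tr=tr,
        dropped=dropped,
    )


def _feedback_cells(run: RunEvents):
    cells: dict[tuple[str, str], list] = {}
    for t in run.trials:
        group = "Hit" if t.is_hit else "Miss"
        cells.setdefault((t.condition, group), []).append(t)
    return cells


def build_cuefeedback_design(
    run: RunEvents,
    tr: float = DEFAULT_TR,
    hrf: HRFSpec = HRFSpec(),
    drift_cutoff: float | None = 128.0,
) -> DesignMatrix:
    """Impulse model: 5 Cue + 10 Feedback (condition x Hit/Miss) regressors,
    each paired with its temporal derivative (30 task columns)."""
    run.validate()
    frame_times = _frame_times(run, tr)
    specs: list[RegressorSpec] = []
    dropped: list[str] = []
    for cond in CONDITIONS:
        onsets = tuple(t.cue_onset for t in run.trials if t.condition == cond)
        specs.append(RegressorSpec(f"cue_{cond}", onsets, (0.0,) * len(onsets),
                                   add_derivative=True))
    cells = _feedback_cells(run)
    for cond in CONDITIONS:
        for group in FEEDBACK_OUTCOMES:
            name = f"feedback_{cond}_{group}"
            trials = cells.get((cond, group), [])
            if not trials:
                dropped.append(name)
                warnings.warn(f"feedback cell {name!r} has no trials; column dropped")
                continue
            onsets = tuple(t.feedback_onset for t in trials)
            specs.append(RegressorSpec(name, onsets, (0.0,) * len(onsets),
                                       add_derivative=True))
    return _assemble(specs, frame_times, tr, hrf, dropped, drift_cutoff)


def build_saturated_design(
    run: RunEvents,
    tr: float = DEFAULT_TR,
    hrf: HRFSpec = HRFSpec(),
    drift_cutoff: float | None = 128.0,
    add_derivatives: bool = False,
) -> DesignMatrix:
    """Boxcar model of every trial component: 5 Cue + 5 Fixation + 3 Probe
    (win/loss/neutral) + 1 RT + 10 Feedback regressors (24 task columns).

    The RT regressor uses the probe onset with the recorded RT as duration;
    trials without a recorded RT contribute nothing to it.  The default
    model carries no derivative columns; ``add_derivatives`` pairs every
    regressor with its temporal derivative (useful for quantifying how much
    derivatives inflate contrast variance in this paradigm)."""
    run.validate()
    frame_times = _frame_times(run, tr)
    specs: list[RegressorSpec] = []
    dropped: list[str] = []
    for cond in CONDITIONS:
        trials = [t for t in run.trials if t.condition == cond]
        specs.append(RegressorSpec(
            f"cue_{cond}",
            tuple(t.cue_onset for t in trials),
            tuple(t.cue_duration for t in trials),
            add_derivative=add_derivatives,
        ))
        specs.append(RegressorSpec(
            f"fixation_{cond}",
            tuple(t.fixation_onset for t in trials),
            tuple(t.fixation_duration for t in trials),
            add_derivative=add_derivatives,
        ))
    for group in ("win", "loss", "neutral"):
        trials = [t for t in run.trials if PROBE_GROUPS[t.condition] == group]
        specs.append(RegressorSpec(
            f"probe_{group}",
            tuple(t.probe_onset for t in trials),
            tuple(t.probe_duration for t in trials),
            add_derivative=add_derivatives,
        ))
    rt_trials = [t for t in run.trials if t.rt is not None]
    if rt_trials:
        specs.append(RegressorSpec(
            "rt",
            tuple(t.probe_onset for t in rt_trials),
            tuple(t.rt for t in rt_trials),
            add_derivative=add_derivatives,
        ))
    else:
        dropped.append("rt")
        warnings.warn("no trials with a recorded RT; rt column dropped")
    cells = _feedback_cells(run)
    for cond in CONDITIONS:
        for group in FEEDBACK_OUTCOMES:
            name = f"feedback_{cond}_{group}"
            trials = cells.get((cond, group), [])
            if not trials:
                dropped.append(name)
                warnings.warn(f"feedback cell {name!r} has no trials; column dropped")
                continue
            specs.append(RegressorSpec(
                name,
                tuple(t.feedback_onset for t in trials),
                tuple(t.feedback_duration for t in trials),
                add_derivative=add_derivatives,
            ))
    return _assemble(specs, frame_times, tr, hrf, dropped, drift_cutoff)


def cosine_drift(frame_times: np.ndarray, cutoff: float = 128.0) -> np.ndarray:
    """Discrete cosine high-pass basis (periods >= ``cutoff`` seconds).

    Returns ``floor(2 * T / cutoff)`` DCT-II columns (at least one), mutually
    orthogonal on the frame grid, T being the run length n_frames * tr.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n = len(frame_times)
    if n < 2:
        raise ValueError("cosine_drift needs at least 2 frames")
    tr = frame_times[1] - frame_times[0]
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed twice the frame spacing")
    total = n * tr
    order = max(1, int(np.floor(2.0 * total / cutoff)))
    i = np.arange(n)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n)) for k in range(1, order + 1)]
    )
    return basis


def concatenate_runs(designs: Sequence[DesignMatrix]) -> DesignMatrix:
    """Stack runs in time: task columns are unioned (zero-filled where a run
    lacks a column); intercept and nuisance columns become per-run blocks."""
    designs = list(designs)
    if not designs:
        raise ValueError("no designs to concatenate")
    tr = designs[0].tr
    if any(d.tr != tr for d in designs):
        raise ValueError("all runs must share the same tr")

    task_names: list[str] = []
    task_roles: dict[str, str] = {}
    for d in designs:
        for n, r in zip(d.column_names, d.column_roles):
            if r in ("task", "derivative") and n not in task_roles:
                task_names.append(n)
                task_roles[n] = r
    n_total = sum(d.n_frames for d in designs)
    values = []
    names: list[str] = list(task_names)
    roles: list[str] = [task_roles[n] for n in task_names]

    task_block = np.zeros((n_total, len(task_names)))
    offset = 0
    for d in designs:
        for j, name in enumerate(task_names):
            if name in d.column_names and d.role(name) in ("task", "derivative"):
                task_block[offset:offset + d.n_frames, j] = d.column(name)
        offset += d.n_frames
    values.append(task_block)

    offset = 0
    for k, d in enumerate(designs, start=1):
        nuis = [n for n in d.column_names if d.role(n) in ("nuisance", "intercept")]
        block = np.zeros((n_total, len(nuis)))
        block[offset:offset + d.n_frames, :] = np.column_stack(
            [d.column(n) for n in nuis]
        )
        values.append(block)
        names.extend(f"run{k}_{n}" for n in nuis)
        roles.extend(d.role(n) for n in nuis)
        offset += d.n_frames

    frame_times = np.arange(n_total) * tr
    dropped = sorted({name for d in designs for name in d.dropped})
    return DesignMatrix(
        values=np.column_stack(values),
        frame_times=frame_times,
        column_names=names,
        column_roles=roles,
        tr=tr,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# standard contrasts
# ---------------------------------------------------------------------------

#: The contrasts studied in the simulations; starred names are the ones the
#: ABCD consortium distributes.
TABLE_CONTRASTS: dict[str, dict[str, float]] = {
    "Cue:LW-Neut": {"cue_LargeWin": 1.0, "cue_Neutral": -1.0},
    "Cue:LL-Neut": {"cue_LargeLoss": 1.0, "cue_Neutral": -1.0},
    "Cue:LW-Base": {"cue_LargeWin": 1.0},
    "FB:WHit-WMiss": {
        "feedback_LargeWin_Hit": 0.5, "feedback_SmallWin_Hit": 0.5,
        "feedback_LargeWin_Miss": -0.5, "feedback_SmallWin_Miss": -0.5,
    },
    "FB:LHit-LMiss": {
        "feedback_LargeLoss_Hit": 0.5, "feedback_SmallLoss_Hit": 0.5,
        "feedback_LargeLoss_Miss": -0.5, "feedback_SmallLoss_Miss": -0.5,
    },
    "FB:LWHit-NeutHit": {"feedback_LargeWin_Hit": 1.0, "feedback_Neutral_Hit": -1.0},
    "FB:LWHit-Base": {"feedback_LargeWin_Hit": 1.0},
}

STARRED_CONTRASTS = ("Cue:LW-Neut", "Cue:LL-Neut", "FB:WHit-WMiss", "FB:LHit-LMiss")


def make_contrasts(design: DesignMatrix) -> list[Contrast]:
    """All standard contrasts whose columns exist in ``design``; contrasts
    referencing a dropped/absent column are skipped with a warning."""
    contrasts = []
    for name, weights in TABLE_CONTRASTS.items():
        missing = [c for c in weights if c not in design.column_names]
        if missing:
            warnings.warn(f"contrast {name!r} skipped: missing columns {missing}")
            continue
        contrasts.append(Contrast.from_dict(name, weights, design,
                                            starred=name in STARRED_CONTRASTS))
    return contrasts
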