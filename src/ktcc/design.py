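"""Task timelines and time-domain design matrices for ROI BOLD modeling.

Three regressor families are supported, all sampled onto a fixed-TR grid
(default TR = 0.8 s):

* **Boxcar** -- per condition level, the 22-s solving stage is partitioned
  into four equal 5.5-s boxcars (S1..S4) plus a 2-s response boxcar; a
  shared 3-s items boxcar and optional left/right button regressors
  complete the model.  Boxcars may be convolved with a canonical
  double-gamma hemodynamic response.
* **FIR** -- per condition (a full crossing of labeling factors), a set of
  piecewise-linear tent bases with knots every 2 s spanning trial onset to
  trial end plus a 5-s hemodynamic lag (27 + 5 = 32 s -> 17 tents).  Tents
  are left unconvolved: they model the hemodynamic response directly, and
  each tent's task time is its peak time minus the assumed 5-s lag.
* **PPI periods** -- the combined items + solving window (25 s) split into
  two equal 12.5-s boxcars for early/late psychophysiological-interaction
  analyses.

Event-to-grid sampling uses fractional-overlap weighting for boxcars (a
sample's value is the fraction of its TR covered by the event) and
pointwise evaluation at frame times for tents (which preserves the tents'
partition of unity exactly).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .stimuli import (
    ITEMS_DURATION_S,
    RESPONSE_DURATION_S,
    SOLVING_DURATION_S,
    TRIAL_DURATION_S,
    StimulusSet,
    TrialSchedule,
)

__all__ = [
    "TimelineTrial",
    "TaskTimeline",
    "DesignMatrix",
    "timeline_from_schedule",
    "build_boxcar_design",
    "build_fir_design",
    "build_ppi_periods",
    "canonical_hrf",
]

DEFAULT_TR_S = 0.8
FIR_RESOLUTION_S = 2.0
HEMODYNAMIC_LAG_S = 5.0
N_SOLVING_PERIODS = 4


@dataclass(frozen=True)
class TimelineTrial:
    """One trial on the run clock, with its condition labels.

    ``labels`` maps factor names to levels, e.g. ``{"tcc": "high",
    "sat": "unsat"}``; an optional ``"button"`` key ("left"/"right") feeds
    the button regressors.
    """

    labels: dict
    onset_s: float  # items-stage onset

    @property
    def items_onset_s(self) -> float:
        return self.onset_s

    @property
    def solving_onset_s(self) -> float:
        return self.onset_s + ITEMS_DURATION_S

    @property
    def response_onset_s(self) -> float:
        return self.onset_s + ITEMS_DURATION_S + SOLVING_DURATION_S

    @property
    def end_s(self) -> float:
        return self.onset_s + TRIAL_DURATION_S


@dataclass
class TaskTimeline:
    """A run's worth of labeled trials on a fixed-TR clock."""

    trials: list[TimelineTrial]
    run_length_s: float
    tr_s: float = DEFAULT_TR_S

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ConfigurationError("tr_s must be positive")
        for t in self.trials:
            if t.onset_s < 0 or t.end_s > self.run_length_s:
                raise ConfigurationError(
                    f"trial at {t.onset_s}s does not fit in run of "
                    f"{self.run_length_s}s"
                )

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.run_length_s / self.tr_s))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_s

    def levels(self, factor: str) -> list[str]:
        return sorted({str(t.labels[factor]) for t in self.trials})


def timeline_from_schedule(
    schedule: TrialSchedule,
    stimuli: StimulusSet | None = None,
    labels: dict | None = None,
    tr_s: float = DEFAULT_TR_S,
    tail_s: float = 20.0,
) -> TaskTimeline:
    """Turn a trial schedule into a labeled timeline.

    Condition labels come from *labels* (instance id -> label dict) or are
    derived from *stimuli* (tcc / sat labels of each instance's design
    cell).  *tail_s* seconds of rest are appended after the final trial so
    late FIR tents remain estimable.
    """
    if labels is None:
        if stimuli is None:
            raise ConfigurationError("provide either stimuli or labels")
        labels = stimuli.labels_by_instance()
    trials = []
    for t in schedule.trials:
        if t.instance_id not in labels:
            raise ConfigurationError(f"no labels for instance {t.instance_id}")
        trials.append(TimelineTrial(labels=dict(labels[t.instance_id]), onset_s=t.onset_s))
    run_length = max(t.end_s for t in trials) + max(tail_s, 0.0)
    return TaskTimeline(trials=trials, run_length_s=run_length, tr_s=tr_s)


@dataclass
class DesignMatrix:
    """A time-by-regressor matrix with per-column provenance.

    ``frame`` is indexed by frame time (s); ``column_info`` maps each
    column name to a metadata dict (``kind`` plus, depending on kind,
    ``factor``/``level``/``period`` for boxcars or ``condition``/``tent``/
    ``tent_time_s``/``task_time_s`` for FIR tents).
    """

    frame: pd.DataFrame
    tr_s: float
    column_info: dict
    meta: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def to_tsv(self, path, sidecar_path=None) -> None:
        """Write the matrix as TSV plus a JSON sidecar with metadata."""
        self.frame.to_csv(path, sep="\t", index_label="time")
        if sidecar_path is None:
            sidecar_path = str(path).rsplit(".", 1)[0] + ".json"
        with open(sidecar_path, "w") as fh:
            json.dump(
                {"tr_s": self.tr_s, "column_info": self.column_info, "meta": self.meta},
                fh,
                indent=1,
            )

    @classmethod
    def from_tsv(cls, path, sidecar_path=None) -> "DesignMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="time")
        if sidecar_path is None:
            sidecar_path = str(path).rsplit(".", 1)[0] + ".json"
        with open(sidecar_path) as fh:
            side = json.load(fh)
        return cls(
            frame=frame,
            tr_s=side["tr_s"],
            column_info=side["column_info"],
            meta=side.get("meta", {}),
        )


def _boxcar_column(
    onsets: np.ndarray, durations: np.ndarray, n_frames: int, tr: float
) -> np.ndarray:
    """Fractional-overlap sampling of a union of events onto the TR grid."""
    col = np.zeros(n_frames)
    for onset, dur in zip(onsets, durations):
        k0 = max(int(np.floor(onset / tr)), 0)
        k1 = min(int(np.ceil((onset + dur) / tr)), n_frames)
        for k in range(k0, k1):
            lo = max(onset, k * tr)
            hi = min(onset + dur, (k + 1) * tr)
            if hi > lo:
                col[k] += (hi - lo) / tr
    return col


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Gamma-density peak around 5-6 s with a late undershoot at 1:6
    amplitude ratio; normalized to unit peak.
    """
    t = np.arange(0, duration_s, tr_s)
    peak = stats.gamma.pdf(t, a=6, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def _convolve_tr(col: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(col, kernel)[: col.size]


def build_boxcar_design(
    timeline: TaskTimeline,
    factor: str,
    hrf_mode: str = "canonical",
    n_periods: int = N_SOLVING_PERIODS,
) -> DesignMatrix:
    """Boxcar design for one dichotomous labeling factor.

    Per factor level: *n_periods* equal-duration solving-stage boxcars
    (22 / 4 = 5.5 s each by default) and one 2-s response boxcar.  Shared
    across levels: a 3-s items boxcar and, when trials carry a ``button``
    label, left/right button regressors over the response stage.
    ``hrf_mode``: ``"none"`` (raw indicators) or ``"canonical"``
    (double-gamma convolution).
    """
    if hrf_mode not in ("none", "canonical"):
        raise ConfigurationError(f"unknown hrf_mode {hrf_mode!r}")
    for t in timeline.trials:
        if factor not in t.labels:
            raise ConfigurationError(
                f"trial at {t.onset_s}s lacks a level for factor {factor!r}"
            )
    n = timeline.n_frames
    tr = timeline.tr_s
    period_s = SOLVING_DURATION_S / n_periods
    cols: dict[str, np.ndarray] = {}
    info: dict[str, dict] = {}
    for level in timeline.levels(factor):
        trials = [t for t in timeline.trials if str(t.labels[factor]) == level]
        for i in range(n_periods):
            name = f"{factor}={level}:S{i + 1}"
            onsets = np.array([t.solving_onset_s + i * period_s for t in trials])
            cols[name] = _boxcar_column(onsets, np.full(len(trials), period_s), n, tr)
            info[name] = {
                "kind": "boxcar",
                "factor": factor,
                "level": level,
                "period": f"S{i + 1}",
                "duration_s": period_s,
            }
        name = f"{factor}={level}:resp"
        onsets = np.array([t.response_onset_s for t in trials])
        cols[name] = _boxcar_column(
            onsets, np.full(len(trials), RESPONSE_DURATION_S), n, tr
        )
        info[name] = {
            "kind": "boxcar",
            "factor": factor,
            "level": level,
            "period": "resp",
            "duration_s": RESPONSE_DURATION_S,
        }
    onsets = np.array([t.items_onset_s for t in timeline.trials])
    cols["items"] = _boxcar_column(
        onsets, np.full(len(timeline.trials), ITEMS_DURATION_S), n, tr
    )
    info["items"] = {"kind": "boxcar", "period": "items", "duration_s": ITEMS_DURATION_S}
    if any("button" in t.labels for t in timeline.trials):
        for side in ("left", "right"):
            trials = [t for t in timeline.trials if t.labels.get("button") == side]
            name = f"button_{side}"
            onsets = np.array([t.response_onset_s for t in trials])
            cols[name] = _boxcar_column(
                onsets, np.full(len(trials), RESPONSE_DURATION_S), n, tr
            )
            info[name] = {"kind": "button", "side": side}
    if hrf_mode == "canonical":
        kernel = canonical_hrf(tr)
        cols = {k: _convolve_tr(v, kernel) for k, v in cols.items()}
    frame = pd.DataFrame(cols, index=timeline.frame_times)
    return DesignMatrix(
        frame=frame,
        tr_s=tr,
        column_info=info,
        meta={
            "mode": "boxcar",
            "factor": factor,
            "hrf_mode": hrf_mode,
            "run_length_s": timeline.run_length_s,
        },
    )


def condition_name(labels: dict, factors) -> str:
    return "|".join(f"{f}={labels[f]}" for f in factors)


def build_fir_design(
    timeline: TaskTimeline,
    factors=("tcc", "sat"),
    resolution_s: float = FIR_RESOLUTION_S,
    lag_s: float = HEMODYNAMIC_LAG_S,
) -> DesignMatrix:
    """FIR tent design for the full crossing of *factors*.

    The tent span runs from trial onset to trial end plus *lag_s*
    (27 + 5 = 32 s by default), with knots every *resolution_s* -> 17
    tents per condition under the defaults.  Each tent has unit peak at
    its knot and linear decay to the neighboring knots; interior tents
    therefore sum to one (partition of unity).  If the span is not a
    multiple of the resolution the knot count is rounded down and a
    warning reports the adjusted count.  The metadata records, per tent,
    its peak time post-onset and the task time it estimates (peak time
    minus the hemodynamic lag).
    """
    factors = list(factors)
    for t in timeline.trials:
        for f in factors:
            if f not in t.labels:
                raise ConfigurationError(
                    f"trial at {t.onset_s}s lacks a level for factor {f!r}"
                )
    level_sets = [timeline.levels(f) for f in factors]
    observed = {condition_name(t.labels, factors) for t in timeline.trials}
    full_crossing = [
        "|".join(f"{f}={l}" for f, l in zip(factors, combo))
        for combo in itertools.product(*level_sets)
    ]
    missing = sorted(set(full_crossing) - observed)
    if missing:
        raise ConfigurationError(
            f"conditions do not form a full crossing; missing {missing}"
        )

    span = TRIAL_DURATION_S + lag_s
    n_tents = int(np.floor(span / resolution_s)) + 1
    span_used = (n_tents - 1) * resolution_s
    if abs(span_used - span) > 1e-9:
        warnings.warn(
            f"FIR span {span}s not commensurate with resolution "
            f"{resolution_s}s; using {n_tents} tents spanning {span_used}s",
            stacklevel=2,
        )
    times = timeline.frame_times
    cols: dict[str, np.ndarray] = {}
    info: dict[str, dict] = {}
    for cond in full_crossing:
        trials = [t for t in timeline.trials if condition_name(t.labels, factors) == cond]
        onsets = np.array([t.onset_s for t in trials])
        cond_levels = {
            f: lv.split("=", 1)[1] for f, lv in zip(factors, cond.split("|"))
        }
        for j in range(n_tents):
            knot = j * resolution_s
            # tent_j(u) = max(0, 1 - |u - knot| / resolution), clipped to [0, span]
            u = times[:, None] - onsets[None, :]
            tent = np.clip(1.0 - np.abs(u - knot) / resolution_s, 0.0, None)
            tent[(u < -1e-12) | (u > span_used + 1e-12)] = 0.0
            name = f"{cond}:t{j:02d}"
            cols[name] = tent.sum(axis=1)
            info[name] = {
                "kind": "fir",
                "condition": cond_levels,
                "tent": j,
                "tent_time_s": knot,
                "task_time_s": knot - lag_s,
            }
    frame = pd.DataFrame(cols, index=times)
    return DesignMatrix(
        frame=frame,
        tr_s=timeline.tr_s,
        column_info=info,
        meta={
            "mode": "fir",
            "factors": factors,
            "resolution_s": resolution_s,
            "lag_s": lag_s,
            "n_tents": n_tents,
            "run_length_s": timeline.run_length_s,
            "tent_task_times_s": [j * resolution_s - lag_s for j in range(n_tents)],
        },
    )


def build_ppi_periods(timeline: TaskTimeline) -> DesignMatrix:
    """Split the combined items + solving window into two equal boxcars.

    The 3 + 22 = 25-s task window yields PPI-1 (first 12.5 s) and PPI-2
    (last 12.5 s); the two periods are disjoint and tile the window.
    """
    task_s = ITEMS_DURATION_S + SOLVING_DURATION_S
    half = task_s / 2.0
    n = timeline.n_frames
    tr = timeline.tr_s
    cols = {}
    info = {}
    for i, name in enumerate(("ppi_1", "ppi_2")):
        onsets = np.array([t.items_onset_s + i * half for t in timeline.trials])
        cols[name] = _boxcar_column(onsets, np.full(len(timeline.trials), half), n, tr)
        info[name] = {"kind": "ppi", "period": i + 1, "duration_s": half}
    frame = pd.DataFrame(cols, index=timeline.frame_times)
    return DesignMatrix(
        frame=frame,
        tr_s=tr,
        column_info=info,
        meta={"mode": "ppi", "run_length_s": timeline.run_length_s},
    )
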