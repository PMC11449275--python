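"""Trial-level behavioral simulation and logistic recovery.

The generative model mirrors a binary-accuracy mixed logistic regression:
for participant ``i`` on trial ``t``,

    P(correct) = logistic(b0 + u_i + b_tcc * 1[high TCC]
                          + b_sat * 1[satisfiable] + b_trial * t),
    u_i ~ Normal(0, sd_participant),

and the yes/no choice is derived from correctness and the instance's
ground-truth satisfiability.  Defaults place overall accuracy near 0.78
with a strong negative high-TCC effect (-1.1 log-odds), a negligible
satisfiability effect, and a small positive per-trial drift.

Recovery is by plain maximum likelihood (Newton-Raphson via statsmodels)
with optional per-participant indicator variables standing in for the
random intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import ConfigurationError, FitConvergenceError, SeparationError
from .stimuli import StimulusSet

__all__ = [
    "BehaviorParams",
    "TrialRecord",
    "LogisticFit",
    "simulate_behavior",
    "records_to_frame",
    "frame_to_records",
    "fit_logistic",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters (log-odds scale)."""

    n_participants: int = 20
    intercept: float = 1.8
    sd_participant: float = 0.8
    beta_tcc: float = -1.1  # effect of high TCC
    beta_sat: float = 0.02  # effect of satisfiable
    beta_trial: float = 0.009  # per-trial drift
    seed: int | None = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.sd_participant < 0:
            raise ConfigurationError("sd_participant must be >= 0")
        for name in ("intercept", "sd_participant", "beta_tcc", "beta_sat", "beta_trial"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    instance_id: str
    tcc: str  # "low" | "high"
    satisfiable: bool
    trial_number: int
    correct: bool
    choice: str  # "yes" | "no"

    def __post_init__(self):
        # correctness and choice must cohere with the ground-truth label
        if self.correct != ((self.choice == "yes") == self.satisfiable):
            raise ConfigurationError("correct is inconsistent with choice/satisfiable")


def simulate_behavior(
    stimuli: StimulusSet, params: BehaviorParams
) -> list[TrialRecord]:
    """Simulate every participant answering every stimulus once.

    Each participant sees the stimuli in an independent random order;
    trial numbers are 1-based within participant.  The yes/no choice is
    derived from the drawn correctness and the instance's satisfiability.
    Fully determined by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    records: list[TrialRecord] = []
    for i in range(params.n_participants):
        u = rng.normal(0.0, params.sd_participant)
        order = rng.permutation(len(stimuli))
        for t, idx in enumerate(order, start=1):
            e = stimuli.entries[idx]
            high = e.cell.tcc.value == "high"
            eta = (
                params.intercept
                + u
                + params.beta_tcc * high
                + params.beta_sat * e.cell.satisfiable
                + params.beta_trial * t
            )
            correct = bool(rng.random() < expit(eta))
            yes = correct == e.cell.satisfiable
            records.append(
                TrialRecord(
                    participant_id=f"p{i:03d}",
                    instance_id=e.instance.id,
                    tcc=e.cell.tcc.value,
                    satisfiable=e.cell.satisfiable,
                    trial_number=t,
                    correct=correct,
                    choice="yes" if yes else "no",
                )
            )
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "instance_id": [r.instance_id for r in records],
            "tcc": [r.tcc for r in records],
            "satisfiable": [r.satisfiable for r in records],
            "trial_number": [r.trial_number for r in records],
            "correct": [r.correct for r in records],
            "choice": [r.choice for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            participant_id=str(r.participant_id),
            instance_id=str(r.instance_id),
            tcc=str(r.tcc),
            satisfiable=bool(r.satisfiable),
            trial_number=int(r.trial_number),
            correct=bool(r.correct),
            choice=str(r.choice),
        )
        for r in frame.itertuples()
    ]


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper (95%)
    converged: bool
    n_obs: int
    n_participants_dropped: int = 0  # constant-outcome participants excluded


def fit_logistic(
    records: list[TrialRecord] | pd.DataFrame,
    predictors=("tcc", "satisfiable", "trial_number"),
    participant_effects: bool = False,
    maxiter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of correctness on predictors.

    Predictors: ``tcc`` -> indicator of high TCC; ``satisfiable`` ->
    indicator of a satisfiable instance; ``trial_number`` -> numeric.
    With ``participant_effects=True`` per-participant indicator columns
    (first participant as reference) stand in for random intercepts.
    Raises :class:`SeparationError` on perfectly separable outcomes and
    :class:`FitConvergenceError` if Newton-Raphson does not converge.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(predictors) < 1:
        raise ConfigurationError("need at least one predictor")
    n_dropped = 0
    if participant_effects:
        # a participant with constant outcomes contributes nothing to the
        # slope likelihood and makes their indicator coefficient diverge
        # (the standard fixed-effects-logit degeneracy); drop them
        const = frame.groupby("participant_id")["correct"].transform("nunique") == 1
        n_dropped = frame.loc[const, "participant_id"].nunique()
        frame = frame.loc[~const]
        if frame.empty:
            raise SeparationError("every participant has constant outcomes")
    y = frame["correct"].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise SeparationError("outcomes are constant; MLE does not exist")
    cols = {"const": np.ones(len(frame))}
    for pred in predictors:
        if pred == "tcc":
            cols["tcc_high"] = (frame["tcc"] == "high").to_numpy(dtype=float)
        elif pred == "satisfiable":
            cols["satisfiable"] = frame["satisfiable"].to_numpy(dtype=float)
        elif pred == "trial_number":
            cols["trial_number"] = frame["trial_number"].to_numpy(dtype=float)
        else:
            raise ConfigurationError(f"unknown predictor {pred!r}")
    if participant_effects:
        ids = sorted(frame["participant_id"].unique())
        for pid in ids[1:]:
            cols[f"pid_{pid}"] = (frame["participant_id"] == pid).to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise FitConvergenceError(f"Newton-Raphson did not converge in {maxiter} steps")
    # quasi-separation shows up as exploding estimates rather than an exception
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 1e3):
        raise SeparationError("estimates diverged; outcomes are (quasi-)separable")
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        converged=converged,
        n_obs=int(res.nobs),
        n_participants_dropped=n_dropped,
    )
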