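"""Ordinary-least-squares fitting of design matrices to ROI time series,
condition contrasts, per-timepoint group tests, and synthetic BOLD.

Per-voxel coefficients are estimated by OLS; the ROI summary at each basis
(tent or boxcar period) is the arithmetic mean of the per-voxel
coefficients.  Contrasts are linear combinations of ROI-mean coefficients
grouped by basis -- e.g. the TCC contrast (beta_high - beta_low) per FIR
tent.  Group inference is a one-sample two-sided t test of per-participant
contrast values against zero at each time point, uncorrected by default.

Synthetic BOLD for validation: series = design x true_beta plus stationary
AR(1) Gaussian noise, independently per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .errors import CollinearityError, ConfigurationError, SampleSizeError

__all__ = [
    "ROITimecourse",
    "GLMFit",
    "ContrastSpec",
    "BUILTIN_CONTRASTS",
    "legendre_drift",
    "fit_glm",
    "compute_contrast",
    "group_timepoint_test",
    "simulate_bold",
]


@dataclass
class ROITimecourse:
    """Voxel time series of one region of interest (time x voxels)."""

    series: pd.DataFrame
    tr_s: float = 0.8

    @property
    def n_voxels(self) -> int:
        return self.series.shape[1]

    def to_tsv(self, path) -> None:
        self.series.to_csv(path, sep="\t", index_label="time")

    @classmethod
    def from_tsv(cls, path, tr_s: float = 0.8) -> "ROITimecourse":
        frame = pd.read_csv(path, sep="\t", index_col="time")
        return cls(series=frame, tr_s=tr_s)


def legendre_drift(n_frames: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns P0..P_order on [-1, 1].

    P0 is the run intercept; higher orders absorb slow scanner drift.
    """
    x = np.linspace(-1.0, 1.0, n_frames)
    return np.polynomial.legendre.legvander(x, order)


def _find_dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # Greedy scan: a column is 'dependent' if adding it does not raise the rank.
    dependent = []
    rank = 0
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept = cand
            rank = r
        else:
            dependent.append(name)
    return dependent


@dataclass
class GLMFit:
    """Per-voxel OLS coefficients plus the ROI-mean summary."""

    coef: pd.DataFrame  # regressors x voxels
    roi_mean_beta: pd.Series  # mean over voxels, per regressor
    resid_var: pd.Series  # per voxel, denominator n - p
    column_info: dict
    meta: dict = field(default_factory=dict)


def fit_glm(
    design: DesignMatrix,
    series,
    drift_order: int = 2,
    mask: np.ndarray | None = None,
) -> GLMFit:
    """Fit the design to an ROI time course (or single series) by OLS.

    Legendre drift columns P0..P(*drift_order*) (P0 = intercept) are
    appended as nuisance regressors.  *mask*, if given, is a boolean
    row-keep vector (censoring).  The augmented design must be full column
    rank; otherwise :class:`CollinearityError` lists the dependent
    columns.  Deterministic: plain least squares per voxel, with the ROI
    summary the arithmetic mean of per-voxel coefficients.
    """
    if isinstance(series, ROITimecourse):
        Y = series.series.to_numpy(dtype=float)
        voxels = list(series.series.columns)
    else:
        Y = np.asarray(series, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        voxels = [f"v{i}" for i in range(Y.shape[1])]
    X = design.values
    names = list(design.columns)
    if Y.shape[0] != X.shape[0]:
        raise ConfigurationError(
            f"series has {Y.shape[0]} frames but design has {X.shape[0]}"
        )
    if drift_order is not None and drift_order >= 0:
        drift = legendre_drift(X.shape[0], drift_order)
        X = np.column_stack([X, drift])
        names = names + [f"drift_P{k}" for k in range(drift_order + 1)]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        X = X[mask]
        Y = Y[mask]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        dep = _find_dependent_columns(X, names)
        raise CollinearityError(
            f"design is rank deficient; dependent columns: {dep}", dep
        )
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    resid_var = (resid**2).sum(axis=0) / dof
    coef = pd.DataFrame(beta, index=names, columns=voxels)
    return GLMFit(
        coef=coef,
        roi_mean_beta=coef.mean(axis=1),
        resid_var=pd.Series(resid_var, index=voxels),
        column_info=design.column_info,
        meta=dict(design.meta),
    )


@dataclass(frozen=True)
class ContrastSpec:
    """A named contrast: selector dicts with weights over condition labels.

    Each term is ``(selector, weight)``; a selector matches every
    condition whose labels include all its key/value pairs, and the term
    contributes ``weight`` times the *mean* coefficient of the matched
    conditions (so a main-effect contrast averages over the other factor).
    Weights of differential contrasts must sum to zero.
    """

    name: str
    terms: tuple

    def __post_init__(self):
        total = sum(w for _, w in self.terms)
        if abs(total) > 1e-12 and len(self.terms) > 1:
            raise ConfigurationError(
                f"contrast {self.name!r}: differential weights must sum to 0"
            )


BUILTIN_CONTRASTS = {
    # main effect of typical-case complexity: beta_high - beta_low
    "tcc": ContrastSpec("tcc", (({"tcc": "high"}, 1.0), ({"tcc": "low"}, -1.0))),
    # main effect of satisfiability: beta_unsat - beta_sat
    "sat": ContrastSpec("sat", (({"sat": "unsat"}, 1.0), ({"sat": "sat"}, -1.0))),
    # interaction: (high,unsat - high,sat) - (low,unsat - low,sat)
    "interaction": ContrastSpec(
        "interaction",
        (
            ({"tcc": "high", "sat": "unsat"}, 1.0),
            ({"tcc": "high", "sat": "sat"}, -1.0),
            ({"tcc": "low", "sat": "unsat"}, -1.0),
            ({"tcc": "low", "sat": "sat"}, 1.0),
        ),
    ),
    # accuracy: beta_correct - beta_incorrect
    "accuracy": ContrastSpec(
        "accuracy", (({"acc": "correct"}, 1.0), ({"acc": "incorrect"}, -1.0))
    ),
}


def _column_condition(info: dict) -> dict | None:
    if info.get("kind") == "fir":
        return info["condition"]
    if info.get("kind") == "boxcar" and "level" in info:
        return {info["factor"]: info["level"]}
    return None


def _matches(condition: dict, selector: dict) -> bool:
    return all(condition.get(k) == v for k, v in selector.items())


def compute_contrast(fit: GLMFit, spec: ContrastSpec | str) -> pd.Series:
    """Evaluate a contrast on the ROI-mean coefficients, per basis.

    For FIR fits the result is indexed by tent index; for boxcar fits by
    period (S1..S4, resp).  Raises :class:`ConfigurationError` when a
    selector matches no coefficient.
    """
    if isinstance(spec, str):
        spec = BUILTIN_CONTRASTS[spec]
    # group columns by basis: tent index or boxcar period
    basis_of = {}
    for name, info in fit.column_info.items():
        if info.get("kind") == "fir":
            basis_of[name] = info["tent"]
        elif info.get("kind") == "boxcar" and "level" in info:
            basis_of[name] = info["period"]
    bases = sorted(set(basis_of.values()), key=lambda b: (isinstance(b, str), b))
    out = {}
    for b in bases:
        total = 0.0
        for selector, weight in spec.terms:
            cols = [
                name
                for name, info in fit.column_info.items()
                if basis_of.get(name) == b
                and _matches(_column_condition(info) or {}, selector)
            ]
            if not cols:
                raise ConfigurationError(
                    f"contrast {spec.name!r}: selector {selector} matches no "
                    f"coefficient at basis {b!r}"
                )
            total += weight * fit.roi_mean_beta[cols].mean()
        out[b] = total
    if not out:
        raise ConfigurationError("fit contains no condition-labeled coefficients")
    return pd.Series(out, name=spec.name)


def group_timepoint_test(
    per_participant_contrasts, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sample two-sided t test of contrast values against 0, per basis.

    *per_participant_contrasts*: participants x timepoints array (or a
    DataFrame / list of Series from :func:`compute_contrast`).  P values
    are uncorrected.  Degenerate variance (all participants identical) is
    flagged: a nonzero constant is reported significant (p = 0), a zero
    constant not (p = 1).
    """
    if isinstance(per_participant_contrasts, (list, tuple)):
        frame = pd.DataFrame([np.asarray(c) for c in per_participant_contrasts])
        index = getattr(per_participant_contrasts[0], "index", None)
    else:
        frame = pd.DataFrame(np.asarray(per_participant_contrasts))
        index = getattr(per_participant_contrasts, "columns", None)
    data = frame.to_numpy(dtype=float)
    n, k = data.shape
    if n < 2:
        raise SampleSizeError("group test requires at least 2 participants")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    t = np.full(k, np.nan)
    p = np.ones(k)
    degenerate = sd == 0
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    p[degenerate & (mean != 0)] = 0.0
    p[degenerate & (mean == 0)] = 1.0
    out = pd.DataFrame(
        {
            "mean": mean,
            "t": t,
            "p": p,
            "significant": p < alpha,
            "degenerate": degenerate,
        }
    )
    if index is not None and len(index) == k:
        out.index = index
    return out


def _ar1_noise(
    rng: np.random.Generator, n: int, n_voxels: int, phi: float, sigma: float
) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation sigma."""
    if sigma == 0:
        return np.zeros((n, n_voxels))
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    e = np.empty((n, n_voxels))
    e[0] = rng.normal(0.0, sigma, size=n_voxels)
    eps = rng.normal(0.0, innov_sd, size=(n - 1, n_voxels))
    for t in range(1, n):
        e[t] = phi * e[t - 1] + eps[t - 1]
    return e


def simulate_bold(
    design: DesignMatrix,
    true_beta,
    phi: float = 0.3,
    sigma: float = 1.0,
    n_voxels: int = 1,
    seed: int | np.random.Generator | None = 0,
) -> ROITimecourse:
    """Synthetic ROI BOLD: ``design x true_beta`` plus AR(1) noise per voxel.

    *true_beta* is an array over design columns or a mapping from column
    name to coefficient (missing columns default to 0).  *phi* in (-1, 1)
    is the lag-1 autocorrelation; *sigma* >= 0 the stationary noise SD.
    """
    if not -1.0 < phi < 1.0:
        raise ConfigurationError("phi must lie in (-1, 1)")
    if sigma < 0:
        raise ConfigurationError("sigma must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if isinstance(true_beta, dict):
        beta = np.array([float(true_beta.get(c, 0.0)) for c in design.columns])
    elif isinstance(true_beta, pd.Series):
        beta = np.array([float(true_beta.get(c, 0.0)) for c in design.columns])
    else:
        beta = np.asarray(true_beta, dtype=float)
        if beta.size != len(design.columns):
            raise ConfigurationError(
                f"true_beta has {beta.size} entries for {len(design.columns)} columns"
            )
    signal = design.values @ beta
    noise = _ar1_noise(rng, signal.size, n_voxels, phi, sigma)
    data = signal[:, None] + noise
    series = pd.DataFrame(
        data, index=design.frame.index, columns=[f"v{i}" for i in range(n_voxels)]
    )
    return ROITimecourse(series=series, tr_s=design.tr_s)
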