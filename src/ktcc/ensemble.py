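"""Random instance ensembles, phase transitions and TCC classification.

Random 0-1 knapsack decision instances drawn in constrainedness bands
exhibit a satisfiability phase transition: as the normalized target profit
``alpha_p`` grows (capacity band held fixed), the probability that a random
instance is satisfiable falls from ~1 (under-constrained region) to ~0
(over-constrained region), crossing 0.5 at the satisfiability threshold
``alpha_s``.  Mean solver effort peaks near ``alpha_s`` -- the
easy-hard-easy pattern.  Typical-case complexity (TCC) is a binary label
derived from band membership: high near the threshold, low in the outer
regions.

Defaults reproduce the study conditions: N = 6 items, values and weights
uniform integers on [1, 100], ``alpha_c`` in [0.40, 0.45], and the three
``alpha_p`` bands [0.35, 0.40] (under-constrained), [0.60, 0.65]
(near-threshold) and [0.85, 0.90] (over-constrained).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BracketError, ConfigurationError, InfeasibleBandError
from .knapsack import (
    Instance,
    Item,
    compute_constrainedness_exact,
    solve_decision,
)

__all__ = [
    "Region",
    "TCC",
    "TCCBands",
    "DEFAULT_BANDS",
    "SamplingConfig",
    "ConstrainednessProfile",
    "PhaseTransitionMap",
    "sample_instance",
    "sample_instances",
    "estimate_sat_probability",
    "estimate_phase_transition",
    "locate_threshold",
    "classify_tcc",
    "profile_instance",
]

MAX_CONSECUTIVE_REJECTIONS = 10_000


class Region(str, enum.Enum):
    """Constrainedness region of an instance's ``alpha_p``."""

    UNDER_CONSTRAINED = "under_constrained"
    NEAR_THRESHOLD = "near_threshold"
    OVER_CONSTRAINED = "over_constrained"
    UNCLASSIFIED = "unclassified"


class TCC(str, enum.Enum):
    """Typical-case complexity label: high near the satisfiability threshold."""

    LOW = "low"
    HIGH = "high"


def _check_band(band, name, lo=0.0, hi=1.0):
    a, b = float(band[0]), float(band[1])
    if not (lo < a <= b < hi) and not (lo < a <= b <= hi):
        raise ConfigurationError(f"{name} must be a non-empty interval in ({lo}, {hi})")
    if a > b:
        raise ConfigurationError(f"{name} is empty: {band}")
    return (a, b)


@dataclass(frozen=True)
class TCCBands:
    """The three disjoint ``alpha_p`` bands used to label region and TCC."""

    under: tuple[float, float] = (0.35, 0.40)
    threshold: tuple[float, float] = (0.60, 0.65)
    over: tuple[float, float] = (0.85, 0.90)

    def __post_init__(self):
        intervals = sorted(
            [
                _check_band(self.under, "under band"),
                _check_band(self.threshold, "threshold band"),
                _check_band(self.over, "over band"),
            ]
        )
        for (_, b_hi), (c_lo, _) in zip(intervals[:-1], intervals[1:]):
            if c_lo <= b_hi:  # closed intervals must not touch
                raise ConfigurationError("TCC bands overlap")


DEFAULT_BANDS = TCCBands()


def classify_tcc(
    alpha_p: float, bands: TCCBands = DEFAULT_BANDS
) -> tuple[Region, TCC | None]:
    """Map ``alpha_p`` to its (region, TCC) label.

    Under-constrained and over-constrained bands carry low TCC, the
    near-threshold band high TCC.  Values outside every band get the
    explicit ``Region.UNCLASSIFIED`` with no TCC label.  Band membership
    is inclusive of both endpoints.
    """
    a = float(alpha_p)
    if bands.under[0] <= a <= bands.under[1]:
        return Region.UNDER_CONSTRAINED, TCC.LOW
    if bands.threshold[0] <= a <= bands.threshold[1]:
        return Region.NEAR_THRESHOLD, TCC.HIGH
    if bands.over[0] <= a <= bands.over[1]:
        return Region.OVER_CONSTRAINED, TCC.LOW
    return Region.UNCLASSIFIED, None


def tcc_distance(alpha_p: float, alpha_s: float) -> float:
    """Continuous diagnostic: distance of ``alpha_p`` from the threshold."""
    return abs(float(alpha_p) - float(alpha_s))


@dataclass(frozen=True)
class ConstrainednessProfile:
    """Constrainedness parameters and categorical labels of one instance."""

    alpha_p: float
    alpha_c: float
    region: Region
    tcc: TCC | None


def profile_instance(
    instance: Instance, bands: TCCBands = DEFAULT_BANDS
) -> ConstrainednessProfile:
    ap, ac = compute_constrainedness_exact(instance)
    region, tcc = classify_tcc(float(ap), bands)
    return ConstrainednessProfile(float(ap), float(ac), region, tcc)


@dataclass(frozen=True)
class SamplingConfig:
    """Instance-generator configuration.

    Items are i.i.d. uniform integers on the closed value/weight ranges;
    capacity and target profit are set by drawing target constrainedness
    values uniformly in the bands and rounding (half-up), then the realized
    constrainedness is re-checked against the bands (rejection sampling).
    """

    n_items: int = 6
    value_range: tuple[int, int] = (1, 100)
    weight_range: tuple[int, int] = (1, 100)
    alpha_c_band: tuple[float, float] = (0.40, 0.45)
    alpha_p_band: tuple[float, float] = (0.60, 0.65)
    seed: int | None = None

    def __post_init__(self):
        if self.n_items < 1:
            raise ConfigurationError("n_items must be >= 1")
        for rng_name in ("value_range", "weight_range"):
            lo, hi = getattr(self, rng_name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{rng_name} must satisfy 1 <= lo <= hi")
        _check_band(self.alpha_c_band, "alpha_c_band")
        _check_band(self.alpha_p_band, "alpha_p_band")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_instance(
    config: SamplingConfig, rng: np.random.Generator, id_prefix: str = "inst"
) -> Instance:
    """Draw one instance whose realized constrainedness lies in the bands.

    Raises :class:`InfeasibleBandError` after 10^4 consecutive rejections
    (band too narrow for integer rounding at this item count).
    """
    for attempt in range(MAX_CONSECUTIVE_REJECTIONS):
        values = rng.integers(
            config.value_range[0], config.value_range[1], endpoint=True, size=config.n_items
        )
        weights = rng.integers(
            config.weight_range[0], config.weight_range[1], endpoint=True, size=config.n_items
        )
        ac_target = rng.uniform(*config.alpha_c_band)
        ap_target = rng.uniform(*config.alpha_p_band)
        c = _round_half_up(ac_target * int(weights.sum()))
        p = _round_half_up(ap_target * int(values.sum()))
        if c < 1 or p < 1:
            continue
        inst = Instance(
            items=tuple(Item(int(v), int(w)) for v, w in zip(values, weights)),
            capacity=c,
            target_profit=p,
            id=f"{id_prefix}",
        )
        ap, ac = compute_constrainedness_exact(inst)
        if (
            config.alpha_p_band[0] <= ap <= config.alpha_p_band[1]
            and config.alpha_c_band[0] <= ac <= config.alpha_c_band[1]
        ):
            return inst
    raise InfeasibleBandError(
        f"no acceptable instance in {MAX_CONSECUTIVE_REJECTIONS} draws for "
        f"alpha_p band {config.alpha_p_band}, alpha_c band {config.alpha_c_band}"
    )


def sample_instances(
    config: SamplingConfig, n: int, rng: np.random.Generator, id_prefix: str = "inst"
) -> list[Instance]:
    return [
        dataclasses.replace(sample_instance(config, rng), id=f"{id_prefix}-{k:04d}")
        for k in range(n)
    ]


def _band_at(config: SamplingConfig, center: float, halfwidth: float) -> SamplingConfig:
    lo = max(1e-6, center - halfwidth)
    hi = min(1.0 - 1e-9, center + halfwidth)
    return dataclasses.replace(config, alpha_p_band=(lo, hi))


def estimate_sat_probability(
    config: SamplingConfig, n: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo ``(P(sat), mean effort_nodes)`` for the config's bands."""
    sat = 0
    effort = 0
    for _ in range(n):
        res = solve_decision(sample_instance(config, rng))
        sat += res.satisfiable
        effort += res.effort_nodes
    return sat / n, effort / n


@dataclass
class PhaseTransitionMap:
    """Monte-Carlo phase-transition summary over an ``alpha_p`` grid."""

    alpha_p_grid: np.ndarray
    n_per_point: int
    n_sat: np.ndarray
    p_sat: np.ndarray
    mean_effort: np.ndarray
    alpha_s_estimate: float | None
    config: SamplingConfig
    seed: int | None = None
    band_halfwidth: float = 0.01

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha_p": self.alpha_p_grid,
                "n": self.n_per_point,
                "n_sat": self.n_sat,
                "p_sat": self.p_sat,
                "mean_effort": self.mean_effort,
            }
        )

    def save(self, path_prefix: str) -> None:
        """Write ``<prefix>.csv`` (tidy table) and ``<prefix>.json`` (header)."""
        self.to_frame().to_csv(f"{path_prefix}.csv", index=False)
        header = {
            "config": dataclasses.asdict(self.config),
            "seed": self.seed,
            "band_halfwidth": self.band_halfwidth,
            "alpha_s_estimate": self.alpha_s_estimate,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(header, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "PhaseTransitionMap":
        frame = pd.read_csv(f"{path_prefix}.csv")
        with open(f"{path_prefix}.json") as fh:
            header = json.load(fh)
        cfg = header["config"]
        for key in ("value_range", "weight_range", "alpha_c_band", "alpha_p_band"):
            cfg[key] = tuple(cfg[key])
        return cls(
            alpha_p_grid=frame["alpha_p"].to_numpy(),
            n_per_point=int(frame["n"].iloc[0]),
            n_sat=frame["n_sat"].to_numpy(),
            p_sat=frame["p_sat"].to_numpy(),
            mean_effort=frame["mean_effort"].to_numpy(),
            alpha_s_estimate=header["alpha_s_estimate"],
            config=SamplingConfig(**cfg),
            seed=header["seed"],
            band_halfwidth=header["band_halfwidth"],
        )


def estimate_phase_transition(
    config: SamplingConfig,
    alpha_p_grid,
    n_per_point: int,
    rng: np.random.Generator,
    band_halfwidth: float = 0.01,
    locate: bool = True,
) -> PhaseTransitionMap:
    """Map the satisfiability phase transition on a grid of ``alpha_p``.

    At each grid value, ``n_per_point`` instances are sampled in a narrow
    band centered on it; the satisfiable proportion and mean solver effort
    (branch-and-bound node expansions) are recorded.  When *locate* is
    true, ``alpha_s_estimate`` is filled by :func:`locate_threshold` using
    a bracket spanned by the grid.
    """
    grid = np.asarray(sorted(float(a) for a in alpha_p_grid))
    if grid.size == 0 or grid[0] <= 0 or grid[-1] >= 1:
        raise ConfigurationError("alpha_p grid must lie strictly inside (0, 1)")
    if n_per_point < 1:
        raise ConfigurationError("n_per_point must be >= 1")
    n_sat = np.zeros(grid.size, dtype=int)
    mean_effort = np.zeros(grid.size)
    for gi, a in enumerate(grid):
        cfg = _band_at(config, a, band_halfwidth)
        p, eff = estimate_sat_probability(cfg, n_per_point, rng)
        n_sat[gi] = round(p * n_per_point)
        mean_effort[gi] = eff
    alpha_s = None
    if locate:
        alpha_s = locate_threshold(
            config, rng, bracket=(float(grid[0]), float(grid[-1]))
        )
    return PhaseTransitionMap(
        alpha_p_grid=grid,
        n_per_point=n_per_point,
        n_sat=n_sat,
        p_sat=n_sat / n_per_point,
        mean_effort=mean_effort,
        alpha_s_estimate=alpha_s,
        config=config,
        seed=config.seed,
        band_halfwidth=band_halfwidth,
    )


def locate_threshold(
    config: SamplingConfig,
    rng: np.random.Generator,
    tol: float = 0.01,
    n_per_step: int = 400,
    bracket: tuple[float, float] = (0.35, 0.90),
    band_halfwidth: float = 0.01,
    method: str = "bisect",
) -> float:
    """Locate the satisfiability threshold ``alpha_s``.

    ``method="bisect"`` (default): stochastic bisection on ``alpha_p`` --
    at each step P(sat) is estimated from ``n_per_step`` fresh instances at
    the bracket midpoint and the bracket is halved toward the side where
    P(sat) crosses 0.5, stopping at width <= *tol*; returns the midpoint.
    ``method="logistic"``: fits a logistic curve to P(sat) sampled on a
    coarse grid across the bracket and returns its 0.5 crossing.

    The bracket must straddle the transition: P(sat) > 0.5 at the lower
    end and < 0.5 at the upper end (checked by Monte Carlo), else
    :class:`BracketError` is raised.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not 0 < lo < hi < 1:
        raise ConfigurationError("bracket must satisfy 0 < lo < hi < 1")
    p_lo, _ = estimate_sat_probability(_band_at(config, lo, band_halfwidth), n_per_step, rng)
    p_hi, _ = estimate_sat_probability(_band_at(config, hi, band_halfwidth), n_per_step, rng)
    if not (p_lo > 0.5 > p_hi):
        raise BracketError(
            f"bracket does not straddle the transition: "
            f"P(sat)={p_lo:.3f} at {lo}, {p_hi:.3f} at {hi}"
        )
    if method == "bisect":
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            p_mid, _ = estimate_sat_probability(
                _band_at(config, mid, band_halfwidth), n_per_step, rng
            )
            if p_mid > 0.5:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)
    if method == "logistic":
        import statsmodels.api as sm

        grid = np.linspace(lo, hi, 9)
        xs, ys = [], []
        for a in grid:
            cfg = _band_at(config, a, band_halfwidth)
            for _ in range(n_per_step):
                inst = sample_instance(cfg, rng)
                ap = float(compute_constrainedness_exact(inst)[0])
                xs.append(ap)
                ys.append(int(solve_decision(inst).satisfiable))
        X = sm.add_constant(np.asarray(xs))
        fit = sm.Logit(np.asarray(ys), X).fit(disp=0)
        b0, b1 = fit.params
        alpha_s = -b0 / b1
        if not lo <= alpha_s <= hi:
            raise BracketError(f"logistic crossing {alpha_s:.3f} outside bracket")
        return float(alpha_s)
    raise ConfigurationError(f"unknown method {method!r}")
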