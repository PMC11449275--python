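"""Factorial stimulus ensembles and session scheduling.

The experimental design crosses typical-case complexity (TCC: low/high)
with satisfiability (satisfiable/unsatisfiable) in a balanced 2x2
factorial.  Low-TCC cells draw from the outer constrainedness bands, where
the satisfiability label is nearly forced (under-constrained -> satisfiable,
over-constrained -> unsatisfiable); both high-TCC cells draw from the
near-threshold band, where each label occurs with probability ~0.5.  Every
candidate is solved exactly to confirm its label.  Within each high-TCC
cell, instances are median-split by solver effort into top/bottom strata so
computational requirements can be balanced.

The full ensemble holds 18 instances per cell (72 total); a balanced
subsample (56 by default, 14 per cell) feeds a session of 7 blocks x 8
trials.  Each trial runs items stage (3 s) -> solving stage (22 s) ->
response stage (2 s), followed by a jittered 8/10/12 s inter-trial rest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import (
    DEFAULT_BANDS,
    SamplingConfig,
    TCC,
    TCCBands,
    sample_instance,
)
from .errors import ConfigurationError, LabelValidationError, QuotaTimeoutError
from .knapsack import (
    Instance,
    compute_constrainedness,
    frame_to_instances,
    instances_to_frame,
    solve_decision,
)

__all__ = [
    "DesignCell",
    "StimulusEntry",
    "StimulusSet",
    "Trial",
    "TrialSchedule",
    "default_cells",
    "build_full_ensemble",
    "subsample_balanced",
    "schedule_session",
]

ITEMS_DURATION_S = 3.0
SOLVING_DURATION_S = 22.0
RESPONSE_DURATION_S = 2.0
TRIAL_DURATION_S = ITEMS_DURATION_S + SOLVING_DURATION_S + RESPONSE_DURATION_S
ITI_CHOICES_S = (8.0, 10.0, 12.0)


@dataclass(frozen=True)
class DesignCell:
    """One cell of the 2x2 TCC x satisfiability factorial."""

    tcc: TCC
    satisfiable: bool
    alpha_p_band: tuple[float, float]

    @property
    def name(self) -> str:
        return f"{self.tcc.value}TCC_{'sat' if self.satisfiable else 'unsat'}"


def default_cells(bands: TCCBands = DEFAULT_BANDS) -> tuple[DesignCell, ...]:
    """The four factorial cells: low-TCC cells in the outer bands, both
    high-TCC cells in the near-threshold band."""
    return (
        DesignCell(TCC.LOW, True, bands.under),
        DesignCell(TCC.LOW, False, bands.over),
        DesignCell(TCC.HIGH, True, bands.threshold),
        DesignCell(TCC.HIGH, False, bands.threshold),
    )


@dataclass(frozen=True)
class StimulusEntry:
    instance: Instance
    cell: DesignCell
    alpha_p: float
    alpha_c: float
    effort_nodes: int
    effort_stratum: str  # "top" | "bottom" | "na"


@dataclass
class StimulusSet:
    """A labeled collection of design-cell entries."""

    entries: list[StimulusEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def cell_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.cell.name] = counts.get(e.cell.name, 0) + 1
        return counts

    def stratum_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for e in self.entries:
            key = (e.cell.name, e.effort_stratum)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def labels_by_instance(self) -> dict[str, dict[str, str]]:
        """Condition labels keyed by instance id, for design-matrix building."""
        return {
            e.instance.id: {
                "tcc": e.cell.tcc.value,
                "sat": "sat" if e.cell.satisfiable else "unsat",
            }
            for e in self.entries
        }

    def to_frame(self) -> pd.DataFrame:
        frame = instances_to_frame([e.instance for e in self.entries])
        meta = {
            e.instance.id: {
                "cell_tcc": e.cell.tcc.value,
                "cell_satisfiable": e.cell.satisfiable,
                "band_lo": e.cell.alpha_p_band[0],
                "band_hi": e.cell.alpha_p_band[1],
                "alpha_p": e.alpha_p,
                "alpha_c": e.alpha_c,
                "effort_nodes": e.effort_nodes,
                "effort_stratum": e.effort_stratum,
            }
            for e in self.entries
        }
        if meta:
            for col in next(iter(meta.values())):
                frame[col] = [meta[i][col] for i in frame["instance_id"]]
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, validate: bool = True) -> "StimulusSet":
        instances = frame_to_instances(frame)
        first = frame.drop_duplicates("instance_id").set_index("instance_id")
        entries = []
        for inst in instances:
            row = first.loc[inst.id]
            cell = DesignCell(
                TCC(row["cell_tcc"]),
                bool(row["cell_satisfiable"]),
                (float(row["band_lo"]), float(row["band_hi"])),
            )
            ap, ac = compute_constrainedness(inst)
            if validate:
                verdict = solve_decision(inst).satisfiable
                if verdict != cell.satisfiable:
                    raise LabelValidationError(
                        f"instance {inst.id}: stored label satisfiable="
                        f"{cell.satisfiable} but exact solve says {verdict}"
                    )
                if not cell.alpha_p_band[0] <= ap <= cell.alpha_p_band[1]:
                    raise LabelValidationError(
                        f"instance {inst.id}: alpha_p={ap:.4f} outside cell band "
                        f"{cell.alpha_p_band}"
                    )
            entries.append(
                StimulusEntry(
                    instance=inst,
                    cell=cell,
                    alpha_p=ap,
                    alpha_c=ac,
                    effort_nodes=int(row["effort_nodes"]),
                    effort_stratum=str(row["effort_stratum"]),
                )
            )
        return cls(entries)

    @classmethod
    def from_csv(cls, path, validate: bool = True) -> "StimulusSet":
        return cls.from_frame(pd.read_csv(path), validate=validate)


def build_full_ensemble(
    config: SamplingConfig | None = None,
    seed: int | None = 0,
    per_cell: int = 18,
    cells: tuple[DesignCell, ...] | None = None,
    max_attempts_per_cell: int = 500_000,
) -> StimulusSet:
    """Rejection-sample the full factorial ensemble (default 4 x 18 = 72).

    Each candidate instance is solved exactly; it is kept only if its
    verdict matches the cell's satisfiability label.  Within high-TCC
    cells, entries are median-split by ``effort_nodes`` into bottom/top
    strata (ties and the odd middle entry go to the bottom stratum).
    *config* supplies item ranges and the ``alpha_c`` band; each cell
    overrides the ``alpha_p`` band.
    """
    if config is None:
        config = SamplingConfig()
    if cells is None:
        cells = default_cells()
    rng = np.random.default_rng(seed)
    entries: list[StimulusEntry] = []
    for cell in cells:
        cfg = dataclasses.replace(config, alpha_p_band=cell.alpha_p_band)
        got: list[StimulusEntry] = []
        attempts = 0
        while len(got) < per_cell:
            if attempts >= max_attempts_per_cell:
                raise QuotaTimeoutError(
                    f"cell {cell.name}: only {len(got)}/{per_cell} instances "
                    f"after {attempts} draws"
                )
            attempts += 1
            inst = sample_instance(cfg, rng)
            res = solve_decision(inst)
            if res.satisfiable != cell.satisfiable:
                continue
            inst = dataclasses.replace(inst, id=f"{cell.name}-{len(got):03d}")
            ap, ac = compute_constrainedness(inst)
            got.append(StimulusEntry(inst, cell, ap, ac, res.effort_nodes, "na"))
        if cell.tcc is TCC.HIGH:
            got = _split_strata(got)
        entries.extend(got)
    return StimulusSet(entries)


def _split_strata(entries: list[StimulusEntry]) -> list[StimulusEntry]:
    # Stable sort by effort: equal efforts keep sampling order, so ties land
    # in the bottom stratum.  Bottom gets ceil(n/2) when n is odd.
    order = sorted(range(len(entries)), key=lambda i: entries[i].effort_nodes)
    n_bottom = (len(entries) + 1) // 2
    strata = {}
    for rank, i in enumerate(order):
        strata[i] = "bottom" if rank < n_bottom else "top"
    return [
        dataclasses.replace(e, effort_stratum=strata[i])
        for i, e in enumerate(entries)
    ]


def subsample_balanced(
    full: StimulusSet, n_total: int = 56, seed: int | None = 0
) -> StimulusSet:
    """Uniform subsample without replacement, balanced across the factorial.

    ``n_total`` must be divisible by 4; each cell contributes
    ``n_total / 4`` entries.  Within high-TCC cells the top/bottom effort
    strata are kept as balanced as the per-cell quota allows (exactly
    balanced when the quota is even; the odd remainder goes to a randomly
    chosen stratum).
    """
    if n_total % 4 != 0:
        raise ConfigurationError(f"n_total must be divisible by 4, got {n_total}")
    quota = n_total // 4
    rng = np.random.default_rng(seed)
    by_cell: dict[str, list[StimulusEntry]] = {}
    for e in full.entries:
        by_cell.setdefault(e.cell.name, []).append(e)
    if len(by_cell) != 4:
        raise ConfigurationError(f"expected 4 design cells, found {sorted(by_cell)}")
    chosen: list[StimulusEntry] = []
    for name in sorted(by_cell):
        cell_entries = by_cell[name]
        if quota > len(cell_entries):
            raise ConfigurationError(
                f"cell {name}: quota {quota} exceeds cell size {len(cell_entries)}"
            )
        strata = {e.effort_stratum for e in cell_entries}
        if strata == {"na"}:
            idx = rng.choice(len(cell_entries), size=quota, replace=False)
            chosen.extend(cell_entries[i] for i in sorted(idx))
        else:
            top = [e for e in cell_entries if e.effort_stratum == "top"]
            bottom = [e for e in cell_entries if e.effort_stratum == "bottom"]
            n_top = quota // 2
            n_bottom = quota // 2
            if quota % 2:
                if rng.integers(2):
                    n_top += 1
                else:
                    n_bottom += 1
            if n_top > len(top) or n_bottom > len(bottom):
                raise ConfigurationError(
                    f"cell {name}: stratum quota ({n_top} top, {n_bottom} bottom) "
                    f"exceeds stratum sizes ({len(top)} top, {len(bottom)} bottom)"
                )
            for pool, k in ((top, n_top), (bottom, n_bottom)):
                idx = rng.choice(len(pool), size=k, replace=False)
                chosen.extend(pool[i] for i in sorted(idx))
    return StimulusSet(chosen)


@dataclass(frozen=True)
class Trial:
    instance_id: str
    block: int
    onset_s: float
    items_duration_s: float = ITEMS_DURATION_S
    solving_duration_s: float = SOLVING_DURATION_S
    response_duration_s: float = RESPONSE_DURATION_S
    iti_s: float = 8.0
    yes_side: str = "left"  # side of the 'YES' button


@dataclass
class TrialSchedule:
    """Ordered trial timeline for one session (default 7 blocks x 8 trials)."""

    trials: list[Trial]

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.trials):
            rows.append(
                {
                    "onset": t.onset_s,
                    "duration": TRIAL_DURATION_S,
                    "trial_type": "knapsack_decision",
                    "instance_id": t.instance_id,
                    "block": t.block,
                    "trial": k + 1,
                    "yes_side": t.yes_side,
                    "iti": t.iti_s,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        """BIDS-style events table (tab-separated)."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrialSchedule":
        frame = pd.read_csv(path, sep="\t")
        trials = [
            Trial(
                instance_id=str(r.instance_id),
                block=int(r.block),
                onset_s=float(r.onset),
                iti_s=float(r.iti),
                yes_side=str(r.yes_side),
            )
            for r in frame.itertuples()
        ]
        return cls(trials)


def schedule_session(
    stimuli: StimulusSet,
    seed: int | None = 0,
    block_size: int = 8,
    itis: tuple[float, ...] = ITI_CHOICES_S,
    start_s: float = 0.0,
) -> TrialSchedule:
    """Randomize stimulus order into blocks and lay out trial onsets.

    Instances are uniformly permuted into ``len(stimuli) / block_size``
    blocks; the inter-trial interval is drawn uniformly from *itis* and the
    'YES' button side uniformly from left/right, independently per trial.
    Onsets satisfy ``onset[k+1] = onset[k] + 27 + iti[k]``.
    """
    n = len(stimuli)
    if n == 0 or n % block_size != 0:
        raise ConfigurationError(
            f"stimulus count {n} not divisible by block size {block_size}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    trials = []
    onset = float(start_s)
    for k, i in enumerate(order):
        iti = float(itis[rng.integers(len(itis))])
        trials.append(
            Trial(
                instance_id=stimuli.entries[i].instance.id,
                block=k // block_size + 1,
                onset_s=onset,
                iti_s=iti,
                yes_side="left" if rng.integers(2) else "right",
            )
        )
        onset += TRIAL_DURATION_S + iti
    return TrialSchedule(trials)
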