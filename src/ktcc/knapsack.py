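"""Exact representation and solving of 0-1 knapsack decision instances.

A knapsack decision instance consists of ``N`` items with integer values
(dollars) and weights (grams), a capacity constraint ``c`` and a target
profit ``p``.  The decision question: does a subset of items exist whose
total weight is at most ``c`` and whose total value is at least ``p``?

The module provides

* :func:`compute_constrainedness` -- the constrainedness parameters
  ``alpha_p = p / sum(v)`` and ``alpha_c = c / sum(w)`` in exact rational
  arithmetic;
* :func:`brute_force_decision` -- exhaustive enumeration (test oracle);
* :func:`solve_decision` -- depth-first branch and bound with deterministic
  effort counters (the package's ex-post complexity measure);
* :func:`verify_witness` -- polynomial-time certificate checking;
* :func:`solve_optimization` -- the dynamic program for the optimization
  variant (maximize value subject to the capacity constraint);
* a lossless CSV / JSON instance dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInstanceError, SizeLimitError

__all__ = [
    "Item",
    "Instance",
    "DecisionResult",
    "compute_constrainedness",
    "brute_force_decision",
    "solve_decision",
    "verify_witness",
    "solve_optimization",
    "instances_to_frame",
    "frame_to_instances",
    "write_instances_csv",
    "read_instances_csv",
    "write_instances_json",
    "read_instances_json",
]

#: Guard for exhaustive enumeration: 2^25 subsets is the largest we enumerate.
BRUTE_FORCE_MAX_ITEMS = 25


def _check_positive_int(x, name: str) -> int:
    if isinstance(x, (bool, float)) or int(x) != x:
        raise InvalidInstanceError(f"{name} must be an integer, got {x!r}")
    x = int(x)
    if x < 1:
        raise InvalidInstanceError(f"{name} must be >= 1, got {x}")
    return x


@dataclass(frozen=True)
class Item:
    """One knapsack item: an integer value (dollars) and weight (grams)."""

    value: int
    weight: int

    def __post_init__(self):
        object.__setattr__(self, "value", _check_positive_int(self.value, "value"))
        object.__setattr__(self, "weight", _check_positive_int(self.weight, "weight"))


@dataclass(frozen=True)
class Instance:
    """A 0-1 knapsack decision instance.

    Degenerate instances (``p > sum(v)`` or ``c >= sum(w)``) are legal; their
    verdict is forced (unsatisfiable / reducible to the value test).
    """

    items: tuple[Item, ...]
    capacity: int
    target_profit: int
    id: str = ""

    def __post_init__(self):
        items = tuple(
            it if isinstance(it, Item) else Item(*it) for it in self.items
        )
        if len(items) == 0:
            raise InvalidInstanceError("instance must contain at least one item")
        object.__setattr__(self, "items", items)
        object.__setattr__(
            self, "capacity", _check_positive_int(self.capacity, "capacity")
        )
        object.__setattr__(
            self,
            "target_profit",
            _check_positive_int(self.target_profit, "target_profit"),
        )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def values(self) -> tuple[int, ...]:
        return tuple(it.value for it in self.items)

    @property
    def weights(self) -> tuple[int, ...]:
        return tuple(it.weight for it in self.items)

    @property
    def total_value(self) -> int:
        return sum(self.values)

    @property
    def total_weight(self) -> int:
        return sum(self.weights)


@dataclass(frozen=True)
class DecisionResult:
    """Verdict of an exact decision solve, plus deterministic effort counters.

    ``effort_nodes`` counts search-tree node expansions and
    ``effort_checks`` counts individual constraint evaluations.  Both are
    reproducible given the documented item ordering and therefore serve as
    the package's algorithm-specific ex-post complexity measure.
    """

    satisfiable: bool
    witness: frozenset[int] | None
    effort_nodes: int
    effort_checks: int

    def __post_init__(self):
        if self.satisfiable and self.witness is None:
            raise ValueError("satisfiable result must carry a witness")
        if not self.satisfiable and self.witness is not None:
            raise ValueError("unsatisfiable result must not carry a witness")
        if self.witness is not None:
            object.__setattr__(self, "witness", frozenset(self.witness))


def compute_constrainedness(instance: Instance) -> tuple[float, float]:
    """Return ``(alpha_p, alpha_c)`` for *instance*.

    ``alpha_p = p / sum(v_i)`` normalizes the target profit by the total
    value on offer; ``alpha_c = c / sum(w_i)`` normalizes the capacity by
    the total weight.  Ratios are formed in exact rational arithmetic and
    rendered to float only on return.
    """
    ap, ac = compute_constrainedness_exact(instance)
    return float(ap), float(ac)


def compute_constrainedness_exact(instance: Instance) -> tuple[Fraction, Fraction]:
    """Exact-rational variant of :func:`compute_constrainedness`."""
    return (
        Fraction(instance.target_profit, instance.total_value),
        Fraction(instance.capacity, instance.total_weight),
    )


def verify_witness(instance: Instance, subset: Iterable[int]) -> bool:
    """Check a satisfiability certificate in O(N).

    True iff the subset's total weight is within capacity and its total
    value reaches the target profit.  The empty subset is a valid witness
    only in the (degenerate, never generated) ``p = 0`` convention, where
    both constraints hold vacuously.
    """
    idx = list(subset)
    if len(set(idx)) != len(idx):
        raise IndexError("witness contains duplicate item indices")
    for i in idx:
        if not 0 <= i < instance.n_items:
            raise IndexError(f"witness index {i} out of range")
    w = sum(instance.items[i].weight for i in idx)
    v = sum(instance.items[i].value for i in idx)
    return w <= instance.capacity and v >= instance.target_profit


def brute_force_decision(instance: Instance) -> DecisionResult:
    """Decide satisfiability by enumerating all ``2^N`` subsets.

    Subsets are enumerated in increasing order of their index bitmask
    (bit ``i`` set = item ``i`` included), and the first qualifying subset
    is returned as witness.  Effort counters reflect the full enumeration:
    ``effort_nodes = 2^N`` subsets examined, two constraint evaluations
    each.  Intended as an oracle for :func:`solve_decision`; guarded at
    ``N <= 25``.
    """
    n = instance.n_items
    if n > BRUTE_FORCE_MAX_ITEMS:
        raise SizeLimitError(
            f"brute force limited to N <= {BRUTE_FORCE_MAX_ITEMS}, got {n}"
        )
    w = np.asarray(instance.weights, dtype=np.int64)
    v = np.asarray(instance.values, dtype=np.int64)
    total = 1 << n
    witness_mask = None
    chunk = 1 << 20
    for start in range(0, total, chunk):
        masks = np.arange(start, min(start + chunk, total), dtype=np.int64)
        bits = (masks[:, None] >> np.arange(n)) & 1
        ok = (bits @ w <= instance.capacity) & (bits @ v >= instance.target_profit)
        hit = np.flatnonzero(ok)
        if hit.size and witness_mask is None:
            witness_mask = int(masks[hit[0]])
            break
    effort_checks = 2 * total
    if witness_mask is None:
        return DecisionResult(False, None, effort_nodes=total, effort_checks=effort_checks)
    witness = frozenset(i for i in range(n) if witness_mask >> i & 1)
    return DecisionResult(True, witness, effort_nodes=total, effort_checks=effort_checks)


def _density_order(instance: Instance) -> list[int]:
    # Value density descending, ties broken by original index; exact rationals
    # so the ordering (and hence every effort counter) is reproducible.
    return sorted(
        range(instance.n_items),
        key=lambda i: (-Fraction(instance.items[i].value, instance.items[i].weight), i),
    )


def solve_decision(instance: Instance) -> DecisionResult:
    """Depth-first branch and bound over include/exclude decisions.

    Items are visited in value-density-descending order (ties by original
    index), include branch first.  A child node is created only if it
    passes two bounds: the weight bound (accumulated weight within
    capacity) and the remaining-value bound (accumulated value plus all
    remaining values can still reach the target).  ``effort_nodes``
    increments once per node visited; ``effort_checks`` once per
    constraint/bound evaluation.  The verdict always agrees with
    :func:`brute_force_decision`; the returned witness (if any) is the
    first one found under this ordering.
    """
    order = _density_order(instance)
    n = instance.n_items
    w = [instance.items[i].weight for i in order]
    v = [instance.items[i].value for i in order]
    c = instance.capacity
    p = instance.target_profit
    # suffix_value[k] = total value of items k..n-1 in search order
    suffix_value = [0] * (n + 1)
    for k in range(n - 1, -1, -1):
        suffix_value[k] = suffix_value[k + 1] + v[k]

    nodes = 0
    checks = 0
    witness: frozenset[int] | None = None

    # Explicit stack: (depth, acc_weight, acc_value, chosen-depth-tuple).
    # Include branch pushed last so it is explored first.
    stack: list[tuple[int, int, int, tuple[int, ...]]] = [(0, 0, 0, ())]
    while stack:
        k, aw, av, chosen = stack.pop()
        nodes += 1
        checks += 1
        if av >= p:  # acc weight <= c holds by construction
            witness = frozenset(order[d] for d in chosen)
            break
        if k == n:
            continue
        exclude_ok = False
        checks += 1
        if av + suffix_value[k + 1] >= p:
            exclude_ok = True
        include_ok = False
        checks += 1
        if aw + w[k] <= c:
            checks += 1
            # include child's remaining-value bound: av + v[k] + suffix[k+1]
            if av + suffix_value[k] >= p:
                include_ok = True
        if exclude_ok:
            stack.append((k + 1, aw, av, chosen))
        if include_ok:
            stack.append((k + 1, aw + w[k], av + v[k], chosen + (k,)))

    if witness is None:
        return DecisionResult(False, None, effort_nodes=nodes, effort_checks=checks)
    return DecisionResult(True, witness, effort_nodes=nodes, effort_checks=checks)


def solve_optimization(
    items: Sequence[Item | tuple[int, int]], capacity: int
) -> tuple[int, frozenset[int]]:
    """Maximize total value subject to the capacity constraint.

    Classic dynamic program over weight states.  Returns the maximum
    attainable value and one achieving subset (reconstructed by
    backtracking; among optima, the one preferring to *exclude* later
    items).  ``best_value >= p`` iff the decision instance with the same
    items, capacity and target ``p`` is satisfiable.
    """
    its = [it if isinstance(it, Item) else Item(*it) for it in items]
    if capacity < 0 or int(capacity) != capacity:
        raise InvalidInstanceError("capacity must be a non-negative integer")
    capacity = int(capacity)
    n = len(its)
    dp = np.zeros(capacity + 1, dtype=np.int64)
    take = np.zeros((n, capacity + 1), dtype=bool)
    for i, it in enumerate(its):
        if it.weight <= capacity:
            cand = dp.copy()
            cand[it.weight :] = dp[: capacity + 1 - it.weight] + it.value
            take[i] = cand > dp
            dp = np.maximum(dp, cand)
    best = int(dp[capacity])
    subset = set()
    cap = capacity
    for i in range(n - 1, -1, -1):
        if take[i, cap]:
            subset.add(i)
            cap -= its[i].weight
    return best, frozenset(subset)


# ---------------------------------------------------------------------------
# Instance I/O: one CSV row per item (capacity/target repeated), or JSON with
# one object per instance.  Both round-trip losslessly.
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "instance_id",
    "item_index",
    "value",
    "weight",
    "capacity",
    "target_profit",
]


def instances_to_frame(instances: Sequence[Instance]) -> pd.DataFrame:
    rows = []
    for inst in instances:
        for j, it in enumerate(inst.items):
            rows.append(
                {
                    "instance_id": inst.id,
                    "item_index": j,
                    "value": it.value,
                    "weight": it.weight,
                    "capacity": inst.capacity,
                    "target_profit": inst.target_profit,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_instances(frame: pd.DataFrame) -> list[Instance]:
    out = []
    for iid, grp in frame.groupby("instance_id", sort=False):
        grp = grp.sort_values("item_index")
        caps = grp["capacity"].unique()
        tps = grp["target_profit"].unique()
        if len(caps) != 1 or len(tps) != 1:
            raise InvalidInstanceError(
                f"instance {iid!r}: capacity/target_profit differ across rows"
            )
        out.append(
            Instance(
                items=tuple(
                    Item(int(r.value), int(r.weight)) for r in grp.itertuples()
                ),
                capacity=int(caps[0]),
                target_profit=int(tps[0]),
                id=str(iid),
            )
        )
    return out


def write_instances_csv(instances: Sequence[Instance], path) -> None:
    instances_to_frame(instances).to_csv(path, index=False)


def read_instances_csv(path) -> list[Instance]:
    return frame_to_instances(pd.read_csv(path))


def _instance_to_dict(inst: Instance) -> dict:
    return {
        "id": inst.id,
        "items": [{"value": it.value, "weight": it.weight} for it in inst.items],
        "capacity": inst.capacity,
        "target_profit": inst.target_profit,
    }


def _instance_from_dict(d: dict) -> Instance:
    return Instance(
        items=tuple(Item(it["value"], it["weight"]) for it in d["items"]),
        capacity=d["capacity"],
        target_profit=d["target_profit"],
        id=str(d.get("id", "")),
    )


def write_instances_json(instances: Sequence[Instance], path) -> None:
    with open(path, "w") as fh:
        json.dump([_instance_to_dict(i) for i in instances], fh, indent=1)


def read_instances_json(path) -> list[Instance]:
    with open(path) as fh:
        return [_instance_from_dict(d) for d in json.load(fh)]
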