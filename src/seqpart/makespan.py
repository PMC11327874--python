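"""Balanced assignment of clusters to folds as a makespan problem.

Clusters are jobs, folds are machines. A longest-processing-time (LPT)
pass seeds the assignment; a tabu search over pairwise cluster exchanges
(including one-sided moves, modeled as swapping with a zero-weight virtual
cluster) then reduces the imbalance. Three optimization criteria are
supported:

    size_balance            max fold load − min fold load
    cluster_count_then_size lexicographic (cluster-count spread, load spread)
    label_balance           sum over class labels of the per-label spread
                            of sequence counts across folds

Cluster weights may be the raw size, ln(1 + size), or size² — down- or
up-weighting large clusters relative to small ones.

Within each fold the clusters are kept sorted by weight (descending), which
lets the optimal weight exchange between two folds be located in a single
merged pass over the two sorted lists: the global spread after exchanging
weights wa, wb is a convex piecewise-linear function of the transferred
weight delta wa − wb, so the best achievable delta is adjacent to the
continuous minimizer, which a two-pointer walk targets directly.
"""

from __future__ import annotations

import bisect
import heapq
import logging
import math
import random
from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .cluster import ClusterSet

logger = logging.getLogger(__name__)


class Weighting(str, Enum):
    IDENTITY = "identity"
    LOG = "log"
    SQUARED = "squared"


class Criterion(str, Enum):
    SIZE_BALANCE = "size_balance"
    CLUSTER_COUNT_THEN_SIZE = "cluster_count_then_size"
    LABEL_BALANCE = "label_balance"


@dataclass
class MakespanConfig:
    n_partitions: int
    weighting: Weighting = Weighting.IDENTITY
    criterion: Criterion = Criterion.SIZE_BALANCE
    max_iterations: Optional[int] = None  # default 10 * n_clusters
    tabu_tenure: int = 50
    swaps_only: bool = False
    seed: Optional[int] = None  # used only when randomize_ties is set
    randomize_ties: bool = False

    def __post_init__(self) -> None:
        self.weighting = Weighting(self.weighting)
        self.criterion = Criterion(self.criterion)
        if self.n_partitions < 2:
            raise ValueError("n_partitions must be >= 2")


def cluster_weight(size: int, weighting: Weighting | str) -> float:
    """Weight of a cluster of ``size`` sequences under the chosen scheme."""
    if size < 1:
        raise ValueError("cluster size must be >= 1")
    weighting = Weighting(weighting)
    if weighting is Weighting.LOG:
        return math.log1p(size)
    if weighting is Weighting.SQUARED:
        return float(size) ** 2
    return float(size)


@dataclass
class PartitionPlan:
    """Assignment of every cluster to one fold, with derived tallies.

    ``fold_members[f]`` holds (-weight, cluster_id) tuples kept sorted, so
    each fold lists clusters by weight descending with ties on cluster_id.
    ``loads`` are summed weights, ``counts`` cluster counts, ``label_loads``
    per-label sequence counts per fold. ``objective`` is the imbalance under
    the criterion the plan was optimized for.
    """

    n_partitions: int
    assignment: dict[int, int]
    fold_members: list[list[tuple[float, int]]]
    loads: list[float]
    counts: list[int]
    label_loads: dict[str, list[int]]
    cluster_weights: dict[int, float]
    cluster_sizes: dict[int, int]
    cluster_labels: dict[int, dict[str, int]]
    objective: object = None

    def recompute_tallies(self) -> None:
        P = self.n_partitions
        self.loads = [0.0] * P
        self.counts = [0] * P
        self.label_loads = {lab: [0] * P for lab in self.label_loads}
        for cid, fold in self.assignment.items():
            self.loads[fold] += self.cluster_weights[cid]
            self.counts[fold] += 1
            for lab, cnt in self.cluster_labels.get(cid, {}).items():
                self.label_loads.setdefault(lab, [0] * P)[fold] += cnt

    def fold_of_sequence(self, cluster_set: ClusterSet) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in cluster_set.clusters:
            fold = self.assignment[c.cluster_id]
            for sid in c.member_ids:
                out[sid] = fold
        return out


def imbalance(plan: PartitionPlan, criterion: Criterion | str):
    """Imbalance score of a plan; 0 means perfectly balanced.

    Returns a float for size_balance and label_balance, and a lexicographic
    (count spread, load spread) pair for cluster_count_then_size.
    """
    criterion = Criterion(criterion)
    load_spread = max(plan.loads) - min(plan.loads)
    if criterion is Criterion.SIZE_BALANCE:
        return load_spread
    if criterion is Criterion.CLUSTER_COUNT_THEN_SIZE:
        return (max(plan.counts) - min(plan.counts), load_spread)
    total = 0.0
    for per_fold in plan.label_loads.values():
        total += max(per_fold) - min(per_fold)
    return total


def _obj_tuple(obj) -> tuple:
    return obj if isinstance(obj, tuple) else (obj,)


def _plan_from_assignment(
    assignment: dict[int, int],
    P: int,
    weights: dict[int, float],
    sizes: dict[int, int],
    labels: dict[int, dict[str, int]],
) -> PartitionPlan:
    all_labels = sorted({lab for d in labels.values() for lab in d})
    plan = PartitionPlan(
        n_partitions=P,
        assignment=dict(assignment),
        fold_members=[[] for _ in range(P)],
        loads=[0.0] * P,
        counts=[0] * P,
        label_loads={lab: [0] * P for lab in all_labels},
        cluster_weights=weights,
        cluster_sizes=sizes,
        cluster_labels=labels,
    )
    for cid, fold in assignment.items():
        bisect.insort(plan.fold_members[fold], (-weights[cid], cid))
    plan.recompute_tallies()
    return plan


def lpt_assign(
    weights: dict[int, float],
    P: int,
    sizes: Optional[dict[int, int]] = None,
    labels: Optional[dict[int, dict[str, int]]] = None,
    rng: Optional[random.Random] = None,
) -> PartitionPlan:
    """Longest-processing-time (decreasing best first) seeding.

    Clusters are taken in decreasing weight (ties by cluster_id) and each
    is placed on the currently least-loaded fold, ties going to the lowest
    fold index (or a uniformly random tied fold when ``rng`` is given).
    """
    if not weights:
        raise ValueError("need at least one cluster")
    sizes = sizes if sizes is not None else {c: 1 for c in weights}
    labels = labels if labels is not None else {c: {} for c in weights}
    order = sorted(weights, key=lambda cid: (-weights[cid], cid))
    heap = [(0.0, f) for f in range(P)]
    heapq.heapify(heap)
    assignment: dict[int, int] = {}
    for cid in order:
        load, fold = heapq.heappop(heap)
        if rng is not None:
            tied = [fold]
            while heap and heap[0][0] == load:
                tied.append(heapq.heappop(heap)[1])
            fold = tied.pop(tied.index(rng.choice(sorted(tied))))
            for f in tied:
                heapq.heappush(heap, (load, f))
        assignment[cid] = fold
        heapq.heappush(heap, (load + weights[cid], fold))
    return _plan_from_assignment(assignment, P, dict(weights), sizes, labels)


# ---------------------------------------------------------------------------
# exchange search


@dataclass(frozen=True)
class Exchange:
    """Swap cluster_a (fold i) with cluster_b (fold j); a None side is the
    zero-weight virtual cluster, i.e. a one-sided move."""

    fold_i: int
    fold_j: int
    cluster_a: Optional[int]
    cluster_b: Optional[int]
    new_objective: object
    new_max_count: int

    @property
    def sort_key(self) -> tuple:
        return (
            _obj_tuple(self.new_objective),
            self.new_max_count,
            self.cluster_a if self.cluster_a is not None else -1,
            self.cluster_b if self.cluster_b is not None else -1,
        )


def _evaluate_exchange(
    plan: PartitionPlan,
    i: int,
    j: int,
    ca: Optional[int],
    cb: Optional[int],
    criterion: Criterion,
) -> Exchange:
    wa = plan.cluster_weights[ca] if ca is not None else 0.0
    wb = plan.cluster_weights[cb] if cb is not None else 0.0
    li = plan.loads[i] - wa + wb
    lj = plan.loads[j] - wb + wa
    ci = plan.counts[i] - (ca is not None) + (cb is not None)
    cj = plan.counts[j] - (cb is not None) + (ca is not None)

    def folded(values, vi, vj):
        lo = hi = None
        for f, v in enumerate(values):
            v = vi if f == i else vj if f == j else v
            lo = v if lo is None or v < lo else lo
            hi = v if hi is None or v > hi else hi
        return hi - lo

    counts_after = list(plan.counts)
    counts_after[i], counts_after[j] = ci, cj
    if criterion is Criterion.SIZE_BALANCE:
        obj = folded(plan.loads, li, lj)
    elif criterion is Criterion.CLUSTER_COUNT_THEN_SIZE:
        obj = (folded(plan.counts, ci, cj), folded(plan.loads, li, lj))
    else:
        total = 0.0
        for lab, per_fold in plan.label_loads.items():
            di = plan.cluster_labels.get(ca, {}).get(lab, 0) if ca is not None else 0
            dj = plan.cluster_labels.get(cb, {}).get(lab, 0) if cb is not None else 0
            total += folded(per_fold, per_fold[i] - di + dj,
                            per_fold[j] - dj + di)
        obj = total
    return Exchange(i, j, ca, cb, obj, max(counts_after))


def _spread_after_delta(plan: PartitionPlan, i: int, j: int,
                        delta: float) -> float:
    """Global load spread when weight ``delta`` moves from fold i to j."""
    li = plan.loads[i] - delta
    lj = plan.loads[j] + delta
    lo, hi = min(li, lj), max(li, lj)
    for f, v in enumerate(plan.loads):
        if f == i or f == j:
            continue
        lo = min(lo, v)
        hi = max(hi, v)
    return hi - lo


def _best_exchange_sorted(plan: PartitionPlan, i: int, j: int,
                          criterion: Criterion,
                          swaps_only: bool) -> Optional[Exchange]:
    """Single merged pass over the two weight-sorted folds.

    The load spread after moving net weight delta = wa − wb is convex in
    delta, so the walk targets the continuous minimizer t and evaluates the
    candidates whose deltas bracket it. One-sided moves enter as virtual
    zero-weight clusters. For cluster_count_then_size the swap candidates
    (count-neutral) use the same walk and the one-sided moves are scanned
    separately with the full lexicographic objective.
    """
    li, lj = plan.loads[i], plan.loads[j]
    others = [v for f, v in enumerate(plan.loads) if f != i and f != j]
    cand_t = [(li - lj) / 2.0]
    if others:
        mo, Mo = min(others), max(others)
        cand_t += [li - Mo, Mo - lj, li - mo, mo - lj]
    t = min(cand_t, key=lambda d: _spread_after_delta(plan, i, j, d))

    # fold_members store (-weight, cid) sorted ascending, i.e. weight
    # descending; unpack to (weight, cid)
    A: list[tuple[float, Optional[int]]] = [
        (-nw, cid) for nw, cid in plan.fold_members[i]
    ]
    B: list[tuple[float, Optional[int]]] = [
        (-nw, cid) for nw, cid in plan.fold_members[j]
    ]
    if not swaps_only:
        A = A + [(0.0, None)]
        B = B + [(0.0, None)]

    best: Optional[Exchange] = None
    p = q = 0
    while p < len(A) and q < len(B):
        wa, ca = A[p]
        wb, cb = B[q]
        if not (ca is None and cb is None):
            ex = _evaluate_exchange(plan, i, j, ca, cb, criterion)
            if best is None or ex.sort_key < best.sort_key:
                best = ex
        if wa - wb > t:
            p += 1
        else:
            q += 1
    if criterion is Criterion.CLUSTER_COUNT_THEN_SIZE and not swaps_only:
        # one-sided moves change cluster counts; scan them explicitly
        for wa, ca in A[:-1]:
            ex = _evaluate_exchange(plan, i, j, ca, None, criterion)
            if best is None or ex.sort_key < best.sort_key:
                best = ex
        for wb, cb in B[:-1]:
            ex = _evaluate_exchange(plan, i, j, None, cb, criterion)
            if best is None or ex.sort_key < best.sort_key:
                best = ex
    return best


def _best_exchange_exhaustive(plan: PartitionPlan, i: int, j: int,
                              criterion: Criterion,
                              swaps_only: bool) -> Optional[Exchange]:
    A: list[Optional[int]] = [cid for _, cid in plan.fold_members[i]]
    B: list[Optional[int]] = [cid for _, cid in plan.fold_members[j]]
    if not swaps_only:
        A = A + [None]
        B = B + [None]
    best: Optional[Exchange] = None
    for ca in A:
        for cb in B:
            if ca is None and cb is None:
                continue
            ex = _evaluate_exchange(plan, i, j, ca, cb, criterion)
            if best is None or ex.sort_key < best.sort_key:
                best = ex
    return best


def best_exchange(plan: PartitionPlan, i: int, j: int,
                  criterion: Criterion | str,
                  swaps_only: bool = False) -> Optional[Exchange]:
    """Best exchange between folds i and j under the global objective.

    Returns the candidate minimizing the post-exchange objective (ties
    resolved toward lower maximum per-fold cluster count, then by cluster
    id), or None when no exchange beats or ties the current objective.
    Weight-spread criteria use the sorted single-pass search; label_balance
    has no single-number transfer structure and scans all pairs.
    """
    criterion = Criterion(criterion)
    if criterion is Criterion.LABEL_BALANCE:
        cand = _best_exchange_exhaustive(plan, i, j, criterion, swaps_only)
    else:
        cand = _best_exchange_sorted(plan, i, j, criterion, swaps_only)
    if cand is None:
        return None
    current = _obj_tuple(imbalance(plan, criterion))
    cand_obj = _obj_tuple(cand.new_objective)
    if cand_obj > current:
        return None
    if cand_obj == current and cand.new_max_count >= max(plan.counts):
        return None  # a tie is only useful if it frees up a crowded fold
    return cand


def _apply_exchange(plan: PartitionPlan, ex: Exchange) -> None:
    i, j = ex.fold_i, ex.fold_j
    if ex.cluster_a is not None:
        w = plan.cluster_weights[ex.cluster_a]
        plan.fold_members[i].remove((-w, ex.cluster_a))
        bisect.insort(plan.fold_members[j], (-w, ex.cluster_a))
        plan.assignment[ex.cluster_a] = j
    if ex.cluster_b is not None:
        w = plan.cluster_weights[ex.cluster_b]
        plan.fold_members[j].remove((-w, ex.cluster_b))
        bisect.insort(plan.fold_members[i], (-w, ex.cluster_b))
        plan.assignment[ex.cluster_b] = i
    plan.recompute_tallies()


def _pair_identity(ex: Exchange) -> frozenset:
    a = ("c", ex.cluster_a) if ex.cluster_a is not None else ("v", ex.fold_i)
    b = ("c", ex.cluster_b) if ex.cluster_b is not None else ("v", ex.fold_j)
    return frozenset((a, b))


def tabu_search(plan: PartitionPlan, config: MakespanConfig) -> PartitionPlan:
    """Iteratively apply the globally best improving exchange.

    Each iteration scans all fold pairs with :func:`best_exchange` and
    applies the strictly best improving exchange. When only equal-objective
    exchanges remain, one is accepted if it strictly reduces the maximum
    per-fold cluster count (keeping folds flexible for later exchanges) and
    its cluster pair has not been exchanged recently (FIFO tabu memory).
    Terminates when neither applies, or after ``max_iterations``. The final
    objective is never worse than the initial one.
    """
    criterion = config.criterion
    max_iter = config.max_iterations
    if max_iter is None:
        max_iter = 10 * len(plan.assignment)
    tabu: deque[frozenset] = deque(maxlen=config.tabu_tenure)
    plan.objective = imbalance(plan, criterion)
    for it in range(max_iter):
        candidates: list[Exchange] = []
        for i in range(plan.n_partitions):
            for j in range(i + 1, plan.n_partitions):
                ex = best_exchange(plan, i, j, criterion, config.swaps_only)
                if ex is not None:
                    candidates.append(ex)
        if not candidates:
            break
        candidates.sort(key=lambda e: e.sort_key)
        current = _obj_tuple(plan.objective)
        chosen: Optional[Exchange] = None
        for ex in candidates:
            if _obj_tuple(ex.new_objective) < current:
                chosen = ex
                break
            # equal objective: accept only the flexibility-improving,
            # non-tabu exchanges
            if (ex.new_max_count < max(plan.counts)
                    and _pair_identity(ex) not in tabu):
                chosen = ex
                break
        if chosen is None:
            break
        _apply_exchange(plan, chosen)
        plan.objective = imbalance(plan, criterion)
        tabu.append(_pair_identity(chosen))
        logger.debug(
            "iteration %d: exchanged %s (fold %d) and %s (fold %d), "
            "objective %s",
            it, chosen.cluster_a, chosen.fold_i, chosen.cluster_b,
            chosen.fold_j, plan.objective,
        )
    return plan


def partition_clusters(cluster_set: ClusterSet,
                       config: MakespanConfig) -> PartitionPlan:
    """Weight clusters, seed with LPT and refine with tabu search."""
    C = len(cluster_set.clusters)
    P = config.n_partitions
    if P > C:
        logger.warning(
            "%d folds requested but only %d clusters: some folds will be "
            "empty", P, C,
        )
    weights = {
        c.cluster_id: cluster_weight(c.size, config.weighting)
        for c in cluster_set.clusters
    }
    sizes = {c.cluster_id: c.size for c in cluster_set.clusters}
    labels = {c.cluster_id: dict(c.label_counts)
              for c in cluster_set.clusters}
    total = sum(weights.values())
    if max(weights.values()) > total / P:
        logger.warning(
            "largest cluster carries %.1f%% of the total weight: balance is "
            "limited by cluster granularity",
            100.0 * max(weights.values()) / total,
        )
    rng = None
    if config.randomize_ties and config.seed is not None:
        rng = random.Random(config.seed)
    plan = lpt_assign(weights, P, sizes=sizes, labels=labels, rng=rng)
    plan.objective = imbalance(plan, config.criterion)
    return tabu_search(plan, config)
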