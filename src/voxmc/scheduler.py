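"""Three-layer load balancing: thread heuristic, workgroup pools, device partitioning.

* :func:`optimal_thread_count` — the balanced thread-count heuristic
  (max concurrent threads per compute unit times available compute units).
* :func:`run_group_pool` — the in-workgroup dynamic pool: threads atomically
  claim photons from a shared counter until it is empty.
* :func:`calibrate` / :func:`partition` — device-level partitioning of the
  total photon count under the linear runtime model ``T = a * n + T0``,
  with strategies S1 (proportional to cores), S2 (proportional to
  throughput 1/a), and S3 (minimax makespan).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DeviceProfile",
    "WorkPartition",
    "GroupPool",
    "optimal_thread_count",
    "calibrate",
    "pilot_photon_counts",
    "partition",
    "predicted_makespan",
    "run_group_pool",
    "DEFAULT_WORKGROUP_SIZE",
    "STRATEGIES",
]

STRATEGIES = ("S1", "S2", "S3")
DEFAULT_WORKGROUP_SIZE = 64

#: Default pilot photon counts for runtime-model calibration.
PILOT_N1 = 1_000_000
PILOT_N2 = 5_000_000


@dataclass(frozen=True)
class DeviceProfile:
    """One compute device under the linear runtime model ``T = a * n + T0``.

    ``a`` is the runtime slope in ms per photon, ``T0`` the fixed overhead in
    ms; both are device-dependent and obtained from pilot runs.
    """

    name: str
    cores: int
    max_threads_per_cu: int = 1
    num_cus: int = 1
    a: float = 1.0
    T0: float = 0.0

    def __post_init__(self) -> None:
        if self.cores < 1:
            raise ValueError("cores must be >= 1")
        if self.max_threads_per_cu < 1 or self.num_cus < 1:
            raise ValueError("thread/CU counts must be >= 1")
        if self.a <= 0:
            raise ValueError("runtime slope a must be > 0")
        if self.T0 < 0:
            raise ValueError("overhead T0 must be >= 0")

    def predict_runtime(self, n: int) -> float:
        """Predicted runtime in ms for a workload of ``n`` photons."""
        return self.a * n + self.T0 if n > 0 else 0.0


@dataclass
class WorkPartition:
    """Integer photon allocations per device, summing to the requested total."""

    allocations: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.allocations.values())

    def as_array(self, ndevices: int) -> np.ndarray:
        return np.array([self.allocations.get(i, 0) for i in range(ndevices)],
                        dtype=np.int64)


@dataclass
class GroupPool:
    """Shared counter of unstarted photons in one workgroup."""

    remaining: int

    def __post_init__(self) -> None:
        if self.remaining < 0:
            raise ValueError("remaining must be >= 0")

    def claim(self) -> bool:
        """Claim one photon; returns False when the pool is empty."""
        if self.remaining <= 0:
            return False
        self.remaining -= 1
        return True


def optimal_thread_count(profile: DeviceProfile) -> int:
    """Balanced thread count: max concurrent threads per CU times CU count."""
    return profile.max_threads_per_cu * profile.num_cus


def calibrate(pilot_runs) -> tuple[float, float]:
    """Fit the runtime model ``T = a * n + T0`` through two pilot runs.

    Exact two-point fit; a negative intercept is clamped to 0 with a warning
    (the model requires non-negative overhead), and a non-positive slope is
    rejected.
    """
    (n1, t1), (n2, t2) = pilot_runs
    if n1 == n2:
        raise ValueError("pilot photon counts must be distinct")
    if t1 < 0 or t2 < 0:
        raise ValueError("pilot runtimes must be >= 0")
    a = (t2 - t1) / (n2 - n1)
    if a <= 0:
        raise ValueError(f"fitted slope a = {a} must be > 0")
    t0 = t1 - a * n1
    if t0 < 0:
        warnings.warn(f"fitted overhead T0 = {t0:.6g} ms < 0; clamping to 0",
                      stacklevel=2)
        t0 = 0.0
    return a, t0


def pilot_photon_counts(total: int) -> tuple[int, int]:
    """Pilot sizes for calibration: (1e6, 5e6), scaled down for small totals."""
    if total >= 10 * PILOT_N1:
        return PILOT_N1, PILOT_N2
    scale = total / (10 * PILOT_N1)
    return max(1, int(round(PILOT_N1 * scale))), max(2, int(round(PILOT_N2 * scale)))


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative real shares (summing to ``total``) to integers
    preserving the sum, assigning leftovers to the largest fractional parts."""
    shares = np.maximum(shares, 0.0)
    floors = np.floor(shares).astype(np.int64)
    deficit = total - int(floors.sum())
    if deficit > 0:
        frac = shares - floors
        order = np.argsort(-frac, kind="stable")
        for j in range(deficit):
            floors[order[j % len(floors)]] += 1
    elif deficit < 0:  # float round-up pathologies; shave from largest
        order = np.argsort(-floors, kind="stable")
        j = 0
        while deficit < 0:
            i = order[j % len(floors)]
            if floors[i] > 0:
                floors[i] -= 1
                deficit += 1
            j += 1
    return floors


def _minimax_continuous(total: int, profiles: list[DeviceProfile]) -> np.ndarray:
    """Continuous minimax allocation: equalize ``a_i n_i + T0_i`` among active
    devices, dropping devices whose overhead already exceeds the optimal
    makespan."""
    m = len(profiles)
    order = sorted(range(m), key=lambda i: profiles[i].T0)
    inv_a_sum = 0.0
    t0_over_a_sum = 0.0
    best = None
    for k, i in enumerate(order):
        p = profiles[i]
        inv_a_sum += 1.0 / p.a
        t0_over_a_sum += p.T0 / p.a
        makespan = (total + t0_over_a_sum) / inv_a_sum
        next_t0 = profiles[order[k + 1]].T0 if k + 1 < m else np.inf
        if makespan >= p.T0 and makespan <= next_t0:
            best = (makespan, k)
            break
    if best is None:  # numerically degenerate; fall back to all active
        makespan = (total + t0_over_a_sum) / inv_a_sum
        best = (makespan, m - 1)
    makespan, k = best
    shares = np.zeros(m)
    for i in order[: k + 1]:
        shares[i] = max(0.0, (makespan - profiles[i].T0) / profiles[i].a)
    return shares


def partition(total: int, profiles: list[DeviceProfile],
              strategy: str = "S3") -> WorkPartition:
    """Partition ``total`` photons across devices.

    S1 allocates proportional to core counts, S2 proportional to throughput
    ``1/a``, and S3 minimizes the makespan ``max_i (a_i n_i + T0_i)`` subject
    to the allocations summing to the total.  All strategies return
    non-negative integers summing exactly to ``total`` (largest-remainder
    rounding).
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")

    if strategy == "S1":
        weights = np.array([p.cores for p in profiles], dtype=float)
        shares = total * weights / weights.sum()
    elif strategy == "S2":
        weights = np.array([1.0 / p.a for p in profiles])
        shares = total * weights / weights.sum()
    else:
        shares = _minimax_continuous(total, profiles)

    counts = _largest_remainder(shares, total)
    return WorkPartition(allocations={i: int(c) for i, c in enumerate(counts)})


def predicted_makespan(partition: WorkPartition,
                       profiles: list[DeviceProfile]) -> float:
    """Finish time of the slowest device: ``max_i (a_i n_i + T0_i)``.

    Devices allocated zero photons never launch and contribute no overhead.
    """
    times = [profiles[i].predict_runtime(n)
             for i, n in partition.allocations.items()]
    return max(times) if times else 0.0


def run_group_pool(group_total: int, workers: int, per_photon_cost) -> np.ndarray:
    """Simulate the in-workgroup dynamic photon pool.

    Workers repeatedly claim photons from a shared counter until it is empty:
    whenever a worker finishes its current photon it claims the next one, so
    each photon is started exactly once and fast workers absorb the heavy
    tail.  Returns how many photons each worker ran (summing to
    ``group_total``).

    ``per_photon_cost`` is a callable ``i -> cost`` or a sequence of costs
    indexed by claim order.
    """
    if group_total < 0:
        raise ValueError("group_total must be >= 0")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    cost = per_photon_cost if callable(per_photon_cost) else per_photon_cost.__getitem__

    counts = np.zeros(workers, dtype=np.int64)
    pool = GroupPool(remaining=group_total)
    # earliest-finish-first claim order; ties broken by worker index
    heap = [(0.0, w) for w in range(workers)]
    heapq.heapify(heap)
    i = 0
    while pool.claim():
        t, w = heapq.heappop(heap)
        counts[w] += 1
        heapq.heappush(heap, (t + float(cost(i)), w))
        i += 1
    return counts


def pool_makespan(group_total: int, workers: int, costs) -> float:
    """Finish time of the slowest worker under the dynamic pool policy."""
    cost = costs if callable(costs) else costs.__getitem__
    times = np.zeros(workers)
    heap = [(0.0, w) for w in range(workers)]
    heapq.heapify(heap)
    for i in range(group_total):
        t, w = heapq.heappop(heap)
        t += float(cost(i))
        times[w] = t
        heapq.heappush(heap, (t, w))
    return float(times.max()) if group_total else 0.0


def static_split_makespan(group_total: int, workers: int, costs) -> float:
    """Finish time of the slowest worker under an equal static split.

    Photons are dealt round-robin (photon ``i`` to worker ``i % workers``),
    the equal-share static policy the dynamic pool is compared against.
    """
    cost = costs if callable(costs) else costs.__getitem__
    times = np.zeros(workers)
    for i in range(group_total):
        times[i % workers] += float(cost(i))
    return float(times.max()) if group_total else 0.0
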