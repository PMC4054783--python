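"""Concordance between motif catalogues and true-pool size estimation.

If several screens for exonic splice enhancers are sampling the same
underlying pool of true motifs, their catalogues should share more hexamers
than independent uniform draws from the 4,096-hexamer universe would.  This
module quantifies that sharing against three nulls:

* ``uniform_universe`` -- each catalogue an independent uniform draw
  (without replacement) from all 4,096 hexamers;
* ``nominated_pool`` -- draws from the union of motifs nominated by any
  screen (e.g. the 905 distinct hexamers nominated by the four screens);
* ``true_pool`` -- draws from a hypothetical pool of true ESEs of a given
  size, which can be inverted to estimate how large the true pool must be
  to explain an observed k-way intersection (capture-recapture logic).

Expectations have closed forms: two samples of sizes n1, n2 drawn uniformly
without replacement from N share hypergeometrically distributed motifs with
mean ``n1*n2/N``; k independent samples share ``N * prod(n_i/N)`` on
average.  Monte Carlo simulation supplies standard deviations, Z-scores and
empirical tail probabilities.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .motif_sets import HEXAMER_UNIVERSE, HexamerSet, intersect_at_least

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapNull:
    """Specification of the null model for catalogue overlap.

    ``kind`` is one of ``uniform_universe``, ``nominated_pool`` or
    ``true_pool``; ``universe_size`` is the number of motifs sampled from
    (4,096 for the uniform null, the pool size otherwise).
    """

    kind: str = "uniform_universe"
    universe_size: int = HEXAMER_UNIVERSE
    reps: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in {"uniform_universe", "nominated_pool", "true_pool"}:
            raise ValueError(f"unknown null kind {self.kind!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")

    @classmethod
    def from_pool(cls, pool: "HexamerSet | int", kind: str = "nominated_pool",
                  reps: int = 10_000, seed: Optional[int] = None) -> "OverlapNull":
        size = len(pool) if isinstance(pool, HexamerSet) else int(pool)
        return cls(kind=kind, universe_size=size, reps=reps, seed=seed)


@dataclass(frozen=True)
class OverlapResult:
    """Observed vs simulated-null intersection of a group of catalogues."""

    observed: int
    expected_mean: float
    expected_sd: float
    fold: float
    z: float
    p: float            # empirical upper-tail probability
    p_label: str        # "<1/reps" style bound when no exceedances
    reps: int


def expected_pairwise_overlap(n1: int, n2: int, universe: int = HEXAMER_UNIVERSE) -> float:
    """Expected overlap of two uniform random catalogues of sizes n1, n2.

    The overlap of two independent without-replacement draws from a
    universe of N motifs is hypergeometric with mean ``n1*n2/N``.
    """
    if universe <= 0:
        raise ValueError("universe size must be positive")
    if n1 > universe or n2 > universe:
        raise ValueError("sample size exceeds the universe")
    return n1 * n2 / universe


def pairwise_overlap_sd(n1: int, n2: int, universe: int = HEXAMER_UNIVERSE) -> float:
    """Standard deviation of the hypergeometric pairwise overlap."""
    N = universe
    var = (n1 * n2 / N) * ((N - n1) / N) * ((N - n2) / (N - 1))
    return math.sqrt(var)


def expected_multiway_overlap(sizes: Sequence[int], universe: int = HEXAMER_UNIVERSE) -> float:
    """Expected k-way intersection of independent uniform draws.

    Each motif is in sample i with probability ``n_i/N`` independently
    across samples, giving ``N * prod(n_i/N)`` motifs in all k samples on
    average.
    """
    if universe <= 0:
        raise ValueError("universe size must be positive")
    if not sizes:
        raise ValueError("need at least one sample size")
    if any(n > universe for n in sizes):
        raise ValueError("sample size exceeds the universe")
    prod = 1.0
    for n in sizes:
        prod *= n / universe
    return universe * prod


def _simulate_intersections(
    sizes: Sequence[int], universe: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulated k-way intersection sizes of uniform draws, one per rep."""
    k = len(sizes)
    out = np.empty(reps, dtype=np.int64)
    counts = np.zeros(universe, dtype=np.int8)
    for i in range(reps):
        counts[:] = 0
        for n in sizes:
            counts[rng.choice(universe, size=n, replace=False)] += 1
        out[i] = int((counts == k).sum())
    return out


def simulate_overlap(
    sizes: Sequence[int],
    null: OverlapNull,
    observed: int,
) -> OverlapResult:
    """Monte Carlo intersection test for catalogues of the given sizes.

    Draws ``null.reps`` replicate groups of catalogues, each of the stated
    sizes, uniformly without replacement from the null universe; records
    the k-way intersection size per replicate.  The empirical P is the
    upper-tail fraction of replicates with intersections at least as large
    as observed; when no replicate reaches it, P is reported as the bound
    ``1/reps`` with label ``"<1/reps"``.
    """
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if any(n > null.universe_size for n in sizes):
        raise ValueError("sample size exceeds the null universe")
    rng = np.random.default_rng(null.seed)
    inter = _simulate_intersections(sizes, null.universe_size, null.reps, rng)
    mean = float(inter.mean())
    sd = float(inter.std(ddof=1)) if null.reps > 1 else 0.0
    fold = observed / mean if mean > 0 else math.inf if observed else 0.0
    z = (observed - mean) / sd if sd > 0 else math.nan
    exceed = int((inter >= observed).sum())
    if exceed == 0:
        p = 1.0 / null.reps
        p_label = f"<{1.0 / null.reps:g}"
    else:
        p = exceed / null.reps
        p_label = f"{p:g}"
    return OverlapResult(observed, mean, sd, fold, z, p, p_label, null.reps)


def observed_overlap(sets: Sequence[HexamerSet]) -> int:
    """Size of the full intersection of the given catalogues."""
    return len(intersect_at_least(list(sets), len(sets)))


def estimate_pool_size(
    sizes: Sequence[int],
    target_intersection: float,
    reps: int = 3_000,
    seed: Optional[int] = None,
    round_to: int = 10,
) -> int:
    """Pool size whose expected k-way intersection matches a target.

    Given catalogue sizes and an observed intersection, finds the integer
    pool size N such that k random samples of those sizes drawn from a pool
    of N motifs intersect in ``target_intersection`` motifs on average.
    The analytic expectation ``N * prod(n_i/N)`` seeds the search at
    ``(prod n_i / target)^(1/(k-1))``; integer bisection on the simulated
    expected intersection (which is strictly decreasing in N) refines it.
    The result is rounded to the nearest ``round_to``.
    """
    if not sizes:
        raise ValueError("need at least one sample size")
    if target_intersection < 1:
        raise ValueError("target intersection must be >= 1")
    if target_intersection > min(sizes):
        raise ValueError("target intersection cannot exceed the smallest catalogue")
    k = len(sizes)
    if k < 2:
        raise ValueError("need at least two catalogues to estimate a pool")
    prod = math.prod(sizes)
    n0 = (prod / target_intersection) ** (1.0 / (k - 1))
    lo = max(sizes)
    hi = max(int(2 * n0), lo + 1)
    ss = np.random.SeedSequence(seed)

    def sim_mean(n: int) -> float:
        rng = np.random.default_rng(ss.spawn(1)[0])
        return float(_simulate_intersections(sizes, n, reps, rng).mean())

    # expand hi until the expected intersection drops below target
    while sim_mean(hi) > target_intersection:
        lo = hi
        hi *= 2
    while hi - lo > max(1, round_to // 2):
        mid = (lo + hi) // 2
        if sim_mean(mid) > target_intersection:
            lo = mid
        else:
            hi = mid
    est = (lo + hi) / 2
    return int(round(est / round_to) * round_to)


def contribution_zscores(
    sets: Sequence[HexamerSet],
    k: int,
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> dict:
    """Per-catalogue Z for membership in the >=k-way intersection.

    For each input catalogue, compares the observed number of its motifs
    that fall inside the >=k-way intersection of all the catalogues against
    a simulated null in which same-sized catalogues are drawn uniformly
    from the 4,096-hexamer universe.  Returns
    ``{name: {"observed", "expected_mean", "expected_sd", "z"}}``; Z is
    NaN (with a warning) when the null standard deviation is zero.
    """
    if len(sets) < k:
        raise ValueError("need at least k catalogues")
    inter = intersect_at_least(list(sets), k)
    observed = [len(s.motifs & inter.motifs) for s in sets]

    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in sets]
    universe = HEXAMER_UNIVERSE
    null_counts = np.empty((reps, len(sets)), dtype=np.int64)
    membership = np.zeros(universe, dtype=np.int8)
    samples: list = [None] * len(sets)
    for r in range(reps):
        membership[:] = 0
        for j, n in enumerate(sizes):
            samples[j] = rng.choice(universe, size=n, replace=False)
            membership[samples[j]] += 1
        in_inter = membership >= k
        for j in range(len(sets)):
            null_counts[r, j] = int(in_inter[samples[j]].sum())

    result = {}
    for j, s in enumerate(sets):
        mean = float(null_counts[:, j].mean())
        sd = float(null_counts[:, j].std(ddof=1))
        if sd == 0:
            warnings.warn(f"degenerate null for {s.name}: sd = 0, Z undefined")
            z = math.nan
        else:
            z = (observed[j] - mean) / sd
        result[s.name] = {
            "observed": observed[j],
            "expected_mean": mean,
            "expected_sd": sd,
            "z": z,
        }
    return result
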