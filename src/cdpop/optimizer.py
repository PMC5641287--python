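"""Calibration-set selection: exchange algorithm, baselines, brute force.

The exchange algorithm is a stochastic local search over fixed-size
subsets of a candidate pool: at each step one selected individual and
one excluded individual are swapped at random, and the swap is kept if
and only if it strictly improves the criterion. Restarts guard against
local optima; a greedy warm start based on mean relatedness to the
target set (Crit_Kin) is available as an alternative initialization.

The baseline samplers mirror the sampling strategies the CD criteria are
benchmarked against: uniform random, stratified with equal family
quotas, and stratified with quotas proportional to family size
(largest-remainder rounding in both cases). ``brute_force_optimize``
enumerates all subsets and serves as the exact oracle at small sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np

from .genotypes import KinshipMatrix

Criterion = Callable[[list[str]], float]

#: subsets above this count are refused by the exhaustive search
BRUTE_FORCE_GUARD = 10_000


@dataclass
class OptimizerConfig:
    """Stopping and initialization settings of the exchange search.

    ``max_iterations`` defaults to ``max(10000, 100 * size)`` proposals
    per restart; ``patience`` stops a restart after that many consecutive
    rejections. ``init='crit_kin_warm'`` seeds the first restart with the
    greedy maximum-relatedness set (remaining restarts stay random).
    """

    size: int
    max_iterations: int | None = None
    patience: int = 2000
    restarts: int = 5
    seed: int = 0
    init: str = "random"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.init not in ("random", "crit_kin_warm"):
            raise ValueError(f"unknown init {self.init!r}")

    def resolved_max_iterations(self) -> int:
        if self.max_iterations is not None:
            return self.max_iterations
        return max(10_000, 100 * self.size)


@dataclass
class CalibrationDesign:
    """A selected calibration set and how it was found.

    ``trace`` records the accepted steps only, as (iteration, accepted,
    criterion value) triples; rejected proposals leave gaps in the
    iteration numbers.
    """

    selected_ids: list[str]
    criterion_name: str
    criterion_value: float
    trace: list[tuple[int, bool, float]] = field(default_factory=list)
    seed: int = 0


def greedy_crit_kin_start(
    K: KinshipMatrix,
    candidate_ids: Sequence[str],
    target_ids: Sequence[str],
    size: int,
) -> list[str]:
    """Greedy maximizer of mean calibration-target relatedness.

    Because the mean relationship is additive over calibration members,
    greedy insertion reduces to taking the ``size`` candidates with the
    highest mean relationship to the target set (stable order on ties).
    """
    candidate_ids = [str(i) for i in candidate_ids]
    ci = K.indices(candidate_ids)
    ti = K.indices(list(target_ids))
    score = K.K[np.ix_(ci, ti)].mean(axis=1)
    order = np.argsort(-score, kind="stable")[:size]
    chosen = set(order.tolist())
    return [c for k, c in enumerate(candidate_ids) if k in chosen]


def exchange_optimize(
    candidate_ids: Sequence[str],
    criterion: Criterion,
    config: OptimizerConfig,
    criterion_name: str = "criterion",
    kinship: KinshipMatrix | None = None,
    target_ids: Sequence[str] | None = None,
) -> CalibrationDesign:
    """Maximize a subset criterion by random single-individual exchanges.

    Swaps are accepted only on strict improvement (ties rejected, which
    prevents cycling). Each restart runs until ``max_iterations``
    proposals or ``patience`` consecutive rejections; the best restart is
    returned. Fully reproducible from ``config.seed``. ``kinship`` and
    ``target_ids`` are only needed for the ``crit_kin_warm`` start.
    """
    candidate_ids = [str(i) for i in candidate_ids]
    n = len(candidate_ids)
    if config.size >= n:
        raise ValueError(f"size {config.size} must be < candidate pool size {n}")
    if config.init == "crit_kin_warm" and (kinship is None or target_ids is None):
        raise ValueError("crit_kin_warm initialization needs kinship and target_ids")
    max_iter = config.resolved_max_iterations()
    ss = np.random.SeedSequence(config.seed)
    best: CalibrationDesign | None = None
    for r, child in enumerate(ss.spawn(config.restarts)):
        rng = np.random.default_rng(child)
        if r == 0 and config.init == "crit_kin_warm":
            selected = list(
                greedy_crit_kin_start(kinship, candidate_ids, target_ids, config.size)
            )
        else:
            selected = [
                candidate_ids[k]
                for k in rng.choice(n, size=config.size, replace=False)
            ]
        excluded = [c for c in candidate_ids if c not in set(selected)]
        value = float(criterion(list(selected)))
        trace: list[tuple[int, bool, float]] = [(0, True, value)]
        rejections = 0
        for it in range(1, max_iter + 1):
            i = int(rng.integers(len(selected)))
            j = int(rng.integers(len(excluded)))
            proposal = list(selected)
            proposal[i] = excluded[j]
            new_value = float(criterion(proposal))
            if new_value > value:
                selected[i], excluded[j] = excluded[j], selected[i]
                value = new_value
                trace.append((it, True, value))
                rejections = 0
            else:
                rejections += 1
                if rejections >= config.patience:
                    break
        pool_order = {c: k for k, c in enumerate(candidate_ids)}
        design = CalibrationDesign(
            selected_ids=sorted(selected, key=pool_order.get),
            criterion_name=criterion_name,
            criterion_value=value,
            trace=trace,
            seed=config.seed,
        )
        if best is None or design.criterion_value > best.criterion_value:
            best = design
    return best


def brute_force_optimize(
    candidate_ids: Sequence[str],
    size: int,
    criterion: Criterion,
    criterion_name: str = "criterion",
) -> CalibrationDesign:
    """Exact maximizer by enumeration of all subsets (test oracle).

    Refuses instances with more than ``BRUTE_FORCE_GUARD`` subsets; use
    ``exchange_optimize`` beyond that. Ties are broken lexicographically
    (the first maximizer in combination order wins).
    """
    candidate_ids = [str(i) for i in candidate_ids]
    n_subsets = math.comb(len(candidate_ids), size)
    if n_subsets > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"{n_subsets} subsets exceed the exhaustive-search guard of "
            f"{BRUTE_FORCE_GUARD}; use exchange_optimize instead"
        )
    if n_subsets == 0:
        raise ValueError("size exceeds the candidate pool")
    best_ids: list[str] | None = None
    best_value = -np.inf
    for subset in combinations(candidate_ids, size):
        value = float(criterion(list(subset)))
        if value > best_value:
            best_value = value
            best_ids = list(subset)
    return CalibrationDesign(
        selected_ids=best_ids,
        criterion_name=criterion_name,
        criterion_value=best_value,
        trace=[(0, True, best_value)],
    )


def _largest_remainder_quotas(
    raw: np.ndarray, total: int, rng: np.random.Generator
) -> np.ndarray:
    base = np.floor(raw).astype(int)
    remainder = total - int(base.sum())
    frac = raw - base
    # seeded permutation breaks ties between equal fractional parts
    order = rng.permutation(len(raw))
    order = order[np.argsort(-frac[order], kind="stable")]
    base[order[:remainder]] += 1
    return base


def sample_baseline(
    candidate_ids: Sequence[str],
    size: int,
    method: str,
    family_of: Mapping[str, str] | None = None,
    seed: int = 0,
) -> CalibrationDesign:
    """Reference samplers: uniform random and the two stratified schemes.

    ``stratified_equal`` aims at the same quota in every family,
    ``stratified_size`` at quotas proportional to family sizes; both
    round by the largest-remainder rule with seeded tie-breaking, then
    sample uniformly without replacement inside each family.
    """
    candidate_ids = [str(i) for i in candidate_ids]
    if not 1 <= size <= len(candidate_ids):
        raise ValueError(f"size {size} out of range for pool of {len(candidate_ids)}")
    rng = np.random.default_rng(seed)
    if method == "random":
        chosen = [candidate_ids[k] for k in rng.choice(len(candidate_ids), size, replace=False)]
    elif method in ("stratified_equal", "stratified_size"):
        if family_of is None:
            raise ValueError(f"{method} requires family labels")
        members: dict[str, list[str]] = {}
        for c in candidate_ids:
            try:
                members.setdefault(family_of[c], []).append(c)
            except KeyError:
                raise ValueError(f"candidate {c!r} has no family label") from None
        families = sorted(members)
        sizes = np.array([len(members[f]) for f in families], dtype=float)
        if method == "stratified_equal":
            raw = np.full(len(families), size / len(families))
        else:
            raw = size * sizes / sizes.sum()
        quotas = _largest_remainder_quotas(raw, size, rng)
        for f, q, s in zip(families, quotas, sizes.astype(int)):
            if q > s:
                raise ValueError(
                    f"family {f!r} has {s} candidates but a quota of {q}"
                )
        chosen = []
        for f, q in zip(families, quotas):
            fam = members[f]
            chosen.extend(fam[k] for k in rng.choice(len(fam), q, replace=False))
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    pool_order = {c: k for k, c in enumerate(candidate_ids)}
    return CalibrationDesign(
        selected_ids=sorted(chosen, key=pool_order.get),
        criterion_name=method,
        criterion_value=float("nan"),
        trace=[],
        seed=seed,
    )
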