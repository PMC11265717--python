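"""NSGA-II and NSGA-III selection machinery and the generation loop.

Both algorithms share the elitist skeleton: at each iteration the population
is doubled by binary tournament selection, crossover, and mutation; the
combined pool is partitioned by repeated non-dominated sorting into
successive Pareto fronts; and whole fronts are admitted into the next
generation until the size limit, with the last partially-admitted front
truncated by crowding distance (NSGA-II) or by reference-direction niching
(NSGA-III, for higher-dimensional objective spaces).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from modesign.core import Population, SequenceIndividual
from modesign.scoring import ScorerBundle, assemble_objectives
from modesign.variation import VariationBundle


# ---------------------------------------------------------------------------
# domination and sorting
# ---------------------------------------------------------------------------

def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff ``a`` is no worse than ``b`` on every objective and strictly
    better on at least one (minimization framing)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal dimension")
    return bool(np.all(a <= b) and np.any(a < b))


@dataclass
class FrontPartition:
    """Pool indices partitioned into successive non-dominated fronts;
    ``fronts[0]`` is the non-dominated set of the whole pool."""

    fronts: list[list[int]]

    def ranks(self, n: int) -> np.ndarray:
        r = np.empty(n, dtype=int)
        for k, front in enumerate(self.fronts):
            r[front] = k
        return r


def non_dominated_sort(objectives: np.ndarray) -> FrontPartition:
    """Fast non-dominated sorting (Deb's bookkeeping, vectorized pairwise
    comparisons); stable within-front ordering by pool index."""
    F = np.asarray(objectives, float)
    if F.ndim != 2 or F.shape[0] == 0:
        raise ValueError("pool must be a non-empty (n, d) array")
    n = F.shape[0]
    # pairwise domination matrix: D[i, j] True iff i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    D = le & lt
    n_dominators = D.sum(axis=0)
    fronts: list[list[int]] = []
    current = np.nonzero(n_dominators == 0)[0]
    remaining = n
    while remaining > 0:
        fronts.append([int(i) for i in current])
        remaining -= current.size
        if remaining == 0:
            break
        n_dominators = n_dominators - D[current].sum(axis=0)
        n_dominators[current] = -1  # already assigned
        current = np.nonzero(n_dominators == 0)[0]
    return FrontPartition(fronts)


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front.

    Per-objective boundary points get infinite distance; interior points sum
    normalized neighbor gaps over objectives.  A zero-range objective
    contributes nothing.
    """
    F = np.asarray(front_objectives, float)
    if F.ndim != 2 or F.shape[0] == 0:
        raise ValueError("front must be a non-empty (n, d) array")
    n, d = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for k in range(d):
        order = np.argsort(F[:, k], kind="stable")
        span = F[order[-1], k] - F[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            gaps = (F[order[2:], k] - F[order[:-2], k]) / span
            dist[order[1:-1]] += gaps
    return dist


# ---------------------------------------------------------------------------
# environmental selection
# ---------------------------------------------------------------------------

def environmental_selection_nsga2(
    objectives: np.ndarray,
    target_size: int,
) -> list[int]:
    """Elitist front-wise admission with crowding-distance truncation of the
    last admitted front.  Returns selected pool indices."""
    F = np.asarray(objectives, float)
    if F.shape[0] < target_size:
        raise ValueError("pool smaller than target size")
    selected: list[int] = []
    for front in non_dominated_sort(F).fronts:
        if len(selected) + len(front) <= target_size:
            selected.extend(front)
            if len(selected) == target_size:
                break
        else:
            dist = crowding_distance(F[front])
            # descending crowding distance, stable in front order
            order = np.argsort(-dist, kind="stable")
            need = target_size - len(selected)
            selected.extend(front[i] for i in order[:need])
            break
    return selected


def binary_tournament(
    ranks: np.ndarray,
    crowding: np.ndarray,
    n_parents: int,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Binary tournaments over uniformly sampled contestant pairs: lower
    front rank wins; ties by larger crowding distance; remaining ties by a
    fair coin."""
    rng = np.random.default_rng(rng)
    n = len(ranks)
    winners = np.empty(n_parents, dtype=int)
    if n == 1:
        winners[:] = 0
        return winners
    for t in range(n_parents):
        i, j = rng.choice(n, size=2, replace=False)
        if ranks[i] != ranks[j]:
            winners[t] = i if ranks[i] < ranks[j] else j
        elif crowding[i] != crowding[j]:
            winners[t] = i if crowding[i] > crowding[j] else j
        else:
            winners[t] = i if rng.random() < 0.5 else j
    return winners


# ---------------------------------------------------------------------------
# NSGA-III reference directions and niching
# ---------------------------------------------------------------------------

@dataclass
class ReferenceDirectionSet:
    """Well-spread unit-simplex directions, one per population slot."""

    directions: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.directions, float)
        if D.ndim != 2:
            raise ValueError("directions must be (n_points, n_dim)")
        if np.abs(D.sum(axis=1) - 1.0).max() > 1e-9 or (D < -1e-12).any():
            raise ValueError("directions must lie on the unit simplex")
        self.directions = D

    def __len__(self) -> int:
        return self.directions.shape[0]


def _project_simplex(X: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the unit simplex."""
    n, d = X.shape
    U = np.sort(X, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ks = np.arange(1, d + 1)
    cond = U - css / ks > 0
    rho = cond.sum(axis=1)
    theta = css[np.arange(n), rho - 1] / rho
    return np.maximum(X - theta[:, None], 0.0)


def reference_directions(
    n_dim: int,
    n_points: int,
    seed: int | np.random.Generator = 0,
    s: float | None = None,
    n_iter: int = 1000,
) -> ReferenceDirectionSet:
    """Well-spread simplex directions by Riesz s-energy minimization.

    Points are initialized uniformly on the simplex (Dirichlet(1)) and the
    pairwise energy ``sum 1 / ||x_i - x_j||^s`` is reduced by normalized
    gradient descent with projection back onto the simplex.  The exponent
    defaults to ``n_dim ** 2``; the procedure is deterministic under the
    seed.
    """
    if n_dim < 2:
        raise ValueError("need at least 2 objective dimensions")
    if n_points < n_dim:
        raise ValueError("need at least n_dim reference directions")
    rng = np.random.default_rng(seed)
    if s is None:
        s = float(n_dim**2)
    X = rng.dirichlet(np.ones(n_dim), size=n_points)
    lr = 0.05
    for _ in range(n_iter):
        diff = X[:, None, :] - X[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(dist2, np.inf)
        dist2 = np.maximum(dist2, 1e-12)
        # d/dx_i sum_j dist_ij^(-s/2) = -s * sum_j diff_ij * dist_ij^(-(s+2)/2);
        # the coefficients span hundreds of orders of magnitude at large s, so
        # they are computed in log space and rescaled per row (only the
        # gradient direction is used)
        logc = (-(s + 2) / 2.0) * np.log(dist2)
        coef = np.exp(logc - logc.max(axis=1, keepdims=True))
        grad = -np.einsum("ij,ijk->ik", coef, diff)
        norms = np.linalg.norm(grad, axis=1, keepdims=True)
        norms = np.maximum(norms, 1e-30)
        X = _project_simplex(X - lr * grad / norms)
        lr *= 0.995
    return ReferenceDirectionSet(X)


def _associate(
    normalized: np.ndarray,
    directions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference direction by perpendicular distance to the ray
    through the origin.  Returns (direction index, distance) per point."""
    D = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    proj = normalized @ D.T                       # (n, r) scalar projections
    perp2 = (normalized**2).sum(axis=1)[:, None] - proj**2
    perp = np.sqrt(np.maximum(perp2, 0.0))
    nearest = np.argmin(perp, axis=1)
    return nearest, perp[np.arange(len(normalized)), nearest]


def environmental_selection_nsga3(
    objectives: np.ndarray,
    target_size: int,
    directions: ReferenceDirectionSet,
    rng: int | np.random.Generator = 0,
) -> list[int]:
    """Front-wise admission with reference-direction niching on the last
    front.

    Objectives are normalized by the pool's ideal point and per-axis maxima
    (degenerate-safe), members are associated to the nearest direction by
    perpendicular distance, and the last front fills the least-populated
    niches first (closest member when the niche is empty, random member
    otherwise; random tie-breaks are seeded).
    """
    rng = np.random.default_rng(rng)
    F = np.asarray(objectives, float)
    if F.shape[0] < target_size:
        raise ValueError("pool smaller than target size")
    partition = non_dominated_sort(F)
    selected: list[int] = []
    last_front: list[int] = []
    for front in partition.fronts:
        if len(selected) + len(front) <= target_size:
            selected.extend(front)
        else:
            last_front = front
            break
    if len(selected) == target_size or not last_front:
        return selected[:target_size]

    ideal = F.min(axis=0)
    span = F.max(axis=0) - ideal
    span[span <= 0] = 1.0
    Z = (F - ideal) / span
    nearest, perp = _associate(Z, directions.directions)

    niche_count = np.zeros(len(directions), dtype=int)
    for i in selected:
        niche_count[nearest[i]] += 1

    pending = {i: (nearest[i], perp[i]) for i in last_front}
    active = set(range(len(directions)))
    need = target_size - len(selected)
    while need > 0:
        candidates_by_niche: dict[int, list[int]] = {}
        for i, (d, _) in pending.items():
            if d in active:
                candidates_by_niche.setdefault(d, []).append(i)
        if not candidates_by_niche:
            # no pending member associates with an active niche: admit the
            # remaining members closest to any active direction
            rest = sorted(pending, key=lambda i: pending[i][1])
            selected.extend(rest[:need])
            break
        counts = {d: niche_count[d] for d in candidates_by_niche}
        min_count = min(counts.values())
        tied = sorted(d for d, c in counts.items() if c == min_count)
        d_pick = tied[int(rng.integers(len(tied)))]
        members = candidates_by_niche[d_pick]
        if niche_count[d_pick] == 0:
            pick = min(members, key=lambda i: (pending[i][1], i))
        else:
            pick = members[int(rng.integers(len(members)))]
        selected.append(pick)
        del pending[pick]
        niche_count[d_pick] += 1
        need -= 1
    return selected


# ---------------------------------------------------------------------------
# generation loop
# ---------------------------------------------------------------------------

EvalMap = Callable[
    [Callable[[SequenceIndividual], np.ndarray], Sequence[SequenceIndividual]],
    list[np.ndarray],
]


def _serial_map(fn, items):
    return [fn(x) for x in items]


def score_population(
    pop: Population,
    bundle: ScorerBundle,
    eval_map: EvalMap = _serial_map,
) -> None:
    """Fill in missing objective vectors, optionally through a parallel map.

    The map contract must preserve item order; with that, worker scheduling
    cannot change results.
    """
    unscored = [m for m in pop.members if m.objectives is None]
    results = eval_map(lambda ind: assemble_objectives(ind, bundle), unscored)
    for m, obj in zip(unscored, results):
        m.objectives = np.asarray(obj, float)


def run_generation(
    pop: Population,
    variation: VariationBundle,
    bundle: ScorerBundle,
    rng: int | np.random.Generator,
    algorithm: str = "nsga2",
    directions: ReferenceDirectionSet | None = None,
    eval_map: EvalMap = _serial_map,
) -> Population:
    """One elitist iteration: double the population with tournament +
    crossover + mutation, score the offspring, and reduce the 2N pool back to
    N by environmental selection.

    Offspring receive pre-drawn child generators (one per pair) so that a
    parallel evaluation backend cannot change the draw order.
    """
    rng = np.random.default_rng(rng)
    if algorithm not in ("nsga2", "nsga3"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if algorithm == "nsga3" and directions is None:
        raise ValueError("nsga3 requires reference directions")
    n = len(pop)
    F = pop.objectives()
    partition = non_dominated_sort(F)
    ranks = partition.ranks(n)
    crowd = np.empty(n)
    for front in partition.fronts:
        crowd[front] = crowding_distance(F[front])

    parents = binary_tournament(ranks, crowd, 2 * ((n + 1) // 2), rng)
    cfg = variation.config
    n_pairs = (n + 1) // 2
    pair_rngs = rng.spawn(n_pairs)
    offspring: list[SequenceIndividual] = []
    for k in range(n_pairs):
        r = pair_rngs[k]
        a = pop.members[parents[2 * k]]
        b = pop.members[parents[2 * k + 1]]
        if r.random() < cfg.p_crossover:
            c1, c2 = variation.crossover(a, b, r)
        else:
            c1, c2 = a.copy(), b.copy()
            c1.objectives = c2.objectives = None
        for child in (c1, c2):
            if r.random() < cfg.p_mutation:
                child = variation.mutate(child, r)
            offspring.append(child)
    offspring = offspring[:n]

    try:
        results = eval_map(
            lambda ind: assemble_objectives(ind, bundle), offspring
        )
    except ValueError as exc:
        raise RuntimeError(f"scorer failure on offspring: {exc}") from exc
    for child, obj in zip(offspring, results):
        child.objectives = np.asarray(obj, float)

    combined = pop.members + offspring
    FC = np.stack([m.objectives for m in combined])
    if algorithm == "nsga2":
        keep = environmental_selection_nsga2(FC, n)
    else:
        keep = environmental_selection_nsga3(FC, n, directions, rng)
    return Population(
        members=[combined[i].copy() for i in keep],
        generation=pop.generation + 1,
    )


def run_ga(
    initial: Population,
    variation: VariationBundle,
    bundle: ScorerBundle,
    n_generations: int,
    seed: int | np.random.Generator,
    algorithm: str = "nsga2",
    eval_map: EvalMap = _serial_map,
    callback: Callable[[Population], None] | None = None,
) -> Population:
    """Score the initial population and run the generation loop.

    All randomness flows from one seeded generator; per-generation and
    per-offspring substreams are spawned from it in documented order
    (generation-major, pair-minor), which makes runs bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    pop = Population([m.copy() for m in initial.members], initial.generation)
    score_population(pop, bundle, eval_map)
    directions = None
    if algorithm == "nsga3":
        n_dim = len(bundle)
        directions = reference_directions(n_dim, len(pop), rng)
    if callback is not None:
        callback(pop)
    for _ in range(n_generations):
        pop = run_generation(
            pop, variation, bundle, rng,
            algorithm=algorithm, directions=directions, eval_map=eval_map,
        )
        if callback is not None:
            callback(pop)
    return pop


def parallel_eval_map(n_workers: int) -> EvalMap:
    """Order-preserving process-pool map satisfying the determinism contract
    (scoring is a pure function of the individual, so scheduling cannot
    change results)."""
    if n_workers <= 1:
        return _serial_map

    def _map(fn, items):
        from joblib import Parallel, delayed

        return Parallel(n_jobs=n_workers)(delayed(fn)(x) for x in items)

    return _map


__all__ = [
    "FrontPartition",
    "ReferenceDirectionSet",
    "binary_tournament",
    "crowding_distance",
    "dominates",
    "environmental_selection_nsga2",
    "environmental_selection_nsga3",
    "non_dominated_sort",
    "parallel_eval_map",
    "reference_directions",
    "run_ga",
    "run_generation",
    "score_population",
]
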