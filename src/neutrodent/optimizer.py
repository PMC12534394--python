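"""Immune-genetic multi-objective optimizer (GIO).

A generational loop hybridizing a real-coded genetic algorithm with
artificial-immune operators, used to tune framework parameter vectors
against several objectives at once (minimization convention):

evaluate -> fast non-dominated sort -> elite preservation -> clonal
expansion and inverse-affinity hypermutation of the elites -> negative
selection against a "self" reference set -> tournament / blend
crossover / Gaussian mutation offspring -> memory-pool update ->
Pareto-archive update (non-dominated, truncated by crowding distance).

Affinity is a scalar quality for the immune operators: the negated sum
of min-max-normalized objectives (equal weights), higher is better.
All randomness flows through one seeded generator, so runs are
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from neutrodent.membership import AgeGroup

__all__ = [
    "GIOConfig",
    "Individual",
    "ParetoArchive",
    "clonal_expand",
    "crossover",
    "crowding_distance",
    "dominates",
    "hypermutate",
    "mutate",
    "negative_selection",
    "nondominated_sort",
    "run_gio",
    "tournament_select",
]


@dataclass
class Individual:
    """One candidate solution with its evaluation and sorting state."""

    genome: np.ndarray
    objectives: Optional[np.ndarray] = None
    affinity: float = -np.inf
    rank: int = 0
    crowding: float = 0.0

    def copy(self) -> "Individual":
        return Individual(
            genome=self.genome.copy(),
            objectives=None if self.objectives is None else self.objectives.copy(),
            affinity=self.affinity,
            rank=self.rank,
            crowding=self.crowding,
        )


@dataclass(frozen=True)
class GIOConfig:
    """Operator rates and pool sizes of the optimizer."""

    pop_size: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    selection_pressure: float = 2.1
    elite_fraction: float = 0.10
    clonal_factor: int = 20
    hypermutation_rate: float = 0.4
    memory_pool: int = 35
    negative_threshold: float = 0.85
    pareto_size: int = 100
    crowding_weight: float = 0.5
    generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate", "hypermutation_rate", "elite_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.negative_threshold < 1.0):
            raise ValueError("negative_threshold must lie in (0, 1)")
        if min(self.pop_size, self.clonal_factor, self.memory_pool, self.pareto_size) < 1:
            raise ValueError("pool sizes must be positive")
        if self.selection_pressure < 1.0:
            raise ValueError("selection pressure must be at least 1")


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance under minimization: a <= b everywhere, < somewhere."""
    return bool(np.all(a <= b) and np.any(a < b))


def nondominated_sort(pop: Sequence[Individual]) -> list[list[Individual]]:
    """Fast non-dominated sorting; assigns each individual its front rank."""
    n = len(pop)
    objs = [ind.objectives for ind in pop]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
    fronts: list[list[Individual]] = []
    current = [i for i in range(n) if domination_count[i] == 0]
    rank = 0
    while current:
        for i in current:
            pop[i].rank = rank
        fronts.append([pop[i] for i in current])
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        current = nxt
        rank += 1
    return fronts


def crowding_distance(front: Sequence[Individual]) -> np.ndarray:
    """NSGA-style crowding distances; boundary individuals get infinity."""
    n = len(front)
    dist = np.zeros(n)
    if n <= 2:
        dist[:] = np.inf
        for ind, d in zip(front, dist):
            ind.crowding = d
        return dist
    objs = np.stack([ind.objectives for ind in front])
    for m in range(objs.shape[1]):
        order = np.argsort(objs[:, m], kind="stable")
        fmin, fmax = objs[order[0], m], objs[order[-1], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if fmax > fmin:
            gaps = (objs[order[2:], m] - objs[order[:-2], m]) / (fmax - fmin)
            dist[order[1:-1]] += gaps
    for ind, d in zip(front, dist):
        ind.crowding = float(d)
    return dist


def _better(a: Individual, b: Individual) -> bool:
    """(rank, -crowding) lexicographic comparison."""
    return (a.rank, -a.crowding) < (b.rank, -b.crowding)


def tournament_select(
    pop: Sequence[Individual], pressure: float, rng: np.random.Generator
) -> Individual:
    """Fractional-pressure tournament selection.

    Draws ``ceil(pressure)`` candidates; with probability
    ``pressure / ceil(pressure)`` returns the (rank, -crowding) best,
    otherwise a uniform candidate.
    """
    if not pop:
        raise ValueError("population must be non-empty")
    k = math.ceil(pressure)
    idx = rng.integers(0, len(pop), size=k)
    candidates = [pop[i] for i in idx]
    best = candidates[0]
    for c in candidates[1:]:
        if _better(c, best):
            best = c
    if rng.random() < pressure / k:
        return best
    return candidates[int(rng.integers(0, k))]


def _clip(genome: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.clip(genome, bounds[:, 0], bounds[:, 1])


def crossover(
    a: Individual,
    b: Individual,
    rate: float,
    rng: np.random.Generator,
    bounds: Optional[np.ndarray] = None,
) -> tuple[Individual, Individual]:
    """Blend crossover: per-gene convex mix with uniform alpha, else copies."""
    if a.genome.shape != b.genome.shape:
        raise ValueError("parent genomes must have the same length")
    if rng.random() < rate:
        alpha = rng.uniform(0.0, 1.0, size=a.genome.shape)
        g1 = alpha * a.genome + (1.0 - alpha) * b.genome
        g2 = alpha * b.genome + (1.0 - alpha) * a.genome
    else:
        g1, g2 = a.genome.copy(), b.genome.copy()
    if bounds is not None:
        g1, g2 = _clip(g1, bounds), _clip(g2, bounds)
    return Individual(genome=g1), Individual(genome=g2)


def mutate(
    ind: Individual,
    rate: float,
    rng: np.random.Generator,
    bounds: np.ndarray,
    age_group: Optional[AgeGroup] = None,
    generation: int = 0,
) -> Individual:
    """Per-gene Gaussian mutation, clipped to bounds.

    Each gene mutates with probability ``rate``, raised 30% in an
    early-childhood context (greater developmental variability) and
    decayed by ``0.99^generation``; perturbation scale is 10% of the
    gene range.
    """
    eff = rate * (1.30 if age_group is AgeGroup.EARLY_CHILDHOOD else 1.0)
    eff = min(1.0, eff * 0.99**generation)
    span = bounds[:, 1] - bounds[:, 0]
    flip = rng.random(size=ind.genome.shape) < eff
    noise = rng.normal(0.0, 0.1, size=ind.genome.shape) * span
    genome = np.where(flip, ind.genome + noise, ind.genome)
    return Individual(genome=_clip(genome, bounds))


def clonal_expand(
    elites: Sequence[Individual], factor: int, rng: np.random.Generator
) -> list[Individual]:
    """Affinity-proportional cloning with largest-remainder rounding.

    Total clone count is ``factor * len(elites)``; every elite receives
    at least one clone; equal affinities yield uniform counts.
    Non-positive affinities are shifted to positive before the share
    computation.
    """
    if not elites:
        raise ValueError("elites must be non-empty")
    aff = np.array([e.affinity for e in elites], dtype=float)
    if not np.all(np.isfinite(aff)):
        raise ValueError("elite affinities must be finite")
    total = factor * len(elites)
    if np.ptp(aff) == 0:
        counts = np.full(len(elites), factor, dtype=int)
    else:
        if aff.min() <= 0:
            aff = aff - aff.min() + np.ptp(aff) / len(aff)
        shares = aff / aff.sum() * total
        counts = np.maximum(np.floor(shares).astype(int), 1)
        remainder = shares - np.floor(shares)
        short = total - counts.sum()
        if short > 0:
            for i in np.argsort(-remainder, kind="stable")[:short]:
                counts[i] += 1
        elif short < 0:
            for i in np.argsort(remainder, kind="stable"):
                if short == 0:
                    break
                if counts[i] > 1:
                    counts[i] -= 1
                    short += 1
    clones = []
    for elite, c in zip(elites, counts):
        for _ in range(int(c)):
            clones.append(elite.copy())
    return clones


def hypermutate(
    clone: Individual,
    rate: float,
    affinity_norm: float,
    rng: np.random.Generator,
    bounds: np.ndarray,
) -> Individual:
    """Inverse-affinity hypermutation: the best clones mutate least.

    Per-gene perturbation probability is ``rate * (1 - affinity_norm)``
    with ``affinity_norm`` in [0, 1].
    """
    if not (0.0 <= affinity_norm <= 1.0):
        raise ValueError("affinity_norm must lie in [0, 1]")
    eff = rate * (1.0 - affinity_norm)
    span = bounds[:, 1] - bounds[:, 0]
    flip = rng.random(size=clone.genome.shape) < eff
    noise = rng.normal(0.0, 0.1, size=clone.genome.shape) * span
    genome = np.where(flip, clone.genome + noise, clone.genome)
    return Individual(genome=_clip(genome, bounds))


def negative_selection(
    pop: Sequence[Individual],
    threshold: float,
    self_set: Sequence[np.ndarray],
    bounds: np.ndarray,
) -> list[Individual]:
    """Remove individuals too similar to any self (disallowed) genome.

    Similarity is ``1 - ||g - s|| / ||range||`` (Euclidean distance
    scaled by the bounds diagonal); individuals whose maximal
    similarity exceeds the threshold are filtered out.
    """
    if not self_set:
        return list(pop)
    diag = float(np.linalg.norm(bounds[:, 1] - bounds[:, 0]))
    if diag == 0:
        diag = 1.0
    selves = np.stack([np.asarray(s, dtype=float) for s in self_set])
    kept = []
    for ind in pop:
        d = np.linalg.norm(selves - ind.genome[None, :], axis=1)
        if np.max(1.0 - d / diag) <= threshold:
            kept.append(ind)
    return kept


@dataclass
class ParetoArchive:
    """Bounded archive of mutually non-dominated individuals."""

    capacity: int = 100
    members: list[Individual] = field(default_factory=list)

    def update(self, candidates: Sequence[Individual]) -> None:
        pool = self.members + [c.copy() for c in candidates]
        # Deduplicate identical objective vectors to keep the archive tight.
        seen: dict[bytes, Individual] = {}
        for ind in pool:
            seen.setdefault(np.round(ind.objectives, 12).tobytes(), ind)
        pool = list(seen.values())
        nd = [
            a for a in pool
            if not any(dominates(b.objectives, a.objectives) for b in pool)
        ]
        if len(nd) > self.capacity:
            crowding_distance(nd)
            nd.sort(key=lambda x: -x.crowding)
            nd = nd[: self.capacity]
        self.members = nd


def _scalarized_affinities(pop: Sequence[Individual]) -> None:
    """Assign affinity = -sum of min-max-normalized objectives (higher better)."""
    objs = np.stack([ind.objectives for ind in pop])
    lo = objs.min(axis=0)
    span = np.ptp(objs, axis=0)
    span[span == 0] = 1.0
    norm = (objs - lo) / span
    for ind, row in zip(pop, norm):
        ind.affinity = -float(row.sum())


def run_gio(
    objective_fn: Callable[[np.ndarray], Sequence[float]],
    bounds: Sequence[tuple[float, float]],
    config: Optional[GIOConfig] = None,
    self_set: Optional[Sequence[np.ndarray]] = None,
    age_group: Optional[AgeGroup] = None,
    callback: Optional[Callable[[int, list[Individual], ParetoArchive], None]] = None,
) -> ParetoArchive:
    """Run the full generational loop and return the Pareto archive.

    ``objective_fn`` maps a genome to a finite objective vector
    (minimized).  ``self_set`` genomes mark disallowed regions for
    negative selection.  The run is fully reproducible from
    ``config.seed``.
    """
    cfg = config if config is not None else GIOConfig()
    rng = np.random.default_rng(cfg.seed)
    b = np.asarray(bounds, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2 or np.any(b[:, 0] > b[:, 1]):
        raise ValueError("bounds must be (n_genes, 2) with low <= high")
    self_set = list(self_set or [])

    def evaluate(ind: Individual) -> None:
        obj = np.asarray(objective_fn(ind.genome), dtype=float)
        if not np.all(np.isfinite(obj)):
            raise ValueError(f"non-finite objectives for genome {ind.genome!r}")
        ind.objectives = obj

    pop = [
        Individual(genome=rng.uniform(b[:, 0], b[:, 1]))
        for _ in range(cfg.pop_size)
    ]
    for ind in pop:
        evaluate(ind)

    archive = ParetoArchive(capacity=cfg.pareto_size)
    memory: list[Individual] = []
    n_elite = max(1, round(cfg.elite_fraction * cfg.pop_size))
    n_mem_inject = max(0, round(0.10 * cfg.pop_size))

    for gen in range(cfg.generations):
        for front in nondominated_sort(pop):
            crowding_distance(front)
        _scalarized_affinities(pop)
        archive.update([ind for ind in pop if ind.rank == 0])

        # Memory pool: best individuals by affinity across generations.
        memory = sorted(memory + [ind.copy() for ind in pop], key=lambda x: -x.affinity)
        memory = memory[: cfg.memory_pool]

        elites = sorted(pop, key=lambda x: (x.rank, -x.crowding))[:n_elite]

        # Immune branch: clonal expansion + inverse-affinity hypermutation.
        e_aff = np.array([e.affinity for e in elites])
        span = np.ptp(e_aff)
        clones = clonal_expand(elites, cfg.clonal_factor, rng)
        mutated_clones = []
        for clone in clones:
            a_norm = 0.5 if span == 0 else float((clone.affinity - e_aff.min()) / span)
            mutated_clones.append(
                hypermutate(clone, cfg.hypermutation_rate, a_norm, rng, b)
            )
        mutated_clones = negative_selection(
            mutated_clones, cfg.negative_threshold, self_set, b
        )
        for ind in mutated_clones:
            evaluate(ind)
        _scalarized_affinities(mutated_clones + pop)
        mutated_clones.sort(key=lambda x: -x.affinity)
        kept_clones = mutated_clones[:n_elite]

        # Genetic branch: tournament / crossover / mutation offspring.
        n_offspring = cfg.pop_size - n_elite - len(kept_clones)
        n_inject = min(n_mem_inject, len(memory), n_offspring)
        n_offspring -= n_inject
        offspring: list[Individual] = []
        while len(offspring) < n_offspring:
            pa = tournament_select(pop, cfg.selection_pressure, rng)
            pb = tournament_select(pop, cfg.selection_pressure, rng)
            c1, c2 = crossover(pa, pb, cfg.crossover_rate, rng, b)
            for child in (c1, c2):
                if len(offspring) < n_offspring:
                    offspring.append(
                        mutate(child, cfg.mutation_rate, rng, b, age_group, gen)
                    )
        offspring = negative_selection(offspring, cfg.negative_threshold, self_set, b)
        while len(offspring) < n_offspring:  # refill after a degenerate filter
            offspring.append(Individual(genome=rng.uniform(b[:, 0], b[:, 1])))
        for ind in offspring:
            evaluate(ind)

        injected = []
        if n_inject:
            idx = rng.choice(len(memory), size=n_inject, replace=False)
            injected = [memory[i].copy() for i in idx]

        pop = [e.copy() for e in elites] + kept_clones + injected + offspring
        if callback is not None:
            callback(gen, pop, archive)

    for front in nondominated_sort(pop):
        crowding_distance(front)
    _scalarized_affinities(pop)
    archive.update([ind for ind in pop if ind.rank == 0])
    return archive
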