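"""Population model: founder creation, generational cycles of sexual
reproduction, point mutation, viability and stabilizing selection.

Generations do not overlap: offspring are drawn (parents sampled uniformly
with replacement), recombined per URR, mutated per base, developed, and
accepted with probability equal to their fitness until M accepted offspring
replace the parental population.  Fitness is exp(-D/sigma) against the
founder's phenotype; unstable offspring have fitness zero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from . import analysis, landscape as ls
from .dynamics import DevelopmentResult, DynamicsParams, develop, distance
from .errors import ConfigurationError, FounderSearchError, ProgressTimeoutError
from .genome import (
    Genotype,
    RegulatoryNetwork,
    _row_sum as genome_row,
    build_network,
    build_w,
    connectivity,
    point_mutate,
    random_genotype,
    recombine,
    redundancy_count,
    tfbs_free_fraction,
)


@dataclass
class Individual:
    genotype: Genotype
    network: RegulatoryNetwork
    result: DevelopmentResult
    fitness: float


@dataclass
class SimulationConfig:
    """Run parameters; defaults follow the reference protocol."""

    n: int = 10
    L: int = 50
    gamma: float = 0.05
    M: int = 500
    generations: int = 2000
    eval_interval: int = 10
    sigma: float = 0.001
    mutation_rate: float = 0.01
    robustness_mutants: int = 100
    seed: int = 0
    alpha: float = 20.0
    tau: int = 10
    tol: float = 1e-4
    max_iter: int = 100
    founder_attempts: int = 100_000
    offspring_attempt_factor: int = 1000
    # individuals sampled per trajectory evaluation (None = whole population)
    eval_sample: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.n, self.L, self.M, self.eval_interval) <= 0:
            raise ConfigurationError("n, L, M, eval_interval must be positive")
        if self.generations < 0:
            raise ConfigurationError("generations must be >= 0")
        if self.generations % self.eval_interval != 0:
            raise ConfigurationError("eval_interval must divide generations")

    @property
    def dynamics(self) -> DynamicsParams:
        return DynamicsParams(
            alpha=self.alpha, tau=self.tau, tol=self.tol, max_iter=self.max_iter
        )


@dataclass
class Population:
    individuals: List[Individual]
    s_opt: np.ndarray  # the founder's phenotype (selection optimum)
    founder: Individual

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)


@dataclass
class GenerationStats:
    attempts: int
    accepted: int
    unstable: int
    rejected_fitness: int

    @property
    def replaced_fraction(self) -> float:
        """Fraction of developed offspring discarded for instability."""
        return self.unstable / self.attempts if self.attempts else 0.0


@dataclass
class TrajectoryRecord:
    generation: int
    mean_robustness: float
    fraction_stable: float
    mean_connectivity: float
    mean_redundancy: float
    event_frequency: Dict[str, float]
    event_effect: Dict[str, float]
    f_s: float
    mean_phi: float
    replaced_fraction: float
    mean_free_fraction: float
    mean_conservation: Optional[float] = None
    mean_fitness: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fitness_of(result: DevelopmentResult, s_opt: np.ndarray, sigma: float) -> float:
    """exp(-D/sigma) for stable phenotypes; unstable individuals score 0."""
    if not result.stable:
        return 0.0
    return float(np.exp(-distance(result.phenotype, s_opt) / sigma))


def make_founder(
    config: SimulationConfig,
    tables: Sequence[ls.SpecificityTable],
    rng: np.random.Generator,
) -> Individual:
    """Draw random genotypes until one develops stably; that phenotype
    becomes the selection optimum."""
    params = config.dynamics
    for _ in range(config.founder_attempts):
        g = random_genotype(config.n, config.L, rng)
        net = build_network(g, tables)
        res = develop(g, net, params)
        if res.stable:
            return Individual(genotype=g, network=net, result=res, fitness=1.0)
    raise FounderSearchError(
        f"no viable founder in {config.founder_attempts} attempts"
    )


def _build_w_cached(
    genotype: Genotype,
    tables: Sequence[ls.SpecificityTable],
    row_cache: dict,
) -> np.ndarray:
    """Interaction matrix with per-URR row memoization (URRs recur heavily
    across offspring because recombination copies them verbatim)."""
    stack = ls.kappa_stack(tables)
    rows = []
    for urr in genotype.urrs:
        row = row_cache.get(urr)
        if row is None:
            row = genome_row(stack, ls.window_indices(urr))
            if len(row_cache) > 200_000:
                row_cache.clear()
            row_cache[urr] = row
        rows.append(row)
    return np.array(rows)


def _develop_cached(
    genotype: Genotype,
    w: np.ndarray,
    params: DynamicsParams,
    dev_cache: dict,
) -> DevelopmentResult:
    """Development depends only on w once signs and initial state are fixed
    (they are, within one simulation), so results can be memoized on w."""
    key = w.tobytes()
    res = dev_cache.get(key)
    if res is None:
        res = develop(genotype, w, params)
        if len(dev_cache) > 100_000:
            dev_cache.clear()
        dev_cache[key] = res
    return res


def next_generation(
    population: Population,
    config: SimulationConfig,
    tables: Sequence[ls.SpecificityTable],
    rng: np.random.Generator,
    caches: Optional[dict] = None,
):
    """One non-overlapping generation; returns (new population, stats)."""
    params = config.dynamics
    M = config.M
    parents = population.individuals
    s_opt = population.s_opt
    accepted: List[Individual] = []
    attempts = unstable = rejected = 0
    cap = config.offspring_attempt_factor * M
    if caches is None:
        caches = {"rows": {}, "dev": {}}
    row_cache, dev_cache = caches["rows"], caches["dev"]
    while len(accepted) < M:
        if attempts >= cap:
            raise ProgressTimeoutError(
                f"only {len(accepted)}/{M} offspring accepted in {attempts} attempts"
            )
        pa = parents[rng.integers(0, len(parents))]
        pb = parents[rng.integers(0, len(parents))]
        child = recombine(pa.genotype, pb.genotype, rng)
        child, _ = point_mutate(child, config.mutation_rate, rng)
        w = _build_w_cached(child, tables, row_cache)
        res = _develop_cached(child, w, params, dev_cache)
        attempts += 1
        if not res.stable:
            unstable += 1
            continue
        fit = float(np.exp(-distance(res.phenotype, s_opt) / config.sigma))
        if rng.random() < fit:
            accepted.append(
                Individual(
                    genotype=child,
                    network=RegulatoryNetwork(w=w),
                    result=res,
                    fitness=fit,
                )
            )
        else:
            rejected += 1
    stats = GenerationStats(
        attempts=attempts,
        accepted=M,
        unstable=unstable,
        rejected_fitness=rejected,
    )
    new_pop = Population(
        individuals=accepted, s_opt=s_opt, founder=population.founder
    )
    return new_pop, stats


def evaluate_population(
    population: Population,
    config: SimulationConfig,
    tables: Sequence[ls.SpecificityTable],
    rng: np.random.Generator,
    generation: int,
    replaced_fraction: float = 0.0,
) -> TrajectoryRecord:
    """Compute one trajectory record (robustness probes + network measures).

    Site annotations are rebuilt lazily for individuals whose networks were
    produced on the fast path.
    """
    inds = population.individuals
    if config.eval_sample is not None and config.eval_sample < len(inds):
        pick = rng.choice(len(inds), size=config.eval_sample, replace=False)
        inds = [inds[int(i)] for i in pick]
    for ind in inds:
        if not ind.network.sites and np.count_nonzero(ind.network.w):
            ind.network = build_network(ind.genotype, tables)
    table = analysis.event_table(
        inds, tables, config.robustness_mutants, rng, config.dynamics
    )
    conns = [connectivity(ind.network) for ind in inds]
    reds = [redundancy_count(ind.network) for ind in inds]
    frees = [tfbs_free_fraction(ind.genotype, ind.network) for ind in inds]
    phis = [
        analysis.rewiring_phi(population.founder.network, ind.network) for ind in inds
    ]
    cons_vals = []
    for ind in inds:
        if ind.network.sites:
            cons_vals.append(analysis.mean_tfbs_conservation(ind, tables))
    return TrajectoryRecord(
        generation=generation,
        mean_robustness=table.robustness(),
        fraction_stable=table.f_s,
        mean_connectivity=float(np.mean(conns)),
        mean_redundancy=float(np.mean(reds)),
        event_frequency=dict(table.f),
        event_effect=dict(table.e),
        f_s=table.f_s,
        mean_phi=float(np.mean(phis)),
        replaced_fraction=replaced_fraction,
        mean_free_fraction=float(np.mean(frees)),
        mean_conservation=float(np.mean(cons_vals)) if cons_vals else None,
        mean_fitness=float(np.mean([ind.fitness for ind in inds])),
    )


def run_simulation(
    config: SimulationConfig,
    tables: Sequence[ls.SpecificityTable],
    on_record: Optional[Callable[[TrajectoryRecord], None]] = None,
    on_final: Optional[Callable[[Population], None]] = None,
) -> List[TrajectoryRecord]:
    """Founder -> clone to M -> generational cycles, recording every
    ``eval_interval`` generations (and at generation 0)."""
    tables = ls.tables_of(tables)
    if len(tables) != config.n:
        raise ConfigurationError("need one specificity table per gene")
    ss = np.random.SeedSequence(config.seed)
    rng_founder, rng_repro, rng_eval = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    founder = make_founder(config, tables, rng_founder)
    population = Population(
        individuals=[founder] * config.M,
        s_opt=founder.result.phenotype,
        founder=founder,
    )
    records: List[TrajectoryRecord] = []

    def record(gen: int, replaced: float) -> None:
        rec = evaluate_population(
            population, config, tables, rng_eval, gen, replaced
        )
        records.append(rec)
        if on_record is not None:
            on_record(rec)

    record(0, 0.0)
    replaced_acc: List[float] = []
    caches = {"rows": {}, "dev": {}}
    for gen in range(1, config.generations + 1):
        population, stats = next_generation(
            population, config, tables, rng_repro, caches
        )
        replaced_acc.append(stats.replaced_fraction)
        if gen % config.eval_interval == 0:
            record(gen, float(np.mean(replaced_acc)))
            replaced_acc = []
    if on_final is not None:
        on_final(population)
    return records
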