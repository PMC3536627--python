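"""Measurement suite: robustness probing, mutation-event classification,
robustness decomposition, TFBS conservation/avoidance, de-novo propensity,
redundancy correction, and network rewiring with its random baseline.

All probes are single point mutations.  Each probe is classified from the
diff of the site annotations of the affected URR (the only URR a point
mutation can change):

* an annotated (offset, TF) pair that loses binding is a *deletion* — unique
  if no site for that (TF, gene) input remains afterwards;
* a pair that gains binding is a *creation* — unique if the input did not
  exist before;
* a pair that binds before and after (possibly with changed kappa) is
  *preserved*;
* no change at all and no overlapping persisting site is *silent*;
* two or more deletions/creations make the event *combined*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import landscape as ls
from .dynamics import DynamicsParams, DEFAULT_PARAMS, develop, distance
from .errors import (
    BaselineError,
    DecompositionError,
    GenerationError,
    InvalidParameterError,
)
from .genome import (
    Genotype,
    PointMutation,
    RegulatoryNetwork,
    _row_sum,
    build_network,
    build_w,
    connectivity,
    random_genotype,
    redundancy_count,
)

CATEGORIES = (
    "silent",
    "preserved",
    "deleted_unique",
    "deleted_redundant",
    "created_unique",
    "created_redundant",
    "combined",
)

_ALT_BASES = {b: [c for c in ls.ALPHABET if c != b] for b in ls.ALPHABET}


@dataclass
class MutationEvent:
    category: str
    stable: bool
    effect: Optional[float]  # phenotype distance; defined only when stable
    components: Tuple[str, ...] = ()  # elementary changes inside the event


@dataclass
class EventTable:
    """Per-category frequencies (normalized over stable probes) and effects."""

    f: Dict[str, float]
    e: Dict[str, float]
    f_s: float  # fraction of probes whose mutant developed stably
    n_probes: int = 0
    combined_components: Dict[str, int] = field(default_factory=dict)

    def robustness(self) -> float:
        """Mean phenotypic distance over stable probes: sum_i f_i * e_i."""
        return float(sum(self.f[c] * self.e[c] for c in CATEGORIES))


@dataclass
class RewiringEstimate:
    phi_raw: float
    phi_random: float
    phi_corrected: float


@dataclass
class BaselineFit:
    """Linear fit phi_random = a + b * connectivity."""

    a: float
    b: float
    r2: float

    def predict(self, c: float) -> float:
        return self.a + self.b * c


@dataclass
class Decomposition:
    cs: float
    rho: Dict[str, float]
    rho_prime: Dict[str, float]
    delta_g: Dict[str, float]


# ---------------------------------------------------------------------------
# single-probe machinery
# ---------------------------------------------------------------------------


def random_point_mutation(genotype: Genotype, rng: np.random.Generator) -> PointMutation:
    """Uniform genome position, uniform alternative base."""
    pos = int(rng.integers(0, genotype.genome_length))
    gene, offset = divmod(pos, genotype.L)
    old = genotype.urrs[gene][offset]
    new = _ALT_BASES[old][rng.integers(0, 3)]
    return PointMutation(gene=gene, position=offset, old_base=old, new_base=new)


def _window_profile(
    urr: str, stack: np.ndarray, position: int
) -> Tuple[np.ndarray, np.ndarray]:
    """kappa of windows overlapping ``position`` and per-TF binder counts."""
    idx = ls.window_indices(urr)
    kap_all = stack[:, idx]  # (n_tf, L-7)
    lo = max(0, position - ls.K + 1)
    hi = min(len(urr) - ls.K, position) + 1
    return kap_all[:, lo:hi], (kap_all > 0).sum(axis=1)


def classify_mutation(
    genotype: Genotype,
    mutation: PointMutation,
    tables: Sequence[ls.SpecificityTable],
) -> str:
    """Category of a point mutation from the affected URR's annotation diff."""
    stack = ls.kappa_stack(tables)
    urr_before = genotype.urrs[mutation.gene]
    urr_after = (
        urr_before[: mutation.position]
        + mutation.new_base
        + urr_before[mutation.position + 1 :]
    )
    return _classify(urr_before, urr_after, mutation.position, stack)[0]


def _classify(
    urr_before: str, urr_after: str, position: int, stack: np.ndarray
) -> Tuple[str, Tuple[str, ...]]:
    kap_b, counts_b = _window_profile(urr_before, stack, position)
    kap_a, counts_a = _window_profile(urr_after, stack, position)
    bound_b = kap_b > 0
    bound_a = kap_a > 0

    deleted = bound_b & ~bound_a
    created = ~bound_b & bound_a
    preserved = bound_b & bound_a

    components: List[str] = []
    for j in np.flatnonzero(deleted.any(axis=1)):
        for _ in range(int(deleted[j].sum())):
            components.append(
                "deleted_unique" if counts_a[j] == 0 else "deleted_redundant"
            )
    for j in np.flatnonzero(created.any(axis=1)):
        for _ in range(int(created[j].sum())):
            components.append(
                "created_unique" if counts_b[j] == 0 else "created_redundant"
            )
    n_elem = len(components)
    if n_elem >= 2:
        return "combined", tuple(components)
    if n_elem == 1:
        return components[0], tuple(components)
    if preserved.any():
        return "preserved", ("preserved",) * int(preserved.sum())
    return "silent", ()


def probe_mutation(
    individual,
    tables: Sequence[ls.SpecificityTable],
    mutation: PointMutation,
    params: DynamicsParams = DEFAULT_PARAMS,
) -> MutationEvent:
    """Classify one probe and measure its phenotypic effect.

    Only the affected URR's row of w is rebuilt before re-developing.
    """
    genotype: Genotype = individual.genotype
    stack = ls.kappa_stack(tables)
    urr_before = genotype.urrs[mutation.gene]
    urr_after = (
        urr_before[: mutation.position]
        + mutation.new_base
        + urr_before[mutation.position + 1 :]
    )
    category, components = _classify(urr_before, urr_after, mutation.position, stack)

    baseline = individual.result.phenotype
    if category == "silent":
        # w unchanged bit for bit: the mutant re-develops identically
        return MutationEvent(category=category, stable=True, effect=0.0)
    w = individual.network.w.copy()
    w[mutation.gene] = _row_sum(stack, ls.window_indices(urr_after))
    res = develop(genotype, w, params)
    if not res.stable:
        return MutationEvent(category=category, stable=False, effect=None,
                             components=components)
    return MutationEvent(
        category=category,
        stable=True,
        effect=distance(res.phenotype, baseline),
        components=components,
    )


# ---------------------------------------------------------------------------
# population-level measurements
# ---------------------------------------------------------------------------


def measure_robustness(
    individual,
    tables: Sequence[ls.SpecificityTable],
    n_mut: int,
    rng: np.random.Generator,
    params: DynamicsParams = DEFAULT_PARAMS,
) -> Tuple[float, float]:
    """(mean phenotypic distance over stable probes, fraction stable).

    Each probe is an independent uniform single point mutation; unstable
    mutants are excluded from the mean but counted in the stable fraction.
    """
    if n_mut < 1:
        raise InvalidParameterError("n_mut must be >= 1")
    dists: List[float] = []
    n_stable = 0
    for _ in range(n_mut):
        mut = random_point_mutation(individual.genotype, rng)
        ev = probe_mutation(individual, tables, mut, params)
        if ev.stable:
            n_stable += 1
            dists.append(ev.effect)
    mean_d = float(np.mean(dists)) if dists else 0.0
    return mean_d, n_stable / n_mut


def event_table(
    population,
    tables: Sequence[ls.SpecificityTable],
    n_mut: int,
    rng: np.random.Generator,
    params: DynamicsParams = DEFAULT_PARAMS,
) -> EventTable:
    """Pool ``n_mut`` probes per individual into per-category statistics.

    Frequencies are normalized over stable probes only; effects are mean
    phenotypic distances of stable probes (0 for categories never observed).
    """
    individuals = getattr(population, "individuals", population)
    counts = {c: 0 for c in CATEGORIES}
    sums = {c: 0.0 for c in CATEGORIES}
    comb_components: Dict[str, int] = {}
    n_total = 0
    n_stable = 0
    for ind in individuals:
        for _ in range(n_mut):
            mut = random_point_mutation(ind.genotype, rng)
            ev = probe_mutation(ind, tables, mut, params)
            n_total += 1
            if ev.category == "combined":
                for c in ev.components:
                    comb_components[c] = comb_components.get(c, 0) + 1
            if ev.stable:
                n_stable += 1
                counts[ev.category] += 1
                sums[ev.category] += ev.effect
    f = {c: (counts[c] / n_stable if n_stable else 0.0) for c in CATEGORIES}
    e = {c: (sums[c] / counts[c] if counts[c] else 0.0) for c in CATEGORIES}
    return EventTable(
        f=f,
        e=e,
        f_s=n_stable / n_total if n_total else 0.0,
        n_probes=n_total,
        combined_components=comb_components,
    )


def decompose_robustness(initial: EventTable, final: EventTable) -> Decomposition:
    """Constant-frequency decomposition of the robustness change.

    With g the stable-normalized category frequencies, the observed change
    per category is rho_i = e_i(init) * g_i(init) - e_i(final) * g_i(final)
    and the constant-frequency counterfactual is
    rho'_i = (e_i(init) - e_i(final)) * g_i(init).  CS sums rho - rho' over
    categories whose frequency dropped and divides by the total change.
    """
    g0 = _normalized_frequencies(initial)
    g1 = _normalized_frequencies(final)
    rho = {
        c: initial.e[c] * g0[c] - final.e[c] * g1[c] for c in CATEGORIES
    }
    rho_prime = {c: (initial.e[c] - final.e[c]) * g0[c] for c in CATEGORIES}
    delta_g = {c: g1[c] - g0[c] for c in CATEGORIES}
    total = sum(rho.values())
    if total == 0.0:
        raise DecompositionError("total robustness change is zero; CS undefined")
    cs = sum(rho[c] - rho_prime[c] for c in CATEGORIES if delta_g[c] < 0) / total
    return Decomposition(cs=float(cs), rho=rho, rho_prime=rho_prime, delta_g=delta_g)


def _normalized_frequencies(table: EventTable) -> Dict[str, float]:
    tot = sum(table.f[c] for c in CATEGORIES)
    if tot == 0.0:
        return {c: 0.0 for c in CATEGORIES}
    return {c: table.f[c] / tot for c in CATEGORIES}


def tfbs_avoidance(table: EventTable, free_fraction: float) -> float:
    """Silent-event frequency normalized by the TFBS-free genome fraction."""
    if free_fraction <= 0.0:
        raise InvalidParameterError("free_fraction must be positive")
    return table.f["silent"] / free_fraction


def de_novo_propensity(
    genotype: Genotype,
    network: RegulatoryNetwork,
    tables: Sequence[ls.SpecificityTable],
) -> float:
    """Mean, over fully TFBS-free 8-mer windows, of the fraction of the 24
    single-point mutants that are binders for any TF."""
    stack = ls.kappa_stack(tables)
    any_binder = (stack > 0).any(axis=0)
    covered = np.zeros((genotype.n, genotype.L), dtype=bool)
    for s in network.sites:
        covered[s.gene, s.offset : s.offset + ls.K] = True
    fracs: List[float] = []
    for g, urr in enumerate(genotype.urrs):
        idx = ls.window_indices(urr)
        for o in range(len(idx)):
            if covered[g, o : o + ls.K].any():
                continue
            mut = ls.mutant_indices(int(idx[o]))
            fracs.append(float(np.count_nonzero(any_binder[mut])) / 24.0)
    if not fracs:
        raise GenerationError("genotype has no fully TFBS-free window")
    return float(np.mean(fracs))


def mean_tfbs_conservation(
    individual, tables: Sequence[ls.SpecificityTable]
) -> float:
    """Mean over all annotated sites of the fraction of the site's 24
    single-point mutants that stay binders for the same TF."""
    sites = individual.network.sites
    if not sites:
        raise GenerationError("individual has no annotated TFBS")
    stack = ls.kappa_stack(tables)
    vals = []
    for s in sites:
        idx = ls.window_indices(individual.genotype.urrs[s.gene])[s.offset]
        mut = ls.mutant_indices(int(idx))
        vals.append(float(np.count_nonzero(stack[s.tf, mut])) / 24.0)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# rewiring
# ---------------------------------------------------------------------------


def rewiring_phi(
    net_founder: RegulatoryNetwork | np.ndarray,
    net_individual: RegulatoryNetwork | np.ndarray,
) -> float:
    """Complement of the Jaccard overlap of the nonzero (i, j) patterns."""
    wf = net_founder.w if isinstance(net_founder, RegulatoryNetwork) else net_founder
    wi = (
        net_individual.w
        if isinstance(net_individual, RegulatoryNetwork)
        else net_individual
    )
    pf = np.asarray(wf) != 0
    pi = np.asarray(wi) != 0
    union = int(np.count_nonzero(pf | pi))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(pf & pi))
    return 1.0 - inter / union


def estimate_rewiring(
    net_founder: RegulatoryNetwork | np.ndarray,
    net_individual: RegulatoryNetwork | np.ndarray,
    baseline: BaselineFit,
) -> RewiringEstimate:
    """Raw phi, its chance level at the individual's connectivity, and the
    baseline-corrected value, bundled."""
    phi_raw = rewiring_phi(net_founder, net_individual)
    conn = connectivity(
        net_individual
        if isinstance(net_individual, RegulatoryNetwork)
        else RegulatoryNetwork(w=net_individual)
    )
    return RewiringEstimate(
        phi_raw=phi_raw,
        phi_random=baseline.predict(conn),
        phi_corrected=phi_corrected(phi_raw, conn, baseline),
    )


def phi_corrected(phi_raw: float, conn: float, baseline: BaselineFit) -> float:
    """Rescale phi so that the chance level maps to 0 and total change to 1."""
    phi_rand = baseline.predict(conn)
    if phi_rand >= 1.0:
        raise BaselineError(f"predicted random phi {phi_rand} >= 1")
    return float(np.clip((phi_raw - phi_rand) / (1.0 - phi_rand), 0.0, 1.0))


def _random_viable(
    n: int,
    L: int,
    tables: Sequence[ls.SpecificityTable],
    rng: np.random.Generator,
    params: DynamicsParams,
    max_attempts: int = 10_000,
) -> np.ndarray:
    for _ in range(max_attempts):
        g = random_genotype(n, L, rng)
        w = build_w(g, tables)
        if develop(g, w, params).stable:
            return w
    raise GenerationError(f"no viable random individual found at L={L}")


def match_length_to_connectivity(
    target: float,
    tables: Sequence[ls.SpecificityTable],
    n: int,
    rng: np.random.Generator,
    n_samples: int = 30,
    max_length: int = 4000,
) -> int:
    """Smallest URR length whose mean random-genotype connectivity reaches
    ``target`` (connectivity is non-decreasing in L in expectation)."""
    if not 0.0 < target <= 1.0:
        raise InvalidParameterError("target connectivity must lie in (0, 1]")

    def mean_conn(L: int) -> float:
        return float(
            np.mean(
                [connectivity(build_w(random_genotype(n, L, rng), tables))
                 for _ in range(n_samples)]
            )
        )

    lo, hi = ls.K, None
    L = 16
    while L <= max_length:
        if mean_conn(L) >= target:
            hi = L
            break
        lo = L
        L *= 2
    if hi is None:
        raise GenerationError(f"connectivity {target} unreachable below L={max_length}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mean_conn(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def phi_random_baseline(
    connectivity_grid: Sequence[float],
    tables: Sequence[ls.SpecificityTable],
    config,
    rng: np.random.Generator,
    n_pairs: int = 50,
    params: DynamicsParams = DEFAULT_PARAMS,
) -> BaselineFit:
    """Fit phi_random = a + b * connectivity on random viable network pairs.

    For each grid point, L is tuned so random genotypes hit the target
    connectivity on average, then ``n_pairs`` independent viable pairs are
    generated and their phi and mean connectivity recorded.
    """
    if len(connectivity_grid) < 2:
        raise InvalidParameterError("need at least two grid points")
    n = config.n
    xs: List[float] = []
    ys: List[float] = []
    for target in connectivity_grid:
        L = match_length_to_connectivity(target, tables, n, rng)
        for _ in range(n_pairs):
            wa = _random_viable(n, L, tables, rng, params)
            wb = _random_viable(n, L, tables, rng, params)
            xs.append(0.5 * (connectivity(wa) + connectivity(wb)))
            ys.append(rewiring_phi(wa, wb))
    fit = stats.linregress(xs, ys)
    return BaselineFit(a=float(fit.intercept), b=float(fit.slope),
                       r2=float(fit.rvalue**2))


def net_redundancy(
    individual,
    tables: Sequence[ls.SpecificityTable],
    config,
    rng: np.random.Generator,
    n_random: int = 100,
) -> Tuple[int, float]:
    """(raw redundancy, redundancy minus the random-network expectation at
    matched connectivity)."""
    raw = redundancy_count(individual.network)
    conn = connectivity(individual.network)
    if conn == 0.0:
        return raw, float(raw)
    L = match_length_to_connectivity(conn, tables, config.n, rng)
    rand_vals = []
    for _ in range(n_random):
        g = random_genotype(config.n, L, rng)
        rand_vals.append(redundancy_count(build_network(g, tables)))
    return raw, float(raw - np.mean(rand_vals))
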