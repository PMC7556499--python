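"""Elitist multi-objective genetic algorithm (NSGA-II), maximization sense.

Used here to search the treatment design space — melatonin dose in
[0, 150] uM, day in [15, 60], species in {Persian, Mexican}, drought level
in [40, 100] % of field capacity — for input combinations that jointly
maximize the five surrogate-predicted morphological responses.

Everything is written from scratch: fast non-dominated sorting, crowding
distance, roulette-wheel parent selection on a rank/crowding fitness,
simulated-binary crossover (SBX) and polynomial mutation for the continuous
genes, a uniform exchange/flip for the discrete species gene, and elitist
(mu + lambda) truncation.  Parent selection by roulette wheel (rather than
the more common binary tournament) follows the procedure this pipeline
reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: (low, high) per gene: melatonin_uM, day, species code, fc_percent.
#: The species gene (index SPECIES_GENE) is discrete in {-1, +1}.
DEFAULT_BOUNDS = ((0.0, 150.0), (15.0, 60.0), (-1.0, 1.0), (40.0, 100.0))
SPECIES_GENE = 2


@dataclass
class GAConfig:
    """Run parameters; the defaults are the study's published settings."""

    pop_size: int = 200
    generations: int = 1000
    mutation_rate: float = 0.5
    crossover_rate: float = 0.7
    seed: int = 0
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0

    def __post_init__(self) -> None:
        if self.pop_size % 2:
            raise ValueError("pop_size must be even")
        for name in ("mutation_rate", "crossover_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance for maximization: a >= b everywhere, > somewhere."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return bool(np.all(a >= b) and np.any(a > b))


def fast_nondominated_sort(objectives: np.ndarray) -> list[np.ndarray]:
    """Partition a population (N x k objectives) into Pareto fronts.

    Front 0 is the non-dominated set; each later front is non-dominated
    once earlier fronts are removed.
    """
    obj = np.atleast_2d(np.asarray(objectives, float))
    n = len(obj)
    ge = np.all(obj[:, None, :] >= obj[None, :, :], axis=2)
    gt = np.any(obj[:, None, :] > obj[None, :, :], axis=2)
    dom = ge & gt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = np.ones(n, bool)
    while remaining.any():
        front = np.nonzero(remaining & (n_dominators == 0))[0]
        if front.size == 0:  # cannot happen with a strict partial order
            raise RuntimeError("non-dominated sort failed to make progress")
        fronts.append(front)
        remaining[front] = False
        n_dominators = n_dominators - dom[front].sum(axis=0)
    return fronts


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """Crowding distance of each member of one front (maximization-agnostic).

    Boundary members on any objective get +inf; interior members get the sum
    over objectives of the normalized gap between their two neighbours.
    Objectives that are constant over the front contribute nothing.
    """
    obj = np.atleast_2d(np.asarray(front_objectives, float))
    n, k = obj.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(k):
        order = np.argsort(obj[:, j], kind="stable")
        span = obj[order[-1], j] - obj[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            gaps = (obj[order[2:], j] - obj[order[:-2], j]) / span
            dist[order[1:-1]] += gaps
    return dist


def selection_fitness(ranks: np.ndarray, crowding: np.ndarray) -> np.ndarray:
    """Scalar fitness for roulette selection: (1 + c) / (2 * rank).

    ``rank`` counts fronts from 1; ``c`` is the crowding distance normalized
    to [0, 1] within each rank (infinite crowding maps to 1).  A lone
    individual in its front therefore has fitness exactly 1/rank.
    """
    ranks = np.asarray(ranks, float)
    crowding = np.asarray(crowding, float)
    c = np.zeros_like(crowding)
    for r in np.unique(ranks):
        mask = ranks == r
        cr = crowding[mask]
        finite = np.isfinite(cr)
        cn = np.zeros(mask.sum())
        if finite.any() and cr[finite].max() > 0:
            cn[finite] = cr[finite] / cr[finite].max()
        cn[~finite] = 1.0
        if not finite.any():
            cn[:] = 1.0
        c[mask] = cn
    return (1.0 + c) / (2.0 * ranks)


def roulette_spin(weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sample k indices with replacement, probability proportional to weight."""
    w = np.asarray(weights, float)
    if w.size == 0:
        raise ValueError("cannot select from an empty population")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("roulette weights must be nonnegative with positive sum")
    p = w / w.sum()
    return rng.choice(len(w), size=k, replace=True, p=p)


def roulette_select(
    ranks: np.ndarray, crowding: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Roulette-wheel parent selection on the rank/crowding fitness."""
    return roulette_spin(selection_fitness(ranks, crowding), k, rng)


def _sbx_pair(a, b, low, high, eta, rng):
    """Simulated-binary crossover of two scalars inside [low, high]."""
    if abs(a - b) < 1e-14:
        return a, b
    u = rng.random()
    beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (1 / (2 * (1 - u))) ** (1 / (eta + 1))
    c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    return float(np.clip(c1, low, high)), float(np.clip(c2, low, high))


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    bounds=DEFAULT_BOUNDS,
    eta: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """SBX on continuous genes, uniform exchange on the species gene.

    With probability ``1 - rate`` the parents pass through unchanged.
    """
    a = np.array(parent_a, float)
    b = np.array(parent_b, float)
    if rng.random() >= rate:
        return a, b
    for g, (low, high) in enumerate(bounds):
        if g == SPECIES_GENE:
            if rng.random() < 0.5:
                a[g], b[g] = b[g], a[g]
        else:
            a[g], b[g] = _sbx_pair(a[g], b[g], low, high, eta, rng)
    return a, b


def mutate(
    individual: np.ndarray,
    rate: float,
    bounds=DEFAULT_BOUNDS,
    rng: np.random.Generator | None = None,
    eta: float = 20.0,
) -> np.ndarray:
    """Polynomial mutation (continuous genes) / flip (species gene).

    ``rate`` is the per-individual probability that mutation happens at all;
    a mutated individual then perturbs each gene with probability 1/n_genes.
    """
    rng = rng or np.random.default_rng()
    x = np.array(individual, float)
    if rng.random() >= rate:
        return x
    n = len(x)
    for g, (low, high) in enumerate(bounds):
        if rng.random() >= 1.0 / n:
            continue
        if g == SPECIES_GENE:
            x[g] = -x[g]
            continue
        span = high - low
        u = rng.random()
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        x[g] = float(np.clip(x[g] + delta * span, low, high))
    return x


def hypervolume_2d(points: np.ndarray, reference: np.ndarray) -> float:
    """Exact dominated hypervolume of a 2-objective set (maximization)."""
    pts = np.atleast_2d(np.asarray(points, float))
    ref = np.asarray(reference, float)
    pts = pts[np.all(pts > ref, axis=1)]
    if len(pts) == 0:
        return 0.0
    order = np.argsort(-pts[:, 0], kind="stable")
    pts = pts[order]
    hv = 0.0
    prev_y = ref[1]
    for x, y in pts:
        if y > prev_y:
            hv += (x - ref[0]) * (y - prev_y)
            prev_y = y
    return hv


def hypervolume_mc(
    points: np.ndarray,
    reference: np.ndarray,
    n_samples: int = 20000,
    seed: int = 0,
) -> float:
    """Seeded Monte-Carlo estimate of the dominated hypervolume (any k)."""
    pts = np.atleast_2d(np.asarray(points, float))
    ref = np.asarray(reference, float)
    upper = pts.max(axis=0)
    if np.any(upper <= ref):
        return 0.0
    rng = np.random.default_rng(seed)
    samples = rng.uniform(ref, upper, size=(n_samples, len(ref)))
    covered = np.zeros(n_samples, bool)
    for p in pts:
        covered |= np.all(samples <= p, axis=1)
    box = float(np.prod(upper - ref))
    return box * covered.mean()


@dataclass
class ParetoFront:
    """Final non-dominated set: designs and their predicted responses."""

    designs: np.ndarray  # N x 4 in original units (species gene +-1)
    objectives: np.ndarray  # N x k in original units
    objective_names: list[str]
    history: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.designs)

    def to_dataframe(self) -> pd.DataFrame:
        from .dataset import FACTOR_COLUMNS, decode_species

        df = pd.DataFrame(self.designs, columns=list(FACTOR_COLUMNS))
        df["species"] = decode_species(df["species"].to_numpy())
        for j, name in enumerate(self.objective_names):
            df[f"pred_{name}"] = self.objectives[:, j]
        return df


def _init_population(pop_size, bounds, rng):
    pop = np.empty((pop_size, len(bounds)))
    for g, (low, high) in enumerate(bounds):
        if g == SPECIES_GENE:
            pop[:, g] = rng.choice([-1.0, 1.0], pop_size)
        else:
            pop[:, g] = rng.uniform(low, high, pop_size)
    return pop


def _rank_and_crowd(objectives):
    fronts = fast_nondominated_sort(objectives)
    ranks = np.empty(len(objectives))
    crowd = np.empty(len(objectives))
    for r, front in enumerate(fronts, start=1):
        ranks[front] = r
        crowd[front] = crowding_distance(objectives[front])
    return fronts, ranks, crowd


def optimize(
    evaluate,
    config: GAConfig,
    bounds=DEFAULT_BOUNDS,
    objective_names: list[str] | None = None,
    track_hypervolume: bool = False,
) -> ParetoFront:
    """Run the generational NSGA-II loop and return the final first front.

    ``evaluate`` maps an (N x n_genes) design matrix to an (N x k) objective
    matrix (larger is better on every column).  The loop is: evaluate ->
    non-dominated sort -> crowding -> roulette parent selection ->
    SBX/mutation -> elitist (mu + lambda) truncation.
    """
    rng = np.random.default_rng(config.seed)
    pop = _init_population(config.pop_size, bounds, rng)
    obj = np.atleast_2d(np.asarray(evaluate(pop), float))
    if obj.shape[0] != len(pop):
        raise RuntimeError("surrogate evaluation returned a wrong-sized matrix")
    log = []
    for gen in range(config.generations):
        fronts, ranks, crowd = _rank_and_crowd(obj)
        if track_hypervolume:
            f0 = obj[fronts[0]]
            ref = obj.min(axis=0) - 1.0 if gen == 0 else log[0]["_ref"]
            hv = (
                hypervolume_2d(f0, ref)
                if obj.shape[1] == 2
                else hypervolume_mc(f0, ref, seed=config.seed)
            )
            log.append({"generation": gen, "front_size": len(fronts[0]), "hypervolume": hv, "_ref": ref})
        parents_idx = roulette_select(ranks, crowd, config.pop_size, rng)
        children = np.empty_like(pop)
        for i in range(0, config.pop_size, 2):
            pa, pb = pop[parents_idx[i]], pop[parents_idx[i + 1]]
            ca, cb = crossover(pa, pb, config.crossover_rate, rng, bounds, config.eta_crossover)
            children[i] = mutate(ca, config.mutation_rate, bounds, rng, config.eta_mutation)
            children[i + 1] = mutate(cb, config.mutation_rate, bounds, rng, config.eta_mutation)
        child_obj = np.atleast_2d(np.asarray(evaluate(children), float))
        if child_obj.shape[0] != len(children):
            raise RuntimeError(
                f"surrogate evaluation failed at generation {gen}: wrong-sized matrix"
            )
        if not np.all(np.isfinite(child_obj)):
            raise RuntimeError(f"surrogate evaluation failed at generation {gen}: non-finite objectives")
        merged = np.vstack([pop, children])
        merged_obj = np.vstack([obj, child_obj])
        fronts, ranks, crowd = _rank_and_crowd(merged_obj)
        # elitist truncation: by front, splitting the last front on crowding
        keep = []
        for front in fronts:
            if len(keep) + len(front) <= config.pop_size:
                keep.extend(front.tolist())
            else:
                need = config.pop_size - len(keep)
                order = np.argsort(-crowd[front], kind="stable")
                keep.extend(front[order[:need]].tolist())
                break
        keep = np.array(keep)
        pop, obj = merged[keep], merged_obj[keep]
    fronts, _, _ = _rank_and_crowd(obj)
    final = fronts[0]
    names = objective_names or [f"objective_{j}" for j in range(obj.shape[1])]
    history = None
    if log:
        history = pd.DataFrame([{k: v for k, v in row.items() if k != "_ref"} for row in log])
    return ParetoFront(pop[final].copy(), obj[final].copy(), list(names), history)


def select_ideal_point(front: ParetoFront, tie_objective: int = 0) -> int:
    """Index of the front member closest to the per-objective maxima.

    Each objective is min-max normalized over the front to [0, 1]
    (constant objectives contribute zero distance) and the member with the
    smallest Euclidean distance to the all-ones vector wins; ties go to the
    larger value of ``tie_objective`` (by default the first objective,
    leaf count in the morphology pipeline).
    """
    obj = front.objectives
    if len(obj) == 0:
        raise ValueError("empty Pareto front")
    lo = obj.min(axis=0)
    hi = obj.max(axis=0)
    span = hi - lo
    z = np.ones_like(obj, dtype=float)
    nz = span > 0
    z[:, nz] = (obj[:, nz] - lo[nz]) / span[nz]
    dist = np.sqrt(np.sum((1.0 - z) ** 2, axis=1))
    best = np.min(dist)
    tied = np.nonzero(np.isclose(dist, best, rtol=0, atol=1e-12))[0]
    if len(tied) > 1:
        tied = tied[np.argsort(-obj[tied, tie_objective], kind="stable")]
    return int(tied[0])
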