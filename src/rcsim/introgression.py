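"""External recurrent-selection pool and donor injection into the main scheme.

The pool restarts from the same founder DH panel as the main scheme and is
advanced by mild recurrent selection (200 of 409 lines per generation on a
weighted own-phenotype index, random pairing, DH offspring so the pool
stays fully homozygous).  Per-trait index weights are re-derived from the
remaining shortfall to the main scheme's current trait means so all traits
progress at similar rates.  Evolution stops once the pool's index mean
exceeds the target; the generation *before* the crossing supplies the
slightly-lower-performance donor lines that replace one parent in a
configurable share of the main scheme's matings.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np

from .founders import Cohort
from .genome import MatingEntry, MatingPlan, produce_offspring
from .traits import DH_TRAITS, TraitArchitecture, TraitConfig, genetic_values, simulate_phenotypes
from .prediction import selection_index

__all__ = [
    "ExternalPool",
    "PoolConvergenceError",
    "create_external_pool",
    "evolve_external_pool",
    "inject_external",
]


class PoolConvergenceError(RuntimeError):
    def __init__(self, cap: int):
        super().__init__(
            f"external pool did not exceed the target mean within {cap} generations"
        )
        self.cap = cap


@dataclasses.dataclass
class ExternalPool:
    """State of the outside recurrent-selection population (fully homozygous)."""

    cohort: Cohort
    generation: int = 0
    weights: np.ndarray = dataclasses.field(default_factory=lambda: np.full(3, 1 / 3))
    history: list = dataclasses.field(default_factory=list)  # per-generation records
    threshold_generation: int | None = None
    previous: Cohort | None = None  # generation before the last advance

    @property
    def size(self) -> int:
        return self.cohort.n


def create_external_pool(founders: Cohort) -> ExternalPool:
    """Start the pool from a copy of the founder panel, tagged external."""
    cohort = Cohort(
        ids=np.array([f"EXT0_{i:04d}" for i in range(founders.n)], dtype=object),
        haplotypes=founders.haplotypes.copy(),
        parents=None,
        label="external_pool_g0",
        cycle=0,
        origin=np.full(founders.n, "external", dtype=object),
    )
    return ExternalPool(cohort=cohort)


def _trait_means(cohort: Cohort, arch: TraitArchitecture) -> np.ndarray:
    return genetic_values(cohort, arch)[:, list(DH_TRAITS)].mean(axis=0)


def _shortfall_weights(current: np.ndarray, target: np.ndarray) -> np.ndarray:
    # traits 1 and 2 are bred upward, the final stage downward
    s = np.array(
        [
            max(0.0, target[0] - current[0]),
            max(0.0, target[1] - current[1]),
            max(0.0, current[2] - target[2]),
        ]
    )
    total = s.sum()
    if total <= 0:
        return np.full(3, 1 / 3)
    return s / total


def evolve_external_pool(
    pool: ExternalPool,
    target_means: np.ndarray,
    arch: TraitArchitecture,
    trait_config: TraitConfig,
    gmap,
    rng: np.random.Generator,
    n_select: int = 200,
    max_generations: int = 100,
) -> tuple[ExternalPool, Cohort]:
    """Advance the pool until its mean index exceeds the target index.

    ``target_means`` are the main scheme's current per-trait true means (DH
    trait variants, gSD units).  Returns the updated pool and the donor
    cohort (the pre-crossing generation, or the current cohort if the
    threshold was already met).  Raises :class:`PoolConvergenceError` after
    ``max_generations`` advances within this call.
    """
    target_means = np.asarray(target_means, dtype=float)
    target_index = float(selection_index(target_means[None, :])[0])
    for step in range(max_generations + 1):
        current = _trait_means(pool.cohort, arch)
        current_index = float(selection_index(current[None, :])[0])
        pool.history.append(
            {
                "generation": pool.generation,
                "means": current,
                "index_mean": current_index,
                "weights": pool.weights.copy(),
                "target_index": target_index,
            }
        )
        if current_index > target_index:
            pool.threshold_generation = pool.generation
            donor = pool.previous if pool.previous is not None else pool.cohort
            return pool, donor
        if step == max_generations:
            raise PoolConvergenceError(max_generations)
        pool.weights = _shortfall_weights(current, target_means)
        phen = simulate_phenotypes(
            pool.cohort,
            arch,
            trait_config,
            trait_indices=DH_TRAITS,
            cycle_measured=pool.generation,
            availability_delay=0,
            rng=rng,
            source="external",
        )
        sel_idx_vals = selection_index(
            phen.values, weights=(pool.weights[0], pool.weights[1], -pool.weights[2])
        )
        order = np.argsort(-sel_idx_vals, kind="stable")[:n_select]
        selected = pool.cohort.subset(order)
        perm = rng.permutation(n_select)
        n_pairs = n_select // 2
        per_pair = _distribute(pool.size, n_pairs)
        entries = [
            MatingEntry(
                parent1=selected.ids[perm[2 * k]],
                parent2=selected.ids[perm[2 * k + 1]],
                n_offspring=per_pair[k],
                pipeline="cross_then_dh",
            )
            for k in range(n_pairs)
        ]
        gen = pool.generation + 1
        offspring = produce_offspring(
            selected,
            MatingPlan(entries=entries),
            gmap,
            rng,
            label=f"EXT{gen}",
            cycle=gen,
        )
        offspring.origin[:] = "external"
        pool.previous = pool.cohort
        pool.cohort = offspring
        pool.generation = gen
    raise PoolConvergenceError(max_generations)  # pragma: no cover


def _distribute(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total - base * parts
    return [base + 1 if k < rem else base for k in range(parts)]


def inject_external(
    plan: MatingPlan,
    donors: Cohort,
    proportion: float,
    rng: np.random.Generator,
) -> MatingPlan:
    """Replace one parent in ``round(p * n_pairs)`` randomly chosen matings.

    Donor lines are drawn without replacement while they last (then with
    replacement) and must be fully homozygous.  The affected entries are
    tagged ``external``; which side of the pair is replaced is random.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must lie in [0, 1]")
    n_pairs = len(plan.entries)
    k = int(round(proportion * n_pairs))
    if k == 0:
        return plan
    if donors is None or donors.n == 0:
        raise ValueError("cannot inject external material from an empty donor cohort")
    if not np.all(donors.is_homozygous()):
        raise AssertionError("donor lines must be fully homozygous DH lines")
    chosen = rng.choice(n_pairs, size=k, replace=False)
    if donors.n >= k:
        donor_ids = donors.ids[rng.choice(donors.n, size=k, replace=False)]
    else:
        donor_ids = donors.ids[rng.choice(donors.n, size=k, replace=True)]
    entries = [copy.copy(e) for e in plan.entries]
    sides = rng.integers(0, 2, size=k)
    for pos, did, side in zip(chosen, donor_ids, sides):
        e = entries[pos]
        if side == 0:
            e.parent1 = did
        else:
            e.parent2 = did
        e.external = True
    return MatingPlan(entries=entries)
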