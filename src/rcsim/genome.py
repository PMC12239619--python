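"""Meiosis and cohort production: gametes, crosses, selfing, DH induction.

Recombination follows the Haldane (no-interference) model: per chromosome
the crossover count is Poisson with mean equal to the chromosome length in
Morgan, crossover positions are uniform, and the starting parental strand is
a fair coin per chromosome.  Mutation is not modelled.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .founders import Cohort, GeneticMap

__all__ = ["MatingEntry", "MatingPlan", "sample_gametes", "sample_gamete", "produce_offspring"]

PIPELINES = ("cross", "cross_then_self", "self", "dh_induction", "cross_then_dh")


@dataclasses.dataclass
class MatingEntry:
    """One mating: a parent pair, an offspring count and a production pipeline.

    Pipelines
    ---------
    cross
        Each offspring gets one independent gamete from each parent.
    cross_then_self
        A single F1 plant is made from the pair and selfed; each offspring is
        two independent F1 gametes (F2 lines).
    self
        Requires parent1 == parent2; offspring from two independent gametes.
    dh_induction
        One gamete of parent1 doubled into a fully homozygous line.
    cross_then_dh
        A single F1 from the pair; each offspring is one doubled F1 gamete.
    """

    parent1: str
    parent2: str
    n_offspring: int = 1
    pipeline: str = "cross"
    external: bool = False  # one parent came from outside the breeding pool

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.pipeline not in PIPELINES:
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        if self.pipeline == "self" and self.parent1 != self.parent2:
            raise ValueError("pipeline 'self' requires parent1 == parent2")


@dataclasses.dataclass
class MatingPlan:
    entries: list[MatingEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_offspring(self) -> int:
        return sum(e.n_offspring for e in self.entries)

    def validate(self, cohort: Cohort) -> None:
        present = set(cohort.ids)
        for e in self.entries:
            for p in (e.parent1, e.parent2):
                if p not in present:
                    raise KeyError(f"parent {p!r} not present in cohort {cohort.label!r}")

    @staticmethod
    def from_pairs(pairs, n_offspring, pipeline: str = "cross_then_self") -> "MatingPlan":
        """Build a plan from parent pairs; ``n_offspring`` is an int or a sequence."""
        if np.isscalar(n_offspring):
            n_offspring = [int(n_offspring)] * len(pairs)
        return MatingPlan(
            entries=[
                MatingEntry(parent1=a, parent2=b, n_offspring=int(n), pipeline=pipeline)
                for (a, b), n in zip(pairs, n_offspring)
            ]
        )


try:  # optional JIT of the per-gamete mosaic assembly
    from numba import njit

    @njit(cache=True)
    def _phase_kernel(pos, k, xo_sorted, offsets, start, out):
        G = k.shape[0]
        L = pos.shape[0]
        for g in range(G):
            o, kk, j = offsets[g], k[g], 0
            for m in range(L):
                while j < kk and xo_sorted[o + j] < pos[m]:
                    j += 1
                out[g, m] = (start[g] + j) % 2

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _phase_numpy(pos, k, xo_sorted, offsets, start, out):
    kmax = int(k.max())
    G = len(k)
    pad = np.full((G, kmax), np.inf)
    for g in range(G):  # ragged -> padded; kmax is small (Poisson(length))
        pad[g, : k[g]] = xo_sorted[offsets[g] : offsets[g] + k[g]]
    counts = (pad[:, :, None] < pos[None, None, :]).sum(axis=1)
    out[:] = (start[:, None] + counts) % 2


def sample_gametes(haplotypes: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Sample one gamete per row of ``haplotypes`` (shape (G, 2, M)) -> (G, M).

    For each (gamete, chromosome) the number of crossovers is
    Poisson(length), positions are uniform on the chromosome, and the
    marker-wise parental strand is the crossover-count parity added to a
    fair-coin start.  The mosaic assembly is JIT-compiled when numba is
    installed; the fallback consumes the random stream identically.
    """
    hap = np.asarray(haplotypes)
    if hap.ndim == 2:  # single individual convenience
        hap = hap[None]
    G, _, M = hap.shape
    out = np.empty((G, M), dtype=hap.dtype)
    for sl in gmap.chromosome_slices():
        pos = gmap.pos[sl]
        length = float(pos[-1] - pos[0]) if len(pos) > 1 else 0.0
        start = rng.integers(0, 2, size=G)
        k = rng.poisson(length, size=G) if length > 0.0 else np.zeros(G, dtype=np.int64)
        total = int(k.sum())
        if total == 0:
            phase = np.broadcast_to(start[:, None], (G, len(pos)))
        else:
            xo = rng.uniform(pos[0], pos[-1], size=total)
            offsets = np.concatenate([[0], np.cumsum(k)[:-1]]).astype(np.int64)
            for g in range(G):  # sort within each gamete's block
                xo[offsets[g] : offsets[g] + k[g]].sort()
            phase = np.empty((G, len(pos)), dtype=np.int64)
            if _HAVE_NUMBA:
                _phase_kernel(pos, k.astype(np.int64), xo, offsets, start.astype(np.int64), phase)
            else:
                _phase_numpy(pos, k, xo, offsets, start, phase)
        h0, h1 = hap[:, 0, sl], hap[:, 1, sl]
        out[:, sl] = np.where(phase == 0, h0, h1)
    return out


def sample_gamete(individual_haplotypes: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Single-meiosis convenience wrapper around :func:`sample_gametes`."""
    return sample_gametes(individual_haplotypes[None], gmap, rng)[0]


def _repeat_hap(hap: np.ndarray, n: int) -> np.ndarray:
    return np.broadcast_to(hap, (n,) + hap.shape)


def produce_offspring(
    cohort: Cohort,
    plan: MatingPlan,
    gmap: GeneticMap,
    rng: np.random.Generator,
    label: str = "offspring",
    cycle: int = 0,
    f1_per_offspring: bool = False,
) -> Cohort:
    """Execute a mating plan against ``cohort`` and return the offspring cohort.

    ``f1_per_offspring`` switches the two-step pipelines from the default
    "one F1 plant per entry, selfed/induced many times" semantics to making
    a fresh F1 meiosis product per offspring.
    """
    plan.validate(cohort)
    lookup = {i: k for k, i in enumerate(cohort.ids)}
    hap_out, ids, parents, origin = [], [], [], []
    counter = 0
    for e in plan.entries:
        i1, i2 = lookup[e.parent1], lookup[e.parent2]
        h1, h2 = cohort.haplotypes[i1], cohort.haplotypes[i2]
        n = e.n_offspring
        if e.pipeline == "cross":
            g1 = sample_gametes(_repeat_hap(h1, n), gmap, rng)
            g2 = sample_gametes(_repeat_hap(h2, n), gmap, rng)
            child = np.stack([g1, g2], axis=1)
        elif e.pipeline == "self":
            g = sample_gametes(_repeat_hap(h1, 2 * n), gmap, rng)
            child = np.stack([g[:n], g[n:]], axis=1)
        elif e.pipeline == "dh_induction":
            g = sample_gametes(_repeat_hap(h1, n), gmap, rng)
            child = np.stack([g, g], axis=1)
        elif e.pipeline in ("cross_then_self", "cross_then_dh"):
            n_f1 = n if f1_per_offspring else 1
            f1 = np.stack(
                [
                    sample_gametes(_repeat_hap(h1, n_f1), gmap, rng),
                    sample_gametes(_repeat_hap(h2, n_f1), gmap, rng),
                ],
                axis=1,
            )  # (n_f1, 2, M)
            if e.pipeline == "cross_then_dh":
                if f1_per_offspring:
                    g = sample_gametes(f1, gmap, rng)
                else:
                    g = sample_gametes(_repeat_hap(f1[0], n), gmap, rng)
                child = np.stack([g, g], axis=1)
            else:
                if f1_per_offspring:
                    ga = sample_gametes(f1, gmap, rng)
                    gb = sample_gametes(f1, gmap, rng)
                else:
                    g = sample_gametes(_repeat_hap(f1[0], 2 * n), gmap, rng)
                    ga, gb = g[:n], g[n:]
                child = np.stack([ga, gb], axis=1)
        else:  # pragma: no cover - guarded in MatingEntry
            raise ValueError(e.pipeline)
        hap_out.append(child)
        for _ in range(n):
            ids.append(f"{label}_{counter:05d}")
            counter += 1
        parents.extend([(e.parent1, e.parent2)] * n)
        origin.extend(["internal"] * n)
    return Cohort(
        ids=np.array(ids, dtype=object),
        haplotypes=np.concatenate(hap_out, axis=0),
        parents=np.array(parents, dtype=object),
        label=label,
        cycle=cycle,
        origin=np.array(origin, dtype=object),
    )
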