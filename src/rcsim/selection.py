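"""Parent selection: truncation with origin caps, random pairing, angle OCS.

The optimum-contribution selector follows the target-degrees decision rule:
with equal contributions and every candidate usable at most once, the
achievable (gain, group-coancestry) plane is min-max normalized between the
max-gain solution (truncation) and a min-coancestry solution found at equal
search budget, and the returned subset maximizes progress from the worst
point along the direction at ``target_degrees`` from the gain axis
(0 degrees = pure gain, 90 degrees = pure diversity).  The metaheuristic is
a simulated-annealing swap search with incremental objective updates.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genome import MatingEntry, MatingPlan

__all__ = [
    "InfeasibleSelectionError",
    "truncation_select",
    "random_pairing",
    "OcsSolution",
    "ocs_select",
    "export_ocs_instance",
    "read_ocs_instance",
]


class InfeasibleSelectionError(ValueError):
    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"origin cap makes selecting {requested} candidates infeasible; "
            f"at most {achievable} are selectable"
        )


def _ranked_order(index_values: np.ndarray, ids) -> list[int]:
    # decreasing index; ties broken by stable id order
    if ids is None:
        ids = np.arange(len(index_values))
    return sorted(range(len(index_values)), key=lambda i: (-index_values[i], ids[i]))


def truncation_select(
    index_values: np.ndarray,
    n: int,
    ids=None,
    origin_cap: int | None = None,
    origins=None,
) -> np.ndarray:
    """Select the top-``n`` candidates by index, optionally capping per-origin counts.

    ``origins`` maps each candidate to the founder lines it descends from
    (a sequence of id-tuples); with ``origin_cap`` a candidate is accepted
    only if acceptance keeps every one of its origins at or below the cap
    (each candidate counts toward all of its origins).  Raises
    :class:`InfeasibleSelectionError` (reporting the achievable maximum)
    when the cap cannot yield ``n`` selections.
    """
    index_values = np.asarray(index_values, dtype=float)
    if n > len(index_values):
        raise ValueError(f"cannot select {n} of {len(index_values)} candidates")
    order = _ranked_order(index_values, ids)
    if origin_cap is None:
        return np.array(order[:n], dtype=np.intp)
    if origins is None:
        raise ValueError("origin_cap requires per-candidate origins")
    counts: dict = {}
    accepted: list[int] = []
    for i in order:
        cand_orig = tuple(origins[i])
        if all(counts.get(o, 0) < origin_cap for o in cand_orig):
            accepted.append(i)
            for o in cand_orig:
                counts[o] = counts.get(o, 0) + 1
            if len(accepted) == n:
                return np.array(accepted, dtype=np.intp)
    raise InfeasibleSelectionError(requested=n, achievable=len(accepted))


def random_pairing(ids, rng: np.random.Generator, n_offspring: int = 1, pipeline: str = "cross_then_self") -> MatingPlan:
    """Uniformly random perfect matching of the given ids into a mating plan."""
    ids = list(ids)
    if len(ids) % 2 != 0:
        raise ValueError(f"random pairing needs an even number of parents, got {len(ids)}")
    perm = rng.permutation(len(ids))
    entries = [
        MatingEntry(parent1=ids[perm[k]], parent2=ids[perm[k + 1]], n_offspring=n_offspring, pipeline=pipeline)
        for k in range(0, len(ids), 2)
    ]
    return MatingPlan(entries=entries)


@dataclasses.dataclass
class OcsSolution:
    """Outcome of the angle-based optimum-contribution search."""

    selected: np.ndarray  # candidate indices, each used exactly once
    pairs: list  # list of (index, index) mating pairs
    gain: float  # mean index EBV of the selected set
    coancestry: float  # mean of the selected x selected relationship block
    norm_gain: float  # gain axis, 0 = min-coancestry endpoint, 1 = truncation
    norm_diversity: float  # 1 - normalized coancestry
    achieved_angle: float  # degrees from the gain axis

    def validate_unique(self) -> None:
        if len(np.unique(self.selected)) != len(self.selected):
            raise AssertionError("OCS solution reuses a candidate")


class _SubsetState:
    """Fixed-size subset with O(N) incremental gain/coancestry updates."""

    def __init__(self, ebv: np.ndarray, G: np.ndarray, selected: np.ndarray):
        self.ebv = ebv
        self.G = G
        self.n = len(selected)
        self.in_set = np.zeros(len(ebv), dtype=bool)
        self.in_set[selected] = True
        self.sum_ebv = float(ebv[selected].sum())
        self.rowsum = G[:, selected].sum(axis=1)  # over all candidates
        self.block_sum = float(self.rowsum[selected].sum())

    def gain(self) -> float:
        return self.sum_ebv / self.n

    def coancestry(self) -> float:
        return self.block_sum / (self.n * self.n)

    def peek_swap(self, out_i: int, in_j: int) -> tuple[float, float]:
        g = self.G
        new_sum = self.sum_ebv - self.ebv[out_i] + self.ebv[in_j]
        new_block = (
            self.block_sum
            - 2.0 * self.rowsum[out_i]
            + g[out_i, out_i]
            + 2.0 * (self.rowsum[in_j] - g[in_j, out_i])
            + g[in_j, in_j]
        )
        return new_sum / self.n, new_block / (self.n * self.n)

    def apply_swap(self, out_i: int, in_j: int) -> None:
        self.sum_ebv = self.sum_ebv - self.ebv[out_i] + self.ebv[in_j]
        self.block_sum = (
            self.block_sum
            - 2.0 * self.rowsum[out_i]
            + self.G[out_i, out_i]
            + 2.0 * (self.rowsum[in_j] - self.G[in_j, out_i])
            + self.G[in_j, in_j]
        )
        self.rowsum += self.G[:, in_j] - self.G[:, out_i]
        self.in_set[out_i] = False
        self.in_set[in_j] = True

    def members(self) -> np.ndarray:
        return np.flatnonzero(self.in_set)


def _anneal(ebv, G, start, score, budget, rng, t0=0.25, t1=1e-4):
    """Maximize ``score(gain, coancestry)`` over same-size subsets by swap SA."""
    state = _SubsetState(ebv, G, start)
    current = score(state.gain(), state.coancestry())
    best_members = state.members().copy()
    best = current
    n_cand = len(ebv)
    if budget <= 0:
        raise ValueError("search budget must be positive")
    temps = t0 * (t1 / t0) ** (np.arange(budget) / max(budget - 1, 1))
    sel_pick = rng.integers(0, state.n, size=budget)
    cand_pick = rng.integers(0, n_cand, size=budget)
    accept_u = rng.random(budget)
    for it in range(budget):
        members = state.members()
        out_i = members[sel_pick[it]]
        in_j = cand_pick[it]
        if state.in_set[in_j]:
            continue
        g, c = state.peek_swap(out_i, in_j)
        new = score(g, c)
        delta = new - current
        if delta >= 0 or accept_u[it] < np.exp(delta / temps[it]):
            state.apply_swap(out_i, in_j)
            current = new
            if current > best:
                best = current
                best_members = state.members().copy()
    return best_members


def ocs_select(
    index_ebv: np.ndarray,
    G: np.ndarray,
    n_parents: int,
    target_degrees: float,
    budget: int = 4000,
    rng: np.random.Generator | int | None = 0,
    ids=None,
    pair: bool = True,
) -> OcsSolution:
    """Select ``n_parents`` equal-contribution parents at a gain/coancestry angle.

    See the module docstring for the objective geometry.  ``budget`` is the
    number of annealing moves (the same budget is spent on locating the
    min-coancestry endpoint).  Pairs among the selected parents are formed
    at random.
    """
    ebv = np.asarray(index_ebv, dtype=float)
    G = np.asarray(G, dtype=float)
    if n_parents % 2 != 0 or n_parents > len(ebv):
        raise ValueError("n_parents must be even and at most the candidate count")
    if not (0.0 <= target_degrees <= 90.0):
        raise ValueError("target_degrees must lie in [0, 90]")
    if budget <= 0:
        raise ValueError("search budget must be positive")
    rng = np.random.default_rng(rng)

    trunc = truncation_select(ebv, n_parents, ids=ids)
    st_a = _SubsetState(ebv, G, trunc)
    gain_a, coan_a = st_a.gain(), st_a.coancestry()

    min_coan = _anneal(ebv, G, trunc, lambda g, c: -c, budget, rng)
    st_b = _SubsetState(ebv, G, min_coan)
    gain_b, coan_b = st_b.gain(), st_b.coancestry()

    dg = gain_a - gain_b
    dc = coan_a - coan_b
    dg = dg if dg > 1e-12 else 1.0
    dc = dc if dc > 1e-12 else 1.0

    theta = np.deg2rad(target_degrees)

    if target_degrees <= 0.0:
        selected = trunc
    elif target_degrees >= 90.0:
        selected = min_coan
    else:
        def score(g, c):
            return np.cos(theta) * (g - gain_b) / dg + np.sin(theta) * (coan_a - c) / dc

        selected = _anneal(ebv, G, trunc, score, budget, rng)

    st = _SubsetState(ebv, G, selected)
    gain, coan = st.gain(), st.coancestry()
    norm_gain = (gain - gain_b) / dg
    norm_div = (coan_a - coan) / dc
    angle = float(np.rad2deg(np.arctan2(max(norm_div, 0.0), max(norm_gain, 0.0))))
    selected = np.sort(selected)
    perm = rng.permutation(len(selected))
    pairs = [
        (int(selected[perm[k]]), int(selected[perm[k + 1]])) for k in range(0, len(selected), 2)
    ] if pair else []
    sol = OcsSolution(
        selected=selected,
        pairs=pairs,
        gain=float(gain),
        coancestry=float(coan),
        norm_gain=float(norm_gain),
        norm_diversity=float(norm_div),
        achieved_angle=min(max(angle, 0.0), 90.0),
    )
    sol.validate_unique()
    return sol


def export_ocs_instance(path, ebv: np.ndarray, G: np.ndarray, ids=None) -> None:
    """Write an OCS instance as plain text (EBV column + relationship matrix)."""
    ids = np.arange(len(ebv)) if ids is None else np.asarray(ids)
    with open(path, "w") as fh:
        fh.write(f"# n {len(ebv)}\n")
        for i, e in zip(ids, ebv):
            fh.write(f"{i}\t{e:.10g}\n")
        for row in np.asarray(G, dtype=float):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_ocs_instance(path):
    with open(path) as fh:
        header = fh.readline().split()
        n = int(header[-1])
        ids, ebv = [], []
        for _ in range(n):
            a, b = fh.readline().split("\t")
            ids.append(a)
            ebv.append(float(b))
        G = np.array([[float(v) for v in fh.readline().split("\t")] for _ in range(n)])
    return np.array(ids, dtype=object), np.array(ebv), G
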