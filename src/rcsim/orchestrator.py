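"""Scheme orchestration: cycle state machine, training windows, replicates.

A replicate proceeds as follows.  A synthetic founder panel (default 409 DH
lines) is drawn and the trait architecture anchored to it.  Founders are
phenotyped once; the top ``n_initial_dh`` lines by gBLUP index enter a
half-diallel whose crosses are selfed into the first F2 pool.  Each
subsequent cycle assembles the training set allowed by the phenotype
availability delays, fits gBLUP per selection trait, ranks the F2 pool on
the three-trait index, selects parents (truncation, with a per-founder cap
in cycle 1, or angle OCS), pairs them at random (optionally swapping in
external donors), and selfs the pairs into the next F2 pool of constant
size.  Product DH lines are extracted from the top F2s every cycle for
evaluation only.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .founders import Cohort, GeneticMap, build_genetic_map, simulate_founder_panel
from .genome import MatingEntry, MatingPlan, produce_offspring
from .introgression import ExternalPool, create_external_pool, evolve_external_pool, inject_external
from .metrics import ReferenceStats, cohort_metrics
from .prediction import build_grm, fit_gblup, selection_index
from .selection import ocs_select, random_pairing, truncation_select
from .traits import (
    CROSS_TRAITS,
    DH_TRAITS,
    TraitArchitecture,
    TraitConfig,
    draw_architecture,
    genetic_values,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "SchemeState", "TrainingRecord", "assemble_training_set",
           "run_cycle", "run_replicate", "run_scenario", "distribute_offspring"]

PHENOTYPING_STRATEGIES = ("baseline", "crosses", "dh")


def distribute_offspring(total: int, parts: int) -> list[int]:
    """Split ``total`` offspring over ``parts`` matings, remainder to the first."""
    base = total // parts
    rem = total - base * parts
    return [base + 1 if k < rem else base for k in range(parts)]


@dataclasses.dataclass
class ScenarioConfig:
    """All parameters of one breeding-scheme scenario.

    Defaults reproduce the baseline rapid-cycle scheme: 409 founder DH
    lines, 10 initial parents in a half-diallel (45 crosses x 23 selfed
    offspring = 1,035 F2), 30 selected F2s forming 15 random pairs x 69
    offspring per cycle, 30 cycles, founder-only phenotypes.
    """

    # population sizes
    n_founders: int = 409
    n_initial_dh: int = 10
    n_selected_f2: int = 30
    f2_pool_size: int = 1035
    n_cycles: int = 30
    n_product_dh_parents: int = 3
    n_dh_per_product_parent: int = 10
    # cycle-1 cap on selected F2s per founder origin; "auto" scales the
    # baseline value (10 per founder when 30 of 1,035 are selected) with the
    # selection size so sweep scenarios stay feasible: ceil(n_selected_f2 / 3)
    cap_first_cycle: int | str | None = "auto"
    # genome
    n_chromosomes: int = 10
    markers_per_chromosome: int = 5000
    chromosome_length: float = 1.6  # Morgan
    founder_heterozygosity: float = 0.218  # panel mean 2pq; F2s start near 10.9% het
    # phenotyping strategy
    phenotyping: str = "baseline"
    cross_delay: int = 2
    dh_delay: int = 4
    dh_n_phenotyped: int = 200
    dh_training_window: int = 4
    phenotype_selected_only: bool = False  # crosses strategy: phenotype only selected F2s
    # introgression
    introgression: bool = False
    external_proportion: float = 0.2
    pool_n_selected: int = 200
    pool_max_generations: int = 100
    # optimum contribution selection
    ocs: bool = False
    target_degrees: float = 40.0
    ocs_budget: int = 4000
    # trait architecture
    trait_config: TraitConfig = dataclasses.field(default_factory=TraitConfig)
    n_reference_crosses: int = 1000
    exclude_qtl_from_array: bool = False
    f1_per_offspring: bool = False
    grm_dtype: str = "float32"  # GRM matmul precision inside the scheme
    ebv_output_dir: str | None = None  # write per-cycle candidate EBV tables as CSV

    def __post_init__(self) -> None:
        for name in (
            "n_founders", "n_initial_dh", "n_selected_f2", "f2_pool_size", "n_cycles",
            "n_product_dh_parents", "n_dh_per_product_parent", "n_chromosomes",
            "markers_per_chromosome", "dh_n_phenotyped", "dh_training_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.phenotyping not in PHENOTYPING_STRATEGIES:
            raise ValueError(f"phenotyping must be one of {PHENOTYPING_STRATEGIES}")
        if self.cross_delay < 0 or self.dh_delay < 0:
            raise ValueError("availability delays must be >= 0")
        if self.n_selected_f2 % 2 != 0:
            raise ValueError("n_selected_f2 must be even (parents are paired)")
        if self.n_selected_f2 > self.f2_pool_size:
            raise ValueError("cannot select more F2 lines than the pool holds")
        if not (0.0 <= self.external_proportion <= 1.0):
            raise ValueError("external_proportion must lie in [0, 1]")
        if isinstance(self.trait_config, dict):
            self.trait_config = TraitConfig(**self.trait_config)

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    @property
    def n_pairs(self) -> int:
        return self.n_selected_f2 // 2

    def offspring_per_pair(self) -> list[int]:
        return distribute_offspring(self.f2_pool_size, self.n_pairs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trait_config"] = {
            "h2": np.asarray(self.trait_config.h2).tolist(),
            "n_additive": self.trait_config.n_additive,
            "n_dominant": self.trait_config.n_dominant,
            "n_qualitative": self.trait_config.n_qualitative,
            "n_quantitative": self.trait_config.n_quantitative,
        }
        return d

    @staticmethod
    def from_yaml(path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return ScenarioConfig(**raw)


@dataclasses.dataclass
class TrainingRecord:
    """A phenotyped cohort retained for breeding-value training."""

    ids: np.ndarray
    genotypes: np.ndarray  # (n, M) uint8
    values: np.ndarray  # (n, 3) selection-trait phenotypes
    version: str  # "dh" or "cross"
    cycle_measured: int
    cycle_available: int
    source: str  # "founder", "internal", "external"


@dataclasses.dataclass
class SchemeState:
    """Mutable state carried across breeding cycles of one replicate."""

    config: ScenarioConfig
    gmap: GeneticMap
    founders: Cohort
    arch: TraitArchitecture
    reference: ReferenceStats
    f2: Cohort
    phenostore: list
    pool: ExternalPool | None
    rng_scheme: np.random.Generator
    rng_pheno: np.random.Generator
    rng_pool: np.random.Generator
    cycle: int = 1
    marker_mask: np.ndarray | None = None  # genotyping-array markers used for GRM

    def array_genotypes(self, cohort: Cohort) -> np.ndarray:
        g = cohort.genotypes()
        return g if self.marker_mask is None else g[:, self.marker_mask]


def _version_traits(version: str):
    return DH_TRAITS if version == "dh" else CROSS_TRAITS


def assemble_training_set(state: SchemeState, strategy: str, cycle: int):
    """Pick the training records visible at ``cycle`` under a strategy.

    Returns ``(records, version, fell_back)``.  Only phenotypes with
    ``cycle_available <= cycle`` are ever visible.  When a strategy has no
    available phenotypes yet (early cycles under a delay) it falls back to
    the founder phenotypes with a logged warning.
    """
    avail = [r for r in state.phenostore if r.cycle_available <= cycle]
    founder_recs = [r for r in avail if r.source == "founder"]
    if strategy == "baseline":
        return founder_recs, "dh", False
    if strategy == "crosses":
        cand = sorted(
            (r for r in avail if r.version == "cross" and r.source == "internal"),
            key=lambda r: r.cycle_measured,
        )
        if cand:
            return [cand[-1]], "cross", False
    elif strategy == "dh":
        internal = sorted(
            (r for r in avail if r.version == "dh" and r.source == "internal"),
            key=lambda r: r.cycle_measured,
        )
        external = sorted(
            (r for r in avail if r.version == "dh" and r.source == "external"),
            key=lambda r: r.cycle_measured,
        )
        if state.config.introgression and external:
            recs = internal[-2:] + external[-2:]
        else:
            recs = internal[-state.config.dh_training_window:]
        if recs:
            return recs, "dh", False
    else:
        raise ValueError(f"unknown phenotyping strategy {strategy!r}")
    logger.warning("cycle %d: no %s phenotypes available yet; falling back to founders", cycle, strategy)
    return founder_recs, "dh", True


def _fit_cycle_model(state: SchemeState, records, version: str):
    """Pooled-GRM gBLUP of the three selection traits; candidates = current F2.

    Allele frequencies are taken on the pooled training+candidate set.  Only
    the training and candidate-by-training GRM blocks are formed (the
    candidate block is added when OCS needs it).
    """
    train_geno = np.concatenate([r.genotypes for r in records], axis=0)
    train_y = np.concatenate([r.values for r in records], axis=0)
    cand_geno = state.array_genotypes(state.f2)
    dtype = np.float32 if state.config.grm_dtype == "float32" else np.float64
    nt, nc = train_geno.shape[0], cand_geno.shape[0]
    zt = train_geno.astype(dtype)
    zc = cand_geno.astype(dtype)
    p = (zt.sum(axis=0) + zc.sum(axis=0)) / (2.0 * (nt + nc))
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        # complete fixation of training and candidates: no genomic signal left,
        # EBVs carry no discrimination (selection falls back to stable id order)
        logger.warning("cycle pool fully monomorphic; EBVs set to zero")
        from .prediction import GBLUPResult, PredictionModel

        results = [
            GBLUPResult(0.0, 0.0, float(train_y[:, t].mean()), np.zeros(nt), np.zeros(nc))
            for t in range(train_y.shape[1])
        ]
        model = PredictionModel(
            train_idx=np.arange(nt), cand_idx=np.arange(nt, nt + nc),
            results=results,
            trait_names=tuple(f"t{t}" for t in _version_traits(version)),
        )
        return model, np.zeros((nc, nc))
    zt -= 2.0 * p
    zc -= 2.0 * p
    G = np.zeros((nt + nc, nt + nc), dtype=dtype)
    G[:nt, :nt] = (zt @ zt.T) / denom
    G[nt:, :nt] = (zc @ zt.T) / denom
    G[:nt, nt:] = G[nt:, :nt].T
    if state.config.ocs:
        G[nt:, nt:] = (zc @ zc.T) / denom
    model = fit_gblup(
        G,
        train_y,
        train_idx=np.arange(nt),
        cand_idx=np.arange(nt, nt + nc),
        trait_names=tuple(f"t{t}" for t in _version_traits(version)),
    )
    cand_block = np.asarray(G[nt:, nt:], dtype=np.float64)
    return model, cand_block


def _phenotype_store_cohort(state, cohort, version, cycle, delay, source, n_subset=None):
    cfg = state.config
    if n_subset is not None and n_subset < cohort.n:
        pick = state.rng_pheno.choice(cohort.n, size=n_subset, replace=False)
        cohort = cohort.subset(np.sort(pick))
    traits = DH_TRAITS if version == "dh" else CROSS_TRAITS
    phen = simulate_phenotypes(
        cohort,
        state.arch,
        cfg.trait_config,
        trait_indices=traits,
        cycle_measured=cycle,
        availability_delay=delay,
        rng=state.rng_pheno,
        source=source,
    )
    state.phenostore.append(
        TrainingRecord(
            ids=cohort.ids.copy(),
            genotypes=state.array_genotypes(cohort),
            values=phen.values,
            version=version,
            cycle_measured=cycle,
            cycle_available=cycle + delay,
            source=source,
        )
    )
    return phen


def initialize_state(config: ScenarioConfig, seed: int) -> SchemeState:
    """Draw founders and architecture, select initial parents, build C1F2."""
    ss = np.random.SeedSequence(seed)
    rng_founder, rng_arch, rng_scheme, rng_pheno, rng_pool = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    gmap = build_genetic_map(
        config.n_chromosomes, config.markers_per_chromosome, config.chromosome_length
    )
    founders = simulate_founder_panel(
        gmap, config.n_founders, config.founder_heterozygosity, rng_founder
    )
    arch = draw_architecture(
        gmap, config.trait_config, founders, rng_arch, n_reference_crosses=config.n_reference_crosses
    )
    reference = ReferenceStats.from_cohorts(founders, arch.reference_cohort, arch)
    marker_mask = None
    if config.exclude_qtl_from_array:
        marker_mask = np.ones(gmap.n_markers, dtype=bool)
        marker_mask[arch.qtl_loci()] = False

    state = SchemeState(
        config=config,
        gmap=gmap,
        founders=founders,
        arch=arch,
        reference=reference,
        f2=founders,  # placeholder until C1F2 exists
        phenostore=[],
        pool=create_external_pool(founders) if config.introgression else None,
        rng_scheme=rng_scheme,
        rng_pheno=rng_pheno,
        rng_pool=rng_pool,
        cycle=0,
        marker_mask=marker_mask,
    )

    # founders phenotyped once (DH traits, no delay) and kept for training
    _phenotype_store_cohort(state, founders, "dh", cycle=0, delay=0, source="founder")

    # initial selection: gBLUP on the founders themselves, top n by DH index
    rec = state.phenostore[0]
    G = build_grm(rec.genotypes, dtype=np.float64)
    model = fit_gblup(G, rec.values, np.arange(founders.n), np.arange(founders.n))
    idx = selection_index(model.ebv)
    top = truncation_select(idx, config.n_initial_dh, ids=founders.ids)
    parents = founders.subset(np.sort(top))

    # half-diallel cross, then selfing, into the first F2 pool
    pairs = [
        (parents.ids[i], parents.ids[j])
        for i in range(parents.n)
        for j in range(i + 1, parents.n)
    ]
    per_entry = distribute_offspring(config.f2_pool_size, len(pairs))
    plan = MatingPlan.from_pairs(pairs, per_entry, pipeline="cross_then_self")
    state.f2 = produce_offspring(
        founders, plan, gmap, rng_scheme, label="C1F2", cycle=1,
        f1_per_offspring=config.f1_per_offspring,
    )
    state.cycle = 1
    return state


def run_cycle(state: SchemeState, config: ScenarioConfig | None = None) -> list[dict]:
    """Execute one breeding cycle; returns metric rows (F2 and product DHs).

    Order of operations: training-set assembly, gBLUP, candidate index,
    parent selection (cycle-1 founder cap or OCS), pairing, optional
    external injection, production of the next F2 pool, product-DH
    extraction, strategy-dependent phenotyping, metrics.
    """
    config = state.config if config is None else config
    c = state.cycle
    records, version, fell_back = assemble_training_set(state, config.phenotyping, c)
    model, cand_G = _fit_cycle_model(state, records, version)
    f2_values = genetic_values(state.f2, state.arch)
    truth = f2_values[:, list(_version_traits(version))]
    ebv_index = selection_index(model.ebv)

    if config.ebv_output_dir is not None:
        from pathlib import Path

        out = Path(config.ebv_output_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.to_frame(state.f2.ids).to_csv(out / f"ebv_cycle{c:02d}.csv", index=False)

    row_common = {
        "cycle": c,
        "training_version": version,
        "n_training": int(sum(len(r.ids) for r in records)),
        "training_fallback": bool(fell_back),
    }
    pool_generations = np.nan

    if c < config.n_cycles:
        # --- parent selection and next-cohort production
        if config.ocs:
            sol = ocs_select(
                ebv_index,
                cand_G,
                config.n_selected_f2,
                config.target_degrees,
                budget=config.ocs_budget,
                rng=state.rng_scheme,
                ids=state.f2.ids,
            )
            plan = MatingPlan(
                entries=[
                    MatingEntry(
                        parent1=state.f2.ids[a], parent2=state.f2.ids[b],
                        n_offspring=1, pipeline="cross_then_self",
                    )
                    for a, b in sol.pairs
                ]
            )
        else:
            cap = config.cap_first_cycle if c == 1 else None
            if cap == "auto":
                cap = int(np.ceil(config.n_selected_f2 / 3))
            origins = state.f2.parents if cap is not None else None
            sel = truncation_select(
                ebv_index, config.n_selected_f2, ids=state.f2.ids,
                origin_cap=cap, origins=origins,
            )
            sel_ids = state.f2.ids[sel]
            plan = random_pairing(sel_ids, state.rng_scheme)
        for e, n_off in zip(plan.entries, config.offspring_per_pair()):
            e.n_offspring = n_off

        parent_cohorts = [state.f2]
        if config.introgression and config.external_proportion > 0:
            targets = f2_values[:, list(DH_TRAITS)].mean(axis=0)
            state.pool, donors = evolve_external_pool(
                state.pool, targets, state.arch, config.trait_config, state.gmap,
                state.rng_pool, n_select=config.pool_n_selected,
                max_generations=config.pool_max_generations,
            )
            pool_generations = state.pool.generation
            plan = inject_external(plan, donors, config.external_proportion, state.rng_scheme)
            parent_cohorts.append(donors)
            if config.phenotyping == "dh":
                _phenotype_store_cohort(
                    state, donors, "dh", cycle=c, delay=config.dh_delay,
                    source="external", n_subset=config.dh_n_phenotyped,
                )
        parent_pool = (
            Cohort.concat(parent_cohorts, label="parents", cycle=c)
            if len(parent_cohorts) > 1 else state.f2
        )
        next_f2 = produce_offspring(
            parent_pool, plan, state.gmap, state.rng_scheme,
            label=f"C{c + 1}F2", cycle=c + 1, f1_per_offspring=config.f1_per_offspring,
        )
    else:
        next_f2 = None

    # --- product DH lines from the top F2s (evaluation only)
    top = truncation_select(ebv_index, config.n_product_dh_parents, ids=state.f2.ids)
    dh_plan = MatingPlan(
        entries=[
            MatingEntry(
                parent1=state.f2.ids[i], parent2=state.f2.ids[i],
                n_offspring=config.n_dh_per_product_parent, pipeline="dh_induction",
            )
            for i in top
        ]
    )
    product_dh = produce_offspring(
        state.f2, dh_plan, state.gmap, state.rng_scheme, label=f"C{c}DH", cycle=c
    )

    # --- strategy-dependent phenotyping of the current cohort
    if config.phenotyping == "crosses":
        n_sub = config.n_selected_f2 if config.phenotype_selected_only else None
        _phenotype_store_cohort(
            state, state.f2, "cross", cycle=c, delay=config.cross_delay,
            source="internal", n_subset=n_sub,
        )
    elif config.phenotyping == "dh":
        pick = state.rng_pheno.choice(
            state.f2.n, size=min(config.dh_n_phenotyped, state.f2.n), replace=False
        )
        dh_source = state.f2.subset(np.sort(pick))
        derive = MatingPlan(
            entries=[
                MatingEntry(parent1=i, parent2=i, n_offspring=1, pipeline="dh_induction")
                for i in dh_source.ids
            ]
        )
        dh_lines = produce_offspring(
            dh_source, derive, state.gmap, state.rng_scheme, label=f"C{c}trainDH", cycle=c
        )
        _phenotype_store_cohort(
            state, dh_lines, "dh", cycle=c, delay=config.dh_delay, source="internal"
        )

    # --- metrics
    f2_row = row_common | {"cohort": "F2"} | cohort_metrics(
        state.f2, state.arch, state.reference, model=model, truth=truth, values=f2_values
    )
    f2_row["pool_generations"] = pool_generations
    dh_row = row_common | {"cohort": "productDH"} | cohort_metrics(
        product_dh, state.arch, state.reference
    )

    if next_f2 is not None:
        state.f2 = next_f2
        state.cycle = c + 1
    else:
        state.cycle = c + 1
    return [f2_row, dh_row]


def run_replicate(config: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Run one full replicate; returns the per-cycle metric table."""
    state = initialize_state(config, seed)
    rows = []
    for _ in range(config.n_cycles):
        rows.extend(run_cycle(state))
    df = pd.DataFrame(rows)
    df.insert(0, "seed", seed)
    return df


def run_scenario(
    config: ScenarioConfig,
    n_replicates: int = 250,
    base_seed: int = 0,
    scenario_name: str = "scenario",
    progress: bool = False,
) -> pd.DataFrame:
    """Replicate a scenario; replicate ``r`` uses seed ``base_seed + r``.

    Every replicate redraws founders, architecture and all stochastic
    events.  Returns one row per (replicate, cycle, cohort).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    frames = []
    for r in range(n_replicates):
        seed = int((base_seed + r) % (2**31))
        df = run_replicate(config, seed)
        df.insert(0, "replicate", r)
        frames.append(df)
        if progress:
            logger.info("scenario %s: replicate %d/%d done", scenario_name, r + 1, n_replicates)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "scenario", scenario_name)
    return out
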