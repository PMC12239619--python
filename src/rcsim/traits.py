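"""Correlated six-trait QTL architecture, genetic values and phenotypes.

Three plant-height traits (stages V4, V6, final) are each expressed in two
variants: *per se* performance of a DH line and performance as a cross,
giving six trait dimensions.  Every QTL is pleiotropic: its six-dimensional
effect vector is drawn from a zero-mean multivariate normal whose
correlation is the genetic correlation matrix, so the trait correlations
emerge from shared loci.  Four QTL classes are modelled per trait:

- additive:       a * (g - 1)                      g = alt-allele count
- dominant:       d * 1[g == 1]
- qualitative epistatic:  e * 1[(g_A, g_B) == target genotype pair]
- quantitative epistatic: a * (g_A - 1) * (1 + k * (g_B - 1))

Trait values are affinely standardized so that the founder DH cohort has
unit variance on each DH trait and a reference cohort of random founder
crosses has unit variance on each cross trait — the "gSD" unit in which all
gains are reported.  Heritabilities are defined against these reference
variances and stay fixed over cycles.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .founders import Cohort, GeneticMap
from .genome import MatingEntry, MatingPlan, produce_offspring

logger = logging.getLogger(__name__)

__all__ = [
    "TRAIT_NAMES",
    "DEFAULT_H2",
    "TraitConfig",
    "TraitArchitecture",
    "PhenotypeSet",
    "complete_correlation_matrix",
    "default_genetic_correlation",
    "default_environmental_correlation",
    "draw_architecture",
    "genetic_values",
    "simulate_phenotypes",
]

TRAIT_NAMES = (
    "PH_v4_DH",
    "PH_v6_DH",
    "PH_final_DH",
    "PH_v4_cross",
    "PH_v6_cross",
    "PH_final_cross",
)
DH_TRAITS = (0, 1, 2)
CROSS_TRAITS = (3, 4, 5)

# Default trait parameter table for the three plant-height stages measured on
# DH lines and on crosses: heritabilities, the genetic correlations that are
# directly available, and environmental correlations.
DEFAULT_H2 = np.array([0.95, 0.95, 0.96, 0.76, 0.77, 0.87])

# genetic correlations within the DH block and within the cross block
_RG_DH = {(0, 1): 0.94, (0, 2): 0.50, (1, 2): 0.58}
_RG_CROSS = {(0, 1): 0.86, (0, 2): 0.21, (1, 2): 0.33}
# same-trait DH-vs-cross genetic correlations
_RG_SAME = {0: 0.62, 1: 0.68, 2: 0.78}

_RE_BELOW = {
    (1, 0): 0.30,
    (2, 0): 0.10, (2, 1): 0.15,
    (3, 0): 0.20, (3, 1): 0.06, (3, 2): 0.02,
    (4, 0): 0.06, (4, 1): 0.20, (4, 2): 0.03, (4, 3): 0.30,
    (5, 0): 0.02, (5, 1): 0.03, (5, 2): 0.20, (5, 3): 0.10, (5, 4): 0.15,
}


def _nearest_psd(mat: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping.

    Returns the projected matrix (rescaled back to unit diagonal) and the
    Frobenius distance of the projection.
    """
    w, v = np.linalg.eigh(mat)
    if w.min() >= 0:
        return mat, 0.0
    w_clipped = np.clip(w, eps, None)
    proj = v @ np.diag(w_clipped) @ v.T
    d = np.sqrt(np.diag(proj))
    proj = proj / np.outer(d, d)
    return proj, float(np.linalg.norm(proj - mat))


def complete_correlation_matrix(
    rho_dh: dict | None = None,
    rho_cross: dict | None = None,
    rho_same: dict | None = None,
    psd_project: bool = True,
) -> np.ndarray:
    """Complete the 6x6 genetic correlation matrix from its available blocks.

    Inputs are the three within-DH correlations, the three within-cross
    correlations, and the three same-trait DH-vs-cross correlations.  Each
    missing cross-block entry (trait i as DH, trait j as cross, i != j) is
    filled as ``sqrt(rho_ij_DH * rho_ij_cross) * rho_j_same`` where
    ``rho_j_same`` is the DH-vs-cross correlation of the trait that is
    observed as a cross.  The square-root form is the one that reproduces
    every directly estimated cell of the default table within +-0.005.
    """
    rho_dh = dict(_RG_DH if rho_dh is None else rho_dh)
    rho_cross = dict(_RG_CROSS if rho_cross is None else rho_cross)
    rho_same = dict(_RG_SAME if rho_same is None else rho_same)
    rg = np.eye(6)
    for (i, j), r in rho_dh.items():
        rg[i, j] = rg[j, i] = r
    for (i, j), r in rho_cross.items():
        rg[3 + i, 3 + j] = rg[3 + j, 3 + i] = r
    for i, r in rho_same.items():
        rg[i, 3 + i] = rg[3 + i, i] = r
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            prod = rho_dh[key] * rho_cross[key]
            if prod < 0:
                raise ValueError(
                    f"negative product under the square root for trait pair {key}"
                )
            rg[i, 3 + j] = rg[3 + j, i] = np.sqrt(prod) * rho_same[j]
    if psd_project:
        rg, dist = _nearest_psd(rg)
        if dist > 0:
            logger.info("genetic correlation matrix projected to PSD (distance %.2e)", dist)
    return rg


def default_genetic_correlation() -> np.ndarray:
    return complete_correlation_matrix()


def default_environmental_correlation() -> np.ndarray:
    re = np.eye(6)
    for (i, j), r in _RE_BELOW.items():
        re[i, j] = re[j, i] = r
    re, dist = _nearest_psd(re)
    if dist > 0:  # pragma: no cover - default table is PSD
        logger.info("environmental correlation matrix projected to PSD (distance %.2e)", dist)
    return re


def _check_correlation(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (6, 6) or not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be a symmetric 6x6 matrix")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError(f"{name} must have unit diagonal")
    if np.any(np.abs(mat) > 1 + 1e-9):
        raise ValueError(f"{name} entries must lie in [-1, 1]")
    return mat


@dataclasses.dataclass
class TraitConfig:
    """Parameters of the six-trait architecture.

    QTL counts are per trait; ``class_variance_shares`` fixes the share of
    genetic variance each QTL class contributes in the reference
    random-cross cohort (a scalar rescale per class, preserving the
    cross-trait effect correlations).
    """

    h2: np.ndarray = dataclasses.field(default_factory=lambda: DEFAULT_H2.copy())
    rho_g: np.ndarray = dataclasses.field(default_factory=default_genetic_correlation)
    rho_e: np.ndarray = dataclasses.field(default_factory=default_environmental_correlation)
    n_additive: int = 500
    n_dominant: int = 500
    n_qualitative: int = 100
    n_quantitative: int = 100
    class_variance_shares: dict = dataclasses.field(
        default_factory=lambda: {"additive": 0.65, "dominant": 0.25, "qualitative": 0.05, "quantitative": 0.05}
    )
    quantitative_k_sd: float = 0.3  # spread of the modifier-locus scaling coefficient

    def __post_init__(self) -> None:
        self.h2 = np.asarray(self.h2, dtype=float)
        if np.any(self.h2 <= 0) or np.any(self.h2 > 1):
            raise ValueError("heritabilities must lie in (0, 1]")
        self.rho_g = _check_correlation(self.rho_g, "rho_g")
        self.rho_e = _check_correlation(self.rho_e, "rho_e")
        for n in (self.n_additive, self.n_dominant, self.n_qualitative, self.n_quantitative):
            if n < 0:
                raise ValueError("QTL counts must be >= 0")


@dataclasses.dataclass
class TraitArchitecture:
    """Drawn QTL records plus the per-trait affine standardization.

    Effect matrices have one row per QTL and six columns (one per trait).
    ``offset``/``scale`` map raw genetic values onto gSD units; founder and
    reference-cross statistics are stored for gain computation.
    """

    loci_additive: np.ndarray  # (Na,) marker indices
    eff_additive: np.ndarray  # (Na, 6)
    loci_dominant: np.ndarray
    eff_dominant: np.ndarray
    loci_qualitative: np.ndarray  # (Nq, 2) ordered locus pairs
    target_qualitative: np.ndarray  # (Nq, 2) genotype pair in {0,1,2}
    eff_qualitative: np.ndarray  # (Nq, 6)
    loci_quantitative: np.ndarray  # (Nk, 2) (locus, modifier locus)
    eff_quantitative: np.ndarray  # (Nk, 6)
    k_quantitative: np.ndarray  # (Nk, 6) per-trait scaling of the modifier
    offset: np.ndarray  # (6,)
    scale: np.ndarray  # (6,)
    n_markers: int = 0
    founder_mean: np.ndarray | None = None  # per-trait, standardized units
    founder_var: np.ndarray | None = None
    reference_mean: np.ndarray | None = None
    reference_var: np.ndarray | None = None
    reference_cohort: Cohort | None = None  # random founder crosses (cross-trait gSD anchor)

    def qtl_loci(self) -> np.ndarray:
        """All marker indices used by any QTL class (unique, sorted)."""
        return np.unique(
            np.concatenate(
                [
                    self.loci_additive,
                    self.loci_dominant,
                    self.loci_qualitative.ravel(),
                    self.loci_quantitative.ravel(),
                ]
            )
        )

    def raw_values(self, genotypes: np.ndarray) -> np.ndarray:
        """Unstandardized genetic values; ``genotypes`` is (n, M) in {0,1,2}."""
        g = genotypes
        n = g.shape[0]
        vals = np.zeros((n, 6))
        if len(self.loci_additive):
            x = g[:, self.loci_additive].astype(np.float64) - 1.0
            vals += x @ self.eff_additive
        if len(self.loci_dominant):
            x = (g[:, self.loci_dominant] == 1).astype(np.float64)
            vals += x @ self.eff_dominant
        if len(self.loci_qualitative):
            hit = (g[:, self.loci_qualitative[:, 0]] == self.target_qualitative[None, :, 0]) & (
                g[:, self.loci_qualitative[:, 1]] == self.target_qualitative[None, :, 1]
            )
            vals += hit.astype(np.float64) @ self.eff_qualitative
        if len(self.loci_quantitative):
            xa = g[:, self.loci_quantitative[:, 0]].astype(np.float64) - 1.0
            xb = g[:, self.loci_quantitative[:, 1]].astype(np.float64) - 1.0
            vals += xa @ self.eff_quantitative + (xa * xb) @ (self.eff_quantitative * self.k_quantitative)
        return vals

    def class_components(self, genotypes: np.ndarray) -> dict:
        """Per-class value components (for variance decomposition checks)."""
        g = genotypes
        comp = {}
        comp["additive"] = (g[:, self.loci_additive].astype(float) - 1.0) @ self.eff_additive
        comp["dominant"] = (g[:, self.loci_dominant] == 1).astype(float) @ self.eff_dominant
        if len(self.loci_qualitative):
            hit = (g[:, self.loci_qualitative[:, 0]] == self.target_qualitative[None, :, 0]) & (
                g[:, self.loci_qualitative[:, 1]] == self.target_qualitative[None, :, 1]
            )
            comp["qualitative"] = hit.astype(float) @ self.eff_qualitative
        else:
            comp["qualitative"] = np.zeros((g.shape[0], 6))
        if len(self.loci_quantitative):
            xa = g[:, self.loci_quantitative[:, 0]].astype(float) - 1.0
            xb = g[:, self.loci_quantitative[:, 1]].astype(float) - 1.0
            comp["quantitative"] = xa @ self.eff_quantitative + (xa * xb) @ (
                self.eff_quantitative * self.k_quantitative
            )
        else:
            comp["quantitative"] = np.zeros((g.shape[0], 6))
        return comp

    def standardize(self, founders: Cohort, reference: Cohort | None = None) -> None:
        """(Re-)solve offset/scale: unit variance on DH traits in ``founders``
        and on cross traits in ``reference`` (defaults to the stored one)."""
        reference = self.reference_cohort if reference is None else reference
        raw_f = self.raw_values(founders.genotypes())
        raw_r = self.raw_values(reference.genotypes())
        mean = np.empty(6)
        sd = np.empty(6)
        for t in range(6):
            src = raw_f if t in DH_TRAITS else raw_r
            mean[t] = src[:, t].mean()
            sd[t] = src[:, t].std(ddof=1)
        if np.any(sd <= 0):
            raise ValueError("degenerate architecture: zero genetic variance in a reference cohort")
        self.scale = 1.0 / sd
        self.offset = -mean / sd
        vf = self.values_from_raw(raw_f)
        vr = self.values_from_raw(raw_r)
        self.founder_mean, self.founder_var = vf.mean(axis=0), vf.var(axis=0, ddof=1)
        self.reference_mean, self.reference_var = vr.mean(axis=0), vr.var(axis=0, ddof=1)

    def values_from_raw(self, raw: np.ndarray) -> np.ndarray:
        return self.offset[None, :] + raw * self.scale[None, :]


def _sample_loci(rng: np.random.Generator, n_markers: int, n: int) -> np.ndarray:
    if n > n_markers:
        raise ValueError(f"need {n} distinct QTL loci but the map has only {n_markers} markers")
    return rng.choice(n_markers, size=n, replace=False)


def _mvn_effects(rng: np.random.Generator, n: int, rho_g: np.ndarray) -> np.ndarray:
    rho_psd, _ = _nearest_psd(rho_g)
    chol = np.linalg.cholesky(rho_psd + 1e-10 * np.eye(6))
    return rng.standard_normal((n, 6)) @ chol.T


def draw_architecture(
    gmap: GeneticMap,
    config: TraitConfig,
    founders: Cohort,
    rng: np.random.Generator | int | None = 0,
    n_reference_crosses: int = 1000,
) -> TraitArchitecture:
    """Sample the pleiotropic QTL architecture and anchor its gSD units.

    Per trait and class, loci are sampled without replacement from the
    marker set (classes and traits may overlap).  Effect vectors are
    multivariate normal with the genetic correlation matrix; class effects
    are then rescaled by a scalar per class so that each class contributes
    its configured share of genetic variance in a seeded reference cohort of
    ``n_reference_crosses`` random founder crosses.  Finally values are
    standardized: founder DH variance 1 on DH traits, reference-cross
    variance 1 on cross traits.
    """
    rng = np.random.default_rng(rng)
    m = gmap.n_markers
    need = max(config.n_additive, config.n_dominant, 2 * config.n_qualitative, 2 * config.n_quantitative)
    if need > m:
        raise ValueError(f"insufficient markers ({m}) for the requested QTL counts")

    loci_a, loci_d, loci_q, targ_q, loci_k = [], [], [], [], []
    for _trait in range(6):
        loci_a.append(_sample_loci(rng, m, config.n_additive))
        loci_d.append(_sample_loci(rng, m, config.n_dominant))
        lq = _sample_loci(rng, m, 2 * config.n_qualitative).reshape(-1, 2)
        loci_q.append(lq)
        targ_q.append(rng.integers(0, 3, size=(config.n_qualitative, 2)))
        loci_k.append(_sample_loci(rng, m, 2 * config.n_quantitative).reshape(-1, 2))
    loci_a = np.concatenate(loci_a) if config.n_additive else np.empty(0, dtype=int)
    loci_d = np.concatenate(loci_d) if config.n_dominant else np.empty(0, dtype=int)
    loci_q = np.concatenate(loci_q) if config.n_qualitative else np.empty((0, 2), dtype=int)
    targ_q = np.concatenate(targ_q) if config.n_qualitative else np.empty((0, 2), dtype=int)
    loci_k = np.concatenate(loci_k) if config.n_quantitative else np.empty((0, 2), dtype=int)

    arch = TraitArchitecture(
        loci_additive=loci_a,
        eff_additive=_mvn_effects(rng, len(loci_a), config.rho_g),
        loci_dominant=loci_d,
        eff_dominant=_mvn_effects(rng, len(loci_d), config.rho_g),
        loci_qualitative=loci_q,
        target_qualitative=targ_q,
        eff_qualitative=_mvn_effects(rng, len(loci_q), config.rho_g),
        loci_quantitative=loci_k,
        eff_quantitative=_mvn_effects(rng, len(loci_k), config.rho_g),
        k_quantitative=rng.normal(0.0, config.quantitative_k_sd, size=(len(loci_k), 6)),
        offset=np.zeros(6),
        scale=np.ones(6),
        n_markers=m,
    )

    # reference cohort: random crosses of distinct founder pairs
    n_f = founders.n
    i1 = rng.integers(0, n_f, size=n_reference_crosses)
    shift = rng.integers(1, n_f, size=n_reference_crosses)
    i2 = (i1 + shift) % n_f
    plan = MatingPlan(
        entries=[
            MatingEntry(parent1=founders.ids[a], parent2=founders.ids[b], n_offspring=1, pipeline="cross")
            for a, b in zip(i1, i2)
        ]
    )
    reference = produce_offspring(founders, plan, gmap, rng, label="refcross", cycle=0)
    reference.origin[:] = "reference"
    arch.reference_cohort = reference

    # scalar per-class rescale to the configured variance shares (measured on
    # the reference cohort, where all classes are expressed)
    comp = arch.class_components(reference.genotypes())
    shares = config.class_variance_shares
    for cls, eff_name in (
        ("additive", "eff_additive"),
        ("dominant", "eff_dominant"),
        ("qualitative", "eff_qualitative"),
        ("quantitative", "eff_quantitative"),
    ):
        v = comp[cls].var(axis=0, ddof=1).mean()
        share = shares.get(cls, 0.0)
        if v <= 0:
            factor = 0.0 if share == 0 else 1.0
        else:
            factor = np.sqrt(share / v)
        setattr(arch, eff_name, getattr(arch, eff_name) * factor)

    arch.standardize(founders, reference)
    return arch


def genetic_values(cohort: Cohort, arch: TraitArchitecture) -> np.ndarray:
    """True genetic values (n, 6) of a cohort in standardized gSD units."""
    if cohort.n_markers != arch.n_markers:
        raise ValueError(
            f"cohort has {cohort.n_markers} markers but the architecture expects {arch.n_markers}"
        )
    return arch.values_from_raw(arch.raw_values(cohort.genotypes()))


@dataclasses.dataclass
class PhenotypeSet:
    """Phenotypes of one cohort for a subset of traits.

    ``cycle_available`` models seed-propagation delays: records must not be
    used for training before that cycle.
    """

    ids: np.ndarray  # (n,)
    trait_indices: tuple  # columns of the 6-trait space that were measured
    values: np.ndarray  # (n, len(trait_indices))
    cycle_measured: int
    cycle_available: int
    source: str = "internal"

    def __post_init__(self) -> None:
        if self.cycle_available < self.cycle_measured:
            raise ValueError("cycle_available must be >= cycle_measured")

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, t in enumerate(self.trait_indices):
            for i, v in zip(self.ids, self.values[:, k]):
                rows.append(
                    {
                        "individual": i,
                        "trait": TRAIT_NAMES[t],
                        "value": v,
                        "cycle_measured": self.cycle_measured,
                        "cycle_available": self.cycle_available,
                        "source": self.source,
                    }
                )
        return pd.DataFrame(rows)


def simulate_phenotypes(
    cohort: Cohort,
    arch: TraitArchitecture,
    config: TraitConfig,
    trait_indices=DH_TRAITS,
    cycle_measured: int = 0,
    availability_delay: int = 0,
    rng: np.random.Generator | int | None = 0,
    source: str = "internal",
) -> PhenotypeSet:
    """Phenotype = genetic value + correlated environmental deviate.

    Environmental deviates are multivariate normal across the six traits
    with the environmental correlation matrix and per-trait variance
    ``(1 - h2) / h2`` times the trait's reference genetic variance (which is
    1 in standardized units), so that regressing phenotype on genetic value
    in a reference-like cohort has R^2 = h2.  Deviates are drawn fresh at
    every phenotyping event.
    """
    trait_indices = tuple(trait_indices)
    if len(trait_indices) == 0:
        raise ValueError("trait subset must be nonempty")
    if availability_delay < 0:
        raise ValueError("availability delay must be >= 0")
    if np.any(config.h2 <= 0):
        raise ValueError("heritabilities must be > 0")
    rng = np.random.default_rng(rng)
    vals = genetic_values(cohort, arch)
    sigma_e = np.sqrt((1.0 - config.h2) / config.h2)
    cov = config.rho_e * np.outer(sigma_e, sigma_e)
    if np.all(sigma_e == 0):
        dev = np.zeros((cohort.n, 6))
    else:
        psd, _ = _nearest_psd_cov(cov)
        w, v = np.linalg.eigh(psd)
        factor = v * np.sqrt(np.clip(w, 0.0, None))  # exact zeros stay exactly zero
        dev = rng.standard_normal((cohort.n, 6)) @ factor.T
    pheno = vals + dev
    return PhenotypeSet(
        ids=cohort.ids.copy(),
        trait_indices=trait_indices,
        values=pheno[:, list(trait_indices)],
        cycle_measured=cycle_measured,
        cycle_available=cycle_measured + availability_delay,
        source=source,
    )


def _nearest_psd_cov(cov: np.ndarray) -> tuple[np.ndarray, float]:
    w, v = np.linalg.eigh(cov)
    if w.min() >= 0:
        return cov, 0.0
    proj = v @ np.diag(np.clip(w, 0, None)) @ v.T
    return proj, float(np.linalg.norm(proj - cov))
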