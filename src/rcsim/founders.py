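"""Founder DH panels: genetic map, calibrated synthetic generator, panel readers.

The default founder material is a synthetic stand-in for a landrace-derived
panel of 409 fully homozygous doubled-haploid (DH) maize lines.  Per-marker
allele frequencies are drawn from a symmetric Beta distribution whose shape
parameter is solved so that the panel hits a target mean expected
heterozygosity ``E[2p(1-p)]``; with the scenario default of 0.218 the F2
progeny of two random panel lines are heterozygous at ~10.9% of genotypes
(an F2 segregates at half the markers at which its two homozygous
grandparents differ).

Real panels can be read from VCF or PLINK ``.ped``/``.map`` text files; all
genotypes must be homozygous (or be forced to a random homozygote).
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np

__all__ = [
    "GeneticMap",
    "Cohort",
    "build_genetic_map",
    "simulate_founder_panel",
    "read_founder_panel",
    "export_vcf",
    "export_map",
]


@dataclasses.dataclass(frozen=True)
class GeneticMap:
    """Marker map: chromosome index and genetic position (Morgan) per marker.

    Markers are stored in map order (chromosome-major, non-decreasing
    position within chromosome) and addressed everywhere by their 0-based
    index into this order.
    """

    chrom: np.ndarray  # (M,) int, 1-based chromosome index
    pos: np.ndarray  # (M,) float, genetic position in Morgan
    marker_ids: np.ndarray  # (M,) str

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=np.int32)
        pos = np.asarray(self.pos, dtype=np.float64)
        ids = np.asarray(self.marker_ids, dtype=object)
        if not (len(chrom) == len(pos) == len(ids)):
            raise ValueError("chrom, pos and marker_ids must have equal length")
        if np.any(pos < 0):
            raise ValueError("genetic positions must be >= 0")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("markers must be sorted by chromosome")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions must be non-decreasing within chromosome {c}")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "marker_ids", ids)

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    @property
    def n_chromosomes(self) -> int:
        return len(np.unique(self.chrom))

    def chromosome_slices(self) -> list[slice]:
        """Contiguous marker slice per chromosome, in chromosome order."""
        slices = []
        start = 0
        for c in np.unique(self.chrom):
            n = int(np.sum(self.chrom == c))
            slices.append(slice(start, start + n))
            start += n
        return slices


@dataclasses.dataclass
class Cohort:
    """A set of lines: phased genotypes plus pedigree and bookkeeping labels.

    ``haplotypes`` has shape (n, 2, M) with alleles coded 0/1.  DH and
    founder-DH lines carry two identical haplotypes.  ``parents`` holds the
    ids of the two crossing parents (both equal for selfing/DH induction,
    ``None`` for founders).
    """

    ids: np.ndarray  # (n,) str
    haplotypes: np.ndarray  # (n, 2, M) uint8
    parents: np.ndarray  # (n, 2) object; None for founders
    label: str = ""
    cycle: int = 0
    origin: np.ndarray | None = None  # (n,) str in {internal, external, reference}

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, M)")
        if len(self.ids) != self.haplotypes.shape[0]:
            raise ValueError("ids and haplotypes disagree on cohort size")
        if self.parents is None:
            self.parents = np.full((len(self.ids), 2), None, dtype=object)
        self.parents = np.asarray(self.parents, dtype=object)
        if self.origin is None:
            self.origin = np.full(len(self.ids), "internal", dtype=object)
        self.origin = np.asarray(self.origin, dtype=object)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def genotypes(self) -> np.ndarray:
        """Allele-count matrix (n, M) with entries in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1, dtype=np.uint8)

    def is_homozygous(self) -> np.ndarray:
        """Per-line flag: both haplotypes identical at every marker."""
        return np.all(self.haplotypes[:, 0, :] == self.haplotypes[:, 1, :], axis=1)

    def subset(self, index, label: str | None = None) -> "Cohort":
        index = np.asarray(index, dtype=np.intp)
        return Cohort(
            ids=self.ids[index],
            haplotypes=self.haplotypes[index],
            parents=self.parents[index],
            label=self.label if label is None else label,
            cycle=self.cycle,
            origin=self.origin[index],
        )

    @staticmethod
    def concat(cohorts: list["Cohort"], label: str = "", cycle: int | None = None) -> "Cohort":
        ids = np.concatenate([c.ids for c in cohorts])
        if len(set(ids)) != len(ids):
            raise ValueError("cannot concatenate cohorts with duplicate ids")
        return Cohort(
            ids=ids,
            haplotypes=np.concatenate([c.haplotypes for c in cohorts]),
            parents=np.concatenate([c.parents for c in cohorts]),
            label=label,
            cycle=cohorts[0].cycle if cycle is None else cycle,
            origin=np.concatenate([c.origin for c in cohorts]),
        )

    def index_of(self, ids) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in np.asarray(ids, dtype=object)], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message detail
            raise KeyError(f"id {exc.args[0]!r} not found in cohort {self.label!r}") from None


def build_genetic_map(
    n_chromosomes: int, markers_per_chromosome: int, chromosome_length: float
) -> GeneticMap:
    """Evenly spaced marker map over ``n_chromosomes`` chromosomes.

    ``chromosome_length`` is in Morgan; markers are placed on
    ``[0, chromosome_length]`` inclusive.  A length of 0 gives a map without
    recombination.
    """
    if n_chromosomes <= 0 or markers_per_chromosome <= 0:
        raise ValueError("n_chromosomes and markers_per_chromosome must be positive")
    if chromosome_length < 0:
        raise ValueError("chromosome_length must be >= 0")
    chrom = np.repeat(np.arange(1, n_chromosomes + 1), markers_per_chromosome)
    if markers_per_chromosome == 1:
        pos_c = np.array([0.0])
    else:
        pos_c = np.linspace(0.0, chromosome_length, markers_per_chromosome)
    pos = np.tile(pos_c, n_chromosomes)
    ids = np.array(
        [f"chr{c}_m{m}" for c in range(1, n_chromosomes + 1) for m in range(markers_per_chromosome)],
        dtype=object,
    )
    return GeneticMap(chrom=chrom, pos=pos, marker_ids=ids)


def _beta_shape_for_heterozygosity(target: float) -> float:
    # For p ~ Beta(a, a): E[2p(1-p)] = a / (2a + 1); invert for a.
    if target >= 0.5:
        return 1e6  # effectively p = 0.5 everywhere
    return target / (1.0 - 2.0 * target)


def simulate_founder_panel(
    gmap: GeneticMap,
    n_lines: int,
    target_heterozygosity: float = 0.218,
    rng: np.random.Generator | int | None = 0,
    ld_block_size: int | None = None,
    label: str = "founders",
    max_tries: int = 20,
) -> Cohort:
    """Draw a fully homozygous founder panel with a U-shaped frequency spectrum.

    Parameters
    ----------
    target_heterozygosity
        Target mean over markers of the expected heterozygosity ``2p(1-p)``;
        must lie in (0, 0.5].  Per-marker frequencies are Beta(a, a) with the
        shape ``a`` solved in closed form from the target.  The realized mean
        is required to land within +-10% of the target (frequencies are
        redrawn up to ``max_tries`` times; the closest draw is kept).
    ld_block_size
        Optional haplotype-block size: within blocks of this many consecutive
        markers each line shares a single latent uniform, inducing strong
        positive association between markers of a block.  Default: no LD.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if not (0.0 < target_heterozygosity <= 0.5):
        raise ValueError("target mean 2p(1-p) must lie in (0, 0.5]")
    rng = np.random.default_rng(rng)
    m = gmap.n_markers
    a = _beta_shape_for_heterozygosity(target_heterozygosity)

    best_p, best_err = None, np.inf
    for _ in range(max_tries):
        p = rng.beta(a, a, size=m)
        realized = np.mean(2.0 * p * (1.0 - p))
        err = abs(realized - target_heterozygosity)
        if err < best_err:
            best_p, best_err = p, err
        if err <= 0.10 * target_heterozygosity:
            break
    p = best_p

    if ld_block_size is None:
        hap = (rng.random((n_lines, m)) < p).astype(np.uint8)
    else:
        if ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        n_blocks = int(np.ceil(m / ld_block_size))
        u = rng.random((n_lines, n_blocks))
        u_full = np.repeat(u, ld_block_size, axis=1)[:, :m]
        hap = (u_full < p).astype(np.uint8)

    haplotypes = np.stack([hap, hap], axis=1)
    ids = np.array([f"{label}_{i:04d}" for i in range(n_lines)], dtype=object)
    return Cohort(ids=ids, haplotypes=haplotypes, parents=None, label=label, cycle=0)


# ---------------------------------------------------------------------------
# Real-panel ingestion (VCF 4.x and PLINK .ped/.map text)
# ---------------------------------------------------------------------------


class HeterozygousGenotypeError(ValueError):
    """Raised when a supposedly DH panel contains heterozygous calls."""


def _resolve_heterozygotes(geno_alleles, rng):
    # geno_alleles: (n, M, 2) int; pick one allele at random and duplicate
    pick = rng.integers(0, 2, size=geno_alleles.shape[:2])
    chosen = np.take_along_axis(geno_alleles, pick[:, :, None], axis=2)[:, :, 0]
    return np.stack([chosen, chosen], axis=2)


def _parse_vcf_text(path: Path):
    """Minimal text VCF parser used when cyvcf2 is unavailable."""
    samples, chroms, poss, ids, rows = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                continue
            if "," in f[4]:
                raise ValueError(f"multi-allelic site at {f[0]}:{f[1]} is not supported")
            chroms.append(f[0])
            poss.append(int(f[1]))
            ids.append(f[2] if f[2] != "." else f"{f[0]}_{f[1]}")
            calls = []
            for s in f[9:]:
                gt = s.split(":")[0].replace("|", "/")
                a = gt.split("/")
                calls.append((int(a[0]), int(a[1])))
            rows.append(calls)
    alleles = np.array(rows, dtype=np.int16)  # (M, n, 2)
    return samples, chroms, poss, ids, np.transpose(alleles, (1, 0, 2))


def _read_vcf(path: Path):
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _parse_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) > 1:
            raise ValueError(f"multi-allelic site at {var.CHROM}:{var.POS} is not supported")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        rows.append([(g[0], g[1]) for g in var.genotypes])
    alleles = np.array(rows, dtype=np.int16)
    return samples, chroms, poss, ids, np.transpose(alleles, (1, 0, 2))


def _read_plink_text(path: Path):
    prefix = Path(str(path).removesuffix(".ped").removesuffix(".map"))
    mapfile, pedfile = prefix.with_suffix(".map"), prefix.with_suffix(".ped")
    chroms, ids, poss = [], [], []
    with open(mapfile) as fh:
        for line in fh:
            f = line.split()
            chroms.append(f[0])
            ids.append(f[1])
            poss.append(float(f[2]))  # genetic distance column, cM
    samples, rows = [], []
    with open(pedfile) as fh:
        for line in fh:
            f = line.split()
            samples.append(f[1])
            alleles = f[6:]
            if len(alleles) != 2 * len(ids):
                raise ValueError(f"line {f[1]}: expected {2 * len(ids)} alleles, got {len(alleles)}")
            # recode: A (or 1) -> 0, anything else -> 1; missing 0 rejected
            pair = []
            for k in range(0, len(alleles), 2):
                a1, a2 = alleles[k], alleles[k + 1]
                if "0" in (a1, a2):
                    raise ValueError(f"missing genotype for sample {f[1]}")
                pair.append((0 if a1 in ("A", "1") else 1, 0 if a2 in ("A", "1") else 1))
            rows.append(pair)
    alleles = np.array(rows, dtype=np.int16)  # (n, M, 2)
    return samples, chroms, [p / 100.0 for p in poss], ids, alleles


def read_founder_panel(
    path,
    format: str = "vcf",
    force_homozygous: bool = False,
    rng: np.random.Generator | int | None = 0,
    morgan_per_bp: float = 1e-8,
) -> tuple[Cohort, GeneticMap]:
    """Read a homozygous panel plus its map from VCF or PLINK text files.

    VCF physical positions are converted to genetic positions with
    ``morgan_per_bp`` (default 1 cM/Mb); PLINK ``.map`` genetic distances
    (cM) are used directly.  Heterozygous calls are rejected unless
    ``force_homozygous`` resolves each to a random homozygote (seeded).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "vcf":
        samples, chroms, poss, mids, alleles = _read_vcf(path)
        pos_morgan = np.asarray(poss, dtype=float) * morgan_per_bp
    elif fmt in ("plink", "plink-text", "ped"):
        samples, chroms, poss, mids, alleles = _read_plink_text(path)
        pos_morgan = np.asarray(poss, dtype=float)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'plink'")

    het = alleles[:, :, 0] != alleles[:, :, 1]
    if het.any():
        if not force_homozygous:
            bad = [
                f"{samples[i]}@{mids[j]}"
                for i, j in zip(*np.nonzero(het))
            ][:10]
            raise HeterozygousGenotypeError(
                "heterozygous calls in panel (set force_homozygous=True to resolve): "
                + ", ".join(bad)
            )
        alleles = _resolve_heterozygotes(alleles, np.random.default_rng(rng))

    # order markers by (chromosome, position)
    chrom_codes = np.array([int(str(c).lstrip("chr") or 0) if str(c).lstrip("chr").isdigit() else hash(c) % 10**6 for c in chroms])
    order = np.lexsort((pos_morgan, chrom_codes))
    gmap = GeneticMap(
        chrom=chrom_codes[order],
        pos=pos_morgan[order],
        marker_ids=np.asarray(mids, dtype=object)[order],
    )
    hap = np.transpose(alleles[:, order, :], (0, 2, 1)).astype(np.uint8)
    cohort = Cohort(
        ids=np.asarray(samples, dtype=object),
        haplotypes=hap,
        parents=None,
        label=path.stem,
        cycle=0,
    )
    return cohort, gmap


def export_map(gmap: GeneticMap, path) -> None:
    """Write the map as 3-column text: chromosome, marker id, position (Morgan)."""
    with open(path, "w") as fh:
        for c, mid, p in zip(gmap.chrom, gmap.marker_ids, gmap.pos):
            fh.write(f"{c}\t{mid}\t{p:.8f}\n")


def export_vcf(cohort: Cohort, gmap: GeneticMap, path, morgan_per_bp: float = 1e-8) -> None:
    """Write the cohort as a minimal phased VCF 4.2 text file.

    Physical positions are back-computed from genetic positions with
    ``morgan_per_bp`` (positions are for inspection only).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in cohort.ids) + "\n")
        h = cohort.haplotypes
        for j in range(gmap.n_markers):
            bp = max(1, int(round(gmap.pos[j] / morgan_per_bp))) if morgan_per_bp > 0 else j + 1
            calls = "\t".join(f"{h[i, 0, j]}|{h[i, 1, j]}" for i in range(cohort.n))
            fh.write(f"{gmap.chrom[j]}\t{bp}\t{gmap.marker_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")
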