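"""Correlated six-trait architecture: completion rule, values, phenotypes."""

import numpy as np
import pytest

from rcsim.founders import Cohort, build_genetic_map, simulate_founder_panel
from rcsim.traits import (
    CROSS_TRAITS,
    DEFAULT_H2,
    DH_TRAITS,
    TraitConfig,
    complete_correlation_matrix,
    default_environmental_correlation,
    default_genetic_correlation,
    draw_architecture,
    genetic_values,
    simulate_phenotypes,
)

# directly estimated correlations of the default trait table
RG_DH = {(0, 1): 0.94, (0, 2): 0.50, (1, 2): 0.58}
RG_CROSS = {(0, 1): 0.86, (0, 2): 0.21, (1, 2): 0.33}
RG_SAME = {0: 0.62, 1: 0.68, 2: 0.78}
# the six completed (starred) cells as printed in the default table
STARRED = {(0, 4): 0.61, (0, 5): 0.25, (1, 3): 0.56, (1, 5): 0.34, (2, 3): 0.20, (2, 4): 0.30}


class TestCorrelationCompletion:
    def test_starred_cells_reproduced(self):
        rg = complete_correlation_matrix(psd_project=False)
        for (i, j), expected in STARRED.items():
            assert rg[i, j] == pytest.approx(expected, abs=0.005)

    def test_sqrt_form_is_the_matching_formula(self):
        """Oracle: of the two candidate completion rules (with and without a
        square root on the product of the two trait-pair correlations) only
        the square-root form reproduces all six completed cells."""

        def complete(with_sqrt):
            out = {}
            for (i, j) in STARRED:
                jj = j - 3
                key = (min(i, jj), max(i, jj))
                prod = RG_DH[key] * RG_CROSS[key]
                factor = np.sqrt(prod) if with_sqrt else prod
                out[(i, j)] = factor * RG_SAME[jj]
            return out

        sqrt_ok = all(
            abs(v - STARRED[k]) <= 0.005 for k, v in complete(with_sqrt=True).items()
        )
        plain_ok = all(
            abs(v - STARRED[k]) <= 0.005 for k, v in complete(with_sqrt=False).items()
        )
        assert sqrt_ok and not plain_ok

    def test_symmetric_unit_diagonal_psd(self):
        for mat in (default_genetic_correlation(), default_environmental_correlation()):
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 1.0)
            assert np.linalg.eigvalsh(mat).min() >= -1e-10

    def test_negative_product_rejected(self):
        bad = dict(RG_DH)
        bad[(0, 1)] = -0.94
        with pytest.raises(ValueError, match="square root"):
            complete_correlation_matrix(rho_dh=bad, psd_project=False)


class TestTraitConfig:
    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError):
            TraitConfig(h2=np.array([0.0, 0.95, 0.96, 0.76, 0.77, 0.87]))
        with pytest.raises(ValueError):
            TraitConfig(h2=np.full(6, 1.2))

    def test_default_h2_diagonal(self):
        assert np.allclose(DEFAULT_H2, [0.95, 0.95, 0.96, 0.76, 0.77, 0.87])


class TestArchitecture:
    def test_standardized_reference_variances(self, small_arch):
        assert np.allclose(small_arch.founder_var[list(DH_TRAITS)], 1.0, atol=0.02)
        assert np.allclose(small_arch.reference_var[list(CROSS_TRAITS)], 1.0, atol=0.02)

    def test_standardization_idempotent(self, small_arch, small_founders):
        scale_before = small_arch.scale.copy()
        offset_before = small_arch.offset.copy()
        small_arch.standardize(small_founders)
        assert np.allclose(small_arch.scale, scale_before, atol=1e-9)
        assert np.allclose(small_arch.offset, offset_before, atol=1e-9)

    def test_realized_founder_correlation(self):
        """Pleiotropic effect vectors reproduce the configured genetic
        correlation between the first two DH-variant stages (0.94 +- 0.05)."""
        gmap = build_genetic_map(10, 300, 1.6)
        founders = simulate_founder_panel(gmap, 409, 0.218, rng=1)
        cfg = TraitConfig(n_additive=300, n_dominant=300, n_qualitative=60, n_quantitative=60)
        arch = draw_architecture(gmap, cfg, founders, rng=2, n_reference_crosses=600)
        vals = genetic_values(founders, arch)
        got = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
        assert got == pytest.approx(0.94, abs=0.05)

    def test_identity_correlation_gives_independent_traits(self):
        gmap = build_genetic_map(10, 300, 1.6)
        founders = simulate_founder_panel(gmap, 409, 0.218, rng=3)
        cfg = TraitConfig(
            rho_g=np.eye(6),
            n_additive=300, n_dominant=300, n_qualitative=60, n_quantitative=60,
        )
        arch = draw_architecture(gmap, cfg, founders, rng=4, n_reference_crosses=600)
        vals = genetic_values(founders, arch)
        corr = np.corrcoef(vals.T)
        off = corr[np.triu_indices(6, 1)]
        # effect-sampling noise with ~700 QTLs per trait is ~0.04 per pair
        assert np.all(np.abs(off) < 0.12)
        assert np.mean(np.abs(off)) < 0.05

    def test_pure_additive_variance_decomposition(self, small_map, small_founders):
        """With dominance and epistasis switched off, the founder genic
        (additive) variance equals the total genetic variance within 1%."""
        cfg = TraitConfig(
            n_additive=60, n_dominant=0, n_qualitative=0, n_quantitative=0,
            class_variance_shares={"additive": 1.0},
        )
        arch = draw_architecture(small_map, cfg, small_founders, rng=5, n_reference_crosses=300)
        geno = small_founders.genotypes()
        comp = arch.class_components(geno)
        total = arch.raw_values(geno)
        for t in range(6):
            assert comp["additive"][:, t].var() == pytest.approx(total[:, t].var(), rel=0.01)

    def test_insufficient_markers_rejected(self, small_founders, small_config):
        tiny = build_genetic_map(1, 10, 1.0)
        with pytest.raises(ValueError, match="markers"):
            draw_architecture(tiny, small_config, small_founders, rng=0)


class TestGeneticValues:
    def _single_qtl_arch(self, small_arch, kind):
        import copy

        arch = copy.deepcopy(small_arch)
        arch.loci_additive = np.array([3]) if kind == "additive" else np.empty(0, dtype=int)
        arch.eff_additive = np.full((1, 6), 2.0) if kind == "additive" else np.empty((0, 6))
        arch.loci_dominant = np.array([3]) if kind == "dominant" else np.empty(0, dtype=int)
        arch.eff_dominant = np.full((1, 6), 1.5) if kind == "dominant" else np.empty((0, 6))
        arch.loci_qualitative = np.empty((0, 2), dtype=int)
        arch.eff_qualitative = np.empty((0, 6))
        arch.target_qualitative = np.empty((0, 2), dtype=int)
        arch.loci_quantitative = np.empty((0, 2), dtype=int)
        arch.eff_quantitative = np.empty((0, 6))
        arch.k_quantitative = np.empty((0, 6))
        arch.offset = np.zeros(6)
        arch.scale = np.ones(6)
        return arch

    def test_additive_coding_convention(self, small_arch, small_map):
        arch = self._single_qtl_arch(small_arch, "additive")
        geno = np.zeros((3, small_map.n_markers), dtype=np.uint8)
        geno[1, 3] = 1
        geno[2, 3] = 2
        vals = arch.raw_values(geno)
        assert np.allclose(vals[:, 0], [-2.0, 0.0, 2.0])

    def test_dominance_only_heterozygote(self, small_arch, small_map):
        arch = self._single_qtl_arch(small_arch, "dominant")
        geno = np.zeros((3, small_map.n_markers), dtype=np.uint8)
        geno[1, 3] = 1
        geno[2, 3] = 2
        vals = arch.raw_values(geno)
        assert np.allclose(vals[:, 0], [0.0, 1.5, 0.0])

    def test_brute_force_per_locus_oracle(self, small_arch):
        """Vectorized evaluation equals an independent per-locus, per-QTL
        summation on a random 5-individual cohort."""
        rng = np.random.default_rng(10)
        geno = rng.integers(0, 3, size=(5, small_arch.n_markers)).astype(np.uint8)
        vals = small_arch.raw_values(geno)
        a = small_arch
        for i in range(5):
            for t in range(6):
                acc = 0.0
                for q, locus in enumerate(a.loci_additive):
                    acc += a.eff_additive[q, t] * (geno[i, locus] - 1.0)
                for q, locus in enumerate(a.loci_dominant):
                    acc += a.eff_dominant[q, t] * (geno[i, locus] == 1)
                for q in range(len(a.loci_qualitative)):
                    la, lb = a.loci_qualitative[q]
                    ta, tb = a.target_qualitative[q]
                    acc += a.eff_qualitative[q, t] * ((geno[i, la] == ta) and (geno[i, lb] == tb))
                for q in range(len(a.loci_quantitative)):
                    la, lb = a.loci_quantitative[q]
                    acc += (
                        a.eff_quantitative[q, t]
                        * (geno[i, la] - 1.0)
                        * (1.0 + a.k_quantitative[q, t] * (geno[i, lb] - 1.0))
                    )
                assert vals[i, t] == pytest.approx(acc, rel=1e-9, abs=1e-9)

    def test_values_depend_only_on_genotype(self, small_arch, small_founders):
        """A DH line and a genotype-identical non-DH line score identically."""
        hap = small_founders.haplotypes[:1]
        twin = Cohort(
            ids=np.array(["twin"], dtype=object),
            haplotypes=hap.copy(),
            parents=np.array([["x", "y"]], dtype=object),
            label="other",
            cycle=5,
        )
        v1 = genetic_values(small_founders.subset([0]), small_arch)
        v2 = genetic_values(twin, small_arch)
        assert np.allclose(v1, v2)

    def test_marker_mismatch_rejected(self, small_arch):
        wrong = Cohort(
            ids=np.array(["a"], dtype=object),
            haplotypes=np.zeros((1, 2, 7), dtype=np.uint8),
            parents=None,
        )
        with pytest.raises(ValueError, match="markers"):
            genetic_values(wrong, small_arch)


class TestPhenotypes:
    def test_h2_one_phenotype_equals_genetic_value(self, small_map, small_founders):
        cfg = TraitConfig(
            h2=np.ones(6),
            n_additive=40, n_dominant=40, n_qualitative=10, n_quantitative=10,
        )
        arch = draw_architecture(small_map, cfg, small_founders, rng=6, n_reference_crosses=300)
        phen = simulate_phenotypes(small_founders, arch, cfg, trait_indices=DH_TRAITS, rng=0)
        vals = genetic_values(small_founders, arch)[:, list(DH_TRAITS)]
        assert np.allclose(phen.values, vals, atol=1e-9)

    def test_h2_realized_as_regression_r2(self):
        """At h2 = 0.95, regressing phenotype on genetic value in a large
        founder-like cohort gives R^2 ~ 0.95 +- 0.01."""
        gmap = build_genetic_map(5, 100, 1.6)
        founders = simulate_founder_panel(gmap, 10_000, 0.218, rng=7)
        cfg = TraitConfig(n_additive=80, n_dominant=80, n_qualitative=20, n_quantitative=20)
        arch = draw_architecture(gmap, cfg, founders, rng=8, n_reference_crosses=400)
        phen = simulate_phenotypes(founders, arch, cfg, trait_indices=(0,), rng=9)
        g = genetic_values(founders, arch)[:, 0]
        # phenotypic variance = founder genetic variance (1) + (1-h2)/h2
        r2 = np.corrcoef(phen.values[:, 0], g)[0, 1] ** 2
        assert r2 == pytest.approx(0.95, abs=0.01)

    def test_environmental_correlation_realized(self, small_arch, small_config, small_map):
        """Environmental deviates carry the configured correlation
        (0.30 between the first two DH-variant stages, +-0.01 at n=100k)."""
        n = 100_000
        cohort = Cohort(
            ids=np.array([f"z{i}" for i in range(n)], dtype=object),
            haplotypes=np.zeros((n, 2, small_map.n_markers), dtype=np.uint8),
            parents=None,
        )
        phen = simulate_phenotypes(
            cohort, small_arch, small_config, trait_indices=(0, 1), rng=13
        )
        vals = genetic_values(cohort, small_arch)[:, :2]
        dev = phen.values - vals
        got = np.corrcoef(dev[:, 0], dev[:, 1])[0, 1]
        assert got == pytest.approx(0.30, abs=0.01)

    def test_availability_delay(self, small_arch, small_config, small_founders):
        phen = simulate_phenotypes(
            small_founders, small_arch, small_config,
            cycle_measured=3, availability_delay=2, rng=0,
        )
        assert phen.cycle_available == 5

    def test_empty_trait_subset_rejected(self, small_arch, small_config, small_founders):
        with pytest.raises(ValueError):
            simulate_phenotypes(small_founders, small_arch, small_config, trait_indices=(), rng=0)
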