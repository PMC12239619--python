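"""Genetic map construction, synthetic DH panels and panel readers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcsim.founders import (
    Cohort,
    HeterozygousGenotypeError,
    build_genetic_map,
    export_map,
    export_vcf,
    read_founder_panel,
    simulate_founder_panel,
)
from rcsim.genome import MatingEntry, MatingPlan, produce_offspring


class TestGeneticMap:
    def test_even_spacing(self):
        gmap = build_genetic_map(1, 3, 1.0)
        assert np.allclose(gmap.pos, [0.0, 0.5, 1.0])
        assert list(gmap.chrom) == [1, 1, 1]

    def test_total_marker_count(self):
        gmap = build_genetic_map(10, 5000, 1.6)
        assert gmap.n_markers == 50_000
        assert gmap.n_chromosomes == 10

    def test_zero_length_map_is_degenerate(self):
        gmap = build_genetic_map(2, 2, 0.0)
        assert np.all(gmap.pos == 0.0)

    @pytest.mark.parametrize("args", [(0, 5, 1.0), (5, 0, 1.0), (-1, 5, 1.0)])
    def test_non_positive_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            build_genetic_map(*args)

    @given(
        n_chrom=st.integers(1, 5),
        m=st.integers(1, 50),
        length=st.floats(0.0, 5.0, allow_nan=False),
    )
    @settings(max_examples=30, deadline=None)
    def test_map_invariants(self, n_chrom, m, length):
        gmap = build_genetic_map(n_chrom, m, length)
        assert gmap.n_markers == n_chrom * m
        assert np.all(gmap.pos >= 0)
        for sl in gmap.chromosome_slices():
            assert np.all(np.diff(gmap.pos[sl]) >= -1e-12)


class TestSyntheticPanel:
    def test_fully_homozygous(self, small_map):
        panel = simulate_founder_panel(small_map, 30, 0.218, rng=0)
        assert panel.is_homozygous().all()
        assert panel.n == 30

    def test_bit_reproducible_given_seed(self, small_map):
        a = simulate_founder_panel(small_map, 20, 0.2, rng=42)
        b = simulate_founder_panel(small_map, 20, 0.2, rng=42)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    @pytest.mark.parametrize("target", [0.109, 0.218, 0.4])
    def test_realized_heterozygosity_within_ten_percent(self, target):
        gmap = build_genetic_map(5, 400, 1.0)
        panel = simulate_founder_panel(gmap, 100, target, rng=5)
        # per-marker frequencies realized in the panel
        p = panel.genotypes().mean(axis=0) / 2.0
        realized = np.mean(2 * p * (1 - p))
        # realized line draws add binomial noise on top of the frequency draw
        assert realized == pytest.approx(target, rel=0.15)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6])
    def test_invalid_target_rejected(self, small_map, bad):
        with pytest.raises(ValueError):
            simulate_founder_panel(small_map, 10, bad, rng=0)

    def test_two_lines_half_frequency_divergence(self):
        # p = 0.5 at every marker: two random lines differ at half the markers
        gmap = build_genetic_map(1, 1000, 0.0)
        panel = simulate_founder_panel(gmap, 2, 0.5, rng=9)
        diff = np.mean(panel.haplotypes[0, 0] != panel.haplotypes[1, 0])
        assert diff == pytest.approx(0.5, abs=0.05)

    def test_near_monomorphic_limit(self, small_map):
        panel = simulate_founder_panel(small_map, 30, 1e-4, rng=1)
        p = panel.genotypes().mean(axis=0) / 2.0
        assert np.mean(2 * p * (1 - p)) < 0.01

    def test_ld_blocks_induce_association(self):
        gmap = build_genetic_map(1, 200, 1.0)
        panel = simulate_founder_panel(gmap, 200, 0.3, rng=3, ld_block_size=10)
        h = panel.haplotypes[:, 0, :]
        within = np.corrcoef(h[:, 0], h[:, 1])[0, 1]  # same block
        assert within > 0.3

    def test_expected_f2_heterozygosity_matches_engine(self, small_map, rng):
        """Analytic F2 heterozygosity (half the parental difference rate)
        agrees with a Monte-Carlo estimate from the genome engine."""
        panel = simulate_founder_panel(small_map, 10, 0.218, rng=21)
        a, b = panel.ids[0], panel.ids[1]
        diff_rate = np.mean(panel.haplotypes[0, 0] != panel.haplotypes[1, 0])
        n = 4000
        plan = MatingPlan(entries=[MatingEntry(a, b, n_offspring=n, pipeline="cross_then_self")])
        f2 = produce_offspring(panel, plan, small_map, rng, label="f2")
        het = np.mean(f2.genotypes() == 1)
        expected = diff_rate / 2.0
        se = np.sqrt(expected * (1 - expected) / (n * small_map.n_markers / 10))  # markers correlated
        assert abs(het - expected) < max(3 * se, 0.01)


class TestPanelIO:
    def _tiny_panel(self):
        gmap = build_genetic_map(2, 2, 1.0)
        hap = np.array(
            [[[1, 0, 1, 1]] * 2, [[0, 0, 1, 0]] * 2, [[1, 1, 0, 0]] * 2], dtype=np.uint8
        )
        cohort = Cohort(
            ids=np.array(["L1", "L2", "L3"], dtype=object),
            haplotypes=hap,
            parents=None,
            label="tiny",
        )
        return cohort, gmap

    def test_vcf_round_trip(self, tmp_path):
        cohort, gmap = self._tiny_panel()
        path = tmp_path / "panel.vcf"
        export_vcf(cohort, gmap, path)
        back, back_map = read_founder_panel(path, format="vcf")
        assert list(back.ids) == ["L1", "L2", "L3"]
        assert np.array_equal(back.haplotypes, cohort.haplotypes)
        assert back_map.n_markers == 4

    def test_plink_text_matches_vcf(self, tmp_path):
        """The same panel written as PLINK .ped/.map text parses to an
        identical cohort (cross-format equality)."""
        cohort, gmap = self._tiny_panel()
        vcf = tmp_path / "panel.vcf"
        export_vcf(cohort, gmap, vcf)
        # write the equivalent PLINK text files (alleles A=0, T=1)
        code = {0: "A", 1: "T"}
        with open(tmp_path / "panel.map", "w") as fh:
            for c, mid, pos in zip(gmap.chrom, gmap.marker_ids, gmap.pos):
                fh.write(f"{c} {mid} {pos * 100} 0\n")
        with open(tmp_path / "panel.ped", "w") as fh:
            for i in range(cohort.n):
                alleles = " ".join(
                    f"{code[int(cohort.haplotypes[i, 0, j])]} {code[int(cohort.haplotypes[i, 1, j])]}"
                    for j in range(gmap.n_markers)
                )
                fh.write(f"FAM {cohort.ids[i]} 0 0 0 -9 {alleles}\n")
        from_vcf, _ = read_founder_panel(vcf, format="vcf")
        from_ped, ped_map = read_founder_panel(tmp_path / "panel.ped", format="plink")
        assert list(from_vcf.ids) == list(from_ped.ids)
        assert np.array_equal(from_vcf.haplotypes, from_ped.haplotypes)
        assert np.allclose(ped_map.pos, gmap.pos)

    def test_heterozygous_call_rejected_with_site_named(self, tmp_path):
        path = tmp_path / "het.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t100\tsnp1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\n"
        )
        with pytest.raises(HeterozygousGenotypeError, match="snp1"):
            read_founder_panel(path, format="vcf")

    def test_force_homozygous_resolves_heterozygotes(self, tmp_path):
        path = tmp_path / "het.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\tsnp1\tA\tT\t.\tPASS\t.\tGT\t0/1\n"
        )
        cohort, _ = read_founder_panel(path, format="vcf", force_homozygous=True, rng=0)
        assert cohort.is_homozygous().all()

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\tsnp1\tA\tT,C\t.\tPASS\t.\tGT\t0/0\n"
        )
        with pytest.raises(ValueError, match="multi-allelic"):
            read_founder_panel(path, format="vcf")

    def test_text_vcf_parser_agrees_with_default_reader(self, tmp_path):
        from rcsim import founders as F

        cohort, gmap = self._tiny_panel()
        path = tmp_path / "panel.vcf"
        export_vcf(cohort, gmap, path)
        samples, chroms, poss, mids, alleles = F._parse_vcf_text(path)
        s2, c2, p2, m2, a2 = F._read_vcf(path)
        assert samples == list(map(str, s2))
        assert list(mids) == list(m2)
        assert np.array_equal(alleles, a2)

    def test_map_export(self, tmp_path):
        _, gmap = self._tiny_panel()
        export_map(gmap, tmp_path / "map.txt")
        lines = (tmp_path / "map.txt").read_text().strip().split("\n")
        assert len(lines) == 4
        assert lines[0].split("\t")[0] == "1"
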