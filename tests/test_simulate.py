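"""Synthetic-cohort generator: determinism, planted effects, coverage model."""

import dataclasses

import numpy as np
import pytest

from cfrefrag.catalog import StrLocus, region_fragment_counts
from cfrefrag.expansion import count_units
from cfrefrag.simulate import (
    HISTONE_MARKS,
    SimulationConfig,
    generate_catalog,
    simulate_cohort,
    simulate_peaks,
    simulate_sample,
    write_cohort,
)

SMALL = SimulationConfig(
    seed=5, n_healthy=2, n_cancer=2, n_alu=10, n_l1=6, n_low_complexity=4,
    n_rare=2, n_unclassified=2, n_blacklisted=2, n_sex_chrom=2, n_dormant=2,
    str_loci_per_unit=3, background_fragments=60.0,
    genome=(("chr1", 120_000), ("chr2", 80_000), ("chrX", 30_000)),
    too_regions_per_type=3,
)


@pytest.fixture(scope="module")
def small_genome():
    return generate_catalog(SMALL)


class TestCatalogConstruction:
    def test_str_reference_is_exact_motif_repeat(self, small_genome):
        for region in small_genome.regions:
            if isinstance(region, StrLocus):
                ref = small_genome.sequences[region.chrom][region.start : region.end]
                assert ref == region.motif * region.n2
                assert 1 <= region.n1 <= 6

    def test_every_family_present(self, small_genome):
        families = {r.family_key for r in small_genome.regions}
        assert {"Alu", "L1", "Simple_repeat", "Low_complexity",
                "MER-rare", "Unknown"} <= families

    def test_blacklist_covers_designated_regions(self, small_genome):
        assert len(small_genome.blacklist) == SMALL.n_blacklisted
        for chrom, start, end in small_genome.blacklist:
            assert any(r.chrom == chrom and r.start >= start and r.end <= end
                       for r in small_genome.regions)

    def test_catalog_determinism(self):
        a = generate_catalog(SMALL)
        b = generate_catalog(SMALL)
        assert a.sequences == b.sequences
        assert [(r.chrom, r.start, r.end, r.rep_name) for r in a.regions] == [
            (r.chrom, r.start, r.end, r.rep_name) for r in b.regions
        ]

    def test_genome_too_small_raises(self):
        tiny = dataclasses.replace(SMALL, genome=(("chr1", 5_000), ("chrX", 3_000)))
        with pytest.raises(ValueError, match="too small"):
            generate_catalog(tiny)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(SMALL, short_fraction_cancer=1.5).validate()


class TestSimulateSample:
    def test_label_and_type_validation(self, small_genome):
        with pytest.raises(ValueError):
            simulate_sample(SMALL, small_genome, "s", "cancer")  # type missing
        with pytest.raises(ValueError):
            simulate_sample(SMALL, small_genome, "s", "cancer",
                            cancer_type="bone")  # unknown type
        with pytest.raises(ValueError):
            simulate_sample(SMALL, small_genome, "s", "healthy",
                            cancer_type="lung")

    def test_zero_expansion_rate_gives_exact_reference_counts(self, small_genome):
        cfg = dataclasses.replace(SMALL, expansion_rate_healthy=0.0)
        rng = np.random.default_rng(3)
        frags = simulate_sample(cfg, small_genome, "s", "healthy", rng=rng)
        str_loci = [r for r in small_genome.regions if isinstance(r, StrLocus)]
        checked = 0
        for locus in str_loci:
            for f in frags:
                if f.chrom != locus.chrom:
                    continue
                units = count_units(f, locus)
                if units is None:
                    continue
                assert units <= locus.n2
                if f.start <= locus.start and f.end >= locus.end:
                    assert units == locus.n2
                    checked += 1
        assert checked > 20

    def test_short_fraction_one_gives_all_short(self, small_genome):
        cfg = dataclasses.replace(SMALL, short_fraction_healthy=1.0)
        rng = np.random.default_rng(4)
        frags = simulate_sample(cfg, small_genome, "s", "healthy", rng=rng)
        assert max(f.length for f in frags) < 175  # short mode 145, sd 10

    def test_poisson_coverage_mean(self, small_genome):
        # with no background, realized counts across regions match the
        # Poisson mean within 3 standard errors
        cfg = dataclasses.replace(SMALL, background_fragments=1e-9,
                                  low_mapq_fraction=0.0)
        rng = np.random.default_rng(6)
        frags = simulate_sample(cfg, small_genome, "s", "healthy", rng=rng)
        active = [r for i, r in enumerate(small_genome.regions)
                  if i not in small_genome.dormant]
        counts = region_fragment_counts(active, frags)
        lam = cfg.coverage_lambda
        se = np.sqrt(lam / len(active))
        assert abs(counts.mean() - lam) < 3 * se + 0.2  # slack for edge overlaps

    def test_dormant_regions_uncovered(self, small_genome):
        rng = np.random.default_rng(8)
        frags = simulate_sample(SMALL, small_genome, "s", "healthy", rng=rng)
        dormant = [small_genome.regions[i] for i in small_genome.dormant]
        assert region_fragment_counts(dormant, frags).sum() == 0

    def test_expansion_rate_monotonically_raises_expansion_fraction(
        self, small_genome
    ):
        # planted monotonicity over a fixed seed bank
        fractions = []
        for rate in (0.02, 0.15, 0.5):
            cfg = dataclasses.replace(SMALL, expansion_rate_cancer=rate)
            expanded = evaluated = 0
            for rep in range(4):
                rng = np.random.default_rng([9, rep])
                frags = simulate_sample(cfg, small_genome, "s", "cancer",
                                        cancer_type="colorectal", rng=rng)
                for locus in small_genome.regions:
                    if not isinstance(locus, StrLocus):
                        continue
                    for f in frags:
                        if f.chrom != locus.chrom:
                            continue
                        units = count_units(f, locus)
                        if units:
                            evaluated += 1
                            expanded += units > locus.n2
            fractions.append(expanded / evaluated)
        assert fractions[0] < fractions[1] < fractions[2]


class TestPeaks:
    def test_designated_regions_meet_majority_and_two_mark_rules(self, small_genome):
        peaks = simulate_peaks(SMALL, small_genome)
        n = SMALL.n_chip_samples
        for ctype, designated in small_genome.too_regions.items():
            for idx in designated:
                region = small_genome.regions[idx]
                marks = 0
                for mark in HISTONE_MARKS:
                    support = sum(
                        any(c == region.chrom and s < region.end and e > region.start
                            for c, s, e in peaks[(ctype, mark, f"chip{i}")])
                        for i in range(n)
                    )
                    marks += support > n / 2
                assert marks >= 2

    def test_off_target_regions_minority_only(self, small_genome):
        peaks = simulate_peaks(SMALL, small_genome)
        n = SMALL.n_chip_samples
        for ctype in SMALL.cancer_types:
            designated = set(small_genome.too_regions[ctype])
            for idx, region in enumerate(small_genome.regions):
                if idx in designated or region.family_key not in {
                    "Alu", "Simple_repeat"
                }:
                    continue
                for mark in HISTONE_MARKS:
                    support = sum(
                        any(c == region.chrom and s < region.end and e > region.start
                            for c, s, e in peaks[(ctype, mark, f"chip{i}")])
                        for i in range(n)
                    )
                    assert support <= n / 2


class TestCohortOutputs:
    def test_written_cohort_is_byte_identical_across_runs(self, tmp_path):
        d1 = write_cohort(simulate_cohort(SMALL), tmp_path / "a")
        d2 = write_cohort(simulate_cohort(SMALL), tmp_path / "b")
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_sample_sheet_layout(self, tmp_path):
        out = write_cohort(simulate_cohort(SMALL), tmp_path / "c")
        lines = (out / "samples.tsv").read_text().splitlines()
        header = lines[0].split("\t")
        assert header == ["sample_id", "path", "seqs_path", "label",
                          "cancer_type", "cohort_split"]
        assert len(lines) - 1 == SMALL.n_healthy + SMALL.n_cancer + 1  # + REF
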