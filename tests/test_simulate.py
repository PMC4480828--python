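"""Synthetic-data generator: determinism, calibration and distributions.

The planting identity — in-track placement probability p = λc/(λc + 1 − c)
gives a population odds ratio of exactly λ against a uniform background —
is the analytic oracle that downstream parameter-recovery tests rely on.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from conftest import track_bp_set
from regvar.simulate import (
    DiseaseSpec,
    GenomeCapacityError,
    SyntheticConfig,
    TrackSpec,
    annotate_consequences,
    generate_genome,
    generate_pool,
    generate_scenario,
    generate_track,
    plant_disease_set,
    planting_probability,
)


class TestGenerateGenome:
    def test_places_requested_disjoint_genes(self):
        cfg = SyntheticConfig(chrom_sizes={"chr1": 100_000}, n_genes=5,
                              pool_size=10, disease_specs=(), track_specs=(
                                  TrackSpec("t", 0.01),), seed=0)
        sizes, genes = generate_genome(cfg)
        assert len(genes) == 5
        for g in genes:
            assert 0 <= g.start < g.end <= sizes[g.chrom]
            assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end

    def test_gene_disjointness_by_interval_oracle(self):
        cfg = SyntheticConfig(chrom_sizes={"chr1": 1_000_000}, n_genes=50,
                              pool_size=10, disease_specs=(), track_specs=(
                                  TrackSpec("t", 0.01),), seed=2)
        _, genes = generate_genome(cfg)
        spans = sorted((g.chrom, g.start, g.end) for g in genes)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 <= s2

    def test_exons_nest_in_gene_and_cds_in_exons(self):
        cfg = SyntheticConfig(chrom_sizes={"chr1": 500_000}, n_genes=30,
                              pool_size=10, disease_specs=(), track_specs=(
                                  TrackSpec("t", 0.01),), seed=3)
        _, genes = generate_genome(cfg)
        for g in genes:
            exonic = set()
            for s, e in g.exons:
                assert g.start <= s < e <= g.end
                exonic.update(range(s, e))
            for s, e in g.cds:
                assert set(range(s, e)) <= exonic

    def test_seed_determinism(self):
        cfg = SyntheticConfig(chrom_sizes={"chr1": 200_000}, n_genes=10,
                              pool_size=10, disease_specs=(), track_specs=(
                                  TrackSpec("t", 0.01),), seed=4)
        assert generate_genome(cfg) == generate_genome(cfg)

    def test_capacity_error_when_genes_cannot_fit(self):
        cfg = SyntheticConfig(chrom_sizes={"chr1": 10_000}, n_genes=500,
                              pool_size=10, disease_specs=(), track_specs=(
                                  TrackSpec("t", 0.01),), seed=0)
        with pytest.raises(GenomeCapacityError):
            generate_genome(cfg)


class TestGenerateTrack:
    def test_length_hits_target_fraction(self):
        sizes = {"chr1": 1_000_000}
        track = generate_track(TrackSpec("t", 0.01, 800), sizes, seed=0)
        assert abs(track.total_length - 10_000) <= 500

    def test_near_full_coverage(self):
        sizes = {"chr1": 100_000}
        track = generate_track(TrackSpec("t", 0.95, 2_000), sizes, seed=1)
        assert track.total_length == pytest.approx(95_000, rel=0.05)

    def test_track_is_merged_and_within_bounds(self):
        sizes = {"chr1": 50_000, "chr2": 30_000}
        track = generate_track(TrackSpec("t", 0.1, 500), sizes, seed=2)
        for iv in track.intervals:
            assert 0 <= iv.start < iv.end <= sizes[iv.chrom]
        starts, ends = track.arrays("chr1")
        assert np.all(starts[1:] > ends[:-1])

    def test_independent_tracks_overlap_like_product_of_fractions(self):
        from regvar.intervals import overlap_length

        sizes = {"chr1": 1_000_000}
        f1, f2 = 0.2, 0.3
        a = generate_track(TrackSpec("a", f1, 500), sizes, seed=0, component=10)
        b = generate_track(TrackSpec("b", f2, 500), sizes, seed=0, component=11)
        got = overlap_length(a, b)
        expected = f1 * f2 * 1_000_000
        # coverage arrives in ~mean_len chunks, so the independent unit is an
        # interval, not a bp: ~f1*G/mean_len Bernoulli(f2) trials of mean_len bp
        n_units = f1 * 1_000_000 / 500
        sd = 500 * np.sqrt(n_units * f2 * (1 - f2))
        assert abs(got - expected) < 3 * sd


class TestGeneratePool:
    def test_unique_keys_and_size(self):
        cfg = SyntheticConfig(chrom_sizes={"chr1": 1_000}, pool_size=10,
                              disease_specs=(), track_specs=(TrackSpec("t", 0.5),),
                              seed=0)
        pool = generate_pool(cfg)
        assert len(pool) == 10
        assert len(pool.keys()) == 10

    def test_af_distribution_matches_beta_by_gof(self):
        cfg = SyntheticConfig(chrom_sizes={"chr1": 2_000_000}, pool_size=10_000,
                              disease_specs=(), track_specs=(TrackSpec("t", 0.5),),
                              af_model=("beta", 0.2, 2.0), seed=7)
        afs = generate_pool(cfg).afs()
        edges = np.array([0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0])
        observed, _ = np.histogram(afs, bins=edges)
        cdf = stats.beta(0.2, 2.0).cdf(edges)
        expected = np.diff(cdf) / (cdf[-1] - cdf[0]) * len(afs)
        gof = stats.chisquare(observed, expected)
        assert gof.pvalue > 0.001

    def test_seed_determinism(self):
        cfg = SyntheticConfig(chrom_sizes={"chr1": 100_000}, pool_size=500,
                              disease_specs=(), track_specs=(TrackSpec("t", 0.5),),
                              seed=9)
        assert generate_pool(cfg).keys() == generate_pool(cfg).keys()


class TestPlanting:
    def test_null_fold_places_at_coverage(self):
        assert planting_probability(1.0, 0.01) == pytest.approx(0.01)
        assert planting_probability(1.0, 0.37) == pytest.approx(0.37)

    def test_plug_in_arithmetic(self):
        assert planting_probability(5.0, 0.01) == pytest.approx(
            0.05 / (0.05 + 0.99)
        )

    def test_population_odds_ratio_identity(self, rng):
        # (p/(1-p)) / (c/(1-c)) == λ exactly, for random (λ, c)
        for _ in range(20):
            lam = float(rng.uniform(0.1, 50))
            c = float(rng.uniform(0.001, 0.999))
            p = planting_probability(lam, c)
            assert (p / (1 - p)) / (c / (1 - c)) == pytest.approx(lam, abs=1e-12)

    def test_empirical_in_track_fraction_within_3_sd(self):
        sizes = {"chr1": 2_000_000}
        track = generate_track(TrackSpec("t", 0.02, 800), sizes, seed=0)
        spec = DiseaseSpec("d", 10_000, "t", 5.0)
        vs = plant_disease_set(spec, sizes, track, seed=0)
        c = track.total_length / 2_000_000
        p = planting_probability(5.0, c)
        in_track = sum(track.contains(v.chrom, v.pos0) for v in vs)
        sd = np.sqrt(10_000 * p * (1 - p))
        assert abs(in_track - 10_000 * p) <= 3 * sd

    def test_planted_set_determinism_and_af(self):
        sizes = {"chr1": 500_000}
        track = generate_track(TrackSpec("t", 0.05, 500), sizes, seed=1)
        spec = DiseaseSpec("d", 200, "t", 2.0)
        a = plant_disease_set(spec, sizes, track, seed=42)
        b = plant_disease_set(spec, sizes, track, seed=42)
        assert a.keys() == b.keys()
        assert all(v.af is not None and 0 <= v.af <= 1 for v in a)


class TestScenario:
    def test_scenario_is_bit_reproducible(self):
        cfg = SyntheticConfig(
            chrom_sizes={"chr1": 300_000}, n_genes=10, pool_size=2_000,
            track_specs=(TrackSpec("promoter", 0.01, 400),),
            disease_specs=(DiseaseSpec("mendelian", 300, "promoter", 10.0),),
            seed=123,
        )
        s1, s2 = generate_scenario(cfg), generate_scenario(cfg)
        assert s1.pool.keys() == s2.pool.keys()
        assert s1.disease_sets["mendelian"].keys() == s2.disease_sets["mendelian"].keys()
        assert track_bp_set(s1.tracks["promoter"]) == track_bp_set(s2.tracks["promoter"])
        assert s1.genes == s2.genes

    def test_unknown_planted_track_rejected(self):
        with pytest.raises(ValueError, match="unknown track"):
            SyntheticConfig(
                track_specs=(TrackSpec("a", 0.1),),
                disease_specs=(DiseaseSpec("d", 10, "b", 2.0),),
            )

    def test_annotation_helper_attaches_terms_and_scores(self):
        cfg = SyntheticConfig(
            chrom_sizes={"chr1": 100_000}, n_genes=0, pool_size=10,
            track_specs=(TrackSpec("t", 0.01),),
            disease_specs=(DiseaseSpec("mendelian", 50, "t", 2.0),), seed=0,
        )
        sc = generate_scenario(cfg)
        vs = annotate_consequences(sc.disease_sets["mendelian"], seed=0)
        assert all(v.consequence is not None for v in vs)
        assert all("gerp" in v.scores and "mutation_assessor" in v.scores
                   for v in vs)
        again = annotate_consequences(sc.disease_sets["mendelian"], seed=0)
        assert [v.consequence for v in vs] == [v.consequence for v in again]
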