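"""Backcross simulator, progeny sampler and fixture generators."""

import numpy as np
import pytest

from himap import cross_engine as ce
from himap import synthetic_data as sd
from himap.genome_core import CB4, GenomicInterval

MB = 1_000_000


class TestBackcross:
    def test_no_recombination_keeps_whole_chromosome(self):
        cfg = sd.BackcrossConfig(chromosome="I", gfp_position=5 * MB,
                                 genetic_length=0.0, generations=10, seed=0)
        traj = sd.simulate_backcross(cfg)
        assert all(iv == GenomicInterval("I", 0, CB4.length("I")) for iv in traj)

    def test_trajectory_nested_and_contains_gfp(self):
        cfg = sd.BackcrossConfig(chromosome="X", gfp_position=10 * MB, seed=5)
        traj = sd.simulate_backcross(cfg)
        assert len(traj) == cfg.generations
        for prev, cur in zip(traj, traj[1:]):
            assert prev.contains(cur)
        for iv in traj:
            assert iv.contains_position(cfg.gfp_position)

    def test_deterministic_under_seed(self):
        cfg = sd.BackcrossConfig(chromosome="II", gfp_position=8 * MB, seed=99)
        assert sd.simulate_backcross(cfg) == sd.simulate_backcross(cfg)
        cfg2 = sd.BackcrossConfig(chromosome="II", gfp_position=8 * MB, seed=100)
        assert sd.simulate_backcross(cfg) != sd.simulate_backcross(cfg2)

    def test_mean_side_length_matches_exponential_oracle(self):
        """Mean one-side retained genetic length after t meioses is
        (1 - exp(-tL))/t Morgans (min of t exponentials truncated at L):
        checked at t=7 within 3 Monte-Carlo SE (fuller sweep in acceptance)."""
        t = 7
        gfp = 10_770_000
        cfg = sd.BackcrossConfig(chromosome="X", gfp_position=gfp, generations=t)
        rng = np.random.default_rng(2024)
        rate = sd.DEFAULT_GENETIC_LENGTH / CB4.length("X")
        sides = {"left": [], "right": []}
        for _ in range(1500):
            iv = sd.simulate_backcross(cfg, rng)[-1]
            sides["left"].append((gfp - iv.start) * rate)
            sides["right"].append((iv.end - gfp) * rate)
        for name, L in (("left", gfp * rate), ("right", (CB4.length("X") - gfp) * rate)):
            obs = np.asarray(sides[name])
            pred = (1 - np.exp(-t * L)) / t
            se = obs.std() / np.sqrt(len(obs))
            assert abs(obs.mean() - pred) < 3 * se

    def test_recombination_suppression_widens_segments(self):
        gfp = 10 * MB
        base = sd.BackcrossConfig(chromosome="X", gfp_position=gfp)
        suppressed = sd.BackcrossConfig(
            chromosome="X", gfp_position=gfp,
            rate_multipliers=[(GenomicInterval("X", 5 * MB, 15 * MB), 0.0)],
        )
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        mean_base = np.mean([sd.simulate_backcross(base, rng1)[-1].length for _ in range(300)])
        mean_sup = np.mean([sd.simulate_backcross(suppressed, rng2)[-1].length for _ in range(300)])
        assert mean_sup > mean_base
        # a fully suppressed interval can never be broken
        rng3 = np.random.default_rng(4)
        for _ in range(100):
            iv = sd.simulate_backcross(suppressed, rng3)[-1]
            assert iv.start <= 5 * MB and iv.end >= 15 * MB

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.BackcrossConfig(chromosome="I", gfp_position=99 * MB)
        with pytest.raises(ValueError):
            sd.BackcrossConfig(chromosome="I", gfp_position=1, generations=0)


class TestProgenyCounts:
    def test_gfp_fraction_converges_to_engine(self):
        mother = ce.parse_genotype("G/+", ce.FEMALE)
        father = ce.parse_genotype("G/+", ce.MALE)
        rec = sd.simulate_progeny_counts(
            mother, father, ce.LocusSpec(), n_eggs=10_000, replicates=1,
            baseline_emb=0.0, baseline_lva=0.0, seed=0,
        )
        pooled = rec.pooled()
        frac = pooled.gfp / pooled.progeny
        se = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(frac - 0.75) < 3 * se

    def test_recessive_lethal_raises_emb_by_quarter(self):
        mother = ce.parse_genotype("G/+", ce.FEMALE)
        father = ce.parse_genotype("G/+", ce.MALE)
        model = ce.ViabilityFertilityModel(
            survival={("G/G", ce.FEMALE): 0, ("G/G", ce.MALE): 0}
        )
        rec = sd.simulate_progeny_counts(
            mother, father, ce.LocusSpec(), model=model, n_eggs=10_000, replicates=1,
            baseline_emb=0.0, baseline_lva=0.0, seed=1,
        )
        emb = rec.pooled().unhatched / rec.pooled().eggs
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(emb - 0.25) < 3 * se

    def test_zero_eggs_rejected(self):
        mother = ce.parse_genotype("G/+", ce.FEMALE)
        father = ce.parse_genotype("G/+", ce.MALE)
        with pytest.raises(ValueError):
            sd.simulate_progeny_counts(mother, father, ce.LocusSpec(), n_eggs=0)

    def test_infeasible_model_rejected(self):
        mother = ce.parse_genotype("G/G", ce.FEMALE)
        father = ce.parse_genotype("G/G", ce.MALE)
        model = ce.ViabilityFertilityModel(
            survival={("G/G", ce.FEMALE): 0, ("G/G", ce.MALE): 0}
        )
        with pytest.raises(ValueError):
            sd.simulate_progeny_counts(mother, father, ce.LocusSpec(), model=model)

    def test_x_transmission_distortion_shifts_sex_ratio(self):
        mother = ce.parse_genotype("G/+", ce.FEMALE, ce.X_LINKED)
        father = ce.parse_genotype("+/O", ce.MALE, ce.X_LINKED)
        rec = sd.simulate_progeny_counts(
            mother, father, ce.LocusSpec(ce.X_LINKED), n_eggs=5000, replicates=1,
            baseline_emb=0.0, baseline_lva=0.0, male_x_transmission=0.8, seed=2,
        )
        pooled = rec.pooled()
        assert pooled.males / pooled.progeny < 0.35  # male share pushed well below 1/2


class TestGenotypeAndCoverageFixtures:
    def test_error_free_matrix_is_consistent_with_truth(self):
        truth = GenomicInterval("III", 4 * MB, 9 * MB)
        panel = sd.uniform_panel("III", 12)
        gm = sd.simulate_genotype_matrix(truth, panel, seed=0)
        for marker, call in gm.calls_for("sim", "III"):
            assert (call == "+") == truth.contains_position(marker.midpoint)

    def test_high_error_rate_flips_calls(self):
        truth = GenomicInterval("III", 4 * MB, 9 * MB)
        panel = sd.uniform_panel("III", 30)
        clean = sd.simulate_genotype_matrix(truth, panel, seed=5)
        noisy = sd.simulate_genotype_matrix(truth, panel, call_error_rate=0.5, seed=5)
        diffs = sum(
            c1 != c2
            for (_, c1), (_, c2) in zip(clean.calls_for("sim", "III"), noisy.calls_for("sim", "III"))
        )
        assert diffs > 5

    def test_sigma_zero_coverage_is_exact_step(self):
        truth = GenomicInterval("I", 2 * MB, 5 * MB)
        track = sd.simulate_coverage(truth, baseline_depth=1.0, fold=5.0, sigma=0.0, seed=0)
        inside = track.depths[200:500]
        outside = np.concatenate([track.depths[:200], track.depths[500:]])
        assert (inside == 5.0).all() and (outside == 1.0).all()


class TestHIDataset:
    def test_deterministic_and_truth_consistent(self):
        model = sd.PlantedHIModel(
            loci=[sd.PlantedLocus(GenomicInterval("X", 14 * MB, 15 * MB), "male_inviable")]
        )
        ds1 = sd.simulate_hi_dataset(model, n_lines=10, seed=7)
        ds2 = sd.simulate_hi_dataset(model, n_lines=10, seed=7)
        assert [l.introgression for l in ds1.lines] == [l.introgression for l in ds2.lines]
        for line in ds1.lines:
            if line.truth_flags["male_inviable"]:
                assert line.introgression.overlaps(GenomicInterval("X", 14 * MB, 15 * MB))
                assert line.record.pooled().males_gfp == 0
                assert not line.truth_flags["male_sterile"]

    def test_null_model_lines_carry_no_truth_flags(self):
        ds = sd.simulate_hi_dataset(sd.PlantedHIModel(), n_lines=5, seed=1)
        for line in ds.lines:
            assert not any(line.truth_flags.values())

    def test_genotypes_round_trip_through_caller(self):
        from himap.marker_genotyping import NoIntrogressionError, call_boundaries

        ds = sd.simulate_hi_dataset(sd.PlantedHIModel(), n_lines=15, seed=3)
        for line in ds.lines:
            chromosome = line.introgression.chromosome
            pairs = line.genotypes.calls_for(line.strain, chromosome)
            try:
                ic = call_boundaries(
                    [c for _, c in pairs], [m for m, _ in pairs], CB4, strain=line.strain
                )
            except NoIntrogressionError:
                continue  # introgression smaller than marker spacing
            assert ic.outer.contains(line.introgression)
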