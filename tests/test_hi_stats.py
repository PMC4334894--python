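"""Phenotype rates, statistical kernels and HI classification."""

import math

import numpy as np
import pytest
from scipy import stats

from himap import cross_engine as ce
from himap import synthetic_data as sd
from himap.hi_stats import (
    PhenotypeRecord,
    ReplicateCounts,
    chi_squared_ratio,
    classify_line,
    compare_to_control,
    dominance_call,
    emb_rate,
    lva_rate,
    scheme_expectations,
)


def _record(reps, **kwargs):
    return PhenotypeRecord(strain="s", replicates=reps, **kwargs)


class TestRates:
    def test_emb_per_replicate_and_pooled(self):
        rec = _record(
            [ReplicateCounts(eggs=100, unhatched=10), ReplicateCounts(eggs=100, unhatched=30)]
        )
        per_rep, pooled = emb_rate(rec)
        assert per_rep == [0.10, 0.30]
        assert pooled == 0.20

    def test_emb_zero_egg_replicate_excluded(self):
        rec = _record([ReplicateCounts(eggs=0), ReplicateCounts(eggs=100, unhatched=20)])
        per_rep, pooled = emb_rate(rec)
        assert per_rep == [0.20] and pooled == 0.20

    @pytest.mark.parametrize(
        "l1,adults,expected", [(80, 70, 0.125), (80, 80, 0.0), (80, 0, 1.0)]
    )
    def test_lva(self, l1, adults, expected):
        rec = _record([ReplicateCounts(eggs=100, l1=l1, adults=adults)])
        assert lva_rate(rec)[1] == expected

    def test_adults_exceeding_l1_rejected(self):
        with pytest.raises(ValueError):
            ReplicateCounts(eggs=100, l1=10, adults=20)


class TestChiSquared:
    def test_perfect_fit_gives_zero(self):
        x2, df, p = chi_squared_ratio([50, 50], [0.5, 0.5])
        assert x2 == 0 and df == 1 and p == 1.0
        x2, _, _ = chi_squared_ratio([75, 25], [0.75, 0.25])
        assert x2 == 0

    def test_hand_computed_two_class_case(self):
        x2, df, p = chi_squared_ratio([60, 40], [0.5, 0.5])
        assert x2 == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_expected_class_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_ratio([5, 5], [1.0, 0.0])

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            chi_squared_ratio([5, 5], [0.6, 0.6])

    def test_monotone_agreement_with_multinomial_likelihood_ratio(self):
        """Pearson X² orders small-count tables like the multinomial LR statistic."""
        expected = (0.75, 0.25)
        n = 20
        tables = [(k, n - k) for k in range(1, n)]

        def lr(obs):
            out = 0.0
            for o, e in zip(obs, expected):
                out += 2 * o * math.log(o / (n * e)) if o else 0.0
            return out

        x2s = [chi_squared_ratio(t, expected)[0] for t in tables]
        lrs = [lr(t) for t in tables]
        rho = stats.spearmanr(x2s, lrs).statistic
        assert rho > 0.99


class TestCompareToControl:
    def test_identical_groups_fast_path(self):
        groups = {"a": [0.1, 0.1, 0.1], "ctrl": [0.1, 0.1, 0.1]}
        omnibus, pairwise = compare_to_control(groups, "ctrl")
        assert omnibus.p == 1.0 and pairwise["a"].p == 1.0

    def test_zero_variance_different_means(self):
        groups = {"a": [0.9, 0.9], "ctrl": [0.1, 0.1]}
        _, pairwise = compare_to_control(groups, "ctrl")
        assert pairwise["a"].p == 0.0

    def test_two_group_anova_equals_squared_t(self, rng):
        a = rng.normal(0.3, 0.05, size=6)
        b = rng.normal(0.5, 0.05, size=6)
        omnibus, pairwise = compare_to_control({"a": a, "ctrl": b}, "ctrl")
        t_stat, t_p = stats.ttest_ind(a, b)
        assert omnibus.statistic == pytest.approx(t_stat**2)
        assert pairwise["a"].p == pytest.approx(t_p)
        # two-group Tukey q = sqrt(2)|t| and matches scipy's integral
        q_p = stats.tukey_hsd(a, b).pvalue[0, 1]
        assert pairwise["a"].p == pytest.approx(q_p, abs=1e-6)

    def test_three_group_separation(self):
        groups = {
            "a": [0.1, 0.1, 0.1, 0.11],
            "b": [0.9, 0.9, 0.9, 0.91],
            "ctrl": [0.1, 0.11, 0.1, 0.1],
        }
        omnibus, pairwise = compare_to_control(groups, "ctrl")
        assert omnibus.p < 0.01
        assert pairwise["b"].p < 0.01
        assert pairwise["a"].p > 0.5


class TestDominance:
    @pytest.mark.parametrize(
        "het,ctrl,expected",
        [(0.40, 0.10, True), (0.30, 0.10, False), (0.351, 0.10, True), (0.35, 0.10, False)],
    )
    def test_control_plus_quarter_rule(self, het, ctrl, expected):
        assert dominance_call(het, ctrl) is expected

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            dominance_call(1.2, 0.1)


class TestSchemeExpectations:
    def test_engine_derived_ratios(self):
        from fractions import Fraction

        auto = scheme_expectations("auto-het")
        assert auto["gfp_overall"] == Fraction(3, 4)
        assert auto["gfp_males"] == Fraction(3, 4)
        xv = scheme_expectations("x-het-male-viable")
        assert xv["gfp_males"] == Fraction(1, 2)
        xi = scheme_expectations("x-het-male-inviable")
        assert xi["gfp_overall"] == Fraction(1, 3)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            scheme_expectations("tetraploid")


class TestClassify:
    def _control(self, seed=0):
        return sd.simulate_control_record(sd.PlantedHIModel(), seed=seed)

    def test_male_sterile_categorical(self):
        rec = _record(
            [ReplicateCounts(eggs=100, unhatched=10, l1=90, adults=80,
                             males_gfp=20, males_nongfp=20, females_gfp=20, females_nongfp=20)],
            linkage=ce.X_LINKED,
        )
        rec.male_cross_progeny = 0
        rec.reciprocal_cross_progeny = 55
        call = classify_line(rec, None, "x-het-male-viable")
        assert call.male_sterile and not call.male_inviable
        assert not call.statistical_flags_evaluated

    def test_male_inviable_categorical(self):
        rec = _record(
            [ReplicateCounts(eggs=100, unhatched=10, l1=90, adults=80,
                             males_gfp=0, males_nongfp=40, females_gfp=20, females_nongfp=20)],
            linkage=ce.X_LINKED,
        )
        call = classify_line(rec, None, "x-het-male-inviable")
        assert call.male_inviable

    def test_homozygous_inviable_after_five_attempts(self):
        rec = _record([ReplicateCounts(eggs=100, unhatched=10, l1=90, adults=85)])
        call = classify_line(rec, None, "auto-het", attempts_to_homozygose=5)
        assert call.homozygous_inviable
        call = classify_line(rec, None, "auto-het", attempts_to_homozygose=4)
        assert not call.homozygous_inviable

    def test_planted_emb_effect_flagged_and_dominant(self, rng):
        # Dominant fully penetrant embryonic lethality: ~75% of progeny die.
        mother = ce.parse_genotype("G/+", ce.FEMALE)
        father = ce.parse_genotype("G/+", ce.MALE)
        model = ce.ViabilityFertilityModel(
            survival={("+/G", ce.FEMALE): 0, ("+/G", ce.MALE): 0,
                      ("G/G", ce.FEMALE): 0, ("G/G", ce.MALE): 0}
        )
        rec = sd.simulate_progeny_counts(
            mother, father, ce.LocusSpec(), model=model, seed=3, strain="dom"
        )
        call = classify_line(rec, self._control(), "auto-het")
        flags = call.flags()
        assert flags["emb_elevated"] and flags["dominant_emb"]

    def test_null_line_mostly_unflagged(self):
        mother = ce.parse_genotype("G/+", ce.FEMALE)
        father = ce.parse_genotype("G/+", ce.MALE)
        rec = sd.simulate_progeny_counts(mother, father, ce.LocusSpec(), seed=11)
        rec.brood_sizes = [148, 150, 152, 149, 151]
        ctrl = self._control(seed=12)
        call = classify_line(rec, ctrl, "auto-het")
        flags = call.flags()
        assert not flags["dominant_emb"] and not flags["male_sterile"]
        assert not flags["gfp_segregation_distorted"]

    def test_missing_control_downgrades_gracefully(self):
        rec = _record([ReplicateCounts(eggs=100, unhatched=10, l1=90, adults=85)])
        call = classify_line(rec, None, "auto-het")
        assert not call.statistical_flags_evaluated
        assert call.warnings
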