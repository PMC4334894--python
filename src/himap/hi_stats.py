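"""Phenotype rates, statistical tests and hybrid-incompatibility classification.

Two viability phenotypes are scored per strain from egg-lay replicates:
embryonic lethality (Emb, unhatched eggs / eggs laid) and larval arrest
(Lva, (hatched L1 - adults) / hatched L1).  Fertility is brood size (eggs
laid over a fixed window).  Rates are compared against a recipient-species
control strain by one-way ANOVA with Tukey's HSD post hoc test on
replicate-level rates; segregation ratios (percentage of males, percentage
of GFP-expressing progeny) are tested against the Mendelian expectations of
the cross engine by Pearson chi-squared on pooled counts.

Categorical HI definitions follow the crossing assay: male sterility is the
absence of progeny from a male-direction cross with progeny present in the
reciprocal; male inviability (X-linked) is the absence of GFP-expressing
male progeny with GFP females present; homozygous inviability is failure to
render an introgression homozygous after five attempts.  A heterozygous line
is called dominant for Emb (or Lva) when its rate exceeds the control rate
plus the 25% expected from fully penetrant recessive lethality of the
homozygous class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import cross_engine as ce

__all__ = [
    "ReplicateCounts",
    "PhenotypeRecord",
    "TestResult",
    "HICall",
    "emb_rate",
    "lva_rate",
    "chi_squared_ratio",
    "compare_to_control",
    "dominance_call",
    "classify_line",
    "scheme_expectations",
    "HOMOZYGOSING_ATTEMPT_THRESHOLD",
]

#: Attempts to render an introgression homozygous before it is deemed inviable.
HOMOZYGOSING_ATTEMPT_THRESHOLD = 5

#: Expected inviable fraction under fully penetrant recessive lethality in a
#: het x het cross; also the dominance margin added to the control rate.
RECESSIVE_LETHAL_FRACTION = 0.25


@dataclass
class ReplicateCounts:
    """Raw counts for one scoring replicate of one strain."""

    eggs: int = 0
    unhatched: int = 0
    l1: int = 0
    adults: int = 0
    males_gfp: int = 0
    males_nongfp: int = 0
    females_gfp: int = 0
    females_nongfp: int = 0

    def __post_init__(self) -> None:
        for name in ("eggs", "unhatched", "l1", "adults",
                     "males_gfp", "males_nongfp", "females_gfp", "females_nongfp"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")
        if self.unhatched > self.eggs:
            raise ValueError("unhatched eggs exceed eggs laid")
        if self.adults > self.l1:
            raise ValueError("adults exceed hatched L1 larvae")

    @property
    def males(self) -> int:
        return self.males_gfp + self.males_nongfp

    @property
    def females(self) -> int:
        return self.females_gfp + self.females_nongfp

    @property
    def progeny(self) -> int:
        return self.males + self.females

    @property
    def gfp(self) -> int:
        return self.males_gfp + self.females_gfp


@dataclass
class PhenotypeRecord:
    """Per-strain phenotype counts across replicates, plus crossing-assay facts.

    ``male_cross_progeny`` / ``reciprocal_cross_progeny`` are progeny counts
    of the male-fertility assay (introgression males x recipient females, and
    the reciprocal); ``homozygosing_attempts_failed`` counts failed attempts
    to render the introgression homozygous.  Any of these may be None when
    the assay was not performed.
    """

    strain: str
    replicates: list[ReplicateCounts] = field(default_factory=list)
    brood_sizes: list[int] = field(default_factory=list)
    zygosity: str = "heterozygous"  # heterozygous | homozygous | hemizygous
    linkage: str = ce.AUTOSOMAL
    male_cross_progeny: int | None = None
    reciprocal_cross_progeny: int | None = None
    homozygosing_attempts_failed: int | None = None

    def pooled(self) -> ReplicateCounts:
        out = ReplicateCounts()
        for r in self.replicates:
            for name in ("eggs", "unhatched", "l1", "adults",
                         "males_gfp", "males_nongfp", "females_gfp", "females_nongfp"):
                setattr(out, name, getattr(out, name) + getattr(r, name))
        return out


def emb_rate(record: PhenotypeRecord) -> tuple[list[float], float]:
    """Embryonic lethality: unhatched / eggs, per replicate and pooled.

    Replicates with zero eggs are undefined and excluded (the pooled rate
    uses pooled counts).  Raises if no replicate has eggs.
    """
    per_rep = [r.unhatched / r.eggs for r in record.replicates if r.eggs > 0]
    pooled = record.pooled()
    if pooled.eggs == 0:
        raise ValueError(f"strain {record.strain}: no eggs laid in any replicate")
    return per_rep, pooled.unhatched / pooled.eggs


def lva_rate(record: PhenotypeRecord) -> tuple[list[float], float]:
    """Larval arrest: (L1 - adults) / L1, per replicate and pooled."""
    per_rep = [(r.l1 - r.adults) / r.l1 for r in record.replicates if r.l1 > 0]
    pooled = record.pooled()
    if pooled.l1 == 0:
        raise ValueError(f"strain {record.strain}: no hatched larvae in any replicate")
    return per_rep, (pooled.l1 - pooled.adults) / pooled.l1


def chi_squared_ratio(
    observed: Sequence[int], expected_fractions: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit X^2 of observed class counts vs expected ratios.

    No continuity correction is applied (multi-class expected-ratio tests;
    see the methods note).  Returns ``(X^2, df, p)`` with ``df = k - 1`` and
    the p-value from the upper tail of the chi-squared distribution.
    """
    obs = np.asarray(observed, dtype=float)
    exp_frac = np.asarray([float(f) for f in expected_fractions], dtype=float)
    if len(obs) != len(exp_frac):
        raise ValueError("observed and expected must have the same number of classes")
    if not math.isclose(exp_frac.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("expected fractions must sum to 1")
    n = obs.sum()
    exp = n * exp_frac
    if np.any(exp <= 0):
        raise ValueError("every expected class count must be positive")
    x2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(x2, df))
    return x2, df, p


@dataclass
class TestResult:
    """One statistical comparison: statistic, p-value, significance tier."""

    statistic: float
    p: float
    test: str
    expectation: object = None
    tier: str = field(init=False)

    def __post_init__(self) -> None:
        if self.p < 0.01:
            self.tier = "**"
        elif self.p < 0.05:
            self.tier = "*"
        else:
            self.tier = ""

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def compare_to_control(
    groups: Mapping[str, Sequence[float]], control: str
) -> tuple[TestResult, dict[str, TestResult]]:
    """One-way ANOVA across all groups, then Tukey HSD vs the control group.

    ``groups`` maps group name to replicate-level rates (or brood sizes).
    Returns the omnibus F test and, per non-control group, the Tukey-adjusted
    pairwise comparison against the control.  When every group has zero
    within-group variance the exact-equality fast path applies: p = 1 for
    groups identical to the control, p = 0 otherwise.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 replicates")

    if all(np.ptp(v) == 0 for v in data.values()):
        # Degenerate: no within-group variance anywhere; compare means exactly.
        ctrl_mean = data[control][0]
        omnibus_p = 1.0 if len({float(v[0]) for v in data.values()}) == 1 else 0.0
        omnibus = TestResult(statistic=0.0 if omnibus_p == 1.0 else math.inf,
                             p=omnibus_p, test="anova")
        pairwise = {
            k: TestResult(
                statistic=0.0 if v[0] == ctrl_mean else math.inf,
                p=1.0 if v[0] == ctrl_mean else 0.0,
                test="tukey-hsd",
            )
            for k, v in data.items()
            if k != control
        }
        return omnibus, pairwise

    samples = [data[k] for k in names]
    f_stat, f_p = stats.f_oneway(*samples)
    omnibus = TestResult(statistic=float(f_stat), p=float(f_p), test="anova")

    if len(names) == 2:
        # With two groups Tukey's HSD reduces exactly to the pooled
        # two-sample t-test (q = sqrt(2)|t|, same p); the closed form avoids
        # the studentized-range integral.
        a, b = samples
        t_stat, t_p = stats.ttest_ind(a, b)
        other = names[1 - names.index(control)]
        res = TestResult(
            statistic=float(abs(t_stat) * math.sqrt(2.0)), p=float(t_p), test="tukey-hsd"
        )
        return omnibus, {other: res}

    tukey = stats.tukey_hsd(*samples)
    ctrl_idx = names.index(control)
    pairwise: dict[str, TestResult] = {}
    for i, name in enumerate(names):
        if name == control:
            continue
        pairwise[name] = TestResult(
            statistic=float(tukey.statistic[i, ctrl_idx]),
            p=float(tukey.pvalue[i, ctrl_idx]),
            test="tukey-hsd",
        )
    return omnibus, pairwise


def dominance_call(
    het_rate: float,
    control_rate: float,
    expected_recessive_fraction: float = RECESSIVE_LETHAL_FRACTION,
) -> bool:
    """Dominant-effect rule for a heterozygous introgression.

    The introgression acts (at least partially) dominantly when the hybrid
    rate exceeds the control rate plus the fraction expected from fully
    penetrant recessive lethality of homozygotes (25% in a het x het cross).
    Strict inequality.
    """
    for r in (het_rate, control_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    return het_rate > control_rate + expected_recessive_fraction


def scheme_expectations(scheme: str) -> dict[str, Fraction]:
    """Mendelian expectations for a named crossing scheme, from the engine.

    Schemes
    -------
    ``auto-het``
        Autosomal G/+ x G/+: 75% GFP overall, 75% of males GFP.
    ``x-het-male-viable``
        X-linked X^G/X^+ female x +/O male, GFP males viable: 50% of males
        GFP, 50% GFP overall.
    ``x-het-male-inviable``
        Same cross with GFP hemizygous males fully inviable: 33.3% of
        surviving progeny GFP.
    ``homozygous``
        True-breeding line: 100% GFP, 50% males expected.
    """
    if scheme == "auto-het":
        locus = ce.LocusSpec(ce.AUTOSOMAL)
        mother = ce.parse_genotype("G/+", ce.FEMALE)
        father = ce.parse_genotype("G/+", ce.MALE)
        dist = ce.expected_progeny(mother, father, locus)
        return {
            "gfp_overall": ce.expected_fraction(dist, ce.gfp),
            "gfp_males": ce.expected_fraction(dist, ce.gfp, given=ce.is_male),
            "male_fraction": ce.expected_fraction(dist, ce.is_male),
        }
    if scheme in ("x-het-male-viable", "x-het-male-inviable"):
        locus = ce.LocusSpec(ce.X_LINKED)
        mother = ce.parse_genotype("G/+", ce.FEMALE, ce.X_LINKED)
        father = ce.parse_genotype("+/O", ce.MALE, ce.X_LINKED)
        model = ce.FULL_VIABILITY
        if scheme == "x-het-male-inviable":
            model = ce.ViabilityFertilityModel(survival={("G/O", ce.MALE): 0})
        dist = ce.expected_progeny(mother, father, locus, model)
        out = {
            "gfp_overall": ce.expected_fraction(dist, ce.gfp),
            "male_fraction": ce.expected_fraction(dist, ce.is_male),
        }
        if scheme == "x-het-male-viable":
            out["gfp_males"] = ce.expected_fraction(dist, ce.gfp, given=ce.is_male)
        return out
    if scheme == "homozygous":
        return {
            "gfp_overall": Fraction(1),
            "male_fraction": Fraction(1, 2),
        }
    raise ValueError(f"unknown crossing scheme {scheme!r}")


@dataclass
class HICall:
    """Classification of one introgression line: flags with their evidence."""

    strain: str
    scheme: str
    male_sterile: bool = False
    male_inviable: bool = False
    homozygous_inviable: bool = False
    emb_elevated: TestResult | None = None
    lva_elevated: TestResult | None = None
    dominant_emb: bool = False
    dominant_lva: bool = False
    fertility_reduced: TestResult | None = None
    fertility_elevated: TestResult | None = None
    sex_ratio_distorted: TestResult | None = None
    gfp_segregation_distorted: TestResult | None = None
    statistical_flags_evaluated: bool = True
    warnings: list[str] = field(default_factory=list)
    # Raw two-sided contrasts vs control, kept regardless of direction so the
    # calibration of the underlying tests is inspectable.
    emb_test: TestResult | None = None
    lva_test: TestResult | None = None
    fertility_test: TestResult | None = None

    def flags(self) -> dict[str, bool]:
        """Boolean view of every flag (statistical flags at p < 0.05)."""
        def sig(t: TestResult | None) -> bool:
            return t is not None and t.significant

        return {
            "male_sterile": self.male_sterile,
            "male_inviable": self.male_inviable,
            "homozygous_inviable": self.homozygous_inviable,
            "emb_elevated": sig(self.emb_elevated),
            "lva_elevated": sig(self.lva_elevated),
            "dominant_emb": self.dominant_emb,
            "dominant_lva": self.dominant_lva,
            "fertility_reduced": sig(self.fertility_reduced),
            "fertility_elevated": sig(self.fertility_elevated),
            "sex_ratio_distorted": sig(self.sex_ratio_distorted),
            "gfp_segregation_distorted": sig(self.gfp_segregation_distorted),
        }


def classify_line(
    record: PhenotypeRecord,
    control: PhenotypeRecord | None,
    scheme: str,
    attempts_to_homozygose: int | None = None,
    all_groups: Mapping[str, Sequence[float]] | None = None,
) -> HICall:
    """Assign HI flags to one introgression line.

    Statistical flags (Emb, Lva, fertility) come from ANOVA + Tukey against
    the control's replicate rates; segregation flags from Pearson chi-squared
    of pooled counts against the scheme's Mendelian expectation; dominance
    from the control-plus-25% rule; categorical flags (male sterility, male
    inviability, homozygous inviability) from the crossing-assay definitions.
    Without a control only categorical and chi-squared flags are emitted and
    ``statistical_flags_evaluated`` is False.
    """
    expectations = scheme_expectations(scheme)
    call = HICall(strain=record.strain, scheme=scheme)
    pooled = record.pooled()

    # --- categorical flags -------------------------------------------------
    if record.male_cross_progeny is not None:
        reciprocal_ok = (record.reciprocal_cross_progeny or 0) > 0
        call.male_sterile = record.male_cross_progeny == 0 and reciprocal_ok
        if record.male_cross_progeny == 0 and not reciprocal_ok:
            call.warnings.append(
                "no progeny in either cross direction: male sterility not assessable"
            )

    if record.linkage == ce.X_LINKED and pooled.progeny > 0:
        call.male_inviable = pooled.males_gfp == 0 and pooled.females_gfp > 0
    if call.male_inviable:
        call.male_sterile = False  # inviability pre-empts the sterility label

    attempts = attempts_to_homozygose
    if attempts is None:
        attempts = record.homozygosing_attempts_failed
    if attempts is not None:
        call.homozygous_inviable = attempts >= HOMOZYGOSING_ATTEMPT_THRESHOLD

    # --- segregation chi-squared flags ------------------------------------
    if pooled.progeny > 0:
        if record.zygosity == "homozygous":
            exp_male = expectations.get("male_fraction", Fraction(1, 2))
            call.sex_ratio_distorted = _chi2_result(
                (pooled.males, pooled.progeny - pooled.males),
                (float(exp_male), 1 - float(exp_male)),
            )
        else:
            exp_gfp = float(expectations["gfp_overall"])
            call.gfp_segregation_distorted = _chi2_result(
                (pooled.gfp, pooled.progeny - pooled.gfp), (exp_gfp, 1 - exp_gfp)
            )
            if "gfp_males" in expectations and pooled.males > 0:
                exp_gm = float(expectations["gfp_males"])
                call.sex_ratio_distorted = _chi2_result(
                    (pooled.males_gfp, pooled.males_nongfp), (exp_gm, 1 - exp_gm)
                )

    # --- control-based statistical flags -----------------------------------
    if control is None:
        call.statistical_flags_evaluated = False
        call.warnings.append("no control strain: Emb/Lva/fertility flags unevaluated")
        return call

    ctrl_name = control.strain or "control"

    def contrast(values: Sequence[float], ctrl_values: Sequence[float]) -> TestResult:
        groups: dict[str, Sequence[float]] = {record.strain: values, ctrl_name: ctrl_values}
        if all_groups:
            for k, v in all_groups.items():
                groups.setdefault(k, v)
        _, pairwise = compare_to_control(groups, ctrl_name)
        return pairwise[record.strain]

    emb_reps, emb_pooled = emb_rate(record)
    ctrl_emb_reps, ctrl_emb_pooled = emb_rate(control)
    call.emb_test = contrast(emb_reps, ctrl_emb_reps)
    if np.mean(emb_reps) > np.mean(ctrl_emb_reps):
        call.emb_elevated = call.emb_test
    if record.zygosity in ("heterozygous", "hemizygous"):
        call.dominant_emb = dominance_call(emb_pooled, ctrl_emb_pooled)

    lva_reps, lva_pooled = lva_rate(record)
    ctrl_lva_reps, ctrl_lva_pooled = lva_rate(control)
    call.lva_test = contrast(lva_reps, ctrl_lva_reps)
    if np.mean(lva_reps) > np.mean(ctrl_lva_reps):
        call.lva_elevated = call.lva_test
    if record.zygosity in ("heterozygous", "hemizygous"):
        call.dominant_lva = dominance_call(lva_pooled, ctrl_lva_pooled)

    if record.brood_sizes and control.brood_sizes:
        call.fertility_test = contrast(
            [float(b) for b in record.brood_sizes],
            [float(b) for b in control.brood_sizes],
        )
        if np.mean(record.brood_sizes) < np.mean(control.brood_sizes):
            call.fertility_reduced = call.fertility_test
        else:
            call.fertility_elevated = call.fertility_test

    # Invariant: a dominant call presupposes a significantly elevated rate.
    call.dominant_emb = call.dominant_emb and _sig(call.emb_elevated)
    call.dominant_lva = call.dominant_lva and _sig(call.lva_elevated)

    return call


def _sig(result: TestResult | None) -> bool:
    return result is not None and result.significant


def _chi2_result(observed: tuple[int, ...], expected: tuple[float, ...]) -> TestResult:
    x2, _, p = chi_squared_ratio(observed, expected)
    return TestResult(statistic=x2, p=p, test="chi-squared", expectation=expected)
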