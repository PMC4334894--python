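"""Exact Mendelian expectations for the GFP-marked crossing schemes.

Every statistical test in the pipeline compares observed progeny ratios to
these engine-derived null expectations.
"""

from himap import cross_engine as ce

auto = ce.LocusSpec(ce.AUTOSOMAL)
xl = ce.LocusSpec(ce.X_LINKED)

# Autosomal G/+ x G/+ cross, all classes viable.
dist = ce.expected_progeny(
    ce.parse_genotype("G/+", ce.FEMALE), ce.parse_genotype("G/+", ce.MALE), auto
)
print("autosomal het x het:")
print(f"  GFP-expressing progeny overall: {float(ce.expected_fraction(dist, ce.gfp)):.1%}")
print(f"  GFP among males:                {float(ce.expected_fraction(dist, ce.gfp, given=ce.is_male)):.1%}")
print(f"  P(male and homozygous G/G):     {float(ce.expected_fraction(dist, lambda c: c.gfp and c.homozygous and c.sex == ce.MALE, pre_selection=True)):.1%}")

# X-linked carrier female x wild-type XO male.
x_mom = ce.parse_genotype("G/+", ce.FEMALE, ce.X_LINKED)
x_dad = ce.parse_genotype("+/O", ce.MALE, ce.X_LINKED)
dist = ce.expected_progeny(x_mom, x_dad, xl)
print("X-linked carrier female x wild male (GFP males viable):")
print(f"  GFP among males:                {float(ce.expected_fraction(dist, ce.gfp, given=ce.is_male)):.1%}")

# Same cross with fully inviable GFP hemizygous males.
model = ce.ViabilityFertilityModel(survival={("G/O", ce.MALE): 0})
dist = ce.expected_progeny(x_mom, x_dad, xl, model)
print("same cross, GFP hemizygous males inviable:")
print(f"  GFP among survivors:            {float(ce.expected_fraction(dist, ce.gfp)):.1%}")

# Homozygosing: chance a random GFP pair from the F1 breeds true.
p = ce.homozygosing_success_probability(
    ce.parse_genotype("G/+", ce.FEMALE), ce.parse_genotype("G/+", ce.MALE), auto
)
print(f"double-homozygote plate probability (het x het F1): {p} (~1 plate in 9)")
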