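"""Refining HI loci by contrasting overlapping introgressions.

An inviable introgression extending to 15.11 Mb against a sterile one
ending at 14.62 Mb localises a male-viability locus to their difference;
a nested pair with inverted severity flags a candidate suppressor.
"""

from himap.genome_core import GenomicInterval
from himap.locus_refinement import (
    MALE_INVIABLE,
    MALE_STERILE,
    AnnotatedIntrogression,
    detect_suppressor,
    refine_interval,
)

a = AnnotatedIntrogression(
    "inviable-line", GenomicInterval("X", 14_000_000, 15_110_000), MALE_INVIABLE
)
b = AnnotatedIntrogression(
    "sterile-line", GenomicInterval("X", 14_000_000, 14_620_000), MALE_STERILE
)
for cand in refine_interval(a, b):
    print(f"candidate {cand.locus_class} locus: "
          f"{cand.interval.start/1e6:.2f}-{cand.interval.end/1e6:.2f} Mb "
          f"({cand.interval.length_mb} Mb)")
print("the extra severity of the inviable line must come from the region")
print("it alone carries: a ~0.49 Mb interval required for male viability.")

# Suppressor inference: a nested introgression far more severe than the
# larger one containing it (4.9% vs 51.1% GFP-expressing males).
sub = AnnotatedIntrogression(
    "nested", GenomicInterval("X", 18_000_000, 20_340_000), MALE_STERILE, severity_metric=4.9
)
sup = AnnotatedIntrogression(
    "containing", GenomicInterval("X", 15_500_000, 20_750_000), MALE_STERILE, severity_metric=51.1
)
for region in detect_suppressor(sub, sup):
    print(f"candidate suppressor region: "
          f"{region.start/1e6:.2f}-{region.end/1e6:.2f} Mb")
print("a suppressor of male inviability plausibly lies inside the larger")
print("introgression but outside the nested one.")
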