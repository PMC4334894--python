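"""Introgression boundary calling from species-specific PCR marker calls.

A simulated donor segment is genotyped with an ordered marker panel; the
caller reports the minimal (inner) and maximal (outer) intervals consistent
with the calls, and flags a deliberately relocated marker as a candidate
assembly error.
"""

from himap import synthetic_data as sd
from himap.genome_core import CB4, GenomicInterval
from himap.marker_genotyping import call_boundaries

truth = GenomicInterval("X", 8_000_000, 15_000_000)
panel = sd.uniform_panel("X", 20)

# Plant an assembly error: one marker inside the segment actually maps
# elsewhere in the genome, so it fails to amplify despite its neighbours.
inside = [m for m in panel.on("X") if truth.contains_position(m.midpoint)]
victim = inside[len(inside) // 2]
matrix = sd.simulate_genotype_matrix(
    truth, panel, assembly_errors=[sd.AssemblyErrorSpec(victim.name)], seed=0
)

pairs = matrix.calls_for("sim", "X")
call = call_boundaries([c for _, c in pairs], [m for m, _ in pairs], CB4, strain="sim")

print(f"true segment:   {truth.start/1e6:.2f}-{truth.end/1e6:.2f} Mb")
print(f"inner interval: {call.inner.start/1e6:.2f}-{call.inner.end/1e6:.2f} Mb (outermost amplifying markers)")
print(f"outer interval: {call.outer.start/1e6:.2f}-{call.outer.end/1e6:.2f} Mb (reported size {call.outer.length_mb} Mb)")
print(f"exception markers (assembly-error candidates): {call.exception_markers}")
print("inner lies within the truth, the truth within the outer interval;")
print("the relocated marker was excluded from boundary computation.")
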