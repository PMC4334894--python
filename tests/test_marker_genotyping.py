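"""PCR boundary calling, exception flagging and callset concordance."""

import numpy as np
import pytest

from himap import synthetic_data as sd
from himap.genome_core import CB4, GenomicInterval
from himap.marker_genotyping import (
    NEG,
    POS,
    NA,
    GenotypeMatrix,
    Marker,
    MarkerPanel,
    NoIntrogressionError,
    call_boundaries,
    compare_callsets,
    flag_assembly_errors,
)

MB = 1_000_000


def _markers(panel):
    return panel.on("I")


class TestCallBoundaries:
    def test_simple_pos_run(self, mb_panel, cb4):
        calls = [NEG, NEG, POS, POS, POS, NEG, NEG]
        ic = call_boundaries(calls, _markers(mb_panel), cb4)
        assert ic.inner == GenomicInterval("I", 3 * MB, 5 * MB)
        assert ic.outer == GenomicInterval("I", 2 * MB, 6 * MB)
        assert ic.size_bp == 4 * MB
        assert ic.exception_markers == []

    def test_interior_neg_exception_bridged(self, mb_panel, cb4):
        calls = [NEG, POS, POS, NEG, POS, POS, NEG]
        ic = call_boundaries(calls, _markers(mb_panel), cb4)
        assert ic.exception_markers == ["I-4"]
        assert ic.inner == GenomicInterval("I", 2 * MB, 6 * MB)
        assert ic.outer == GenomicInterval("I", 1 * MB, 7 * MB)

    def test_all_neg_raises(self, mb_panel, cb4):
        with pytest.raises(NoIntrogressionError):
            call_boundaries([NEG] * 7, _markers(mb_panel), cb4)

    def test_run_reaching_panel_edge_extends_to_chromosome_end(self, mb_panel, cb4):
        calls = [POS, POS, POS, NEG, NEG, NEG, NEG]
        ic = call_boundaries(calls, _markers(mb_panel), cb4)
        assert ic.outer.start == 0
        assert ic.outer.end == 4 * MB

    def test_na_calls_are_transparent(self, mb_panel, cb4):
        calls = [NEG, NA, POS, NA, POS, NEG, NEG]
        ic = call_boundaries(calls, _markers(mb_panel), cb4)
        assert ic.inner == GenomicInterval("I", 3 * MB, 5 * MB)
        assert ic.outer == GenomicInterval("I", 1 * MB, 6 * MB)

    def test_two_adjacent_contradictions_become_second_segment(self, mb_panel, cb4):
        calls = [POS, POS, NEG, NEG, POS, POS, NEG]
        ic = call_boundaries(calls, _markers(mb_panel), cb4)
        assert ic.exception_markers == []
        assert len(ic.extra_segments) == 1
        assert ic.warnings  # disjoint POS runs warned

    def test_single_pos_marker_uses_amplicon_span_for_inner(self, mb_panel, cb4):
        # A lone POS at the panel edge has no flanking consensus on both
        # sides, so it is a genuine (terminal) single-marker introgression.
        calls = [POS, NEG, NEG, NEG, NEG, NEG, NEG]
        ic = call_boundaries(calls, _markers(mb_panel), cb4)
        assert ic.inner == GenomicInterval("I", 1 * MB - 200, 1 * MB + 200)
        assert ic.outer == GenomicInterval("I", 0, 2 * MB)


class TestAssemblyErrors:
    def test_neg_in_pos_run_flagged(self, mb_panel):
        calls = [POS, POS, POS, NEG, POS, POS, POS]
        assert flag_assembly_errors(calls, _markers(mb_panel)) == ["I-4"]

    def test_pos_in_neg_run_flagged_mirror(self, mb_panel):
        calls = [NEG, NEG, NEG, POS, NEG, NEG, NEG]
        assert flag_assembly_errors(calls, _markers(mb_panel)) == ["I-4"]

    def test_adjacent_pair_not_flagged(self, mb_panel):
        calls = [POS, POS, NEG, NEG, POS, POS, POS]
        assert flag_assembly_errors(calls, _markers(mb_panel)) == []

    def test_edge_consensus_falls_back_to_one(self, mb_panel):
        # flanking run of length 1 at the panel edge still vouches
        calls = [POS, NEG, POS, POS, POS, POS, POS]
        assert flag_assembly_errors(calls, _markers(mb_panel)) == ["I-2"]

    def test_planted_relocated_marker_recovered(self):
        panel = sd.uniform_panel("X", 15)
        truth = GenomicInterval("X", 5 * MB, 15 * MB)
        inside = [m for m in panel.on("X") if truth.contains_position(m.midpoint)]
        victim = inside[len(inside) // 2]
        gm = sd.simulate_genotype_matrix(
            truth, panel, assembly_errors=[sd.AssemblyErrorSpec(victim.name)], seed=0
        )
        pairs = gm.calls_for("sim", "X")
        flagged = flag_assembly_errors([c for _, c in pairs], [m for m, _ in pairs])
        assert flagged == [victim.name]


class TestRoundTrip:
    def test_inner_truth_outer_nesting_on_random_fixtures(self):
        """No-error simulation: inner ⊆ truth ⊆ outer whenever >=2 markers covered."""
        rng = np.random.default_rng(7)
        n = 0
        while n < 200:
            chromosome = ["I", "II", "III", "IV", "V", "X"][int(rng.integers(6))]
            length = CB4.length(chromosome)
            panel = sd.uniform_panel(chromosome, int(rng.integers(5, 25)))
            a, b = sorted(int(x) for x in rng.integers(0, length, size=2))
            if b - a < 2:
                continue
            truth = GenomicInterval(chromosome, a, b)
            covered = sum(
                truth.contains_position(m.midpoint) for m in panel.on(chromosome)
            )
            if covered < 2:
                continue
            n += 1
            gm = sd.simulate_genotype_matrix(truth, panel, seed=int(rng.integers(2**31)))
            pairs = gm.calls_for("sim", chromosome)
            ic = call_boundaries([c for _, c in pairs], [m for m, _ in pairs], CB4)
            assert truth.contains(ic.inner)
            assert ic.outer.contains(truth)

    def test_outer_size_monotone_in_marker_density(self):
        """Denser nested panels never widen the outer interval."""
        truth = GenomicInterval("X", 8 * MB, 13 * MB)
        prev_size = None
        for n_markers in (6, 12, 24, 48):
            panel = sd.uniform_panel("X", n_markers)
            gm = sd.simulate_genotype_matrix(truth, panel, seed=1)
            pairs = gm.calls_for("sim", "X")
            ic = call_boundaries([c for _, c in pairs], [m for m, _ in pairs], CB4)
            if prev_size is not None:
                assert ic.size_bp <= prev_size + 1  # midpoint jitter tolerance
            prev_size = ic.size_bp


class TestConcordance:
    def test_identical_intervals(self):
        iv = GenomicInterval("X", 0, 7_100_000)
        ic = _call_for(iv)
        rep = compare_callsets(ic, iv)
        assert rep.jaccard == 1.0
        assert (rep.left_offset_bp, rep.right_offset_bp) == (0, 0)

    def test_pcr_wider_than_reference(self):
        """PCR interval 0–7.75 Mb vs depth-based 0–7.10 Mb: J = 7.10/7.75."""
        ic = _call_for(GenomicInterval("X", 0, 7_750_000))
        rep = compare_callsets(ic, GenomicInterval("X", 0, 7_100_000))
        assert rep.jaccard == pytest.approx(7.10 / 7.75)
        assert rep.right_offset_bp == 650_000

    def test_disjoint_and_cross_chromosome(self):
        ic = _call_for(GenomicInterval("X", 0, 1 * MB))
        assert compare_callsets(ic, GenomicInterval("X", 2 * MB, 3 * MB)).jaccard == 0.0
        cross = compare_callsets(ic, GenomicInterval("I", 0, 1 * MB))
        assert cross.jaccard == 0.0 and not cross.same_chromosome and cross.warnings


def _call_for(outer):
    from himap.marker_genotyping import IntrogressionCall

    inner = GenomicInterval(outer.chromosome, outer.start + 1, outer.end - 1)
    return IntrogressionCall(
        strain="s", chromosome=outer.chromosome, inner=inner, outer=outer
    )


class TestGenotypeMatrix:
    def test_invalid_call_rejected(self, mb_panel):
        with pytest.raises(ValueError, match="invalid call"):
            GenotypeMatrix({"s1": {"I-1": "±"}}, mb_panel)

    def test_unknown_marker_rejected(self, mb_panel):
        with pytest.raises(ValueError, match="unknown marker"):
            GenotypeMatrix({"s1": {"Z-9": POS}}, mb_panel)
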