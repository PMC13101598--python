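"""Motif location, orientation handling and sample/control alignment."""

import numpy as np
import pytest

from editquant import ControlSequence, MotifSpec, reverse_complement
from editquant.alignment import (
    AmbiguousMotifError,
    ControlMismatchError,
    MotifNotFoundError,
    align_sample_control,
    control_bases_at_motif,
    locate_motif,
)

from conftest import DNMT3A_GUIDE, GZMA_GUIDE, embed_motif


def random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


class TestMotifSpec:
    def test_wt_must_differ_from_edit(self):
        with pytest.raises(ValueError, match="differ"):
            MotifSpec(GZMA_GUIDE, True, "A", "A")

    def test_wt_must_occur_in_oriented_motif(self):
        # CCCCACCCCACCCCACCCCA has no T forward; as revcomp it has no A
        with pytest.raises(ValueError, match="contains no"):
            MotifSpec("CCCCACCCCACCCCACCCCA", True, "T", "C")

    def test_oriented_motif_reverse(self):
        spec = MotifSpec(GZMA_GUIDE, False, "T", "C")
        assert spec.oriented_motif == reverse_complement(GZMA_GUIDE)


class TestLocateMotif:
    def test_exact_forward(self):
        spec = MotifSpec(GZMA_GUIDE, True, "A", "G")
        loc = locate_motif(GZMA_GUIDE, spec)
        assert loc.sample_interval == (0, 20)
        assert loc.protospacer_of_offset[0] == 1
        assert loc.call_index(1) == 0

    def test_reverse_complement_numbering(self):
        """With motif_fwd false, position 20 maps to the leftmost call."""
        template, offset = embed_motif(reverse_complement(DNMT3A_GUIDE), seed=11)
        spec = MotifSpec(DNMT3A_GUIDE, False, "T", "C")
        loc = locate_motif(template, spec)
        assert loc.sample_interval == (offset, offset + 20)
        assert loc.protospacer_of_offset[0] == 20
        assert loc.call_index(20) == offset
        # brute-force check of the full coordinate map
        for k in range(20):
            assert loc.protospacer_of_offset[k] == 20 - k

    def test_tolerates_mismatches(self):
        template, offset = embed_motif(GZMA_GUIDE, seed=12)
        mutated = list(template)
        mutated[offset + 4] = "G"  # protospacer position 5 fully edited
        spec = MotifSpec(GZMA_GUIDE, True, "A", "G")
        loc = locate_motif("".join(mutated), spec)
        assert loc.sample_interval == (offset, offset + 20)
        assert loc.n_mismatches == 1

    def test_absent_motif_raises(self):
        spec = MotifSpec(GZMA_GUIDE, True, "A", "G")
        with pytest.raises(MotifNotFoundError, match=GZMA_GUIDE):
            locate_motif(random_seq(13, 200), spec)

    def test_duplicate_locus_ambiguous(self):
        template = random_seq(14, 40) + GZMA_GUIDE + random_seq(15, 30) + \
            GZMA_GUIDE + random_seq(16, 40)
        spec = MotifSpec(GZMA_GUIDE, True, "A", "G")
        with pytest.raises(AmbiguousMotifError, match="2 loci"):
            locate_motif(template, spec)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exact_substring_search(self, seed):
        """On clean fixtures the hit equals str.find (oracle equivalence)."""
        template, offset = embed_motif(GZMA_GUIDE, seed=seed)
        spec = MotifSpec(GZMA_GUIDE, True, "A", "G")
        loc = locate_motif(template, spec)
        assert loc.sample_interval[0] == template.find(GZMA_GUIDE) == offset
        assert loc.n_mismatches == 0


class TestAlignSampleControl:
    def test_identical_sequences(self):
        seq = random_seq(20, 150)
        aln = align_sample_control(seq, ControlSequence(seq))
        assert aln.control_orientation == "forward"
        assert aln.identity == 1.0
        assert all(aln.pairs[i] == i for i in range(len(seq)))

    def test_reverse_complement_control(self):
        seq = random_seq(21, 150)
        ctrl = ControlSequence(reverse_complement(seq))
        aln = align_sample_control(seq, ctrl)
        assert aln.control_orientation == "reverse-complement"
        assert aln.identity == 1.0
        # oriented control is the read-strand sequence
        assert aln.oriented_control == seq

    def test_truncated_control_offsets(self):
        seq = random_seq(22, 200)
        ctrl = ControlSequence(seq[50:])
        aln = align_sample_control(seq, ctrl)
        assert aln.control_orientation == "forward"
        for i in range(50, 200):
            assert aln.pairs[i] == i - 50

    def test_unrelated_control_rejected(self):
        with pytest.raises(ControlMismatchError, match="does not match"):
            align_sample_control(random_seq(23, 100), ControlSequence(random_seq(24, 100)))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            align_sample_control("ACGT", ControlSequence("ACGTACGTACGTACGTACGTACGT"))


class TestControlBasesAtMotif:
    def test_identical_control_matches_sample(self):
        template, offset = embed_motif(GZMA_GUIDE, seed=30)
        spec = MotifSpec(GZMA_GUIDE, True, "A", "G")
        loc = locate_motif(template, spec)
        ctrl = ControlSequence(template)
        aln = align_sample_control(template, ctrl)
        bases = control_bases_at_motif(loc, aln, ctrl)
        for pos, base in bases.items():
            assert base == GZMA_GUIDE[pos - 1]

    def test_edited_sample_keeps_wt_control_base(self):
        template, offset = embed_motif(GZMA_GUIDE, seed=31)
        mutated = list(template)
        mutated[offset + 4] = "G"  # fully edited at protospacer position 5
        sample = "".join(mutated)
        spec = MotifSpec(GZMA_GUIDE, True, "A", "G")
        loc = locate_motif(sample, spec)
        ctrl = ControlSequence(template)
        aln = align_sample_control(sample, ctrl)
        bases = control_bases_at_motif(loc, aln, ctrl)
        assert bases[5] == "A"
        assert sample[loc.call_index(5)] == "G"

    def test_control_missing_motif_is_unaligned(self):
        template, offset = embed_motif(GZMA_GUIDE, seed=32, left=100, right=40)
        ctrl = ControlSequence(template[:60])  # ends before the motif
        spec = MotifSpec(GZMA_GUIDE, True, "A", "G")
        loc = locate_motif(template, spec)
        aln = align_sample_control(template, ctrl)
        bases = control_bases_at_motif(loc, aln, ctrl)
        assert set(bases.values()) == {"unaligned"}
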