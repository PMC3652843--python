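"""Composite-motif scanner semantics: exact cores, bounded spacer, both strands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foxe1_targets import (
    CompositeMotifConfig,
    annotate_hit,
    find_core,
    revcomp,
    scan_sequence,
    select_representative,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=200)


def brute_force_scan(seq: str, config: CompositeMotifConfig):
    """Independent oracle: enumerate all core-offset pairs on both strands."""
    expected = set()
    up, down = config.upstream_core, config.downstream_core
    for u in range(len(seq)):
        for d in range(len(seq)):
            if seq[u : u + len(up)] == up and seq[d : d + len(down)] == down:
                spacer = d - (u + len(up))
                if config.min_spacer <= spacer <= config.max_spacer:
                    expected.add((1, u, d, spacer))
    rc_up, rc_down = revcomp(up), revcomp(down)
    for d in range(len(seq)):
        for u in range(len(seq)):
            if seq[d : d + len(rc_down)] == rc_down and seq[u : u + len(rc_up)] == rc_up:
                spacer = u - (d + len(rc_down))
                if config.min_spacer <= spacer <= config.max_spacer:
                    expected.add((-1, u, d, spacer))
    return expected


def as_tuples(hits):
    return {
        (h.strand, h.upstream_core_start, h.downstream_core_start, h.spacer_len)
        for h in hits
    }


class TestRevcomp:
    def test_foxe1_core_maps_to_its_minus_strand_form(self):
        assert revcomp("AAACA") == "TGTTT"
        assert revcomp("TTGG") == "CCAA"

    def test_empty(self):
        assert revcomp("") == ""

    def test_n_maps_to_n(self):
        assert revcomp("ANT") == "ANT"

    @given(dna_n)
    @settings(derandomize=True)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestFindCore:
    def test_overlapping_occurrences(self):
        assert find_core("AAACAAACA", "AAACA") == [0, 4]

    def test_no_match(self):
        assert find_core("GGGG", "TTGG") == []

    def test_n_never_matches_core(self):
        assert find_core("TTNG" * 5, "TTGG") == []

    def test_empty_core_rejected(self):
        with pytest.raises(ValueError):
            find_core("ACGT", "")

    @given(dna, st.text(alphabet="ACGT", min_size=1, max_size=5))
    @settings(derandomize=True)
    def test_matches_naive_sliding_window(self, seq, core):
        naive = [i for i in range(len(seq)) if seq[i : i + len(core)] == core]
        assert find_core(seq, core) == naive


class TestScanSequence:
    def test_plus_strand_worked_example(self, motif_config):
        # published Hspa5 promoter fragment: one hit, plus strand, 10 bp spacer
        hits = scan_sequence("GACTTGGCAGAAAAGAAAAACACTG", motif_config, "Hspa5")
        assert [(h.strand, h.spacer_len) for h in hits] == [(1, 10)]

    def test_minus_strand_worked_example(self, motif_config):
        # published Casp4 fragment: FoxE1 core appears as TGTTT, NF1 core as CCAA
        hits = scan_sequence("TTGTGTTTGCTTGTTCCCAAGAG", motif_config, "Casp4")
        assert [(h.strand, h.spacer_len) for h in hits] == [(-1, 8)]

    def test_spacer_below_window_excluded(self, motif_config):
        assert scan_sequence("TTGG" + "A" * 4 + "AACA", motif_config) == []
        # spacer of exactly min_spacer is accepted
        assert [h.spacer_len for h in scan_sequence("TTGG" + "C" * 5 + "AAACA", motif_config)] == [5]

    def test_short_sequence_returns_empty(self, motif_config):
        assert scan_sequence("TTGGAAACA", motif_config) == []

    def test_opposite_core_order_is_not_a_hit(self, motif_config):
        assert scan_sequence("AAACA" + "G" * 10 + "TTGG", motif_config) == []

    def test_n_in_spacer_permitted_but_not_in_core(self, motif_config):
        assert len(scan_sequence("TTGG" + "N" * 8 + "AAACA", motif_config)) == 1
        assert scan_sequence("TTGN" + "C" * 8 + "AAACA", motif_config) == []

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=300))
    @settings(derandomize=True, max_examples=200)
    def test_oracle_equivalence(self, seq):
        config = CompositeMotifConfig()
        assert as_tuples(scan_sequence(seq, config)) == brute_force_scan(seq, config)

    def test_oracle_equivalence_on_seeded_random_sequences(self, motif_config):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            assert as_tuples(scan_sequence(seq, motif_config)) == brute_force_scan(
                seq, motif_config
            )

    def test_strand_symmetry(self, motif_config):
        rng = np.random.default_rng(11)
        span = lambda h: h.span(motif_config)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=250))
            fwd = scan_sequence(seq, motif_config)
            rev = scan_sequence(revcomp(seq), motif_config)
            mirrored = {
                (-h.strand, len(seq) - h.leftmost - span(h), h.spacer_len) for h in fwd
            }
            assert {(h.strand, h.leftmost, h.spacer_len) for h in rev} == mirrored

    def test_widening_spacer_window_never_removes_hits(self, motif_config):
        rng = np.random.default_rng(5)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            narrow = as_tuples(scan_sequence(seq, motif_config))
            wide_cfg = CompositeMotifConfig(max_spacer=motif_config.max_spacer + 10)
            wide = as_tuples(scan_sequence(seq, wide_cfg))
            assert narrow <= wide


class TestAnnotateHit:
    def test_plus_strand_display_matches_published_cell(self, motif_config):
        seq = "GACTTGGCAGAAAAGAAAAACACTG"
        (hit,) = scan_sequence(seq, motif_config)
        assert annotate_hit(hit, seq, motif_config) == "GACTTGG-CAGAAAAGAA-AAACACTG"

    def test_minus_strand_display_matches_published_cell(self, motif_config):
        seq = "TTGTGTTTGCTTGTTCCCAAGAG"
        (hit,) = scan_sequence(seq, motif_config)
        assert annotate_hit(hit, seq, motif_config) == "TTGTGTTT-GCTTGTTC-CCAAGAG"

    def test_left_flank_truncated_at_sequence_start(self, motif_config):
        seq = "TTGG" + "C" * 6 + "AAACA" + "GGG"
        (hit,) = scan_sequence(seq, motif_config)
        assert annotate_hit(hit, seq, motif_config) == "TTGG-CCCCCC-AAACAGGG"

    def test_mismatched_sequence_rejected(self, motif_config):
        seq = "TTGG" + "C" * 6 + "AAACA"
        (hit,) = scan_sequence(seq, motif_config)
        with pytest.raises(ValueError):
            annotate_hit(hit, "T" * len(seq), motif_config)


class TestReferenceFragments:
    def test_every_reported_row_is_recovered(self, reference_hits, motif_config):
        """Each curated fragment yields a hit at the reported spacer and strand."""
        for row in reference_hits.itertuples(index=False):
            hits = scan_sequence(row.sequence, motif_config, source_id=row.gene)
            assert (row.spacer_len, row.strand) in {
                (h.spacer_len, h.strand) for h in hits
            }, row.gene

    def test_representative_selection_matches_reported_spacers(
        self, reference_hits, motif_config
    ):
        """The greedy one-per-NF1-core representative equals every printed row,
        including the A-rich Cdh1 promoter where two FoxE1 cores pair with one
        NF1 core."""
        for row in reference_hits.itertuples(index=False):
            hits = select_representative(
                scan_sequence(row.sequence, motif_config, source_id=row.gene)
            )
            assert [(h.spacer_len, h.strand) for h in hits] == [
                (row.spacer_len, row.strand)
            ], row.gene
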