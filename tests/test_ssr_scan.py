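"""SSR scanner vs brute-force oracle, context calls, cross-species loci."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plastidkit._seq import revcomp
from plastidkit.core_io import AlignmentMatrix, SeqRecord
from plastidkit.ssr_scan import (
    DEFAULT_MIN_UNITS,
    SSRHit,
    SSRParams,
    contextualize_ssrs,
    find_ssrs,
    ssr_loci,
    ssr_summary,
)

from conftest import random_dna
from oracles import ssr_oracle


def _hit_tuples(hits):
    return {(h.motif, h.period, h.units, h.start, h.end) for h in hits}


class TestScanner:
    # tandem-free flanks so only the embedded tract can qualify
    LEFT = "GCTAGGATCCGGTACGGCTC"
    RIGHT = "GTCCTAGCGTTGACGGATGC"

    def test_mononucleotide_at_threshold(self):
        rec = SeqRecord("x", self.LEFT + "A" * 10 + self.RIGHT)
        (hit,) = find_ssrs(rec)
        assert (hit.motif, hit.units, hit.start) == ("A", 10, 20)
        assert hit.tract_length == hit.period * hit.units

    def test_below_threshold_ignored(self):
        rec = SeqRecord("x", self.LEFT + "A" * 9 + self.RIGHT)
        assert find_ssrs(rec) == []

    def test_gap_characters_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            find_ssrs(SeqRecord("x", "ACGT-ACGT"))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        s = random_dna(rng, 2500, p=(0.4, 0.1, 0.1, 0.4))
        assert _hit_tuples(find_ssrs(SeqRecord("x", s))) == ssr_oracle(s, DEFAULT_MIN_UNITS)

    @given(st.text(alphabet="AT", min_size=20, max_size=200))
    def test_matches_oracle_on_adversarial_two_letter_text(self, s):
        assert _hit_tuples(find_ssrs(SeqRecord("x", s))) == ssr_oracle(s, DEFAULT_MIN_UNITS)

    def test_reported_period_is_minimal(self, rng):
        s = random_dna(rng, 4000, p=(0.4, 0.1, 0.1, 0.4)) + "AT" * 10 + "ACG" * 8
        for h in find_ssrs(SeqRecord("x", s)):
            for d in range(1, h.period):
                if h.period % d == 0:
                    assert h.motif != h.motif[:d] * (h.period // d)

    def test_strand_symmetric_counts_per_period(self, rng):
        s = random_dna(rng, 3000, p=(0.4, 0.1, 0.1, 0.4)) + "A" * 11 + "GA" * 6
        fwd = find_ssrs(SeqRecord("x", s))
        rev = find_ssrs(SeqRecord("x", revcomp(s)))
        for p in range(1, 7):
            assert sum(h.period == p for h in fwd) == sum(h.period == p for h in rev)

    def test_counts_monotone_in_thresholds(self, rng):
        s = random_dna(rng, 3000, p=(0.4, 0.1, 0.1, 0.4))
        base = len(find_ssrs(SeqRecord("x", s)))
        stricter = SSRParams({p: u + 1 for p, u in DEFAULT_MIN_UNITS.items()})
        assert len(find_ssrs(SeqRecord("x", s), stricter)) <= base


class TestContext:
    def test_planted_contexts_match_generator_truth(self, small_bundle):
        hits = find_ssrs(small_bundle.ancestor)
        hits = contextualize_ssrs(hits, small_bundle.features, small_bundle.partition)
        by_start = {h.start: h for h in hits}
        # planted: intron tract inside rps16, CDS tract inside ycf4, IGS elsewhere
        planted = {s.start: s for s in small_bundle.planted_ssrs}
        assert by_start[610].context == "intron"
        assert by_start[610].gene == "rps16"
        assert by_start[1650].context == "CDS"
        assert by_start[1650].gene == "ycf4"
        for start in (720, 740, 1400):
            assert by_start[start].context == "IGS"
            assert by_start[start].region == "LSC"
        assert planted.keys() <= by_start.keys()

    def test_junction_spanning_region_label(self, small_bundle):
        part = small_bundle.partition
        hit = SSRHit("A", 10, 10, part.lsc[1] - 5, part.lsc[1] + 5)
        (out,) = contextualize_ssrs([hit], [], part)
        assert out.region == "junction-spanning"


class TestLoci:
    def _aln(self, rows):
        return AlignmentMatrix.from_strings([f"s{i}" for i in range(len(rows))], rows)

    def test_identical_descriptors_not_polymorphic(self):
        rows = ["C" * 5 + "A" * 10 + "C" * 5] * 3
        aln = self._aln(rows)
        hits = {f"s{i}": [SSRHit("A", 1, 10, 5, 15)] for i in range(3)}
        (locus,) = ssr_loci(aln, hits)
        assert locus.polymorphic is False

    def test_unit_count_difference_is_polymorphic(self):
        rows = ["C" * 5 + "A" * 12 + "C" * 5, "C" * 5 + "A" * 10 + "GC" + "C" * 5]
        aln = self._aln(rows)
        hits = {"s0": [SSRHit("A", 1, 12, 5, 17)], "s1": [SSRHit("A", 1, 10, 5, 15)]}
        (locus,) = ssr_loci(aln, hits)
        assert locus.polymorphic is True
        assert locus.descriptors == {"s0": ("A", 12), "s1": ("A", 10)}

    def test_projection_through_gapped_rows(self):
        rows = ["AA--" + "A" * 10 + "CC", "AAGG" + "A" * 10 + "CC"]
        aln = self._aln(rows)
        # s0's tract starts at ungapped position 2 -> column 4
        hits = {"s0": [SSRHit("A", 1, 10, 2, 12)], "s1": [SSRHit("A", 1, 10, 4, 14)]}
        (locus,) = ssr_loci(aln, hits)
        assert locus.columns == (4, 14)
        assert locus.polymorphic is False

    def test_unknown_species_rejected(self):
        aln = self._aln(["ACGT" * 5, "ACGT" * 5])
        with pytest.raises(KeyError, match="ghost"):
            ssr_loci(aln, {"ghost": [SSRHit("A", 1, 10, 0, 10)]})

    def test_planted_locus_and_polymorphism_counts(self, small_bundle):
        per_sp = {
            spid: find_ssrs(rec) for spid, rec in small_bundle.species.items()
        }
        loci = ssr_loci(small_bundle.alignment, per_sp)
        planted_poly = sum(
            1 for s in small_bundle.planted_ssrs if s.species_units
        )
        starts = {l.columns[0] for l in loci}
        assert {s.start for s in small_bundle.planted_ssrs} <= starts
        assert sum(l.polymorphic for l in loci) == planted_poly


class TestSummary:
    def test_empty_input_zero_row(self):
        table = ssr_summary({"g1": []})
        row = next(r for r in table.rows if r[0] == "g1")
        assert row[1:] == [0] * (len(table.header) - 1)

    def test_planted_period_counts(self, small_bundle):
        hits = find_ssrs(small_bundle.ancestor)
        hits = contextualize_ssrs(hits, small_bundle.features, small_bundle.partition)
        table = ssr_summary({"anc": hits})
        row = next(r for r in table.rows if r[0] == "anc")
        idx = {h: i for i, h in enumerate(table.header)}
        # at least the planted tract of each period class is counted
        for col, minimum in [("mono", 1), ("di", 1), ("tri", 1), ("tetra", 1), ("penta", 1)]:
            assert row[idx[col]] >= minimum
        assert row[idx["total"]] == len(hits)
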