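"""Library design: site filtering, tiling, variant generation, oligos."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosdisplay.library_design import (
    ECOLI_RANKED_CODONS,
    PHOSPHOMIMETIC,
    SMAI_SITE,
    WILD_TYPE,
    DesignError,
    DisorderedRegion,
    PeptideTile,
    PhosphositeRecord,
    compute_library_stats,
    filter_phosphosites,
    generate_variants,
    reverse_translate,
    tile_region,
    translate,
)


def site(ac="P1", pos=5, res="S", loc=0.9, func=0.6, **kw):
    return PhosphositeRecord(ac, pos, res, loc, func, **kw)


class TestFilterPhosphosites:
    def test_passing_site_kept_unrescued(self):
        kept = filter_phosphosites([site(loc=0.80, func=0.50)])
        assert len(kept) == 1 and not kept[0].rescued

    def test_best_site_rescued_when_none_pass(self):
        sites = [
            site(pos=1, loc=0.9, func=0.30),
            site(pos=2, loc=0.6, func=0.40),
        ]
        kept = filter_phosphosites(sites)
        assert len(kept) == 1
        assert kept[0].position == 2 and kept[0].functional_score == 0.40
        assert kept[0].rescued

    def test_failing_site_dropped_when_sibling_passes(self):
        # exhaustive check of the predicate on a toy 6-site table
        sites = [
            site("A", 1, loc=0.8, func=0.5),   # passes
            site("A", 2, loc=0.9, func=0.1),   # fails func
            site("B", 1, loc=0.74, func=0.9),  # fails loc
            site("B", 2, loc=0.75, func=0.4524),  # passes (inclusive cutoffs)
            site("C", 1, loc=0.5, func=0.2),   # fails both -> rescued (best)
            site("C", 2, loc=0.5, func=0.1),
        ]
        kept = filter_phosphosites(sites)
        by_key = {(s.protein_ac, s.position): s for s in kept}
        assert set(by_key) == {("A", 1), ("B", 2), ("C", 1)}
        assert not by_key[("A", 1)].rescued
        assert not by_key[("B", 2)].rescued
        assert by_key[("C", 1)].rescued

    def test_rescue_accession_keeps_all_sites(self):
        sites = [site("KPNA4", 1, loc=0.1, func=0.1), site("KPNA4", 2)]
        kept = filter_phosphosites(sites, rescue_accessions={"KPNA4"})
        assert len(kept) == 2
        flags = {s.position: s.rescued for s in kept}
        assert flags[1] is True and flags[2] is False

    def test_rescue_tie_breaks_to_lowest_position(self):
        sites = [site(pos=9, func=0.3, loc=0.2), site(pos=3, func=0.3, loc=0.2)]
        kept = filter_phosphosites(sites)
        assert [s.position for s in kept] == [3]

    def test_non_st_residue_rejected(self):
        with pytest.raises(DesignError, match="non-S/T"):
            filter_phosphosites([site(res="Y")])

    def test_score_out_of_range_is_input_error(self):
        with pytest.raises(ValueError):
            PhosphositeRecord("P1", 1, "S", 1.2, 0.5)

    def test_every_input_protein_contributes_output(self):
        # rescue guarantee over a randomized-ish table
        sites = [
            site(f"P{i}", p, loc=0.1 * (p % 10), func=0.05 * (p % 20))
            for i in range(8)
            for p in range(1, 5)
        ]
        kept = filter_phosphosites(sites)
        assert {s.protein_ac for s in kept} == {s.protein_ac for s in sites}
        for s in kept:
            if not s.rescued:
                assert s.localization_prob >= 0.75
                assert s.functional_score >= 0.4524


def brute_force_tiles(start, end, length, step):
    """Independent enumeration of expected tile coordinates."""
    if end - start + 1 < length:
        return [(start, end)]
    coords = []
    s = start
    while s + length - 1 <= end:
        coords.append((s, s + length - 1))
        s += step
    if coords[-1][1] < end:
        coords.append((end - length + 1, end))
    return coords


class TestTiling:
    PROTEOME = {"P1": "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"}  # 40 aa

    def test_exact_length_region_single_tile(self):
        tiles = tile_region(DisorderedRegion("P1", 1, 16), self.PROTEOME)
        assert [(t.start, t.end) for t in tiles] == [(1, 16)]
        assert tiles[0].sequence == self.PROTEOME["P1"][:16]

    def test_length_24_gives_three_tiles(self):
        tiles = tile_region(DisorderedRegion("P1", 1, 24), self.PROTEOME)
        assert [(t.start, t.end) for t in tiles] == [(1, 16), (5, 20), (9, 24)]

    def test_length_18_end_anchored(self):
        tiles = tile_region(DisorderedRegion("P1", 1, 18), self.PROTEOME)
        assert [(t.start, t.end) for t in tiles] == [(1, 16), (3, 18)]

    def test_short_region_single_short_tile(self):
        tiles = tile_region(DisorderedRegion("P1", 5, 10), self.PROTEOME)
        assert [(t.start, t.end) for t in tiles] == [(5, 10)]
        assert tiles[0].sequence == self.PROTEOME["P1"][4:10]

    def test_region_outside_protein_rejected(self):
        with pytest.raises(DesignError):
            tile_region(DisorderedRegion("P1", 30, 45), self.PROTEOME)

    @given(
        start=st.integers(1, 120),
        span=st.integers(0, 140),
        step=st.integers(1, 8),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_covers(self, start, span, step):
        end = start + span
        proteome = {"PX": "A" * 300}
        tiles = tile_region(DisorderedRegion("PX", start, end), proteome,
                            length=16, step=step)
        assert [(t.start, t.end) for t in tiles] == brute_force_tiles(
            start, end, 16, step
        )
        covered = set()
        for t in tiles:
            covered.update(range(t.start, t.end + 1))
            assert t.length <= 16
        assert covered == set(range(start, end + 1))


class TestGenerateVariants:
    def make_tile(self, seq="AAAASAAAATAAAAAA", start=1):
        return PeptideTile("P1", start, start + len(seq) - 1, seq)

    def test_single_site_gives_wt_and_pm(self):
        tile = self.make_tile()
        entries, uncovered = generate_variants([tile], [site("P1", 5, "S")])
        assert not uncovered
        assert {e.variant for e in entries} == {WILD_TYPE, PHOSPHOMIMETIC}
        wt, = (e for e in entries if e.variant == WILD_TYPE)
        pm, = (e for e in entries if e.variant == PHOSPHOMIMETIC)
        diffs = [i for i, (a, b) in enumerate(zip(wt.peptide_seq, pm.peptide_seq))
                 if a != b]
        assert diffs == [4]
        assert pm.peptide_seq[4] == "E" and wt.peptide_seq[4] == "S"

    def test_two_sites_same_tile_never_double_mutant(self):
        tile = self.make_tile()
        entries, _ = generate_variants(
            [tile], [site("P1", 5, "S"), site("P1", 10, "T")]
        )
        peptides = {e.peptide_seq for e in entries}
        assert len(entries) == 3  # shared wt + two single mutants
        assert tile.sequence in peptides
        for e in entries:
            n_mut = sum(a != b for a, b in zip(tile.sequence, e.peptide_seq))
            assert n_mut <= 1

    def test_site_in_three_tiles_gives_three_pairs(self):
        seq = "A" * 40
        seq = seq[:19] + "S" + seq[20:]
        proteome = {"P1": seq}
        tiles = tile_region(DisorderedRegion("P1", 1, 40), proteome)
        s = site("P1", 20, "S")
        entries, _ = generate_variants(tiles, [s])
        pm = [e for e in entries if e.variant == PHOSPHOMIMETIC]
        covering = [t for t in tiles if t.covers(20)]
        assert len(pm) == len(covering) >= 3

    def test_residue_mismatch_raises(self):
        tile = self.make_tile()
        with pytest.raises(DesignError, match="mismatch"):
            generate_variants([tile], [site("P1", 6, "S")])  # pos 6 is A

    def test_uncovered_site_reported(self):
        tile = self.make_tile()
        _, uncovered = generate_variants([tile], [site("P1", 100, "S")])
        assert [s.position for s in uncovered] == [100]


class TestReverseTranslate:
    def test_round_trip_identity(self):
        pep = "MSPEPTIDEWKLYSTR"
        assert translate(reverse_translate(pep)) == pep

    def test_contrived_table_avoids_motif(self):
        table = {"P": ("CCC", "CCG"), "G": ("GGG", "GGC")}
        oligo = reverse_translate("PG", codon_table=table)
        assert translate(oligo) == "PG"
        assert SMAI_SITE not in oligo

    def test_flank_junction_motif_removed(self):
        table = {"G": ("GGG", "GGC")}
        oligo = reverse_translate("G", codon_table=table, flank_5prime="AACCC")
        assert SMAI_SITE not in "AACCC" + oligo
        assert translate(oligo) == "G"

    def test_top_codons_used_when_clean(self):
        assert reverse_translate("MK") == "ATGAAA"

    def test_unencodable_amino_acid_raises(self):
        with pytest.raises(ValueError):
            reverse_translate("X")

    def test_impossible_motif_raises(self):
        table = {"P": ("CCC",), "G": ("GGG",)}
        with pytest.raises(DesignError, match="cannot avoid"):
            reverse_translate("PG", codon_table=table)

    @given(
        pep=st.text(alphabet=sorted(ECOLI_RANKED_CODONS), min_size=1, max_size=20)
    )
    @settings(max_examples=150, deadline=None)
    def test_round_trip_and_no_motif_anywhere(self, pep):
        flank5, flank3 = "TCTGGTGGAGGATCCCC", "GGGTGGTGGTTCCGGA"
        oligo = reverse_translate(pep, flank_5prime=flank5, flank_3prime=flank3)
        assert translate(oligo) == pep
        construct = flank5 + oligo + flank3
        assert all(
            construct[i : i + 6] != SMAI_SITE for i in range(len(construct) - 5)
        )


class TestLibraryStats:
    def test_empty_design(self):
        stats = compute_library_stats([])
        assert stats.n_peptides == stats.n_pairs == stats.n_phosphosites == 0

    def test_one_tile_two_sites(self):
        tile = PeptideTile("P1", 1, 16, "AAAASAAAATAAAAAA")
        entries, _ = generate_variants(
            [tile], [site("P1", 5, "S"), site("P1", 10, "T")]
        )
        stats = compute_library_stats(entries)
        assert stats.n_peptides == 3
        assert stats.n_pairs == 2
        assert stats.n_phosphosites == 2
        assert stats.fraction_complete_pairs == 1.0

    def test_coverage_histogram_counts_tiles_per_site(self):
        seq = "A" * 40
        seq = seq[:19] + "S" + seq[20:]
        tiles = tile_region(DisorderedRegion("P1", 1, 40), {"P1": seq})
        entries, _ = generate_variants(tiles, [site("P1", 20, "S")])
        stats = compute_library_stats(entries)
        n_covering = sum(1 for t in tiles if t.covers(20))
        assert stats.site_coverage_histogram == {n_covering: 1}
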