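"""Construct-grammar unit and property tests.

The assembly rules are pure bookkeeping, so everything here is checked
without a folding engine: back-fold complementarity, region round-trips,
graft geometry and the residual-nucleotide accounting.
"""

import dataclasses
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sbhdesign.grammar import (
    DEFAULT_0B_PATTERN,
    ASL,
    BulgeElement,
    GeometryError,
    NotCleavableError,
    SpacerRecord,
    apply_u6_g,
    assemble_sbh,
    build_backfold,
    check_backfold_complementarity,
    graft_unit,
    residual_5p_nt,
)
from sbhdesign.sequences import is_watson_crick, revcomp_rna
from sbhdesign.units import BASIC_LOOP, CSY4, NO_LOOP, CleavingUnit


def random_spacer(rng: random.Random, length: int = 20) -> SpacerRecord:
    return SpacerRecord(
        f"r{rng.randrange(10**9)}",
        "".join(rng.choice("ACGU") for _ in range(length)),
    )


class TestSpacerRecord:
    def test_normalizes_dna(self):
        rec = SpacerRecord("a", "GATTACAGATTACAGATTAC")
        assert "T" not in rec.sequence and rec.sequence.count("U") == 6

    @pytest.mark.parametrize("seq", ["ACGU" * 6, "ACGUACGUA"])
    def test_rejects_out_of_range_lengths(self, seq):
        with pytest.raises(ValueError, match="length"):
            SpacerRecord("bad", seq)

    def test_rejects_empty_name(self):
        with pytest.raises(ValueError, match="name"):
            SpacerRecord("", "ACGU" * 5)


class TestBackfold:
    def test_full_coverage_is_revcomp(self):
        sp = SpacerRecord("g", "G" * 20)
        assert build_backfold(sp, 0) == "C" * 20

    def test_free_count_shortens_backfold(self):
        sp = SpacerRecord("g", "G" * 20)
        assert build_backfold(sp, 5) == "C" * 15

    def test_covers_loop_proximal_segment(self):
        # back-fold pairs the 5' spacer segment, leaving the 3' x free
        sp = SpacerRecord("s", "GGGGGGGGGGAAAAAAAAAA")
        assert build_backfold(sp, 10) == "CCCCCCCCCC"

    def test_spacer_bulge_skips_complements(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        bf = build_backfold(sp, 0, (BulgeElement(6, 2, "spacer"),))
        assert len(bf) == 18
        # realign back-fold to the spacer under the bulge map: positions
        # 0..5 pair spacer 0..5, bulge skips spacer 6..7, rest pairs 8..19
        construct = assemble_sbh(sp, bulge_pattern=(BulgeElement(6, 2, "spacer"),))
        s0 = construct.regions["spacer"][0]
        spacer_partners = sorted(j - s0 for i, j in construct.pairs)
        assert spacer_partners == [*range(0, 6), *range(8, 20)]

    def test_backfold_bulge_inserts_filler(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        bf = build_backfold(sp, 0, (BulgeElement(4, 2, "backfold"),))
        assert len(bf) == 22

    def test_bulge_beyond_stem_is_geometry_error(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        with pytest.raises(GeometryError):
            build_backfold(sp, 10, (BulgeElement(11, 2),))

    def test_x_out_of_range(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        with pytest.raises(ValueError, match="free_count_x"):
            build_backfold(sp, 21)


class TestAssembly:
    def test_length_bookkeeping(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        c = assemble_sbh(sp, loop_unit=BASIC_LOOP, free_count_x=0)
        assert len(c.full_sequence) == 20 + 4 + 20

    def test_degenerate_native_guide(self):
        sp = SpacerRecord("s", "ACGUACGUACGUACGUACGU")
        c = assemble_sbh(sp, loop_unit=NO_LOOP, free_count_x=20)
        assert c.full_sequence == sp.sequence
        assert c.backfold == ""

    def test_length_law_with_bulges(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        c = assemble_sbh(sp, bulge_pattern=DEFAULT_0B_PATTERN)
        spacer_bulge_nt = sum(b.length for b in DEFAULT_0B_PATTERN)
        assert len(c.full_sequence) == (20 - spacer_bulge_nt) + 4 + 20

    def test_regions_round_trip_and_spacer_slice(self):
        rng = random.Random(11)
        for _ in range(50):
            sp = random_spacer(rng)
            x = rng.randrange(0, 10)
            c = assemble_sbh(sp, free_count_x=x,
                             bulge_pattern=DEFAULT_0B_PATTERN if x == 0 else ())
            assert c.region_seq("spacer") == sp.sequence
            rebuilt = "".join(
                c.region_seq(name) for name in ("backfold", "loop", "spacer")
            )
            assert rebuilt == c.full_sequence

    def test_scaffold_region_appended(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        c = assemble_sbh(sp, include_scaffold=True)
        s0, s1 = c.regions["scaffold"]
        assert s1 == len(c.full_sequence) and s1 - s0 > 70

    @given(st.text(alphabet="ACGU", min_size=10, max_size=20), st.data())
    def test_backfold_complementarity_property(self, seq, data):
        sp = SpacerRecord("h", seq)
        x = data.draw(st.integers(0, len(seq)))
        c = assemble_sbh(sp, free_count_x=x)
        assert check_backfold_complementarity(c)
        # every expected pair joins back-fold and spacer symmetrically
        full = c.full_sequence
        assert all(is_watson_crick(full[i], full[j]) for i, j in c.pairs)


class TestGraft:
    @pytest.fixture
    def base(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        return assemble_sbh(sp, bulge_pattern=DEFAULT_0B_PATTERN)

    def _grafted(self, base, mode):
        return graft_unit(base, dataclasses.replace(CSY4, graft_mode=mode))

    def test_apex_length_bookkeeping(self, base):
        g = self._grafted(base, "apex")
        expected = len(base.full_sequence) - len(base.loop_unit.sequence) + len(CSY4.sequence)
        assert len(g.full_sequence) == expected

    def test_stem_pairs_monotone_across_geometries(self, base):
        counts = [
            self._grafted(base, mode).stem_pair_count
            for mode in ("apex", "distal_bulge", "proximal_bulge")
        ]
        assert counts[0] > counts[1] > counts[2]
        assert counts == [16, 11, 4]

    def test_residual_nt_shrinks_toward_nano(self, base):
        residuals = [
            residual_5p_nt(self._grafted(base, mode))
            for mode in ("apex", "distal_bulge", "proximal_bulge")
        ]
        assert residuals[0] > residuals[1] > residuals[2]
        # Csy4's 8-nt post-cut tag: fully unstructured at the apex, mostly
        # absorbed into the medium stem, fully absorbed in the nano stem
        assert residuals == [8, 3, 0]

    def test_cut_at_unit_spacer_junction_gives_zero(self, base):
        unit = CleavingUnit("blunt", "GAAAGAAA", cut_offset=8)
        g = graft_unit(base, unit)
        assert residual_5p_nt(g) == 0

    def test_grafted_stem_still_complementary(self, base):
        for mode in ("distal_bulge", "proximal_bulge"):
            g = self._grafted(base, mode)
            assert check_backfold_complementarity(g)
            rebuilt = "".join(
                g.region_seq(n) for n in ("backfold", "loop", "spacer")
            )
            assert rebuilt == g.full_sequence

    def test_bulge_graft_requires_bulges(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        plain = assemble_sbh(sp)
        with pytest.raises(GeometryError, match="bulged"):
            graft_unit(plain, dataclasses.replace(CSY4, graft_mode="distal_bulge"))

    def test_residual_requires_cut_site(self, base):
        g = graft_unit(base, dataclasses.replace(BASIC_LOOP, graft_mode="apex"))
        with pytest.raises(NotCleavableError):
            residual_5p_nt(g)


class TestU6G:
    @pytest.mark.parametrize("seq,expected", [("GACU", "GACU"), ("ACGU", "GACGU")])
    def test_examples(self, seq, expected):
        assert apply_u6_g(seq) == expected

    @given(st.text(alphabet="ACGU", min_size=1, max_size=30))
    def test_idempotent(self, seq):
        once = apply_u6_g(seq)
        assert apply_u6_g(once) == once


class TestASLType:
    def test_layout(self):
        asl = ASL("GGC" + "A" * 14 + "GCC")
        assert asl.core == "A" * 14
        assert asl.flank5 == "GGC" and asl.flank3 == "GCC"
        assert asl.flank3 == revcomp_rna(asl.flank5)

    def test_unit_exposes_flank_pairs(self):
        unit = ASL("GGC" + "A" * 14 + "GCC").as_unit()
        assert unit.internal_pairs == ((0, 19), (1, 18), (2, 17))
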