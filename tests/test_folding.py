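"""Folding backend, expected-fold construction and folding-score tests.

Engine-derived expected values (structures, energies) were computed once
with the pinned ViennaRNA backend at 37 degrees C and frozen here.
"""

import random

import pytest

from sbhdesign.folding import (
    FoldResult,
    FoldingScore,
    TargetStructure,
    combined_score,
    folding_score,
    predict_mfe,
    spacer_folding_score,
    stem_free_energy,
    target_structure,
)
from sbhdesign.grammar import (
    DEFAULT_0B_PATTERN,
    DEFAULT_0BSTAR_PATTERN,
    ASL,
    SpacerRecord,
    assemble_sbh,
)
from sbhdesign.io import synth_spacers


class TestPredictMfe:
    def test_unpairable_sequence_is_open_with_zero_energy(self, engine):
        r = predict_mfe("AAAAAAA", engine)
        assert r.structure == "......." and r.mfe == 0.0

    def test_frozen_hairpin_fixture(self, engine):
        r = predict_mfe("GGGGAAAACCCC", engine)
        assert r.structure == "((((....))))"
        assert r.mfe == pytest.approx(-5.4, abs=0.01)

    def test_bulge_destabilizes_perfect_duplex(self, engine):
        # 20-bp hairpin vs the same duplex with a 2-nt spacer-strand bulge
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        perfect = assemble_sbh(sp)
        from sbhdesign.grammar import BulgeElement

        bulged = assemble_sbh(sp, bulge_pattern=(BulgeElement(10, 2),))
        assert stem_free_energy(perfect, engine) < stem_free_energy(bulged, engine)

    def test_deterministic_across_calls(self, engine):
        seq = "GGCAUGCCAAGGCAUGCCAA"
        assert predict_mfe(seq, engine) == predict_mfe(seq, engine)

    def test_fold_result_validates_lengths(self):
        with pytest.raises(ValueError):
            FoldResult("ACGU", "...", 0.0)


class TestTargetStructure:
    def test_plain_hairpin_target(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        c = assemble_sbh(sp)  # x=0, 4-nt loop, no bulges
        assert target_structure(c).structure == "(" * 20 + "...." + ")" * 20

    def test_bulged_target_counts(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        c = assemble_sbh(sp, bulge_pattern=DEFAULT_0B_PATTERN)
        ts = target_structure(c)
        assert ts.structure.count("(") == 16  # 20 - two 2-nt skipped bulges
        s0, s1 = c.regions["spacer"]
        spacer_part = ts.structure[s0:s1]
        assert spacer_part.count(")") == 16 and spacer_part.count(".") == 4

    def test_free_spacer_positions_are_dots(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        c = assemble_sbh(sp, free_count_x=6)
        assert target_structure(c).structure.endswith("." * 6)

    def test_scaffold_unconstrained(self):
        sp = SpacerRecord("s", "GCAUGCAUGCAUGCAUGCAU")
        c = assemble_sbh(sp, include_scaffold=True)
        ts = target_structure(c)
        s0, s1 = c.regions["scaffold"]
        assert not any(ts.constrained_mask[s0:s1])
        assert all(ts.constrained_mask[:s0])


class TestFoldingScore:
    def test_identical_prediction_scores_one(self):
        target = TargetStructure("((((....))))", (True,) * 12)
        pred = FoldResult("GGGGAAAACCCC", "((((....))))", -5.4)
        assert float(folding_score(pred, target)) == 1.0

    def test_all_unpaired_prediction_matches_dots_only(self):
        target = TargetStructure("((((....))))", (True,) * 12)
        pred = FoldResult("GGGGAAAACCCC", "." * 12, 0.0)
        assert float(folding_score(pred, target)) == pytest.approx(4 / 12)

    def test_one_mispaired_helix_position(self):
        # hand-enumerated: pairs (0,8),(1,7),(2,6) expected; prediction
        # drops the innermost pair -> positions 2 and 6 mismatch
        target = TargetStructure("(((...)))", (True,) * 9)
        pred = FoldResult("GGGAAACCC", "((.....))", -1.0)
        assert float(folding_score(pred, target)) == pytest.approx(7 / 9)

    def test_partner_identity_required(self):
        # same "paired" state but shifted partner must not count as a match
        target = TargetStructure("((..))", (True,) * 6)
        pred = FoldResult("GGAACC", "(.()).", -1.0)
        assert float(folding_score(pred, target)) == pytest.approx(0 / 6)

    def test_length_mismatch_raises(self):
        target = TargetStructure("((..))", (True,) * 6)
        with pytest.raises(ValueError, match="length"):
            folding_score(FoldResult("AAA", "...", 0.0), target)

    def test_bounds_on_randomized_pairs(self):
        rng = random.Random(5)
        for _ in range(100):
            n = rng.randrange(4, 30)
            stem = rng.randrange(0, n // 2 + 1)
            structure = "(" * stem + "." * (n - 2 * stem) + ")" * stem
            target = TargetStructure(structure, (True,) * n)
            pred_stem = rng.randrange(0, n // 2 + 1)
            pred = FoldResult(
                "A" * n,
                "(" * pred_stem + "." * (n - 2 * pred_stem) + ")" * pred_stem,
                0.0,
            )
            value = float(folding_score(pred, target))
            assert 0.0 <= value <= 1.0
            if pred.structure == structure:
                assert value == 1.0

    def test_probability_mode(self, engine):
        sp = SpacerRecord("s", "GCGCGCGCGCAUAUAUAUAU")
        c = assemble_sbh(sp)
        ts = target_structure(c)
        probs = engine.pair_probabilities(c.full_sequence)
        pred = predict_mfe(c.full_sequence, engine)
        value = float(folding_score(pred, ts, mode="probability", pair_probs=probs))
        assert 0.0 <= value <= 1.0

    def test_score_type_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            FoldingScore(1.5)


@pytest.fixture(scope="module")
def asl():
    return ASL("GGC" + "AUAUCGAUAGCAUA" + "GCC")


@pytest.fixture(scope="module")
def spacers():
    return synth_spacers(3, gc_target=0.6, seed=42)


class TestCombinedScore:
    def test_single_spacer_equals_fs1(self, engine, asl, spacers):
        fs1 = float(spacer_folding_score(asl, spacers[0], engine))
        assert combined_score(asl, spacers[:1], engine) == fs1

    def test_product_and_permutation_invariance(self, engine, asl, spacers):
        fs = [float(spacer_folding_score(asl, sp, engine)) for sp in spacers]
        expected = fs[0] * fs[1] * fs[2]
        assert combined_score(asl, spacers, engine) == pytest.approx(expected)
        shuffled = [spacers[2], spacers[0], spacers[1]]
        assert combined_score(asl, shuffled, engine) == pytest.approx(expected)

    def test_monotone_non_increasing_when_appending(self, engine, asl, spacers):
        one = combined_score(asl, spacers[:1], engine)
        two = combined_score(asl, spacers[:2], engine)
        three = combined_score(asl, spacers, engine)
        assert one >= two >= three

    def test_empty_spacer_list_rejected(self, engine, asl):
        with pytest.raises(ValueError):
            combined_score(asl, [], engine)


class TestStemFreeEnergy:
    def test_unpairable_guide_scores_zero_energy(self, engine):
        # degenerate native guide over an all-A spacer: nothing can pair
        sp = SpacerRecord("a", "A" * 20)
        c = assemble_sbh(sp, free_count_x=20)
        assert stem_free_energy(c, engine) == 0.0

    def test_bulges_destabilize_the_stem(self, engine):
        # SBH(0) -> SBH(0B) destabilization is deterministic here; the full
        # SBH(0B*) chain is a statistical property (alternative registers
        # occasionally stabilize the basal-bulged sequence), checked on a
        # handful of seeded spacers (the acceptance suite does 50)
        chain_ok = 0
        for sp in synth_spacers(5, gc_target=0.5, seed=9):
            g0 = stem_free_energy(assemble_sbh(sp), engine)
            g0b = stem_free_energy(
                assemble_sbh(sp, bulge_pattern=DEFAULT_0B_PATTERN), engine
            )
            gstar = stem_free_energy(
                assemble_sbh(sp, bulge_pattern=DEFAULT_0BSTAR_PATTERN), engine
            )
            assert g0 <= g0b + 1e-9
            chain_ok += g0b <= gstar + 1e-9
        assert chain_ok >= 4
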