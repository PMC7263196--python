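"""Mismatched-guide enumeration, annotation and ranking.

The central invariant of the negative-selection design: a single-mismatch
guide adjacent to a single-base edit sees 1 mismatch on the unedited target
(still cleaved) and 2 on the edited target (spared).
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pinpoint.seqcore import InvalidEditError, complement_base, dna_of, rna_of
from pinpoint.guide_design import (
    EMPIRICAL_PRIOR,
    GuideVariant,
    Mismatch,
    SpacerEdit,
    UnsupportedScoringError,
    annotate_guide,
    enumerate_guides,
    guide_spacer_rna,
    matched_spacer,
    rank_guides,
    score_guide,
)
from pinpoint.target_scan import Protospacer, find_protospacers

GALK = "AGGCTGTAACTGCGGGATCA"


def random_target(rng) -> Protospacer:
    spacer = "".join(rng.choice(list("ACGT"), size=20))
    return Protospacer(spacer=spacer, pam="TGG", strand="+", start=1, end=20)


def oracle_annotate(target_spacer_dna, guide, edit):
    """Independent oracle: physically construct the (edited) non-PAM strand
    and the guide RNA and compare base-by-base."""
    spacer = list(target_spacer_dna)
    if edit is not None:
        for off, (r, a) in enumerate(zip(edit.ref_run, edit.alt_run)):
            assert spacer[edit.k - 1 + off] == r
            spacer[edit.k - 1 + off] = a
    nonpam = [complement_base(b) for b in spacer]
    grna = list(guide_spacer_rna(guide))
    wc = {("A", "U"), ("T", "A"), ("G", "C"), ("C", "G")}
    return [k + 1 for k in range(20) if (nonpam[k], grna[k]) not in wc]


class TestMatchedSpacer:
    def test_galk(self, galk_target):
        assert matched_spacer(galk_target) == "AGGCUGUAACUGCGGGAUCA"

    def test_round_trip(self, galk_target):
        assert dna_of(matched_spacer(galk_target)) == galk_target.spacer
        assert len(matched_spacer(galk_target)) == 20


class TestEnumerateGuides:
    def test_t504a_single_mismatch_designs(self, galk_target, t504a):
        guides = enumerate_guides(galk_target, t504a, max_mm=1)
        names = {g.name for g in guides}
        assert len(guides) == 6
        assert {"A8C", "G6C"} <= names
        # proximal_first: the N8 (k+1) designs come before the N6 designs
        assert [g.name[1] for g in guides] == ["8"] * 3 + ["6"] * 3

    def test_t504a_double_mismatch_designs(self, galk_target, t504a):
        guides = enumerate_guides(galk_target, t504a, max_mm=2)
        names = {g.name for g in guides}
        assert {"A8C/A9C", "T5G/G6C"} <= names
        positions = {tuple(m.position for m in g.mismatches) for g in guides}
        assert {(8, 9), (5, 6)} <= positions

    def test_boundary_edit_at_n1(self):
        t = Protospacer(spacer="T" + "ACG" * 6 + "A", pam="TGG", strand="+", start=1, end=20)
        edit = SpacerEdit(k=1, ref_run="T", alt_run="A")
        with pytest.warns(UserWarning):
            guides = enumerate_guides(t, edit, max_mm=2)
        assert all(min(m.position for m in g.mismatches) >= 2 for g in guides)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("max_mm", [1, 2])
    def test_count_matches_brute_force(self, seed, max_mm):
        rng = np.random.default_rng(seed)
        t = random_target(rng)
        k = int(rng.integers(1, 21))
        ref = t.spacer[k - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        edit = SpacerEdit(k=k, ref_run=ref, alt_run=str(alt))
        # independent count: positions x 3 bases (+ 9 per contiguous pair)
        n_singles = 3 * sum(1 for p in (k - 1, k + 1) if 1 <= p <= 20)
        n_doubles = 9 * ((k + 2 <= 20) + (k - 2 >= 1)) if max_mm == 2 else 0
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            guides = enumerate_guides(t, edit, max_mm=max_mm)
        assert len(guides) == n_singles + n_doubles
        assert len({g.name for g in guides}) == len(guides)

    def test_multi_base_edit_rejected(self, galk_target):
        with pytest.raises(UnsupportedScoringError):
            enumerate_guides(galk_target, SpacerEdit(k=7, ref_run="TA", alt_run="AT"))


class TestAnnotateGuide:
    def test_a8c_vs_unedited(self, galk_target):
        g = GuideVariant(galk_target, (Mismatch(8, "A", "C"),))
        anns = annotate_guide(g)
        assert len(anns) == 1
        a = anns[0]
        assert (a.position, a.nonpam_base, a.sgrna_base) == (8, "T", "C")
        assert a.pairing.label == "Py:Py"

    def test_a8c_vs_edited_has_two_mismatches(self, galk_target, t504a):
        g = GuideVariant(galk_target, (Mismatch(8, "A", "C"),))
        anns = annotate_guide(g, t504a)
        assert [a.position for a in anns] == [7, 8]

    def test_matched_guide_vs_unedited(self, galk_target):
        assert annotate_guide(GuideVariant(galk_target)) == []

    def test_t5g_g6c_vs_unedited(self, galk_target):
        g = GuideVariant(galk_target, (Mismatch(5, "T", "G"), Mismatch(6, "G", "C")))
        assert len(annotate_guide(g)) == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_strand_construction_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        t = random_target(rng)
        k = int(rng.integers(2, 20))
        ref = t.spacer[k - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        edit = SpacerEdit(k=k, ref_run=ref, alt_run=alt)
        p = k + 1 if rng.random() < 0.5 else k - 1
        orig = t.base_at(p)
        repl = str(rng.choice([b for b in "ACGT" if b != orig]))
        g = GuideVariant(t, (Mismatch(p, orig, repl),))
        for e in (None, edit):
            got = [a.position for a in annotate_guide(g, e)]
            assert got == oracle_annotate(t.spacer, g, e)

    @given(st.integers(2, 19), st.data())
    def test_negative_selection_premise(self, k, data):
        # adjacent single-mismatch guide: edited target always has exactly
        # one more mismatch than the unedited one, i.e. 2 vs 1
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        t = random_target(rng)
        ref = t.spacer[k - 1]
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        edit = SpacerEdit(k=k, ref_run=ref, alt_run=alt)
        p = data.draw(st.sampled_from([k - 1, k + 1]))
        orig = t.base_at(p)
        repl = data.draw(st.sampled_from([b for b in "ACGT" if b != orig]))
        g = GuideVariant(t, (Mismatch(p, orig, repl),))
        assert len(annotate_guide(g, None)) == 1
        assert len(annotate_guide(g, edit)) == 2


class TestScoreGuide:
    def test_a8c_recommended_with_prior(self, galk_target, t504a):
        g = GuideVariant(galk_target, (Mismatch(8, "A", "C"),))
        s = score_guide(g, t504a)
        assert s.tier == "recommended"
        assert s.mismatches_vs_unedited == 1 and s.mismatches_vs_edited == 2
        assert s.designed_pairing.label == "Py:Py"
        assert s.empirical_prior == 43.7
        assert s.edit_class == "transversion"

    def test_double_mismatch_not_recommended(self, galk_target, t504a):
        g = GuideVariant(galk_target, (Mismatch(5, "T", "G"), Mismatch(6, "G", "C")))
        s = score_guide(g, t504a)
        assert s.tier == "not_recommended" and s.mismatches_vs_unedited == 2

    def test_wobble_design_not_recommended(self, galk_target, t504a):
        # A8G: non-PAM strand T pairs with sgRNA G -> dT:rG wobble
        g = GuideVariant(galk_target, (Mismatch(8, "A", "G"),))
        s = score_guide(g, t504a)
        assert s.designed_pairing.wobble and s.tier == "not_recommended"

    def test_matched_guide_invalid(self, galk_target, t504a):
        s = score_guide(GuideVariant(galk_target), t504a)
        assert s.tier == "invalid" and s.mismatches_vs_edited == 1

    def test_unlike_class_pairing_moderate(self, galk_target, t504a):
        # G6A: non-PAM strand C vs sgRNA A -> Py:Pu, no wobble
        g = GuideVariant(galk_target, (Mismatch(6, "G", "A"),))
        s = score_guide(g, t504a)
        assert s.tier == "moderate" and s.designed_pairing.label == "Py:Pu"
        assert s.empirical_prior == 15.6

    def test_multi_base_edit_unsupported(self, galk_target):
        g = GuideVariant(galk_target, (Mismatch(8, "A", "C"),))
        with pytest.raises(UnsupportedScoringError):
            score_guide(g, SpacerEdit(k=6, ref_run="GT", alt_run="TA"))

    @pytest.mark.parametrize("seed", range(15))
    def test_recommended_guides_satisfy_design_rules(self, seed):
        rng = np.random.default_rng(seed)
        t = random_target(rng)
        k = int(rng.integers(2, 20))
        ref = t.spacer[k - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        edit = SpacerEdit(k=k, ref_run=ref, alt_run=alt)
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            guides = enumerate_guides(t, edit, max_mm=2)
        for s in (score_guide(g, edit) for g in guides):
            if s.tier == "recommended":
                assert s.mismatches_vs_unedited == 1
                assert s.mismatches_vs_edited >= 2
                assert s.designed_pairing.label in ("Py:Py", "Pu:Pu")
                assert not s.designed_pairing.wobble

    def test_recommended_transversion_gives_consecutive_like_class_pairs(
        self, galk_target, t504a
    ):
        # after the edit, both the edited position and the designed position
        # carry like-class (Py:Py or Pu:Pu) pairs for a recommended
        # transversion design: two consecutive like-class mispairs.
        # T504A: non-PAM strand T pairs with the guide's U -> Py:Py at N7.
        g = GuideVariant(galk_target, (Mismatch(8, "A", "C"),))
        anns = annotate_guide(g, t504a)
        assert [a.pairing.label for a in anns] == ["Py:Py", "Py:Py"]
        assert all(a.pairing.label in ("Py:Py", "Pu:Pu") for a in anns)


class TestRankGuides:
    def test_fig_designs_order(self, galk_target, t504a):
        names = {"A8C", "G6C", "T5G/G6C"}
        guides = [
            g
            for g in enumerate_guides(galk_target, t504a, max_mm=2)
            if g.name in names
        ]
        ranked = rank_guides(guides, t504a)
        assert [s.guide.name for s in ranked] == ["A8C", "G6C", "T5G/G6C"]

    def test_single_candidate(self, galk_target, t504a):
        g = GuideVariant(galk_target, (Mismatch(8, "A", "C"),))
        assert [s.guide.name for s in rank_guides([g], t504a)] == ["A8C"]

    def test_permutation_invariant(self, galk_target, t504a):
        guides = enumerate_guides(galk_target, t504a, max_mm=2)
        ranked = [s.guide.name for s in rank_guides(guides, t504a)]
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(guides)
            rng.shuffle(perm)
            assert [s.guide.name for s in rank_guides(perm, t504a)] == ranked

    def test_empty_input(self, t504a):
        assert rank_guides([], t504a) == []


class TestGuideVariantValidation:
    def test_name_convention(self, galk_target):
        g = GuideVariant(galk_target, (Mismatch(9, "A", "C"), Mismatch(8, "A", "C")))
        assert g.name == "A8C/A9C"  # sorted ascending regardless of input order
        assert GuideVariant(galk_target).name == "matched"

    def test_wrong_original_base_rejected(self, galk_target):
        with pytest.raises(InvalidEditError):
            GuideVariant(galk_target, (Mismatch(8, "G", "C"),))

    def test_edit_must_match_spacer(self, galk_target):
        with pytest.raises(InvalidEditError):
            SpacerEdit(k=7, ref_run="A", alt_run="C").validate_against(galk_target)


def test_prior_table_is_complete():
    # every (edit class, pairing label) combination has an entry
    assert set(EMPIRICAL_PRIOR) == {
        (c, p)
        for c in ("transition", "transversion")
        for p in ("Pu:Pu", "Py:Py", "Pu:Py", "Py:Pu")
    }
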