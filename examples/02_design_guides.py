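"""Design target-mismatched sgRNAs for the single-base edit T504A in galK.

A matched guide cannot select for a single-base edit (Cas9 tolerates one
mismatch), so guides carry a deliberate mismatch adjacent to the edit:
unedited target = 1 mismatch (cleaved), edited target = 2 (spared).
"""

from pinpoint import (
    SpacerEdit,
    annotate_guide,
    enumerate_guides,
    find_protospacers,
    guide_spacer_rna,
    rank_guides,
)

seq = "T" * 497 + "AGGCTGTAACTGCGGGATCA" + "TGG"
target = [t for t in find_protospacers(seq, "galK") if t.start == 498][0]
edit = SpacerEdit(k=7, ref_run="T", alt_run="A")  # T504A in spacer coordinates

guides = enumerate_guides(target, edit, max_mm=2)
print(f"{len(guides)} candidate guides for T504A (single + double mismatch)")
print(f"{'guide':<10}{'tier':<17}{'pair':<7}{'mm_un':<7}{'mm_ed':<7}prior%")
for s in rank_guides(guides, edit)[:8]:
    pair = s.designed_pairing.label if s.designed_pairing else "."
    prior = f"{s.empirical_prior:.1f}" if s.empirical_prior is not None else "."
    print(f"{s.guide.name:<10}{s.tier:<17}{pair:<7}"
          f"{s.mismatches_vs_unedited:<7}{s.mismatches_vs_edited:<7}{prior}")

best = rank_guides(guides, edit)[0].guide
print(f"\ntop design {best.name}: sgRNA spacer 5'-{guide_spacer_rna(best)}-3'")
print("mismatches vs edited target (N' non-PAM strand : N'' sgRNA):")
for a in annotate_guide(best, edit):
    print(f"  N{a.position}: {a.nonpam_base}:{a.sgrna_base}  {a.pairing.label}")

# 'recommended' = 1 mismatch vs unedited, >=2 vs edited, like-class
# (Py:Py/Pu:Pu) designed mispair, no G:U-type wobble; the prior column is
# the observed genome-wide success frequency for that design class.
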