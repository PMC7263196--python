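"""Enumeration, annotation and ranking of target-mismatched sgRNAs.

The design problem: Cas9 negative selection eliminates unedited cells by
cleaving the unchanged target, but Cas9 tolerates a single sgRNA/target
mismatch, so a single-base genomic edit is not by itself enough to protect
edited cells from cleavage — matched guides give very low single-base
editing efficiency.  The remedy is to build the sgRNA with a deliberate
mismatch immediately adjacent to the intended edit: the unedited target
then carries one mismatch (still cleaved, unedited cells die) while the
edited target carries two (escapes cleavage, edited cells survive).

This module enumerates such guide variants, annotates every non-Watson–Crick
position of a guide against the (optionally edited) target's non-PAM strand
in the N′:N′′ convention, and ranks designs by empirically grounded rules:

1. transversion edits select better than transitions;
2. the designed mispair should be Py:Py or Pu:Pu (like-class mispairs
   distort the DNA:RNA duplex most);
3. G:U-type wobble pairs hybridize and are ineffective;
4. guides with two mismatches against the *unedited* target fail to cleave
   it and abolish selection, so double-mismatch designs are kept but
   down-ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .seqcore import (
    InvalidEditError,
    PairClass,
    classify_substitution,
    complement_base,
    dna,
    pair_class,
    rna_of,
)
from .target_scan import SPACER_LEN, Protospacer

__all__ = [
    "SpacerEdit",
    "Mismatch",
    "GuideVariant",
    "MismatchAnnotation",
    "GuideScore",
    "EMPIRICAL_PRIOR",
    "TIER_ORDER",
    "matched_spacer",
    "guide_spacer_rna",
    "enumerate_guides",
    "annotate_guide",
    "score_guide",
    "rank_guides",
    "UnsupportedScoringError",
]

_BASE_ORDER = "ACGT"


class UnsupportedScoringError(ValueError):
    """Scoring requested for an edit the tier rules do not cover."""


@dataclass(frozen=True)
class SpacerEdit:
    """A desired substitution of 1–4 contiguous bases, in spacer coordinates.

    ``k`` is the spacer index (N_k) of the first edited base; ``ref_run`` and
    ``alt_run`` are equal-length runs in PAM-strand orientation that must
    differ at every position.
    """

    k: int
    ref_run: str
    alt_run: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_run", dna(self.ref_run))
        object.__setattr__(self, "alt_run", dna(self.alt_run))
        if not 1 <= len(self.ref_run) <= 4:
            raise InvalidEditError("edit run must be 1-4 bases")
        if len(self.ref_run) != len(self.alt_run):
            raise InvalidEditError("ref_run and alt_run must have equal length")
        if any(r == a for r, a in zip(self.ref_run, self.alt_run)):
            raise InvalidEditError("ref and alt must differ at every edited position")
        if not 1 <= self.k <= SPACER_LEN - len(self.ref_run) + 1:
            raise InvalidEditError(f"edit at N{self.k} does not fit in the spacer")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.k, self.k + len(self.ref_run)))

    @property
    def is_single(self) -> bool:
        return len(self.ref_run) == 1

    @property
    def edit_class(self) -> str:
        """Transition/transversion class of the first edited base."""
        return classify_substitution(self.ref_run[0], self.alt_run[0])

    def validate_against(self, target: Protospacer) -> None:
        found = target.spacer[self.k - 1 : self.k - 1 + len(self.ref_run)]
        if found != self.ref_run:
            raise InvalidEditError(
                f"spacer reads {found} at N{self.k}, edit expects {self.ref_run}"
            )

    def apply(self, spacer: str) -> str:
        """Return the spacer with the edit applied (PAM-strand orientation)."""
        i = self.k - 1
        return spacer[:i] + self.alt_run + spacer[i + len(self.alt_run) :]


@dataclass(frozen=True)
class Mismatch:
    """One deliberate spacer substitution in a guide: N_position orig→repl (DNA letters)."""

    position: int
    original: str
    replacement: str

    def __post_init__(self) -> None:
        if self.original == self.replacement:
            raise InvalidEditError("guide mismatch must change the base")

    @property
    def name(self) -> str:
        return f"{self.original}{self.position}{self.replacement}"


@dataclass(frozen=True)
class GuideVariant:
    """An sgRNA spacer derived from a target with 0–2 deliberate mismatches.

    The conventional name concatenates each mismatch as ``<orig><k><repl>``
    (DNA letters, ascending position, '/'-joined); the mismatch-free guide
    is called ``matched``.
    """

    target: Protospacer
    mismatches: tuple[Mismatch, ...] = ()

    def __post_init__(self) -> None:
        if len(self.mismatches) > 2:
            raise InvalidEditError("at most 2 deliberate mismatches per guide")
        positions = [m.position for m in self.mismatches]
        if len(set(positions)) != len(positions):
            raise InvalidEditError("mismatch positions must be distinct")
        for m in self.mismatches:
            if not 1 <= m.position <= SPACER_LEN:
                raise InvalidEditError(f"mismatch position {m.position} outside spacer")
            if self.target.base_at(m.position) != m.original:
                raise InvalidEditError(
                    f"target spacer has {self.target.base_at(m.position)} at "
                    f"N{m.position}, not {m.original}"
                )
        object.__setattr__(
            self, "mismatches", tuple(sorted(self.mismatches, key=lambda m: m.position))
        )

    @property
    def name(self) -> str:
        if not self.mismatches:
            return "matched"
        return "/".join(m.name for m in self.mismatches)

    @property
    def spacer_dna(self) -> str:
        s = list(self.target.spacer)
        for m in self.mismatches:
            s[m.position - 1] = m.replacement
        return "".join(s)


def matched_spacer(t: Protospacer) -> str:
    """The perfectly matched sgRNA spacer for a target (RNA, 5'→3')."""
    return rna_of(t.spacer)


def guide_spacer_rna(g: GuideVariant) -> str:
    """The guide's sgRNA spacer sequence (RNA, 5'→3')."""
    return rna_of(g.spacer_dna)


def enumerate_guides(
    target: Protospacer,
    edit: SpacerEdit,
    max_mm: int = 1,
    placement: Literal["adjacent", "proximal_first"] = "proximal_first",
) -> list[GuideVariant]:
    """Enumerate mismatched guides flanking a single-base edit.

    Single-mismatch variants are placed at N_{k+1} (PAM-proximal side) and
    N_{k-1} (distal side), each with all 3 replacement bases.  With
    ``max_mm=2``, contiguous double-mismatch variants at {k+1, k+2} and
    {k-2, k-1} are added (9 replacement combinations per pair).  The order is
    deterministic: with ``placement="proximal_first"`` the k+1-side designs
    come first; with ``"adjacent"`` sides are listed in ascending position
    order.  A side that runs off the spacer is omitted with a warning.
    """
    if not edit.is_single:
        raise UnsupportedScoringError(
            "mismatched-guide enumeration applies to single-base edits; "
            "multi-base edits already escape cleavage with a matched guide"
        )
    if max_mm not in (1, 2):
        raise ValueError("max_mm must be 1 or 2")
    edit.validate_against(target)
    k = edit.k

    def singles(p: int) -> list[GuideVariant]:
        orig = target.base_at(p)
        return [
            GuideVariant(target, (Mismatch(p, orig, repl),))
            for repl in _BASE_ORDER
            if repl != orig
        ]

    def doubles(p1: int, p2: int) -> list[GuideVariant]:
        o1, o2 = target.base_at(p1), target.base_at(p2)
        out = []
        for r1 in _BASE_ORDER:
            if r1 == o1:
                continue
            for r2 in _BASE_ORDER:
                if r2 == o2:
                    continue
                out.append(
                    GuideVariant(target, (Mismatch(p1, o1, r1), Mismatch(p2, o2, r2)))
                )
        return out

    proximal_ok = k + 1 <= SPACER_LEN
    distal_ok = k - 1 >= 1
    if not proximal_ok:
        warnings.warn(f"edit at N{k}: no room PAM-proximal of the edit; side omitted")
    if not distal_ok:
        warnings.warn(f"edit at N{k}: no room PAM-distal of the edit; side omitted")

    blocks: list[list[GuideVariant]] = []
    single_blocks = []
    if proximal_ok:
        single_blocks.append(("proximal", singles(k + 1)))
    if distal_ok:
        single_blocks.append(("distal", singles(k - 1)))
    if placement == "adjacent":
        single_blocks.sort(key=lambda b: 0 if b[0] == "distal" else 1)
    blocks.extend(b for _, b in single_blocks)

    if max_mm == 2:
        double_blocks = []
        if k + 2 <= SPACER_LEN:
            double_blocks.append(("proximal", doubles(k + 1, k + 2)))
        if k - 2 >= 1:
            double_blocks.append(("distal", doubles(k - 2, k - 1)))
        if placement == "adjacent":
            double_blocks.sort(key=lambda b: 0 if b[0] == "distal" else 1)
        blocks.extend(b for _, b in double_blocks)

    return [g for block in blocks for g in block]


@dataclass(frozen=True)
class MismatchAnnotation:
    """One non-Watson–Crick position between guide and target, N′:N′′ convention.

    ``nonpam_base`` (N′) is the non-PAM-strand DNA base, i.e. the complement
    of the — optionally edited — PAM-strand spacer base; ``sgrna_base`` (N′′)
    is the guide base at the same spacer index.
    """

    position: int
    nonpam_base: str
    sgrna_base: str
    pairing: PairClass


def annotate_guide(
    g: GuideVariant, edit: SpacerEdit | None = None
) -> list[MismatchAnnotation]:
    """All mismatched positions of a guide against the (edited) target.

    The guide's RNA spacer is compared base-by-base, position-aligned,
    against the non-PAM strand of the target with ``edit`` applied (or the
    unedited target when ``edit`` is None).  Every position that does not
    form a Watson–Crick pair is returned, classified.
    """
    spacer = g.target.spacer
    if edit is not None:
        edit.validate_against(g.target)
        spacer = edit.apply(spacer)
    sgrna = guide_spacer_rna(g)
    out: list[MismatchAnnotation] = []
    for k in range(1, SPACER_LEN + 1):
        nonpam = complement_base(spacer[k - 1])
        pc = pair_class(nonpam, sgrna[k - 1])
        if pc.is_mismatch:
            out.append(
                MismatchAnnotation(
                    position=k,
                    nonpam_base=nonpam,
                    sgrna_base=sgrna[k - 1],
                    pairing=pc,
                )
            )
    return out


#: Observed single-base editing frequencies (percent) by edit class and
#: designed N′:N′′ mispair, from a 16-target genome-wide negative-selection
#: screen.  Like-class mispairs (Py:Py / Pu:Pu) next to a transversion edit
#: worked best; transitions with unlike-class mispairs never worked.  Stored
#: verbatim as ordinal weights, not calibrated probabilities.
EMPIRICAL_PRIOR: dict[tuple[str, str], float] = {
    ("transversion", "Py:Py"): 43.7,
    ("transversion", "Pu:Pu"): 43.7,
    ("transversion", "Py:Pu"): 15.6,
    ("transversion", "Pu:Py"): 9.3,
    ("transition", "Py:Py"): 6.3,
    ("transition", "Pu:Pu"): 25.0,
    ("transition", "Py:Pu"): 0.0,
    ("transition", "Pu:Py"): 0.0,
}

TIER_ORDER = ("recommended", "moderate", "not_recommended", "invalid")


@dataclass(frozen=True)
class GuideScore:
    """Negative-selection suitability of one guide for one single-base edit.

    ``invalid`` — the edited target carries <2 mismatches, so edited cells
    are still cleaved and selection cannot work (e.g. the matched guide).
    ``not_recommended`` — ≥2 mismatches against the unedited target (unedited
    cells escape cleavage) or a wobble designed pair.  ``recommended`` —
    exactly 1 mismatch vs unedited, ≥2 vs edited, like-class (Py:Py/Pu:Pu)
    designed mispair, no wobble.  ``moderate`` — same but unlike-class
    mispair.
    """

    guide: GuideVariant
    mismatches_vs_unedited: int
    mismatches_vs_edited: int
    designed_pairing: PairClass | None
    edit_class: str
    empirical_prior: float | None
    tier: str


def score_guide(g: GuideVariant, edit: SpacerEdit) -> GuideScore:
    """Tier a guide for negative selection of a single-base edit."""
    if not edit.is_single:
        raise UnsupportedScoringError(
            "scoring is defined for single-base edits only; use a matched "
            "guide for multi-base edits"
        )
    edit.validate_against(g.target)
    if any(m.position in edit.positions for m in g.mismatches):
        raise InvalidEditError("guide mismatch coincides with the edited position")
    mm_unedited = len(annotate_guide(g, None))
    mm_edited = len(annotate_guide(g, edit))

    designed: PairClass | None = None
    if g.mismatches:
        # the designed pair is the deliberate mismatch closest to the edit
        m = min(g.mismatches, key=lambda m: (abs(m.position - edit.k), m.position))
        designed = pair_class(complement_base(m.original), rna_of(m.replacement))

    wobble = any(
        pair_class(complement_base(m.original), rna_of(m.replacement)).wobble
        for m in g.mismatches
    )

    if mm_edited < 2:
        tier = "invalid"
    elif mm_unedited >= 2 or wobble:
        tier = "not_recommended"
    elif designed is not None and designed.label in ("Py:Py", "Pu:Pu"):
        tier = "recommended"
    else:
        tier = "moderate"

    prior = None
    if len(g.mismatches) == 1 and designed is not None:
        prior = EMPIRICAL_PRIOR.get((edit.edit_class, designed.label))

    return GuideScore(
        guide=g,
        mismatches_vs_unedited=mm_unedited,
        mismatches_vs_edited=mm_edited,
        designed_pairing=designed,
        edit_class=edit.edit_class,
        empirical_prior=prior,
        tier=tier,
    )


def rank_guides(
    candidates: Iterable[GuideVariant], edit: SpacerEdit
) -> list[GuideScore]:
    """Score and rank candidate guides for the same (target, edit).

    Sort key: tier, then empirical prior (descending, unknown last), fewer
    deliberate mismatches, PAM-proximal-side placement first, then name —
    stable and invariant to input order.
    """
    scored = [score_guide(g, edit) for g in candidates]

    def key(s: GuideScore):
        proximal_side = all(m.position > edit.k for m in s.guide.mismatches)
        prior = s.empirical_prior if s.empirical_prior is not None else -1.0
        return (
            TIER_ORDER.index(s.tier),
            -prior,
            len(s.guide.mismatches),
            0 if proximal_side else 1,
            s.guide.name,
        )

    return sorted(scored, key=key)
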