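"""Elementary nucleotide operations and base-pair classification.

Everything downstream of this module — protospacer scanning, mismatched-guide
annotation, oligo design — is built on four primitives: reverse complement,
DNA→RNA conversion, transition/transversion typing of a substitution, and
classification of a DNA:RNA base pair formed between the non-PAM genomic
strand and an sgRNA spacer.

Pair classification follows the N′:N′′ convention used in negative-selection
guide design: the first base is the non-PAM-strand DNA base (N′), the second
the sgRNA base (N′′).  A pair is labelled by the purine/pyrimidine class of
each partner (``Pu:Pu``, ``Py:Py``, ``Pu:Py``, ``Py:Pu``); Watson–Crick
pairs (A:U, T:A, G:C, C:G) and G:U-type wobble pairs (dG:rU, dT:rG) are
flagged separately because they hybridize and therefore discriminate poorly
in negative selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "AlphabetError",
    "InvalidEditError",
    "PairClass",
    "dna",
    "rna",
    "revcomp",
    "complement_base",
    "rna_of",
    "dna_of",
    "base_class",
    "classify_substitution",
    "pair_class",
]

DNA_BASES = frozenset("ACGT")
RNA_BASES = frozenset("ACGU")
PURINES = frozenset("AG")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

BaseClassT = Literal["purine", "pyrimidine"]
SubstitutionClassT = Literal["transition", "transversion"]


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


class InvalidEditError(ValueError):
    """An edit specification is malformed (e.g. ref equals alt)."""


def dna(s: str) -> str:
    """Normalize to uppercase and validate as non-empty DNA."""
    s = s.upper()
    if not s:
        raise AlphabetError("empty sequence")
    bad = set(s) - DNA_BASES
    if bad:
        raise AlphabetError(f"non-DNA character(s) {sorted(bad)} in sequence")
    return s


def rna(s: str) -> str:
    """Normalize to uppercase and validate as non-empty RNA."""
    s = s.upper()
    if not s:
        raise AlphabetError("empty sequence")
    bad = set(s) - RNA_BASES
    if bad:
        raise AlphabetError(f"non-RNA character(s) {sorted(bad)} in sequence")
    return s


def complement_base(b: str) -> str:
    """Watson–Crick complement of a single DNA base."""
    b = dna(b)
    if len(b) != 1:
        raise AlphabetError("expected a single base")
    return b.translate(_COMPLEMENT)


def revcomp(s: str) -> str:
    """Reverse complement of a DNA sequence (an involution)."""
    return dna(s).translate(_COMPLEMENT)[::-1]


def rna_of(s: str) -> str:
    """DNA → RNA: replace T with U."""
    return dna(s).replace("T", "U")


def dna_of(s: str) -> str:
    """RNA → DNA: replace U with T."""
    return rna(s).replace("U", "T")


def base_class(b: str) -> BaseClassT:
    """Purine (A, G) or pyrimidine (C, T/U) class of a single base."""
    b = b.upper()
    if b not in DNA_BASES | RNA_BASES:
        raise AlphabetError(f"not a nucleotide base: {b!r}")
    return "purine" if b in PURINES else "pyrimidine"


def classify_substitution(ref: str, alt: str) -> SubstitutionClassT:
    """Type a base substitution as transition or transversion.

    A transition keeps the purine/pyrimidine class (A<->G, C<->T); a
    transversion swaps it.  For every reference base exactly one of its
    three alternatives is a transition.
    """
    ref, alt = dna(ref), dna(alt)
    if len(ref) != 1 or len(alt) != 1:
        raise InvalidEditError("classify_substitution takes single bases")
    if ref == alt:
        raise InvalidEditError(f"ref equals alt ({ref}); not a substitution")
    return "transition" if base_class(ref) == base_class(alt) else "transversion"


@dataclass(frozen=True)
class PairClass:
    """Classification of one non-PAM-strand DNA base paired with one sgRNA base.

    Attributes
    ----------
    label:
        Purine/pyrimidine pairing label ordered non-PAM:sgRNA, one of
        ``Pu:Pu``, ``Py:Py``, ``Pu:Py``, ``Py:Pu``.
    watson_crick:
        True for A:U, T:A, G:C, C:G — i.e. not a mismatch.
    wobble:
        True for dG:rU or dT:rG, the wobble geometries that still hybridize
        in a DNA:RNA duplex.
    wobble_kind:
        Which wobble orientation was seen (``"dG:rU"`` or ``"dT:rG"``), or
        None.
    """

    label: str
    watson_crick: bool
    wobble: bool
    wobble_kind: str | None = None

    @property
    def is_mismatch(self) -> bool:
        return not self.watson_crick


_PU_PY = {"purine": "Pu", "pyrimidine": "Py"}


def pair_class(nonpam_base: str, sgrna_base: str) -> PairClass:
    """Classify the pair formed by a non-PAM-strand DNA base and an sgRNA base."""
    d = dna(nonpam_base)
    r = rna(sgrna_base)
    if len(d) != 1 or len(r) != 1:
        raise AlphabetError("pair_class takes single bases")
    label = f"{_PU_PY[base_class(d)]}:{_PU_PY[base_class(r)]}"
    watson_crick = r == rna_of(complement_base(d))
    wobble_kind = None
    if d == "G" and r == "U":
        wobble_kind = "dG:rU"
    elif d == "T" and r == "G":
        wobble_kind = "dT:rG"
    return PairClass(
        label=label,
        watson_crick=watson_crick,
        wobble=wobble_kind is not None,
        wobble_kind=wobble_kind,
    )
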