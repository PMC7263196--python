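"""Mutagenic single-stranded oligonucleotide design.

Recombineering incorporates a short single-stranded DNA at the replication
fork; the oligo carries the desired 1–4-base substitution flanked by
homology arms.  This module builds such oligos against a reference sequence
(hard-failing if the reference disagrees with the stated ref bases) and
enumerates the substitution sets that convert a sense codon into a premature
stop codon (TAA/TAG/TGA) — the loss-of-function edits used to score editing
efficiency on indicator plates.

Defaults follow ssDNA-recombineering convention: 35-nt arms each side
(a 70-mer class oligo for a single-base edit), PAM-strand ("+") orientation.
Lagging-strand choice and chemical modifications are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

from .seqcore import InvalidEditError, dna, revcomp

__all__ = [
    "OligoDesign",
    "StopEdit",
    "STOP_CODONS",
    "DEFAULT_ARM",
    "design_oligo",
    "stop_codon_edits",
    "ReferenceMismatchError",
    "ArmOutOfBoundsError",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_ARM = 35


class ReferenceMismatchError(ValueError):
    """The reference sequence disagrees with the stated ref bases at the edit site."""


class ArmOutOfBoundsError(ValueError):
    """A homology arm would extend past the reference sequence boundary."""


@dataclass(frozen=True)
class OligoDesign:
    """A mutagenic ssDNA oligo: left arm + substituted run + right arm.

    ``start``/``end`` are the 1-based inclusive genomic span the oligo covers
    on the reference; ``edits`` lists (position, ref, alt) per changed base.
    ``sequence`` is written 5'→3' on ``strand`` ("-" emits the reverse
    complement of the edited window).
    """

    sequence: str
    start: int
    end: int
    edits: tuple[tuple[int, str, str], ...]
    arm_left: int
    arm_right: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if len(self.sequence) != self.arm_left + len(self.edits_run) + self.arm_right:
            raise ValueError("oligo length must equal arm_left + edit + arm_right")

    @property
    def edits_run(self) -> str:
        return "".join(alt for _, _, alt in self.edits)


def design_oligo(
    ref_seq: str,
    pos: int,
    ref_run: str,
    alt_run: str,
    arm: int = DEFAULT_ARM,
    strand: Literal["+", "-"] = "+",
) -> OligoDesign:
    """Design a mutagenic oligo replacing ``ref_run`` with ``alt_run`` at ``pos``.

    The reference must read ``ref_run`` at ``pos`` (1-based); any
    disagreement is a hard error, never silently overridden.  Arms of
    ``arm`` nt are taken from the reference on each side and must fit within
    it.
    """
    ref_seq = dna(ref_seq)
    ref_run = dna(ref_run)
    alt_run = dna(alt_run)
    if len(ref_run) != len(alt_run) or not 1 <= len(ref_run) <= 4:
        raise InvalidEditError("edit must replace a 1-4 base run with an equal-length run")
    if any(r == a for r, a in zip(ref_run, alt_run)):
        raise InvalidEditError("ref and alt must differ at every edited position")
    if arm < 0:
        raise ValueError("arm length must be non-negative")
    i = pos - 1
    found = ref_seq[i : i + len(ref_run)]
    if found != ref_run:
        raise ReferenceMismatchError(
            f"reference reads {found!r} at {pos}, edit expects {ref_run!r}"
        )
    start = pos - arm
    end = pos + len(ref_run) - 1 + arm
    if start < 1 or end > len(ref_seq):
        raise ArmOutOfBoundsError(
            f"arms of {arm} nt around {pos} exceed the reference (1..{len(ref_seq)})"
        )
    seq = ref_seq[start - 1 : i] + alt_run + ref_seq[i + len(ref_run) : end]
    if strand == "-":
        seq = revcomp(seq)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    edits = tuple(
        (pos + j, ref_run[j], alt_run[j])
        for j in range(len(ref_run))
        if ref_run[j] != alt_run[j]
    )
    return OligoDesign(
        sequence=seq,
        start=start,
        end=end,
        edits=edits,
        arm_left=arm,
        arm_right=arm,
        strand=strand,
    )


@dataclass(frozen=True)
class StopEdit:
    """A substitution set converting one sense codon into a stop codon.

    Positions in ``substitutions`` are 1-based on the window passed to
    :func:`stop_codon_edits` (add ``window_start - 1`` for genomic
    coordinates).
    """

    codon_index: int
    codon_before: str
    codon_after: str
    substitutions: tuple[tuple[int, str, str], ...]

    @property
    def n_changed(self) -> int:
        return len(self.substitutions)


def stop_codon_edits(
    cds_window: str,
    frame_offset: int = 0,
    max_changes: int = 1,
    first_codon_number: int = 1,
) -> list[StopEdit]:
    """Enumerate substitutions that create a premature stop in each codon.

    ``frame_offset`` (0-2) is the number of window bases before the first
    full codon; ``first_codon_number`` numbers that codon (e.g. its CDS codon
    index).  For every codon fully inside the window, all substitution sets
    of size <= ``max_changes`` that turn it into TAA/TAG/TGA are returned,
    minimal sets first within each codon.  Codons that already are stops are
    skipped with a warning.
    """
    cds_window = dna(cds_window)
    if not 0 <= frame_offset <= 2:
        raise ValueError("frame_offset must be 0..2")
    if not 1 <= max_changes <= 4:
        raise ValueError("max_changes must be 1..4")
    out: list[StopEdit] = []
    for ci, w0 in enumerate(range(frame_offset, len(cds_window) - 2, 3)):
        codon = cds_window[w0 : w0 + 3]
        codon_number = first_codon_number + ci
        if codon in STOP_CODONS:
            warnings.warn(f"codon {codon_number} ({codon}) is already a stop; skipped")
            continue
        edits: list[StopEdit] = []
        for stop in STOP_CODONS:
            diffs = tuple(
                (w0 + j + 1, codon[j], stop[j]) for j in range(3) if codon[j] != stop[j]
            )
            if 0 < len(diffs) <= min(max_changes, 3):
                edits.append(
                    StopEdit(
                        codon_index=codon_number,
                        codon_before=codon,
                        codon_after=stop,
                        substitutions=diffs,
                    )
                )
        edits.sort(key=lambda e: (e.n_changed, e.codon_after))
        out.extend(edits)
    return out
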