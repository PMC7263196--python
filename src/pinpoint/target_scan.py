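"""SpCas9 protospacer scanning and the N1–N20 spacer coordinate system.

A protospacer is the 20-nt genomic sequence (N1..N20, N20 adjacent to the
PAM) followed by a 5'-NGG PAM on the same strand.  Both strands are scanned;
coordinates are 1-based inclusive on the input sequence and always refer to
the 20-nt spacer (the PAM is reported separately).

Spacer positions split into a PAM-distal region (N1–N12) and a PAM-proximal
region (N13–N20).  Guide/target pairing in the proximal region contributes
more to Cas9 target recognition, but single-base-mismatched guides work for
negative selection in either region; the region tag is carried as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .seqcore import dna, revcomp

__all__ = [
    "Protospacer",
    "SpacerIndex",
    "PROXIMAL_START",
    "SPACER_LEN",
    "find_protospacers",
    "targets_covering",
    "spacer_index",
    "OutOfTargetError",
]

SPACER_LEN = 20
PAM_LEN = 3
#: first spacer index counted as PAM-proximal (N13..N20 proximal, N1..N12 distal)
PROXIMAL_START = 13

StrandT = Literal["+", "-"]


class OutOfTargetError(ValueError):
    """A genomic position does not fall inside the given protospacer."""


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt Cas9 target with its PAM, strand and 1-based coordinates.

    ``spacer`` is given in PAM-strand orientation, 5'→3', so its i-th base is
    spacer index N_i and N20 abuts the PAM.  ``start``/``end`` are 1-based
    inclusive coordinates of the spacer on the *input* sequence; on the "-"
    strand the spacer equals the reverse complement of the input slice.
    """

    spacer: str
    pam: str
    strand: StrandT
    start: int
    end: int
    source_id: str = "seq"

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(self.spacer)}")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must be NGG, got {self.pam!r}")
        if self.end - self.start + 1 != SPACER_LEN:
            raise ValueError("start/end must span exactly 20 nt")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def base_at(self, k: int) -> str:
        """Spacer base at index N_k (1..20), PAM-strand orientation."""
        if not 1 <= k <= SPACER_LEN:
            raise OutOfTargetError(f"spacer index {k} outside 1..{SPACER_LEN}")
        return self.spacer[k - 1]


@dataclass(frozen=True)
class SpacerIndex:
    """A spacer coordinate N_k with its PAM-distal/proximal region tag."""

    k: int
    region: Literal["PAM-distal", "PAM-proximal"]


def _region(k: int) -> Literal["PAM-distal", "PAM-proximal"]:
    return "PAM-proximal" if k >= PROXIMAL_START else "PAM-distal"


def _pam_matches(window: str, pam: str) -> bool:
    # N in the PAM pattern is a wildcard; sequence bases never wildcard.
    return all(p == "N" or p == b for p, b in zip(pam, window))


def find_protospacers(
    seq: str, source_id: str = "seq", pam: str = "NGG"
) -> list[Protospacer]:
    """Exhaustively scan both strands for 20-nt spacers followed by an NGG PAM.

    Every 23-nt window on either strand whose last three bases match the PAM
    pattern yields one Protospacer.  Overlapping hits are all reported.
    Returns an empty list (not an error) for sequences shorter than 23 nt,
    sorted by (start, strand).
    """
    seq = dna(seq)
    pam = pam.upper()
    n = len(seq)
    win = SPACER_LEN + PAM_LEN
    hits: list[Protospacer] = []
    if n < win:
        return hits
    for i in range(n - win + 1):  # i: 0-based start of the spacer
        if _pam_matches(seq[i + SPACER_LEN : i + win], pam):
            hits.append(
                Protospacer(
                    spacer=seq[i : i + SPACER_LEN],
                    pam=seq[i + SPACER_LEN : i + win],
                    strand="+",
                    start=i + 1,
                    end=i + SPACER_LEN,
                    source_id=source_id,
                )
            )
    rc = revcomp(seq)
    for j in range(n - win + 1):
        if _pam_matches(rc[j + SPACER_LEN : j + win], pam):
            # map reverse-complement coordinates back to the input sequence
            hits.append(
                Protospacer(
                    spacer=rc[j : j + SPACER_LEN],
                    pam=rc[j + SPACER_LEN : j + win],
                    strand="-",
                    start=n - (j + SPACER_LEN) + 1,
                    end=n - j,
                    source_id=source_id,
                )
            )
    hits.sort(key=lambda t: (t.start, t.strand))
    return hits


def targets_covering(targets: Iterable[Protospacer], pos: int) -> list[Protospacer]:
    """Subset of targets whose 20-nt spacer span contains the 1-based position."""
    if pos < 1:
        raise ValueError("positions are 1-based; pos must be >= 1")
    return [t for t in targets if t.start <= pos <= t.end]


def spacer_index(t: Protospacer, pos: int) -> SpacerIndex:
    """Map a genomic position inside a target to its spacer index N_k.

    On the "+" strand N1 sits at ``start``; on the "-" strand N1 sits at
    ``end`` (the spacer reads toward decreasing coordinates).
    """
    if not t.start <= pos <= t.end:
        raise OutOfTargetError(
            f"position {pos} outside target {t.start}..{t.end} ({t.source_id})"
        )
    k = pos - t.start + 1 if t.strand == "+" else t.end - pos + 1
    return SpacerIndex(k=k, region=_region(k))


def genomic_position(t: Protospacer, k: int) -> int:
    """Inverse of :func:`spacer_index`: the genomic coordinate of N_k."""
    if not 1 <= k <= SPACER_LEN:
        raise OutOfTargetError(f"spacer index {k} outside 1..{SPACER_LEN}")
    return t.start + k - 1 if t.strand == "+" else t.end - k + 1
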