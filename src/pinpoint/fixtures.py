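"""Sequence I/O and seed-deterministic synthetic fixtures.

``load_sequences`` reads FASTA (or GenBank with CDS features) through
Biopython and normalizes to uppercase DNA.  ``make_fixture`` builds a
synthetic multi-gene FASTA with planted Cas9 targets and a truth table, so
the whole toolkit — scanning, guide design, planning — is exercisable
end-to-end without any external dataset.

The fixture always includes a synthetic galK-like gene carrying the
real galK protospacer AGGCTGTAACTGCGGGATCA at positions 498–517 (its PAM is
a fixture choice, TGG, since the genomic PAM is not part of the spacer).
With a reading frame starting at position 1, codon 168 of that gene spans
502–504 and reads TGT, so the classic T504A premature-stop edit (spacer
index N7) is reproducible against this fixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqcore import dna, revcomp
from .target_scan import SPACER_LEN, find_protospacers

__all__ = [
    "GALK_SPACER",
    "GALK_SPACER_START",
    "GALK_PAM",
    "GALK_EDIT_POS",
    "SequenceRecord",
    "FixtureSpec",
    "Fixture",
    "ParseError",
    "load_sequences",
    "make_fixture",
    "write_fixture",
    "write_fasta",
]

#: the galK protospacer (N1..N20) at genomic positions 498..517
GALK_SPACER = "AGGCTGTAACTGCGGGATCA"
GALK_SPACER_START = 498
#: synthetic: the genomic PAM of this target is not printed anywhere public
GALK_PAM = "TGG"
#: the classic nonsense edit site: T504A, spacer index N7
GALK_EDIT_POS = 504

FASTA_WIDTH = 70


class ParseError(ValueError):
    """A sequence file could not be parsed."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence with optional CDS spans (1-based inclusive)."""

    id: str
    seq: str
    cds_spans: tuple[tuple[int, int], ...] = ()


def load_sequences(path: str | Path, fmt: str | None = None) -> list[SequenceRecord]:
    """Read FASTA or GenBank records, normalized to uppercase DNA.

    The format is inferred from the suffix (.gb/.gbk/.genbank → GenBank)
    unless given.  GenBank CDS feature spans are carried along so reading
    frames can be derived.  Empty or malformed files raise ParseError.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            cds = []
            for feat in getattr(rec, "features", []):
                if feat.type == "CDS":
                    cds.append((int(feat.location.start) + 1, int(feat.location.end)))
            records.append(
                SequenceRecord(id=rec.id, seq=dna(str(rec.seq)), cds_spans=tuple(cds))
            )
    except (ValueError, KeyError) as exc:
        raise ParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not records:
        raise ParseError(f"no sequence records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, 70-column lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), FASTA_WIDTH):
                fh.write(rec.seq[i : i + FASTA_WIDTH] + "\n")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic fixture generator.

    ``n_genes`` genes of ``gene_length`` nt at GC fraction ``gc`` each carry
    one planted protospacer+PAM (random strand) with an edit site at spacer
    index ``edit_k`` (N11 by default, the genome-wide screen convention).
    Generation is deterministic in ``seed``.  ``include_galk`` prepends the
    galK-like worked-example gene (edit site N7 at position 504).
    """

    n_genes: int = 16
    gene_length: int = 1000
    gc: float = 0.5
    edit_k: int = 11
    seed: int = 0
    include_galk: bool = True

    def __post_init__(self) -> None:
        if self.gene_length < SPACER_LEN + 3:
            raise ValueError("gene_length too short to hold a target")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if not 1 <= self.edit_k <= SPACER_LEN:
            raise ValueError("edit_k must be a spacer index 1..20")


@dataclass(frozen=True)
class Fixture:
    records: tuple[SequenceRecord, ...]
    truth: pd.DataFrame


TRUTH_COLUMNS = [
    "gene_id",
    "start",
    "end",
    "strand",
    "spacer",
    "pam",
    "edit_pos",
    "edit_k",
]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _plant(seq: list[str], insert: str, start0: int) -> None:
    seq[start0 : start0 + len(insert)] = list(insert)


def _galk_gene(rng: np.random.Generator, length: int, gc: float) -> SequenceRecord:
    length = max(length, GALK_SPACER_START - 1 + SPACER_LEN + 3 + 40)
    seq = list(_random_seq(rng, length, gc))
    _plant(seq, GALK_SPACER + GALK_PAM, GALK_SPACER_START - 1)
    return SequenceRecord(id="galK_like", seq=dna("".join(seq)), cds_spans=((1, length // 3 * 3),))


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate synthetic genes with planted protospacers and a truth table.

    Each gene embeds one spacer+NGG PAM verbatim at recorded coordinates; if
    the random background happens to contain a second copy of a planted
    spacer, the gene is regenerated with a warning so truth rows stay
    unambiguous.  Byte-identical output for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    rows: list[dict] = []

    if spec.include_galk:
        gene = _galk_gene(rng, spec.gene_length, spec.gc)
        rows.append(
            {
                "gene_id": gene.id,
                "start": GALK_SPACER_START,
                "end": GALK_SPACER_START + SPACER_LEN - 1,
                "strand": "+",
                "spacer": GALK_SPACER,
                "pam": GALK_PAM,
                "edit_pos": GALK_EDIT_POS,
                "edit_k": GALK_EDIT_POS - GALK_SPACER_START + 1,
            }
        )
        records.append(gene)

    for gi in range(spec.n_genes):
        gene_id = f"gene{gi + 1:02d}"
        for attempt in range(20):
            seq = list(_random_seq(rng, spec.gene_length, spec.gc))
            spacer = _random_seq(rng, SPACER_LEN, spec.gc)
            pam = str(rng.choice(list("ACGT"))) + "GG"
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                # spacer at [start, start+19], PAM just 3' of it
                start = int(rng.integers(1, spec.gene_length - SPACER_LEN - 3 + 2))
                _plant(seq, spacer + pam, start - 1)
            else:
                # forward strand reads revcomp(PAM) then revcomp(spacer)
                start = int(rng.integers(4, spec.gene_length - SPACER_LEN + 2))
                _plant(seq, revcomp(spacer + pam), start - 4)
            gene_seq = dna("".join(seq))
            hits = [
                t
                for t in find_protospacers(gene_seq, gene_id)
                if t.spacer == spacer
            ]
            planted = [
                t for t in hits if t.start == start and t.strand == strand
            ]
            if len(planted) == 1 and len(hits) == 1:
                break
            warnings.warn(f"{gene_id}: planted target collision; regenerating")
        else:
            raise RuntimeError(f"could not plant a unique target in {gene_id}")
        edit_pos = start + spec.edit_k - 1 if strand == "+" else start + SPACER_LEN - spec.edit_k
        rows.append(
            {
                "gene_id": gene_id,
                "start": start,
                "end": start + SPACER_LEN - 1,
                "strand": strand,
                "spacer": spacer,
                "pam": pam,
                "edit_pos": edit_pos,
                "edit_k": spec.edit_k,
            }
        )
        records.append(SequenceRecord(id=gene_id, seq=gene_seq))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return Fixture(records=tuple(records), truth=truth)


def write_fixture(fix: Fixture, fasta_path: str | Path, truth_path: str | Path) -> None:
    """Write a fixture as FASTA + tab-separated truth table ('.' for missing)."""
    write_fasta(fix.records, fasta_path)
    fix.truth.to_csv(truth_path, sep="\t", index=False, na_rep=".")
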