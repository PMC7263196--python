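"""Design mutagenic recombineering oligos, including premature-stop edits.

Enumerates the substitutions that turn galK codon 168 (TGT, positions
502-504) into a stop codon, then builds the ssDNA oligo for the classic
single-base version, T504A.
"""

import warnings

from pinpoint import design_oligo, stop_codon_edits
from pinpoint.fixtures import FixtureSpec, make_fixture

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    gene = make_fixture(FixtureSpec(n_genes=0, seed=0)).records[0]

codon = gene.seq[501:504]
print(f"galK codon 168 = {codon} (positions 502-504)")
for e in stop_codon_edits(codon, max_changes=3, first_codon_number=168):
    subs = ", ".join(f"pos{p} {r}->{a}" for p, r, a in e.substitutions)
    print(f"  {e.codon_before} -> {e.codon_after}  ({e.n_changed} change(s): {subs})")

d = design_oligo(gene.seq, 504, "T", "A", arm=35)
print(f"\nT504A oligo ({len(d.sequence)}-mer, span {d.start}..{d.end}, strand {d.strand}):")
print(d.sequence)

# The single-change design (T->A at codon position 3, i.e. genomic T504A)
# creates TGA; with 35-nt homology arms the oligo is a standard 71-mer.
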