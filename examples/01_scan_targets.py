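"""Scan a sequence for SpCas9 targets (20-nt spacer + NGG PAM) on both strands.

Builds a small synthetic gene carrying the galK protospacer at positions
498-517 and lists every target covering the classic edit site, position 504.
"""

import warnings

from pinpoint import find_protospacers, spacer_index, targets_covering
from pinpoint.fixtures import FixtureSpec, make_fixture

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    gene = make_fixture(FixtureSpec(n_genes=0, seed=0)).records[0]

targets = find_protospacers(gene.seq, gene.id)
print(f"{gene.id}: {len(gene.seq)} nt, {len(targets)} Cas9 targets on both strands")

for t in targets_covering(targets, 504):
    si = spacer_index(t, 504)
    print(f"  {t.start}..{t.end} ({t.strand})  spacer={t.spacer}  PAM={t.pam}"
          f"  -> position 504 is N{si.k} ({si.region})")

# Position 504 maps to spacer index N7 of the 498-517 target: the edit sits
# in the PAM-distal half, where mismatched-guide selection still works.
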