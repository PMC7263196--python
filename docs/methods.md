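# Methods

## Coordinate and pairing conventions

All genomic coordinates are 1-based inclusive. A protospacer is the 20-nt
PAM-strand sequence N1..N20 with N20 adjacent to the 5'-NGG PAM; scanning is
exhaustive over both strands and reports every overlapping hit (off-target
uniqueness filtering is deliberately out of scope). On the "−" strand the
reported spacer is the reverse complement of the input slice and N1 sits at
the higher coordinate. `N` in input sequences matches nothing; only the
PAM pattern's first position is a wildcard.

Spacer positions N13–N20 are tagged PAM-proximal and N1–N12 PAM-distal.
Published single-mismatch designs behave equivalently at distal (N5–N9) and
proximal (N14–N18) positions, so the 12/13 boundary is a bookkeeping choice
between those two observed bands, carried as metadata and with no effect on
tiering.

Guide/target pairing uses the N′:N′′ convention: N′ is the non-PAM-strand
DNA base (the complement of the PAM-strand spacer base), N′′ the sgRNA base
at the same index. Pairs are labelled by purine/pyrimidine class
(`Pu:Pu`, `Py:Py`, `Pu:Py`, `Py:Pu`); A:U, T:A, G:C, C:G are Watson–Crick.
Wobble is flagged for both DNA:RNA orientations, dG:rU and dT:rG, and the
flag records which — published data only name "G:U" without fixing the
orientation, so neither is assumed ineffective alone; both are treated as
hybridizing and therefore unsuitable as the designed mispair.

## Guide enumeration, tiering and ranking

For a single-base edit at N_k, single-mismatch variants are enumerated at
N_{k+1} and N_{k−1} (3 replacement bases each) and, on request, contiguous
double-mismatch variants at {k+1, k+2} and {k−2, k−1} (9 combinations per
pair). The default listing order puts the PAM-proximal side (k+1) first,
matching the genome-wide convention of placing the mismatch immediately
after the edited base; the distal side is kept because both sides are known
to work. Straddling doubles (k−1 with k+1) are never generated: no
published design uses them. All replacement bases are enumerated — ranking,
not enumeration, encodes preference, so no design is silently discarded.

Tier assignment for a guide g against edit e, from the mismatch counts
vs the unedited target (`mm_u`) and the edited target (`mm_e`):

- `invalid` — `mm_e < 2`: edited cells are still cleaved; selection cannot
  work. The matched guide always lands here for a single-base edit.
- `not_recommended` — `mm_u ≥ 2` (unedited cells escape cleavage and
  selection collapses) or the designed pair is a wobble. Double-mismatch
  designs are generated but always land here: of four published doubles
  only one succeeded, so they are opt-in, not default.
- `recommended` — `mm_u = 1`, `mm_e ≥ 2`, designed pair Py:Py or Pu:Pu,
  no wobble.
- `moderate` — as recommended but with an unlike-class (Py:Pu/Pu:Py)
  designed pair.

The designed pair of a multi-mismatch guide is taken at the deliberate
mismatch closest to the edit. For a transversion edit every recommended
design yields two consecutive like-class mispairs on the edited target
(edit position + designed position), which is the empirically efficient
geometry; this follows from complementation flipping the purine/pyrimidine
class.

Single-mismatch guides carry an empirical prior: the observed single-base
editing frequency (percent) from a 16-target genome-wide screen, keyed by
(edit class, designed pairing): transversion — 43.7 for Py:Py and Pu:Pu,
15.6 Py:Pu, 9.3 Pu:Py; transition — 25 Pu:Pu, 6.3 Py:Py, 0 otherwise.
These are stored verbatim as ordinal weights, not calibrated
probabilities: the underlying denominators are not fully recoverable, and
the numbers are used only to order designs within a tier. Ranking is by
(tier, prior descending, fewer mismatches, proximal side first, name) —
stable, deterministic, permutation-invariant.

## Oligo and stop-codon design

Mutagenic oligos are left arm + substituted run (1–4 contiguous bases) +
right arm, with a hard failure if the reference disagrees with the stated
ref bases — a disagreement means the wrong sequence or coordinate and must
never be silently "fixed". The default arm is 35 nt per side (a ~70-mer),
the ssDNA-recombineering norm; arm length and strand are configurable and
lagging-strand choice is out of scope. Premature-stop enumeration brute
forces, per codon, every substitution set of size ≤ `max_changes` reaching
TAA/TAG/TGA, minimal sets first; codons already terminating are skipped
with a warning. Edits crossing codon boundaries are reported per affected
codon.

## Experiment plan and statistics

The combinatorial plan crosses, per target, the three alternative-base
oligos (A→G/T/C, T→G/A/C, G→A/T/C, C→G/A/T) with a guide panel
(conventionally 1 matched + 3 mismatched). Because exactly one alternative
of any base is a transition, oligo rows always split 1/3 : 2/3
transition : transversion — 64/128 at 16 targets × 4 guides.

Editing efficiency is white/(white+red) with a Wilson score 95% interval;
Wilson is preferred over Wald (degenerate at 0/1) and is cross-checked
against Clopper–Pearson in the tests. Replicate-level mean ± sd is emitted
when ≥2 replicates are supplied. Survival is colonies × dilution / µg DNA
with the dilution bookkeeping explicit. Success tables count an
electroporation successful when ≥ `success_threshold` (default 1) of its
sequenced colonies carry the edit, and report percentages under both
denominators — electroporations and colonies — because either convention is
defensible.

## Selection simulator

The generative model is the minimal scaffolding consistent with the
observed selection behaviour, not a mechanistic Cas9 model. Per cell:
oligo incorporated with probability `lam`; Cas9 non-functional (escape)
with probability `eps`; otherwise killed iff cleaved, with probability
`c(m)` depending only on the guide/target mismatch count m ∈ {0, 1, 2+}.
Cleavage depends on count only, not position or pairing class — a
pairing-class-dependent c(m) is a documented extension hook. Defaults:
`eps = 1e-5` (the observed ~1-in-10⁵ escape subpopulation that survives
selection without editing), `lam = 0.05` (a typical ssDNA recombineering
frequency; no published value exists for this system), `c = (1, 1, 0)`
(full tolerance of one mismatch, none of two). Both parameters are echoed
in every report. Plating dilution is a binomial thinning after selection.
Absolute CFU values are not reproducible — total cell input is unknown —
so the simulator is used for ratios and efficiencies only.

Survivor counts are sampled as chained binomials (exactly equivalent to
per-cell Bernoulli draws), giving white (edited) and red (unedited)
survivors; closed-form expectations
E[white] = n·lam·(eps + (1−eps)(1−c(m_e))) etc. serve as the cross-check,
with the reported expected efficiency being the ratio of expectations
(the large-n limit). Two regimes frame the method: a matched guide under
full tolerance has expected efficiency = lam (selection-blind), while a
single-mismatch guide with c(2+)=0 reaches
lam/(lam + (1−lam)·eps) ≈ 0.9998 at the defaults.

Parameter recovery maximizes a composite likelihood — white ~
Bin(n, lam·s_e), red ~ Bin(n, (1−lam)·s_u), their weak coupling through the
shared edited count ignored (negligible at these n) — on log-spaced
(lam, eps) grids with two local refinement passes. Grid search is chosen
over gradient methods deliberately: it is deterministic and robust when
eps sits many orders of magnitude below lam. Profile intervals
(1.92 log-likelihood drop) are read off the coarse global grid and are
therefore at least one grid step wide; with very informative data they can
collapse to a single grid point. Recovery requires designs with at least
two distinct (c(m_edited), c(m_unedited)) structures — e.g. one selective
and one matched design — otherwise a non-identifiability error is raised;
an eps maximized at the grid floor (1e-9) is flagged as boundary-limited
rather than estimated.

## Synthetic fixtures

The fixture generator emulates a genome-wide screen: n random genes
(default 16 × 1 kb at GC 0.5), each with one planted spacer+NGG target on a
random strand and an edit site at N11 (the genome-wide placement
convention), plus a galK-like gene carrying the real galK protospacer at
498–517 with a synthetic PAM (TGG; the genomic PAM is not printed in any
public source) and a reading frame that puts codon 168 (TGT) at 502–504,
so the T504A worked example holds verbatim. Planting is rejected and
retried (with a warning) if the random background duplicates the spacer,
so truth rows are unambiguous; output is byte-identical for a fixed seed.
What fixtures do not emulate: real sequence composition, chromosomal
context, gene essentiality, and target-to-target variability in editability
— passing the closed-loop tests shows the design machinery is coherent,
not that any particular genomic locus will edit.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale: oracle-equivalence
suites use ≥1000 random instances; simulator checks use 10⁶ cells × 100
replicates (Monte-Carlo agreement within 3 standard errors) and 2 designs
× 10 replicates for recovery (lam within ±20% relative error). These sizes
make the whole suite complete in seconds while keeping Monte-Carlo error
far below the margins tested. All randomness flows through explicit numpy
Generator seeds; ties in ranking break lexicographically by guide name for
reproducibility.
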