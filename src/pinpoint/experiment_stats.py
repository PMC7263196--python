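"""Combinatorial electroporation planning and colony-count statistics.

A genome-wide single-base editing screen crosses, per target, the three
alternative-base mutagenic oligos (A→G/T/C, T→G/A/C, G→A/T/C, C→G/A/T)
with a guide panel (conventionally one matched sgRNA plus three
single-mismatched sgRNAs).  Sixteen targets × 3 oligos × 4 guides gives the
192-electroporation design; because exactly one of the three alternatives
of any base is a transition, the oligo rows always split 1/3 transition to
2/3 transversion (64/128 at 16 targets).

Editing efficiency is the fraction of white (edited, loss-of-function)
colonies among white + red on indicator plates; selection stringency is
measured as surviving CFU per µg of transformed DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .seqcore import classify_substitution, dna

__all__ = [
    "GuidePlanSpec",
    "TargetPlanSpec",
    "EfficiencyEstimate",
    "build_plan",
    "default_guide_panel",
    "tally_edit_classes",
    "efficiency",
    "replicate_summary",
    "survival_rate",
    "success_table",
]

PLAN_COLUMNS = [
    "target",
    "oligo",
    "ref",
    "alt",
    "edit_class",
    "guide",
    "pairing",
    "wobble",
]


@dataclass(frozen=True)
class GuidePlanSpec:
    """One guide in the per-target panel: its id, designed N′:N′′ pairing label
    ('.' for the matched guide) and wobble flag."""

    guide_id: str
    pairing: str = "."
    wobble: bool = False


@dataclass(frozen=True)
class TargetPlanSpec:
    """Per-target plan input: the reference base at the edit site, the
    alternative bases to attempt (default: all three), and the guide panel."""

    target_id: str
    ref_base: str
    alt_bases: tuple[str, ...] = ()
    guides: tuple[GuidePlanSpec, ...] = ()

    def resolved_alts(self) -> tuple[str, ...]:
        if self.alt_bases:
            return self.alt_bases
        return tuple(b for b in "ACGT" if b != dna(self.ref_base))


def default_guide_panel(target_id: str) -> tuple[GuidePlanSpec, ...]:
    """The conventional 4-guide panel: 1 matched + 3 mismatched placeholders."""
    return (
        GuidePlanSpec(f"{target_id}:matched", ".", False),
        *(GuidePlanSpec(f"{target_id}:mm{i}", ".", False) for i in (1, 2, 3)),
    )


def build_plan(targets: Sequence[TargetPlanSpec]) -> pd.DataFrame:
    """Full electroporation cross product: per target, oligos × guides.

    Each row records the oligo's substitution (ref→alt, with its
    transition/transversion class) and the guide's designed pairing label.
    Row count is Σ_targets (oligos × guides).
    """
    if not targets:
        raise ValueError("empty plan specification")
    rows = []
    for t in targets:
        ref = dna(t.ref_base)
        guides = t.guides or default_guide_panel(t.target_id)
        for alt in t.resolved_alts():
            alt = dna(alt)
            oligo_id = f"{t.target_id}:{ref}>{alt}"
            cls = classify_substitution(ref, alt)
            for g in guides:
                rows.append(
                    {
                        "target": t.target_id,
                        "oligo": oligo_id,
                        "ref": ref,
                        "alt": alt,
                        "edit_class": cls,
                        "guide": g.guide_id,
                        "pairing": g.pairing,
                        "wobble": g.wobble,
                    }
                )
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def tally_edit_classes(plan: pd.DataFrame) -> tuple[int, int]:
    """(transition rows, transversion rows) of a plan; sums to len(plan)."""
    counts = plan["edit_class"].value_counts()
    return int(counts.get("transition", 0)), int(counts.get("transversion", 0))


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Editing efficiency white/(white+red) with a Wilson 95% interval."""

    point: float
    ci_low: float
    ci_high: float
    n: int


def efficiency(white: int, red: int) -> EfficiencyEstimate:
    """Editing efficiency from colony counts, with a Wilson score 95% CI."""
    if white < 0 or red < 0:
        raise ValueError("colony counts must be non-negative")
    n = white + red
    if n == 0:
        raise ValueError("efficiency undefined: no colonies counted")
    lo, hi = proportion_confint(white, n, alpha=0.05, method="wilson")
    return EfficiencyEstimate(point=white / n, ci_low=float(lo), ci_high=float(hi), n=n)


def replicate_summary(counts: Sequence[tuple[int, int]]) -> dict:
    """Mean ± sd of per-replicate efficiencies (for >=2 independent platings)."""
    if len(counts) < 1:
        raise ValueError("need at least one replicate")
    effs = np.array([efficiency(w, r).point for w, r in counts])
    return {
        "mean": float(effs.mean()),
        "sd": float(effs.std(ddof=1)) if len(effs) > 1 else float("nan"),
        "n_replicates": len(effs),
    }


def survival_rate(
    colonies_total: int, dna_mass_ug: float, dilution_factor: float = 1.0
) -> float:
    """Surviving CFU per µg of transformed DNA, with explicit dilution bookkeeping."""
    if dna_mass_ug <= 0:
        raise ValueError("DNA mass must be positive")
    if colonies_total < 0 or dilution_factor <= 0:
        raise ValueError("counts must be >=0 and dilution factor positive")
    return colonies_total * dilution_factor / dna_mass_ug


def success_table(
    records: pd.DataFrame, success_threshold: int = 1
) -> pd.DataFrame:
    """Editing-success frequencies by (edit_class, designed pairing).

    ``records`` needs columns ``edit_class``, ``pairing``, ``n_sequenced``,
    ``n_edited`` (colonies sequenced / confirmed edited per electroporation).
    An electroporation is a success when at least ``success_threshold`` of
    its sequenced colonies carry the edit.  Percentages are reported with
    both denominators — electroporations and sequenced colonies — since
    either convention is defensible.
    """
    required = {"edit_class", "pairing", "n_sequenced", "n_edited"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["n_edited"] > records["n_sequenced"]).any():
        raise ValueError("n_edited cannot exceed n_sequenced")
    rec = records.copy()
    rec["success"] = rec["n_edited"] >= success_threshold
    grouped = rec.groupby(["edit_class", "pairing"], sort=True)
    out = grouped.agg(
        attempts=("success", "size"),
        successes=("success", "sum"),
        colonies_sequenced=("n_sequenced", "sum"),
        colonies_edited=("n_edited", "sum"),
    ).reset_index()
    out["pct_of_electroporations"] = 100.0 * out["successes"] / out["attempts"]
    out["pct_of_colonies"] = np.where(
        out["colonies_sequenced"] > 0,
        100.0 * out["colonies_edited"] / out["colonies_sequenced"],
        0.0,
    )
    return out


def edit_class_marginals(table: pd.DataFrame) -> pd.DataFrame:
    """Marginal success counts of a :func:`success_table` result by edit class."""
    marg = table.groupby("edit_class", sort=True).agg(
        attempts=("attempts", "sum"),
        successes=("successes", "sum"),
    ).reset_index()
    marg["pct_of_electroporations"] = 100.0 * marg["successes"] / marg["attempts"]
    return marg
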