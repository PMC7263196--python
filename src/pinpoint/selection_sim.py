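"""Stochastic simulator of recombineering followed by Cas9 negative selection.

The generative model is deliberately minimal scaffolding for design
evaluation; it is not a mechanistic model of Cas9 kinetics.  Per cell:

* the mutagenic oligo is incorporated with probability ``lam``
  (the recombineering frequency);
* with probability ``eps`` the cell belongs to the escape subpopulation in
  which CRISPR-Cas9 is non-functional (~1e-5 of cells in practice) and
  survives regardless;
* otherwise the cell is killed iff its target is cleaved, with probability
  ``c(m)`` depending only on the number of guide/target mismatches
  m ∈ {0, 1, 2+}.  Mismatch tolerance means c(0) ≈ c(1) ≈ 1 while
  c(2+) ≈ 0 — the default map.

Edited cells carry ``m_edited`` mismatches against the guide, unedited
cells ``m_unedited`` (both obtained from guide annotation).  Survivor counts
give white (edited) and red (unedited) colonies and hence the simulated
editing efficiency white/(white+red).  Closed-form expectations are
available for cross-checking, and ``recover_params`` estimates (lam, eps)
from simulated or observed colony counts by grid maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SimParams",
    "SimOutcome",
    "ExpectedOutcome",
    "ParamEstimate",
    "NonIdentifiableError",
    "cleavage_prob",
    "simulate",
    "expected_outcome",
    "recover_params",
]


class NonIdentifiableError(ValueError):
    """The design set cannot separate recombineering frequency from escape rate."""


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SimParams:
    """Population size, recombineering frequency, escape rate and cleavage map.

    ``cleave`` maps mismatch count m ∈ {0, 1, 2} (2 meaning "2 or more") to
    the cleavage probability c(m); it must be non-increasing in m, encoding
    decaying mismatch tolerance.
    """

    n_cells: int = 1_000_000
    lam: float = 0.05
    eps: float = 1e-5
    cleave: tuple[float, float, float] = (1.0, 1.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        _check_prob("lam", self.lam)
        _check_prob("eps", self.eps)
        if len(self.cleave) != 3:
            raise ValueError("cleave must give c(0), c(1), c(2+)")
        for m, c in enumerate(self.cleave):
            _check_prob(f"cleave[{m}]", c)
        if not (self.cleave[0] >= self.cleave[1] >= self.cleave[2]):
            raise ValueError("cleavage probability must be non-increasing in mismatches")


def cleavage_prob(cleave: Sequence[float], m: int) -> float:
    """c(m) with m capped at 2 ("2 or more mismatches")."""
    if m < 0:
        raise ValueError("mismatch count must be >= 0")
    return float(cleave[min(m, 2)])


def _survival_probs(params: SimParams, m_edited: int, m_unedited: int) -> tuple[float, float]:
    """Per-cell survival probability for (edited, unedited) cells."""
    ce = cleavage_prob(params.cleave, m_edited)
    cu = cleavage_prob(params.cleave, m_unedited)
    s_e = params.eps + (1.0 - params.eps) * (1.0 - ce)
    s_u = params.eps + (1.0 - params.eps) * (1.0 - cu)
    return s_e, s_u


@dataclass(frozen=True)
class SimOutcome:
    """Survivor counts of one simulated electroporation (plating replicate)."""

    white: int
    red: int
    replicate: int = 0

    @property
    def survivors_total(self) -> int:
        return self.white + self.red

    @property
    def efficiency(self) -> float:
        """white/(white+red); NaN when no cell survived."""
        n = self.survivors_total
        return self.white / n if n else float("nan")


def simulate(
    params: SimParams,
    m_edited: int,
    m_unedited: int,
    n_reps: int = 1,
    plating_fraction: float = 1.0,
) -> list[SimOutcome]:
    """Simulate selection outcomes for one guide design.

    Equivalent to per-cell Bernoulli draws (edit incorporation, escape,
    cleavage) but sampled as chained binomials for speed.  A
    ``plating_fraction`` < 1 thins survivors binomially, modelling
    dilution before plating.  Reproducible given ``params.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _check_prob("plating_fraction", plating_fraction)
    s_e, s_u = _survival_probs(params, m_edited, m_unedited)
    rng = np.random.default_rng(params.seed)
    out = []
    for rep in range(n_reps):
        n_edited = rng.binomial(params.n_cells, params.lam)
        white = rng.binomial(n_edited, s_e)
        red = rng.binomial(params.n_cells - n_edited, s_u)
        if plating_fraction < 1.0:
            white = rng.binomial(white, plating_fraction)
            red = rng.binomial(red, plating_fraction)
        out.append(SimOutcome(white=int(white), red=int(red), replicate=rep))
    return out


@dataclass(frozen=True)
class ExpectedOutcome:
    white: float
    red: float
    efficiency: float


def expected_outcome(
    params: SimParams, m_edited: int, m_unedited: int
) -> ExpectedOutcome:
    """Closed-form expectations of the simulator.

    E[white] = n·lam·(eps + (1−eps)(1−c(m_e))), analogously for red; the
    efficiency reported is the ratio of expectations E[w]/(E[w]+E[r]),
    which is the large-n limit of E[w/(w+r)].
    """
    s_e, s_u = _survival_probs(params, m_edited, m_unedited)
    ew = params.n_cells * params.lam * s_e
    er = params.n_cells * (1.0 - params.lam) * s_u
    eff = ew / (ew + er) if ew + er > 0 else float("nan")
    return ExpectedOutcome(white=ew, red=er, efficiency=eff)


@dataclass(frozen=True)
class ParamEstimate:
    """Grid maximum-likelihood estimates of (lam, eps) with profile intervals."""

    lam: float
    eps: float
    lam_interval: tuple[float, float]
    eps_interval: tuple[float, float]
    log_likelihood: float
    eps_at_lower_bound: bool = False


_EPS_FLOOR = 1e-9


def _loglik_grid(
    lam_grid: np.ndarray,
    eps_grid: np.ndarray,
    designs: Sequence[tuple[int, int]],
    outcomes: Sequence[Sequence[SimOutcome]],
    n_cells: int,
    cleave: Sequence[float],
) -> np.ndarray:
    """Composite log-likelihood on the (lam, eps) grid.

    White and red survivor counts are each marginally binomial
    (white ~ Bin(n, lam·s_e), red ~ Bin(n, (1−lam)·s_u)); their weak
    dependence through the shared edited count is ignored, which is
    negligible at the population sizes simulated here.
    """
    L = lam_grid[:, None]  # (n_lam, 1)
    E = eps_grid[None, :]  # (1, n_eps)
    ll = np.zeros((lam_grid.size, eps_grid.size))
    for (m_e, m_u), reps in zip(designs, outcomes):
        ce = cleavage_prob(cleave, m_e)
        cu = cleavage_prob(cleave, m_u)
        s_e = E + (1.0 - E) * (1.0 - ce)
        s_u = E + (1.0 - E) * (1.0 - cu)
        p_w = np.clip(L * s_e, 1e-300, 1.0)
        p_r = np.clip((1.0 - L) * s_u, 1e-300, 1.0)
        for o in reps:
            ll += stats.binom.logpmf(o.white, n_cells, p_w)
            ll += stats.binom.logpmf(o.red, n_cells, p_r)
    return ll


def recover_params(
    designs: Sequence[tuple[int, int]],
    outcomes: Sequence[Sequence[SimOutcome]],
    n_cells: int,
    cleave: Sequence[float] = (1.0, 1.0, 0.0),
    n_grid: int = 41,
    n_refine: int = 2,
) -> ParamEstimate:
    """Maximum-likelihood (lam, eps) from outcomes of >=2 guide designs.

    ``designs`` gives the (m_edited, m_unedited) mismatch counts of each
    design; ``outcomes`` the matching replicate lists.  Estimation is a
    log-spaced grid search with local grid refinement — deterministic and
    robust for eps values many orders of magnitude below lam.  Profile
    1.92-log-likelihood intervals are read off the final grid.

    Raises :class:`NonIdentifiableError` when every design induces the same
    (c(m_edited), c(m_unedited)) pair, since then no contrast separates
    recombineering frequency from escape.
    """
    if len(designs) != len(outcomes):
        raise ValueError("designs and outcomes must align")
    if len(designs) < 2:
        raise NonIdentifiableError("need outcomes from at least two guide designs")
    cpairs = {
        (cleavage_prob(cleave, m_e), cleavage_prob(cleave, m_u))
        for m_e, m_u in designs
    }
    if len(cpairs) < 2:
        raise NonIdentifiableError(
            "all designs share the same cleavage structure; include one design "
            "under selection and one without"
        )

    # global coarse grid: intervals and boundary diagnosis are read off this one
    lam_grid0 = np.geomspace(1e-4, 0.9, n_grid)
    eps_grid0 = np.geomspace(_EPS_FLOOR, 0.1, n_grid)
    ll0 = _loglik_grid(lam_grid0, eps_grid0, designs, outcomes, n_cells, cleave)
    i, j = np.unravel_index(np.argmax(ll0), ll0.shape)
    eps_at_bound = j == 0
    best0 = ll0[i, j]
    lam_prof = ll0.max(axis=1)
    eps_prof = ll0.max(axis=0)
    lam_ok = lam_grid0[lam_prof >= best0 - 1.92]
    eps_ok = eps_grid0[eps_prof >= best0 - 1.92]

    # local refinement around the coarse argmax for the point estimates
    lam_lo = lam_grid0[max(i - 1, 0)]
    lam_hi = lam_grid0[min(i + 1, n_grid - 1)]
    eps_lo = eps_grid0[max(j - 1, 0)]
    eps_hi = eps_grid0[min(j + 1, n_grid - 1)]
    lam_grid, eps_grid, ll = lam_grid0, eps_grid0, ll0
    for _ in range(n_refine):
        lam_grid = np.geomspace(lam_lo, lam_hi, n_grid)
        eps_grid = np.geomspace(eps_lo, eps_hi, n_grid)
        ll = _loglik_grid(lam_grid, eps_grid, designs, outcomes, n_cells, cleave)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        lam_lo = lam_grid[max(i - 1, 0)]
        lam_hi = lam_grid[min(i + 1, n_grid - 1)]
        eps_lo = eps_grid[max(j - 1, 0)]
        eps_hi = eps_grid[min(j + 1, n_grid - 1)]

    return ParamEstimate(
        lam=float(lam_grid[i]),
        eps=float(eps_grid[j]),
        lam_interval=(float(lam_ok.min()), float(lam_ok.max())),
        eps_interval=(float(eps_ok.min()), float(eps_ok.max())),
        log_likelihood=float(ll[i, j]),
        eps_at_lower_bound=eps_at_bound,
    )
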