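"""Poisson-binomial model for photobleaching step counts in membrane vesicles.

A vesicle receives ``K ~ Poisson(lam)`` protein complexes, each built from
``m`` fluorescent-protein subunits.  Every subunit is detectably fluorescent
with independent probability ``p`` (the fluorescence detection efficiency,
FDE), so the number of photobleaching steps observed for one vesicle is

    S | K  ~  Binomial(K * m, p),        K ~ Poisson(lam).

This module evaluates the marginal distribution of ``S`` by truncated series
summation, exposes the closed-form empty/dark-vesicle fractions, and carries
the geometric side calculations (vesicle yield per cell, complexes per cell)
used to place the fitted Poisson mean on a per-cell scale.

All fractions are returned in [0, 1]; percentage formatting is the caller's
concern.  No file I/O happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "OligomerModel",
    "StepPMF",
    "CellGeometry",
    "CONDITION_1_TO_SMAX",
    "CONDITION_GE1",
    "poisson_truncation_order",
    "step_count_pmf",
    "step_count_pmf_grid",
    "detected_step_distribution",
    "empty_vesicle_fraction",
    "dark_vesicle_fraction",
    "predicted_visible_fraction",
    "binomial_step_pmf",
    "imv_yield_per_cell",
    "complexes_per_cell",
]

#: Normalisation conventions for the detected (s >= 1) step distribution.
#: ``CONDITION_1_TO_SMAX`` conditions on the spot being analyzable, i.e. on
#: 1 <= S <= s_max, so that censored (> s_max) spots are excluded from both
#: the data and the model.  ``CONDITION_GE1`` conditions only on S >= 1.
CONDITION_1_TO_SMAX = "condition_1_to_smax"
CONDITION_GE1 = "condition_ge1"

_CONVENTIONS = (CONDITION_1_TO_SMAX, CONDITION_GE1)


@dataclass(frozen=True)
class OligomerModel:
    """One candidate stoichiometry model.

    Parameters
    ----------
    m : int
        Subunits (fluorophore fusions) per complex, >= 1.
    lam : float
        Poisson mean number of complexes per vesicle, > 0.
    p : float
        Fluorescence detection efficiency in (0, 1].
    s_max : int
        Largest analyzable step bin; spots with more steps are censored.
    """

    m: int
    lam: float
    p: float
    s_max: int = 8

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m}")
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if not 0 < self.p <= 1:
            raise ValueError(f"p (FDE) must be in (0, 1], got {self.p}")
        if int(self.s_max) != self.s_max or self.s_max < 1:
            raise ValueError(f"s_max must be an integer >= 1, got {self.s_max}")


@dataclass(frozen=True)
class StepPMF:
    """Marginal pmf of the observed step count S, with its truncation bound.

    ``probs[s]`` is P(S = s) for s = 0..len(probs)-1; ``truncation_error``
    bounds the Poisson tail mass omitted when the series over the number of
    complexes K was cut at a finite order.
    """

    probs: np.ndarray
    truncation_error: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if np.any(self.probs < -1e-15) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("pmf entries must lie in [0, 1]")
        if self.truncation_error < 0:
            raise ValueError("truncation_error must be >= 0")


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder cell and spherical vesicle dimensions, in micrometres."""

    cell_length: float
    cell_width: float
    vesicle_diameter: float

    def __post_init__(self) -> None:
        if not self.cell_width > 0:
            raise ValueError("cell_width must be > 0")
        if self.cell_length < self.cell_width:
            raise ValueError("cell_length must be >= cell_width (spherocylinder)")
        if not self.vesicle_diameter > 0:
            raise ValueError("vesicle_diameter must be > 0")


def poisson_truncation_order(lam: float, tol: float = 1e-9) -> tuple[int, float]:
    """Smallest K with Poisson upper-tail mass P(K' > K) <= tol.

    Returns ``(K, tail)`` where ``tail`` is the actual omitted mass bound.
    A hard cap at ``10*lam + 200`` guards against non-convergence from an
    invalid rate.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not 0 < tol <= 1e-6:
        raise ValueError("tol must be in (0, 1e-6]")
    hard_cap = int(10 * lam + 200)
    # isf gives a good starting point; walk to the exact smallest K.
    k = max(0, int(stats.poisson.isf(tol, lam)) - 2) if lam > 0 else 0
    while stats.poisson.sf(k, lam) > tol:
        k += 1
        if k > hard_cap:
            raise ValueError(f"Poisson series did not converge below cap for lam={lam}")
    return k, float(stats.poisson.sf(k, lam))


def step_count_pmf(
    model: OligomerModel,
    s_max_raw: int | None = None,
    k_tail_tol: float = 1e-9,
) -> StepPMF:
    """Marginal pmf of the observed step count S for one vesicle.

    Evaluates ``P(S=s) = sum_k Poisson(k; lam) * Binomial(s; k*m, p)`` with
    the Poisson series truncated at the smallest order whose omitted tail
    mass is <= ``k_tail_tol`` (recorded in the result).
    """
    if s_max_raw is None:
        s_max_raw = model.s_max
    if s_max_raw < 0:
        raise ValueError("s_max_raw must be >= 0")
    k_star, tail = poisson_truncation_order(model.lam, k_tail_tol)
    k = np.arange(k_star + 1)
    n = k * model.m
    s = np.arange(s_max_raw + 1)
    # binom.pmf(s, 0, p) is 1 at s=0 and 0 elsewhere, as required for K=0.
    b = stats.binom.pmf(s[None, :], n[:, None], model.p)
    w = stats.poisson.pmf(k, model.lam)
    return StepPMF(probs=w @ b, truncation_error=tail)


def step_count_pmf_grid(
    m: int,
    lams: np.ndarray,
    ps: np.ndarray,
    s_max: int,
    k_tail_tol: float = 1e-9,
) -> np.ndarray:
    """Vectorised ``step_count_pmf`` over parameter grids.

    Returns an array of shape ``(len(lams), len(ps), s_max + 1)`` with
    ``out[i, j, s] = P(S = s | m, lams[i], ps[j])``.  Shared by the grid
    optimiser in :mod:`stepstoich.fitting`.
    """
    lams = np.asarray(lams, dtype=float)
    ps = np.asarray(ps, dtype=float)
    if lams.size == 0 or ps.size == 0:
        raise ValueError("empty parameter grid")
    k_star, _ = poisson_truncation_order(float(lams.max()), k_tail_tol)
    k = np.arange(k_star + 1)
    n = k * m
    s = np.arange(s_max + 1)
    b = stats.binom.pmf(
        s[None, None, :], n[:, None, None], ps[None, :, None]
    )  # (K+1, P, S+1)
    w = stats.poisson.pmf(k[None, :], lams[:, None])  # (L, K+1)
    return np.einsum("lk,kps->lps", w, b)


def detected_step_distribution(
    model: OligomerModel, convention: str = CONDITION_1_TO_SMAX
) -> np.ndarray:
    """Expected fraction of analyzed spots in each step bin 1..s_max.

    ``condition_1_to_smax`` renormalises over bins 1..s_max (censored spots
    excluded from the denominator, mirroring how the data histogram is
    built); ``condition_ge1`` divides by P(S >= 1) so the fractions sum to
    <= 1 over the analyzable bins.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    pmf = step_count_pmf(model, s_max_raw=model.s_max)
    num = pmf.probs[1:]
    total = num.sum()
    if total <= 1e-12:
        raise ValueError("degenerate model: essentially no detectable spots")
    if convention == CONDITION_1_TO_SMAX:
        return num / total
    return num / (1.0 - pmf.probs[0])


def empty_vesicle_fraction(lam: float) -> float:
    """Probability a vesicle holds zero complexes: ``exp(-lam)``."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return math.exp(-lam)


def dark_vesicle_fraction(model: OligomerModel) -> float:
    """Probability a vesicle shows zero fluorophores: ``exp(-lam*(1-(1-p)^m))``.

    A vesicle is dark if it is empty or every subunit of every complex failed
    to mature; thinning the Poisson count of complexes by the per-complex
    visibility ``1 - (1-p)^m`` gives the closed form.  Equals
    :func:`empty_vesicle_fraction` when p = 1.
    """
    return math.exp(-model.lam * (1.0 - (1.0 - model.p) ** model.m))


def predicted_visible_fraction(model: OligomerModel) -> float:
    """Fraction of vesicles with at least one detectable fluorophore."""
    return 1.0 - dark_vesicle_fraction(model)


def binomial_step_pmf(n_total: int, p: float) -> np.ndarray:
    """Binomial pmf of visible subunits in a purified standard oligomer.

    For a standard of ``n_total`` fluorescent-protein domains with detection
    efficiency ``p``, returns P(s visible) for s = 0..n_total.
    """
    if int(n_total) != n_total or n_total < 1:
        raise ValueError("n_total must be an integer >= 1")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    return stats.binom.pmf(np.arange(n_total + 1), n_total, p)


def imv_yield_per_cell(geom: CellGeometry) -> float:
    """Number of vesicles one cell's membrane can supply, by area ratio.

    The cell is a spherocylinder (cylinder of length L - w and diameter w
    plus two hemispherical caps), whose surface area is ``pi * w * L``; each
    vesicle is a sphere of the stated diameter.  A 2 x 1 um cell and 100 nm
    vesicles give a ratio of 200.
    """
    if geom.vesicle_diameter > geom.cell_width:
        raise ValueError("vesicle cannot be larger than the cell width")
    area_cell = math.pi * geom.cell_width * geom.cell_length
    area_vesicle = math.pi * geom.vesicle_diameter**2
    return area_cell / area_vesicle


def complexes_per_cell(lam: float, yield_per_cell: float) -> float:
    """Average complexes per cell implied by a per-vesicle Poisson mean."""
    if lam < 0 or yield_per_cell < 0:
        raise ValueError("lam and yield_per_cell must be >= 0")
    return lam * yield_per_cell
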