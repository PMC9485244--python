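"""Censored-histogram fitting and oligomer-state selection.

The observed step histogram (bins 1..s_max, spots with more steps censored)
is compared with the expected Poisson-binomial step distribution under each
candidate stoichiometry m.  For every m the Poisson mean and the FDE are fit
by minimum root-mean-square deviation (RMSD) between observed and expected
bin fractions on a bounded grid with one local refinement pass, and the
stoichiometry with the smallest best-fit RMSD is selected (ties broken
toward smaller m, the parsimonious choice).  Purified-standard histograms,
where the subunit count is known, are fit with a single-parameter binomial
model to estimate the FDE alone.

Error bars on bin fractions come from multinomial Monte Carlo resampling of
N spots from the fitted expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import (
    CONDITION_1_TO_SMAX,
    CONDITION_GE1,
    OligomerModel,
    binomial_step_pmf,
    dark_vesicle_fraction,
    empty_vesicle_fraction,
    step_count_pmf_grid,
)

__all__ = [
    "StepHistogram",
    "LambdaPFit",
    "FitResult",
    "MonteCarloEnvelope",
    "DEFAULT_LAM_GRID",
    "DEFAULT_P_GRID",
    "histogram_from_step_calls",
    "correct_contaminants",
    "rmsd",
    "fit_lambda_p",
    "poisson_mean_scan",
    "fit_fde_binomial",
    "select_oligomer",
    "monte_carlo_envelope",
    "OligomerModelSelector",
    "BinomialFDEEstimator",
]

#: Default (start, stop, step) search grids.  The Poisson mean covers the
#: physically sensible sub-10-complexes-per-vesicle range; the FDE floor of
#: 0.30 is kept well below typical fluorescent-protein maturation
#: efficiencies so the data, not the prior, excludes low values.
DEFAULT_LAM_GRID = (0.05, 8.0, 0.05)
DEFAULT_P_GRID = (0.30, 1.00, 0.01)


@dataclass(frozen=True)
class StepHistogram:
    """Counts of analyzed spots per observed step number.

    ``counts[s-1]`` is the number of spots called with s steps, s = 1..s_max.
    Spots beyond s_max are censored: recorded in ``n_censored`` and excluded
    from the analyzed total.  ``contaminant_estimate`` is the expected number
    of single-step surface contaminants in this dataset; ``corrected`` marks
    whether bin 1 has already been reduced by it.
    """

    counts: np.ndarray
    n_censored: int = 0
    contaminant_estimate: float = 0.0
    corrected: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", arr)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("counts must be a 1-D vector of step bins")
        if np.any(arr < 0):
            raise ValueError("counts must be >= 0")
        if self.n_censored < 0 or self.contaminant_estimate < 0:
            raise ValueError("n_censored and contaminant_estimate must be >= 0")

    @property
    def s_max(self) -> int:
        return int(self.counts.size)

    @property
    def n_total_analyzed(self) -> float:
        return float(self.counts.sum())

    def fractions(self) -> np.ndarray:
        total = self.n_total_analyzed
        if total <= 0:
            raise ValueError("degenerate histogram: no analyzed spots")
        return self.counts / total


@dataclass(frozen=True)
class LambdaPFit:
    """Best-fit (Poisson mean, FDE) for one assumed stoichiometry."""

    m: int
    lam: float
    p: float
    rmsd: float
    at_boundary: bool


@dataclass(frozen=True)
class FitResult:
    """Per-stoichiometry fit table and the selected oligomer state.

    ``per_m_table`` has one row per candidate m with columns
    (m, lam, fde, rmsd, empty_fraction, dark_fraction, pred_1..pred_smax,
    at_boundary).  ``selected_m`` attains the minimum RMSD; ties break
    toward smaller m.
    """

    per_m_table: pd.DataFrame
    selected_m: int
    fit_bins: tuple[int, ...]
    convention: str

    @property
    def selected_row(self) -> pd.Series:
        return self.per_m_table.set_index("m").loc[self.selected_m]

    @property
    def lam(self) -> float:
        return float(self.selected_row["lam"])

    @property
    def fde(self) -> float:
        return float(self.selected_row["fde"])

    @property
    def rmsd(self) -> float:
        return float(self.selected_row["rmsd"])

    def predicted_fractions(self, m: int | None = None) -> np.ndarray:
        row = self.per_m_table.set_index("m").loc[m if m is not None else self.selected_m]
        cols = [c for c in self.per_m_table.columns if c.startswith("pred_")]
        return row[cols].to_numpy(dtype=float)


@dataclass(frozen=True)
class MonteCarloEnvelope:
    """Per-bin SD of histogram fractions under multinomial resampling."""

    per_bin_sd: np.ndarray
    n_trials: int
    seed: int | None

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_bin_sd, dtype=float)
        object.__setattr__(self, "per_bin_sd", arr)
        if np.any(arr < 0):
            raise ValueError("per_bin_sd must be >= 0")


def histogram_from_step_calls(
    calls: "pd.DataFrame",
    s_max: int = 8,
    contaminant_estimate: float = 0.0,
) -> StepHistogram:
    """Tally a step-call table into a StepHistogram.

    Uncallable traces are dropped; censored calls (n_steps > s_max) feed
    ``n_censored`` only.  ``contaminant_estimate`` is carried as metadata
    for a later bin-1 correction.
    """
    callable_mask = calls["n_steps"].notna()
    n = calls.loc[callable_mask, "n_steps"].astype(int)
    in_range = n[(n >= 1) & (n <= s_max)]
    counts = np.bincount(in_range, minlength=s_max + 1)[1 : s_max + 1]
    n_censored = int((n > s_max).sum())
    return StepHistogram(
        counts=counts.astype(float),
        n_censored=n_censored,
        contaminant_estimate=contaminant_estimate,
    )


def correct_contaminants(
    hist: StepHistogram, contaminant_count: float | None = None
) -> StepHistogram:
    """Subtract single-step surface contaminants from bin 1, floored at zero.

    ``contaminant_count`` defaults to the histogram's own estimate.  A
    histogram can only be corrected once.
    """
    if hist.corrected:
        raise ValueError("histogram is already contaminant-corrected")
    if contaminant_count is None:
        contaminant_count = hist.contaminant_estimate
    if contaminant_count < 0:
        raise ValueError("contaminant_count must be >= 0")
    counts = hist.counts.copy()
    counts[0] = max(0.0, counts[0] - contaminant_count)
    return replace(
        hist, counts=counts, contaminant_estimate=float(contaminant_count), corrected=True
    )


def rmsd(
    observed: np.ndarray,
    expected: np.ndarray,
    bins: Sequence[int] | None = None,
) -> float:
    """Root-mean-square deviation between fraction vectors.

    With ``bins`` given (1-based step-bin labels), both vectors are taken as
    full bin-1..s_max vectors and only the stated bins enter the mean.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if bins is not None:
        idx = np.asarray(list(bins), dtype=int) - 1
        if idx.size == 0:
            raise ValueError("empty bin set")
        if np.any(idx < 0) or np.any(idx >= obs.size):
            raise ValueError("bins out of range")
        obs, exp = obs[idx], exp[idx]
    if obs.size == 0:
        raise ValueError("empty bin set")
    return float(np.sqrt(np.mean((obs - exp) ** 2)))


def _grid_values(spec: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = spec
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


@lru_cache(maxsize=128)
def _expected_fraction_grid(
    m: int,
    s_max: int,
    convention: str,
    lam_spec: tuple[float, float, float],
    p_spec: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected bin-1..s_max fractions over a (lam, p) grid, cached.

    The grid depends only on the model, not the data, so it is shared
    across histograms and seeds.
    """
    lams = _grid_values(lam_spec)
    ps = _grid_values(p_spec)
    probs = step_count_pmf_grid(m, lams, ps, s_max)
    num = probs[..., 1:]
    if convention == CONDITION_1_TO_SMAX:
        frac = num / num.sum(axis=-1, keepdims=True)
    elif convention == CONDITION_GE1:
        frac = num / (1.0 - probs[..., :1])
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return lams, ps, frac


def _default_fit_bins(s_max: int) -> tuple[int, ...]:
    return tuple(range(2, s_max + 1))


def fit_lambda_p(
    hist: StepHistogram,
    m: int,
    fit_bins: Sequence[int] | None = None,
    convention: str = CONDITION_1_TO_SMAX,
    lam_grid: tuple[float, float, float] = DEFAULT_LAM_GRID,
    p_grid: tuple[float, float, float] = DEFAULT_P_GRID,
    pin_p: float | None = None,
    refine: bool = True,
) -> LambdaPFit:
    """Grid-minimum-RMSD fit of (Poisson mean, FDE) for one stoichiometry.

    Observed fractions use the analyzed total (bins 1..s_max) as
    denominator; both observed and expected vectors are then restricted to
    ``fit_bins`` (default 2..s_max, excluding the contaminant-prone first
    bin).  After the coarse grid argmin, one refinement pass re-searches a
    +/- one-cell neighbourhood at 10x finer resolution.  ``pin_p`` fixes the
    FDE (e.g. 1.0 for a maturation-free monomer scan).
    """
    if fit_bins is None:
        fit_bins = _default_fit_bins(hist.s_max)
    fit_bins = tuple(int(b) for b in fit_bins)
    if len(fit_bins) == 0:
        raise ValueError("empty fit_bins")
    obs_full = hist.fractions()
    if not np.any(hist.counts[[b - 1 for b in fit_bins]] > 0):
        raise ValueError("histogram has no counts in fit_bins")
    idx = np.asarray(fit_bins, dtype=int) - 1

    p_spec = (pin_p, pin_p, 1.0) if pin_p is not None else p_grid
    lams, ps, frac = _expected_fraction_grid(m, hist.s_max, convention, lam_grid, p_spec)
    r = np.sqrt(np.mean((frac[..., idx] - obs_full[idx]) ** 2, axis=-1))
    i, j = np.unravel_index(np.argmin(r), r.shape)
    lam_hat, p_hat, r_hat = float(lams[i]), float(ps[j]), float(r[i, j])

    if refine:
        lam_lo = max(lam_grid[0], lam_hat - lam_grid[2])
        lam_hi = min(lam_grid[1], lam_hat + lam_grid[2])
        lam_fine = np.linspace(lam_lo, lam_hi, 21)
        if pin_p is not None:
            p_fine = np.array([pin_p])
        else:
            p_lo = max(p_grid[0], p_hat - p_grid[2])
            p_hi = min(p_grid[1], p_hat + p_grid[2])
            p_fine = np.linspace(p_lo, p_hi, 21)
        probs = step_count_pmf_grid(m, lam_fine, p_fine, hist.s_max)
        num = probs[..., 1:]
        if convention == CONDITION_1_TO_SMAX:
            frac_fine = num / num.sum(axis=-1, keepdims=True)
        else:
            frac_fine = num / (1.0 - probs[..., :1])
        rf = np.sqrt(np.mean((frac_fine[..., idx] - obs_full[idx]) ** 2, axis=-1))
        i2, j2 = np.unravel_index(np.argmin(rf), rf.shape)
        if rf[i2, j2] <= r_hat:
            lam_hat, p_hat, r_hat = float(lam_fine[i2]), float(p_fine[j2]), float(rf[i2, j2])

    at_boundary = (
        math.isclose(lam_hat, lam_grid[0])
        or math.isclose(lam_hat, lam_grid[1])
        or (pin_p is None and (math.isclose(p_hat, p_grid[0]) or math.isclose(p_hat, p_grid[1])))
    )
    return LambdaPFit(m=m, lam=lam_hat, p=p_hat, rmsd=r_hat, at_boundary=at_boundary)


def poisson_mean_scan(
    hist: StepHistogram,
    m: int = 1,
    p: float = 1.0,
    fit_bins: Sequence[int] | None = None,
    convention: str = CONDITION_1_TO_SMAX,
    lam_grid: tuple[float, float, float] = DEFAULT_LAM_GRID,
) -> pd.DataFrame:
    """RMSD as a function of the Poisson mean at a pinned FDE.

    Reproduces the one-parameter scan used to show where the monomer model's
    optimum lies.  Returns a DataFrame with columns (lam, rmsd).
    """
    if fit_bins is None:
        fit_bins = _default_fit_bins(hist.s_max)
    idx = np.asarray(list(fit_bins), dtype=int) - 1
    obs_full = hist.fractions()
    lams, _, frac = _expected_fraction_grid(
        m, hist.s_max, convention, lam_grid, (p, p, 1.0)
    )
    r = np.sqrt(np.mean((frac[:, 0, idx] - obs_full[idx]) ** 2, axis=-1))
    return pd.DataFrame({"lam": lams, "rmsd": r})


def _binomial_fraction_grid(
    n_total: int, ps: np.ndarray, s_max: int, convention: str
) -> np.ndarray:
    """Expected bin-1..s_max fractions for a pure binomial standard."""
    from scipy import stats

    s = np.arange(s_max + 1)
    pmf = stats.binom.pmf(s[None, :], n_total, ps[:, None])  # (P, S+1)
    num = pmf[:, 1:]
    if convention == CONDITION_1_TO_SMAX:
        support = num[:, : min(n_total, s_max)].sum(axis=1, keepdims=True)
        return num / support
    if convention == CONDITION_GE1:
        return num / (1.0 - pmf[:, :1])
    raise ValueError(f"unknown convention {convention!r}")


def fit_fde_binomial(
    hist: StepHistogram,
    n_total: int,
    fit_bins: Sequence[int] | None = None,
    convention: str = CONDITION_1_TO_SMAX,
    p_grid: tuple[float, float, float] = DEFAULT_P_GRID,
    refine: bool = True,
) -> tuple[float, float]:
    """Single-parameter FDE fit for a purified standard of known size.

    The expected fractions are the binomial pmf of visible subunits,
    conditioned per ``convention``.  Default fit bins are 2..n_total for
    standards larger than a dimer and 1..n_total otherwise (a dimer fit on
    bin 2 alone would be degenerate, so the corrected bin 1 is used).
    Returns ``(p_hat, rmsd_hat)``.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if fit_bins is None:
        fit_bins = tuple(range(2, n_total + 1)) if n_total > 2 else tuple(
            range(1, n_total + 1)
        )
    fit_bins = tuple(int(b) for b in fit_bins)
    idx = np.asarray(fit_bins, dtype=int) - 1
    obs_full = hist.fractions()
    if np.any(idx >= hist.s_max):
        raise ValueError("fit_bins out of histogram range")

    ps = _grid_values(p_grid)
    frac = _binomial_fraction_grid(n_total, ps, hist.s_max, convention)
    r = np.sqrt(np.mean((frac[:, idx] - obs_full[idx]) ** 2, axis=-1))
    j = int(np.argmin(r))
    p_hat, r_hat = float(ps[j]), float(r[j])
    if refine:
        p_lo = max(p_grid[0], p_hat - p_grid[2])
        p_hi = min(p_grid[1], p_hat + p_grid[2])
        p_fine = np.linspace(p_lo, p_hi, 21)
        frac_fine = _binomial_fraction_grid(n_total, p_fine, hist.s_max, convention)
        rf = np.sqrt(np.mean((frac_fine[:, idx] - obs_full[idx]) ** 2, axis=-1))
        j2 = int(np.argmin(rf))
        if rf[j2] <= r_hat:
            p_hat, r_hat = float(p_fine[j2]), float(rf[j2])
    return p_hat, r_hat


def select_oligomer(
    hist: StepHistogram,
    m_range: Iterable[int] = range(1, 9),
    fit_bins: Sequence[int] | None = None,
    convention: str = CONDITION_1_TO_SMAX,
    lam_grid: tuple[float, float, float] = DEFAULT_LAM_GRID,
    p_grid: tuple[float, float, float] = DEFAULT_P_GRID,
    pin_p: float | None = None,
) -> FitResult:
    """Fit every candidate stoichiometry and select the minimum-RMSD model.

    Returns a :class:`FitResult` whose per-m table carries the best-fit
    parameters, RMSD, predicted bin fractions, and the empty- and
    dark-vesicle fractions implied by each fit.
    """
    m_values = [int(m) for m in m_range]
    if not m_values:
        raise ValueError("empty m_range")
    if fit_bins is None:
        fit_bins = _default_fit_bins(hist.s_max)
    rows = []
    for m in m_values:
        fit = fit_lambda_p(
            hist,
            m,
            fit_bins=fit_bins,
            convention=convention,
            lam_grid=lam_grid,
            p_grid=p_grid,
            pin_p=pin_p,
        )
        model = OligomerModel(m=m, lam=fit.lam, p=fit.p, s_max=hist.s_max)
        from .model import detected_step_distribution

        pred = detected_step_distribution(model, convention)
        row = {
            "m": m,
            "lam": fit.lam,
            "fde": fit.p,
            "rmsd": fit.rmsd,
            "empty_fraction": empty_vesicle_fraction(fit.lam),
            "dark_fraction": dark_vesicle_fraction(model),
            "at_boundary": fit.at_boundary,
        }
        for s in range(1, hist.s_max + 1):
            row[f"pred_{s}"] = float(pred[s - 1])
        rows.append(row)
    table = pd.DataFrame(rows)
    selected_m = int(table.loc[table["rmsd"].idxmin(), "m"])  # idxmin -> first = smallest m
    return FitResult(
        per_m_table=table,
        selected_m=selected_m,
        fit_bins=tuple(int(b) for b in fit_bins),
        convention=convention,
    )


def monte_carlo_envelope(
    expected_fractions: np.ndarray,
    n_spots: int,
    n_trials: int = 5000,
    seed: int | None = None,
) -> MonteCarloEnvelope:
    """Multinomial resampling SD of bin fractions.

    Draws ``n_trials`` multinomial samples of ``n_spots`` spots from the
    expected fractions (any missing mass goes to an auxiliary overflow
    category that is discarded) and returns the per-bin SD of the sampled
    fractions.  Bit-reproducible for a fixed seed.
    """
    q = np.asarray(expected_fractions, dtype=float)
    if np.any(q < 0) or q.sum() > 1 + 1e-9:
        raise ValueError("expected_fractions must be >= 0 and sum to <= 1")
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    rest = max(0.0, 1.0 - q.sum())
    pvals = np.append(q, rest)
    pvals = pvals / pvals.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_spots, pvals, size=n_trials)[:, : q.size]
    sds = draws.std(axis=0, ddof=1) / n_spots
    return MonteCarloEnvelope(per_bin_sd=sds, n_trials=n_trials, seed=seed)


class OligomerModelSelector(BaseEstimator):
    """Estimator selecting the oligomer state from a censored step histogram.

    Scikit-learn-style wrapper over :func:`select_oligomer`: ``fit`` accepts
    a :class:`StepHistogram` or a plain count vector for bins 1..s_max and
    exposes the selected stoichiometry and its parameters as fitted
    attributes.

    Attributes
    ----------
    selected_m_ : int
        Stoichiometry with the smallest best-fit RMSD (ties to smaller m).
    lambda_, fde_, rmsd_ : float
        Best-fit Poisson mean, detection efficiency and RMSD at selected_m_.
    per_m_table_ : pandas.DataFrame
        Full per-candidate fit table.
    empty_fraction_, dark_fraction_ : float
        Implied no-complex and no-visible-fluorophore vesicle fractions.
    """

    def __init__(
        self,
        m_values: tuple[int, ...] = tuple(range(1, 9)),
        fit_bins: tuple[int, ...] | None = None,
        convention: str = CONDITION_1_TO_SMAX,
        lam_grid: tuple[float, float, float] = DEFAULT_LAM_GRID,
        p_grid: tuple[float, float, float] = DEFAULT_P_GRID,
        pin_p: float | None = None,
    ):
        self.m_values = m_values
        self.fit_bins = fit_bins
        self.convention = convention
        self.lam_grid = lam_grid
        self.p_grid = p_grid
        self.pin_p = pin_p

    def _as_histogram(self, X) -> StepHistogram:
        if isinstance(X, StepHistogram):
            return X
        return StepHistogram(counts=np.asarray(X, dtype=float))

    def fit(self, X, y=None) -> "OligomerModelSelector":
        hist = self._as_histogram(X)
        result = select_oligomer(
            hist,
            m_range=self.m_values,
            fit_bins=self.fit_bins,
            convention=self.convention,
            lam_grid=self.lam_grid,
            p_grid=self.p_grid,
            pin_p=self.pin_p,
        )
        self.result_ = result
        self.per_m_table_ = result.per_m_table
        self.selected_m_ = result.selected_m
        self.lambda_ = result.lam
        self.fde_ = result.fde
        self.rmsd_ = result.rmsd
        self.empty_fraction_ = float(result.selected_row["empty_fraction"])
        self.dark_fraction_ = float(result.selected_row["dark_fraction"])
        self.predicted_fractions_ = result.predicted_fractions()
        return self

    def predict(self, X=None) -> int:
        """Selected oligomer state (X is ignored; kept for API symmetry)."""
        if not hasattr(self, "selected_m_"):
            raise RuntimeError("fit before predict")
        return self.selected_m_


class BinomialFDEEstimator(BaseEstimator):
    """Estimator of the FDE from a purified standard of known subunit count.

    ``fit`` accepts a :class:`StepHistogram` or count vector; fitted
    attributes are ``fde_`` and ``rmsd_``.
    """

    def __init__(
        self,
        n_total: int = 4,
        fit_bins: tuple[int, ...] | None = None,
        convention: str = CONDITION_1_TO_SMAX,
        p_grid: tuple[float, float, float] = DEFAULT_P_GRID,
    ):
        self.n_total = n_total
        self.fit_bins = fit_bins
        self.convention = convention
        self.p_grid = p_grid

    def fit(self, X, y=None) -> "BinomialFDEEstimator":
        hist = X if isinstance(X, StepHistogram) else StepHistogram(
            counts=np.asarray(X, dtype=float)
        )
        p_hat, r_hat = fit_fde_binomial(
            hist,
            self.n_total,
            fit_bins=self.fit_bins,
            convention=self.convention,
            p_grid=self.p_grid,
        )
        self.fde_ = p_hat
        self.rmsd_ = r_hat
        return self
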