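"""In-memory end-to-end pipeline: simulate -> count -> histogram -> select.

Mirrors what the CLI does through files, for recovery studies and tests.
"""

from __future__ import annotations

import numpy as np

from .fitting import (
    FitResult,
    StepHistogram,
    correct_contaminants,
    histogram_from_step_calls,
    select_oligomer,
)
from .simulate import SimulationConfig, sample_vesicle_population, simulate_trace
from .step_counting import PDDStepCounter

__all__ = ["simulate_step_histogram", "simulate_and_select"]


def simulate_step_histogram(
    cfg: SimulationConfig,
    s_max: int = 8,
    counter: PDDStepCounter | None = None,
) -> StepHistogram:
    """Simulate a dataset and step-count every detectable spot.

    The contaminant estimate attached to the histogram is the expected
    count — ``contaminant_rate`` times all membrane-positive entities —
    exactly the quantity an experimenter reads off the untagged control.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_pop, rng_traces = [np.random.default_rng(s) for s in ss.spawn(2)]
    pop = sample_vesicle_population(cfg, rng_pop)
    detected = pop.detected()

    traces = (
        simulate_trace(int(n), cfg, rng_traces, spot_id=str(sid))
        for sid, n in zip(detected["vesicle_id"], detected["n_visible"])
    )
    if counter is None:
        counter = PDDStepCounter(mu_step=cfg.mu_step, s_max=s_max)
    counter.fit()
    calls = counter.transform(traces)
    return histogram_from_step_calls(
        calls,
        s_max=s_max,
        contaminant_estimate=cfg.contaminant_rate * pop.n_membrane_positive,
    )


def simulate_and_select(
    cfg: SimulationConfig,
    s_max: int = 8,
    correct_bin1: bool = True,
    **select_kwargs,
) -> FitResult:
    """Full recovery pipeline returning the oligomer-state fit result."""
    hist = simulate_step_histogram(cfg, s_max=s_max)
    if correct_bin1:
        hist = correct_contaminants(hist)
    return select_oligomer(hist, **select_kwargs)
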