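# stepstoich

Subunit stoichiometry of membrane protein complexes from single-molecule
photobleaching of individual membrane vesicles.

## The problem

When a membrane protein complex is fluorescently tagged and a preparation of
~100 nm inverted membrane vesicles (IMVs) is imaged at the single-vesicle
level, each diffraction-limited spot photobleaches in discrete steps — one
step per detectable fluorophore.  The histogram of step counts across many
vesicles encodes the oligomerization state *m* of the complex, but two
confounders stand between the histogram and *m*:

* vesicles receive a **random number of complexes** (Poisson partitioning
  with mean λ), so a tetramer does not simply produce 4-step spots;
* a fluorescent protein is detectable only with probability *p* < 1 (the
  **fluorescence detection efficiency, FDE**, dominated by chromophore
  maturation), so steps are binomially thinned.

`stepstoich` implements the full analysis chain for this experiment:

1. **Step counting** from raw traces via the pairwise difference
   distribution (PDD): all pairwise intensity differences of a trace cluster
   at integer multiples of the unitary step quantum (~1320 photons/frame
   here); the highest-photon-level peak equals the total drop and hence the
   step count.
2. **Model fitting**: the censored step histogram (bins 1–8; more steps are
   unreliable and censored; single-step surface contaminants subtracted from
   bin 1) is compared with the expected step distribution under each
   candidate *m*,

   P(S = s) = Σ_k Pois(k; λ) · Binom(s; k·m, p),

   conditioned on the analyzable range 1 ≤ S ≤ 8.  For each *m*, (λ, p) are
   fit by minimum RMSD on a grid with local refinement; the *m* with the
   smallest best-fit RMSD is selected (ties to smaller *m*).
3. **Uncertainty**: per-bin error bars by multinomial Monte Carlo
   resampling (default 5000 trials of N spots).
4. **Side calculations**: empty-vesicle fraction e^(−λ), dark-vesicle
   fraction e^(−λ(1−(1−p)^m)), vesicle yield per cell from spherocylinder
   geometry, and complexes per cell.
5. **Synthetic data**: a generator producing vesicle populations and
   photobleaching traces (bleaching, blinking, brightness spread, read
   noise, surface contaminants) with known ground truth, so the entire
   pipeline is testable end to end.

The fitting and counting stages are scikit-learn style estimators
(`OligomerModelSelector`, `BinomialFDEEstimator`, `PDDStepCounter`) and
compose with sklearn tooling; plain functions wrap them for one-off use.

## Worked example

Simulate a tetramer experiment (m = 4, λ = 1 complex/vesicle, FDE = 0.7,
800 vesicles → ~500 detected spots), count steps, and select the model:

```python
import numpy as np
from stepstoich import (SimulationConfig, OligomerModelSelector,
                        simulate_step_histogram, correct_contaminants,
                        monte_carlo_envelope)

cfg = SimulationConfig(m_true=4, lam_true=1.0, p_true=0.7,
                       n_vesicles=800, seed=1)
hist = correct_contaminants(simulate_step_histogram(cfg))
print("analyzed spots:", int(hist.n_total_analyzed),
      "| censored (>8 steps):", hist.n_censored)

sel = OligomerModelSelector().fit(hist)
print(f"selected m = {sel.selected_m_}, lambda = {sel.lambda_:.3f}, "
      f"FDE = {sel.fde_:.3f}, RMSD = {sel.rmsd_:.5f}")
print(f"empty vesicles: {100*sel.empty_fraction_:.1f}%")
```

prints

```
analyzed spots: 448 | censored (>8 steps): 45
selected m = 4, lambda = 0.855, FDE = 0.693, RMSD = 0.00905
empty vesicles: 42.5%
```

The selector recovers the tetramer, a Poisson mean near 1, and an FDE near
0.7 from traces alone; `sel.per_m_table_` holds the whole per-candidate fit
table (the RMSD minimum sits at m = 4 and rises on both sides), and
`monte_carlo_envelope(sel.predicted_fractions_, n_spots=448)` attaches the
per-bin SDs.  A fitted λ ≈ 1 together with the geometric vesicle yield of a
2 × 1 µm cell (200 vesicles of 100 nm) implies ~200 complexes per cell.

The same analysis is available from the shell:

```bash
stepstoich simulate --out data --seed 1 --n-vesicles 800
stepstoich count --traces data/traces.tsv --out-calls calls.tsv --out-hist hist.tsv
stepstoich fit --hist hist.tsv --out fit.json --seed 1
stepstoich report --fit-report fit.json
```

All file formats are plain TSV/JSON and round-trip bit-exactly; histograms
from a real experiment (columns `step_bin`, `count`, with `# n_censored:`
and `# contaminant_estimate:` headers) can be fed straight to
`stepstoich fit`.

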