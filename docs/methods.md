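# Methods

## Statistical model

A vesicle preparation is modelled as a population of independent reaction
chambers.  Vesicle *i* receives `K_i ~ Poisson(λ)` protein complexes —
the homogeneity of the source membrane justifies Poisson partitioning — and
each complex carries exactly *m* fluorescent-protein subunits.  Each subunit
is detectably fluorescent with independent probability *p* (the fluorescence
detection efficiency, FDE), which absorbs chromophore maturation failure and
any other all-or-none loss of signal.  The number of photobleaching steps
observed for one vesicle is therefore

    S | K ~ Binomial(K·m, p),      K ~ Poisson(λ),

with marginal pmf `P(S=s) = Σ_k Pois(k;λ)·Binom(s;k·m,p)`.  Useful closed
forms follow from Poisson thinning:

* empty-vesicle fraction (no complexes): `e^(−λ)`;
* dark-vesicle fraction (no visible fluorophore): `e^(−λ(1−(1−p)^m))`,
  because a complex is entirely dark with probability `(1−p)^m` and thinning
  a Poisson count leaves a Poisson count;
* for m = 1 the marginal is exactly `Poisson(λp)` — λ and p are identified
  only through their product (this matters for model selection; see
  Limitations).

The series is evaluated by truncating the Poisson sum at the smallest order
K* whose upper-tail mass is below a tolerance (default 1e−9, exposed as
`k_tail_tol`); the omitted mass is recorded on the returned pmf object so
every evaluation carries its own error bound.

## Step counting by pairwise difference distribution (PDD)

For a trace that loses fluorophores one at a time, every pair of occupancy
levels differs by a whole number of unitary steps, so the multiset of
pairwise differences `I_i − I_j` (earlier frame minus later frame, i < j)
clusters at integer multiples of the step quantum μ.  The highest-photon
cluster sits at the full drop — initial occupancy × μ — and encodes the
step count without segmenting individual step times.

Implementation choices (the quantities below are analysis decisions, not
measured constants):

* **Histogram**: differences binned at 100 photons (scaled as μ/13.2 when a
  different quantum is supplied, which makes step calls invariant under
  joint rescaling of trace and quantum) over [0, 12μ], normalised,
  boxcar-smoothed over 3 bins.  Negative differences (noise, blinking) fall
  outside the support and are dropped.
* **Zero cluster**: same-level pairs produce a dominant peak near zero that
  carries no step information.  Bins below 0.45μ are ignored both as peak
  candidates and as the prominence reference.
* **Peak acceptance**: a local maximum qualifies if its prominence is at
  least `min_prominence` (default 0.002) times the largest frequency outside
  the zero cluster.  The threshold is small because the full-drop cluster of
  an n-step trace contains only (frames at full level) × (dark frames)
  pairs — intrinsically ~1% of all pairs for large n — while the reference
  unitary-step cluster aggregates every adjacent-level pair.  Noise-only
  traces remain uncallable at this threshold because their histogram has
  essentially no mass beyond the zero cluster.
* **Assignment**: the last-peak position is divided by μ with decision
  boundaries at (n ± 0.5)μ; an exact half-integer rounds up (deterministic,
  measure-zero tie rule).  A last peak below 0.5μ is *uncallable* — a
  distinct outcome from zero steps.  Calls above `s_max` (default 8, the
  reliability limit of step picking) are censored and tallied separately;
  a peak beyond (s_max+3)μ is additionally flagged as a probable aggregate.
* **Calibration**: the quantum (default 1320 photons/frame) can be
  re-estimated from ≥ 20 measured unitary drops via a 10%-trimmed mean, with
  a MAD-based relative spread.  Fewer than 20 drops are refused rather than
  silently accepted.

On noiseless staircases the caller is exact for all k ≤ 8 and any μ > 0,
is invariant under joint rescaling, and tolerates a 3-frame blink
(temporary one-quantum dip).

## Histogram fitting and model selection

The observed histogram counts analyzable spots per step number s = 1..8;
spots with more steps are censored, and an expected number of single-step
surface contaminants (default rate: 2.7% of all membrane-positive entities)
is subtracted from bin 1, floored at zero, at most once.

Observed fractions use the analyzed total (corrected bins 1..8) as
denominator.  Expected fractions condition the model the same way
(`condition_1_to_smax`, i.e. renormalised over 1 ≤ S ≤ 8), so censoring is
treated symmetrically on both sides; a `condition_ge1` alternative
(divide by 1 − P(S=0)) is exposed for sensitivity analysis.  Fitting uses
bins 2–8 by default, keeping the contaminant-prone first bin out of the
objective; including the corrected bin 1 is an option and does not change
selections on simulated data.

For each candidate m in 1..8, (λ, p) minimise the RMSD between observed and
expected fractions over the fit bins on a grid — λ in [0.05, 8] step 0.05,
p in [0.30, 1.00] step 0.01 — followed by one refinement pass at 10× finer
resolution around the coarse argmin.  The FDE floor of 0.30 is deliberately
below typical fluorescent-protein maturation efficiencies (> 0.5) so that
data, not the prior, excludes low values.  A grid-then-refine search was
chosen over gradient methods because the 2-parameter bounded problem is
cheap, the argmin is reproducible, and the RMSD surface can be multimodal
in m-mismatched fits.  Fits that end on a grid edge are flagged
(`at_boundary`).  The selected stoichiometry is the m with the smallest
best-fit RMSD; exact ties break toward smaller m (parsimony).

For purified standards of known subunit count n (dimers, tetramers), the
same machinery reduces to a one-parameter binomial FDE fit; default fit
bins are 2..n for n > 2 and 1..n (contaminant-corrected) for dimers, where
restricting to bin 2 alone would be degenerate.

Per-bin uncertainties are multinomial Monte Carlo SDs: 5000 independent
trials of N spots drawn from the fitted expectation (any probability mass
outside the analyzable bins goes to a discarded overflow category).  The
SDs converge to `sqrt(q(1−q)/N)` and are bit-reproducible for a fixed seed.

## Geometric side calculations

The source cell is modelled as a spherocylinder of length L and width w
(area πwL: a cylinder of length L−w plus two hemispherical caps); vesicles
are spheres of diameter d.  The per-cell vesicle yield is the area ratio
`wL/d²` — 200 for a 2 × 1 µm cell and 100 nm vesicles — and multiplying by
the fitted λ gives complexes per cell (200 at λ = 1).  The ratio is
invariant under uniform rescaling of all three lengths, and a vesicle wider
than the cell is rejected.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

* per-vesicle complex counts `Poisson(λ)`, visible subunits
  `Binomial(K·m, p)`;
* single-step contaminants appended at a fixed fraction (default 2.7%) of
  all membrane-positive entities, each with exactly one visible fluorophore;
* traces of 550 frames at 100 ms: each visible fluorophore draws a
  brightness `Normal(μ, (cv·μ)²)` truncated positive, an exponential bleach
  time, and an alternating on/off blink process (starting on); frame
  intensity integrates the on-fraction over each exposure and adds Gaussian
  read noise.  Traces are background-subtracted by construction.

Trace-level photophysical defaults are phenomenological; only the exposure,
recording length, step quantum, contaminant rate and the qualitative
presence of blinking are experimentally anchored.  The free defaults were
set from an error budget so that PDD calling resolves up to eight
fluorophores reliably, the design target for the analyzable range:

* `brightness_cv = 0.05`: the full drop of an n-step trace is the *sum* of
  n brightnesses, with SD `√n·cv·μ`; against fixed boundaries at
  (n ± 0.5)μ, correct integer assignment of n = 8 requires
  `√8·cv ≪ 0.5`, and cv = 0.05 leaves 3.5σ of headroom.
* `bleach_mean_time = 8 s`: completion within the 55 s recording needs the
  slowest of n fluorophores to bleach (P ≈ (1−e^(−55/τ))^n), while
  early bleaching during the very first frames erodes the full-level
  cluster; τ = 8 s balances the two for n ≤ 8.
* `blink_off_rate = 0.2 /s`, `blink_on_rate = 2.0 /s`: visible blinking
  (~9% instantaneous off-fraction) without destroying level structure.
* `read_noise_sd = 150` photons: well below μ/2, realistic for
  background-subtracted EMCCD photon counts.

Measured per-n call accuracy under these defaults is 93–99% for n = 1..8.
All of these are config fields, never hard-coded downstream, and the dataset
manifest flags them as placeholders.

What the generator does **not** emulate: pixel-level images or PSFs,
aggregates brighter than the censoring limit, focal drift, EMCCD
gain/excess noise, vesicle size variation, or measured mNeonGreen blink
kinetics (unquantified under these imaging conditions).  Passing tests
therefore demonstrate the correctness of the analysis chain under the
stated statistical assumptions, not performance on any particular real
dataset; in real data the brightness dispersion of fluorophores is likely
larger than the default cv, and step-call accuracy at high step counts will
be correspondingly lower.

## Degenerate inputs and edge behaviour

Uncallable traces (no qualifying peak, or last peak below 0.5μ) are
reported as such and excluded from histograms; censored calls never enter
bins 1..8.  Histograms with no counts in the fit bins, or with all mass
censored, are rejected.  Double contaminant correction is rejected.  An
m = 1 fit reports one representative (λ, p) pair from the λp-degenerate
optimum.  Empty difference sets and traces shorter than 50 frames are
rejected at construction.

## Known limitations

* **Monomer identifiability**: minimum-RMSD selection cannot reliably
  distinguish a monomer truth from higher-m alternatives at N ≈ 500
  analyzed spots.  The m = 1 family (exactly Poisson) is one-dimensional,
  while every m ≥ 2 candidate has two free parameters; the best m ≥ 2
  mimic of a detected-Poisson histogram differs by an RMSD of only
  0.003–0.012 across the λ range, below the multinomial noise scale at
  N = 500.  Separating those hypotheses needs either far larger N, an FDE
  plausibility constraint, or an auxiliary statistic — the predicted
  empty-vesicle fraction is the natural one, since monomer fits imply few
  empty vesicles while multimer fits imply many.
* **Tetramer selection at N ≈ 500 is near the noise floor**: the best
  m = 5 mimic of exact tetramer fractions differs by RMSD ≈ 0.017,
  comparable to multinomial noise at N = 500, so roughly one seed in ten
  selects m = 5; recovery rates improve quickly with N.
* RMSD is the selection objective by design (matching the analysis this
  package reproduces); no likelihood-based alternative is provided, and no
  mixed-population models (for example, part monomer, part tetramer) are
  fit.
* The PDD caller assumes a global step quantum; traces whose total
  brightness deviates from an integer multiple of μ by more than 0.5μ are
  assigned to the nearest integer with no warning.
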