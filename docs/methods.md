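# Methods

## Equilibrium models

All model code works in molar; I/O layers carry explicit units (`conc_unit`
column, unit-suffixed CLI flags) because the experiments span nM probe to
mM competitor and silent unit scaling is the classic failure mode here.

**Direct isotherm.** A single receptor site binding a labelled probe with
explicit ligand depletion: the bound-probe fraction is the physical root of
the quadratic in the complex concentration. Assumptions: one class of
independent sites, equilibrium reached, activity ≈ concentration.

**Ternary competition.** One receptor, two mutually exclusive ligands
(probe A with K_A, competitor B with K_B). The free receptor concentration
is the unique root in [0, R_T] of the mass balance

    f([R]) = [R]·(1 + A_T/(K_A+[R]) + B_T/(K_B+[R])) − R_T = 0,

equivalently the physical root of a cubic. We evaluate the trigonometric
closed form and then apply three Newton iterations on f: the raw closed
form loses up to ~1e−7 relative accuracy when one K dwarfs the root
(cancellation between the −a/3 and cosine terms), and the polish restores
~1e−10 worst-case agreement with the bisection solver over a log-uniform
sweep of K values and totals in [1e−9, 1e−2] M at negligible cost. The
arccos argument is clamped to [−1, 1]; a discriminant below 1e−30 M⁶
(degenerate, measure-zero inputs) triggers a fall back to the bisection
solver with a warning.

**Oracle solver.** An independent verifier used in tests and as the
degenerate-case fallback, never in the fitting hot path: bisection of f on
[0, R_T], which brackets by construction (f is strictly increasing,
f(0) ≤ 0 ≤ f(R_T)). Termination is on *relative* width of the root
(default 1e−12). Because f′([R])·[R] ≤ R_T at the root, this bounds the
receptor mass-balance residual by ~tol·R_T even where f is steep; probe
and competitor balances hold exactly by construction.

**Anisotropy model.** r = (r_free(1−FB) + g·r_bound·FB)/((1−FB) + g·FB).
g is the bound/free fluorescence-intensity ratio; the default g = 1
reduces to linear anisotropy mixing, appropriate when binding does not
change the probe quantum yield. g can be fixed at another value or floated
in fits, since published descriptions of this assay family do not always
state whether the intensity correction was applied.

## Affinity fitting

* Unweighted least squares on anisotropy residuals, per replicate, with K
  optimised as log10 K on [−9, −1] (constructs span five orders of
  magnitude; log-space avoids boundary trapping and negative K).
* Initialisation: 41-point log-spaced K grid; at each grid point the
  endpoints enter the g = 1 model linearly and are profiled out by linear
  least squares; the best grid point seeds an lmfit Levenberg–Marquardt
  refinement of (log10 K, r_free, r_bound[, g]).
* Endpoints are fitted jointly with K by default rather than fixed from
  control wells (the alternative is available by fixing g and supplying
  endpoints); each replicate is fitted independently and the K estimates
  aggregated as mean ± SEM (SEM undefined, with a warning, for a single
  replicate). Replicates whose optimiser pins K at a bound are flagged
  not-converged and excluded from aggregation with a warning.
* Identifiability guards: a flat anisotropy series or a collapsed fitted
  dynamic range raises a fit error; fewer than 4 positive, distinct
  titrant concentrations per replicate raises a fit error.
* **Lower-bound classification.** After a competition fit, the fitted model
  predicts the probe displacement at the highest competitor concentration
  reached, as a fraction of the zero-competitor occupancy. If that
  displacement is below 0.8 the titration never approached its saturated
  baseline (typically a solubility ceiling) and the result is reported as
  "K_D > value". The 0.8 default is a policy choice codifying a judgment
  call — published analyses state the solubility rationale but no numeric
  rule — and is configurable. Note that the classification is intentionally
  conservative near the boundary: a competitor whose displacement at the
  ceiling is ~80 % sits on the point-estimate/lower-bound knife edge and
  noisy fits may land on either side.
* Uncertainty in K_A is not propagated into K_B (reported as a caveat, not
  modelled); no IC50→K_i approximation is used anywhere since the exact
  model supersedes it.

## NMR titration mapping

* Statistic: percent change = 1 − I_bound/I_unbound per residue, after
  normalisation, stored as a fraction and displayed ×100. Negative values
  (intensity gain) are retained.
* **Normalisation** (default `least_perturbed_median`): the reference set
  is the 20 % of shared residues whose log intensity ratio is closest to
  the *median* log ratio; each dataset is scaled so the median intensity
  of that set is 1. Using the median anchor makes the selection invariant
  to any global gain difference between datasets, and using least-perturbed
  residues keeps the binding signal itself from biasing the scale. This
  assumes fewer than half the scored residues are strongly perturbed —
  true for short motifs in a long disordered window. `total` and `max`
  normalisations are available. The exact statistic used in published
  analyses of this kind is generally unstated; this is a policy choice.
* **Binning**: two built-in light-to-dark schemes, a 4-bin scheme
  (>90, 80–90, 70–80, <70 percent; lower-exclusive/upper-inclusive) and a
  3-bin scheme (>70, 40–70, <40). Missing residues (peak overlap,
  unassigned, present in only one dataset) are assigned the darkest bin,
  the standard surface-colouring convention.
* **Motif detection**: maximal runs of residues with change ≥ threshold
  (default 0.5), bridging at most `max_gap` (default 1) *scored*
  below-threshold residues. Missing residues never break a run: they carry
  no information, and the binning convention above treats them like
  strongly attenuated residues; counting them against the gap would split
  real motifs wherever two overlapped peaks happen to be adjacent. Region
  boundaries are delimited by the outermost hits and then extended across
  at most `max_gap` directly adjacent missing residues (an overlap gap at
  a motif edge is plausibly part of the footprint). Regions spanning fewer
  than `min_run` (default 4) residues are discarded. These defaults
  reproduce planted two-motif profiles exactly in the noise-free case;
  they codify as a reproducible rule what is often done by visual
  inspection.
* Residue numbering is 1-based in the native full-length protein;
  expression-tag artifacts are excluded from profiles upstream.

## Cell localization statistics

* Unit of analysis is the cell, pooled across biological replicates, with
  per-replicate counts reported for provenance. This mirrors common
  practice but ignores replicate-level correlation; a hierarchical model
  would be more conservative and is out of scope.
* Two-tailed two-sample t test on mean nuclear GFP intensity, diffuse vs
  speckled, pooled variance by default ("Student"), Welch by flag. The t
  statistic carries the sign of (diffuse mean − speckled mean). Classes
  with fewer than two cells or zero pooled variance yield a structured
  not-applicable result rather than an exception, since variants locked in
  a single localization pattern are not testable.

## Synthetic data generator

Defaults encode the study conditions the analyses target:

| parameter | default | meaning |
| --- | --- | --- |
| probe_total | 40 nM | labelled probe in both FA modes |
| receptor_total | 6 µM | receptor in competition mode |
| direct range | 0.001–300 µM | log-spaced receptor axis, 12 points |
| competition series | 2 mM ÷ 3ᵏ, 12 points | serial dilution down to ~0.011 µM |
| noise_sd_anisotropy | 0.005 | additive Gaussian, plausible plate-reader noise |
| n_replicates | 3 | technical replicates |
| r_free / r_bound | 0.08 / 0.20 | typical fluorescein-peptide endpoints; only relative displacement matters |
| NMR window | residues 204–283 | disordered-region construct |
| planted regions | 220–235 (depth 0.85), 265–275 (0.80) | two binding motifs |
| missing_fraction | 0.10 | uniformly planted overlap-missing residues |
| noise_sd_intensity | 0.10 | per-dataset multiplicative log-normal |
| cells | 90 cells / 3 replicates, log-normal intensity (median 500, σ 0.8), logistic P(diffuse) midpoint 500 slope 3 | concentration-threshold localization model |

Noise models are additive Gaussian for anisotropy (instrument-like) and
multiplicative log-normal for NMR and cell intensities
(positivity-preserving); these are standard minimal choices, not measured
error models. The cell generator with slope 0 is the exact null (class
independent of intensity) used for type-I-error calibration;
`binding_competent=False` emulates deletion variants that leave the
adaptor speckled at any expression level. What the generators do *not*
emulate: correlated residuals, plate drift, pipetting error on the
concentration axis, peak-picking errors, exchange-regime dependence of
NMR line widths, replicate-level batch effects, or segmentation error in
cell intensities — so passing closed-loop tests demonstrates correctness
of the estimators under the stated noise models, not robustness to every
real-world artefact.

## Validation problem sizes

The validation script and acceptance tests use: 1000-system log-uniform
sweeps for oracle agreement and conservation; a 100-point receptor grid
for the zero-competitor reduction; 100 Monte-Carlo fits per affinity level
(1, 10, 100 µM) for recovery and 100 per condition for lower-bound
classification; 200 simulations for noisy NMR boundary recovery; 2000
null simulations (~30 cells per class) for t-test calibration. These sizes
give stable medians and rates (spot-checked across seeds) while keeping a
full run around 20 seconds.

## Known limitations

* The competition model treats the receptor as a single site; avidity from
  receptor oligomerisation or from two motifs on one chain is captured
  only as an apparent K_D of the construct, by design.
* Lower-bound classification depends on the fitted K estimate itself; for
  competitors near the displacement threshold the flag is seed-sensitive.
* The t test inherits mild conservatism under strongly skewed (log-normal)
  intensities at n ≈ 30 per class (rejection ~4–5 % at nominal 5 %).
* Peak-list parsing keys on residue numbers only; it does not validate
  residue types against a sequence.
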