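# Methods

`microdev` models the postnatal colonization of brain sub-regions by
microglia and quantifies the functional maturation that accompanies it. This
note documents the models, the estimation machinery, the numerical choices,
and what the synthetic-data suites do and do not demonstrate.

## Compartmental models of colonization

A brain region (hippocampus, cerebellum) is a small set of layers
(compartments); the state is the microglial density `M_i(t)` (cells/mm³) in
layer `i` at postnatal age `t` (days; `t` is postnatal, not embryonic).
Three nested model classes are implemented.

**Modified logistic.** Density relaxes to an equilibrium that is inversely
proportional to the growing layer volume:

    dM_i/dt = r M_i (1 − M_i V_i(t)/κ) − c M_i + spreading_i

with growth rate `r` (1/day), carrying-capacity scale `κ` (cells, so the
equilibrium density is `κ/V_i(t)`), and apoptosis `c` (1/day).

**Linear with decaying source.** Linear proliferation/apoptosis plus an
influx from outside the region that decays exponentially:

    dM_i/dt = (p − c) M_i + s0_i e^{−λ t} + spreading_i

**Two-population.** Each layer's microglia split into a proliferative
population `A` and a quiescent population `B`. Proliferation (`a1`) and
differentiation (`a2`, both directions) each decompose into an intrinsic
(constant) rate and an extrinsic coefficient multiplying a dimensionless
environmental factor `E_i(t)`:

    dA_i/dt = (a1_int_A + a1_ext_A E) A − (a2_int_AB + a2_ext_AB E) A
              + (a2_int_BA + a2_ext_BA E) B − c_A A + spreading_A
    dB_i/dt = (a2_int_AB + a2_ext_AB E) A + (a1_int_B + a1_ext_B E) B
              − (a2_int_BA + a2_ext_BA E) B − c_B B + spreading_B

Both differentiation directions are representable; any dominance of `A→B`
is an inference result, not a structural constraint. Kinetic rates are
shared across the layers of a region; initial densities, volume parameters,
and external influx are per-layer, so layer-specific milestones emerge from
layer-specific `E_i(t)`.

**Volume and environment.** Each layer's volume follows logistic growth
`V_i(t) = v_inf/(1 + (v_inf/v0 − 1) e^{−g t})`, fitted jointly with the cell
model (the data only constrain that volumes rise and saturate, so the
minimal saturating form is used). The environmental factor is
`E_i(t) = V_i(t)/v_inf_i ∈ [0, 1]`; any proportionality constant is
absorbed into the extrinsic rate coefficients.

**Spreading acts on counts.** A directed edge `i→j` with rate `β` (1/day)
moves `β M_i V_i` cells/day out of layer `i` and deposits them in `j`
(divided by `V_j` to return to densities). This makes total cell count
`Σ M_i V_i` exactly conserved under pure spreading with frozen volumes — a
tested invariant. Influx through the reserved `EXTERNAL` source is a density
source `β_ext e^{−λ_ext t}`. Two published routes ship as presets:
hippocampus `EXTERNAL→CA→DG` (invasion through the Cornu Ammonis, then
inward to the dentate gyrus) and cerebellum `WM→GL→ML` (outward from the
white matter).

**Observables.** Density is `A+B`; volume is `V`. The %Ki67 observable maps
model state through a visibility-window model: a cell is scored Ki67⁺ if it
entered the cycle within the last `τ_k` days, so

    %Ki67_i = 100 · τ_k · [a1_A(t) A_i + a1_B(t) B_i] / (A_i + B_i)

capped at 100, defined as 0 (with a warning) where the population is empty;
`τ_k` is a fittable parameter bounded in (0, 1.5] days. For one-population
models the bracket reduces to the per-capita birth rate (for the logistic
model `r·max(0, 1 − M/K)`; for the linear model `p + s_i(t)/M_i`). This
rate×window form is the minimal identifiable choice linking a rate
parameter to a percentage observable.

**Derived milestones.**

* *P/Q switch time*: the earliest time the quiescent fraction
  `B/(A+B)` crosses 1/2 from below, located by linear interpolation between
  grid points; absence of a crossing is a valid (None) result.
* *Doubling time*: `ln 2 / max(ε, (dM/dt)/M)` with the derivative taken
  from the model right-hand side (not finite differences) at the state
  interpolated to the requested age; `ε = 1e−12`, with `+∞` returned for
  non-growing populations.

## Bayesian calibration

Observations are modeled as independent Gaussians centered on the model
output, with one noise scale per observable class (volume, density, %Ki67)
shared across layers — the classes have incommensurate units, and
per-class scales are the coarsest granularity that respects that. The noise
scales are sampled alongside the kinetic parameters. All priors are
independent uniforms with lower bound zero; upper bounds are user-supplied,
with shipped defaults (rates ≤ 10/day, noise scales ≤ 10× the data standard
deviation of the class, densities ≤ 10× the observed maximum, `τ_k` ≤ 1.5).

Sampling uses Metropolis–Hastings with adaptive proposal covariance
(Haario-style): a multivariate normal proposal whose covariance is the
running empirical covariance of the chain history scaled by `2.38²/d` plus
a `1e−8` ridge, adapting from iteration 200. Two standard stabilizers are
layered on top:

* a Robbins–Monro global step-size factor tuned toward the optimal
  random-walk acceptance rate 0.234, which rescues the early phase when the
  empirical covariance is still uninformative;
* a 5% fixed-covariance mixture component in the proposal
  (Roberts–Rosenthal style), which prevents the classic adaptive-Metropolis
  freeze where a coordinate that has not yet moved keeps a collapsed
  proposal variance and never escapes; internally the walk runs in
  box-normalized coordinates so these ingredients are balanced across
  parameters whose natural scales differ by orders of magnitude;
* optional mode-refined start points (`fit_model(refine_starts=True)`,
  the default): from each chain's own uniform random start, a few hundred
  derivative-free Nelder–Mead steps on the *profile* likelihood — each free
  noise scale set analytically to its RMS residual — move chains out of the
  flat prior tails. The sampler itself retains the plain
  uniform-inside-the-box initialization contract.

Chains are reproducible bit-for-bit from the seed. Defaults: 3 chains
(split-R̂ needs several), ≥ 2000 iterations, first 50% discarded as burn-in.
Convergence is summarized by split-R̂ with a 1.05 flag; degenerate
(zero-variance) chains report R̂ = 1 with a warning.

## Model selection

AIC and BIC use the best log-likelihood seen by the chains (a sampler-only
workflow; an optional local refinement from the best draw can tighten it)
with `n_params` the number of *sampled* coordinates. WAIC uses the
variance-based penalty (the standard recommendation):

    WAIC = −2 Σ_obs [ log mean_draws lik − var_draws loglik ]

computed from the per-draw, per-observation log-likelihoods retained with
the chains. Models are ranked per criterion (lower is better); the
*consensus* winner is the model ranked first by all three, otherwise the
comparison is labeled discordant. Topology comparison fits the same model
class under alternative spreading-edge sets and ranks the variants the same
way.

## Dual-labeling cell-cycle simulator

The EdU/BrdU assay is simulated on an asynchronous population: per-cell
cycle lengths are lognormal with mean `tc_mean` and CV `tc_cv` (default
0.15 — enough dispersion to break the exact aliasing of a deterministic
population, where an interval of 2×tc is indistinguishable from tc), S
phase occupies the first `ts` hours of the cycle (default 4 h), and initial
phases are uniform over each cell's own cycle. Pulses are instantaneous
(bioavailability is short relative to the 6–24 h intervals), labels are
permanent, and no death or cycle exit occurs within the ≤ 24 h window — a
deliberate idealization appropriate at ages of near-universal cycling; a
`cycling_fraction` parameter scales all fractions for partly quiescent
populations. The cycle-length estimate is the interval at which the
double-labeled fraction peaks (ties resolve to the smaller interval; an
all-zero curve is inconclusive).

## Histology metrics

All inputs are counts, never images. Definitions: stereological density =
cells / (area × thickness), totals = density × structure volume; Ph index =
100 × engulfed/apoptotic; clearance ratio (apoptotic load) =
apoptotic/microglia; phagocytic capacity = % of microglia with ≥ 1 pouch,
with mean pouches per phagocytic cell; un-engulfed fraction =
`100 (1 − min(1, engaged × pouches / load))`. One apoptotic cell per pouch
is assumed unless per-pouch contents are supplied. The clearance time of a
labeled apoptotic cohort observed at two times assumes first-order
disappearance, `τ = dt / ln(n_t1/n_t2)` — removal of a marked cohort by
phagocytosis is a constant-hazard process, and two time points cannot
constrain anything richer. The coupling index is the engulfed-to-apoptotic
ratio (1 = phagocytosis keeps pace with apoptosis), optionally normalized
to a control condition. Metric–metric association uses Pearson correlation
over ages with the exact t-transform p-value (n−2 df) and the conventional
0.05/0.01/0.001 tiers, reported raw by default with an optional Holm
adjustment.

## Synthetic data

The generators produce every input the pipeline consumes with known ground
truth: model curves plus independent Gaussian replicate noise per
observation, truncated at zero (truncation preserves validity without
abandoning the stated noise model; at the shipped noise levels it is rare).
Default design: ages {2, 4, 7, 10, 14, 21, 28} days, 4 replicates per age —
matching a realistic mouse histology design.

Shipped presets ("hippocampus-like" CA/DG, "cerebellum-like" WM/GL/ML, and
a single-layer reduction) have parameters chosen once so the noise-free
curves reproduce the documented qualitative shapes — %Ki67 ≈ 40% at P2
collapsing below 10% by P7, density rising to a mid-series peak then
declining, P/Q switches between day 3 and 4 (hippocampus; the cerebellar
granular layer switches last, near day 4.2). They are fixtures with
convenient round numbers, not estimates of real tissue parameters. What the
synthetic suites therefore show is *internal* consistency — the estimation
machinery recovers parameters of data generated by its own model family —
not that real hippocampi obey the model; replicate noise is iid Gaussian by
construction, with none of the animal-level correlation, stereological
sampling error, or model misspecification real data would carry.

The phagocytosis generator draws apoptotic counts as Poisson(n·load),
engaged microglia as Binomial(n, engagement), pouch multiplicities from a
user distribution, and sets engulfed = min(apoptotic, pouches), so every
table satisfies the consuming invariants by construction.

## Numerical choices

* Default integrator: SciPy's implicit first-order BDF, `rtol 1e−8 /
  atol 1e−10`. Solver failures during sampling are treated as rejected
  proposals (logged), never as crashes.
* Calibration fast path: a compiled fixed-grid classical RK4
  (`SolverConfig(method="RK4")`, substeps ≤ 0.1 day). The systems are small
  and smooth on the day scale; the fast path agrees with the BDF reference
  to ~1e−8 relative on the oracle cases (test-covered) at ~100× lower
  per-solve overhead, which is what makes thousands-of-solves MCMC studies
  practical.
* Negative-state handling: BDF may undershoot slightly; values in
  `[−1e−6, 0]` are clamped to zero, anything lower is a hard integration
  error.
* Ties and degenerate inputs: the dual-label peak resolves ties toward the
  smaller interval; %Ki67 of an empty population is 0 with a warning;
  undefined ratios (zero microglia/apoptotic cells) return NaN sentinels
  with warnings; constant series yield NaN correlations.

## Validation-study conditions

The seeded studies in `microdev.experiments` run at reduced, fixed
settings chosen to exercise the full machinery at desk scale: 3 chains,
2000–2500 iterations, the RK4 fast path, and free-parameter subsets
(`a1_int_A`, `a2_ext_AB`, `c_B` and the two cell-level noise scales for
recovery; analogous small sets per model class for selection) with the
remaining coordinates held at their generating values. Recovery is assessed
as 95%-credible-interval coverage of each free rate and as the absolute
error of the posterior-mean P/Q switch time over thinned draws; selection
as the consensus-winner frequency across seeds. Full-scale fits (every
parameter free, longer chains) use the same code path and only cost more
wall-clock time.

## Known limitations

* Compartments are the only spatial resolution; no PDE/continuum version.
* Structural identifiability of the *full* two-population parameter set
  from (volume, density, %Ki67) alone is not established; the extrinsic
  coefficients trade off against the normalization of `E` (absorbed here
  into the coefficients), which is why the recovery suite frees an
  identifiable subset and reports, rather than hides, the conditioning of
  the rest.
* The Ki67 visibility-window map is a modeling choice; other monotone maps
  from birth rate to %Ki67 would fit equally well at this data resolution.
* The cell-cycle simulator omits label dilution, analog cross-reactivity,
  death and cycle exit; at ages where many cells are quiescent the
  `cycling_fraction` scaling is a first-order correction only.
* Perturbation data (e.g. gene knockouts altering spreading) are
  representable by re-fitting `β`, but no dedicated machinery is provided.
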