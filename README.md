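# microdev

Quantitative toolkit for **postnatal microglial development**: how microglia
colonize brain sub-regions (hippocampal CA/DG, cerebellar WM/GL/ML), when
they switch from a proliferative to a mitotically quiescent state, and how
their phagocytic function matures alongside.

It is written for computational and systems biologists working on glial
population dynamics: people who have (or simulate) developmental time series
of sub-region volume, microglial density and %Ki67⁺ microglia, plus
histology count tables, and want to calibrate mechanistic models to them.

## What it implements

**Compartmental ODE models of colonization.** Three nested classes, per
layer of a brain region, on postnatal time `t` (days):

* *logistic* — `dM/dt = r·M·(1 − M·V(t)/κ) − c·M + spreading`, equilibrium
  density inversely proportional to the growing layer volume `V(t)`;
* *linear + source* — `dM/dt = (p − c)·M + s₀·e^(−λt) + spreading`, with an
  exponentially decaying influx from outside the region;
* *two-population* — each layer's microglia split into proliferative **A**
  and quiescent **B** populations with intrinsic rates plus extrinsic rates
  modulated by an environmental factor `E(t) = V(t)/V_∞` coupled to the
  layer volume:

  ```
  dA/dt = (a1_int_A + a1_ext_A·E)·A − (a2_int_AB + a2_ext_AB·E)·A
          + (a2_int_BA + a2_ext_BA·E)·B − c_A·A + spreading_A
  dB/dt = (a2_int_AB + a2_ext_AB·E)·A + (a1_int_B + a1_ext_B·E)·B
          − (a2_int_BA + a2_ext_BA·E)·B − c_B·B + spreading_B
  ```

Spreading between layers is count-conserving and directed (presets:
`EXTERNAL→CA→DG`, `WM→GL→ML`). Systems integrate with SciPy's implicit BDF
(a compiled fixed-grid RK4 fast path serves calibration workloads).

**Bayesian calibration and model selection.** Gaussian iid likelihood with
one sampled noise scale per observable class; uniform priors with lower
bound zero; adaptive-covariance Metropolis–Hastings (Haario scaling
2.38²/d, Robbins–Monro step-size control, split-R̂ diagnostics); model
ranking by AIC, BIC and WAIC (variance-penalty form, from per-draw
pointwise log-likelihoods), including comparison of alternative spreading
topologies.

**Derived milestones.** The proliferative-to-quiescent (**P/Q**) switch
time — the earliest time the quiescent fraction `B/(A+B)` crosses ½ — with
posterior uncertainty, and the population doubling time
`ln 2 / ((dM/dt)/M)` from the model right-hand side.

**Cell-cycle assay simulator.** The sequential EdU/BrdU dual
thymidine-analog protocol on an asynchronously cycling population: the
inter-injection interval at which the EdU⁺/BrdU⁺ fraction peaks estimates
the cell-cycle duration.

**Histology metrics.** Stereological density, phagocytic (Ph) index,
clearance ratio (apoptotic load per microglia), phagocytic capacity,
un-engulfed fraction, first-order apoptotic-cohort clearance time,
apoptosis–phagocytosis coupling, and Pearson correlation matrices across
developmental metrics.

**Synthetic data.** Generators for every input, with known ground truth and
presets that reproduce the documented qualitative shapes (%Ki67 ≈ 40% at P2
collapsing below 10% by P7; density peaking mid-series; P/Q switch between
day 3 and 4). See `docs/methods.md` for model details and limitations.

## Worked example

Generate a hippocampus-like synthetic dataset, calibrate the
two-population model, and read off the P/Q switch:

```python
import warnings; warnings.filterwarnings("ignore")
from microdev import ODEModelCalibrator
from microdev.inference import PriorBounds
from microdev.synthetic import hippocampus_like_truth, generate_timeseries_dataset

truth = hippocampus_like_truth(seed=7)
data, _ = generate_timeseries_dataset(truth)          # 2 layers x 7 ages x 4 replicates

est = ODEModelCalibrator(
    model_kind="two_pop",
    topology=truth.topo,
    base_params=truth.params,
    free_names=("a1_int_A", "a2_ext_AB", "c_B", "sigma_density", "sigma_pct_ki67"),
    bounds=PriorBounds({
        "a1_int_A": (0, 4), "a2_ext_AB": (0, 8), "c_B": (0, 1),
        "sigma_density": (1e-6, 3000), "sigma_pct_ki67": (1e-6, 25),
    }),
    tau_k=truth.tau_k, sigmas=truth.sigmas,
    n_iter=2500, seed=7,
)
est.fit(data.subset(["density", "pct_ki67"]))

print(est.summary_[["mean", "q2.5", "q97.5", "rhat"]].round(3))
mean, sd = est.switch_time_posterior("DG")
print(f"\nP/Q switch (DG): {mean:.2f} +/- {sd:.2f} days   (generating value {truth.switch_times['DG']:.2f})")
print(f"WAIC: {est.score_.waic:.1f}")
```

Output:

```
                   mean     q2.5    q97.5   rhat
parameter
a1_int_A          1.180    1.154    1.211  1.036
a2_ext_AB         1.946    1.888    2.014  1.033
c_B               0.103    0.101    0.105  1.011
sigma_density   320.962  268.029  394.041  1.005
sigma_pct_ki67    2.095    1.723    2.551  1.019

P/Q switch (DG): 3.08 +/- 0.02 days   (generating value 3.04)
WAIC: 1049.9
```

Reading it: the intrinsic proliferation rate of the P population
(`a1_int_A`, generating value 1.2/day), the volume-driven differentiation
coefficient (`a2_ext_AB`, 2.0/day per unit E) and the quiescent apoptosis
rate (`c_B`, 0.10/day) are recovered inside tight 95% credible intervals;
the noise scales land near their generating values (350 cells/mm³ and 2.5
Ki67 percentage points); all split-R̂ ≤ 1.04 indicate mixed chains; and the
dentate-gyrus switch from majority-proliferative to majority-quiescent is
placed at postnatal day ≈ 3.1.

A CLI wraps the same machinery (`microdev synth | simulate | fit | select |
spreading | metrics | cellcycle`); try
`microdev cellcycle --tc 12 --seed 2 --out cc.csv`.

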