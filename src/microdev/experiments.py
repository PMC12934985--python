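"""Seeded synthetic-data validation studies.

Each study generates data from a known ground truth, runs the calibration
machinery at reduced settings, and reports how well the truth is recovered:

* :func:`twopop_recovery_study` — credible-interval coverage of the
  two-population kinetic rates and P/Q switch-time error on
  hippocampus-like data;
* :func:`model_selection_study` — how often the two-population model is the
  consensus AIC/BIC/WAIC winner on data it generated;
* :func:`topology_recovery_study` — how often the generating spreading
  direction wins the topology comparison.

The study conditions (free parameters, prior boxes, chain lengths) are fixed
module constants so results are comparable across runs; chains use the
fixed-grid RK4 fast path and mode-refined starts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import LayerTimeSeries
from .inference import (
    ParameterSpace,
    PriorBounds,
    compare_spreading_topologies,
    fit_model,
    rank_models,
)
from .models import SolverConfig
from .synthetic import (
    generate_timeseries_dataset,
    hippocampus_like_truth,
    single_layer_truth,
    spreading_truth,
)
from .topology import RegionTopology

__all__ = [
    "RECOVERY_FREE",
    "RECOVERY_BOUNDS",
    "twopop_recovery_replicate",
    "twopop_recovery_study",
    "model_selection_replicate",
    "model_selection_study",
    "topology_recovery_replicate",
    "topology_recovery_study",
]

FAST = SolverConfig(method="RK4")

# -- two-population recovery conditions -------------------------------------
RECOVERY_FREE = ("a1_int_A", "a2_ext_AB", "c_B", "sigma_density", "sigma_pct_ki67")
RECOVERY_BOUNDS = PriorBounds(
    {
        "a1_int_A": (0.0, 4.0),
        "a2_ext_AB": (0.0, 8.0),
        "c_B": (0.0, 1.0),
        "sigma_density": (1e-6, 3000.0),
        "sigma_pct_ki67": (1e-6, 25.0),
    }
)
RECOVERY_TRUTH_VALUES = {"a1_int_A": 1.2, "a2_ext_AB": 2.0, "c_B": 0.10,
                         "sigma_density": 350.0, "sigma_pct_ki67": 2.5}


def twopop_recovery_replicate(
    seed: int, n_iter: int = 2500, switch_layer: str = "DG"
) -> dict:
    """One seeded recovery replicate on hippocampus-like data.

    Generates a noisy dataset, fits the two-population model (kinetic rates
    and noise scales free; everything else at truth), and reports per-rate
    95% credible-interval coverage plus the posterior-mean switch-time error.
    """
    truth = hippocampus_like_truth(seed=seed)
    data, _ = generate_timeseries_dataset(truth, rng=np.random.default_rng(seed))
    data = data.subset(["density", "pct_ki67"])
    space = ParameterSpace(
        "two_pop", truth.topo, truth.params, RECOVERY_FREE,
        base_tau_k=truth.tau_k, base_sigmas=truth.sigmas,
    )
    fit = fit_model(
        data, space, RECOVERY_BOUNDS, n_chains=3, n_iter=n_iter,
        seed=seed, solver_cfg=FAST,
    )
    out = {"seed": seed}
    for name in RECOVERY_FREE:
        lo = fit.summary.loc[name, "q2.5"]
        hi = fit.summary.loc[name, "q97.5"]
        true_val = RECOVERY_TRUTH_VALUES[name]
        out[f"covered_{name}"] = bool(lo <= true_val <= hi)
    st_mean, st_sd = fit.switch_time_posterior(
        switch_layer, np.linspace(2.0, 28.0, 105), n_draws=60, solver_cfg=FAST
    )
    out["switch_mean"] = st_mean
    out["switch_sd"] = st_sd
    out["switch_true"] = truth.switch_times[switch_layer]
    out["switch_abs_err"] = abs(st_mean - truth.switch_times[switch_layer])
    out["max_rhat"] = float(fit.summary["rhat"].max())
    return out


def twopop_recovery_study(
    n_replicates: int = 20, seed: int = 0, n_iter: int = 2500
) -> pd.DataFrame:
    """Coverage study over seeded replicates; one row per replicate."""
    rows = [
        twopop_recovery_replicate(seed * 1000 + k, n_iter=n_iter)
        for k in range(n_replicates)
    ]
    return pd.DataFrame(rows)


# -- model-class selection ---------------------------------------------------

_SELECTION_SIGMAS = ("sigma_density", "sigma_pct_ki67")
_SELECTION_BOUNDS = {
    "r": (0.0, 10.0),
    "kappa": (0.0, 1e5),
    "p": (0.0, 10.0),
    "c": (0.0, 10.0),
    "lam": (0.0, 10.0),
    "s0.DG": (0.0, 1e5),
    "a1_int_A": (0.0, 4.0),
    "a2_ext_AB": (0.0, 8.0),
    "c_B": (0.0, 1.0),
    "sigma_density": (1e-6, 5000.0),
    "sigma_pct_ki67": (1e-6, 30.0),
}


def _candidate_spaces(truth, data: LayerTimeSeries) -> dict[str, ParameterSpace]:
    """The three model classes, each with its natural free parameters."""
    from .models import LinearSourceParams, LogisticParams

    layer = truth.topo.layers[0]
    df = data.frame
    first_age = data.ages()[0]
    m0_emp = float(
        df.loc[(df["observable"] == "density") & (df["age_days"] == first_age), "value"].mean()
    )
    vol = dict(truth.params.volume)
    logistic = LogisticParams(
        r=1.0, kappa=5000.0, c=0.0, m0={layer: m0_emp}, volume=vol
    )
    linear = LinearSourceParams(
        p=0.5, c=0.1, s0={layer: 100.0}, lam=0.5, m0={layer: m0_emp}, volume=vol
    )
    return {
        "logistic": ParameterSpace(
            "logistic", truth.topo, logistic,
            ("r", "kappa") + _SELECTION_SIGMAS,
            base_tau_k=truth.tau_k, base_sigmas=truth.sigmas,
        ),
        "linear": ParameterSpace(
            "linear", truth.topo, linear,
            ("p", "c", "s0.DG", "lam") + _SELECTION_SIGMAS,
            base_tau_k=truth.tau_k, base_sigmas=truth.sigmas,
        ),
        "two_pop": ParameterSpace(
            "two_pop", truth.topo, truth.params,
            ("a1_int_A", "a2_ext_AB", "c_B") + _SELECTION_SIGMAS,
            base_tau_k=truth.tau_k, base_sigmas=truth.sigmas,
        ),
    }


def model_selection_replicate(seed: int, n_iter: int = 2000) -> dict:
    """Fit all three model classes to one two-population dataset and rank."""
    truth = single_layer_truth(seed=seed)
    data, _ = generate_timeseries_dataset(truth, rng=np.random.default_rng(seed))
    data = data.subset(["density", "pct_ki67"])
    scores = []
    for kind, space in _candidate_spaces(truth, data).items():
        bounds = PriorBounds({n: _SELECTION_BOUNDS[n] for n in space.free_names})
        fit = fit_model(
            data, space, bounds, n_chains=3, n_iter=n_iter, seed=seed,
            solver_cfg=FAST,
        )
        scores.append(fit.score)
    ranking = rank_models(scores)
    return {"seed": seed, **{k: ranking[k][0] for k in ("aic", "bic", "waic")},
            "consensus": ranking["consensus"]}


def model_selection_study(
    n_replicates: int = 20, seed: int = 0, n_iter: int = 2000
) -> pd.DataFrame:
    rows = [
        model_selection_replicate(seed * 1000 + k, n_iter=n_iter)
        for k in range(n_replicates)
    ]
    return pd.DataFrame(rows)


# -- spreading-topology recovery ---------------------------------------------

_TOPOLOGY_DIRECTIONS = ("outward", "inward", "none")


def topology_recovery_replicate(
    seed: int, direction: str = "outward", n_iter: int = 2000
) -> dict:
    """Generate directional-spreading data; ask which topology wins."""
    truth = spreading_truth(direction, seed=seed)
    data, _ = generate_timeseries_dataset(truth, rng=np.random.default_rng(seed))
    data = data.subset(["density"])
    candidates = [spreading_truth(d, seed=seed).topo for d in _TOPOLOGY_DIRECTIONS]

    base = truth.params
    df = data.frame
    first_age = data.ages()[0]
    dens0 = df[(df["observable"] == "density") & (df["age_days"] == first_age)]
    m0_emp = {
        layer: float(dens0.loc[dens0["layer"] == layer, "value"].mean())
        for layer in truth.topo.layers
    }

    def space_builder(topo: RegionTopology) -> ParameterSpace:
        from dataclasses import replace

        params = replace(
            base, m0=m0_emp, beta={e: 0.1 for e in topo.edges}
        )
        beta_names = tuple(f"beta.{s}->{d}" for s, d in topo.edges)
        return ParameterSpace(
            "logistic", topo, params,
            ("r", "kappa", "c") + beta_names + ("sigma_density",),
            base_tau_k=truth.tau_k, base_sigmas=truth.sigmas,
        )

    def bounds_builder(space: ParameterSpace) -> PriorBounds:
        b = {"r": (0.0, 10.0), "kappa": (0.0, 1e5), "c": (0.0, 10.0),
             "sigma_density": (1e-6, 5000.0)}
        for name in space.free_names:
            if name.startswith("beta."):
                b[name] = (0.0, 5.0)
        return PriorBounds(b)

    best, ranking, _ = compare_spreading_topologies(
        "logistic", candidates, data, space_builder, bounds_builder,
        n_chains=3, n_iter=n_iter, seed=seed, solver_cfg=FAST,
    )
    winner_idx = _TOPOLOGY_DIRECTIONS[
        candidates.index(next(t for t in candidates if t is best))
    ]
    return {"seed": seed, "generating": direction, "winner": winner_idx,
            "consensus": ranking.get("consensus", "n/a")}


def topology_recovery_study(
    n_replicates: int = 10, seed: int = 0, direction: str = "outward",
    n_iter: int = 2000,
) -> pd.DataFrame:
    rows = [
        topology_recovery_replicate(seed * 1000 + k, direction, n_iter=n_iter)
        for k in range(n_replicates)
    ]
    return pd.DataFrame(rows)
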