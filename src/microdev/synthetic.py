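"""Synthetic datasets with known ground truth.

Generates every input the pipeline consumes — developmental time series,
phagocytosis count tables, dual-labeling observations — from known
parameters, emulating the statistical structure of the real measurements:
independent Gaussian replicate noise around the model curves, truncated at
zero. The shipped presets reproduce the qualitative developmental shapes
(%Ki67 near 40% at P2 collapsing below 10% by P7; density rising to a
mid-series peak then declining; a P/Q switch between day 3 and 4); they are
fixtures with convenient round numbers, not fitted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cellcycle import CyclePopulation, LabelFractions, simulate_dual_labeling
from .data import OBSERVABLES, LayerTimeSeries
from .metrics import PhagocytosisTable
from .models import (
    LinearSourceParams,
    LogisticParams,
    SolverConfig,
    TwoPopParams,
    VolumeParams,
    predict_observables,
    simulate_model,
    switch_time,
)
from .topology import EXTERNAL, RegionTopology, cerebellum_topology, hippocampus_topology

__all__ = [
    "GroundTruth",
    "hippocampus_like_truth",
    "cerebellum_like_truth",
    "single_layer_truth",
    "spreading_truth",
    "DEFAULT_AGES",
    "generate_timeseries_dataset",
    "generate_phagocytosis_table",
    "generate_cellcycle_observations",
]

DEFAULT_AGES = (2.0, 4.0, 7.0, 10.0, 14.0, 21.0, 28.0)

_PARAM_CLASS_NAMES = {"logistic": LogisticParams, "linear": LinearSourceParams,
                      "two_pop": TwoPopParams}


@dataclass
class GroundTruth:
    """A generating model: parameters, topology, noise scales and seed.

    ``switch_times`` (per layer, days; None if no switch) is derived on a
    fine grid at construction for two-population truths.
    """

    model_kind: str
    params: object
    topo: RegionTopology
    sigmas: Mapping[str, float]
    seed: int
    tau_k: float = 0.25
    switch_times: dict = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.sigmas) - set(OBSERVABLES)
        if unknown:
            raise ValueError(f"unknown observables in sigmas: {sorted(unknown)}")
        if self.model_kind == "two_pop" and not self.switch_times:
            grid = np.linspace(2.0, 28.0, 261)
            traj = simulate_model(self.model_kind, self.params, self.topo, grid,
                                  SolverConfig(rtol=1e-8, atol=1e-10))
            self.switch_times = {
                layer: switch_time(traj, layer) for layer in self.topo.layers
            }

    # -- JSON round trip (edge keys flattened to "SRC->DST") ---------------
    def to_json(self, path: str | Path) -> None:
        import dataclasses as dc

        def flatten(obj):
            if isinstance(obj, dict):
                return {
                    ("->".join(k) if isinstance(k, tuple) else k): flatten(v)
                    for k, v in obj.items()
                }
            return obj

        payload = {
            "model_kind": self.model_kind,
            "params": flatten(dc.asdict(self.params)),
            "topology": {
                "region": self.topo.region_name,
                "layers": list(self.topo.layers),
                "edges": [list(e) for e in self.topo.edges],
            },
            "sigmas": dict(self.sigmas),
            "seed": self.seed,
            "tau_k": self.tau_k,
            "switch_times": self.switch_times,
            "description": self.description,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        kind = payload["model_kind"]
        pd_ = payload["params"]
        pd_["volume"] = {l: VolumeParams(**v) for l, v in pd_["volume"].items()}
        for key in ("beta", "beta_A", "beta_B"):
            if key in pd_:
                pd_[key] = {tuple(k.split("->")): v for k, v in pd_[key].items()}
        params = _PARAM_CLASS_NAMES[kind](**pd_)
        topo = RegionTopology(
            payload["topology"]["region"],
            tuple(payload["topology"]["layers"]),
            tuple(tuple(e) for e in payload["topology"]["edges"]),
        )
        return cls(
            model_kind=kind, params=params, topo=topo, sigmas=payload["sigmas"],
            seed=payload["seed"], tau_k=payload["tau_k"],
            switch_times=payload["switch_times"], description=payload["description"],
        )


# ---------------------------------------------------------------------------
# Shipped presets
# ---------------------------------------------------------------------------

_HIPP_SIGMAS = {"volume": 0.08, "density": 350.0, "pct_ki67": 2.5}


def hippocampus_like_truth(seed: int = 0) -> GroundTruth:
    """Two-population truth over CA/DG with EXTERNAL->CA->DG spreading.

    Noise-free curves: %Ki67 = 40% at P2 falling below 10% by P7, density
    peaking mid-series, P/Q switch near day 3 (DG slightly earlier than CA).
    """
    topo = hippocampus_topology()
    params = TwoPopParams(
        a1_int_A=1.2, a1_int_B=0.06, a2_ext_AB=2.0, c_A=0.05, c_B=0.10,
        A0={"CA": 1500.0, "DG": 1100.0}, B0={},
        volume={"CA": VolumeParams(1.0, 3.0, 0.20), "DG": VolumeParams(0.5, 1.5, 0.30)},
        beta_A={(EXTERNAL, "CA"): 150.0, ("CA", "DG"): 0.02},
        beta_B={("CA", "DG"): 0.02},
        lam_ext=0.5,
    )
    return GroundTruth(
        model_kind="two_pop", params=params, topo=topo, sigmas=dict(_HIPP_SIGMAS),
        seed=seed, tau_k=1.0 / 3.0, description="hippocampus-like two-population preset",
    )


def cerebellum_like_truth(seed: int = 0) -> GroundTruth:
    """Two-population truth over WM/GL/ML with outward spreading.

    Lower densities than the hippocampal preset and later switches (around
    day 4), the granular layer switching last.
    """
    topo = cerebellum_topology()
    params = TwoPopParams(
        a1_int_A=1.2, a1_int_B=0.05, a2_ext_AB=2.2, c_A=0.05, c_B=0.10,
        A0={"WM": 1400.0, "GL": 700.0, "ML": 500.0}, B0={},
        volume={
            "WM": VolumeParams(0.30, 1.2, 0.28),
            "GL": VolumeParams(0.50, 2.5, 0.20),
            "ML": VolumeParams(0.40, 1.8, 0.24),
        },
        beta_A={("WM", "GL"): 0.05, ("GL", "ML"): 0.05},
        beta_B={("WM", "GL"): 0.02, ("GL", "ML"): 0.02},
    )
    return GroundTruth(
        model_kind="two_pop", params=params, topo=topo, sigmas=dict(_HIPP_SIGMAS),
        seed=seed, tau_k=1.0 / 3.0, description="cerebellum-like two-population preset",
    )


def single_layer_truth(seed: int = 0) -> GroundTruth:
    """One-layer (DG-like) two-population truth without spreading.

    The cheapest ground truth that still shows the density peak and the
    %Ki67 collapse; used for model-selection and parameter-recovery studies.
    """
    topo = RegionTopology("dg_like", ("DG",))
    params = TwoPopParams(
        a1_int_A=1.2, a1_int_B=0.06, a2_ext_AB=2.0, c_A=0.05, c_B=0.10,
        A0={"DG": 1100.0}, B0={},
        volume={"DG": VolumeParams(0.5, 1.5, 0.30)},
    )
    return GroundTruth(
        model_kind="two_pop", params=params, topo=topo, sigmas=dict(_HIPP_SIGMAS),
        seed=seed, tau_k=1.0 / 3.0, description="single-layer two-population preset",
    )


def spreading_truth(direction: str = "outward", seed: int = 0) -> GroundTruth:
    """Logistic-model truth over WM/GL/ML with directional spreading.

    ``direction``: ``outward`` (WM->GL->ML), ``inward`` (ML->GL->WM) or
    ``none``. Used to test whether topology comparison recovers the
    generating spreading route.
    """
    layers = ("WM", "GL", "ML")
    edges = {
        "outward": (("WM", "GL"), ("GL", "ML")),
        "inward": (("ML", "GL"), ("GL", "WM")),
        "none": (),
    }
    if direction not in edges:
        raise ValueError(f"direction must be one of {sorted(edges)}")
    topo = RegionTopology("cerebellum_variant", layers, edges[direction])
    beta = {e: 0.35 for e in edges[direction]}
    params = LogisticParams(
        r=0.9, kappa=9000.0, c=0.02,
        m0={"WM": 2500.0, "GL": 600.0, "ML": 400.0},
        volume={
            "WM": VolumeParams(0.30, 1.2, 0.20),
            "GL": VolumeParams(0.50, 2.5, 0.12),
            "ML": VolumeParams(0.40, 1.8, 0.16),
        },
        beta=beta,
    )
    return GroundTruth(
        model_kind="logistic", params=params, topo=topo,
        sigmas={"volume": 0.08, "density": 250.0, "pct_ki67": 2.5},
        seed=seed, tau_k=1.0 / 3.0,
        description=f"logistic spreading preset ({direction})",
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_timeseries_dataset(
    truth: GroundTruth,
    ages: Sequence[float] = DEFAULT_AGES,
    n_replicates: int = 4,
    rng: np.random.Generator | None = None,
    observables: Sequence[str] = OBSERVABLES,
) -> tuple[LayerTimeSeries, GroundTruth]:
    """Simulate the truth and add independent Gaussian replicate noise.

    Each observation is ``N(model prediction, sigma_observable)`` truncated
    at zero. With all sigmas zero the observations equal the predictions
    exactly. Returns the dataset together with its ground truth.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ages = np.asarray(sorted(ages), dtype=float)
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    traj = simulate_model(truth.model_kind, truth.params, truth.topo, ages)
    obs = predict_observables(traj, tau_k=truth.tau_k)
    grids = {"volume": obs.volume, "density": obs.density, "pct_ki67": obs.pct_ki67}
    rows = []
    for li, layer in enumerate(truth.topo.layers):
        for ai, age in enumerate(ages):
            for rep in range(1, n_replicates + 1):
                for kind in observables:
                    mean = grids[kind][li, ai]
                    value = mean + rng.normal(0.0, truth.sigmas[kind]) if truth.sigmas[kind] else mean
                    rows.append(
                        {
                            "region": truth.topo.region_name,
                            "layer": layer,
                            "age_days": age,
                            "replicate": rep,
                            "observable": kind,
                            "value": max(0.0, value),
                        }
                    )
    dataset = LayerTimeSeries(truth.topo.region_name, pd.DataFrame(rows))
    return dataset, truth


def generate_phagocytosis_table(
    n_microglia: int,
    lambda_load: float,
    engagement_prob: float,
    pouch_dist: Mapping[int, float] | None = None,
    seed: int = 0,
) -> PhagocytosisTable:
    """Random phagocytosis count table with all invariants satisfied.

    ``lambda_load`` is the mean apoptotic load (apoptotic cells per
    microglia): apoptotic count ~ Poisson(n * lambda_load). Engaged microglia
    ~ Binomial(n, engagement_prob); their pouch numbers follow ``pouch_dist``
    (a distribution over counts >= 1; default: single pouches). Each pouch
    holds one apoptotic cell, so engulfed = min(apoptotic, total pouches).
    """
    if n_microglia <= 0:
        raise ValueError("n_microglia must be positive")
    if not (0.0 <= engagement_prob <= 1.0):
        raise ValueError("engagement_prob must be in [0,1]")
    if lambda_load < 0:
        raise ValueError("lambda_load must be >= 0")
    pouch_dist = dict(pouch_dist or {1: 1.0})
    if any(k < 1 for k in pouch_dist) or not np.isclose(sum(pouch_dist.values()), 1.0):
        raise ValueError("pouch_dist must be a distribution over counts >= 1")
    rng = np.random.default_rng(seed)
    n_apoptotic = int(rng.poisson(n_microglia * lambda_load))
    n_engaged = int(rng.binomial(n_microglia, engagement_prob))
    ks = sorted(pouch_dist)
    probs = np.array([pouch_dist[k] for k in ks])
    pouch_counts = rng.choice(ks, size=n_engaged, p=probs)
    histogram = {0: n_microglia - n_engaged}
    for k in ks:
        n_k = int(np.count_nonzero(pouch_counts == k))
        if n_k:
            histogram[k] = n_k
    total_pouches = int(pouch_counts.sum()) if n_engaged else 0
    return PhagocytosisTable(
        n_microglia=n_microglia,
        n_apoptotic=n_apoptotic,
        n_apoptotic_engulfed=min(n_apoptotic, total_pouches),
        pouch_histogram=histogram,
    )


def generate_cellcycle_observations(
    tc_mean: float,
    tc_cv: float,
    ts: float,
    intervals: Sequence[float],
    n_cells: int,
    seed: int = 0,
    cycling_fraction: float = 1.0,
) -> tuple[list[LabelFractions], dict]:
    """Dual-labeling observations at each interval, bundled with the truth."""
    pop = CyclePopulation(
        n_cells=n_cells, tc_mean=tc_mean, tc_cv=tc_cv, ts=ts, seed=seed,
        cycling_fraction=cycling_fraction,
    )
    observed = [simulate_dual_labeling(pop, i) for i in intervals]
    truth = {"tc_mean": tc_mean, "tc_cv": tc_cv, "ts": ts, "n_cells": n_cells,
             "seed": seed, "cycling_fraction": cycling_fraction}
    return observed, truth
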