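"""microdev: ODE modeling and Bayesian calibration of microglial development.

Quantitative toolkit for postnatal microglial colonization of brain
sub-regions: nested compartmental ODE models (logistic, linear-with-source,
two-population proliferative/quiescent), adaptive Metropolis–Hastings
calibration with AIC/BIC/WAIC model selection, derived developmental
milestones (P/Q switch time, doubling time), phagocytosis and clearance
metrics from histology count tables, and a simulator of the sequential
EdU/BrdU dual-labeling cell-cycle assay.
"""

from .topology import EXTERNAL, RegionTopology, hippocampus_topology, cerebellum_topology
from .models import (
    VolumeParams,
    LogisticParams,
    LinearSourceParams,
    TwoPopParams,
    SolverConfig,
    Trajectory,
    ObservableSeries,
    volume_trajectory,
    environmental_factor,
    simulate_model,
    predict_observables,
    subpopulation_fractions,
    switch_time,
    doubling_time,
)

__version__ = "0.1.0"

from .estimator import ODEModelCalibrator  # noqa: E402


def __getattr__(name):
    # lazy submodule access: microdev.inference, microdev.metrics, ...
    import importlib

    if name in (
        "inference", "metrics", "cellcycle", "synthetic", "experiments",
        "io", "data", "cli",
    ):
        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
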