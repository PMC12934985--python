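"""Scikit-learn-style front end for Bayesian model calibration.

:class:`ODEModelCalibrator` wraps the parameter-space / likelihood / sampler
machinery behind the estimator protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes), so a
calibration can sit inside sklearn tooling. The functional interface in
:mod:`microdev.inference` remains the primitive layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import COLUMNS, LayerTimeSeries
from .inference import ParameterSpace, PriorBounds, default_bounds, fit_model
from .models import SolverConfig, predict_observables, simulate_model
from .topology import RegionTopology

__all__ = ["ODEModelCalibrator"]


class ODEModelCalibrator(BaseEstimator):
    """Calibrate a colonization model to a developmental time series.

    Parameters
    ----------
    model_kind : {"logistic", "linear", "two_pop"}
        Model class to fit.
    topology : RegionTopology
        Layers and spreading edges of the region.
    base_params : model parameter object
        Values for every parameter; coordinates named in ``free_names`` are
        sampled, the rest stay fixed.
    free_names : tuple of str
        Sampled coordinates (model fields, dotted per-layer/edge paths,
        ``tau_k``, ``sigma_<observable>``).
    bounds : PriorBounds or None
        Uniform prior box; None uses the shipped defaults derived from the
        data.
    tau_k : float
        Ki67 visibility window (days) when not sampled.
    sigmas : dict or None
        Per-observable noise scales when not sampled.
    n_chains, n_iter, seed, burn_in_frac, solver_method, refine_starts
        Sampler settings (see :func:`microdev.inference.fit_model`).

    Attributes
    ----------
    result_ : FitResult
        Chains, posterior summary and information criteria.
    summary_ : pandas.DataFrame
        Per-parameter posterior summary with split-Rhat.
    score_ : ModelScore
        AIC/BIC/WAIC of the fitted model.
    params_ : model parameter object
        Parameters rebuilt at the marginal posterior medians.
    tau_k_ : float
        Posterior-median Ki67 window (or the fixed value).
    n_obs_ : int
        Number of observations used.
    """

    def __init__(
        self,
        model_kind: str = "two_pop",
        topology: RegionTopology | None = None,
        base_params=None,
        free_names: tuple[str, ...] = (),
        bounds: PriorBounds | None = None,
        tau_k: float = 0.25,
        sigmas: dict | None = None,
        n_chains: int = 3,
        n_iter: int = 2000,
        seed: int = 0,
        burn_in_frac: float = 0.5,
        solver_method: str = "RK4",
        refine_starts: bool = True,
    ):
        self.model_kind = model_kind
        self.topology = topology
        self.base_params = base_params
        self.free_names = free_names
        self.bounds = bounds
        self.tau_k = tau_k
        self.sigmas = sigmas
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.seed = seed
        self.burn_in_frac = burn_in_frac
        self.solver_method = solver_method
        self.refine_starts = refine_starts

    # -- estimator protocol -------------------------------------------------

    def _as_dataset(self, X) -> LayerTimeSeries:
        if isinstance(X, LayerTimeSeries):
            return X
        if isinstance(X, pd.DataFrame):
            missing = [c for c in COLUMNS if c not in X.columns]
            if missing:
                raise ValueError(f"data frame missing columns {missing}")
            return LayerTimeSeries(str(X["region"].iloc[0]), X.copy())
        raise TypeError("X must be a LayerTimeSeries or a long-format DataFrame")

    def fit(self, X, y=None) -> "ODEModelCalibrator":
        """Run the adaptive-MH calibration on a long-format dataset."""
        if self.topology is None or self.base_params is None:
            raise ValueError("topology and base_params are required before fit")
        data = self._as_dataset(X)
        sigmas = self.sigmas or {"volume": 1.0, "density": 1.0, "pct_ki67": 1.0}
        space = ParameterSpace(
            self.model_kind, self.topology, self.base_params,
            tuple(self.free_names), base_tau_k=self.tau_k, base_sigmas=sigmas,
        )
        bounds = self.bounds or default_bounds(space, data)
        result = fit_model(
            data, space, bounds,
            n_chains=self.n_chains, n_iter=self.n_iter, seed=self.seed,
            burn_in_frac=self.burn_in_frac,
            solver_cfg=SolverConfig(method=self.solver_method),
            refine_starts=self.refine_starts,
        )
        self.result_ = result
        self.summary_ = result.summary
        self.score_ = result.score
        params, tau_k, fitted_sigmas = result.posterior_median_params()
        self.params_ = params
        self.tau_k_ = tau_k
        self.sigmas_ = fitted_sigmas
        self.n_obs_ = result.score.n_obs
        return self

    def predict(self, ages) -> pd.DataFrame:
        """Posterior-median model observables at the requested ages.

        Returns a long frame (layer, age_days, observable, value) matching
        the input data schema, so predictions align row-wise with data.
        """
        self._check_fitted()
        grid = np.asarray(sorted(set(float(a) for a in np.atleast_1d(ages))))
        traj = simulate_model(
            self.model_kind, self.params_, self.topology, grid,
            SolverConfig(method=self.solver_method),
        )
        obs = predict_observables(traj, tau_k=self.tau_k_)
        rows = []
        grids = {"density": obs.density, "volume": obs.volume, "pct_ki67": obs.pct_ki67}
        for li, layer in enumerate(self.topology.layers):
            for ai, age in enumerate(grid):
                for kind, arr in grids.items():
                    rows.append({"layer": layer, "age_days": age,
                                 "observable": kind, "value": arr[li, ai]})
        return pd.DataFrame(rows)

    def switch_time_posterior(self, layer: str, t_grid=None, n_draws: int = 60):
        """Posterior mean and sd of the P/Q switch time in one layer."""
        self._check_fitted()
        if self.model_kind != "two_pop":
            raise ValueError("switch times require the two-population model")
        grid = t_grid if t_grid is not None else np.linspace(2.0, 28.0, 105)
        return self.result_.switch_time_posterior(
            layer, grid, n_draws=n_draws,
            solver_cfg=SolverConfig(method=self.solver_method),
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise RuntimeError("this ODEModelCalibrator instance is not fitted yet")
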