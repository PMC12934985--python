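"""Bayesian calibration of the colonization models.

Observations are taken to be independent and normally distributed around the
model output, with one noise scale per observable class (volume, density,
%Ki67) sampled alongside the kinetic parameters. Priors are uniform boxes
with lower bound zero. Posteriors are drawn with a Metropolis–Hastings
sampler whose multivariate-normal proposal covariance adapts to the running
empirical covariance of the chain (Haario-style: scale 2.38^2/d plus a small
ridge), and models are ranked by AIC, BIC and WAIC computed from the chains.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import OBSERVABLES, LayerTimeSeries
from .models import (
    IntegrationError,
    LinearSourceParams,
    LogisticParams,
    SolverConfig,
    TwoPopParams,
    VolumeParams,
    predict_observables,
    simulate_model,
    switch_time,
)
from .topology import RegionTopology

__all__ = [
    "PriorBounds",
    "ParameterSpace",
    "ChainSet",
    "ModelScore",
    "FitResult",
    "ModelLikelihood",
    "log_prior",
    "run_adaptive_mh",
    "posterior_summary",
    "split_rhat",
    "information_criteria",
    "rank_models",
    "fit_model",
    "compare_spreading_topologies",
    "default_bounds",
]

_PARAM_CLASSES = {
    "logistic": LogisticParams,
    "linear": LinearSourceParams,
    "two_pop": TwoPopParams,
}

SIGMA_NAMES = {f"sigma_{obs}" for obs in OBSERVABLES}


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorBounds:
    """Independent uniform prior box, one (lower, upper) pair per parameter.

    All rate/scale parameters have lower bound zero (enforced here); upper
    bounds must be supplied by the user or by :func:`default_bounds`.
    """

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bound for {name!r} must have lower < upper, got ({lo}, {hi})")
            if lo < 0:
                raise ValueError(f"rate/scale parameter {name!r} needs lower bound >= 0")

    def as_arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        missing = [n for n in names if n not in self.bounds]
        if missing:
            raise KeyError(f"no prior bound supplied for parameters {missing}")
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])
        return lo, hi


def log_prior(theta: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """Uniform-box log density: constant inside, -inf outside."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < lo) or np.any(theta > hi):
        return -np.inf
    return -float(np.sum(np.log(hi - lo)))


# ---------------------------------------------------------------------------
# Parameter space: vector <-> model parameters
# ---------------------------------------------------------------------------


def _params_to_dict(params) -> dict:
    d = dataclasses.asdict(params)
    return d


def _rebuild_params(kind: str, d: dict):
    d = copy.deepcopy(d)
    d["volume"] = {
        layer: vp if isinstance(vp, VolumeParams) else VolumeParams(**vp)
        for layer, vp in d["volume"].items()
    }
    return _PARAM_CLASSES[kind](**d)


def _set_path(d: dict, name: str, value: float) -> None:
    """Assign into the nested parameter dict by dotted path.

    Paths: plain field (``r``), per-layer entry (``m0.CA``), volume field
    (``volume.CA.v0``), per-edge rate (``beta.CA->DG`` or
    ``beta_A.EXTERNAL->CA``).
    """
    parts = name.split(".")
    node = d
    for part in parts[:-1]:
        if part not in node:
            raise KeyError(f"unknown parameter path {name!r} (at {part!r})")
        node = node[part]
    leaf = parts[-1]
    if "->" in leaf:
        src, dst = leaf.split("->")
        node[(src, dst)] = value
    else:
        if leaf not in node and parts[:-1]:
            # per-layer mappings may start empty (e.g. m0 for a new layer)
            node[leaf] = value
        elif leaf not in node:
            raise KeyError(f"unknown parameter {name!r}")
        else:
            node[leaf] = value


@dataclass
class ParameterSpace:
    """Maps a flat sampled vector onto model parameters, tau_k and sigmas.

    ``free_names`` lists the sampled coordinates in order; everything else is
    held at the values in ``base``. Special names: ``tau_k`` (Ki67 window)
    and ``sigma_<observable>`` (noise scales).
    """

    model_kind: str
    topo: RegionTopology
    base: object  # LogisticParams | LinearSourceParams | TwoPopParams
    free_names: tuple[str, ...]
    base_tau_k: float = 0.25
    base_sigmas: Mapping[str, float] = field(
        default_factory=lambda: {obs: 1.0 for obs in OBSERVABLES}
    )

    def __post_init__(self) -> None:
        if self.model_kind not in _PARAM_CLASSES:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        self.free_names = tuple(self.free_names)
        self._base_dict = _params_to_dict(self.base)
        self.build(np.array([self._default_value(n) for n in self.free_names]))

    def _default_value(self, name: str) -> float:
        if name == "tau_k":
            return self.base_tau_k
        if name in SIGMA_NAMES:
            return self.base_sigmas[name[len("sigma_"):]]
        return 0.1

    @property
    def n_params(self) -> int:
        return len(self.free_names)

    def build(self, theta: np.ndarray):
        """Return (model params, tau_k, sigma dict) for a sampled vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.free_names),):
            raise ValueError(
                f"theta has shape {theta.shape}, expected ({len(self.free_names)},)"
            )
        d = copy.deepcopy(self._base_dict)
        tau_k = self.base_tau_k
        sigmas = dict(self.base_sigmas)
        for name, value in zip(self.free_names, theta):
            if name == "tau_k":
                tau_k = float(value)
            elif name in SIGMA_NAMES:
                sigmas[name[len("sigma_"):]] = float(value)
            else:
                _set_path(d, name, float(value))
        return _rebuild_params(self.model_kind, d), tau_k, sigmas


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


class ModelLikelihood:
    """Gaussian likelihood of a LayerTimeSeries under a colonization model.

    Calling with a sampled vector returns ``(total, pointwise)`` where
    ``pointwise`` has one entry per observation row (needed for WAIC).
    A solver failure yields ``-inf`` and is treated as a rejected proposal.
    """

    def __init__(
        self,
        data: LayerTimeSeries,
        space: ParameterSpace,
        solver_cfg: SolverConfig | None = None,
    ):
        self.space = space
        self.solver_cfg = solver_cfg or SolverConfig()
        df = data.frame
        unknown = set(df["layer"]) - set(space.topo.layers)
        if unknown:
            raise ValueError(
                f"data layers {sorted(unknown)} not in topology {space.topo.layers}"
            )
        self.t_grid = np.sort(df["age_days"].unique()).astype(float)
        age_index = {a: i for i, a in enumerate(self.t_grid)}
        self._rows_layer = df["layer"].map(space.topo.layer_index).to_numpy()
        self._rows_age = df["age_days"].map(age_index).to_numpy()
        self._rows_obs = df["observable"].to_numpy()
        self._values = df["value"].to_numpy(dtype=float)
        self.n_obs = len(df)

    def predicted(self, theta: np.ndarray) -> np.ndarray:
        params, tau_k, _ = self.space.build(theta)
        traj = simulate_model(
            self.space.model_kind, params, self.space.topo, self.t_grid, self.solver_cfg
        )
        obs = predict_observables(traj, tau_k=tau_k)
        grids = {"volume": obs.volume, "density": obs.density, "pct_ki67": obs.pct_ki67}
        mu = np.empty(self.n_obs)
        for kind in OBSERVABLES:
            mask = self._rows_obs == kind
            if mask.any():
                mu[mask] = grids[kind][self._rows_layer[mask], self._rows_age[mask]]
        return mu

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray | None]:
        _, _, sigmas = self.space.build(theta)
        sig = np.array([sigmas[k] for k in self._rows_obs])
        if np.any(sig <= 0):
            return -np.inf, None
        try:
            mu = self.predicted(theta)
        except IntegrationError as exc:
            warnings.warn(f"solver failure treated as rejected proposal: {exc}")
            return -np.inf, None
        resid = self._values - mu
        pointwise = -0.5 * np.log(2.0 * np.pi * sig**2) - 0.5 * (resid / sig) ** 2
        return float(pointwise.sum()), pointwise


def make_log_posterior(
    likelihood: ModelLikelihood, bounds: PriorBounds
) -> tuple[Callable, np.ndarray, np.ndarray]:
    """Posterior closure returning (log_post, loglik, pointwise)."""
    lo, hi = bounds.as_arrays(likelihood.space.free_names)

    def log_post(theta):
        lp = log_prior(theta, lo, hi)
        if not np.isfinite(lp):
            return -np.inf, -np.inf, None
        ll, pointwise = likelihood(theta)
        if not np.isfinite(ll):
            return -np.inf, -np.inf, None
        return lp + ll, ll, pointwise

    return log_post, lo, hi


# ---------------------------------------------------------------------------
# Adaptive Metropolis–Hastings
# ---------------------------------------------------------------------------


@dataclass
class ChainSet:
    """MCMC draws plus per-draw diagnostics.

    ``pointwise_loglik`` is (n_chains, n_iter, n_obs) or None when the target
    supplies no pointwise decomposition (e.g. analytic test targets).
    """

    draws: np.ndarray  # (n_chains, n_iter, d)
    log_posterior: np.ndarray  # (n_chains, n_iter)
    loglik: np.ndarray  # (n_chains, n_iter)
    acceptance_rate: np.ndarray  # (n_chains,)
    seed: int
    burn_in: int
    param_names: tuple[str, ...]
    pointwise_loglik: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.acceptance_rate <= 0) or np.any(self.acceptance_rate >= 1):
            raise ValueError("acceptance rates must lie strictly inside (0, 1)")
        if self.pointwise_loglik is not None:
            if self.pointwise_loglik.shape[:2] != self.draws.shape[:2]:
                raise ValueError("pointwise log-likelihood rows must match draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def retained(self) -> np.ndarray:
        """Post-burn-in draws pooled across chains, (n_retained, d)."""
        return self.draws[:, self.burn_in:, :].reshape(-1, self.draws.shape[2])

    def retained_pointwise(self) -> np.ndarray:
        if self.pointwise_loglik is None:
            raise ValueError("chains carry no pointwise log-likelihoods")
        n_obs = self.pointwise_loglik.shape[2]
        return self.pointwise_loglik[:, self.burn_in:, :].reshape(-1, n_obs)


def _normalize_target(log_post: Callable) -> Callable:
    """Accept targets returning a float or a (lp, loglik, pointwise) tuple."""

    def wrapped(theta):
        out = log_post(theta)
        if isinstance(out, tuple):
            return out
        return float(out), float(out), None

    return wrapped


def run_adaptive_mh(
    log_post: Callable,
    bounds,
    n_chains: int = 3,
    n_iter: int = 5000,
    seed: int = 0,
    burn_in_frac: float = 0.5,
    adapt_start: int = 200,
    eps: float = 1e-8,
    param_names: Sequence[str] | None = None,
    target_acceptance: float = 0.234,
    init_points: np.ndarray | None = None,
) -> ChainSet:
    """Adaptive-covariance Metropolis–Hastings over a uniform prior box.

    The proposal is multivariate normal; after ``adapt_start`` iterations its
    covariance is the running empirical covariance of the chain history
    scaled by 2.38^2/d, plus ``eps * I``. A Robbins–Monro global step-size
    factor is additionally tuned toward ``target_acceptance`` (the optimal
    random-walk acceptance rate), which stabilizes the early phase when the
    empirical covariance is still poor. Initial points are drawn uniformly
    inside ``bounds`` per chain. Fully reproducible from ``seed``.

    Internally the walk runs in box-normalized coordinates
    ``u = (theta - lo)/(hi - lo)`` — a linear reparameterization that leaves
    the uniform prior and the accept/reject ratio untouched but makes the
    ``eps`` ridge and the pre-adaptation proposal meaningful when parameter
    scales differ by orders of magnitude (rates ~1/day vs densities ~10^3).

    ``bounds`` is either a PriorBounds (with ``param_names``) or an
    (d, 2) array of (lower, upper) rows.
    """
    if n_chains < 3:
        raise ValueError("need n_chains >= 3 (split-Rhat requires several chains)")
    if n_iter < 2000:
        raise ValueError("need n_iter >= 2000 for a usable adaptive run")
    if isinstance(bounds, PriorBounds):
        if param_names is None:
            param_names = tuple(bounds.bounds.keys())
        lo, hi = bounds.as_arrays(param_names)
    else:
        arr = np.asarray(bounds, dtype=float)
        lo, hi = arr[:, 0], arr[:, 1]
        if param_names is None:
            param_names = tuple(f"p{i}" for i in range(lo.size))
    d = lo.size
    target = _normalize_target(log_post)
    scale = 2.38**2 / d

    draws = np.empty((n_chains, n_iter, d))
    lps = np.empty((n_chains, n_iter))
    lls = np.empty((n_chains, n_iter))
    pointwise_store: list | None = None
    accept_rates = np.empty(n_chains)

    if init_points is not None:
        init_points = np.asarray(init_points, dtype=float)
        if init_points.shape != (n_chains, d):
            raise ValueError(f"init_points must have shape ({n_chains}, {d})")

    width = hi - lo
    unscale = lambda u: lo + u * width  # noqa: E731

    root = np.random.SeedSequence(seed)
    for c, ss in enumerate(root.spawn(n_chains)):
        rng = np.random.default_rng(ss)
        # box-normalized coordinates u in [0, 1]^d
        if init_points is not None:
            u = (init_points[c] - lo) / width
        else:
            u = rng.uniform(0.0, 1.0, d)
        lp, ll, pw = target(unscale(u))
        tries = 0
        while not np.isfinite(lp):
            tries += 1
            if tries > 200:
                raise RuntimeError(
                    "could not find a finite-posterior start point inside the prior box"
                )
            u = rng.uniform(0.0, 1.0, d)
            lp, ll, pw = target(unscale(u))
        if pw is not None and pointwise_store is None:
            pointwise_store = [np.empty((n_iter, len(pw))) for _ in range(n_chains)]

        # running mean / scatter of the (normalized) chain history
        mean = u.copy()
        scatter = np.zeros((d, d))
        count = 1
        pre_chol = np.linalg.cholesky(
            scale * np.diag(np.full(d, 1.0 / 20.0) ** 2) + eps * np.eye(d)
        )
        chol = pre_chol
        log_eta = 0.0  # Robbins–Monro global step-size factor
        n_accept = 0

        for it in range(n_iter):
            # small fixed-covariance mixture component keeps directions the
            # empirical covariance has not yet explored from freezing
            if rng.uniform() < 0.05:
                prop = u + pre_chol @ rng.standard_normal(d)
            else:
                prop = u + np.exp(0.5 * log_eta) * (chol @ rng.standard_normal(d))
            lp_p, ll_p, pw_p = target(unscale(prop))
            accepted = np.log(rng.uniform()) < lp_p - lp
            if accepted:
                u, lp, ll, pw = prop, lp_p, ll_p, pw_p
                n_accept += 1
            log_eta += (it + 1) ** -0.6 * (float(accepted) - target_acceptance)
            draws[c, it] = unscale(u)
            lps[c, it] = lp
            lls[c, it] = ll
            if pointwise_store is not None:
                pointwise_store[c][it] = pw

            count += 1
            delta = u - mean
            mean += delta / count
            scatter += np.outer(delta, u - mean)
            if it + 1 >= adapt_start:
                cov = scatter / (count - 1)
                chol = np.linalg.cholesky(scale * cov + eps * np.eye(d))

        rate = n_accept / n_iter
        if rate < 0.001:
            raise RuntimeError(
                f"chain {c} accepted {rate:.2%} of proposals; "
                "revise prior bounds or initial scales"
            )
        accept_rates[c] = rate

    pointwise = np.stack(pointwise_store) if pointwise_store is not None else None
    return ChainSet(
        draws=draws,
        log_posterior=lps,
        loglik=lls,
        acceptance_rate=accept_rates,
        seed=seed,
        burn_in=int(burn_in_frac * n_iter),
        param_names=tuple(param_names),
        pointwise_loglik=pointwise,
    )


# ---------------------------------------------------------------------------
# Diagnostics and model scores
# ---------------------------------------------------------------------------


def split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat of one parameter from a (n_chains, n_iter) array."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    within = halves.var(axis=1, ddof=1).mean()
    between = n * means.var(ddof=1)
    if within == 0:
        warnings.warn("zero-variance chains; Rhat reported as 1 (degenerate chain)")
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def posterior_summary(chains: ChainSet, rhat_flag: float = 1.05) -> pd.DataFrame:
    """Posterior means, sds, percentiles and split-Rhat per parameter."""
    if chains.burn_in >= chains.draws.shape[1]:
        raise ValueError("burn-in must be smaller than the number of iterations")
    post = chains.draws[:, chains.burn_in:, :]
    pooled = post.reshape(-1, post.shape[2])
    rows = []
    for j, name in enumerate(chains.param_names):
        col = pooled[:, j]
        rhat = split_rhat(post[:, :, j])
        rows.append(
            {
                "parameter": name,
                "mean": col.mean(),
                "sd": col.std(ddof=1) if col.size > 1 else 0.0,
                "q2.5": np.percentile(col, 2.5),
                "q50": np.percentile(col, 50),
                "q97.5": np.percentile(col, 97.5),
                "rhat": rhat,
                "converged": rhat <= rhat_flag,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class ModelScore:
    """Information-criterion scores of one fitted model (lower is better)."""

    model_id: str
    max_loglik: float
    aic: float
    bic: float
    waic: float
    n_params: int
    n_obs: int
    effective_params_waic: float

    def __post_init__(self) -> None:
        if not np.isclose(self.aic, 2 * self.n_params - 2 * self.max_loglik):
            raise ValueError("AIC identity violated")
        if not np.isclose(
            self.bic, self.n_params * np.log(self.n_obs) - 2 * self.max_loglik
        ):
            raise ValueError("BIC identity violated")


def information_criteria(chains: ChainSet, model_id: str = "model") -> ModelScore:
    """AIC/BIC from the best sampled log-likelihood; WAIC from pointwise draws.

    WAIC uses the variance penalty: ``-2 * sum_i [lppd_i - var_draws(ll_i)]``
    with ``lppd_i = log mean_draws exp(ll_i)``.
    """
    pw = chains.retained_pointwise()
    if pw.shape[0] < 2:
        raise ValueError("WAIC needs at least 2 retained draws")
    n_obs = pw.shape[1]
    n_params = len(chains.param_names)
    max_ll = float(np.max(chains.loglik))
    lppd = logsumexp(pw, axis=0) - np.log(pw.shape[0])
    p_waic = pw.var(axis=0, ddof=1)
    waic = -2.0 * float(np.sum(lppd - p_waic))
    return ModelScore(
        model_id=model_id,
        max_loglik=max_ll,
        aic=2 * n_params - 2 * max_ll,
        bic=n_params * np.log(n_obs) - 2 * max_ll,
        waic=waic,
        n_params=n_params,
        n_obs=n_obs,
        effective_params_waic=float(np.sum(p_waic)),
    )


def rank_models(scores: Sequence[ModelScore]) -> dict:
    """Rank fitted models by each criterion; lower scores win.

    Returns a dict with per-criterion orderings (model ids, best first) and a
    ``consensus`` entry: the model ranked first by all three criteria, or
    ``"discordant"`` if the criteria disagree.
    """
    if not scores:
        raise ValueError("no scores supplied")
    n_obs = {s.n_obs for s in scores}
    if len(n_obs) > 1:
        raise ValueError(f"scores computed on different data sizes {sorted(n_obs)}")
    out = {}
    winners = set()
    for crit in ("aic", "bic", "waic"):
        order = sorted(scores, key=lambda s: getattr(s, crit))
        out[crit] = [s.model_id for s in order]
        winners.add(order[0].model_id)
    out["consensus"] = winners.pop() if len(winners) == 1 else "discordant"
    return out


# ---------------------------------------------------------------------------
# End-to-end fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """One calibrated model: chains, summary table, information criteria."""

    chains: ChainSet
    summary: pd.DataFrame
    score: ModelScore
    space: ParameterSpace

    def posterior_median_params(self):
        """Model parameters built at the marginal posterior medians."""
        theta = self.summary["q50"].loc[list(self.space.free_names)].to_numpy()
        return self.space.build(theta)

    def refine_max_loglik(
        self, likelihood: "ModelLikelihood", maxfev: int = 300
    ) -> ModelScore:
        """Optional local refinement of the AIC/BIC likelihood anchor.

        Nelder–Mead from the best sampled draw tightens the in-chain maximum
        log-likelihood; returns an updated ModelScore (WAIC unchanged).
        """
        from scipy.optimize import minimize

        flat_ll = self.chains.loglik.reshape(-1)
        best = np.unravel_index(np.argmax(flat_ll), self.chains.loglik.shape)
        theta0 = self.chains.draws[best[0], best[1]]

        def neg(th):
            ll, _ = likelihood(th)
            return -ll if np.isfinite(ll) else 1e300

        res = minimize(neg, theta0, method="Nelder-Mead", options={"maxfev": maxfev})
        max_ll = max(float(-res.fun), float(flat_ll.max()))
        n_params, n_obs = self.score.n_params, self.score.n_obs
        return dataclasses.replace(
            self.score,
            max_loglik=max_ll,
            aic=2 * n_params - 2 * max_ll,
            bic=n_params * np.log(n_obs) - 2 * max_ll,
        )

    def switch_time_posterior(
        self, layer: str, t_grid, n_draws: int = 100, solver_cfg=None
    ) -> tuple[float, float]:
        """Mean and sd of the P/Q switch time over thinned posterior draws."""
        pooled = self.chains.retained()
        idx = np.linspace(0, pooled.shape[0] - 1, min(n_draws, pooled.shape[0])).astype(int)
        times = []
        for theta in pooled[idx]:
            params, _, _ = self.space.build(theta)
            traj = simulate_model(
                self.space.model_kind, params, self.space.topo, np.asarray(t_grid, float),
                solver_cfg or SolverConfig(rtol=1e-6, atol=1e-8),
            )
            ts = switch_time(traj, layer)
            if ts is not None:
                times.append(ts)
        if not times:
            return float("nan"), float("nan")
        arr = np.array(times)
        return float(arr.mean()), float(arr.std(ddof=1) if arr.size > 1 else 0.0)


def default_bounds(
    space: ParameterSpace, data: LayerTimeSeries, rate_max: float = 10.0
) -> PriorBounds:
    """Shipped default prior box: rates <= ``rate_max``/day, noise scales up
    to 10x the data sd of their observable, densities up to 10x the observed
    maximum, tau_k in (0, 1.5]."""
    df = data.frame
    bounds: dict[str, tuple[float, float]] = {}
    dens_max = df.loc[df["observable"] == "density", "value"].max()
    for name in space.free_names:
        if name == "tau_k":
            bounds[name] = (1e-6, 1.5)
        elif name in SIGMA_NAMES:
            obs = name[len("sigma_"):]
            sd = df.loc[df["observable"] == obs, "value"].std()
            sd = sd if np.isfinite(sd) and sd > 0 else 1.0
            bounds[name] = (1e-9, 10.0 * sd)
        elif name.split(".")[0] in ("m0", "A0", "B0"):
            bounds[name] = (0.0, 10.0 * float(dens_max))
        elif name == "kappa":
            vol_max = df.loc[df["observable"] == "volume", "value"].max()
            vol_max = vol_max if np.isfinite(vol_max) else 1.0
            bounds[name] = (0.0, 10.0 * float(dens_max) * float(vol_max))
        else:
            bounds[name] = (0.0, rate_max)
    return PriorBounds(bounds)


def _refined_starts(
    likelihood: ModelLikelihood, bounds: PriorBounds, n_chains: int,
    seed: int, maxfev: int = 600,
) -> np.ndarray:
    """Mode-refined chain start points via profile likelihood.

    From each chain's own uniform random start, the kinetic coordinates are
    optimized (derivative-free Nelder-Mead) with every sampled noise scale
    profiled out analytically: given the kinetics, the Gaussian likelihood
    is maximized by setting each observable-class sigma to its RMS residual.
    This moves the chains out of the flat tails of the box prior so the
    adaptive phase explores the posterior bulk instead of locating it.
    Profiled sigmas are clipped into their prior intervals.
    """
    from scipy.optimize import minimize

    names = likelihood.space.free_names
    lo, hi = bounds.as_arrays(names)
    width = hi - lo
    sigma_pos = {i: n[len("sigma_"):] for i, n in enumerate(names) if n in SIGMA_NAMES}
    kin_pos = [i for i in range(len(names)) if i not in sigma_pos]
    obs_kinds = likelihood._rows_obs
    values = likelihood._values
    class_masks = {k: obs_kinds == k for k in np.unique(obs_kinds)}

    def profiled(theta: np.ndarray) -> tuple[float, dict]:
        """Negative log-likelihood with free sigmas at their optimum."""
        try:
            mu = likelihood.predicted(theta)
        except IntegrationError:
            return 1e300, {}
        _, _, sigmas = likelihood.space.build(theta)
        best_sig = {}
        neg_ll = 0.0
        for kind, mask in class_masks.items():
            resid = values[mask] - mu[mask]
            n = resid.size
            free_idx = [i for i, k in sigma_pos.items() if k == kind]
            if free_idx:
                sig = float(np.sqrt(np.mean(resid**2)))
                sig = float(np.clip(sig, lo[free_idx[0]] + 1e-12, hi[free_idx[0]]))
                best_sig[kind] = sig
            else:
                sig = sigmas[kind]
            neg_ll += 0.5 * n * np.log(2 * np.pi * sig**2) + float(
                np.sum(resid**2)
            ) / (2 * sig**2)
        return neg_ll, best_sig

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    starts = np.empty((n_chains, lo.size))
    for c in range(n_chains):
        theta = rng.uniform(lo, hi)
        if kin_pos:

            def neg_kin(kin):
                full = theta.copy()
                full[kin_pos] = kin
                return profiled(full)[0]

            kin_bounds = [(lo[i] + 1e-9 * width[i], hi[i] - 1e-9 * width[i])
                          for i in kin_pos]
            res = minimize(
                neg_kin, theta[kin_pos], method="Nelder-Mead",
                bounds=kin_bounds, options={"maxfev": maxfev, "fatol": 1e-3},
            )
            # warm restart: a fresh simplex around the first optimum often
            # escapes the flat ridges of the profile surface
            res = minimize(
                neg_kin, res.x, method="Nelder-Mead",
                bounds=kin_bounds, options={"maxfev": maxfev, "fatol": 1e-3},
            )
            theta[kin_pos] = res.x
        _, best_sig = profiled(theta)
        for i, kind in sigma_pos.items():
            if kind in best_sig:
                theta[i] = best_sig[kind]
        starts[c] = np.clip(theta, lo + 1e-9 * width, hi - 1e-9 * width)
    return starts


def fit_model(
    data: LayerTimeSeries,
    space: ParameterSpace,
    bounds: PriorBounds | None = None,
    n_chains: int = 3,
    n_iter: int = 5000,
    seed: int = 0,
    burn_in_frac: float = 0.5,
    solver_cfg: SolverConfig | None = None,
    refine_starts: bool = True,
) -> FitResult:
    """Calibrate one model/topology to a time series and score it.

    ``refine_starts`` runs a short derivative-free mode search from each
    chain's uniform random start before sampling (recommended: the posterior
    is typically far more concentrated than the prior box).
    """
    bounds = bounds or default_bounds(space, data)
    likelihood = ModelLikelihood(data, space, solver_cfg=solver_cfg)
    log_post, lo, hi = make_log_posterior(likelihood, bounds)
    init = _refined_starts(likelihood, bounds, n_chains, seed) if refine_starts else None
    chains = run_adaptive_mh(
        log_post,
        bounds,
        n_chains=n_chains,
        n_iter=n_iter,
        seed=seed,
        burn_in_frac=burn_in_frac,
        param_names=space.free_names,
        init_points=init,
    )
    summary = posterior_summary(chains)
    score = information_criteria(chains, model_id=space.model_kind)
    return FitResult(chains=chains, summary=summary, score=score, space=space)


def compare_spreading_topologies(
    model_kind: str,
    topologies: Sequence[RegionTopology],
    data: LayerTimeSeries,
    space_builder: Callable[[RegionTopology], ParameterSpace],
    bounds_builder: Callable[[ParameterSpace], PriorBounds] | None = None,
    n_chains: int = 3,
    n_iter: int = 5000,
    seed: int = 0,
    solver_cfg: SolverConfig | None = None,
) -> tuple[RegionTopology, dict, list[FitResult]]:
    """Fit one model class under alternative spreading topologies and rank.

    ``space_builder`` supplies the parameter space (base parameters and free
    names, typically including the per-edge beta rates) for each candidate
    topology. Returns (winning topology, ranking dict, per-topology fits).
    With a single candidate it is returned unconditionally.
    """
    layer_sets = {tuple(sorted(t.layers)) for t in topologies}
    if len(layer_sets) > 1:
        raise ValueError("candidate topologies must share the same layer set")
    fits = []
    scores = []
    for k, topo in enumerate(topologies):
        space = space_builder(topo)
        bounds = bounds_builder(space) if bounds_builder else default_bounds(space, data)
        fit = fit_model(
            data, space, bounds, n_chains=n_chains, n_iter=n_iter,
            seed=seed + k, solver_cfg=solver_cfg,
        )
        fit.score = dataclasses.replace(fit.score, model_id=f"topology_{k}")
        fits.append(fit)
        scores.append(fit.score)
    if len(topologies) == 1:
        return topologies[0], {"consensus": "topology_0"}, fits
    ranking = rank_models(scores)
    if ranking["consensus"] == "discordant":
        # fall back to the WAIC winner while reporting discordance
        best_id = ranking["waic"][0]
    else:
        best_id = ranking["consensus"]
    best = topologies[int(best_id.split("_")[1])]
    return best, ranking, fits
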