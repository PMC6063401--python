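"""Parameter spaces, maximum-likelihood fitting and posterior sampling.

Each model exposes exactly the parameters its strategies demand (Table-style
bounds below); scale parameters (base noise SDs, the fixed criterion and the
prior widths) are fitted in log space.  Optimization and MCMC operate in a
transformed unit cube in which the prior -- uniform on each bounded
interval, uniform in log space for scale parameters -- is exactly uniform,
so posterior densities need no Jacobian terms.

MLE uses seeded Latin-hypercube multistart with a bound-constrained
derivative-free local search; the contract is multistart dominance, not a
particular optimizer.  Posterior sampling uses an affine-invariant ensemble
sampler (emcee) with split-Rhat / effective-sample-size diagnostics, and
stores the per-draw per-trial log-likelihood matrix needed downstream by
PSIS-LOO and the marginal-likelihood estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

import emcee

from .likelihood import GridSpec, dataset_log_likelihood
from .models import ModelSpec

__all__ = [
    "PARAMETER_BOUNDS",
    "ParamSpec",
    "ParameterSpace",
    "build_parameter_space",
    "FitResult",
    "fit_mle",
    "PosteriorSamples",
    "sample_posterior",
    "run_ensemble",
]

#: name -> (lower, upper, fitted-in-log-space)
PARAMETER_BOUNDS = {
    "sigma0_vest": (0.5, 80.0, True),
    "sigma0_vis_high": (0.5, 80.0, True),
    "sigma0_vis_med": (0.5, 80.0, True),
    "sigma0_vis_low": (0.5, 80.0, True),
    "w_vest": (0.0, 1.0, False),
    "w_vis": (0.0, 1.0, False),
    "lambda": (0.0, 1.0, False),
    "p_c": (0.0, 1.0, False),
    "kappa_c": (0.25, 180.0, True),
    "eta_high": (0.0, 1.0, False),
    "eta_med": (0.0, 1.0, False),
    "eta_low": (0.0, 1.0, False),
    "sigma_prior": (1.0, 120.0, True),
    "delta_prior": (1.0, 120.0, True),
}


@dataclass(frozen=True)
class ParamSpec:
    name: str
    low: float
    high: float
    log_scale: bool


class ParameterSpace:
    """Ordered active parameters of a model, with unit-cube transforms."""

    def __init__(self, params):
        self.params = tuple(params)
        self.names = tuple(p.name for p in self.params)
        lo = np.array([np.log(p.low) if p.log_scale else p.low for p in self.params])
        hi = np.array([np.log(p.high) if p.log_scale else p.high for p in self.params])
        self._lo, self._hi = lo, hi
        self._log = np.array([p.log_scale for p in self.params])

    def __len__(self):
        return len(self.params)

    def __repr__(self):
        return f"ParameterSpace({', '.join(self.names)})"

    def from_unit(self, z):
        """Map a unit-cube vector to a named parameter dictionary."""
        z = np.asarray(z, dtype=float)
        t = self._lo + z * (self._hi - self._lo)
        vals = np.where(self._log, np.exp(t), t)
        return dict(zip(self.names, vals.tolist()))

    def to_unit(self, theta):
        v = np.array([theta[n] for n in self.names], dtype=float)
        t = np.where(self._log, np.log(v), v)
        return (t - self._lo) / (self._hi - self._lo)

    def contains(self, z):
        z = np.asarray(z, dtype=float)
        return bool(np.all(z >= 0.0) and np.all(z <= 1.0))


def build_parameter_space(spec: ModelSpec, tasks=None) -> ParameterSpace:
    """Active parameters of a model, in deterministic order.

    Follows the factor definitions: noise parameters whenever measurements
    enter the decision; eccentricity coefficients only for shape 'X'; the
    lapse for every strategy except stochastic fusion; ``p_c``/``kappa_c``/
    ``eta`` by strategy; prior widths only when the respective prior
    component is consulted.
    """
    if tasks is not None and set(tasks) != set(spec.tasks):
        spec = ModelSpec(spec.explicit, spec.implicit, spec.noise, spec.prior,
                         tuple(tasks))
    names = []
    if spec.uses_measurement_noise:
        names += ["sigma0_vest", "sigma0_vis_high", "sigma0_vis_med",
                  "sigma0_vis_low"]
        if spec.noise == "X":
            names += ["w_vest", "w_vis"]
    if spec.uses_lapse:
        names.append("lambda")
    active = set()
    if "unity" in spec.tasks and spec.explicit is not None:
        active.add(spec.explicit)
    if "inertial" in spec.tasks and spec.implicit is not None:
        active.add(spec.implicit)
    if active & {"Bay", "BayPM"}:
        names.append("p_c")
    if "Fix" in active:
        names.append("kappa_c")
    if "SFu" in active:
        names += ["eta_high", "eta_med", "eta_low"]
    if spec.uses_prior:
        names.append("sigma_prior")
        if spec.prior == "E" and spec.uses_separate_scenario:
            names.append("delta_prior")
    if not names:
        raise ValueError(f"model {spec.name} has no active parameters")
    return ParameterSpace(ParamSpec(n, *PARAMETER_BOUNDS[n]) for n in names)


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    theta: dict
    ll: float
    trace: list
    space: ParameterSpace
    seed: int
    converged: bool = True


def fit_mle(data: pd.DataFrame, spec: ModelSpec, n_starts=10, seed=0,
            grid: GridSpec = GridSpec(), extra_starts=(), maxfev=None,
            xtol=1e-3, ftol=1e-4) -> FitResult:
    """Multistart maximum-likelihood fit.

    Latin-hypercube starts in the transformed unit cube plus any
    ``extra_starts`` (parameter dictionaries).  Returns the best local
    optimum; the per-start trace records every start and its achieved
    log-likelihood.
    """
    space = build_parameter_space(spec)
    k = len(space)

    def negll(z):
        theta = space.from_unit(np.clip(z, 0.0, 1.0))
        return -dataset_log_likelihood(data, spec, theta, grid).total

    sampler = qmc.LatinHypercube(d=k, seed=seed)
    starts = list(sampler.random(n_starts))
    starts += [space.to_unit(t) for t in extra_starts]
    eps = 1e-9
    bounds = [(eps, 1.0 - eps)] * k
    if maxfev is None:
        maxfev = 150 * (k + 1)
    options = {"xtol": xtol, "ftol": ftol, "maxfev": maxfev}
    trace = []
    best = None
    any_success = False
    for z0 in starts:
        z0 = np.clip(np.asarray(z0, dtype=float), eps, 1.0 - eps)
        res = minimize(negll, z0, method="Powell", bounds=bounds, options=options)
        any_success = any_success or bool(res.success)
        trace.append({"z0": z0, "theta": space.from_unit(res.x),
                      "ll": -float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        warnings.warn("no optimizer start reported convergence; "
                      "returning best-so-far", RuntimeWarning)
    return FitResult(theta=space.from_unit(best.x), ll=-float(best.fun),
                     trace=trace, space=space, seed=seed,
                     converged=any_success)


# ---------------------------------------------------------------------------
# Posterior sampling
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """MCMC draws plus the per-draw per-trial log-likelihood matrix."""

    samples: pd.DataFrame          # S x k, original parameter scale
    z: np.ndarray                  # S x k, unit-cube scale
    loglik: np.ndarray             # S x N_trials
    total_ll: np.ndarray           # S
    walker: np.ndarray             # S
    space: ParameterSpace
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_samples(self):
        return self.samples.shape[0]

    def credible_interval(self, name, level=0.95):
        lo = (1.0 - level) / 2.0
        q = self.samples[name].quantile([lo, 1.0 - lo])
        return float(q.iloc[0]), float(q.iloc[1])


def run_ensemble(log_prob, ndim, n_walkers, n_steps, seed, init,
                 blobs=False, progress=False):
    """Run the affine-invariant ensemble sampler on a log-density.

    ``init``: (n_walkers, ndim) starting points. Returns the sampler.
    """
    rng = np.random.default_rng(seed)
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
    sampler.run_mcmc(init, n_steps, progress=progress)
    return sampler


def _diagnostics(chain):
    """Split-Rhat and bulk ESS per dimension (walkers treated as chains)."""
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(np.swapaxes(chain, 0, 1))  # (chain, draw, dim)
        rhat = az.rhat(ds)["x"].values
        ess = az.ess(ds)["x"].values
    return np.asarray(rhat, dtype=float), np.asarray(ess, dtype=float)


def sample_posterior(data: pd.DataFrame, spec: ModelSpec, n_samples=5000,
                     n_walkers=None, burn_in=None, seed=0, init_theta=None,
                     grid: GridSpec = GridSpec(), rhat_threshold=1.1,
                     progress=False) -> PosteriorSamples:
    """Sample the parameter posterior with a bounded uniform prior.

    The prior is uniform on each parameter's interval (uniform in log space
    for scale parameters), i.e. uniform on the transformed unit cube.
    ``n_samples`` is the number of retained post-burn-in draws; burn-in
    defaults to half the run.  Emits a convergence warning (never a silent
    failure) when split-Rhat exceeds ``rhat_threshold``.
    """
    space = build_parameter_space(spec)
    k = len(space)
    if n_walkers is None:
        n_walkers = 2 * (k + 1)
    n_post_steps = max(int(np.ceil(n_samples / n_walkers)), 2)
    if burn_in is None:
        burn_in = n_post_steps
    n_steps = n_post_steps + burn_in

    def log_prob(z):
        if not space.contains(z):
            return -np.inf, np.full(len(data), np.nan)
        theta = space.from_unit(z)
        total, per_trial, _ = dataset_log_likelihood(data, spec, theta, grid)
        return total, per_trial

    rng = np.random.default_rng(seed)
    if init_theta is not None:
        z_center = space.to_unit(init_theta)
        init = np.clip(z_center + 0.02 * rng.standard_normal((n_walkers, k)),
                       1e-4, 1.0 - 1e-4)
    else:
        init = qmc.LatinHypercube(d=k, seed=seed).random(n_walkers)
        init = np.clip(init, 1e-4, 1.0 - 1e-4)
    sampler = run_ensemble(log_prob, k, n_walkers, n_steps, seed, init,
                           blobs=True, progress=progress)

    chain = sampler.get_chain(discard=burn_in)            # (steps, walkers, k)
    blobs = sampler.get_blobs(discard=burn_in)            # (steps, walkers, N)
    lls = sampler.get_log_prob(discard=burn_in)           # (steps, walkers)
    rhat, ess = _diagnostics(chain)
    if np.any(rhat > rhat_threshold):
        warnings.warn(
            f"split-Rhat above {rhat_threshold}: {np.round(rhat, 3)}; "
            "chains may not have converged", RuntimeWarning)

    z_flat = chain.reshape(-1, k)
    walker = np.tile(np.arange(n_walkers), chain.shape[0])
    ll_flat = np.asarray(blobs).reshape(-1, len(data))
    tot_flat = lls.reshape(-1)
    if z_flat.shape[0] > n_samples:  # thin deterministically to the target size
        stride_idx = np.linspace(0, z_flat.shape[0] - 1, n_samples).astype(int)
        z_flat, walker = z_flat[stride_idx], walker[stride_idx]
        ll_flat, tot_flat = ll_flat[stride_idx], tot_flat[stride_idx]
    theta_rows = [space.from_unit(z) for z in z_flat]
    samples = pd.DataFrame(theta_rows, columns=space.names)
    return PosteriorSamples(
        samples=samples, z=z_flat, loglik=ll_flat, total_ll=tot_flat,
        walker=walker, space=space, seed=seed,
        diagnostics={"rhat": rhat, "ess": ess,
                     "acceptance": float(np.mean(sampler.acceptance_fraction))},
    )
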