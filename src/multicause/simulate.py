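"""Synthetic experiments: stimulus design, observer simulation, recovery.

The generator reproduces the study's stimulus design: the mean heading is
uniform on the discrete set {-25, -20, ..., 25} degrees; the disparity
magnitude is drawn with equal probability from {0, 5, 10, 20, 40} degrees
(zero disparity therefore occurs on exactly 1/5 of trials), nonzero
disparities get a random sign; the visual reliability level is uniform over
{high, med, low}.  Headings are ``s_vis = mean - disparity/2`` and
``s_vest = mean + disparity/2``, giving 297 unique bisensory conditions
(9 signed disparities x 11 means x 3 reliabilities).  Default per-task trial
counts sit mid-range of the study's totals: 500 unisensory, 900 unity
judgments, 2500 inertial discriminations.

Also provided: forward simulation of any observer model, a model/parameter
recovery harness, and the model-free summaries (proportion of 'unity'
reports by disparity and reliability; vestibular bias, i.e. minus the point
of subjective equality of cumulative-Gaussian psychometric fits, per visual
heading bin and reliability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .inference import build_parameter_space, fit_mle
from .likelihood import GridSpec, dataset_log_likelihood
from .models import (
    DESIGN_DISPARITY_MAGNITUDES,
    DESIGN_MEANS,
    RELIABILITIES,
    ModelSpec,
    make_observer,
)
from .model_comparison import info_criteria

__all__ = [
    "DesignSpec",
    "generate_design",
    "simulate_observer",
    "RecoveryReport",
    "model_recovery",
    "summarize_unity",
    "summarize_bias",
    "TYPICAL_THETA",
    "default_theta_sampler",
    "VIS_BINS",
]

#: Plausible observer parameters (group posterior means of the joint fits
#: reported for this paradigm); used as default generating values for
#: synthetic observers and recovery studies.
TYPICAL_THETA = {
    "sigma0_vest": 6.49,
    "sigma0_vis_high": 4.08,
    "sigma0_vis_med": 6.32,
    "sigma0_vis_low": 11.57,
    "w_vest": 0.04,
    "w_vis": 0.07,
    "lambda": 0.01,
    "p_c": 0.56,
    "kappa_c": 26.5,
    "sigma_prior": 49.77,
    "delta_prior": 23.51,
    # stochastic fusion: reliability-graded unity-report probabilities
    "eta_high": 0.75,
    "eta_med": 0.65,
    "eta_low": 0.55,
}


def default_theta_sampler(model: ModelSpec, rng, jitter=0.15):
    """Draw generating parameters near :data:`TYPICAL_THETA`.

    Scale parameters get multiplicative log-normal jitter; bounded ones get
    additive jitter, clipped inside their allowed ranges.
    """
    space = build_parameter_space(model)
    theta = {}
    for p in space.params:
        base = TYPICAL_THETA[p.name]
        if p.log_scale:
            val = base * float(np.exp(jitter * rng.standard_normal()))
        else:
            width = p.high - p.low
            val = base + 0.5 * jitter * width * float(rng.standard_normal())
        theta[p.name] = float(np.clip(val, p.low * 1.001, p.high * 0.999))
    return theta

#: Visual-heading bins for the bias summary (degrees); the center bin is the
#: single value 0.
VIS_BINS = (
    (-45.0, -30.0), (-27.5, -22.5), (-20.0, -15.0), (-12.5, -7.5),
    (-5.0, -2.5), (0.0, 0.0), (2.5, 5.0), (7.5, 12.5), (15.0, 20.0),
    (22.5, 27.5), (30.0, 45.0),
)


@dataclass(frozen=True)
class DesignSpec:
    """Stimulus-design settings of the synthetic experiment."""

    means: tuple = tuple(DESIGN_MEANS)
    disparity_magnitudes: tuple = DESIGN_DISPARITY_MAGNITUDES
    reliabilities: tuple = RELIABILITIES
    n_unisensory: int = 500
    n_unity: int = 900
    n_inertial: int = 2500
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_unisensory, self.n_unity, self.n_inertial):
            if n < 0:
                raise ValueError("trial counts must be non-negative")

    @property
    def n_bisensory_conditions(self):
        """Number of unique bisensory stimulus conditions."""
        n_disp = 2 * sum(1 for d in self.disparity_magnitudes if d > 0) + 1
        return n_disp * len(self.means) * len(self.reliabilities)


def _bisensory_block(spec, task, n, rng):
    mag = rng.choice(spec.disparity_magnitudes, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    disp = mag * np.where(mag > 0, sign, 1.0)
    mean = rng.choice(spec.means, size=n)
    rel = rng.choice(spec.reliabilities, size=n)
    return pd.DataFrame({
        "task": task,
        "s_vis": mean - disp / 2.0,
        "s_vest": mean + disp / 2.0,
        "coherence": rel,
        "response": pd.Series([pd.NA] * n, dtype="object"),
    })


def generate_design(spec: DesignSpec, seed=None) -> pd.DataFrame:
    """Generate a stimuli-only trial table for the three tasks.

    Unisensory trials are split evenly across the four stimulus streams
    (vestibular, and visual at each reliability); bisensory trials follow
    the design distribution described in the module docstring.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    blocks = []
    n = spec.n_unisensory
    if n:
        stream = rng.integers(0, 4, size=n)
        s = rng.choice(spec.means, size=n).astype(float)
        vis = stream > 0
        rel = np.array(spec.reliabilities, dtype=object)[np.maximum(stream - 1, 0)]
        blocks.append(pd.DataFrame({
            "task": "unisensory",
            "s_vis": np.where(vis, s, np.nan),
            "s_vest": np.where(vis, np.nan, s),
            "coherence": np.where(vis, rel, None),
            "response": pd.Series([pd.NA] * n, dtype="object"),
        }))
    if spec.n_unity:
        blocks.append(_bisensory_block(spec, "unity", spec.n_unity, rng))
    if spec.n_inertial:
        blocks.append(_bisensory_block(spec, "inertial", spec.n_inertial, rng))
    return pd.concat(blocks, ignore_index=True)


def simulate_observer(design: pd.DataFrame, spec: ModelSpec, theta, seed=0,
                      n_s=201) -> pd.DataFrame:
    """Draw responses for every trial by forward-sampling the observer.

    Measurements are sampled from the (truncated) noise distributions and
    passed through the measurement-conditional decision rule (lapses
    included); the binary response is then a Bernoulli draw.
    """
    missing = set(design["task"]) - set(spec.tasks)
    if missing:
        raise ValueError(f"model does not cover tasks {missing}")
    obs = make_observer(spec, theta, n_s=n_s)
    rng = np.random.default_rng(seed)
    data = design.reset_index(drop=True).copy()
    p_yes = np.empty(len(data))

    uni = data["task"] == "unisensory"
    if uni.any():
        sub = data.loc[uni]
        for modality, col in (("vis", "s_vis"), ("vest", "s_vest")):
            rows = sub.loc[sub[col].notna()]
            if not len(rows):
                continue
            if modality == "vis":
                for c_vis, rsub in rows.groupby("coherence"):
                    x = obs.draw_measurement(
                        rsub[col].to_numpy(dtype=float), "vis", c_vis, rng)
                    p_yes[rsub.index.to_numpy()] = obs.choice_prob_right(
                        x, None, c_vis, task="unisensory")
            else:
                x = obs.draw_measurement(
                    rows[col].to_numpy(dtype=float), "vest", None, rng)
                p_yes[rows.index.to_numpy()] = obs.choice_prob_right(
                    None, x, None, task="unisensory")

    for task in ("unity", "inertial"):
        mask = data["task"] == task
        if not mask.any():
            continue
        for c_vis, sub in data.loc[mask].groupby("coherence"):
            xv = obs.draw_measurement(
                sub["s_vis"].to_numpy(dtype=float), "vis", c_vis, rng)
            xe = obs.draw_measurement(
                sub["s_vest"].to_numpy(dtype=float), "vest", None, rng)
            if task == "unity":
                p = obs.choice_prob_unity(xv, xe, c_vis)
            else:
                p = obs.choice_prob_right(xv, xe, c_vis, task="inertial")
            p_yes[sub.index.to_numpy()] = p

    u = rng.uniform(size=len(data))
    yes_token = data["task"].map(
        {"unity": "unity", "inertial": "right", "unisensory": "right"})
    no_token = data["task"].map(
        {"unity": "separate", "inertial": "left", "unisensory": "left"})
    data["response"] = np.where(u < p_yes, yes_token, no_token)
    return data


# ---------------------------------------------------------------------------
# Model recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Selection counts (generating x fitted models) and fit details."""

    selection: pd.DataFrame
    details: list = field(default_factory=list)
    failures: list = field(default_factory=list)


def model_recovery(models, theta_sampler, n_datasets, design: DesignSpec,
                   metric="aicc", n_starts=4, seed=0, maxfev=None,
                   grid: GridSpec = GridSpec()) -> RecoveryReport:
    """Simulate from each model, refit all models, tally the winners.

    ``theta_sampler(model, rng) -> dict`` supplies generating parameters.
    The winner per dataset maximizes the chosen metric evidence (-AICc/2 or
    -BIC/2).  Fit failures are recorded, never silently dropped.
    """
    if len(models) < 2:
        raise ValueError("model recovery needs at least two candidate models")
    if metric not in ("aicc", "bic"):
        raise ValueError(f"unsupported recovery metric {metric!r}")
    rng = np.random.default_rng(seed)
    names = [m.name for m in models]
    sel = pd.DataFrame(0, index=names, columns=names)
    details, failures = [], []
    for gen in models:
        for rep in range(n_datasets):
            theta0 = theta_sampler(gen, rng)
            dseed = int(rng.integers(2**31 - 1))
            data = simulate_observer(generate_design(design, seed=dseed),
                                     gen, theta0, seed=dseed + 1, n_s=grid.n_s)
            data = data[data["task"].isin(gen.tasks)]
            scores = {}
            for cand in models:
                try:
                    fit = fit_mle(data, cand, n_starts=n_starts, maxfev=maxfev,
                                  seed=int(rng.integers(2**31 - 1)), grid=grid)
                    k = len(build_parameter_space(cand))
                    aicc, bic = info_criteria(fit.ll, k, len(data))
                    scores[cand.name] = -0.5 * (aicc if metric == "aicc" else bic)
                except Exception as err:  # recorded, not dropped
                    failures.append({"generator": gen.name, "candidate": cand.name,
                                     "replicate": rep, "error": repr(err)})
            if scores:
                winner = max(scores, key=scores.get)
                sel.loc[gen.name, winner] += 1
                details.append({"generator": gen.name, "replicate": rep,
                                "theta": theta0, "scores": scores,
                                "winner": winner})
    return RecoveryReport(selection=sel, details=details, failures=failures)


# ---------------------------------------------------------------------------
# Model-free summaries
# ---------------------------------------------------------------------------


def summarize_unity(data: pd.DataFrame) -> pd.DataFrame:
    """Proportion of 'unity' reports by signed disparity and reliability."""
    sub = data[data["task"] == "unity"]
    if not len(sub):
        raise ValueError("no unity-judgment trials in the data")
    disp = (sub["s_vest"] - sub["s_vis"]).round(6)
    out = (sub.assign(disparity=disp, unity=sub["response"] == "unity")
           .groupby(["disparity", "coherence"])
           .agg(n=("unity", "size"), prop_unity=("unity", "mean"))
           .reset_index())
    return out


def _fit_psychometric(s, n_right, n_total, lapse=0.0):
    """ML cumulative-Gaussian fit; returns (pse, slope_sd, converged)."""

    def nll(p):
        mu, log_sigma = p
        f = ndtr((s - mu) / np.exp(log_sigma))
        pr = lapse / 2.0 + (1.0 - lapse) * f
        pr = np.clip(pr, 1e-9, 1.0 - 1e-9)
        return -np.sum(n_right * np.log(pr) + (n_total - n_right) * np.log(1.0 - pr))

    best = None
    for mu0 in (0.0, float(np.mean(s))):
        res = minimize(nll, np.array([mu0, np.log(8.0)]), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(np.exp(best.x[1])), bool(best.success)


def summarize_bias(data: pd.DataFrame, lapse=0.0, bins=VIS_BINS) -> pd.DataFrame:
    """Vestibular bias (= minus the L/R PSE) per visual-heading bin.

    For each visual bin and reliability a cumulative Gaussian is fitted to
    the proportion of rightward responses as a function of ``s_vest``;
    non-converged fits are flagged, not dropped.
    """
    sub = data[data["task"] == "inertial"].copy()
    if not len(sub):
        raise ValueError("no inertial-discrimination trials in the data")
    sub["right"] = sub["response"] == "right"
    rows = []
    for lo, hi in bins:
        if lo == hi:
            m = sub["s_vis"] == lo
        else:
            m = (sub["s_vis"] >= lo) & (sub["s_vis"] <= hi)
        for c_vis, g in sub.loc[m].groupby("coherence"):
            tab = (g.groupby("s_vest")["right"]
                   .agg(["sum", "size"]).reset_index())
            if len(tab) < 3 or tab["size"].sum() < 10:
                rows.append({"bin_lo": lo, "bin_hi": hi, "coherence": c_vis,
                             "n": int(tab["size"].sum()), "bias": np.nan,
                             "sigma": np.nan, "converged": False})
                continue
            pse, sig, ok = _fit_psychometric(
                tab["s_vest"].to_numpy(dtype=float),
                tab["sum"].to_numpy(dtype=float),
                tab["size"].to_numpy(dtype=float), lapse=lapse)
            rows.append({"bin_lo": lo, "bin_hi": hi, "coherence": c_vis,
                         "n": int(tab["size"].sum()), "bias": -pse,
                         "sigma": sig, "converged": ok})
    return pd.DataFrame(rows)
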