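"""Trial-table I/O, run configuration and the analysis pipeline.

Trial tables are delimited text (CSV) with header columns
``subject, task, s_vis, s_vest, coherence, response`` (``subject`` optional);
empty fields denote absent stimuli (e.g. ``s_vis`` on vestibular-only
trials).  Responses are ``unity``/``separate`` for the unity-judgment task
and ``right``/``left`` for the discrimination tasks.  Malformed rows are
rejected with their line numbers.

The pipeline mirrors the analysis strategy of the factorial study: fit each
model per subject (maximum likelihood; posterior sampling when the metric
requires it), assemble a subjects-x-models evidence table, run hierarchical
Bayesian model selection with factor aggregation, and report absolute
goodness of fit.  Every output embeds the configuration hash and master
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import build_parameter_space, fit_mle, sample_posterior
from .likelihood import GridSpec, dataset_log_likelihood
from .model_comparison import (
    absolute_goodness_of_fit,
    factor_level_bms,
    group_bms,
    info_criteria,
    marginal_likelihood_whm,
    psis_loo,
)
from .models import (
    ModelSpec,
    RELIABILITIES,
    TASKS,
    explicit_model_space,
    implicit_model_space,
    joint_model_space,
)
from .simulate import DesignSpec, generate_design, simulate_observer

__all__ = [
    "COLUMNS",
    "TrialTableError",
    "read_trials",
    "write_trials",
    "RunConfig",
    "run_pipeline",
    "enumerate_models",
    "build_factors",
]

log = logging.getLogger("multicause")

COLUMNS = ("task", "s_vis", "s_vest", "coherence", "response")
_RESPONSES = {"unisensory": {"right", "left"},
              "inertial": {"right", "left"},
              "unity": {"unity", "separate"}}


class TrialTableError(ValueError):
    """Raised when a trial table violates the schema."""


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; rejects malformed rows by line number."""
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise TrialTableError(f"{path}: missing columns {sorted(missing)}")
    problems = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        task = row["task"]
        if task not in TASKS:
            problems.append(f"line {line}: unknown task {task!r}")
            continue
        resp = row["response"]
        if not (pd.isna(resp) or resp in _RESPONSES[task]):
            problems.append(
                f"line {line}: response {resp!r} invalid for task {task!r}")
        has_vis = pd.notna(row["s_vis"])
        has_vest = pd.notna(row["s_vest"])
        if task == "unisensory":
            if has_vis == has_vest:
                problems.append(f"line {line}: unisensory rows need exactly "
                                "one heading")
            if has_vis and row["coherence"] not in RELIABILITIES:
                problems.append(f"line {line}: visual rows need a reliability")
        else:
            if not (has_vis and has_vest):
                problems.append(f"line {line}: bisensory rows need both headings")
            if row["coherence"] not in RELIABILITIES:
                problems.append(f"line {line}: unknown reliability "
                                f"{row['coherence']!r}")
    if problems:
        raise TrialTableError("; ".join(problems[:20]))
    return df


def write_trials(data: pd.DataFrame, path):
    """Write a trial table in the canonical CSV dialect."""
    cols = [c for c in ("subject",) + COLUMNS if c in data.columns]
    data.to_csv(path, index=False, columns=cols)
    return path


def enumerate_models(tasks):
    """The factorial model space appropriate for a set of tasks."""
    tasks = set(tasks)
    if tasks == {"unity"}:
        return explicit_model_space()
    if tasks == {"inertial"}:
        return implicit_model_space()
    if {"unity", "inertial"} <= tasks:
        return joint_model_space()
    raise ValueError(f"no canonical model space for tasks {sorted(tasks)}")


def build_factors(models):
    """Factor partitions (strategy / noise / prior) over a model list.

    Each factor covers only the models for which the factor is defined
    (e.g. stochastic fusion has no noise or prior component).
    """
    factors = {}
    strat = {}
    for m in models:
        key = (f"{m.explicit}/{m.implicit}" if m.explicit and m.implicit
               else (m.explicit or m.implicit))
        strat.setdefault(key, []).append(m.name)
    if len(strat) > 1:
        factors["strategy"] = strat
    noise = {}
    for m in models:
        if m.uses_measurement_noise:
            noise.setdefault(m.noise, []).append(m.name)
    if len(noise) > 1:
        factors["noise"] = noise
    prior = {}
    for m in models:
        if m.uses_prior:
            prior.setdefault(m.prior, []).append(m.name)
    if len(prior) > 1:
        factors["prior"] = prior
    return factors


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ALLOWED_KEYS = {"seed", "tasks", "metric", "models", "subjects", "fit",
                 "mcmc", "grid", "design", "output"}
_ALLOWED_FIT = {"n_starts", "maxfev"}
_ALLOWED_MCMC = {"n_samples", "n_walkers", "burn_in"}
_ALLOWED_GRID = {"n_x", "n_s", "gl_order"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (strict: unknown keys are errors)."""

    tasks: tuple
    subjects: list
    metric: str = "aicc"
    models: list = None
    seed: int = 0
    fit: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    output: str = None

    def __post_init__(self):
        if self.metric not in ("loo", "aicc", "bic", "lml"):
            raise ValueError(f"unknown comparison metric {self.metric!r}")
        unknown = set(self.fit) - _ALLOWED_FIT
        unknown |= set(self.mcmc) - _ALLOWED_MCMC
        unknown |= set(self.grid) - _ALLOWED_GRID
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw):
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(tasks=tuple(raw["tasks"]), subjects=list(raw["subjects"]),
                   metric=raw.get("metric", "aicc"),
                   models=raw.get("models"), seed=int(raw.get("seed", 0)),
                   fit=raw.get("fit", {}), mcmc=raw.get("mcmc", {}),
                   grid=raw.get("grid", {}), design=raw.get("design", {}),
                   output=raw.get("output"))

    def config_hash(self):
        blob = json.dumps({
            "tasks": list(self.tasks), "subjects": self.subjects,
            "metric": self.metric, "models": self.models, "seed": self.seed,
            "fit": self.fit, "mcmc": self.mcmc, "grid": self.grid,
            "design": self.design}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def model_specs(self):
        if self.models:
            return [ModelSpec.from_name(n, tasks=self.tasks) for n in self.models]
        return enumerate_models(self.tasks)

    def grid_spec(self):
        return GridSpec(**self.grid)


def _load_subject(entry, tasks, design_kwargs, seed):
    if isinstance(entry, str) or "path" in entry:
        path = entry if isinstance(entry, str) else entry["path"]
        data = read_trials(path)
    else:
        sim = entry["simulate"]
        spec = ModelSpec.from_name(sim["model"], tasks=tasks)
        design = DesignSpec(seed=seed, **design_kwargs)
        data = simulate_observer(generate_design(design), spec,
                                 sim["theta"], seed=seed + 1)
    return data[data["task"].isin(tasks)].reset_index(drop=True)


def run_pipeline(config: RunConfig):
    """Fit, compare and summarize; returns (and optionally writes) results.

    Failures are isolated per subject x model: the offending cell is dropped
    from the evidence table and recorded under ``failures``.
    """
    t0 = time.time()
    models = config.model_specs()
    grid = config.grid_spec()
    rng = np.random.default_rng(config.seed)
    evidence = {}
    fits = {}
    gofs = {}
    failures = []
    needs_mcmc = config.metric in ("loo", "lml")
    for si, entry in enumerate(config.subjects):
        name = entry.get("name", f"S{si + 1}") if isinstance(entry, dict) else f"S{si + 1}"
        sub_seed = int(rng.integers(2**31 - 1))
        data = _load_subject(entry, config.tasks, config.design, sub_seed)
        row = {}
        for m in models:
            try:
                fit = fit_mle(data, m, seed=sub_seed,
                              n_starts=config.fit.get("n_starts", 10),
                              maxfev=config.fit.get("maxfev"), grid=grid)
                k = len(build_parameter_space(m))
                aicc, bic = info_criteria(fit.ll, k, len(data))
                score = {"aicc": -aicc / 2.0, "bic": -bic / 2.0}.get(config.metric)
                loo = None
                if needs_mcmc:
                    post = sample_posterior(
                        data, m, seed=sub_seed + 1, init_theta=fit.theta,
                        grid=grid, **config.mcmc)
                    if config.metric == "loo":
                        score = psis_loo(post.loglik).loo
                        loo = score
                    else:
                        score = marginal_likelihood_whm(post, seed=sub_seed)
                row[m.name] = score
                fits.setdefault(name, {})[m.name] = {
                    "theta": fit.theta, "ll": fit.ll, "aicc": aicc, "bic": bic}
                if loo is not None:
                    gofs.setdefault(name, {})[m.name] = \
                        absolute_goodness_of_fit(data, loo).g
            except Exception as err:
                failures.append({"subject": name, "model": m.name,
                                 "error": repr(err)})
                log.warning("subject %s model %s failed: %r", name, m.name, err)
        evidence[name] = row
    ev = pd.DataFrame(evidence).T
    ev = ev.dropna(axis=1)
    results = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "metric": config.metric,
        "evidence": ev.to_dict(),
        "fits": fits,
        "goodness_of_fit": gofs,
        "failures": failures,
    }
    if ev.shape[1] >= 2 and len(ev):
        bms = group_bms(ev, seed=config.seed)
        results["bms"] = {
            "phi_tilde": bms.phi_tilde.to_dict(),
            "freq_mean": bms.freq_mean.to_dict(),
            "bor": bms.bor,
        }
        factors = build_factors(models)
        results["factors"] = {}
        for fname, comps in factors.items():
            covered = [m for ms in comps.values() for m in ms]
            sub_ev = ev[[c for c in ev.columns if c in covered]]
            if sub_ev.shape[1] < 2:
                continue
            comps_sub = {c: [m for m in ms if m in sub_ev.columns]
                         for c, ms in comps.items()}
            comps_sub = {c: ms for c, ms in comps_sub.items() if ms}
            if len(comps_sub) < 2:
                continue
            _, fres = factor_level_bms(sub_ev, {fname: comps_sub},
                                       seed=config.seed)
            r = fres[fname]
            results["factors"][fname] = {
                "phi_tilde": r.phi_tilde.to_dict(),
                "freq_mean": r.freq_mean.to_dict(),
                "bor": r.bor,
            }
    results["wall_time_s"] = round(time.time() - t0, 3)
    if config.output:
        out = Path(config.output)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(results, indent=2,
                                                     default=float))
        ev.to_csv(out / "evidence.csv")
    return results
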