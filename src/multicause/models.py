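"""Generative observer models for visuo-vestibular causal inference.

An observer receives a visual heading measurement ``x_vis`` (with known
reliability level ``c_vis``) and a vestibular measurement ``x_vest``, both
noisy versions of the presented headings ``s_vis`` and ``s_vest`` (degrees,
rightward positive).  The observer entertains two causal scenarios: a single
common heading (C=1) or two distinct headings (C=2), and combines them
according to one of several causal-inference strategies:

* ``Bay``   -- Bayesian model averaging / posterior thresholding,
* ``BayPM`` -- Bayesian probability matching,
* ``Fix``   -- fixed measurement-difference criterion ``|x_vis-x_vest| < kappa_c``,
* ``SFu``   -- stochastic fusion (explicit task only; reports 'unity' with a
  reliability-dependent probability and ignores the measurements),
* ``FFu``   -- forced fusion (implicit task only; always assumes C=1).

Sensory noise is Gaussian, either constant (shape ``C``) or growing with
heading eccentricity (shape ``X``); the prior over headings is either the
correlated, discrete distribution of the experimental design (``E``) or a
factorized central Gaussian (``I``).  All computations here are conditional
on the internal measurements; marginalization over measurements lives in
:mod:`multicause.likelihood`.

Conventions: angles in degrees; disparity ``Delta = s_vest - s_vis``;
measurements live on ``DOMAIN = (-90, 90)`` and noise densities are
renormalized (truncated) on that interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "DOMAIN",
    "DESIGN_MEANS",
    "DESIGN_DISPARITY_MAGNITUDES",
    "RELIABILITIES",
    "TASKS",
    "NoiseParams",
    "PriorParams",
    "StrategyParams",
    "ModelSpec",
    "StimulusCondition",
    "Observer",
    "noise_sd",
    "measurement_density",
    "prior_density",
    "make_observer",
    "explicit_model_space",
    "implicit_model_space",
    "joint_model_space",
]

DOMAIN = (-90.0, 90.0)

#: Mean headings of the experimental design (11 values, 5 deg steps).
DESIGN_MEANS = np.arange(-25.0, 26.0, 5.0)

#: Disparity magnitudes; 0 is drawn with probability 1/5, nonzero ones get a
#: random sign.
DESIGN_DISPARITY_MAGNITUDES = (0.0, 5.0, 10.0, 20.0, 40.0)

RELIABILITIES = ("high", "med", "low")
TASKS = ("unisensory", "unity", "inertial")

EXPLICIT_STRATEGIES = ("Bay", "BayPM", "Fix", "SFu")
IMPLICIT_STRATEGIES = ("Bay", "BayPM", "Fix", "FFu")

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(x, mu, sigma):
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * _SQRT2PI)


def _trunc_norm_z(mu, sigma, lo, hi):
    """Normalization constant of a normal truncated to [lo, hi]."""
    return ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma)


def step(t, level=0.0):
    """Heaviside step with the tie convention step(level) = 1/2."""
    t = np.asarray(t, dtype=float)
    return np.where(t > level, 1.0, np.where(t < level, 0.0, 0.5))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

SIGMA0_BOUNDS = (0.5, 80.0)
KAPPA_BOUNDS = (0.25, 180.0)
PRIOR_SD_BOUNDS = (1.0, 120.0)


@dataclass(frozen=True)
class NoiseParams:
    """Sensory noise model.

    ``sigma0_vis`` is one base SD per visual reliability level, ordered
    (high, med, low).  For shape ``X`` the SD grows with eccentricity as
    ``sigma(s) = sigma0 * sqrt(1 + w**2 * s**2)`` with ``s`` in degrees; for
    shape ``C`` the eccentricity coefficients are ignored (and must be 0).
    """

    sigma0_vest: float
    sigma0_vis: tuple
    w_vest: float = 0.0
    w_vis: float = 0.0
    shape: str = "C"

    def __post_init__(self):
        if self.shape not in ("C", "X"):
            raise ValueError(f"unknown noise shape {self.shape!r}")
        sds = (self.sigma0_vest,) + tuple(self.sigma0_vis)
        if len(self.sigma0_vis) != 3:
            raise ValueError("sigma0_vis must have one entry per reliability level")
        for sd in sds:
            if not (SIGMA0_BOUNDS[0] <= sd <= SIGMA0_BOUNDS[1]):
                raise ValueError(f"base SD {sd} outside {SIGMA0_BOUNDS}")
        for w in (self.w_vest, self.w_vis):
            if not (0.0 <= w <= 1.0):
                raise ValueError("eccentricity coefficients must lie in [0, 1]")
        if self.shape == "C" and (self.w_vest != 0.0 or self.w_vis != 0.0):
            raise ValueError("shape='C' requires zero eccentricity coefficients")

    def base_sd(self, modality, c_vis=None):
        if modality == "vest":
            return self.sigma0_vest
        if modality == "vis":
            if c_vis not in RELIABILITIES:
                raise ValueError(
                    f"visual modality requires a reliability level, got {c_vis!r}"
                )
            return self.sigma0_vis[RELIABILITIES.index(c_vis)]
        raise ValueError(f"unknown modality {modality!r}")

    def sd(self, s, modality, c_vis=None):
        sigma0 = self.base_sd(modality, c_vis)
        if self.shape == "C":
            return np.broadcast_to(sigma0, np.shape(s)).astype(float) if np.ndim(s) else float(sigma0)
        w = self.w_vest if modality == "vest" else self.w_vis
        s = np.asarray(s, dtype=float)
        out = sigma0 * np.sqrt(1.0 + (w * s) ** 2)
        return out if out.ndim else float(out)


def noise_sd(s, modality, c_vis, noise: NoiseParams):
    """Sensory SD at heading ``s`` (degrees) for the given modality/reliability."""
    return noise.sd(s, modality, c_vis)


def measurement_density(x, s, modality, c_vis, noise: NoiseParams,
                        domain=DOMAIN, variant="truncated"):
    """Density of the noisy measurement ``x`` given heading ``s``.

    ``variant='truncated'`` (default) renormalizes the normal density on
    ``domain``; ``'plain'`` is the untruncated normal; ``'wrapped'`` wraps
    the normal on a 360-degree circle centered on ``domain``.
    """
    sigma = noise.sd(s, modality, c_vis)
    x = np.asarray(x, dtype=float)
    if variant == "plain":
        return _norm_pdf(x, s, sigma)
    if variant == "truncated":
        z = _trunc_norm_z(s, sigma, domain[0], domain[1])
        dens = _norm_pdf(x, s, sigma) / z
        return np.where((x >= domain[0]) & (x <= domain[1]), dens, 0.0)
    if variant == "wrapped":
        period = domain[1] - domain[0]
        dens = np.zeros_like(x, dtype=float)
        for k in range(-5, 6):
            dens += _norm_pdf(x + k * period, s, sigma)
        return dens
    raise ValueError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class PriorParams:
    """Observer prior over headings.

    ``kind='I'``: factorized central Gaussian over each heading with SD
    ``sigma_prior`` (``delta_prior`` unused).  ``kind='E'``: discrete prior
    on the design grid; the weight of a (mean, disparity) cell is
    proportional to ``N(mean | 0, sigma_prior^2) * N(disparity | 0,
    delta_prior^2)``, with the C=2 support excluding zero disparity.
    """

    sigma_prior: float
    delta_prior: float = None
    kind: str = "I"

    def __post_init__(self):
        if self.kind not in ("E", "I"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not (PRIOR_SD_BOUNDS[0] <= self.sigma_prior <= PRIOR_SD_BOUNDS[1]):
            raise ValueError(f"sigma_prior outside {PRIOR_SD_BOUNDS}")
        if self.kind == "E" and self.delta_prior is not None:
            if not (PRIOR_SD_BOUNDS[0] <= self.delta_prior <= PRIOR_SD_BOUNDS[1]):
                raise ValueError(f"delta_prior outside {PRIOR_SD_BOUNDS}")


def empirical_support(prior: PriorParams, C):
    """Discrete support and normalized weights of the empirical prior.

    Returns ``(s_vis, s_vest, w)`` arrays.  For C=1 ``s_vis == s_vest`` (the
    11 design means); for C=2 the support is means x nonzero signed
    disparities (88 pairs).
    """
    if C == 1:
        s = DESIGN_MEANS.copy()
        w = np.exp(-0.5 * (s / prior.sigma_prior) ** 2)
        return s, s, w / w.sum()
    if prior.delta_prior is None:
        raise ValueError("the separate-causes empirical prior requires "
                         "delta_prior")
    disps = np.array([d * sgn for d in DESIGN_DISPARITY_MAGNITUDES if d > 0.0
                      for sgn in (-1.0, 1.0)])
    mm, dd = np.meshgrid(DESIGN_MEANS, disps, indexing="ij")
    mm, dd = mm.ravel(), dd.ravel()
    s_vis = mm - dd / 2.0
    s_vest = mm + dd / 2.0
    w = np.exp(-0.5 * (mm / prior.sigma_prior) ** 2
               - 0.5 * (dd / prior.delta_prior) ** 2)
    return s_vis, s_vest, w / w.sum()


def prior_density(s_vis, s_vest, C, prior: PriorParams, domain=DOMAIN):
    """Prior density (kind 'I') or mass (kind 'E') at a heading pair.

    For C=1 the two headings must coincide; the value returned is the
    density/mass of the common heading.
    """
    if C not in (1, 2):
        raise ValueError("C must be 1 or 2")
    if prior.kind == "I":
        sp = prior.sigma_prior
        z = _trunc_norm_z(0.0, sp, domain[0], domain[1])
        if C == 1:
            if not np.allclose(s_vis, s_vest):
                raise ValueError("C=1 requires a common heading")
            return _norm_pdf(s_vis, 0.0, sp) / z
        return (_norm_pdf(s_vis, 0.0, sp) / z) * (_norm_pdf(s_vest, 0.0, sp) / z)
    sv, se, w = empirical_support(prior, C)
    s_vis = np.atleast_1d(np.asarray(s_vis, dtype=float))
    s_vest = np.atleast_1d(np.asarray(s_vest, dtype=float))
    out = np.zeros(np.broadcast_shapes(s_vis.shape, s_vest.shape))
    sv_b = np.broadcast_to(s_vis, out.shape)
    se_b = np.broadcast_to(s_vest, out.shape)
    for k in range(len(w)):
        hit = np.isclose(sv_b, sv[k]) & np.isclose(se_b, se[k])
        out = np.where(hit, w[k], out)
    return out if out.size > 1 else float(out.ravel()[0])


@dataclass(frozen=True)
class StrategyParams:
    """Decision-strategy parameters.

    Only the parameters demanded by the chosen strategies may be set:
    ``p_c`` for Bayesian strategies, ``kappa_c`` for the fixed criterion,
    ``eta`` (one unity-report probability per reliability level) for
    stochastic fusion.  ``SFu`` carries no lapse parameter.
    """

    explicit: str = None
    implicit: str = None
    p_c: float = None
    kappa_c: float = None
    eta: tuple = None
    lapse: float = 0.0

    def __post_init__(self):
        if self.explicit is not None and self.explicit not in EXPLICIT_STRATEGIES:
            raise ValueError(f"unknown explicit strategy {self.explicit!r}")
        if self.implicit is not None and self.implicit not in IMPLICIT_STRATEGIES:
            raise ValueError(f"unknown implicit strategy {self.implicit!r}")
        strategies = {self.explicit, self.implicit}
        if strategies & {"Bay", "BayPM"}:
            if self.p_c is None or not (0.0 <= self.p_c <= 1.0):
                raise ValueError("Bayesian strategies require p_c in [0, 1]")
        if "Fix" in strategies:
            if self.kappa_c is None or not (
                KAPPA_BOUNDS[0] <= self.kappa_c <= KAPPA_BOUNDS[1]
            ):
                raise ValueError(f"Fix strategy requires kappa_c in {KAPPA_BOUNDS}")
        if self.explicit == "SFu":
            if self.eta is None or len(self.eta) != 3:
                raise ValueError("SFu requires eta = (eta_high, eta_med, eta_low)")
            if any(not (0.0 <= e <= 1.0) for e in self.eta):
                raise ValueError("eta entries must lie in [0, 1]")
            if self.lapse:
                raise ValueError("stochastic fusion has no lapse parameter")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError("lapse must lie in [0, 1]")

    def eta_for(self, c_vis):
        return self.eta[RELIABILITIES.index(c_vis)]


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the factorial model space.

    ``explicit``/``implicit`` name the causal-inference strategy used in the
    unity-judgment and inertial-discrimination tasks (None when the task is
    not covered); ``noise`` is 'C' or 'X'; ``prior`` is 'E' or 'I'.
    """

    explicit: str = None
    implicit: str = None
    noise: str = "C"
    prior: str = "I"
    tasks: tuple = TASKS

    def __post_init__(self):
        if self.noise not in ("C", "X"):
            raise ValueError(f"unknown noise shape {self.noise!r}")
        if self.prior not in ("E", "I"):
            raise ValueError(f"unknown prior kind {self.prior!r}")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks {unknown}")
        if "unity" in self.tasks and self.explicit is None:
            raise ValueError("unity task requires an explicit strategy")
        if "inertial" in self.tasks and self.implicit is None:
            raise ValueError("inertial task requires an implicit strategy")
        if self.explicit is not None and self.explicit not in EXPLICIT_STRATEGIES:
            raise ValueError(f"unknown explicit strategy {self.explicit!r}")
        if self.implicit is not None and self.implicit not in IMPLICIT_STRATEGIES:
            raise ValueError(f"unknown implicit strategy {self.implicit!r}")

    # -- which ingredients does the model actually use? ---------------------
    @property
    def uses_measurement_noise(self):
        tasks = set(self.tasks)
        if tasks & {"unisensory", "inertial"}:
            return True
        return "unity" in tasks and self.explicit != "SFu"

    @property
    def uses_prior(self):
        if "inertial" in self.tasks:
            return True
        return "unity" in self.tasks and self.explicit in ("Bay", "BayPM")

    @property
    def uses_separate_scenario(self):
        """Whether the C=2 scenario enters any decision rule."""
        if "unity" in self.tasks and self.explicit in ("Bay", "BayPM"):
            return True
        return "inertial" in self.tasks and self.implicit in ("Bay", "BayPM", "Fix")

    @property
    def uses_lapse(self):
        tasks = set(self.tasks)
        if tasks & {"unisensory", "inertial"}:
            return True
        return "unity" in tasks and self.explicit != "SFu"

    @property
    def name(self):
        if self.explicit is not None and self.implicit is not None:
            strat = f"{self.explicit}/{self.implicit}"
        else:
            strat = self.explicit or self.implicit or "none"
        parts = [strat]
        if self.uses_measurement_noise:
            parts.append(self.noise)
        if self.uses_prior:
            parts.append(self.prior)
        return "-".join(parts)

    @classmethod
    def from_name(cls, name, tasks=TASKS):
        bits = name.split("-")
        strat = bits[0]
        explicit = implicit = None
        if "/" in strat:
            explicit, implicit = strat.split("/")
        elif "unity" in tasks:
            explicit = strat
        else:
            implicit = strat
        noise = bits[1] if len(bits) > 1 else "C"
        prior = bits[2] if len(bits) > 2 else "I"
        return cls(explicit=explicit, implicit=implicit, noise=noise,
                   prior=prior, tasks=tuple(tasks))


def explicit_model_space():
    """The seven models of the unity-judgment (explicit) task."""
    models = []
    for noise in ("C", "X"):
        for prior in ("E", "I"):
            models.append(ModelSpec(explicit="Bay", noise=noise, prior=prior,
                                    tasks=("unity",)))
    models.append(ModelSpec(explicit="Fix", noise="C", tasks=("unity",)))
    models.append(ModelSpec(explicit="Fix", noise="X", tasks=("unity",)))
    models.append(ModelSpec(explicit="SFu", tasks=("unity",)))
    return models


def implicit_model_space():
    """The twelve models of the inertial-discrimination (implicit) task."""
    return [
        ModelSpec(implicit=strategy, noise=noise, prior=prior, tasks=("inertial",))
        for strategy in ("Bay", "Fix", "FFu")
        for noise in ("C", "X")
        for prior in ("E", "I")
    ]


def joint_model_space():
    """The sixteen models of the joint (all-task) fits."""
    return [
        ModelSpec(explicit=e, implicit=i, noise=noise, prior=prior, tasks=TASKS)
        for (e, i) in (("Bay", "Bay"), ("Fix", "Fix"), ("Bay", "FFu"), ("Fix", "FFu"))
        for noise in ("C", "X")
        for prior in ("E", "I")
    ]


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus condition: headings, visual reliability and task."""

    task: str
    s_vest: float = None
    s_vis: float = None
    c_vis: str = None

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        for s in (self.s_vis, self.s_vest):
            if s is not None and not (DOMAIN[0] <= s < DOMAIN[1] + 1e-12):
                raise ValueError(f"heading {s} outside {DOMAIN}")
        if self.task in ("unity", "inertial"):
            if self.s_vis is None or self.s_vest is None:
                raise ValueError(f"{self.task} task requires both headings")
            if self.c_vis not in RELIABILITIES:
                raise ValueError("bisensory tasks require a visual reliability level")
        else:
            if (self.s_vis is None) == (self.s_vest is None):
                raise ValueError("unisensory task requires exactly one heading")
            if self.s_vis is not None and self.c_vis not in RELIABILITIES:
                raise ValueError("visual stimuli require a reliability level")

    @property
    def modality(self):
        if self.task != "unisensory":
            return None
        return "vis" if self.s_vis is not None else "vest"

    @property
    def mean_heading(self):
        return 0.5 * (self.s_vis + self.s_vest)

    @property
    def disparity(self):
        return self.s_vest - self.s_vis


# ---------------------------------------------------------------------------
# Observer: measurement-conditional computations
# ---------------------------------------------------------------------------


class Observer:
    """A fully specified observer (structure + parameters).

    All public methods are vectorized over arrays of measurements and return
    probabilities conditional on the internal measurements; they implement
    the decision stage only.  ``n_s`` controls the quadrature grid used for
    the continuous (independent) prior.
    """

    def __init__(self, spec: ModelSpec, noise: NoiseParams,
                 prior: PriorParams = None, strategy: StrategyParams = None,
                 n_s: int = 201, domain=DOMAIN):
        if prior is not None and prior.kind != spec.prior:
            raise ValueError("prior kind does not match the model spec")
        if noise.shape != spec.noise:
            raise ValueError("noise shape does not match the model spec")
        if strategy is None:
            strategy = StrategyParams()
        if (spec.explicit, spec.implicit) != (strategy.explicit, strategy.implicit):
            raise ValueError("strategies do not match the model spec")
        if spec.uses_prior and prior is None:
            raise ValueError("this model requires prior parameters")
        self.spec = spec
        self.noise = noise
        self.prior = prior
        self.strategy = strategy
        self.n_s = int(n_s)
        self.domain = tuple(domain)

    # -- prior supports ------------------------------------------------------
    @cached_property
    def _support_c1(self):
        """(s, w): common-heading support and normalized weights."""
        if self.prior.kind == "E":
            s, _, w = empirical_support(self.prior, 1)
            return s, w
        lo, hi = self.domain
        s = np.linspace(lo, hi, self.n_s)
        tw = np.full(self.n_s, s[1] - s[0])
        tw[0] *= 0.5
        tw[-1] *= 0.5
        w = tw * _norm_pdf(s, 0.0, self.prior.sigma_prior)
        return s, w / w.sum()

    @cached_property
    def _support_c2(self):
        """(s_vis, s_vest, w) for the separate-causes scenario (kind 'E')."""
        return empirical_support(self.prior, 2)

    # -- likelihood matrices -------------------------------------------------
    def _lik(self, x, modality, c_vis, s_nodes):
        """Truncated-normal likelihood matrix, shape (len(x), len(s_nodes))."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        sigma = np.atleast_1d(self.noise.sd(s_nodes, modality, c_vis))
        lo, hi = self.domain
        z = _trunc_norm_z(s_nodes, sigma, lo, hi)
        return _norm_pdf(x[:, None], s_nodes[None, :], sigma[None, :]) / z[None, :]

    def _pos_mask(self, s_nodes):
        """'Rightward' indicator over support nodes; mass at 0 split equally."""
        return step(np.asarray(s_nodes, dtype=float))

    # -- scenario likelihoods and posteriors ---------------------------------
    def _pairwise(self, x_vis, x_vest, c_vis, need_c2=True):
        """Scenario likelihoods and rightward numerators for measurement pairs.

        Builds each likelihood matrix once; returns a dict with ``p1``,
        ``p2``, ``num1``, ``num2`` (the latter two are the contributions of
        rightward headings, mass at 0 split equally).  The separate-causes
        quantities are skipped when ``need_c2`` is false (forced fusion).
        """
        x_vis = np.atleast_1d(np.asarray(x_vis, dtype=float))
        x_vest = np.atleast_1d(np.asarray(x_vest, dtype=float))
        s1, w1 = self._support_c1
        Lv1 = self._lik(x_vis, "vis", c_vis, s1)
        Le1 = self._lik(x_vest, "vest", None, s1)
        prod1 = Lv1 * Le1
        p1 = prod1 @ w1
        num1 = prod1 @ (w1 * self._pos_mask(s1))
        if not need_c2:
            p2 = num2 = None
        elif self.prior.kind == "E":
            sv, se, w2 = self._support_c2
            Lv2 = self._lik(x_vis, "vis", c_vis, sv)
            Le2 = self._lik(x_vest, "vest", None, se)
            prod2 = Lv2 * Le2
            p2 = prod2 @ w2
            num2 = prod2 @ (w2 * self._pos_mask(se))
        else:
            mvis = Lv1 @ w1
            mvest = Le1 @ w1
            p2 = mvis * mvest
            num2 = mvis * (Le1 @ (w1 * self._pos_mask(s1)))
        return {"p1": p1, "p2": p2, "num1": num1, "num2": num2,
                "x_vis": x_vis, "x_vest": x_vest}

    def scenario_likelihoods(self, x_vis, x_vest, c_vis):
        """p(x_vis, x_vest | C=1) and p(x_vis, x_vest | C=2), elementwise."""
        st = self._pairwise(x_vis, x_vest, c_vis)
        return st["p1"], st["p2"]

    def _posterior_c1(self, st):
        p_c = self.strategy.p_c
        if p_c is None:
            raise ValueError("posterior over causes requires p_c")
        num = p_c * st["p1"]
        den = num + (1.0 - p_c) * st["p2"]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), p_c)

    def posterior_common_cause(self, x_vis, x_vest, c_vis):
        """Pr(C=1 | x_vis, x_vest, c_vis) for the Bayesian strategies."""
        return self._posterior_c1(self._pairwise(x_vis, x_vest, c_vis))

    def _pr_right(self, st, C):
        den = st["p1"] if C == 1 else st["p2"]
        num = st["num1"] if C == 1 else st["num2"]
        fallback = step(0.5 * (st["x_vis"] + st["x_vest"]) if C == 1
                        else np.broadcast_to(st["x_vest"], den.shape))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0),
                            fallback)

    def pr_right_given_scenario(self, x_vis, x_vest, c_vis, C):
        """Pr(s_vest > 0 | x_vis, x_vest, C)."""
        return self._pr_right(self._pairwise(x_vis, x_vest, c_vis), C)

    # -- decision rules -------------------------------------------------------
    def _lapse_mix(self, d):
        lam = self.strategy.lapse
        return lam / 2.0 + (1.0 - lam) * d

    def choice_prob_unity(self, x_vis, x_vest, c_vis):
        """Pr(report 'unity' | measurements) under the explicit strategy."""
        strat = self.strategy.explicit
        if strat is None:
            raise ValueError("model has no explicit strategy")
        if strat == "SFu":
            shape = np.broadcast_shapes(np.shape(x_vis), np.shape(x_vest))
            return np.full(shape if shape else (1,), self.strategy.eta_for(c_vis))
        if strat == "Bay":
            d = step(self._posterior_c1(self._pairwise(x_vis, x_vest, c_vis)), 0.5)
        elif strat == "BayPM":
            d = self._posterior_c1(self._pairwise(x_vis, x_vest, c_vis))
        elif strat == "Fix":
            x_vis = np.atleast_1d(np.asarray(x_vis, dtype=float))
            x_vest = np.atleast_1d(np.asarray(x_vest, dtype=float))
            d = step(self.strategy.kappa_c - np.abs(x_vis - x_vest))
        return self._lapse_mix(d)

    def implicit_causal_weight(self, x_vis, x_vest, c_vis):
        """Implicit weight v1 of the common-cause scenario.

        For probability matching the Bernoulli scenario draw is marginalized
        analytically, so the returned weight equals the posterior Pr(C=1|x).
        """
        strat = self.strategy.implicit
        if strat is None:
            raise ValueError("model has no implicit strategy")
        shape = np.broadcast_shapes(np.shape(x_vis), np.shape(x_vest))
        if strat == "FFu":
            return np.ones(shape if shape else (1,))
        if strat in ("Bay", "BayPM"):
            return self.posterior_common_cause(x_vis, x_vest, c_vis)
        x_vis = np.atleast_1d(np.asarray(x_vis, dtype=float))
        x_vest = np.atleast_1d(np.asarray(x_vest, dtype=float))
        return step(self.strategy.kappa_c - np.abs(x_vis - x_vest))

    def choice_prob_right(self, x_vis, x_vest, c_vis=None, task="inertial"):
        """Pr(report 'right' | measurements) for a discrimination task."""
        if task == "unisensory":
            if (x_vis is None) == (x_vest is None):
                raise ValueError("unisensory task requires exactly one measurement")
            x = x_vest if x_vis is None else x_vis
            return self._lapse_mix(step(np.asarray(x, dtype=float)))
        if task != "inertial":
            raise ValueError(f"not a discrimination task: {task!r}")
        if x_vis is None or x_vest is None:
            raise ValueError("inertial discrimination requires both measurements")
        strat = self.strategy.implicit
        if strat is None:
            raise ValueError("model has no implicit strategy")
        st = self._pairwise(x_vis, x_vest, c_vis, need_c2=(strat != "FFu"))
        r1 = self._pr_right(st, 1)
        if strat == "FFu":
            return self._lapse_mix(step(r1, 0.5))
        r2 = self._pr_right(st, 2)
        if strat == "Bay":
            v1 = self._posterior_c1(st)
            d = step(v1 * r1 + (1.0 - v1) * r2, 0.5)
        elif strat == "BayPM":
            v1 = self._posterior_c1(st)
            d = v1 * step(r1, 0.5) + (1.0 - v1) * step(r2, 0.5)
        else:  # Fix
            x_vis = np.atleast_1d(np.asarray(x_vis, dtype=float))
            x_vest = np.atleast_1d(np.asarray(x_vest, dtype=float))
            band = step(self.strategy.kappa_c - np.abs(x_vis - x_vest))
            d = np.where(band == 1.0, step(r1, 0.5),
                         np.where(band == 0.0, step(r2, 0.5),
                                  0.5 * (step(r1, 0.5) + step(r2, 0.5))))
        return self._lapse_mix(d)

    def draw_measurement(self, s, modality, c_vis, rng, size=None):
        """Sample truncated-normal measurements for heading(s) ``s``."""
        s = np.asarray(s, dtype=float)
        sigma = self.noise.sd(s, modality, c_vis)
        lo, hi = self.domain
        a = ndtr((lo - s) / sigma)
        b = ndtr((hi - s) / sigma)
        u = rng.uniform(size=size if size is not None else s.shape)
        return s + sigma * ndtri(a + u * (b - a))


# ---------------------------------------------------------------------------
# Parameter-dictionary plumbing
# ---------------------------------------------------------------------------

THETA_KEYS = (
    "sigma0_vest", "sigma0_vis_high", "sigma0_vis_med", "sigma0_vis_low",
    "w_vest", "w_vis", "lambda", "p_c", "kappa_c",
    "eta_high", "eta_med", "eta_low", "sigma_prior", "delta_prior",
)


def make_observer(spec: ModelSpec, theta: dict, n_s: int = 201,
                  domain=DOMAIN) -> Observer:
    """Build an :class:`Observer` from a named parameter dictionary.

    Missing structural parameters default sensibly (zero eccentricity for
    constant noise, zero lapse for stochastic fusion); parameters that the
    model does not use are ignored.
    """
    if spec.uses_measurement_noise:
        noise = NoiseParams(
            sigma0_vest=theta["sigma0_vest"],
            sigma0_vis=(theta["sigma0_vis_high"], theta["sigma0_vis_med"],
                        theta["sigma0_vis_low"]),
            w_vest=theta.get("w_vest", 0.0) if spec.noise == "X" else 0.0,
            w_vis=theta.get("w_vis", 0.0) if spec.noise == "X" else 0.0,
            shape=spec.noise,
        )
    else:
        noise = NoiseParams(sigma0_vest=1.0, sigma0_vis=(1.0, 1.0, 1.0),
                            shape=spec.noise)
    prior = None
    if spec.uses_prior:
        prior = PriorParams(
            sigma_prior=theta["sigma_prior"],
            delta_prior=theta.get("delta_prior") if spec.prior == "E" else None,
            kind=spec.prior,
        )
    needs_pc = "Bay" in (spec.explicit, spec.implicit) or "BayPM" in (
        spec.explicit, spec.implicit)
    needs_kappa = "Fix" in (spec.explicit, spec.implicit)
    strategy = StrategyParams(
        explicit=spec.explicit,
        implicit=spec.implicit,
        p_c=theta.get("p_c") if needs_pc else None,
        kappa_c=theta.get("kappa_c") if needs_kappa else None,
        eta=(theta["eta_high"], theta["eta_med"], theta["eta_low"])
        if spec.explicit == "SFu" else None,
        lapse=theta.get("lambda", 0.0) if spec.uses_lapse else 0.0,
    )
    return Observer(spec, noise, prior, strategy, n_s=n_s, domain=domain)
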