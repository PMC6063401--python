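"""Trial response probabilities and dataset log-likelihoods.

Response probabilities marginalize the measurement-conditional decision
rules of :mod:`multicause.models` over the unseen noisy measurements:

``Pr(r | s_vest)              = int Pr(r | x_vest) p(x_vest | s_vest) dx``
``Pr(r | s_vis, s_vest, c)    = int int Pr(r | x_vis, x_vest, c)
                                 p(x_vis|s_vis, c) p(x_vest|s_vest) dx dx``

The integrals run over the measurement domain (default [-90, 90] deg) on a
single global equispaced grid, so the decision statistics are computed once
per (parameter vector, reliability, task) and reused across trials.  Plain
trapezoidal rules are first-order inaccurate here because decision rules are
step functions of the measurements.  Every decision rule is therefore
decomposed into smooth fields plus indicator components ``A(x) * [T(x) > 0]``
with a smooth statistic ``T``; grid cells whose corners straddle ``T = 0``
are re-integrated exactly against the separable Gaussian measurement
density, with the boundary located by bilinear interpolation of ``T``
(Gauss-Legendre along the visual axis, analytic Gaussian mass along the
vestibular axis).  A Monte Carlo sampling oracle is provided for
cross-validation of the quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, roots_legendre

from .models import (
    DOMAIN,
    ModelSpec,
    Observer,
    StimulusCondition,
    _norm_pdf,
    _trunc_norm_z,
    make_observer,
    step,
)

__all__ = [
    "GridSpec",
    "LogLik",
    "OracleEstimate",
    "response_prob_unisensory",
    "response_prob_bisensory",
    "bisensory_response_probs",
    "dataset_log_likelihood",
    "mc_response_prob_oracle",
    "PROB_FLOOR",
]

#: Per-trial probabilities are clamped at this floor before taking logs.
PROB_FLOOR = 1e-10

#: Gauss-Legendre order for boundary-cell re-integration.
_GL_ORDER = 8


@dataclass(frozen=True)
class GridSpec:
    """Numerical-integration settings.

    ``n_x``: nodes per measurement dimension; ``n_s``: nodes of the heading
    grid used for the continuous (independent) prior.
    """

    n_x: int = 401
    n_s: int = 201
    domain: tuple = DOMAIN
    gl_order: int = _GL_ORDER

    def x_nodes(self):
        x = np.linspace(self.domain[0], self.domain[1], self.n_x)
        tw = np.full(self.n_x, x[1] - x[0])
        tw[0] *= 0.5
        tw[-1] *= 0.5
        return x, tw


class LogLik(NamedTuple):
    total: float
    per_trial: np.ndarray
    n_clamped: int


class OracleEstimate(NamedTuple):
    estimate: float
    se: float
    n_draws: int


# ---------------------------------------------------------------------------
# Scenario statistic grids (row index = x_vest node, column = x_vis node)
# ---------------------------------------------------------------------------


class _ScenarioGrids:
    """Posterior statistics of an observer on the (x_vest, x_vis) node grid.

    Everything is computed lazily: strategies that never consult the
    posterior (fixed criterion, fusion variants) pay nothing here.
    """

    def __init__(self, obs: Observer, c_vis, x):
        self.obs = obs
        self.c_vis = c_vis
        self.x = x

    def _c1_inputs(self):
        if not hasattr(self, "_Av1"):
            obs, x = self.obs, self.x
            s1, w1 = obs._support_c1
            self._Av1 = obs._lik(x, "vis", self.c_vis, s1)
            self._Ae1 = obs._lik(x, "vest", None, s1)
            self._w1 = w1
            self._pos1 = obs._pos_mask(s1)
        return self._Av1, self._Ae1, self._w1, self._pos1

    def _c1_matrices(self):
        if not hasattr(self, "_p1"):
            Av1, Ae1, w1, pos1 = self._c1_inputs()
            self._p1 = (Ae1 * w1) @ Av1.T
            self._n1 = (Ae1 * (w1 * pos1)) @ Av1.T
        return self._p1, self._n1

    def _c2_matrices(self):
        if not hasattr(self, "_p2"):
            obs, x = self.obs, self.x
            if obs.prior.kind == "E":
                sv, se, w2 = obs._support_c2
                Av2 = obs._lik(x, "vis", self.c_vis, sv)
                Ae2 = obs._lik(x, "vest", None, se)
                self._p2 = (Ae2 * w2) @ Av2.T
                self._n2 = (Ae2 * (w2 * obs._pos_mask(se))) @ Av2.T
            else:
                Av1, Ae1, w1, pos1 = self._c1_inputs()
                mvis = Av1 @ w1
                mvest = Ae1 @ w1
                nvest = Ae1 @ (w1 * pos1)
                self._p2 = mvest[:, None] * mvis[None, :]
                self._n2 = nvest[:, None] * mvis[None, :]
        return self._p2, self._n2

    @property
    def p1(self):
        return self._c1_matrices()[0]

    @property
    def n1(self):
        return self._c1_matrices()[1]

    @property
    def p2(self):
        return self._c2_matrices()[0]

    @property
    def n2(self):
        return self._c2_matrices()[1]

    @property
    def xe_grid(self):
        return self.x[:, None]

    @property
    def xv_grid(self):
        return self.x[None, :]

    def posterior_c1(self):
        if not hasattr(self, "_p1_post"):
            p_c = self.obs.strategy.p_c
            num = p_c * self.p1
            den = num + (1.0 - p_c) * self.p2
            with np.errstate(invalid="ignore", divide="ignore"):
                self._p1_post = np.where(
                    den > 0.0, num / np.where(den > 0.0, den, 1.0), p_c)
        return self._p1_post

    def r1(self):
        if not hasattr(self, "_r1"):
            with np.errstate(invalid="ignore", divide="ignore"):
                fallback = step(0.5 * (self.xe_grid + self.xv_grid))
                self._r1 = np.where(
                    self.p1 > 0.0,
                    self.n1 / np.where(self.p1 > 0.0, self.p1, 1.0), fallback)
        return self._r1

    def r2(self):
        if not hasattr(self, "_r2"):
            with np.errstate(invalid="ignore", divide="ignore"):
                fallback = np.broadcast_to(step(self.x)[:, None], self.p2.shape)
                self._r2 = np.where(
                    self.p2 > 0.0,
                    self.n2 / np.where(self.p2 > 0.0, self.p2, 1.0), fallback)
        return self._r2


# ---------------------------------------------------------------------------
# Decision fields: node values + indicator components A(x) * [T(x) > 0]
# ---------------------------------------------------------------------------


def _bilin(G, rows, cols, u, v):
    """Bilinear interpolation of grid ``G`` inside cells (rows, cols)."""
    g00 = G[rows, cols]
    g01 = G[rows, cols + 1]
    g10 = G[rows + 1, cols]
    g11 = G[rows + 1, cols + 1]
    return (g00 * (1 - u) * (1 - v) + g01 * u * (1 - v)
            + g10 * (1 - u) * v + g11 * u * v)


def _unity_bay(obs, grids, x):
    T = grids.posterior_c1() - 0.5
    return step(T), [(None, T)], None


def _unity_baypm(obs, grids, x):
    return grids.posterior_c1(), [], None


def _band_stat(obs, grids):
    return obs.strategy.kappa_c - np.abs(grids.xv_grid - grids.xe_grid)


def _unity_fix(obs, grids, x):
    T = _band_stat(obs, grids)
    return step(T), [(None, T)], None


def _implicit_ffu(obs, grids, x):
    T = grids.r1() - 0.5
    return step(T), [(None, T)], None


def _implicit_bay(obs, grids, x):
    P1 = grids.posterior_c1()
    T = P1 * grids.r1() + (1.0 - P1) * grids.r2() - 0.5
    return step(T), [(None, T)], None


def _implicit_baypm(obs, grids, x):
    P1 = grids.posterior_c1()
    T1 = grids.r1() - 0.5
    T2 = grids.r2() - 0.5
    F = P1 * step(T1) + (1.0 - P1) * step(T2)

    def multi_eval(rows, cols, u, v):
        p1b = _bilin(P1, rows, cols, u, v)
        s1 = step(_bilin(T1, rows, cols, u, v))
        s2 = step(_bilin(T2, rows, cols, u, v))
        return p1b * s1 + (1.0 - p1b) * s2

    return F, [(P1, T1), (1.0 - P1, T2)], multi_eval


def _implicit_fix(obs, grids, x):
    T1 = grids.r1() - 0.5
    T2 = grids.r2() - 0.5
    Tb = _band_stat(obs, grids)
    s1, s2, B = step(T1), step(T2), step(Tb)
    F = B * s1 + (1.0 - B) * s2

    def multi_eval(rows, cols, u, v):
        b = step(_bilin(Tb, rows, cols, u, v))
        e1 = step(_bilin(T1, rows, cols, u, v))
        e2 = step(_bilin(T2, rows, cols, u, v))
        return b * e1 + (1.0 - b) * e2

    return F, [(B, T1), (1.0 - B, T2), (s1 - s2, Tb)], multi_eval


# ---------------------------------------------------------------------------
# 2-D quadrature with exact boundary-cell treatment
# ---------------------------------------------------------------------------


def _axis_moments(x, mu, sigma):
    """Per-cell basis integrals of the Gaussian density along one axis.

    Returns ``(U0, U1)`` of shape (n_cells, n_cond): integrals over each
    cell of ``(1-u) p(x)`` and ``u p(x)`` with ``u`` the local coordinate.
    """
    h = x[1] - x[0]
    z = (x[:, None] - mu[None, :]) / sigma[None, :]
    cdf = ndtr(z)
    pdf = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    i0 = cdf[1:] - cdf[:-1]                       # mass per cell
    # first moment of x over the cell: mu*i0 - sigma*(pdf_hi - pdf_lo)
    m1 = mu[None, :] * i0 - sigma[None, :] * (pdf[1:] - pdf[:-1])
    u_mom = (m1 - x[:-1, None] * i0) / h          # integral of u * p
    return i0 - u_mom, u_mom


def _boundary_cells(T):
    c00 = T[:-1, :-1]
    c01 = T[:-1, 1:]
    c10 = T[1:, :-1]
    c11 = T[1:, 1:]
    tmin = np.minimum(np.minimum(c00, c01), np.minimum(c10, c11))
    tmax = np.maximum(np.maximum(c00, c01), np.maximum(c10, c11))
    return np.nonzero((tmin < 0.0) & (tmax > 0.0))


def _cell_corrections(x, T, A, rows, cols, mu_vis, sigma_vis, mu_vest,
                      sigma_vest, moments_vis, moments_vest, gl):
    """Exact minus bilinear-smeared integral of ``A * [T>0]`` over cells.

    ``T`` is interpolated bilinearly within each cell; its zero contour
    defines the indicator region.  Returns (n_cond,) corrections summed over
    the given cells.
    """
    h = x[1] - x[0]
    u_q, w_q = gl
    t00 = T[rows, cols][:, None]
    t01 = T[rows, cols + 1][:, None]
    t10 = T[rows + 1, cols][:, None]
    t11 = T[rows + 1, cols + 1][:, None]
    if A is None:
        a_cell = 1.0
    else:
        a_cell = 0.25 * (A[rows, cols] + A[rows, cols + 1]
                         + A[rows + 1, cols] + A[rows + 1, cols + 1])
        a_cell = a_cell[:, None]

    # --- exact integral of [T>0] against the density --------------------
    # At visual offset u: T is linear in v from alpha(u) to gamma(u).
    alpha = t00 + (t01 - t00) * u_q[None, :]          # (K, Q)
    gamma = t10 + (t11 - t10) * u_q[None, :]
    diff = gamma - alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        v_star = np.where(diff != 0.0, -alpha / np.where(diff != 0.0, diff, 1.0),
                          np.inf)
    v_star = np.clip(v_star, 0.0, 1.0)
    # region where T>0: [v_star, 1] if increasing, [0, v_star] if decreasing
    inc = diff > 0.0
    pos_at_0 = alpha > 0.0
    v_lo = np.where(inc, np.where(pos_at_0, 0.0, v_star), 0.0)
    v_hi = np.where(inc, 1.0, np.where(pos_at_0, v_star, 0.0))
    # constant-sign columns
    const = np.isclose(diff, 0.0)
    v_lo = np.where(const, 0.0, v_lo)
    v_hi = np.where(const, np.where(pos_at_0, 1.0, 0.0), v_hi)

    xe_lo = x[rows][:, None]
    xv_q = x[cols][:, None] + h * u_q[None, :]        # (K, Q)
    mu_e = mu_vest[None, None, :]
    sig_e = sigma_vest[None, None, :]
    z_lo = (xe_lo[:, :, None] + h * v_lo[:, :, None] - mu_e) / sig_e
    z_hi = (xe_lo[:, :, None] + h * v_hi[:, :, None] - mu_e) / sig_e
    mass_e = ndtr(z_hi) - ndtr(z_lo)                  # (K, Q, C)
    dens_v = _norm_pdf(xv_q[:, :, None], mu_vis[None, None, :],
                       sigma_vis[None, None, :])
    exact = h * np.einsum("q,kqc->kc", w_q, dens_v * mass_e)

    # --- bilinear smear of the corner step values ------------------------
    s00 = step(t00[:, 0])[:, None]
    s01 = step(t01[:, 0])[:, None]
    s10 = step(t10[:, 0])[:, None]
    s11 = step(t11[:, 0])[:, None]
    U0, U1 = moments_vis
    V0, V1 = moments_vest
    u0, u1 = U0[cols], U1[cols]                       # (K, C)
    v0, v1 = V0[rows], V1[rows]
    smear = (s00 * u0 * v0 + s01 * u1 * v0 + s10 * u0 * v1 + s11 * u1 * v1)

    return np.sum(a_cell * (exact - smear), axis=0)


def _subdivision_correction(x, F, multi_eval, rows, cols, mu_v, sg_v, mu_e,
                            sg_e, moments_vis, moments_vest, n_sub=12):
    """Exact-by-subdivision re-integration of cells crossed by several
    decision boundaries, where per-component corrections would interact."""
    h = x[1] - x[0]
    k = rows.size
    edges = np.arange(n_sub + 1) / n_sub
    centers = (edges[:-1] + edges[1:]) / 2.0
    u = centers[None, :, None]
    v = centers[None, None, :]
    f_sub = multi_eval(rows[:, None, None], cols[:, None, None], u, v)
    # per-axis Gaussian mass of each sub-column / sub-row, per condition
    xv_edges = x[cols][:, None] + h * edges[None, :]
    xe_edges = x[rows][:, None] + h * edges[None, :]
    cdf_v = ndtr((xv_edges[:, :, None] - mu_v[None, None, :])
                 / sg_v[None, None, :])
    cdf_e = ndtr((xe_edges[:, :, None] - mu_e[None, None, :])
                 / sg_e[None, None, :])
    mass_v = cdf_v[:, 1:, :] - cdf_v[:, :-1, :]      # (K, n_sub, C)
    mass_e = cdf_e[:, 1:, :] - cdf_e[:, :-1, :]
    exact = np.einsum("kuv,kuc,kvc->c", f_sub, mass_v, mass_e)
    U0, U1 = moments_vis
    V0, V1 = moments_vest
    u0, u1 = U0[cols], U1[cols]
    v0, v1 = V0[rows], V1[rows]
    f00 = F[rows, cols][:, None]
    f01 = F[rows, cols + 1][:, None]
    f10 = F[rows + 1, cols][:, None]
    f11 = F[rows + 1, cols + 1][:, None]
    smear = np.sum(f00 * u0 * v0 + f01 * u1 * v0 + f10 * u0 * v1
                   + f11 * u1 * v1, axis=0)
    return exact - smear


def _integrate_field(x, tw, F, components, multi_eval, s_vis, sigma_vis,
                     s_vest, sigma_vest, gl_order=_GL_ORDER):
    """Marginalize a decision field over both measurement densities.

    Returns one pre-lapse response probability per condition.
    """
    mu_v = np.atleast_1d(np.asarray(s_vis, dtype=float))
    sg_v = np.atleast_1d(np.asarray(sigma_vis, dtype=float))
    mu_e = np.atleast_1d(np.asarray(s_vest, dtype=float))
    sg_e = np.atleast_1d(np.asarray(sigma_vest, dtype=float))
    dens_v = _norm_pdf(x[:, None], mu_v[None, :], sg_v[None, :]) * tw[:, None]
    dens_e = _norm_pdf(x[:, None], mu_e[None, :], sg_e[None, :]) * tw[:, None]
    zv = dens_v.sum(axis=0)
    ze = dens_e.sum(axis=0)
    p = np.einsum("rc,ri,ic->c", dens_e, F, dens_v)
    if components:
        gl_nodes, gl_weights = roots_legendre(gl_order)
        gl = (0.5 * (gl_nodes + 1.0), 0.5 * gl_weights)
        moments_vis = _axis_moments(x, mu_v, sg_v)
        moments_vest = _axis_moments(x, mu_e, sg_e)
        n_cols = F.shape[1] - 1
        cell_ids = [r * n_cols + c for r, c in
                    (_boundary_cells(T) for _, T in components)]
        multi = np.array([], dtype=int)
        if multi_eval is not None and len(components) > 1:
            all_ids, counts = np.unique(np.concatenate(cell_ids),
                                        return_counts=True)
            multi = all_ids[counts > 1]
        for (A, T), ids in zip(components, cell_ids):
            if multi.size:
                ids = np.setdiff1d(ids, multi, assume_unique=False)
            if ids.size == 0:
                continue
            rows, cols = ids // n_cols, ids % n_cols
            p += _cell_corrections(x, T, A, rows, cols, mu_v, sg_v, mu_e,
                                   sg_e, moments_vis, moments_vest, gl)
        if multi.size:
            p += _subdivision_correction(x, F, multi_eval, multi // n_cols,
                                         multi % n_cols, mu_v, sg_v, mu_e,
                                         sg_e, moments_vis, moments_vest)
    return np.clip(p / (zv * ze), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Public response-probability API
# ---------------------------------------------------------------------------


def response_prob_unisensory(s, modality, c_vis, spec, theta=None,
                             grid: GridSpec = GridSpec()):
    """Pr(respond 'right' | heading s) in the unisensory discrimination task.

    With a symmetric prior and symmetric truncated noise the posterior sign
    rule reduces exactly to ``x > 0``, so the marginalization over the
    measurement is the truncated-normal mass right of zero.
    """
    obs = spec if isinstance(spec, Observer) else make_observer(
        spec, theta, n_s=grid.n_s, domain=grid.domain)
    s = np.asarray(s, dtype=float)
    sigma = obs.noise.sd(s, modality, c_vis)
    lo, hi = obs.domain
    z = _trunc_norm_z(s, sigma, lo, hi)
    p_right = (ndtr((hi - s) / sigma) - ndtr((0.0 - s) / sigma)) / z
    lam = obs.strategy.lapse
    return lam / 2.0 + (1.0 - lam) * p_right


def _build_field(obs, grids, x, task):
    """Decision field Pr(response | x) at the nodes plus indicator components."""
    if task == "unity":
        builders = {"Bay": _unity_bay, "BayPM": _unity_baypm, "Fix": _unity_fix}
        return builders[obs.strategy.explicit](obs, grids, x)
    builders = {"Bay": _implicit_bay, "BayPM": _implicit_baypm,
                "Fix": _implicit_fix, "FFu": _implicit_ffu}
    return builders[obs.strategy.implicit](obs, grids, x)


def bisensory_response_probs(conds: pd.DataFrame, spec, theta=None,
                             grid: GridSpec = GridSpec()):
    """Probability of 'unity' (unity task) / 'right' (inertial task).

    ``conds`` needs columns task, s_vis, s_vest, coherence; one probability
    per row is returned.  Conditions sharing (task, coherence) reuse the
    same decision field.
    """
    obs = spec if isinstance(spec, Observer) else make_observer(
        spec, theta, n_s=grid.n_s, domain=grid.domain)
    x, tw = grid.x_nodes()
    out = np.empty(len(conds))
    lam = obs.strategy.lapse
    grid_cache = {}
    for (task, c_vis), sub in conds.groupby(["task", "coherence"], sort=False):
        pos = conds.index.get_indexer(sub.index.to_numpy())
        if task == "unity" and obs.strategy.explicit == "SFu":
            out[pos] = obs.strategy.eta_for(c_vis)
            continue
        if task not in ("unity", "inertial"):
            raise ValueError(f"not a bisensory task: {task!r}")
        if c_vis not in grid_cache:
            grid_cache[c_vis] = _ScenarioGrids(obs, c_vis, x)
        grids = grid_cache[c_vis]
        F, components, multi_eval = _build_field(obs, grids, x, task)
        s_vis = sub["s_vis"].to_numpy(dtype=float)
        s_vest = sub["s_vest"].to_numpy(dtype=float)
        sigma_vis = np.atleast_1d(obs.noise.sd(s_vis, "vis", c_vis))
        sigma_vest = np.atleast_1d(obs.noise.sd(s_vest, "vest", None))
        p = _integrate_field(x, tw, F, components, multi_eval, s_vis,
                             sigma_vis, s_vest, sigma_vest,
                             gl_order=grid.gl_order)
        out[pos] = lam / 2.0 + (1.0 - lam) * p
    return out


def response_prob_bisensory(cond: StimulusCondition, spec, theta=None,
                            grid: GridSpec = GridSpec()):
    """Response probability for a single bisensory condition.

    Returns Pr('unity') for the unity task and Pr('right') for inertial
    discrimination.
    """
    df = pd.DataFrame([{"task": cond.task, "s_vis": cond.s_vis,
                        "s_vest": cond.s_vest, "coherence": cond.c_vis}])
    return float(bisensory_response_probs(df, spec, theta, grid)[0])


def mc_response_prob_oracle(cond: StimulusCondition, spec, theta=None,
                            n_draws=10_000, seed=0, grid: GridSpec = GridSpec(),
                            chunk=100_000):
    """Monte Carlo estimate of a response probability by forward sampling.

    Draws measurements from the (truncated) noise distributions, applies the
    measurement-conditional decision rule, samples binary responses and
    averages them.  Independent of the quadrature path; used as a test
    oracle.  ``se = sqrt(p(1-p)/M)``.
    """
    if n_draws < 1_000:
        raise ValueError("oracle needs at least 1000 draws")
    obs = spec if isinstance(spec, Observer) else make_observer(
        spec, theta, n_s=grid.n_s, domain=grid.domain)
    rng = np.random.default_rng(seed)
    n_yes = 0
    left = int(n_draws)
    while left > 0:
        m = min(chunk, left)
        if cond.task == "unisensory":
            s = cond.s_vis if cond.modality == "vis" else cond.s_vest
            xm = obs.draw_measurement(np.full(m, s), cond.modality, cond.c_vis, rng)
            p = obs.choice_prob_right(
                xm if cond.modality == "vis" else None,
                xm if cond.modality == "vest" else None,
                cond.c_vis, task="unisensory")
        else:
            xv = obs.draw_measurement(np.full(m, cond.s_vis), "vis", cond.c_vis, rng)
            xe = obs.draw_measurement(np.full(m, cond.s_vest), "vest", None, rng)
            if cond.task == "unity":
                p = obs.choice_prob_unity(xv, xe, cond.c_vis)
            else:
                p = obs.choice_prob_right(xv, xe, cond.c_vis, task="inertial")
        n_yes += int((rng.uniform(size=m) < p).sum())
        left -= m
    p_hat = n_yes / n_draws
    se = np.sqrt(max(p_hat * (1.0 - p_hat), PROB_FLOOR) / n_draws)
    return OracleEstimate(p_hat, se, int(n_draws))


# ---------------------------------------------------------------------------
# Dataset log-likelihood
# ---------------------------------------------------------------------------

_YES = {"unity": "unity", "inertial": "right", "unisensory": "right"}


def dataset_log_likelihood(data: pd.DataFrame, spec: ModelSpec, theta,
                           grid: GridSpec = GridSpec()) -> LogLik:
    """Total and per-trial log-likelihood of a trial table under one model.

    Trials are conditionally independent given the parameters, so the total
    is the sum of the per-trial log-probabilities (joint fits across tasks
    simply concatenate the trial tables).  Probabilities are clamped at
    ``PROB_FLOOR``; the number of clamped trials is reported.
    """
    data = data.reset_index(drop=True)
    missing = set(data["task"]) - set(_YES)
    if missing:
        raise ValueError(f"unknown tasks in data: {missing}")
    obs = make_observer(spec, theta, n_s=grid.n_s, domain=grid.domain)
    p_yes = np.empty(len(data))

    uni = data["task"] == "unisensory"
    if uni.any():
        sub = data.loc[uni]
        vis = sub["s_vis"].notna()
        if vis.any():
            for c_vis, rsub in sub.loc[vis].groupby("coherence"):
                p_yes[rsub.index.to_numpy()] = response_prob_unisensory(
                    rsub["s_vis"].to_numpy(dtype=float), "vis", c_vis, obs,
                    grid=grid)
        if (~vis).any():
            rows = sub.loc[~vis]
            p_yes[rows.index.to_numpy()] = response_prob_unisensory(
                rows["s_vest"].to_numpy(dtype=float), "vest", None, obs,
                grid=grid)

    bis = ~uni
    if bis.any():
        sub = data.loc[bis]
        conds = (sub[["task", "coherence", "s_vis", "s_vest"]]
                 .drop_duplicates().reset_index(drop=True))
        probs = bisensory_response_probs(conds, obs, grid=grid)
        lookup = pd.Series(probs, index=pd.MultiIndex.from_frame(conds))
        trial_key = pd.MultiIndex.from_frame(
            sub[["task", "coherence", "s_vis", "s_vest"]])
        p_yes[sub.index.to_numpy()] = lookup.loc[trial_key].to_numpy()

    yes = np.array([r == _YES[t] for t, r in zip(data["task"], data["response"])])
    p_obs = np.where(yes, p_yes, 1.0 - p_yes)
    n_clamped = int((p_obs < PROB_FLOOR).sum())
    per_trial = np.log(np.maximum(p_obs, PROB_FLOOR))
    return LogLik(float(per_trial.sum()), per_trial, n_clamped)
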