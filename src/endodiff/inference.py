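"""Joint structural+error likelihood and multistart maximum-likelihood fits.

The objective is the -2 log-likelihood of independent Gaussian residuals
with model-dependent heteroscedastic standard deviations,

    -2 l = sum_jk (Z_jk - g_j(t_k))^2 / eps_jk^2  +  sum_jk 2 ln eps_jk ,

up to the constant m*ln(2*pi), where g is the per-replicate ODE solution
and eps the error model evaluated at g.  Replicate initial conditions are
fixed to each replicate's day-0 measurements (day-0 records are therefore
excluded from the sums), and all structural/error parameters are pooled
across replicates.

Fitting uses multistart optimization: space-filling Latin-hypercube start
points over the box search space (rates and nmax in log10), a global
differential-evolution phase per start (rand/1/bin with dithered mutation)
followed by a Nelder-Mead polish.  The loss over common states (LOCS)
restricts the same objective to the observables shared by all lineages
(ns, nd, nq), giving every candidate model a comparable footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from scipy.stats import qmc

from . import _fast
from .model_core import (
    COMMON_STATES,
    ModelSpec,
    ParameterSpace,
    parameter_space,
)
from .simulate import integrate

__all__ = [
    "FitResult",
    "neg2loglik",
    "locs",
    "fit",
    "initial_conditions_from_day0",
    "make_objective",
    "SIGMA_MIN_DEFAULT",
    "UnderdeterminedDataError",
]

# Floor on the error-model sd (cells/mm^2); prevents infinite weights when
# a proportional error model meets a zero predicted mean.
SIGMA_MIN_DEFAULT = 1e-6


class UnderdeterminedDataError(ValueError):
    """Raised when the data cannot constrain a fit (e.g. one time point)."""


@dataclass
class FitResult:
    """Outcome of one optimization start (or the best across starts)."""

    spec: ModelSpec
    theta: dict[str, float]
    xi: dict[str, float]
    neg2loglik: float
    start_index: int
    converged: bool
    n_obs_used: int
    n_floored: int = 0

    @property
    def params(self) -> dict[str, float]:
        return {**self.theta, **self.xi}

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_code(),
            "theta": self.theta,
            "xi": self.xi,
            "neg2loglik": self.neg2loglik,
            "start_index": self.start_index,
            "converged": self.converged,
            "n_obs_used": self.n_obs_used,
            "n_floored": self.n_floored,
        }


def initial_conditions_from_day0(
    data: pd.DataFrame, spec: ModelSpec
) -> dict[str, dict[str, float]]:
    """Per-replicate day-0 state vectors from the observation table.

    States absent at day 0 (e.g. transition states when fitting M2/M3 to
    common-state data, or the dead pool) default to 0.
    """
    day0 = data[data["time_d"] == 0.0]
    ics: dict[str, dict[str, float]] = {}
    for rep in sorted(data["replicate_id"].unique()):
        rows = day0[day0["replicate_id"] == rep]
        lookup = dict(zip(rows["state"], rows["value"]))
        ics[rep] = {s: float(lookup.get(s, 0.0)) for s in spec.states}
    return ics


def _split_params(
    ps: ParameterSpace, x: np.ndarray, spec: ModelSpec
) -> tuple[dict[str, float], dict[str, float]]:
    d = ps.dict_from_vector(x)
    theta = {n: d[n] for n in spec.struct_param_names}
    xi = {n: d[n] for n in spec.error_param_names}
    return theta, xi


def _pack_data(spec: ModelSpec, data: pd.DataFrame, initial_conditions, states):
    """Flatten the long table into the arrays the compiled kernel expects."""
    state_list = spec.states
    state_idx = {s: j for j, s in enumerate(state_list)}
    reps = sorted(data["replicate_id"].unique())
    if not reps:
        raise ValueError("observation table is empty")
    for rep in reps:
        if rep not in initial_conditions:
            raise ValueError(f"no initial condition for replicate {rep!r}")

    post = data[data["time_d"] > 0.0]
    times_per_rep = [np.sort(post[post["replicate_id"] == r]["time_d"].unique())
                     for r in reps]
    n_t_max = max((len(t) for t in times_per_rep), default=0) + 1
    n_rep = len(reps)
    t_obs = np.zeros((n_rep, n_t_max))
    obs_mask = np.zeros((n_rep, n_t_max), dtype=np.bool_)
    z_obs = np.full((n_rep, n_t_max, len(state_list)), np.nan)
    y0_mat = np.zeros((n_rep, len(state_list)))

    for r, rep in enumerate(reps):
        ic = initial_conditions[rep]
        y0_mat[r] = [max(float(ic.get(s, 0.0)), 0.0) for s in state_list]
        tt = times_per_rep[r]
        t_obs[r, 1:1 + len(tt)] = tt
        obs_mask[r, 1:1 + len(tt)] = True
        # pad remaining slots with increasing dummy times (masked out)
        last = tt[-1] if len(tt) else 0.0
        for k in range(1 + len(tt), n_t_max):
            last += 1.0
            t_obs[r, k] = last
        sub = post[post["replicate_id"] == rep]
        tpos = {t: 1 + i for i, t in enumerate(tt)}
        for t, s, v in zip(sub["time_d"], sub["state"], sub["value"]):
            if s in state_idx:
                z_obs[r, tpos[t], state_idx[s]] = v

    if states is None:
        state_mask = np.ones(len(state_list), dtype=np.bool_)
    else:
        state_mask = np.array([s in states for s in state_list], dtype=np.bool_)
    return y0_mat, t_obs, z_obs, obs_mask, state_mask


def neg2loglik(
    spec: ModelSpec,
    theta: dict[str, float],
    xi: dict[str, float],
    data: pd.DataFrame,
    initial_conditions: dict[str, dict[str, float]],
    states=None,
    sigma_min: float = SIGMA_MIN_DEFAULT,
    return_diagnostics: bool = False,
):
    """-2 log-likelihood (up to m*ln(2*pi)) over all post-day-0 records.

    Means come from per-replicate integration (reference solve_ivp route)
    starting from that replicate's initial condition.  ``states`` restricts
    the sums to a subset of observables.
    """
    if data.empty:
        raise ValueError("observation table is empty")
    err_id = _fast.ERROR_ID[spec.error.value]
    a = float(xi.get("a", 0.0))
    b = float(xi.get("b", 0.0))
    y0_mat, t_obs, z_obs, obs_mask, state_mask = _pack_data(
        spec, data, initial_conditions, states
    )
    loss = 0.0
    n_used = 0
    n_floor = 0
    for r in range(len(y0_mat)):
        m = obs_mask[r]
        times = np.concatenate(([0.0], t_obs[r][m]))
        traj = integrate(spec, theta, y0_mat[r], times)
        g_all = traj.means[1:]
        z_all = z_obs[r][m]
        for it in range(z_all.shape[0]):
            for js in range(z_all.shape[1]):
                if not state_mask[js] or np.isnan(z_all[it, js]):
                    continue
                g = g_all[it, js]
                if err_id == 0:
                    eps = a
                elif err_id == 1:
                    eps = b * g
                else:
                    eps = a + b * g
                if eps < sigma_min:
                    eps = sigma_min
                    n_floor += 1
                loss += ((z_all[it, js] - g) / eps) ** 2 + 2.0 * np.log(eps)
                n_used += 1
    if return_diagnostics:
        return loss, {"n_obs_used": n_used, "n_floored": n_floor}
    return loss


def locs(
    theta: dict[str, float],
    xi: dict[str, float],
    data: pd.DataFrame,
    spec: ModelSpec,
    initial_conditions: dict[str, dict[str, float]],
    sigma_min: float = SIGMA_MIN_DEFAULT,
) -> float:
    """Loss over common states: the objective restricted to ns, nd, nq."""
    return neg2loglik(
        spec, theta, xi, data, initial_conditions,
        states=COMMON_STATES, sigma_min=sigma_min,
    )


def make_objective(
    spec: ModelSpec,
    data: pd.DataFrame,
    initial_conditions: dict[str, dict[str, float]],
    states=None,
    sigma_min: float = SIGMA_MIN_DEFAULT,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    fixed_params: dict[str, float] | None = None,
):
    """Compiled unit-cube objective for optimizers and profile scans.

    Returns ``(ps, f)`` where ``ps`` is the `ParameterSpace` and ``f`` maps
    a unit-cube vector to the -2 log-likelihood (inf on solver failure).
    ``fixed_params`` pins named parameters to given natural-unit values
    regardless of the corresponding unit-cube coordinate (used for
    noise-free weighted-least-squares fits and conditional objectives).
    """
    ps = parameter_space(spec)
    err_id = _fast.ERROR_ID[spec.error.value]
    lin = _fast.LINEAGE_ID[spec.lineage.value]
    gro = _fast.GROWTH_ID[spec.growth.value]
    y0_mat, t_obs, z_obs, obs_mask, state_mask = _pack_data(
        spec, data, initial_conditions, states
    )
    struct_names = [n for n in spec.struct_param_names if n != "nmax"]
    struct_pos = np.array([ps.index(n) for n in struct_names])
    nmax_pos = ps.index("nmax") if "nmax" in ps.names else -1
    a_pos = ps.index("a") if "a" in ps.names else -1
    b_pos = ps.index("b") if "b" in ps.names else -1
    fixed_idx, fixed_val = [], []
    for name, val in (fixed_params or {}).items():
        fixed_idx.append(ps.index(name))
        fixed_val.append(float(val))
    fixed_idx = np.array(fixed_idx, dtype=int)
    fixed_val = np.array(fixed_val)

    def f(u: np.ndarray) -> float:
        x = ps.from_unit(u)
        if fixed_idx.size:
            x[fixed_idx] = fixed_val
        th = x[struct_pos]
        nmax = x[nmax_pos] if nmax_pos >= 0 else 1.0
        a = x[a_pos] if a_pos >= 0 else 0.0
        b = x[b_pos] if b_pos >= 0 else 0.0
        loss, status, _, _ = _fast.neg2loglik_packed(
            lin, gro, err_id, th, nmax, a, b,
            y0_mat, t_obs, z_obs, obs_mask, state_mask,
            sigma_min, rtol, atol,
        )
        return loss if status == _fast.OK and np.isfinite(loss) else np.inf

    return ps, f


def _check_determined(data: pd.DataFrame) -> None:
    n_times = data.loc[data["time_d"] > 0.0, "time_d"].nunique()
    if n_times < 2:
        raise UnderdeterminedDataError(
            f"fit requires >= 2 distinct post-day-0 time points, got {n_times}"
        )


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    initial_conditions: dict[str, dict[str, float]] | None = None,
    n_starts: int = 100,
    budget: int = 100_000,
    seed: int = 0,
    states=None,
    sigma_min: float = SIGMA_MIN_DEFAULT,
    fixed_params: dict[str, float] | None = None,
) -> list[FitResult]:
    """Multistart maximum-likelihood fit; results sorted best first.

    ``budget`` is the approximate number of objective evaluations per
    start, split ~65/35 between the differential-evolution phase and the
    Nelder-Mead polish.  Deterministic under ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    _check_determined(data)
    if initial_conditions is None:
        initial_conditions = initial_conditions_from_day0(data, spec)
    ps, f = make_objective(spec, data, initial_conditions, states, sigma_min,
                           fixed_params=fixed_params)
    d = len(ps)

    ss = np.random.SeedSequence(seed)
    lhs_seed, *start_seeds = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n_starts + 1)
    ]
    sampler = qmc.LatinHypercube(d=d, seed=lhs_seed, optimization="random-cd")
    starts = sampler.random(n_starts)

    de_budget = max(int(0.5 * budget), 20)
    nm_budget = max(int(0.25 * budget), 50)
    pop_n = max(4 * d, 20)
    popsize = max(4, -(-pop_n // d))
    gens = max(1, de_budget // (popsize * d) - 1)
    nm_opts = {"maxfev": nm_budget, "xatol": 1e-8, "fatol": 1e-10,
               "adaptive": d > 8}

    results: list[FitResult] = []
    for i in range(n_starts):
        de = differential_evolution(
            f,
            bounds=[(0.0, 1.0)] * d,
            strategy="rand1bin",
            maxiter=gens,
            popsize=popsize,
            mutation=(0.5, 1.0),
            recombination=0.9,
            tol=0.0,
            seed=start_seeds[i],
            x0=starts[i],
            polish=False,
            init="latinhypercube",
        )
        nm = minimize(f, de.x, method="Nelder-Mead",
                      bounds=[(0.0, 1.0)] * d, options=nm_opts)
        # a second simplex descent from the raw start point: the DE
        # population can be captured by broad shallow attractors while a
        # direct simplex walk follows narrow curved valleys to deep optima
        nm2 = minimize(f, starts[i], method="Nelder-Mead",
                       bounds=[(0.0, 1.0)] * d, options=nm_opts)
        cand = [(float(de.fun), de.x), (float(nm.fun), nm.x),
                (float(nm2.fun), nm2.x)]
        loss, x_best = min(cand, key=lambda c: c[0])
        x_nat = ps.from_unit(x_best)
        for name, val in (fixed_params or {}).items():
            x_nat[ps.index(name)] = val
        theta, xi = _split_params(ps, x_nat, spec)
        results.append(FitResult(
            spec=spec, theta=theta, xi=xi, neg2loglik=loss,
            start_index=i, converged=bool(np.isfinite(loss)),
            n_obs_used=0,
        ))

    results.sort(key=lambda r: (not r.converged, r.neg2loglik))
    if not results[0].converged:
        raise RuntimeError(
            f"all {n_starts} starts failed to converge for {spec.to_code()}"
        )
    # attach data-usage diagnostics at the optimum
    best = results[0]
    _, diag = neg2loglik(
        spec, best.theta, best.xi, data, initial_conditions,
        states=states, sigma_min=sigma_min, return_diagnostics=True,
    )
    for r in results:
        r.n_obs_used = diag["n_obs_used"]
    best.n_floored = diag["n_floored"]
    return results
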