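"""Practical identifiability via profile likelihood, plus a numerical
local structural-identifiability check.

The profile of parameter ``psi_i`` is the log-likelihood re-maximized over
all remaining parameters at each fixed value of ``psi_i``,

    PL(psi_i) = max_{psi_j, j != i} l(Psi) .

The 95% confidence interval is the connected set around the MLE where
``PL >= l_max - chi2_1(0.95)/2`` (the standard likelihood-ratio threshold
on the log-likelihood scale, ~1.921).  A parameter whose interval reaches
the search-box boundary before crossing the threshold is reported as
practically non-identifiable (unbounded CI).

``local_identifiability_rank`` is a numerical *local* surrogate for a
global differential-algebra structural analysis: it stacks finite-
difference sensitivities of all observables at all output times with
respect to the structural parameters and checks the matrix rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .inference import FitResult, make_objective
from .model_core import ModelSpec
from .simulate import integrate

__all__ = [
    "ProfileResult",
    "profile_objective",
    "profile_parameter",
    "local_identifiability_rank",
]

# chi2_1(0.95)/2 on the log-likelihood scale
def _threshold(alpha: float) -> float:
    return 0.5 * chi2.ppf(alpha, df=1)


@dataclass
class ProfileResult:
    """Profile likelihood of one parameter with its confidence interval."""

    name: str
    grid: np.ndarray            # parameter values (natural units)
    profile: np.ndarray         # PL(psi) on the log-likelihood scale
    ci: tuple[float, float]     # possibly +-inf
    identifiable: bool
    mle_value: float
    loglik_max: float
    alpha: float = 0.95

    def to_dict(self) -> dict:
        lo, hi = self.ci
        return {
            "name": self.name,
            "ci": [None if not np.isfinite(lo) else float(lo),
                   None if not np.isfinite(hi) else float(hi)],
            "identifiable": bool(self.identifiable),
            "mle_value": float(self.mle_value),
            "alpha": self.alpha,
        }


def _inner_max(
    loss_fn, u_fixed_idx, u_fixed_val, u_start, d, maxfev
):
    """Maximize the log-likelihood over the free coordinates (unit cube)."""
    free = [j for j in range(d) if j != u_fixed_idx]

    def reduced(v):
        u = np.empty(d)
        u[free] = np.clip(v, 0.0, 1.0)
        u[u_fixed_idx] = u_fixed_val
        return loss_fn(u)

    if not free:  # 1-parameter model: nothing to optimize over
        return reduced(np.empty(0)), u_start
    v0 = u_start[free]
    res = minimize(
        reduced, v0, method="Nelder-Mead",
        bounds=[(0.0, 1.0)] * len(free),
        options={"maxfev": maxfev, "xatol": 1e-7, "fatol": 1e-9},
    )
    u_best = np.empty(d)
    u_best[free] = np.clip(res.x, 0.0, 1.0)
    u_best[u_fixed_idx] = u_fixed_val
    return float(res.fun), u_best


def profile_objective(
    loss_fn,
    u_mle: np.ndarray,
    index: int,
    grid_unit: np.ndarray,
    maxfev: int = 400,
    fail_tol: float = 0.2,
):
    """Profile a -2 log-likelihood over the unit cube along one coordinate.

    Returns (PL values on the log-likelihood scale, warm-started inner
    optima).  The inner optimizer is warm-started from the neighbouring
    grid point, sweeping outward from the MLE.
    """
    d = len(u_mle)
    pl = np.full(len(grid_unit), -np.inf)
    n_fail = 0
    order = np.argsort(np.abs(grid_unit - u_mle[index]))
    warm_right = u_mle.copy()
    warm_left = u_mle.copy()
    for idx in order:
        warm = warm_right if grid_unit[idx] >= u_mle[index] else warm_left
        loss, u_best = _inner_max(loss_fn, index, grid_unit[idx], warm, d, maxfev)
        if not np.isfinite(loss):
            n_fail += 1
            continue
        pl[idx] = -0.5 * loss
        if grid_unit[idx] >= u_mle[index]:
            warm_right = u_best
        else:
            warm_left = u_best
    if n_fail > fail_tol * len(grid_unit):
        raise RuntimeError(
            f"inner optimization failed on {n_fail}/{len(grid_unit)} grid points"
        )
    return pl


def _ci_from_profile(grid, pl, mle_val, llmax, thresh, at_box):
    """Connected threshold-crossing interval around the MLE.

    ``at_box`` = (left grid point is the box bound, right is the box
    bound).  Returns ((lo, hi), identifiable).
    """
    level = llmax - thresh
    i_mle = int(np.argmin(np.abs(grid - mle_val)))
    lo, hi = -np.inf, np.inf
    lo_found = hi_found = False
    for i in range(i_mle, 0, -1):  # walk left
        if pl[i - 1] < level <= pl[i]:
            # linear interpolation between grid points
            f = (pl[i] - level) / (pl[i] - pl[i - 1])
            lo = grid[i] + f * (grid[i - 1] - grid[i])
            lo_found = True
            break
        if pl[i - 1] < level:
            lo, lo_found = grid[i - 1], True
            break
    for i in range(i_mle, len(grid) - 1):  # walk right
        if pl[i + 1] < level <= pl[i]:
            f = (pl[i] - level) / (pl[i] - pl[i + 1])
            hi = grid[i] + f * (grid[i + 1] - grid[i])
            hi_found = True
            break
        if pl[i + 1] < level:
            hi, hi_found = grid[i + 1], True
            break
    if not lo_found and at_box[0]:
        lo = -np.inf
    if not hi_found and at_box[1]:
        hi = np.inf
    identifiable = np.isfinite(lo) and np.isfinite(hi)
    return (float(lo), float(hi)), identifiable


def profile_parameter(
    spec: ModelSpec,
    data,
    mle: FitResult,
    param: str,
    n_grid: int = 21,
    span: float = 1.0,
    alpha: float = 0.95,
    seed: int = 0,
    initial_conditions=None,
    maxfev: int = 400,
    states=None,
) -> ProfileResult:
    """Profile-likelihood CI for one parameter of a fitted model.

    ``n_grid`` points per side of the MLE; ``span`` is the half-width in
    decades for log-scale parameters (rates, nmax) — ratios scan their
    full [0, 1] box.  The grid extends adaptively toward the box bounds
    if the threshold is not crossed; a bound reached without a crossing
    gives an unbounded CI and ``identifiable = False``.
    """
    if not mle.converged:
        raise ValueError("profiling requires a converged MLE")
    from .inference import initial_conditions_from_day0

    if initial_conditions is None:
        initial_conditions = initial_conditions_from_day0(data, spec)
    ps, f = make_objective(spec, data, initial_conditions, states=states)
    if param not in ps.names:
        raise ValueError(f"unknown parameter {param!r} for {spec.to_code()}")
    idx = ps.index(param)
    x_mle = ps.vector_from_dict({**mle.theta, **mle.xi})
    u_mle = np.clip(ps.to_unit(x_mle), 0.0, 1.0)
    llmax = -0.5 * float(mle.neg2loglik)
    thresh = _threshold(alpha)

    lo_nat, hi_nat = ps.lower[idx], ps.upper[idx]
    if ps.log_mask[idx]:
        decades = np.log10(hi_nat) - np.log10(lo_nat)
        half = span / decades  # decades -> unit-cube width
    else:
        half = 0.5 if ps.kinds[idx] == "ratio" else span / 2.0
    u0 = u_mle[idx]
    left = np.linspace(max(0.0, u0 - half), u0, n_grid)
    right = np.linspace(u0, min(1.0, u0 + half), n_grid)[1:]
    grid_u = np.concatenate([left, right])

    level_reached = False
    for _ in range(4):  # adaptive extension toward the box bounds
        pl = profile_objective(f, u_mle, idx, grid_u, maxfev=maxfev)
        llmax_eff = max(llmax, float(np.max(pl)))
        level = llmax_eff - thresh
        left_ok = pl[0] < level or grid_u[0] <= 0.0
        right_ok = pl[-1] < level or grid_u[-1] >= 1.0
        if left_ok and right_ok:
            level_reached = True
            break
        ext = []
        if not left_ok:
            new_lo = max(0.0, grid_u[0] - half)
            ext.append(np.linspace(new_lo, grid_u[0], n_grid)[:-1])
        ext.append(grid_u)
        if not right_ok:
            new_hi = min(1.0, grid_u[-1] + half)
            ext.append(np.linspace(grid_u[-1], new_hi, n_grid)[1:])
        grid_u = np.concatenate(ext)
    if not level_reached:
        pl = profile_objective(f, u_mle, idx, grid_u, maxfev=maxfev)
        llmax_eff = max(llmax, float(np.max(pl)))

    grid_nat = np.array([ps.from_unit(_set(u_mle, idx, g))[idx] for g in grid_u])
    at_box = (grid_u[0] <= 1e-12, grid_u[-1] >= 1.0 - 1e-12)
    ci, identifiable = _ci_from_profile(
        grid_nat, pl, x_mle[idx], llmax_eff, thresh, at_box
    )
    return ProfileResult(
        name=param, grid=grid_nat, profile=pl, ci=ci,
        identifiable=identifiable, mle_value=float(x_mle[idx]),
        loglik_max=llmax_eff, alpha=alpha,
    )


def _set(u, i, v):
    out = u.copy()
    out[i] = v
    return out


def local_identifiability_rank(
    spec: ModelSpec,
    theta: dict[str, float],
    n0,
    times,
    params: list[str] | None = None,
    rel_step: float = 1e-5,
    rank_tol: float = 1e-8,
    observable_scales=None,
):
    """Numerical local identifiability at ``theta``: rank of the stacked
    output-sensitivity matrix.

    Central finite differences of every observable at every output time
    with respect to each structural parameter, stacked into a
    (n_times*n_states, n_params) matrix; columns are scaled by the
    parameter magnitude (relative sensitivities) so the rank is invariant
    to units.  Full rank means the parameters are locally distinguishable
    from noiseless observations at this point.  ``params`` may repeat a
    name to probe an artificially duplicated parameter.

    Returns (rank, full_rank_flag, singular_values).
    """
    if params is None:
        params = list(spec.struct_param_names)
    times = np.asarray(times, dtype=float)
    base = integrate(spec, theta, n0, times).means
    if np.allclose(base, 0.0):
        raise ValueError("degenerate all-zero trajectory; rank undefined")
    if observable_scales is None:
        scales = np.ones(len(spec.states))
    else:
        scales = np.asarray(observable_scales, dtype=float)
        if np.any(scales <= 0):
            raise ValueError("observable scales must be positive")
    cols = []
    for name in params:
        v = float(theta[name])
        h = rel_step * max(abs(v), 1e-8)
        th_hi = dict(theta, **{name: v + h})
        th_lo = dict(theta, **{name: v - h})
        hi = integrate(spec, th_hi, n0, times).means
        lo = integrate(spec, th_lo, n0, times).means
        sens = (hi - lo) / (2.0 * h) * max(abs(v), 1e-8)
        cols.append((sens * scales[None, :]).ravel())
    s_mat = np.column_stack(cols)
    sv = np.linalg.svd(s_mat, compute_uv=False)
    rank = int(np.sum(sv > rank_tol * sv[0]))
    return rank, rank == len(params), sv
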