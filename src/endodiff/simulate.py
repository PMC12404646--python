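"""Forward simulation of the population models and noisy observation.

`integrate` solves the ODE with `scipy.integrate.solve_ivp` (adaptive
explicit Runge-Kutta; the systems are non-stiff at the parameter scales of
interest) at rtol 1e-8 / atol 1e-10, returning a `Trajectory` of state
means and, when error parameters are given, model standard deviations.

`observe` draws synthetic measurements from a trajectory, either through
the fitted heteroscedastic error model (``z = g + eps * eta``,
``eta ~ N(0, I)``) or through the design-study noise
(``N = n * (1 + eps_level * eta)``) used for sampling-period selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _fast
from .model_core import Growth, ModelSpec, error_sd, rhs

__all__ = ["Trajectory", "integrate", "observe", "pack_theta", "fast_integrate"]

RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10


class IntegrationError(RuntimeError):
    """The ODE solver failed (typically blow-up under extreme parameters)."""


@dataclass
class Trajectory:
    """Dense model solution: state means and optional model sds over time."""

    times: np.ndarray                  # days, strictly increasing
    means: np.ndarray                  # (n_times, n_states), cells/mm^2
    spec: ModelSpec
    theta: dict[str, float]
    sds: np.ndarray | None = None      # (n_times, n_states) or None
    xi: dict[str, float] | None = None

    @property
    def states(self) -> tuple[str, ...]:
        return self.spec.states

    def state(self, name: str) -> np.ndarray:
        return self.means[:, self.states.index(name)]

    def at_time(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.means[idx]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export with columns time_d, state, mean, sd."""
        rows = []
        for j, s in enumerate(self.states):
            sd = self.sds[:, j] if self.sds is not None else np.nan
            rows.append(pd.DataFrame({
                "time_d": self.times, "state": s,
                "mean": self.means[:, j], "sd": sd,
            }))
        return pd.concat(rows, ignore_index=True)


def pack_theta(spec: ModelSpec, theta: dict[str, float]):
    """Encode (spec, theta) for the compiled kernels.

    Returns (lineage_id, growth_id, struct array without nmax, nmax).
    """
    lin = _fast.LINEAGE_ID[spec.lineage.value]
    gro = _fast.GROWTH_ID[spec.growth.value]
    names = [n for n in spec.struct_param_names if n != "nmax"]
    th = np.array([float(theta[n]) for n in names])
    nmax = float(theta.get("nmax", 1.0))
    if spec.growth is not Growth.EXPONENTIAL and not nmax > 0:
        raise ValueError("nmax > 0 required for logistic/gompertz growth")
    return lin, gro, th, nmax


def _validate_times_y0(spec: ModelSpec, n0, times) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("times must be a 1-D array with at least 2 entries")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must start at t >= 0 and be strictly increasing")
    if isinstance(n0, dict):
        y0 = np.array([float(n0[s]) for s in spec.states])
    else:
        y0 = np.asarray(n0, dtype=float)
    if y0.shape != (len(spec.states),):
        raise ValueError(
            f"initial state needs {len(spec.states)} entries for {spec.to_code()}"
        )
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")
    return times, y0


def integrate(
    spec: ModelSpec,
    theta: dict[str, float],
    n0,
    times,
    xi: dict[str, float] | None = None,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    sigma_min: float = 0.0,
) -> Trajectory:
    """Solve the model ODE and evaluate it on ``times``.

    ``n0`` is the state at ``times[0]`` (dict keyed by state name or array
    in ``spec.states`` order).  When ``xi`` is given the trajectory also
    carries the error-model standard deviations.
    """
    times, y0 = _validate_times_y0(spec, n0, times)
    sol = solve_ivp(
        lambda t, y: rhs(spec, y, theta),
        (times[0], times[-1]),
        y0,
        method="RK45",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed for {spec.to_code()}: {sol.message}"
        )
    means = np.maximum(sol.y.T, 0.0)
    if not np.all(np.isfinite(means)):
        raise IntegrationError(f"non-finite trajectory for {spec.to_code()}")
    sds = None
    if xi is not None:
        sds = error_sd(means, xi, spec.error, sigma_min=sigma_min, strict=False)
    return Trajectory(times=times, means=means, spec=spec, theta=dict(theta),
                      sds=sds, xi=dict(xi) if xi else None)


def fast_integrate(
    spec: ModelSpec,
    theta: dict[str, float],
    n0,
    times,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> np.ndarray:
    """Compiled-route trajectory means (used in optimization/scan loops)."""
    times, y0 = _validate_times_y0(spec, n0, times)
    lin, gro, th, nmax = pack_theta(spec, theta)
    out, status = _fast.integrate_grid(lin, gro, th, nmax, y0, times, rtol, atol)
    if status != _fast.OK:
        raise IntegrationError(
            f"compiled integration failed for {spec.to_code()} (status {status})"
        )
    return out


def observe(
    traj: Trajectory,
    seed: int,
    mode: str = "error_model",
    eps_level: float | None = None,
    replicate_id: str = "r1",
    times=None,
) -> pd.DataFrame:
    """Draw one replicate's noisy observations from a trajectory.

    mode="error_model": ``z = g + sd * eta`` with the trajectory's attached
    error-model sds.  mode="design_noise": ``N = n (1 + eps_level * eta)``.
    Negative draws are clipped to 0 (counts are physically nonnegative).
    Identical (traj, seed) gives identical output.
    """
    if mode not in ("error_model", "design_noise"):
        raise ValueError(f"unknown observation mode {mode!r}")
    if mode == "error_model" and traj.sds is None:
        raise ValueError("trajectory has no sds; integrate with xi to attach them")
    if mode == "design_noise" and eps_level is None:
        raise ValueError("design_noise mode requires eps_level")

    if times is None:
        idx = np.arange(len(traj.times))
    else:
        times = np.asarray(times, dtype=float)
        idx = np.array([int(np.argmin(np.abs(traj.times - t))) for t in times])
        if not np.allclose(traj.times[idx], times, atol=1e-9):
            raise ValueError("requested observation times not on the trajectory grid")

    rng = np.random.default_rng(seed)
    t_sel = traj.times[idx]
    g = traj.means[idx]
    eta = rng.standard_normal(g.shape)
    if mode == "error_model":
        z = g + traj.sds[idx] * eta
    else:
        z = g * (1.0 + eps_level * eta)
    z = np.maximum(z, 0.0)

    frames = []
    for j, s in enumerate(traj.states):
        frames.append(pd.DataFrame({
            "replicate_id": replicate_id,
            "time_d": t_sel,
            "state": s,
            "value": z[:, j],
            "split": "none",
        }))
    return pd.concat(frames, ignore_index=True)
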