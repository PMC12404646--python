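"""Variance-based global sensitivity analysis of model outputs.

First-order Sobol indices S1 measure the share of output variance
explained by each structural parameter alone; total-order indices ST add
all interactions involving it.  Parameters are sampled uniformly over a
box (by default the 95% confidence box of the reference fit, with
non-physical negative rate bounds clipped to 0), the model is integrated
per sample, and indices are estimated per (parameter, output, time) with
Saltelli-type estimators over Sobol' quasirandom sample matrices
(`scipy.stats.sobol_indices`).

``n_samples`` counts total model evaluations; the base sample size is the
largest power of two with ``n_base * (d + 2) <= n_samples``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _fast
from .model_core import REFERENCE_CI, ModelSpec

__all__ = ["SobolResult", "sobol_indices", "reference_bounds"]


def reference_bounds(params=None) -> dict[str, tuple[float, float]]:
    """Structural-parameter sampling box from the reference fit's CIs.

    Negative lower bounds (the DE proliferation rate CI dips below zero)
    are clipped to 0: rates are non-negative physical quantities.
    """
    if params is None:
        params = ("beta_s", "p_sd", "delta_s", "beta_d", "delta_d", "nmax")
    return {p: (max(0.0, REFERENCE_CI[p][0]), REFERENCE_CI[p][1]) for p in params}


@dataclass
class SobolResult:
    """First/total-order Sobol indices per (parameter, output, time)."""

    params: tuple[str, ...]
    outputs: tuple[str, ...]
    times: np.ndarray
    s1: np.ndarray            # (n_params, n_outputs, n_times)
    st: np.ndarray            # (n_params, n_outputs, n_times)
    n_base: int
    n_evals: int
    n_failed: int
    bounds: dict[str, tuple[float, float]]

    def index(self, param: str, output: str, kind: str = "s1") -> np.ndarray:
        arr = self.s1 if kind == "s1" else self.st
        return arr[self.params.index(param), self.outputs.index(output)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.params):
            for j, o in enumerate(self.outputs):
                rows.append(pd.DataFrame({
                    "parameter": p, "output": o, "time_d": self.times,
                    "s1": self.s1[i, j], "st": self.st[i, j],
                }))
        return pd.concat(rows, ignore_index=True)


def sobol_indices(
    spec: ModelSpec,
    bounds: dict[str, tuple[float, float]],
    n0,
    outputs,
    times,
    n_samples: int = 40_000,
    seed: int = 0,
    theta_base: dict[str, float] | None = None,
    max_fail_frac: float = 0.01,
) -> SobolResult:
    """Estimate S1/ST of ``outputs`` at ``times`` w.r.t. the parameters in
    ``bounds``; remaining parameters stay frozen at ``theta_base``.

    Deterministic under ``seed``.  Samples whose integration fails are
    counted and mean-imputed; more than ``max_fail_frac`` of them raises.
    Outputs with zero variance (e.g. a state at its fixed initial value)
    yield NaN indices.
    """
    if not bounds:
        raise ValueError("bounds must name at least one parameter")
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    theta_base = dict(theta_base or {})
    params = tuple(n for n in spec.param_names if n in bounds)
    if len(params) != len(bounds):
        unknown = set(bounds) - set(params)
        raise ValueError(f"unknown parameters in bounds: {sorted(unknown)}")
    d = len(params)
    outputs = tuple(outputs)
    out_idx = np.array([spec.states.index(o) for o in outputs])
    times = np.asarray(times, dtype=float)
    if isinstance(n0, dict):
        y0 = np.array([float(n0[s]) for s in spec.states])
    else:
        y0 = np.asarray(n0, dtype=float)
    t_grid = np.concatenate(([0.0], times)) if times[0] > 0 else times

    n_base = 1
    while n_base * 2 * (d + 2) <= n_samples:
        n_base *= 2
    n_evals = n_base * (d + 2)

    lin = _fast.LINEAGE_ID[spec.lineage.value]
    gro = _fast.GROWTH_ID[spec.growth.value]
    struct_names = [n for n in spec.struct_param_names if n != "nmax"]
    n_failed = 0

    def func(x: np.ndarray) -> np.ndarray:
        nonlocal n_failed
        n = x.shape[1]
        out = np.empty((len(outputs) * len(times), n))
        failed = []
        for i in range(n):
            th_full = dict(theta_base)
            for j, p in enumerate(params):
                th_full[p] = x[j, i]
            th = np.array([th_full[nm] for nm in struct_names])
            nmax = float(th_full.get("nmax", 1.0))
            traj, status = _fast.integrate_grid(
                lin, gro, th, nmax, y0, t_grid, 1e-8, 1e-10
            )
            if status != _fast.OK:
                failed.append(i)
                out[:, i] = np.nan
                continue
            sel = traj[-len(times):, :][:, out_idx]  # (n_times, n_out)
            out[:, i] = sel.T.ravel()
        n_failed += len(failed)
        if failed:
            col_mean = np.nanmean(out, axis=1)
            for i in failed:
                out[:, i] = col_mean
        return out

    dists = [
        stats.uniform(loc=bounds[p][0], scale=bounds[p][1] - bounds[p][0])
        for p in params
    ]
    res = stats.sobol_indices(
        func=func, n=n_base, dists=dists,
        rng=np.random.default_rng(seed),
    )
    if n_failed > max_fail_frac * n_evals:
        raise RuntimeError(
            f"integration failed on {n_failed}/{n_evals} Sobol samples"
        )
    shape = (len(outputs), len(times), d)
    s1 = np.moveaxis(res.first_order.reshape(shape), 2, 0)
    st = np.moveaxis(res.total_order.reshape(shape), 2, 0)
    return SobolResult(
        params=params, outputs=outputs, times=times,
        s1=s1, st=st, n_base=n_base, n_evals=n_evals,
        n_failed=n_failed, bounds=dict(bounds),
    )
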