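"""Stratified data splitting, BIC over common states, and model ranking.

Candidate lineages observe different state sets (M2/M3 add transition
populations), so raw training losses are not comparable across models.
Ranking therefore evaluates every fitted candidate through the loss over
common states (LOCS) — the likelihood restricted to the observables all
lineages share (live iPSC, live DE, cumulative dead) — on a held-out
selection subset, and converts it to the Bayesian information criterion

    BIC = k * ln(m_s) - 2 * l ,

with ``k`` the number of fitted parameters (structural + error), ``m_s``
the number of selection observations over common states, and
``l = -LOCS/2`` the log-likelihood up to the Gaussian constant (which
cancels in rankings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult, locs
from .model_core import COMMON_STATES

__all__ = ["stratified_split", "bic", "rank_models", "selection_count"]


def stratified_split(
    data: pd.DataFrame,
    seed: int,
    counts: tuple[int, int, int] = (3, 1, 1),
) -> pd.DataFrame:
    """Tag each post-day-0 time point train/select/test, per replicate.

    All states sharing a (replicate, time point) get the same tag, which
    prevents leakage between observables of the same day and spreads
    replicate-level systematic noise across the subsets.  Day-0 rows keep
    the tag ``none`` (they serve as initial conditions, not likelihood
    terms).  Deterministic under ``seed``.
    """
    n_train, n_select, n_test = counts
    need = n_train + n_select + n_test
    out = data.copy()
    out["split"] = "none"
    rng = np.random.default_rng(seed)
    for rep in sorted(out["replicate_id"].unique()):
        mask = (out["replicate_id"] == rep) & (out["time_d"] > 0.0)
        times = np.sort(out.loc[mask, "time_d"].unique())
        if len(times) < need:
            raise ValueError(
                f"replicate {rep!r} has {len(times)} post-day-0 time points; "
                f"need >= {need} for a {counts} split"
            )
        perm = rng.permutation(times)
        tags = {}
        for t in perm[:n_train]:
            tags[t] = "train"
        for t in perm[n_train:n_train + n_select]:
            tags[t] = "select"
        for t in perm[n_train + n_select:need]:
            tags[t] = "test"
        for t in perm[need:]:
            tags[t] = "train"
        out.loc[mask, "split"] = out.loc[mask, "time_d"].map(tags)
    return out


def bic(loglik: float, k: int, m_s: int) -> float:
    """Bayesian information criterion, k*ln(m_s) - 2*loglik."""
    if m_s < 1:
        raise ValueError("m_s must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * math.log(m_s) - 2.0 * loglik


def selection_count(data: pd.DataFrame) -> int:
    """Number of selection-set records over common states (the BIC m_s)."""
    sel = data[(data["split"] == "select") & (data["state"].isin(COMMON_STATES))]
    return len(sel)


@dataclass
class ModelRanking:
    """Ascending-BIC table over candidate models."""

    table: pd.DataFrame  # columns: spec, k, loss_select, bic, rank, converged
    m_s: int

    def top(self) -> str:
        return str(self.table.iloc[0]["spec"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def rank_models(
    fits: dict[str, FitResult] | list[FitResult],
    data_select: pd.DataFrame,
    initial_conditions: dict[str, dict[str, float]],
) -> ModelRanking:
    """Rank one best fit per candidate by BIC over common states.

    ``data_select`` must carry split tags; only rows tagged ``select`` over
    the common states enter the loss and the count ``m_s``.  Candidates
    whose fit failed rank last and are flagged.  Ties break by model code.
    """
    if isinstance(fits, list):
        fits = {f.spec.to_code(): f for f in fits}
    sel = data_select[data_select["split"] == "select"]
    if sel.empty:
        raise ValueError("no rows tagged 'select' in data_select")
    m_s = selection_count(data_select)

    rows = []
    for code in sorted(fits):
        f = fits[code]
        spec = f.spec
        if f.converged and np.isfinite(f.neg2loglik):
            # keep day-0 rows so initial conditions resolve, but only
            # select-tagged post-day-0 rows enter the sums
            keep = (data_select["split"] == "select") | (data_select["time_d"] == 0.0)
            try:
                loss_sel = locs(
                    f.theta, f.xi, data_select[keep], spec, initial_conditions
                )
                ll = -0.5 * loss_sel
                b = bic(ll, spec.k, m_s)
                ok = True
            except Exception:
                # evaluation blew up at this parameter point: flag, rank last
                loss_sel, b, ok = np.inf, np.inf, False
        else:
            loss_sel, b, ok = np.inf, np.inf, False
        rows.append({
            "spec": code, "k": spec.k, "loss_select": loss_sel,
            "bic": b, "converged": ok,
        })
    table = pd.DataFrame(rows).sort_values(
        ["bic", "spec"], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ModelRanking(table=table, m_s=m_s)
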