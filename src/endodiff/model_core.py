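"""Core definitions of the 27-member model family.

Directed differentiation of induced pluripotent stem cells (iPSCs) into
definitive endoderm (DE) is modelled as a small compartmental ODE system.
A concrete model is the combination of three orthogonal choices:

* a **lineage** — how many discrete cell states sit between iPSC and DE:

  - ``M1``: iPSC (``ns``) differentiates directly into DE (``nd``);
  - ``M2``: one intermediate "transition" population ``nt`` expressing
    exactly one of the two DE surface markers (CD117/CD184);
  - ``M3``: two parallel single-positive transition populations ``nt1``
    (CD117+/CD184-) and ``nt2`` (CD184+/CD117-);

  every lineage additionally tracks the cumulative dead-cell pool ``nq``;

* a **growth law** — the per-capita growth factor ``f(n)``: exponential
  (``f = 1``), logistic (``f = 1 - n/nmax``) or Gompertz
  (``f = ln(nmax/n)``);

* an **error model** — how the measurement standard deviation depends on
  the predicted mean ``g``: additive (``sd = a``), proportional
  (``sd = b*g``) or combined (``sd = a + b*g``).

3 x 3 x 3 = 27 candidate models.  Cell divisions are symmetric: a dividing
cell of state ``j`` produces two daughters that stay in ``j`` with
probability ``p`` (self-renewal) or both advance to the next state with
probability ``1 - p``, which makes the per-capita differentiation rate
``2(1-p) * b_j(n_j)``.  Death is first-order with constant per-capita rate
``delta_j`` and feeds the (monotone) dead pool.

All densities are in cells/mm^2 and all rates in 1/day.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Lineage",
    "Growth",
    "ErrorModel",
    "ModelSpec",
    "ParameterSpace",
    "growth_rate",
    "rhs",
    "error_sd",
    "parameter_space",
    "cells_per_well_to_density",
    "density_to_cells_per_well",
    "DEFAULT_WELL_AREA_MM2",
    "NMAX_UPPER_DEFAULT",
    "REFERENCE_PARAMS",
    "REFERENCE_CI",
    "COMMON_STATES",
]

# Growth area of one well of a standard 12-well plate, mm^2.
DEFAULT_WELL_AREA_MM2 = 380.0

# Upper bound on the carrying capacity: a confluent monolayer of circular
# 15-um cells, 1e6 um^2/mm^2 / (pi * 7.5^2 um^2) ~= 5658.8 cells/mm^2.
NMAX_UPPER_DEFAULT = 1e6 / (math.pi * 7.5**2)

# Positive floor applied to n inside the Gompertz log (the ODE term
# n*ln(nmax/n) -> 0 as n -> 0 but the naive expression overflows).
_GOMPERTZ_FLOOR = 1e-12

COMMON_STATES = ("ns", "nd", "nq")


class Lineage(str, enum.Enum):
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"


class Growth(str, enum.Enum):
    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"


class ErrorModel(str, enum.Enum):
    ADDITIVE = "additive"
    PROPORTIONAL = "proportional"
    COMBINED = "combined"


_STATES = {
    Lineage.M1: ("ns", "nd", "nq"),
    Lineage.M2: ("ns", "nt", "nd", "nq"),
    Lineage.M3: ("ns", "nt1", "nt2", "nd", "nq"),
}

# Structural parameter names per lineage (order is the canonical vector
# order used everywhere: optimizers, profiles, sensitivity analysis).
_STRUCT_PARAMS = {
    Lineage.M1: ("beta_s", "p_sd", "delta_s", "beta_d", "delta_d"),
    Lineage.M2: (
        "beta_s", "p_st", "delta_s",
        "beta_t", "p_td", "delta_t",
        "beta_d", "delta_d",
    ),
    Lineage.M3: (
        "beta_s", "p_st", "p_t1", "delta_s",
        "beta_t1", "p_t1d", "delta_t1",
        "beta_t2", "p_t2d", "delta_t2",
        "beta_d", "delta_d",
    ),
}

_ERROR_PARAMS = {
    ErrorModel.ADDITIVE: ("a",),
    ErrorModel.PROPORTIONAL: ("b",),
    ErrorModel.COMBINED: ("a", "b"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One member of the 27-model family: lineage x growth x error."""

    lineage: Lineage
    growth: Growth
    error: ErrorModel

    def __post_init__(self) -> None:
        object.__setattr__(self, "lineage", Lineage(self.lineage))
        object.__setattr__(self, "growth", Growth(self.growth))
        object.__setattr__(self, "error", ErrorModel(self.error))

    # -- inventories -----------------------------------------------------
    @property
    def states(self) -> tuple[str, ...]:
        return _STATES[self.lineage]

    @property
    def live_states(self) -> tuple[str, ...]:
        return self.states[:-1]

    @property
    def struct_param_names(self) -> tuple[str, ...]:
        names = _STRUCT_PARAMS[self.lineage]
        if self.growth is not Growth.EXPONENTIAL:
            names = names + ("nmax",)
        return names

    @property
    def error_param_names(self) -> tuple[str, ...]:
        return _ERROR_PARAMS[self.error]

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.struct_param_names + self.error_param_names

    @property
    def k_struct(self) -> int:
        return len(self.struct_param_names)

    @property
    def k_error(self) -> int:
        return len(self.error_param_names)

    @property
    def k(self) -> int:
        return self.k_struct + self.k_error

    # -- serialization ---------------------------------------------------
    def to_code(self) -> str:
        return f"{self.lineage.value}-{self.growth.value}-{self.error.value}"

    @classmethod
    def from_code(cls, code: str) -> "ModelSpec":
        try:
            lineage, growth, error = code.split("-")
            return cls(Lineage(lineage), Growth(growth), ErrorModel(error))
        except ValueError as exc:
            raise ValueError(
                f"invalid model code {code!r}; expected "
                "'<M1|M2|M3>-<exponential|logistic|gompertz>-"
                "<additive|proportional|combined>'"
            ) from exc

    @classmethod
    def all_specs(cls) -> list["ModelSpec"]:
        """The full 27-model registry, in lexicographic code order."""
        specs = [
            cls(lin, gro, err)
            for lin in Lineage
            for gro in Growth
            for err in ErrorModel
        ]
        return sorted(specs, key=lambda s: s.to_code())

    def __str__(self) -> str:  # pragma: no cover
        return self.to_code()


# ---------------------------------------------------------------------------
# Reference parameter set: maximum-likelihood estimates (with 95% profile
# confidence intervals) for the Gompertz M1 model with combined error,
# inferred from the in vitro study this package models.  Used as the
# default generating values of the synthetic-study module and as the
# nominal point for sensitivity/scenario analyses.
# ---------------------------------------------------------------------------
REFERENCE_PARAMS: dict[str, float] = {
    "beta_s": 10.119,    # 1/day, iPSC max proliferation rate
    "p_sd": 0.49823,     # self-renewal probability of dividing iPSCs
    "delta_s": 0.52186,  # 1/day, iPSC death rate
    "beta_d": 0.1881,    # 1/day, DE max proliferation rate
    "delta_d": 0.47299,  # 1/day, DE death rate
    "nmax": 718.57,      # cells/mm^2, carrying capacity
    "a": 116.54,         # cells/mm^2, additive error floor
    "b": 0.34287,        # proportional error coefficient
}

REFERENCE_CI: dict[str, tuple[float, float]] = {
    "beta_s": (5.1404, 19.085),
    "p_sd": (0.48376, 0.51249),
    "delta_s": (0.0033041, 1.2024),
    "beta_d": (-0.095345, 0.79051),
    "delta_d": (0.36077, 0.6344),
    "nmax": (394.64, 1978.7),
    "a": (88.265, 155.68),
    "b": (0.2683, 0.45133),
}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------
def growth_rate(n, growth: Growth | str, nmax: float | None = None):
    """Per-capita growth factor f(n) for one population.

    The caller multiplies by ``n``; for Gompertz the product
    ``n * ln(nmax/n)`` tends to 0 as ``n -> 0``, which is preserved here by
    flooring ``n`` at a tiny positive value inside the log.
    """
    growth = Growth(growth)
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("population density n must be nonnegative")
    if growth is Growth.EXPONENTIAL:
        return np.ones_like(n) if n.shape else 1.0
    if nmax is None or not nmax > 0:
        raise ValueError(f"{growth.value} growth requires nmax > 0")
    if growth is Growth.LOGISTIC:
        out = 1.0 - n / nmax
    else:  # Gompertz
        out = np.log(nmax / np.maximum(n, _GOMPERTZ_FLOOR))
    return float(out) if out.shape == () else out


def _f(growth: Growth, n: float, nmax: float) -> float:
    # internal scalar growth factor; n already clipped to >= 0
    if growth is Growth.EXPONENTIAL:
        return 1.0
    if growth is Growth.LOGISTIC:
        return 1.0 - n / nmax
    # log difference keeps a runaway integrator step (n -> inf) IEEE-finite
    # in sign (-inf growth), so the solver rejects it instead of crashing
    return math.log(nmax) - math.log(max(n, _GOMPERTZ_FLOOR))


def _project(y_raw: np.ndarray, d: np.ndarray) -> np.ndarray:
    # nonnegativity projection: a depleted state cannot keep draining.
    # Above carrying capacity the symmetric-division transfer rate turns
    # negative, which would otherwise push an empty compartment below zero
    # and make trajectories depend on integrator restarts.
    d[(y_raw <= 0.0) & (d < 0.0)] = 0.0
    return d


def rhs(spec: ModelSpec, state, theta: dict[str, float]) -> np.ndarray:
    """Time derivative of the state vector (cells/mm^2/day).

    ``state`` follows ``spec.states`` order; tiny negative entries produced
    by an integrator step are clipped to 0 before evaluating the rates, so
    the dead pool derivative is always nonnegative on valid input.
    """
    y_raw = np.asarray(state, dtype=float)
    y = np.maximum(y_raw, 0.0)
    if y.shape != (len(spec.states),):
        raise ValueError(
            f"state must have {len(spec.states)} entries for {spec.to_code()}"
        )
    g = spec.growth
    nmax = theta.get("nmax", 0.0)
    if g is not Growth.EXPONENTIAL and not nmax > 0:
        raise ValueError("nmax > 0 required for logistic/gompertz growth")

    if spec.lineage is Lineage.M1:
        ns, nd, _ = y
        bs = theta["beta_s"] * _f(g, ns, nmax)
        bd = theta["beta_d"] * _f(g, nd, nmax)
        psd = 2.0 * (1.0 - theta["p_sd"]) * bs
        dns = bs * ns - theta["delta_s"] * ns - psd * ns
        dnd = bd * nd - theta["delta_d"] * nd + psd * ns
        dnq = theta["delta_s"] * ns + theta["delta_d"] * nd
        return _project(y_raw, np.array([dns, dnd, dnq]))

    if spec.lineage is Lineage.M2:
        ns, nt, nd, _ = y
        bs = theta["beta_s"] * _f(g, ns, nmax)
        bt = theta["beta_t"] * _f(g, nt, nmax)
        bd = theta["beta_d"] * _f(g, nd, nmax)
        pst = 2.0 * (1.0 - theta["p_st"]) * bs
        ptd = 2.0 * (1.0 - theta["p_td"]) * bt
        dns = bs * ns - theta["delta_s"] * ns - pst * ns
        dnt = bt * nt - theta["delta_t"] * nt + pst * ns - ptd * nt
        dnd = bd * nd - theta["delta_d"] * nd + ptd * nt
        dnq = (
            theta["delta_s"] * ns + theta["delta_t"] * nt
            + theta["delta_d"] * nd
        )
        return _project(y_raw, np.array([dns, dnt, dnd, dnq]))

    ns, nt1, nt2, nd, _ = y
    bs = theta["beta_s"] * _f(g, ns, nmax)
    bt1 = theta["beta_t1"] * _f(g, nt1, nmax)
    bt2 = theta["beta_t2"] * _f(g, nt2, nmax)
    bd = theta["beta_d"] * _f(g, nd, nmax)
    pst1 = 2.0 * (1.0 - theta["p_st"]) * theta["p_t1"] * bs
    pst2 = 2.0 * (1.0 - theta["p_st"]) * (1.0 - theta["p_t1"]) * bs
    pt1d = 2.0 * (1.0 - theta["p_t1d"]) * bt1
    pt2d = 2.0 * (1.0 - theta["p_t2d"]) * bt2
    dns = bs * ns - theta["delta_s"] * ns - pst1 * ns - pst2 * ns
    dnt1 = bt1 * nt1 - theta["delta_t1"] * nt1 + pst1 * ns - pt1d * nt1
    dnt2 = bt2 * nt2 - theta["delta_t2"] * nt2 + pst2 * ns - pt2d * nt2
    dnd = bd * nd - theta["delta_d"] * nd + pt1d * nt1 + pt2d * nt2
    dnq = (
        theta["delta_s"] * ns + theta["delta_t1"] * nt1
        + theta["delta_t2"] * nt2 + theta["delta_d"] * nd
    )
    return _project(y_raw, np.array([dns, dnt1, dnt2, dnd, dnq]))


def error_sd(
    mean,
    xi: dict[str, float],
    error: ErrorModel | str,
    sigma_min: float = 0.0,
    strict: bool = True,
):
    """Measurement standard deviation per observable (cells/mm^2).

    additive: ``a``; proportional: ``b*g``; combined: ``a + b*g``, applied
    elementwise to the predicted means ``g``.  If ``sigma_min > 0`` the
    result is floored at it; otherwise a nonpositive sd raises unless
    ``strict=False`` (simulation of a degenerate noise-free model is
    legitimate; a zero sd in a likelihood is not).
    """
    error = ErrorModel(error)
    g = np.asarray(mean, dtype=float)
    if np.any(g < 0):
        raise ValueError("mean values must be nonnegative")
    if error is ErrorModel.ADDITIVE:
        sd = np.full_like(g, float(xi["a"]))
    elif error is ErrorModel.PROPORTIONAL:
        sd = float(xi["b"]) * g
    else:
        sd = float(xi["a"]) + float(xi["b"]) * g
    if sigma_min > 0:
        sd = np.maximum(sd, sigma_min)
    elif strict and np.any(sd <= 0):
        raise ValueError(
            "error model yields nonpositive sd; set sigma_min > 0 to floor it"
        )
    return float(sd) if sd.shape == () else sd


# ---------------------------------------------------------------------------
# Parameter search space
# ---------------------------------------------------------------------------
_KIND_RATE = "rate"       # 1/day, searched in log10 over [1e-4, 1e2]
_KIND_RATIO = "ratio"     # dimensionless in [0, 1], linear
_KIND_NMAX = "nmax"       # cells/mm^2 in [ub/25, ub], searched in log10
_KIND_ERR_A = "err_a"     # cells/mm^2 in [0, ub], linear
_KIND_ERR_B = "err_b"     # dimensionless in [0, 10], linear

_LOG_KINDS = (_KIND_RATE, _KIND_NMAX)


def _param_kind(name: str) -> str:
    if name == "nmax":
        return _KIND_NMAX
    if name == "a":
        return _KIND_ERR_A
    if name == "b":
        return _KIND_ERR_B
    if name.startswith("p_"):
        return _KIND_RATIO
    return _KIND_RATE


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered box search space with a unit-cube transform.

    Rates and ``nmax`` span several decades and are mapped to the unit cube
    through log10; ratios and error parameters linearly.  Optimizers and
    profile scans work in the unit cube throughout.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    kinds: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def log_mask(self) -> np.ndarray:
        return np.array([k in _LOG_KINDS for k in self.kinds])

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi, m = self.lower, self.upper, self.log_mask
        u = np.empty_like(x)
        u[~m] = (x[~m] - lo[~m]) / (hi[~m] - lo[~m])
        u[m] = (np.log10(x[m]) - np.log10(lo[m])) / (
            np.log10(hi[m]) - np.log10(lo[m])
        )
        return u

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        lo, hi, m = self.lower, self.upper, self.log_mask
        x = np.empty_like(u)
        x[~m] = lo[~m] + u[~m] * (hi[~m] - lo[~m])
        x[m] = 10.0 ** (
            np.log10(lo[m]) + u[m] * (np.log10(hi[m]) - np.log10(lo[m]))
        )
        return x

    def dict_from_vector(self, x: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(x, dtype=float)))

    def vector_from_dict(self, params: dict[str, float]) -> np.ndarray:
        return np.array([params[n] for n in self.names], dtype=float)


def parameter_space(
    spec: ModelSpec, nmax_upper: float = NMAX_UPPER_DEFAULT
) -> ParameterSpace:
    """Box bounds for all parameters of ``spec`` (structural then error)."""
    if not nmax_upper > 0:
        raise ValueError("nmax_upper must be positive")
    names, lower, upper, kinds = [], [], [], []
    for name in spec.param_names:
        kind = _param_kind(name)
        if kind == _KIND_RATE:
            lo, hi = 1e-4, 1e2
        elif kind == _KIND_RATIO:
            lo, hi = 0.0, 1.0
        elif kind == _KIND_NMAX:
            lo, hi = nmax_upper / 25.0, nmax_upper
        elif kind == _KIND_ERR_A:
            lo, hi = 0.0, nmax_upper
        else:
            lo, hi = 0.0, 10.0
        names.append(name)
        lower.append(lo)
        upper.append(hi)
        kinds.append(kind)
    return ParameterSpace(
        tuple(names), np.array(lower), np.array(upper), tuple(kinds)
    )


# ---------------------------------------------------------------------------
# Unit helpers
# ---------------------------------------------------------------------------
def cells_per_well_to_density(
    cells: float, well_area_mm2: float = DEFAULT_WELL_AREA_MM2
) -> float:
    """Convert a per-well cell count to a density in cells/mm^2."""
    if not well_area_mm2 > 0:
        raise ValueError("well area must be positive")
    return cells / well_area_mm2


def density_to_cells_per_well(
    density: float, well_area_mm2: float = DEFAULT_WELL_AREA_MM2
) -> float:
    """Convert a density in cells/mm^2 to a per-well cell count."""
    if not well_area_mm2 > 0:
        raise ValueError("well area must be positive")
    return density * well_area_mm2
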