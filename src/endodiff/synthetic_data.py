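"""Synthetic study generator emulating the in vitro measurement design.

The emulated experiment plates iPSCs at one of two densities (900 000 and
300 000 cells per well of a 12-well plate, 4 and 2 replicates), induces
definitive-endoderm differentiation, and harvests one well per replicate
per day for five days, counting live populations by CD117/CD184 flow-
cytometry gating plus the cumulative dead-cell count.

Generation per replicate:

1. the day-0 state is drawn from the affine plating map (plating
   efficiency ~50%, of which 10% already express both DE markers at
   day 0) with multiplicative Gaussian replicate scatter — this scattered
   state is what the day-0 record carries, since the inference pipeline
   anchors each replicate's trajectory to its day-0 values;
2. the generating model is integrated from that state;
3. days >= 1 are observed through the generating error model
   (``z = g + eps*eta``, clipped at 0).

Flow-gating misclassification is not modelled: observation noise enters
only through the error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiments import PlatingMap
from .model_core import (
    DEFAULT_WELL_AREA_MM2,
    REFERENCE_PARAMS,
    ModelSpec,
)
from .simulate import integrate, observe

__all__ = ["StudyConfig", "generate_study", "default_config"]

# Default affine plating map (density units): a quarter of the plated
# cells are attached at day 0, split 90/10 between the iPSC and DE gates,
# no offset.  The fraction is set so that every default day-0 density
# stays below the reference carrying capacity (nmax = 718.57 cells/mm^2);
# above it the saturating growth laws suppress differentiation and the
# model's qualitative protocol predictions (DE peak rising with plating
# density) no longer hold, so the real study's day-0 densities must also
# have been below capacity.
_ATTACHED_FRACTION = 0.25
_DE_FRACTION = 0.1


@dataclass
class StudyConfig:
    """Design of one synthetic study (defaults mirror the in vitro one)."""

    plating_levels: dict[float, int] = field(
        default_factory=lambda: {900_000.0: 4, 300_000.0: 2}
    )  # cells/well -> replicate count
    days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    spec: ModelSpec = field(
        default_factory=lambda: ModelSpec.from_code("M1-gompertz-combined")
    )
    theta: dict[str, float] = field(
        default_factory=lambda: {
            k: REFERENCE_PARAMS[k]
            for k in ("beta_s", "p_sd", "delta_s", "beta_d", "delta_d", "nmax")
        }
    )
    xi: dict[str, float] = field(
        default_factory=lambda: {
            "a": REFERENCE_PARAMS["a"], "b": REFERENCE_PARAMS["b"],
        }
    )
    plating_map: PlatingMap = field(
        default_factory=lambda: PlatingMap(
            beta1=_ATTACHED_FRACTION * (1 - _DE_FRACTION), beta01=0.0,
            beta2=_ATTACHED_FRACTION * _DE_FRACTION, beta02=0.0,
        )
    )
    day0_scatter: float = 0.10   # relative sd of the day-0 state draw
    well_area_mm2: float = DEFAULT_WELL_AREA_MM2
    observe_states: tuple[str, ...] | None = None  # default: all lineage states
    seed: int = 0

    def __post_init__(self):
        if not self.plating_levels:
            raise ValueError("at least one plating level required")
        if any(n < 1 for n in self.plating_levels.values()):
            raise ValueError("replicate counts must be >= 1")
        if 0.0 not in [float(d) for d in self.days]:
            raise ValueError("sampled days must include day 0")
        if self.observe_states is not None:
            bad = set(self.observe_states) - set(self.spec.states)
            if bad:
                raise ValueError(
                    f"states {sorted(bad)} are not part of lineage "
                    f"{self.spec.lineage.value}"
                )


def default_config(seed: int = 0, **overrides) -> StudyConfig:
    valid = StudyConfig.__dataclass_fields__
    unknown = set(overrides) - set(valid)
    if unknown:
        raise TypeError(f"unknown StudyConfig fields {sorted(unknown)}")
    return StudyConfig(seed=seed, **overrides)


def generate_study(config: StudyConfig) -> tuple[pd.DataFrame, dict]:
    """Generate one study; returns (observation table, ground truth).

    The ground truth carries the generating parameters and each
    replicate's exact day-0 state, for parameter-recovery tests.
    Deterministic under ``config.seed``.
    """
    spec = config.spec
    days = np.sort(np.asarray(config.days, dtype=float))
    live_extra = [s for s in spec.states if s not in ("ns", "nd", "nq")]
    rng = np.random.default_rng(config.seed)

    frames = []
    truth_ics: dict[str, dict[str, float]] = {}
    for level in sorted(config.plating_levels, reverse=True):
        n_rep = config.plating_levels[level]
        n_p = level / config.well_area_mm2
        mapped = config.plating_map.day0_state(n_p)
        for r in range(1, n_rep + 1):
            rep = f"w{int(level / 1000)}k-{r}"
            ic = {s: 0.0 for s in spec.states}
            for s in ("ns", "nd"):
                ic[s] = max(
                    mapped[s] * rng.normal(1.0, config.day0_scatter), 0.0
                )
            truth_ics[rep] = dict(ic)
            traj = integrate(spec, config.theta, ic, days, xi=config.xi)
            obs_seed = int(rng.integers(2**31 - 1))
            noisy = observe(
                traj, seed=obs_seed, mode="error_model",
                replicate_id=rep, times=days[days > 0],
            )
            day0 = pd.DataFrame({
                "replicate_id": rep, "time_d": 0.0,
                "state": list(spec.states),
                "value": [ic[s] for s in spec.states],
                "split": "none",
            })
            frames.append(pd.concat([day0, noisy], ignore_index=True))

    data = pd.concat(frames, ignore_index=True).reset_index(drop=True)
    if config.observe_states is not None:
        data = data[data["state"].isin(config.observe_states)]
        data = data.reset_index(drop=True)
    truth = {
        "spec": spec.to_code(),
        "theta": dict(config.theta),
        "xi": dict(config.xi),
        "day0_states": truth_ics,
        "seed": config.seed,
        "observed_states": list(spec.states),
        "transition_states": live_extra,
    }
    return data, truth
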