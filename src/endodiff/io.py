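"""File formats, run configuration and provenance.

The canonical observation format is a long-format CSV with header
``replicate_id,time_d,state,value[,split]``; one row per (replicate, time
point, observable).  Fits, rankings, profiles and ground truths travel as
JSON.  Every artifact written by the CLI embeds the model code, the seed
and the package version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_observations",
    "write_observations",
    "validate_observations",
    "write_json",
    "read_json",
    "RunConfig",
    "provenance",
]

_VALID_STATES = {"ns", "nt", "nt1", "nt2", "nd", "nq"}
_VALID_SPLITS = {"train", "select", "test", "none"}
_REQUIRED_COLS = ["replicate_id", "time_d", "state", "value"]


class ObservationFormatError(ValueError):
    """The observation table violates the long-format schema."""


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalize) a long-format observation table."""
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ObservationFormatError(f"missing columns: {missing}")
    out = df.copy()
    if "split" not in out.columns:
        out["split"] = "none"
    out["time_d"] = out["time_d"].astype(float)
    out["value"] = out["value"].astype(float)

    bad_state = ~out["state"].isin(_VALID_STATES)
    if bad_state.any():
        row = out.index[bad_state][0]
        raise ObservationFormatError(
            f"unknown state {out.loc[row, 'state']!r} at row {row}"
        )
    bad_split = ~out["split"].isin(_VALID_SPLITS)
    if bad_split.any():
        row = out.index[bad_split][0]
        raise ObservationFormatError(
            f"unknown split tag {out.loc[row, 'split']!r} at row {row}"
        )
    neg = out["value"] < 0
    if neg.any():
        row = out.index[neg][0]
        raise ObservationFormatError(
            f"negative value at row {row} (column 'value')"
        )
    if out["time_d"].lt(0).any():
        row = out.index[out["time_d"] < 0][0]
        raise ObservationFormatError(f"negative time at row {row}")
    dup = out.duplicated(subset=["replicate_id", "time_d", "state"])
    if dup.any():
        row = out.index[dup][0]
        key = out.loc[row, ["replicate_id", "time_d", "state"]].tolist()
        raise ObservationFormatError(f"duplicate record for {key} at row {row}")
    # all states of one (replicate, time) must share a split tag
    n_tags = out.groupby(["replicate_id", "time_d"])["split"].nunique()
    if (n_tags > 1).any():
        key = n_tags.index[(n_tags > 1).to_numpy()][0]
        raise ObservationFormatError(
            f"states at replicate/time {key} carry different split tags"
        )
    return out


def read_observations(path) -> pd.DataFrame:
    """Read and validate a long-format observation CSV."""
    df = pd.read_csv(path)
    return validate_observations(df)


def write_observations(df: pd.DataFrame, path) -> None:
    validate_observations(df).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------
_CONFIG_FIELDS = {
    "spec": str,
    "specs": list,
    "seed": int,
    "n_starts": int,
    "budget": int,
    "well_area_mm2": float,
    "split_counts": list,
    "out_dir": str,
    "data": str,
    "nmax_upper": float,
}


@dataclass
class RunConfig:
    """Validated key/value run configuration (YAML on disk)."""

    spec: str | None = None
    specs: list[str] | None = None
    seed: int = 0
    n_starts: int = 100
    budget: int = 100_000
    well_area_mm2: float = 380.0
    split_counts: tuple[int, int, int] = (3, 1, 1)
    out_dir: str = "."
    data: str | None = None
    nmax_upper: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("run config must be a YAML mapping")
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; "
                f"valid keys: {sorted(_CONFIG_FIELDS)}"
            )
        cfg = cls()
        for k, v in raw.items():
            if k == "split_counts":
                v = tuple(int(x) for x in v)
                if len(v) != 3:
                    raise ValueError("split_counts must have 3 entries")
            setattr(cfg, k, v)
        return cfg


def provenance(spec_code: str | None, seed: int | None) -> dict:
    from . import __version__

    return {
        "package": "endodiff",
        "version": __version__,
        "spec": spec_code,
        "seed": seed,
    }
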