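"""Configuration, presets, seeds and tabular serialization.

Every run is driven by a :class:`RunConfig` assembled from YAML/JSON config
files and/or CLI flags, validated before dispatch.  Tables are written as
CSV with a provenance header (parameters, seed, package version) in
``#``-prefixed comment lines, deterministic column order and 12 significant
digits, so identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .game import CentipedeSpec, make_custom, make_icg
from .reasoning import RP_KINDS

__all__ = [
    "RunConfig",
    "load_config",
    "read_preset",
    "spec_from_config",
    "write_table",
    "read_table",
    "read_empirical",
    "seed_streams",
]

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Validated parameters shared by the command-line entry points."""

    game: str = "icg4"
    spec_path: str | None = None
    rp: str = "inertia"
    eps: float = 0.19
    beta: float = 0.31
    Z: int = 500
    mu: float = 1e-3
    R: int = 50_000
    k_max: int | None = None
    cost: float = 0.0
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.rp not in RP_KINDS:
            raise ValueError(f"rp must be one of {RP_KINDS}, got {self.rp!r}")
        if not (0.0 <= self.eps < 1.0):
            raise ValueError(f"eps must lie in [0, 1), got {self.eps}")
        if self.beta < 0:
            raise ValueError(f"beta must be nonnegative, got {self.beta}")
        if self.Z < 2:
            raise ValueError(f"Z must be at least 2, got {self.Z}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if self.R < 1:
            raise ValueError(f"R must be positive, got {self.R}")
        if self.cost < 0:
            raise ValueError(f"cost must be nonnegative, got {self.cost}")
        return self

    def spec(self) -> CentipedeSpec:
        if self.spec_path:
            with open(self.spec_path) as fh:
                raw = yaml.safe_load(fh)
            return spec_from_config(raw)
        return spec_from_config(read_preset(self.game))

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def load_config(path, **overrides) -> RunConfig:
    """Read a YAML/JSON config file, apply overrides, validate."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**raw).validate()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_preset(name: str) -> dict:
    ref = importlib.resources.files("tomcg.presets").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise ValueError(f"unknown game preset {name!r}")
    return yaml.safe_load(ref.read_text())


def spec_from_config(raw: dict) -> CentipedeSpec:
    """Build a game spec from a preset/config mapping."""
    variant = raw.get("variant", "incremental")
    if variant == "incremental":
        return make_icg(
            L=int(raw["L"]),
            M=raw.get("M", 0.5),
            growth=raw.get("growth", 2),
            split=raw.get("split", 0.8),
        )
    schedule = raw.get("schedule") or []
    pass_through = raw.get("pass_through") or []
    if not schedule or not pass_through:
        raise ValueError(
            "constant/custom game configs need explicit 'schedule' rows and "
            "'pass_through' (the ccg6 preset is a template to be filled in)"
        )
    return make_custom(schedule, pass_through)


def seed_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-module substreams expanded from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def write_table(records, path, kind: str, provenance: dict | None = None) -> None:
    """Write a tidy table (`DataFrame` or list of dicts) with provenance.

    ``kind`` is one of distribution / matrix / trajectory / surface and is
    recorded in the header; matrices keep their strategy-labelled index.
    """
    if kind not in ("distribution", "matrix", "trajectory", "surface"):
        raise ValueError(f"unknown table kind {kind!r}")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"kind": kind, "version": __version__}
    if provenance:
        header.update(provenance)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True, default=str) + "\n")
        df.to_csv(fh, float_format=_FLOAT_FMT, index=(kind == "matrix"), lineterminator="\n")


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#", index_col=0 if kind == "matrix" else None)


def read_empirical(path, spec: CentipedeSpec):
    """Read an empirical ending-step table (columns: step, count-or-prob).

    ``step`` is an integer in ``[1, L]`` or the string ``"pass"`` for games
    in which nobody took; the second column may hold counts or
    probabilities (normalized either way).
    """
    from .calibration import EmpiricalStepDistribution

    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("empirical table needs a step column and a value column")
    probs = np.zeros(spec.L + 1)
    for _, row in df.iterrows():
        step = row[cols[0]]
        idx = spec.L if str(step).strip().lower() in ("pass", "never") else int(step) - 1
        probs[idx] += float(row[cols[1]])
    total = probs.sum()
    if total <= 0:
        raise ValueError("empirical table has no mass")
    return EmpiricalStepDistribution(
        spec=spec, probs=probs / total, source=str(path)
    )
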