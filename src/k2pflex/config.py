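"""Run configuration: shipped defaults, user overrides, validation.

A run is configured by a single TOML file.  The package ships a
versioned defaults file (``data/defaults.toml``); a user file is merged
on top of it key by key, so every analysis parameter in any output is
traceable either to the user config or to a shipped default.
"""

from __future__ import annotations

import copy
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .core import K2PFlexError

__all__ = ["RunConfig", "load_config", "validate_config", "load_tm_helices"]


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _shipped_defaults() -> dict:
    with resources.files("k2pflex.data").joinpath("defaults.toml").open("rb") as fh:
        return tomllib.load(fh)


def load_tm_helices(protein: str = "SYNTHETIC", path: str | Path | None = None) -> list[tuple[int, int]]:
    """Residue ranges of the M1-M4 helices for the RMSD selection."""
    if path is None:
        with resources.files("k2pflex.data").joinpath("tm_helices.toml").open("rb") as fh:
            table = tomllib.load(fh)
    else:
        with open(path, "rb") as fh:
            table = tomllib.load(fh)
    if protein not in table:
        raise K2PFlexError(
            f"no TM helix ranges for {protein!r}; available: {sorted(table)}"
        )
    return [tuple(v) for v in table[protein].values()]


@dataclass
class RunConfig:
    """Validated analysis configuration (defaults merged with user file)."""

    settings: dict = field(default_factory=_shipped_defaults)
    inputs: dict = field(default_factory=dict)  # paths: topology, trajectory, refs
    seed: int = 0
    outdir: str = "k2pflex-out"
    source: str = "shipped defaults"

    def __getitem__(self, key: str):
        return self.settings[key]


def load_config(path: str | Path | None = None, seed: int | None = None, outdir: str | None = None) -> RunConfig:
    """Shipped defaults, optionally overridden by a user TOML file."""
    settings = _shipped_defaults()
    inputs: dict = {}
    src = "shipped defaults"
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        inputs = user.pop("input", {})
        run = user.pop("run", {})
        settings = _deep_merge(settings, user)
        src = str(path)
        if seed is None:
            seed = run.get("seed")
        if outdir is None:
            outdir = run.get("outdir")
    return RunConfig(
        settings=settings,
        inputs=inputs,
        seed=0 if seed is None else int(seed),
        outdir=outdir or "k2pflex-out",
        source=src,
    )


def validate_config(config: RunConfig) -> list[str]:
    """Pre-flight checks; returns a list of problems (empty = valid)."""
    problems: list[str] = []
    s = config.settings

    area = s.get("area", {})
    if area.get("raster", 0.25) <= 0:
        problems.append(f"area.raster must be > 0, got {area.get('raster')}")
    if area.get("slice_thickness", 1.0) <= 0:
        problems.append("area.slice_thickness must be > 0")

    state = s.get("state", {})
    if state.get("margin", 0.5) < 0:
        problems.append("state.margin must be >= 0")
    if state.get("stride", 1) < 1:
        problems.append("state.stride must be >= 1")

    pressure = s.get("pressure", {})
    if pressure.get("bin_width", 1.0) <= 0:
        problems.append("pressure.bin_width must be > 0")
    if pressure.get("kinetic_mode") == "thermal" and "temperature" not in pressure:
        problems.append("pressure.kinetic_mode='thermal' requires pressure.temperature")

    occ = s.get("occupancy", {})
    if occ.get("dewetting_threshold", 5.0) <= 0:
        problems.append("occupancy.dewetting_threshold must be > 0")
    if occ.get("contact_threshold", 4.0) <= 0:
        problems.append("occupancy.contact_threshold must be > 0")
    sites = occ.get("sites", [])
    prev = None
    for site in sites:
        lo, hi = site["z"]
        if hi <= lo:
            problems.append(f"site {site['name']}: empty z interval [{lo}, {hi}]")
        if prev is not None and hi > prev[1]:
            problems.append(
                f"sites {prev[0]} and {site['name']} overlap or are out of order"
            )
        prev = (site["name"], lo)

    gating = s.get("gating", {})
    adjacency = gating.get("adjacency", {})
    for c, adj in adjacency.items():
        if adjacency.get(adj) != c:
            problems.append(f"gating.adjacency is not symmetric at chain {c}")
    if gating.get("atom_mode", "CA") not in ("CA", "min-heavy"):
        problems.append(f"gating.atom_mode must be 'CA' or 'min-heavy'")

    for key, path in config.inputs.items():
        if path and not Path(path).exists():
            problems.append(f"input.{key}: file not found: {path}")
    return problems
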