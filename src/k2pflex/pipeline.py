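"""End-to-end report: run every conformational analysis on a trajectory.

``run_report`` consumes a :class:`~k2pflex.config.RunConfig`, runs the
RMSD, gating-distance, state-classification, landscape and event-order
stages (plus bilayer geometry when the inputs contain lipids), writes
the CSV/JSON products into the output directory and finishes with a
provenance manifest (package version, config hash, per-file checksums).
Outputs are deterministic given inputs and seed; any stage failure
aborts the run, removes partial outputs and names the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

from . import __version__
from .config import RunConfig, load_tm_helices, validate_config
from .core import K2PFlexError, SelectionError, SelectionSpec
from .io import read_structure, read_trajectory
from .geometry import area_per_lipid, bilayer_thickness
from .state import (
    GatingPairConfig,
    classify_states,
    detect_event_sequence,
    gating_distances,
    landscape_table,
    rmsd_series,
)
from .synthetic import make_reference_pair

__all__ = ["run_report"]

log = logging.getLogger("k2pflex")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(
        {"settings": config.settings, "inputs": {k: str(v) for k, v in config.inputs.items()},
         "seed": config.seed},
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()


def _gating_config(config: RunConfig) -> GatingPairConfig:
    g = config["gating"]
    return GatingPairConfig(
        fenestration=tuple(g["fenestration"]),
        zipper=tuple(g["zipper"]),
        expansion=tuple(g["expansion"]),
        adjacency=dict(g["adjacency"]),
        atom_mode=g["atom_mode"],
    )


def run_report(config: RunConfig) -> Path:
    """Run all applicable stages; returns the output directory."""
    problems = validate_config(config)
    if problems:
        raise K2PFlexError("invalid configuration: " + "; ".join(problems))
    if "trajectory" not in config.inputs:
        raise K2PFlexError("run_report requires input.trajectory")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read inputs"
        t0 = _time.perf_counter()
        traj = read_trajectory(config.inputs.get("topology"), config.inputs["trajectory"])
        if "down_ref" in config.inputs and "up_ref" in config.inputs:
            down = read_structure(config.inputs["down_ref"])
            up = read_structure(config.inputs["up_ref"])
        else:
            refs = config["reference_distances"]
            down, up = make_reference_pair(
                {"down": dict(refs["down"]), "up": dict(refs["up"])}
            )
        log.info("read inputs: %d frames (%.2f s)", len(traj), _time.perf_counter() - t0)

        helix_protein = config.settings.get("protein", "SYNTHETIC")
        tm_spec = SelectionSpec(
            resid_ranges=load_tm_helices(helix_protein), atom_names=["CA"]
        )
        gcfg = _gating_config(config)
        state_cfg = config["state"]

        stage = "rmsd"
        rd = rmsd_series(traj, down, tm_spec)
        ru = rmsd_series(traj, up, tm_spec)
        import pandas as pd

        path = outdir / "rmsd.csv"
        pd.DataFrame(
            {"time": rd[:, 0], "rmsd_down": rd[:, 1], "rmsd_up": ru[:, 1]}
        ).to_csv(path, index=False)
        written.append(path)
        log.info("rmsd: %d frames", len(traj))

        stage = "gating"
        gd = gating_distances(traj, gcfg)
        path = outdir / "gating.csv"
        gd.to_frame().to_csv(path, index=False)
        written.append(path)

        stage = "classify"
        states = classify_states(traj, down, up, tm_spec, margin=state_cfg["margin"])
        path = outdir / "states.csv"
        states.to_frame().to_csv(path, index=False)
        written.append(path)

        stage = "landscape"
        table = landscape_table(
            traj, {"down": down, "up": up}, gcfg, stride=state_cfg["stride"]
        )
        path = outdir / "landscape.csv"
        table.to_csv(path, index=False)
        written.append(path)

        stage = "events"
        refs = config["reference_distances"]
        report = detect_event_sequence(
            gd,
            down_values=dict(refs["down"]),
            up_values=dict(refs["up"]),
            smoothing_window=state_cfg["smoothing_window"],
            dwell=state_cfg["dwell"],
        )
        path = outdir / "events.json"
        path.write_text(json.dumps(report.to_dict(), indent=2))
        written.append(path)

        stage = "bilayer"
        phosphate_spec = SelectionSpec(**{
            k: v for k, v in config["selections"]["phosphates"].items()
            if k in ("atom_names", "resnames", "chain")
        })
        try:
            summary = bilayer_thickness(traj, phosphate_spec)
            n_per_leaflet = config.settings.get("bilayer", {}).get("n_lipids_per_leaflet")
            if n_per_leaflet:
                summary.apl_series = area_per_lipid(traj, n_per_leaflet).apl_series
            path = outdir / "bilayer.csv"
            summary.to_frame().to_csv(path, index=False)
            written.append(path)
        except SelectionError:
            log.info("bilayer: no phosphate-like atoms; stage skipped")

        stage = "manifest"
        manifest = {
            "package": "k2pflex",
            "version": __version__,
            "config_source": config.source,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "files": {p.name: _sha256(p) for p in written},
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        log.info("report complete: %d files in %s", len(written) + 1, outdir)
        return outdir
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise K2PFlexError(f"report stage '{stage}' failed: {exc}") from exc
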