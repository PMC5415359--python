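"""Conformational-state metrics for the down <-> up gating transition.

The down->up movement of a mechanosensitive K2P channel is tracked by

* Cα RMSD of the transmembrane helices against the down and up
  reference structures (after least-squares rigid superposition);
* three inter-residue "gating" distances per chain: the *fenestration*
  (G324 Cα to P198 Cα of the adjacent chain), the *zipper* (W326-R237,
  same chain) and the *expansion* (M322-G212, same chain);
* a per-frame state label (down / up / intermediate) from the two RMSDs;
* a landscape table of the gating distances sampled at a stride, with
  one row per crystal reference for comparison;
* change-point detection of the event sequence unzip -> expand -> close,
  per chain, by midpoint crossing of the smoothed distance series.

Residue numbers are author numbers; the residues named above are the
TREK-2 defaults and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.spatial.transform import Rotation

from .core import (
    Frame,
    K2PFlexError,
    SelectionError,
    SelectionSpec,
    Trajectory,
    min_image_distance,
    select,
)

__all__ = [
    "GatingPairConfig",
    "GatingDistances",
    "StateSeries",
    "EventReport",
    "superpose",
    "rmsd_series",
    "gating_distances",
    "classify_states",
    "landscape_table",
    "detect_event_sequence",
    "METRICS",
]

METRICS = ("fenestration", "zipper", "expansion")


# ----------------------------------------------------------------------
# Superposition / RMSD
# ----------------------------------------------------------------------

def _matched_coordinates(
    mobile: Frame, reference: Frame, spec: SelectionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate pairs matched 1:1 by (chain, resid, atom name)."""
    idx_m = select(mobile, spec)
    idx_r = select(reference, spec)
    key_m = {
        (mobile.chains[i], int(mobile.resids[i]), mobile.names[i]): i for i in idx_m
    }
    key_r = {
        (reference.chains[i], int(reference.resids[i]), reference.names[i]): i
        for i in idx_r
    }
    if len(key_m) != len(idx_m) or len(key_r) != len(idx_r):
        raise SelectionError(
            "selection is ambiguous: duplicate (chain, resid, atom name) keys"
        )
    if set(key_m) != set(key_r):
        missing = sorted(set(key_r) ^ set(key_m))[:5]
        raise SelectionError(
            f"selections do not map 1:1 between structures; e.g. {missing}"
        )
    order = [key_r[k] for k in sorted(key_r)]
    mo = [key_m[k] for k in sorted(key_r)]
    return mobile.positions[mo], reference.positions[order]


def superpose(
    mobile: Frame, reference: Frame, spec: SelectionSpec
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition (Kabsch) of matched selections.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile coordinates onto the
    reference; the rotation is proper (det = +1) and the RMSD (Å) is
    the minimised value.
    """
    x, y = _matched_coordinates(mobile, reference, spec)
    n = x.shape[0]
    if n < 3:
        raise K2PFlexError(f"superposition needs >= 3 atoms, got {n}")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    s = np.linalg.svd(y0.T @ x0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise K2PFlexError("degenerate (collinear) selection: rotation undetermined")
    rot, rssd = Rotation.align_vectors(y0, x0)
    rmsd = rssd / np.sqrt(n)
    rmat = rot.as_matrix()
    return rmat, yc - rmat @ xc, float(rmsd)


def apply_transform(frame: Frame, rotation: np.ndarray, translation: np.ndarray) -> Frame:
    """Copy of *frame* with ``rotation @ x + translation`` applied."""
    out = frame.copy()
    out.positions = frame.positions @ np.asarray(rotation).T + np.asarray(translation)
    return out


def rmsd_series(
    traj: Trajectory, reference: Frame, spec: SelectionSpec
) -> np.ndarray:
    """(time, rmsd) pairs: per-frame Kabsch RMSD against *reference*."""
    out = np.empty((len(traj), 2))
    for k, frame in enumerate(traj):
        _, _, r = superpose(frame, reference, spec)
        out[k] = (frame.time, r)
    return out


# ----------------------------------------------------------------------
# Gating distances
# ----------------------------------------------------------------------

@dataclass
class GatingPairConfig:
    """Residue pairs defining the three gating distances.

    Pairs are (first, second) author resids.  The fenestration pairs the
    first residue of one chain with the second residue of the *adjacent*
    chain, as given by the explicit ``adjacency`` map (never inferred);
    zipper and expansion are within-chain.  ``atom_mode`` is ``"CA"``
    (default) or ``"min-heavy"`` (minimum heavy-atom distance).
    """

    fenestration: tuple[int, int] = (324, 198)
    zipper: tuple[int, int] = (326, 237)
    expansion: tuple[int, int] = (322, 212)
    adjacency: dict[str, str] = field(default_factory=lambda: {"A": "B", "B": "A"})
    atom_mode: str = "CA"

    def __post_init__(self) -> None:
        if self.atom_mode not in ("CA", "min-heavy"):
            raise K2PFlexError(f"atom_mode must be 'CA' or 'min-heavy', got {self.atom_mode!r}")
        for c, adj in self.adjacency.items():
            if self.adjacency.get(adj) != c:
                raise K2PFlexError("adjacency map must be symmetric")

    def pair(self, metric: str) -> tuple[int, int]:
        return getattr(self, metric)


@dataclass
class GatingDistances:
    """Per-frame, per-chain gating distances (Å)."""

    times: np.ndarray
    chains: list[str]
    distances: dict[str, dict[str, np.ndarray]]  # chain -> metric -> series
    config: GatingPairConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chain in self.chains:
            d = self.distances[chain]
            for k, t in enumerate(self.times):
                rows.append(
                    {
                        "time": t,
                        "chain": chain,
                        "fenestration": d["fenestration"][k],
                        "zipper": d["zipper"][k],
                        "expansion": d["expansion"][k],
                    }
                )
        return pd.DataFrame(rows)


def _residue_atoms(frame: Frame, chain: str, resid: int, mode: str) -> np.ndarray:
    if mode == "CA":
        spec = SelectionSpec(chain=chain, resid_ranges=[(resid, resid)], atom_names=["CA"])
    else:
        spec = SelectionSpec(chain=chain, resid_ranges=[(resid, resid)])
    try:
        idx = select(frame, spec)
    except SelectionError as exc:
        raise SelectionError(
            f"residue {resid} (chain {chain}) has no "
            f"{'CA atom' if mode == 'CA' else 'atoms'}: {exc}"
        ) from exc
    if mode != "CA":
        heavy = [i for i in idx if frame.elements[i] != "H"]
        if not heavy:
            raise SelectionError(f"residue {resid} (chain {chain}) has no heavy atoms")
        idx = np.array(heavy)
    return idx

def _pair_distance(frame: Frame, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    best = np.inf
    for i in idx_a:
        for j in idx_b:
            d = min_image_distance(frame.positions[i], frame.positions[j], frame.box)
            best = min(best, d)
    return best


def gating_distances(
    traj: Trajectory, config: GatingPairConfig | None = None
) -> GatingDistances:
    """Minimum-image fenestration / zipper / expansion distances."""
    config = config or GatingPairConfig()
    first = traj[0]
    chains = sorted(config.adjacency)
    # resolve atom indices once; topology is constant across frames
    idx: dict[tuple[str, str, int], np.ndarray] = {}
    for chain in chains:
        for metric in METRICS:
            a, b = config.pair(metric)
            partner = config.adjacency[chain] if metric == "fenestration" else chain
            idx[(chain, metric, 0)] = _residue_atoms(first, chain, a, config.atom_mode)
            idx[(chain, metric, 1)] = _residue_atoms(first, partner, b, config.atom_mode)

    dists = {c: {m: np.empty(len(traj)) for m in METRICS} for c in chains}
    for k, frame in enumerate(traj):
        for chain in chains:
            for metric in METRICS:
                dists[chain][metric][k] = _pair_distance(
                    frame, idx[(chain, metric, 0)], idx[(chain, metric, 1)]
                )
    return GatingDistances(
        times=traj.times, chains=chains, distances=dists, config=config
    )


# ----------------------------------------------------------------------
# State classification
# ----------------------------------------------------------------------

@dataclass
class StateSeries:
    """Per-frame state labels from RMSD to the two references."""

    times: np.ndarray
    labels: list[str]  # "down" | "up" | "intermediate"
    rmsd_down: np.ndarray
    rmsd_up: np.ndarray
    margin: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "label": self.labels,
                "rmsd_down": self.rmsd_down,
                "rmsd_up": self.rmsd_up,
            }
        )


def classify_states(
    traj: Trajectory,
    down_ref: Frame,
    up_ref: Frame,
    spec: SelectionSpec,
    margin: float = 0.5,
) -> StateSeries:
    """Label frames by the nearer reference when the RMSD gap exceeds
    *margin* (Å); otherwise "intermediate"."""
    if margin < 0:
        raise K2PFlexError("margin must be >= 0")
    rd = rmsd_series(traj, down_ref, spec)[:, 1]
    ru = rmsd_series(traj, up_ref, spec)[:, 1]
    labels = []
    for d, u in zip(rd, ru):
        if d + margin < u:
            labels.append("down")
        elif u + margin < d:
            labels.append("up")
        else:
            labels.append("intermediate")
    return StateSeries(
        times=traj.times, labels=labels, rmsd_down=rd, rmsd_up=ru, margin=margin
    )


# ----------------------------------------------------------------------
# Landscape table
# ----------------------------------------------------------------------

def landscape_table(
    traj: Trajectory,
    crystal_refs: dict[str, Frame] | None = None,
    config: GatingPairConfig | None = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Gating-distance tuples sampled every *stride* frames, plus one row
    per crystal reference computed with the same pair configuration.

    Columns: source, time, chain, fenestration, zipper, expansion.
    Crystal rows carry their name as ``source`` and NaN time.
    """
    if stride < 1:
        raise K2PFlexError("stride must be >= 1")
    config = config or GatingPairConfig()
    sub = Trajectory(traj.frames[::stride], topology_source=traj.topology_source)
    gd = gating_distances(sub, config)
    table = gd.to_frame()
    table.insert(0, "source", "trajectory")
    rows = [table]
    for name, ref in (crystal_refs or {}).items():
        ref_gd = gating_distances(Trajectory([ref]), config)
        t = ref_gd.to_frame()
        t["time"] = np.nan
        t.insert(0, "source", name)
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


# ----------------------------------------------------------------------
# Event-sequence detection
# ----------------------------------------------------------------------

@dataclass
class EventReport:
    """Detected per-chain event times (ps) and their ordering.

    ``order_ok`` is true for a chain iff all three events were detected
    and t_unzip <= t_expand <= t_close.  Chains are detected and
    reported independently: the two subunits of the dimer move
    stochastically and need not transition together.
    """

    events: dict[str, dict[str, float | None]]  # chain -> {unzip, expand, close}
    order_ok: dict[str, bool]

    @property
    def all_ordered(self) -> bool:
        return all(self.order_ok.values())

    def to_dict(self) -> dict:
        return {"events_ps": self.events, "order_ok": self.order_ok}


def _first_sustained_crossing(
    series: np.ndarray, midpoint: float, upward: bool, dwell: int
) -> int | None:
    on_up = series >= midpoint if upward else series <= midpoint
    if dwell < 1:
        dwell = 1
    # first index from which the series stays on the up side for >= dwell frames
    run = 0
    for i in range(len(on_up) - 1, -1, -1):
        run = run + 1 if on_up[i] else 0
        on_up[i] = run >= dwell
    hits = np.flatnonzero(on_up)
    return int(hits[0]) if hits.size else None


def detect_event_sequence(
    gd: GatingDistances,
    down_values: dict[str, float],
    up_values: dict[str, float],
    smoothing_window: int = 5,
    dwell: int = 5,
) -> EventReport:
    """Event times from midpoint crossings of the smoothed distances.

    For each chain and each metric, the event time is the first frame at
    which the moving-average-smoothed series crosses the midpoint
    between the down and up reference values *and remains across* for at
    least *dwell* frames.  Undetected events are reported as ``None``.
    """
    events: dict[str, dict[str, float | None]] = {}
    order_ok: dict[str, bool] = {}
    for chain in gd.chains:
        ev: dict[str, float | None] = {}
        for event, metric in (
            ("unzip", "zipper"),
            ("expand", "expansion"),
            ("close", "fenestration"),
        ):
            lo, hi = down_values[metric], up_values[metric]
            if lo == hi:
                raise K2PFlexError(
                    f"down and up reference values for {metric} must differ"
                )
            series = gd.distances[chain][metric]
            smooth = uniform_filter1d(
                series.astype(float), size=max(1, smoothing_window), mode="nearest"
            )
            i = _first_sustained_crossing(
                smooth, midpoint=0.5 * (lo + hi), upward=hi > lo, dwell=dwell
            )
            ev[event] = None if i is None else float(gd.times[i])
        events[chain] = ev
        ts = [ev["unzip"], ev["expand"], ev["close"]]
        order_ok[chain] = (
            all(t is not None for t in ts) and ts[0] <= ts[1] <= ts[2]
        )
    return EventReport(events=events, order_ok=order_ok)
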