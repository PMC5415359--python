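"""Selectivity-filter, pore-hydration and lipid-contact occupancies.

* **Ion occupancy** — each K⁺ ion is assigned per frame to the filter
  site (S0..S4, z-intervals along the pore axis) containing its axial
  coordinate; a site's occupancy is the fraction of frames in which at
  least one ion sits in it.  A z-density histogram of the ions is
  reported alongside.
* **Water profile / dewetting** — waters within a cylinder around the
  pore axis are counted per frame and histogrammed along z; *dewetting*
  events are maximal runs of frames whose cavity water count stays
  below a threshold for at least a minimum duration.
* **Lipid contacts** — per-frame minimum distance from lipid-tail atoms
  to a target residue (the fenestration gatekeeper P198, or the
  M2/M3-tip groove anchor S240), flagged "bound" below a threshold
  (default 4 Å) and paired with a structural metric (fenestration or
  groove width) for state-dependence scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Frame,
    K2PFlexError,
    SelectionError,
    SelectionSpec,
    Trajectory,
    min_image_displacement,
    select,
)
from .state import _pair_distance, _residue_atoms

__all__ = [
    "FilterSites",
    "OccupancyResult",
    "WaterProfile",
    "DewettingReport",
    "LipidContactSeries",
    "ion_occupancy",
    "water_profile",
    "detect_dewetting",
    "lipid_contact_series",
    "groove_series",
    "sites_from_planes",
]


@dataclass
class FilterSites:
    """Ordered, non-overlapping z-intervals for the filter sites.

    Intervals are listed extracellular side first (S0 topmost along +z).
    The axis is the z axis through ``axis_xy``; only the axial (z)
    coordinate decides site membership.
    """

    intervals: list[tuple[str, float, float]]
    axis_xy: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        prev_lo = None
        for name, lo, hi in self.intervals:
            if hi <= lo:
                raise K2PFlexError(f"site {name}: empty interval [{lo}, {hi}]")
            if prev_lo is not None and hi > prev_lo:
                raise K2PFlexError(
                    f"site intervals must be ordered and non-overlapping; "
                    f"{name} overlaps or is out of order"
                )
            prev_lo = lo

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.intervals]

    def assign(self, z: float) -> str | None:
        for name, lo, hi in self.intervals:
            if lo <= z < hi:
                return name
        return None


def sites_from_planes(plane_z: list[float], labels: list[str] | None = None) -> FilterSites:
    """Derive site intervals from carbonyl-oxygen plane z-positions.

    Consecutive plane midpoints bound the inner sites; the topmost site
    (S0) spans one inter-plane spacing above the top plane.  Planes are
    given bottom-up or top-down; they are sorted descending internally.
    """
    z = sorted(plane_z, reverse=True)
    if len(z) < 2:
        raise K2PFlexError("need at least two planes to derive site intervals")
    mids = [0.5 * (a + b) for a, b in zip(z, z[1:])]
    top_spacing = z[0] - z[1]
    bottom_spacing = z[-2] - z[-1]
    # boundaries, top down: S0 upper edge, the inter-plane midpoints,
    # then one spacing below the last midpoint
    bounds = [z[0] + top_spacing] + mids + [mids[-1] - bottom_spacing]
    n_sites = len(bounds) - 1
    labels = labels or [f"S{i}" for i in range(n_sites)]
    intervals = [
        (name, lo, hi) for name, hi, lo in zip(labels, bounds, bounds[1:])
    ]
    return FilterSites(intervals=intervals)


@dataclass
class OccupancyResult:
    """Site-resolved ion occupancy and axial ion density."""

    site_probability: dict[str, float]
    per_frame_sites: list[list[str | None]]  # frame -> per-ion assignment
    density_z: np.ndarray  # bin centres, Å
    density: np.ndarray  # mean ions per frame per bin
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site": list(self.site_probability), "probability": list(self.site_probability.values())}
        )


def ion_occupancy(
    traj: Trajectory,
    sites: FilterSites,
    ion_spec: SelectionSpec,
    density_bin_width: float = 0.5,
    per_ion: bool = False,
) -> OccupancyResult:
    """Per-site occupancy probability and axial ion density.

    A site is "occupied" in a frame when at least one selected ion's z
    coordinate falls inside its interval.  With ``per_ion=True`` the
    probability is instead the mean number of selected ions in the site
    per frame.
    """
    idx = select(traj[0], ion_spec)
    z_all = np.array([frame.positions[idx, 2] for frame in traj])
    names = sites.names
    counts = dict.fromkeys(names, 0.0)
    assignments: list[list[str | None]] = []
    for row in z_all:
        frame_sites = [sites.assign(z) for z in row]
        assignments.append(frame_sites)
        if per_ion:
            for s in frame_sites:
                if s is not None:
                    counts[s] += 1
        else:
            for s in set(s for s in frame_sites if s is not None):
                counts[s] += 1
    prob = {n: counts[n] / len(traj) for n in names}

    z_lo = min(lo for _, lo, _ in sites.intervals) - 2.0
    z_hi = max(hi for _, _, hi in sites.intervals) + 2.0
    n_bins = max(1, int(np.ceil((z_hi - z_lo) / density_bin_width)))
    hist, edges = np.histogram(z_all.ravel(), bins=n_bins, range=(z_lo, z_hi))
    return OccupancyResult(
        site_probability=prob,
        per_frame_sites=assignments,
        density_z=0.5 * (edges[:-1] + edges[1:]),
        density=hist / len(traj),
        bin_width=density_bin_width,
    )


@dataclass
class WaterProfile:
    """Axial water density and per-frame cavity counts."""

    z: np.ndarray  # bin centres, Å
    density: np.ndarray  # mean waters per frame per bin
    cavity_counts: np.ndarray  # per-frame count inside the cavity interval
    times: np.ndarray
    cylinder_radius: float
    cavity_z: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z, "mean_waters": self.density})


def water_profile(
    traj: Trajectory,
    water_spec: SelectionSpec,
    cavity_z: tuple[float, float],
    cylinder_radius: float = 5.0,
    axis_xy: tuple[float, float] | None = None,
    bin_width: float = 1.0,
    z_range: tuple[float, float] | None = None,
) -> WaterProfile:
    """Count waters inside a cylinder around the pore axis.

    The axis is vertical through ``axis_xy`` (default: mean xy of the
    selected waters in the first frame).  Waters within
    ``cylinder_radius`` of the axis are histogrammed along z; the cavity
    count per frame is the number inside the ``cavity_z`` interval.
    """
    idx = select(traj[0], water_spec)
    if axis_xy is None:
        axis_xy = tuple(traj[0].positions[idx, :2].mean(axis=0))
    axis = np.asarray(axis_xy)
    if z_range is None:
        z_range = (cavity_z[0] - 5.0, cavity_z[1] + 5.0)
    n_bins = max(1, int(np.ceil((z_range[1] - z_range[0]) / bin_width)))
    hist = np.zeros(n_bins)
    counts = np.empty(len(traj))
    for k, frame in enumerate(traj):
        xy = frame.positions[idx, :2]
        dxy = min_image_displacement(xy, axis, None if frame.box is None else frame.box[:2])
        inside = np.linalg.norm(dxy, axis=1) <= cylinder_radius
        z = frame.positions[idx, 2][inside]
        h, edges = np.histogram(z, bins=n_bins, range=z_range)
        hist += h
        counts[k] = int(((z >= cavity_z[0]) & (z < cavity_z[1])).sum())
    return WaterProfile(
        z=0.5 * (edges[:-1] + edges[1:]),
        density=hist / len(traj),
        cavity_counts=counts,
        times=traj.times,
        cylinder_radius=cylinder_radius,
        cavity_z=cavity_z,
    )


@dataclass
class DewettingReport:
    """Maximal dry intervals of the cavity water-count series."""

    intervals: list[tuple[int, int]]  # inclusive frame indices
    intervals_ps: list[tuple[float, float]]
    threshold: float
    min_duration: int
    counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "intervals_frames": [list(iv) for iv in self.intervals],
            "intervals_ps": [list(iv) for iv in self.intervals_ps],
            "threshold": self.threshold,
            "min_duration_frames": self.min_duration,
        }


def detect_dewetting(
    cavity_counts: np.ndarray,
    threshold: float = 5.0,
    min_duration: int = 1,
    times: np.ndarray | None = None,
) -> DewettingReport:
    """Maximal runs of frames with count < threshold, each >= min_duration.

    Runs separated by even a single wet frame are reported separately;
    no merging is performed.
    """
    counts = np.asarray(cavity_counts, dtype=float)
    if times is None:
        times = np.arange(counts.size, dtype=float)
    dry = counts < threshold
    intervals: list[tuple[int, int]] = []
    start = None
    for i, d in enumerate(dry):
        if d and start is None:
            start = i
        elif not d and start is not None:
            if i - start >= min_duration:
                intervals.append((start, i - 1))
            start = None
    if start is not None and counts.size - start >= min_duration:
        intervals.append((start, counts.size - 1))
    return DewettingReport(
        intervals=intervals,
        intervals_ps=[(float(times[a]), float(times[b])) for a, b in intervals],
        threshold=threshold,
        min_duration=min_duration,
        counts=counts,
    )


@dataclass
class LipidContactSeries:
    """Minimum lipid-tail distance to a target residue, with bound flag."""

    times: np.ndarray
    min_distance: np.ndarray  # Å, per frame (per chain, averaged? no: global min)
    bound: np.ndarray  # bool
    threshold: float
    structural_metric: np.ndarray | None = None  # paired metric, Å
    metric_name: str = ""

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time": self.times,
            "min_lipid_dist_A": self.min_distance,
            "bound": self.bound,
        }
        if self.structural_metric is not None:
            data[self.metric_name or "structural_metric_A"] = self.structural_metric
        return pd.DataFrame(data)


def _min_distance_series(
    traj: Trajectory, target_idx: np.ndarray, lipid_idx: np.ndarray
) -> np.ndarray:
    out = np.empty(len(traj))
    for k, frame in enumerate(traj):
        d = min_image_displacement(
            frame.positions[lipid_idx][:, None, :],
            frame.positions[target_idx][None, :, :],
            frame.box,
        )
        out[k] = np.linalg.norm(d, axis=-1).min()
    return out


def lipid_contact_series(
    traj: Trajectory,
    target_residue: int,
    lipid_tail_spec: SelectionSpec,
    target_chain: str | None = None,
    threshold: float = 4.0,
    paired_metric: np.ndarray | None = None,
    metric_name: str = "fenestration_A",
) -> LipidContactSeries:
    """Minimum-image minimum distance from lipid tails to a residue.

    ``bound`` is true when the distance is below *threshold* (4 Å by
    default, the contact criterion for lipids occupying the fenestration
    site at P198).  An optional paired structural metric of the same
    length is carried through for scatter analysis.
    """
    first = traj[0]
    chains = [target_chain] if target_chain else sorted(set(first.chains))
    target_idx: list[int] = []
    for c in chains:
        try:
            target_idx.extend(
                select(first, SelectionSpec(chain=c, resid_ranges=[(target_residue, target_residue)]))
            )
        except SelectionError:
            continue
    if not target_idx:
        raise SelectionError(f"target residue {target_residue} not found")
    lipid_idx = select(first, lipid_tail_spec)
    dist = _min_distance_series(traj, np.array(target_idx), lipid_idx)
    if paired_metric is not None and len(paired_metric) != len(traj):
        raise K2PFlexError("paired metric length must match the trajectory")
    return LipidContactSeries(
        times=traj.times,
        min_distance=dist,
        bound=dist < threshold,
        threshold=threshold,
        structural_metric=None if paired_metric is None else np.asarray(paired_metric),
        metric_name=metric_name,
    )


def groove_series(
    traj: Trajectory,
    lipid_tail_spec: SelectionSpec,
    groove_pair: tuple[int, int] = (226, 243),
    lipid_anchor: int = 240,
    chain: str = "A",
    threshold: float = 4.0,
    atom_mode: str = "CA",
) -> LipidContactSeries:
    """M2/M3-tip groove width paired with the lipid distance to its anchor.

    The groove metric is the distance between the two tip residues
    (F226-L243 by default); the contact metric is the minimum lipid-tail
    distance to the anchor residue (S240).
    """
    first = traj[0]
    a_idx = _residue_atoms(first, chain, groove_pair[0], atom_mode)
    b_idx = _residue_atoms(first, chain, groove_pair[1], atom_mode)
    groove = np.array(
        [_pair_distance(frame, a_idx, b_idx) for frame in traj]
    )
    contact = lipid_contact_series(
        traj,
        target_residue=lipid_anchor,
        lipid_tail_spec=lipid_tail_spec,
        target_chain=chain,
        threshold=threshold,
        paired_metric=groove,
        metric_name="groove_A",
    )
    return contact
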