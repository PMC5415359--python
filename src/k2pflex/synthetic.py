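"""Synthetic inputs with recorded ground truth.

Real stretch-simulation trajectories of K2P channels are multi-hundred-ns
MD runs that cannot be regenerated on demand, so every analysis stage in
this package is exercised against synthetic systems whose expected output
is known by construction:

* an idealised two-chain Cα-only channel model in "down" and "up"
  conformations, and noisy sigmoidal transitions between them with
  planted per-chain event times (unzip -> expand -> close);
* planar two-leaflet bilayers with configurable phosphate-plane
  separation and area per lipid;
* particle systems with analytically known forces (ideal gas, harmonic
  pair, truncated Lennard-Jones fluid) for the local-stress module;
* pore-axis ion/water traces with prescribed filter-site occupancies and
  dewetting intervals.

The channel model is deliberately minimal: two chains related by a
two-fold rotation about z, each a bundle of four ideal helices (M1-M4)
of Cα beads.  The six residues that define the gating metrics
(G324/P198 fenestration across chains, W326/R237 zipper and M322/G212
expansion within a chain) are placed explicitly so that the three
distances equal the requested reference values exactly; everything else
is a static scaffold.  This gives planted distance series that the
state-metrics stage must recover, not a physical model of the protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Frame, K2PFlexError, Trajectory

__all__ = [
    "TransitionSpec",
    "BilayerSpec",
    "PoreTraceSpec",
    "ForceSystemSpec",
    "PairForces",
    "TransitionGroundTruth",
    "BilayerGroundTruth",
    "PoreGroundTruth",
    "ForceGroundTruth",
    "make_reference_pair",
    "make_transition_trajectory",
    "make_interpolated_trajectory",
    "make_bilayer",
    "make_bilayer_trajectory",
    "make_pore_trace",
    "make_force_system",
    "DEFAULT_REFERENCE_DISTANCES",
    "EVENT_METRIC",
    "KB_KJ_MOL_K",
]

KB_KJ_MOL_K = 8.314462618e-3  # Boltzmann constant, kJ/mol/K

# Which planted event drives which gating metric.
EVENT_METRIC = {"unzip": "zipper", "expand": "expansion", "close": "fenestration"}

# Idealised down/up reference distances (Å).  The fenestration closes
# (distance falls) while zipper and expansion open (distances rise) on
# the down -> up transition, matching the observed direction of each
# movement; the several-Å separations make midpoint-crossing detection
# well-posed.
DEFAULT_REFERENCE_DISTANCES = {
    "down": {"fenestration": 12.0, "zipper": 6.0, "expansion": 8.0},
    "up": {"fenestration": 6.0, "zipper": 14.0, "expansion": 14.0},
}

_CHAINS = ("A", "B")
_BOX = np.array([90.0, 90.0, 90.0])

# Helix residue spans of the synthetic scaffold (author numbering chosen
# to contain every residue the analyses address by number).
_HELICES = {
    "M1": ((70, 100), (6.0, 6.0)),
    "M2": ((190, 215), (6.0, -6.0)),
    "M3": ((218, 248), (-6.0, -6.0)),
    "M4": ((300, 335), (-6.0, 6.0)),
}
_MARKER_RESNAMES = {
    198: "PRO",
    212: "GLY",
    226: "PHE",
    237: "ARG",
    240: "SER",
    243: "LEU",
    322: "MET",
    324: "GLY",
    326: "TRP",
}

# Fixed marker anchors in chain-local coordinates (cytoplasmic half,
# z < 0) and unit directions along which the moving partner sits.
_P198_LOC = np.array([4.0, -5.0, -8.0])
_G212_LOC = np.array([3.0, -6.0, -14.0])
_R237_LOC = np.array([-4.0, -6.0, -10.0])


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


_U_FEN = _unit([1.0, 0.3, 0.2])
_U_ZIP = _unit([0.2, 1.0, -0.5])
_U_EXP = _unit([-0.5, 0.3, 1.0])

_CHAIN_CENTER = {"A": np.array([12.0, 0.0, 0.0]), "B": np.array([-12.0, 0.0, 0.0])}


def _c2(v: np.ndarray) -> np.ndarray:
    """Two-fold rotation about the z axis."""
    return np.array([-v[0], -v[1], v[2]])


def _chain_xform(chain: str, v: np.ndarray) -> np.ndarray:
    return v if chain == "A" else _c2(v)


def adjacent_chain(chain: str) -> str:
    return "B" if chain == "A" else "A"


# ----------------------------------------------------------------------
# Channel model
# ----------------------------------------------------------------------

def _scaffold_atoms() -> tuple[list, np.ndarray]:
    """Static Cα scaffold for both chains: (labels, positions)."""
    labels = []  # (name, resname, resid, chain, element)
    pos = []
    rise, radius, twist = 1.5, 2.3, np.deg2rad(100.0)
    for chain in _CHAINS:
        center = _CHAIN_CENTER[chain]
        for (lo, hi), (hx, hy) in _HELICES.values():
            n = hi - lo + 1
            z0 = -0.5 * rise * (n - 1)
            for i, resid in enumerate(range(lo, hi + 1)):
                local = np.array(
                    [
                        hx + radius * np.cos(twist * i),
                        hy + radius * np.sin(twist * i),
                        z0 + rise * i,
                    ]
                )
                resname = _MARKER_RESNAMES.get(resid, "ALA")
                labels.append(("CA", resname, resid, chain, "C"))
                pos.append(center + _chain_xform(chain, local))
    return labels, np.array(pos)


def _marker_positions(distances: dict[str, dict[str, float]]) -> dict[tuple[str, int], np.ndarray]:
    """Positions of the six gating-marker Cα atoms per chain.

    ``distances`` maps chain -> {fenestration, zipper, expansion} (Å).
    The three anchors (P198, G212, R237) are fixed; their partners are
    placed at the requested distance along fixed directions, so the
    resulting inter-atom distances equal the request exactly.
    """
    out: dict[tuple[str, int], np.ndarray] = {}
    anchors = {}
    for chain in _CHAINS:
        c = _CHAIN_CENTER[chain]
        anchors[(chain, 198)] = c + _chain_xform(chain, _P198_LOC)
        anchors[(chain, 212)] = c + _chain_xform(chain, _G212_LOC)
        anchors[(chain, 237)] = c + _chain_xform(chain, _R237_LOC)
    out.update(anchors)
    for chain in _CHAINS:
        d = distances[chain]
        adj = adjacent_chain(chain)
        out[(chain, 326)] = anchors[(chain, 237)] + d["zipper"] * _chain_xform(chain, _U_ZIP)
        out[(chain, 322)] = anchors[(chain, 212)] + d["expansion"] * _chain_xform(chain, _U_EXP)
        out[(chain, 324)] = anchors[(adj, 198)] + d["fenestration"] * _chain_xform(chain, _U_FEN)
    return out


def _build_frame(distances: dict[str, dict[str, float]], time: float = 0.0) -> Frame:
    labels, pos = _scaffold_atoms()
    markers = _marker_positions(distances)
    pos = pos.copy()
    for i, (name, _resname, resid, chain, _el) in enumerate(labels):
        key = (chain, resid)
        if name == "CA" and key in markers:
            pos[i] = markers[key]
    return Frame(
        names=[l[0] for l in labels],
        resnames=[l[1] for l in labels],
        resids=[l[2] for l in labels],
        chains=[l[3] for l in labels],
        elements=[l[4] for l in labels],
        positions=pos,
        box=_BOX.copy(),
        time=time,
    )


def make_reference_pair(
    reference_distances: dict[str, dict[str, float]] | None = None,
) -> tuple[Frame, Frame]:
    """Idealised (down, up) reference conformations.

    The gating distances of each returned frame equal the requested
    reference values exactly (both chains identical).
    """
    refs = reference_distances or DEFAULT_REFERENCE_DISTANCES
    down = _build_frame({c: dict(refs["down"]) for c in _CHAINS})
    up = _build_frame({c: dict(refs["up"]) for c in _CHAINS})
    return down, up


@dataclass
class TransitionSpec:
    """Planted down->up transition with per-chain event times (ps).

    Each chain's three gating-distance series are logistic steps centred
    at the planted event times (width ``sigmoid_width_ps``) plus i.i.d.
    Gaussian noise of sd ``noise_sd``.  The generator enforces
    unzip <= expand <= close per chain, the order in which the three
    movements occur, so that recovery tests are well-posed.
    """

    n_chains: int = 2
    event_times: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "A": {"unzip": 20.0, "expand": 40.0, "close": 60.0},
            "B": {"unzip": 30.0, "expand": 50.0, "close": 70.0},
        }
    )
    reference_distances: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REFERENCE_DISTANCES.items()}
    )
    noise_sd: float = 0.0
    n_frames: int = 100
    dt: float = 1.0
    sigmoid_width_ps: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains != 2:
            raise K2PFlexError("the channel model is a homodimer: n_chains must be 2")
        t_end = (self.n_frames - 1) * self.dt
        for chain, ev in self.event_times.items():
            if not ev["unzip"] <= ev["expand"] <= ev["close"]:
                raise K2PFlexError(
                    f"chain {chain}: event order must be unzip <= expand <= close, "
                    f"got {ev}"
                )
            for name, t in ev.items():
                if not 0.0 <= t <= t_end:
                    raise K2PFlexError(
                        f"chain {chain}: event '{name}' at {t} ps outside the "
                        f"simulated window [0, {t_end}] ps"
                    )


@dataclass
class TransitionGroundTruth:
    """Planted truth for a synthetic transition."""

    times: np.ndarray
    event_times: dict[str, dict[str, float]]
    distances: dict[str, dict[str, np.ndarray]]  # chain -> metric -> series (Å)
    reference_distances: dict[str, dict[str, float]]
    noise_sd: float

    def to_dict(self) -> dict:
        return {
            "times_ps": self.times.tolist(),
            "event_times_ps": self.event_times,
            "distances_A": {
                c: {m: s.tolist() for m, s in d.items()} for c, d in self.distances.items()
            },
            "reference_distances_A": self.reference_distances,
            "noise_sd_A": self.noise_sd,
        }


def make_transition_trajectory(
    spec: TransitionSpec,
) -> tuple[Trajectory, TransitionGroundTruth]:
    """Noisy sigmoidal down->up transition with planted events."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.n_frames) * spec.dt
    down = spec.reference_distances["down"]
    up = spec.reference_distances["up"]

    series: dict[str, dict[str, np.ndarray]] = {}
    for chain in _CHAINS:
        series[chain] = {}
        for event, metric in EVENT_METRIC.items():
            t0 = spec.event_times[chain][event]
            sig = 1.0 / (1.0 + np.exp(-(times - t0) / spec.sigmoid_width_ps))
            d = down[metric] + (up[metric] - down[metric]) * sig
            if spec.noise_sd > 0:
                d = d + rng.normal(0.0, spec.noise_sd, size=d.shape)
            series[chain][metric] = d

    frames = []
    for k, t in enumerate(times):
        dist_k = {c: {m: float(series[c][m][k]) for m in series[c]} for c in _CHAINS}
        frames.append(_build_frame(dist_k, time=float(t)))
    truth = TransitionGroundTruth(
        times=times,
        event_times={c: dict(v) for c, v in spec.event_times.items()},
        distances=series,
        reference_distances={k: dict(v) for k, v in spec.reference_distances.items()},
        noise_sd=spec.noise_sd,
    )
    return Trajectory(frames, topology_source="synthetic-transition"), truth


def make_interpolated_trajectory(
    start: Frame, end: Frame, n_frames: int, dt: float = 1.0
) -> Trajectory:
    """Linear coordinate interpolation between two conformations."""
    if start.n_atoms != end.n_atoms:
        raise K2PFlexError("interpolation endpoints must have the same atoms")
    frames = []
    for k in range(n_frames):
        lam = k / (n_frames - 1) if n_frames > 1 else 0.0
        f = start.copy()
        f.positions = (1 - lam) * start.positions + lam * end.positions
        f.time = k * dt
        frames.append(f)
    return Trajectory(frames, topology_source="synthetic-interpolation")


# ----------------------------------------------------------------------
# Bilayer model
# ----------------------------------------------------------------------

@dataclass
class BilayerSpec:
    """Planar two-leaflet bilayer of coarse pseudo-lipids.

    One phosphate-like head bead per lipid sits at z = ±thickness/2
    (plus optional per-lipid Gaussian jitter); tail beads extend toward
    the midplane.  The xy box area is n_lipids_per_leaflet x
    area_per_lipid, so the area-per-lipid recovery is exact arithmetic.
    Defaults emulate an unstretched POPC bilayer (36 Å phosphate-plane
    separation, 64 Ų per lipid, 120 lipids per leaflet).
    """

    n_lipids_per_leaflet: int = 120
    thickness: float = 36.0
    area_per_lipid: float = 64.0
    tail_atoms_per_lipid: int = 4
    leaflet_z_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise K2PFlexError("thickness must be > 0")
        if self.area_per_lipid <= 0:
            raise K2PFlexError("area_per_lipid must be > 0")
        if self.n_lipids_per_leaflet <= 0:
            raise K2PFlexError("n_lipids_per_leaflet must be > 0")


@dataclass
class BilayerGroundTruth:
    thickness: float
    area_per_lipid: float
    n_lipids_per_leaflet: int

    def to_dict(self) -> dict:
        return {
            "thickness_A": self.thickness,
            "area_per_lipid_A2": self.area_per_lipid,
            "n_lipids_per_leaflet": self.n_lipids_per_leaflet,
        }


def _bilayer_frame(spec: BilayerSpec, rng: np.random.Generator, time: float) -> Frame:
    n = spec.n_lipids_per_leaflet
    box_l = np.sqrt(n * spec.area_per_lipid)
    grid = int(np.ceil(np.sqrt(n)))
    pitch = box_l / grid
    tail_spacing = (spec.thickness / 2) / (spec.tail_atoms_per_lipid + 1)

    names, resnames, resids, chains, elements = [], [], [], [], []
    pos = []
    resid = 0
    for leaflet, sign in (("U", 1.0), ("L", -1.0)):
        placed = 0
        for gy in range(grid):
            for gx in range(grid):
                if placed >= n:
                    break
                resid += 1
                placed += 1
                x = (gx + 0.5) * pitch
                y = (gy + 0.5) * pitch
                zh = sign * spec.thickness / 2
                if spec.leaflet_z_jitter > 0:
                    zh += rng.normal(0.0, spec.leaflet_z_jitter)
                names.append("P")
                resnames.append("LIP")
                resids.append(resid)
                chains.append(leaflet)
                elements.append("P")
                pos.append([x, y, zh])
                for t in range(spec.tail_atoms_per_lipid):
                    names.append(f"T{t + 1}")
                    resnames.append("LIP")
                    resids.append(resid)
                    chains.append(leaflet)
                    elements.append("C")
                    pos.append([x, y, zh - sign * (t + 1) * tail_spacing])
    box_z = spec.thickness + 40.0
    return Frame(
        names=names,
        resnames=resnames,
        resids=resids,
        chains=chains,
        elements=elements,
        positions=np.array(pos),
        box=np.array([box_l, box_l, box_z]),
        time=time,
    )


def make_bilayer(spec: BilayerSpec) -> tuple[Frame, BilayerGroundTruth]:
    """Single bilayer frame plus its planted geometry."""
    rng = np.random.default_rng(spec.seed)
    frame = _bilayer_frame(spec, rng, time=0.0)
    return frame, BilayerGroundTruth(
        thickness=spec.thickness,
        area_per_lipid=spec.area_per_lipid,
        n_lipids_per_leaflet=spec.n_lipids_per_leaflet,
    )


def make_bilayer_trajectory(
    spec: BilayerSpec, n_frames: int, dt: float = 1.0
) -> tuple[Trajectory, BilayerGroundTruth]:
    """Bilayer trajectory with per-frame resampled head-group jitter."""
    rng = np.random.default_rng(spec.seed)
    frames = [_bilayer_frame(spec, rng, time=k * dt) for k in range(n_frames)]
    truth = BilayerGroundTruth(
        thickness=spec.thickness,
        area_per_lipid=spec.area_per_lipid,
        n_lipids_per_leaflet=spec.n_lipids_per_leaflet,
    )
    return Trajectory(frames, topology_source="synthetic-bilayer"), truth


# ----------------------------------------------------------------------
# Pore traces
# ----------------------------------------------------------------------

@dataclass
class PoreTraceSpec:
    """Prescribed filter-site ion schedule and cavity water counts.

    ``site_boundaries`` lists ``(name, z_lo, z_hi)`` intervals along the
    pore (z) axis, ordered and non-overlapping, extracellular side up
    (S0 topmost).  ``ion_site_schedule`` is an (n_frames, n_ions) array
    of site names (or ``None`` for "outside the filter").  Waters are
    placed uniformly inside the cavity cylinder except during
    ``dewetting_intervals`` (inclusive frame intervals), where the count
    drops to ``dewet_count``; displaced waters are parked outside the
    cylinder so the atom count stays constant.
    """

    site_boundaries: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("S0", 12.0, 15.0),
            ("S1", 9.0, 12.0),
            ("S2", 6.0, 9.0),
            ("S3", 3.0, 6.0),
            ("S4", 0.0, 3.0),
        ]
    )
    ion_site_schedule: list[list[str | None]] = field(default_factory=list)
    water_counts: list[int] = field(default_factory=list)
    dewetting_intervals: list[tuple[int, int]] = field(default_factory=list)
    cavity_z: tuple[float, float] = (-12.0, 0.0)
    cylinder_radius: float = 5.0
    dewet_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ion_site_schedule:
            raise K2PFlexError("ion_site_schedule must not be empty")
        n = len(self.ion_site_schedule)
        if self.water_counts and len(self.water_counts) != n:
            raise K2PFlexError(
                f"water_counts length {len(self.water_counts)} != "
                f"{n} scheduled frames"
            )
        prev_lo = None
        for name, lo, hi in self.site_boundaries:
            if hi <= lo:
                raise K2PFlexError(f"site {name}: empty interval [{lo}, {hi}]")
            if prev_lo is not None and hi > prev_lo:
                raise K2PFlexError(
                    "site intervals must be ordered top (S0) to bottom and "
                    f"non-overlapping; {name} violates this"
                )
            prev_lo = lo  # next site must lie entirely below this one
        for lo, hi in self.dewetting_intervals:
            if not (0 <= lo <= hi < n):
                raise K2PFlexError(f"dewetting interval [{lo}, {hi}] outside 0..{n - 1}")


@dataclass
class PoreGroundTruth:
    site_occupancy: dict[str, float]
    water_counts: np.ndarray
    dewetting_intervals: list[tuple[int, int]]
    n_ions: int

    def to_dict(self) -> dict:
        return {
            "site_occupancy": self.site_occupancy,
            "water_counts": self.water_counts.tolist(),
            "dewetting_intervals": [list(iv) for iv in self.dewetting_intervals],
            "n_ions": self.n_ions,
        }


def make_pore_trace(spec: PoreTraceSpec) -> tuple[Trajectory, PoreGroundTruth]:
    """Ion/water trajectory realising a prescribed occupancy schedule."""
    rng = np.random.default_rng(spec.seed)
    n_frames = len(spec.ion_site_schedule)
    n_ions = len(spec.ion_site_schedule[0])
    centres = {name: 0.5 * (lo + hi) for name, lo, hi in spec.site_boundaries}
    site_names = [name for name, _, _ in spec.site_boundaries]

    counts = np.array(
        spec.water_counts if spec.water_counts else [10] * n_frames, dtype=int
    )
    for lo, hi in spec.dewetting_intervals:
        counts[lo : hi + 1] = spec.dewet_count
    n_waters = int(counts.max()) if counts.size else 0
    n_waters = max(n_waters, 1)

    z_lo, z_hi = spec.cavity_z
    box = np.array([60.0, 60.0, 80.0])
    axis_xy = box[:2] / 2

    # occupancy truth from the schedule: fraction of frames with >= 1 ion
    occ = {name: 0 for name in site_names}
    for row in spec.ion_site_schedule:
        for name in set(s for s in row if s is not None):
            if name not in centres:
                raise K2PFlexError(f"scheduled site {name!r} is not defined")
            occ[name] += 1
    occupancy = {name: occ[name] / n_frames for name in site_names}

    frames = []
    for k in range(n_frames):
        names, resnames, resids, chains, elements = [], [], [], [], []
        pos = []
        for j, site in enumerate(spec.ion_site_schedule[k]):
            z = centres[site] if site is not None else box[2] / 2 - 5.0
            names.append("K")
            resnames.append("K")
            resids.append(j + 1)
            chains.append("I")
            elements.append("K")
            pos.append([axis_xy[0], axis_xy[1], z])
        c = int(counts[k])
        for w in range(n_waters):
            names.append("OW")
            resnames.append("SOL")
            resids.append(100 + w)
            chains.append("W")
            elements.append("O")
            if w < c:  # inside the cavity cylinder
                r = spec.cylinder_radius * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                z = rng.uniform(z_lo, z_hi)
                pos.append([axis_xy[0] + r * np.cos(th), axis_xy[1] + r * np.sin(th), z])
            else:  # parked well outside the cylinder
                th = rng.uniform(0, 2 * np.pi)
                r = spec.cylinder_radius * 3 + rng.uniform(0, 5)
                z = rng.uniform(z_lo, z_hi)
                pos.append([axis_xy[0] + r * np.cos(th), axis_xy[1] + r * np.sin(th), z])
        frames.append(
            Frame(
                names=names,
                resnames=resnames,
                resids=resids,
                chains=chains,
                elements=elements,
                positions=np.array(pos),
                box=box.copy(),
                time=float(k),
            )
        )
    truth = PoreGroundTruth(
        site_occupancy=occupancy,
        water_counts=counts,
        dewetting_intervals=list(spec.dewetting_intervals),
        n_ions=n_ions,
    )
    return Trajectory(frames, topology_source="synthetic-pore"), truth


# ----------------------------------------------------------------------
# Force systems for the local-stress module
# ----------------------------------------------------------------------

@dataclass
class PairForces:
    """Per-frame pairwise force tables.

    ``pairs[k]`` is an (P, 2) int array of atom indices for frame k and
    ``forces[k]`` the matching (P, 3) array of forces **on atom i due to
    atom j**, in kJ/mol/Å.  Each interacting pair appears once.
    """

    pairs: list[np.ndarray]
    forces: list[np.ndarray]

    def write(self, path: str | Path) -> None:
        """Columnar text table: frame i j fx fy fz (kJ/mol/nm)."""
        with open(path, "w") as fh:
            fh.write("# frame i j fx fy fz (kJ/mol/nm)\n")
            for k, (p, f) in enumerate(zip(self.pairs, self.forces)):
                for (i, j), (fx, fy, fz) in zip(p, f):
                    fh.write(
                        f"{k} {i} {j} {fx * 10:.8e} {fy * 10:.8e} {fz * 10:.8e}\n"
                    )

    @classmethod
    def read(cls, path: str | Path, n_frames: int) -> "PairForces":
        rows: dict[int, list] = {k: [] for k in range(n_frames)}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split()
                k = int(parts[0])
                rows[k].append(
                    (int(parts[1]), int(parts[2]),
                     float(parts[3]) / 10, float(parts[4]) / 10, float(parts[5]) / 10)
                )
        pairs, forces = [], []
        for k in range(n_frames):
            if rows[k]:
                arr = np.array(rows[k], dtype=float)
                pairs.append(arr[:, :2].astype(int))
                forces.append(arr[:, 2:])
            else:
                pairs.append(np.empty((0, 2), dtype=int))
                forces.append(np.empty((0, 3)))
        return cls(pairs=pairs, forces=forces)


@dataclass
class ForceSystemSpec:
    """Particle system with analytically known forces.

    kinds: ``ideal_gas`` (no pair forces, Maxwell-Boltzmann velocities),
    ``harmonic_pair`` (two particles, f = -k (r - r0) r̂, optional fixed
    separation), ``lj_fluid`` (truncated Lennard-Jones).  Positions are
    resampled independently every frame; there is no integration.
    Units: Å, ps, amu, kJ/mol.
    """

    kind: str = "ideal_gas"
    n_particles: int = 200
    temperature: float = 310.0
    box: tuple[float, float, float] = (30.0, 30.0, 30.0)
    mass: float = 39.948  # amu
    spring_k: float = 10.0  # kJ/mol/Å^2
    rest_length: float = 3.0  # Å
    separation: float | None = None  # harmonic pair; None -> resampled
    epsilon: float = 1.0  # kJ/mol
    sigma: float = 3.4  # Å
    cutoff: float = 8.5  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ideal_gas", "harmonic_pair", "lj_fluid"):
            raise K2PFlexError(f"unknown force-system kind: {self.kind!r}")
        if self.temperature <= 0:
            raise K2PFlexError("temperature must be > 0")


@dataclass
class ForceGroundTruth:
    kind: str
    temperature: float
    number_density: float  # particles / Å^3
    kinetic_pressure_bar: float  # rho k T, ideal contribution

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "temperature_K": self.temperature,
            "number_density_per_A3": self.number_density,
            "kinetic_pressure_bar": self.kinetic_pressure_bar,
        }


# kJ/mol/Å^3 -> bar (= 16.6054 bar per kJ/mol/nm^3, scaled by 10^3)
PRESSURE_UNIT_BAR = 16.605390671738466e3


def _mb_velocities(rng, n, temperature, mass) -> np.ndarray:
    # kB T / m in kJ/mol/amu = nm^2/ps^2; x100 -> Å^2/ps^2
    sd = np.sqrt(KB_KJ_MOL_K * temperature / mass) * 10.0
    return rng.normal(0.0, sd, size=(n, 3))


def _lj_forces(pos: np.ndarray, box: np.ndarray, eps, sig, cutoff):
    n = pos.shape[0]
    pairs, forces = [], []
    for i in range(n - 1):
        d = pos[i] - pos[i + 1 :]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        sel = np.flatnonzero((r < cutoff) & (r > 1e-8))
        for s in sel:
            j = i + 1 + s
            rr = r[s]
            sr6 = (sig / rr) ** 6
            fmag = 24 * eps * (2 * sr6**2 - sr6) / rr  # dU/dr with sign folded in
            forces.append(fmag * d[s] / rr)  # force on i due to j
            pairs.append((i, j))
    if pairs:
        return np.array(pairs, dtype=int), np.array(forces)
    return np.empty((0, 2), dtype=int), np.empty((0, 3))


def make_force_system(
    spec: ForceSystemSpec, n_frames: int
) -> tuple[Trajectory, PairForces, ForceGroundTruth]:
    """Trajectory with velocities plus exact per-frame pair-force tables."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    vol = float(np.prod(box))
    n = 2 if spec.kind == "harmonic_pair" else spec.n_particles

    frames, pair_list, force_list = [], [], []
    for k in range(n_frames):
        if spec.kind == "harmonic_pair":
            if spec.separation is not None:
                r = spec.separation
            else:
                r = spec.rest_length + rng.normal(0.0, 0.5)
            base = rng.uniform(0, box[2])
            # pair aligned with z so its virial spans several z-bins
            pos = np.array(
                [
                    [box[0] / 2, box[1] / 2, base % box[2]],
                    [box[0] / 2, box[1] / 2, (base + r) % box[2]],
                ]
            )
            vel = np.zeros((2, 3))
            # force on particle 0 due to 1: separation vector points -z
            d01 = pos[0] - pos[1]
            d01 -= box * np.round(d01 / box)
            dist = np.linalg.norm(d01)
            f0 = -spec.spring_k * (dist - spec.rest_length) * d01 / dist
            pairs = np.array([[0, 1]], dtype=int)
            forces = f0[None, :]
        else:
            pos = rng.uniform(0, 1, size=(n, 3)) * box
            vel = _mb_velocities(rng, n, spec.temperature, spec.mass)
            if spec.kind == "ideal_gas":
                pairs = np.empty((0, 2), dtype=int)
                forces = np.empty((0, 3))
            else:
                pairs, forces = _lj_forces(pos, box, spec.epsilon, spec.sigma, spec.cutoff)
        frames.append(
            Frame(
                names=["AR"] * n,
                resnames=["AR"] * n,
                resids=list(range(1, n + 1)),
                chains=["X"] * n,
                elements=["AR"] * n,
                positions=pos,
                box=box.copy(),
                time=float(k),
                velocities=vel,
                masses=np.full(n, spec.mass),
            )
        )
        pair_list.append(pairs)
        force_list.append(forces)

    density = n / vol
    truth = ForceGroundTruth(
        kind=spec.kind,
        temperature=spec.temperature,
        number_density=density,
        kinetic_pressure_bar=density * KB_KJ_MOL_K * spec.temperature * PRESSURE_UNIT_BAR / 1.0,
    )
    return (
        Trajectory(frames, topology_source=f"synthetic-{spec.kind}"),
        PairForces(pairs=pair_list, forces=force_list),
        truth,
    )


def write_ground_truth(truth, path: str | Path) -> None:
    """JSON sidecar for any generator's ground truth."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
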