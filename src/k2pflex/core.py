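"""Core domain types shared by every analysis stage.

A :class:`Frame` is a column-oriented snapshot of a molecular system
(positions in Å, optional velocities in Å/ps, an orthorhombic periodic
box) together with the topology labels needed for residue-level
selections: atom names, residue names, author residue numbers and chain
identifiers.  A :class:`Trajectory` is a time-ordered sequence of frames
with a constant atom count.

Residue numbers throughout the package are PDB *author* numbers (so
``resid 324`` means the residue the depositors called 324), never an
internal 0-based index.  Internal indices exist only as return values of
:func:`select` and are never written to reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "K2PFlexError",
    "SelectionError",
    "StructureError",
    "TrajectoryError",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SelectionSpec",
    "select",
    "min_image_displacement",
    "min_image_distance",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "vdw_radius",
]


class K2PFlexError(Exception):
    """Base class for all package errors."""


class SelectionError(K2PFlexError):
    """An atom selection matched nothing or was ambiguous."""


class StructureError(K2PFlexError):
    """A structure file or Frame violates an invariant."""


class TrajectoryError(K2PFlexError):
    """A trajectory file or Trajectory violates an invariant."""


# Bondi-style van der Waals radii (Å).  Used by the cross-sectional area
# module; the table id is recorded in output metadata so the radii behind
# any reported area are auditable.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "K": 2.75,
    "NA": 2.27,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_VDW_RADIUS: float = 1.70
VDW_TABLE_ID = "bondi-2013"


def vdw_radius(element: str) -> float:
    """Radius for an element symbol; unknown elements get 1.7 Å."""
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)


@dataclass
class AtomRecord:
    """One atom: identity labels plus coordinates (Å)."""

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    position: np.ndarray
    vdw_radius: float | None = None
    mass: float | None = None
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise StructureError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.serial}: non-finite position")
        if self.vdw_radius is None:
            self.vdw_radius = vdw_radius(self.element)
        if self.vdw_radius <= 0:
            raise StructureError(f"atom {self.serial}: vdw radius must be > 0")
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=float)


class Frame:
    """A single snapshot, stored column-wise for vectorised analysis.

    Parameters
    ----------
    names, resnames, chains, elements : sequences of str
    resids : sequence of int (author numbering)
    positions : (N, 3) array, Å
    box : optional 3-vector of orthorhombic box lengths, Å
    time : frame time, ps
    velocities : optional (N, 3) array, Å/ps
    masses : optional (N,) array, amu
    """

    def __init__(
        self,
        *,
        names: Sequence[str],
        resnames: Sequence[str],
        resids: Sequence[int],
        chains: Sequence[str],
        elements: Sequence[str],
        positions: np.ndarray,
        box: np.ndarray | None = None,
        time: float = 0.0,
        velocities: np.ndarray | None = None,
        masses: np.ndarray | None = None,
        serials: Sequence[int] | None = None,
        radii: np.ndarray | None = None,
    ) -> None:
        self.names = np.asarray(names, dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resids = np.asarray(resids, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        for arr, label in (
            (self.names, "names"),
            (self.resnames, "resnames"),
            (self.resids, "resids"),
            (self.chains, "chains"),
            (self.elements, "elements"),
        ):
            if arr.shape[0] != n:
                raise StructureError(f"{label} length {arr.shape[0]} != {n} atoms")
        if not np.all(np.isfinite(self.positions)):
            raise StructureError("non-finite coordinates")
        if box is not None:
            box = np.asarray(box, dtype=float).reshape(3)
            if np.any(box <= 0):
                raise StructureError(f"box lengths must be > 0, got {box}")
        self.box = box
        self.time = float(time)
        self.velocities = (
            None if velocities is None else np.asarray(velocities, dtype=float).reshape(-1, 3)
        )
        if self.velocities is not None and self.velocities.shape[0] != n:
            raise StructureError("velocity array length mismatch")
        self.masses = None if masses is None else np.asarray(masses, dtype=float).reshape(-1)
        if self.masses is not None and self.masses.shape[0] != n:
            raise StructureError("mass array length mismatch")
        self.serials = (
            np.arange(1, n + 1) if serials is None else np.asarray(serials, dtype=int)
        )
        if radii is None:
            self.radii = np.array([vdw_radius(e) for e in self.elements], dtype=float)
        else:
            self.radii = np.asarray(radii, dtype=float).reshape(-1)

    # ------------------------------------------------------------------
    @classmethod
    def from_atoms(
        cls,
        atoms: Sequence[AtomRecord],
        box: np.ndarray | None = None,
        time: float = 0.0,
    ) -> "Frame":
        if len(atoms) == 0:
            raise StructureError("empty atom list")
        has_vel = all(a.velocity is not None for a in atoms)
        has_mass = all(a.mass is not None for a in atoms)
        return cls(
            names=[a.name for a in atoms],
            resnames=[a.resname for a in atoms],
            resids=[a.resid for a in atoms],
            chains=[a.chain for a in atoms],
            elements=[a.element for a in atoms],
            positions=np.array([a.position for a in atoms], dtype=float),
            box=box,
            time=time,
            velocities=np.array([a.velocity for a in atoms]) if has_vel else None,
            masses=np.array([a.mass for a in atoms]) if has_mass else None,
            serials=[a.serial for a in atoms],
            radii=np.array([a.vdw_radius for a in atoms], dtype=float),
        )

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                resname=str(self.resnames[i]),
                resid=int(self.resids[i]),
                chain=str(self.chains[i]),
                element=str(self.elements[i]),
                position=self.positions[i].copy(),
                vdw_radius=float(self.radii[i]),
                mass=None if self.masses is None else float(self.masses[i]),
                velocity=None if self.velocities is None else self.velocities[i].copy(),
            )

    def copy(self) -> "Frame":
        return Frame(
            names=self.names.copy(),
            resnames=self.resnames.copy(),
            resids=self.resids.copy(),
            chains=self.chains.copy(),
            elements=self.elements.copy(),
            positions=self.positions.copy(),
            box=None if self.box is None else self.box.copy(),
            time=self.time,
            velocities=None if self.velocities is None else self.velocities.copy(),
            masses=None if self.masses is None else self.masses.copy(),
            serials=self.serials.copy(),
            radii=self.radii.copy(),
        )

    def require_box(self) -> np.ndarray:
        if self.box is None:
            raise StructureError("this analysis requires periodic box dimensions")
        return self.box

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Frame {self.n_atoms} atoms, t={self.time} ps>"


class Trajectory:
    """Time-ordered sequence of frames with constant atom count."""

    def __init__(self, frames: Sequence[Frame], topology_source: str = "") -> None:
        if len(frames) == 0:
            raise TrajectoryError("trajectory must contain at least one frame")
        n = frames[0].n_atoms
        times = [f.time for f in frames]
        for f in frames:
            if f.n_atoms != n:
                raise TrajectoryError(
                    f"atom count changed across frames ({n} vs {f.n_atoms})"
                )
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrajectoryError("frame times must be strictly increasing")
        self.frames = list(frames)
        self.topology_source = topology_source

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Trajectory {len(self.frames)} frames, "
            f"{self.frames[0].n_atoms} atoms>"
        )


@dataclass
class SelectionSpec:
    """Declarative atom selection on author residue numbering.

    All supplied criteria are ANDed.  ``resid_ranges`` is a list of
    inclusive ``[lo, hi]`` intervals, ORed among themselves.
    """

    chain: str | None = None
    resid_ranges: list[tuple[int, int]] = field(default_factory=list)
    atom_names: list[str] | None = None
    resnames: list[str] | None = None
    exclude_names: list[str] | None = None

    def describe(self) -> str:
        parts = []
        if self.chain is not None:
            parts.append(f"chain={self.chain}")
        if self.resid_ranges:
            parts.append(f"resids={self.resid_ranges}")
        if self.atom_names:
            parts.append(f"names={self.atom_names}")
        if self.resnames:
            parts.append(f"resnames={self.resnames}")
        if self.exclude_names:
            parts.append(f"exclude={self.exclude_names}")
        return ", ".join(parts) if parts else "all atoms"


def select(frame: Frame, spec: SelectionSpec) -> np.ndarray:
    """Indices (topology order) of atoms matching *spec*.

    Raises :class:`SelectionError` when nothing matches — a silent empty
    selection would propagate as an empty analysis, which is never what
    the caller meant.
    """
    mask = np.ones(frame.n_atoms, dtype=bool)
    if spec.chain is not None:
        mask &= frame.chains == spec.chain
    if spec.resid_ranges:
        rmask = np.zeros(frame.n_atoms, dtype=bool)
        for lo, hi in spec.resid_ranges:
            rmask |= (frame.resids >= lo) & (frame.resids <= hi)
        mask &= rmask
    if spec.atom_names is not None:
        mask &= np.isin(frame.names, np.asarray(spec.atom_names, dtype=object))
    if spec.resnames is not None:
        mask &= np.isin(frame.resnames, np.asarray(spec.resnames, dtype=object))
    if spec.exclude_names is not None:
        mask &= ~np.isin(frame.names, np.asarray(spec.exclude_names, dtype=object))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection matched no atoms: {spec.describe()}")
    return idx


def min_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Minimum-image displacement ``a - b`` for an orthorhombic box.

    Broadcasts over leading dimensions; ``box=None`` means no wrapping.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        if np.any(box <= 0):
            raise StructureError(f"box lengths must be > 0, got {box}")
        d = d - box * np.round(d / box)
    return d


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    """Euclidean distance under the minimum-image convention."""
    d = min_image_displacement(a, b, box)
    return float(np.linalg.norm(d, axis=-1)) if d.ndim == 1 else np.linalg.norm(d, axis=-1)
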