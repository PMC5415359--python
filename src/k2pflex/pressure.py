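"""Local stress tensor on a z-grid and the lateral pressure profile.

The local stress follows the Hardy / Irving-Kirkwood-Noll construction
for pairwise-additive forces.  For a slab (bin) *b* of volume ``V_b``::

    sigma(b) = -(1/V_b) [ sum_{i in b} m_i v_i (x) v_i
                          + sum_{pairs (i,j)} w_b(i,j) r_ij (x) f_ij ]

where ``f_ij`` is the force on *i* due to *j*, ``r_ij`` the
minimum-image separation, and ``w_b(i,j)`` the fraction of the straight
minimum-image segment between the two particles that lies in bin *b*
(the Irving-Kirkwood contour with a top-hat bond function).  The
weights form a partition of unity, so the volume-weighted bin sum
reproduces the whole-box virial stress exactly — the invariant the test
suite checks.

The lateral pressure profile is then ``P = -sigma`` per bin with

    P_par(z)  = (P_xx(z) + P_yy(z)) / 2
    P_perp(z) = P_zz(z)
    P_L(z)    = P_par(z) - P_perp(z)

and the surface tension gamma = -integral P_L(z) dz.

Forces are consumed, not computed: every frame needs a pair-force table
(see :class:`~k2pflex.synthetic.PairForces`) except in the ideal-gas
case.  If velocities are absent the kinetic term may be replaced by the
ideal thermal term rho(z) kT I at a user-supplied temperature; the
substitution is recorded in the result's metadata.

Units: positions Å, velocities Å/ps, masses amu, forces kJ/mol/Å;
stresses and pressures are reported in bar (1 kJ/mol/nm³ = 16.6054 bar).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import K2PFlexError, Trajectory
from .synthetic import KB_KJ_MOL_K, PairForces

__all__ = [
    "StressField",
    "PressureProfile",
    "ProfileComparison",
    "local_stress",
    "global_stress",
    "pressure_profile",
    "compare_profiles",
    "segment_bin_weights",
    "BAR_PER_KJ_MOL_A3",
]

# 16.6054 bar per kJ/mol/nm^3, times 10^3 nm^3/Å^3
BAR_PER_KJ_MOL_A3 = 16.605390671738466e3
_A2_PER_NM2 = 0.01  # amu Å²/ps² -> kJ/mol


@dataclass
class StressField:
    """Frame-averaged per-bin stress tensors (bar) on a z-grid (Å)."""

    edges: np.ndarray  # n_bins + 1 edges, Å
    sigma: np.ndarray  # (n_bins, 3, 3), bar
    bin_volume: float  # Å^3
    n_frames: int
    kinetic_mode: str  # "velocities" | "thermal"
    metadata: dict = field(default_factory=dict)

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def segment_bin_weights(
    z_start: float, dz: float, n_bins: int, lz: float
) -> np.ndarray:
    """Fraction of the segment ``[z_start, z_start + dz]`` per z-bin.

    The segment wraps periodically (|dz| <= lz/2 under minimum image);
    the weights always sum to one exactly.
    """
    h = lz / n_bins
    w = np.zeros(n_bins)
    length = abs(dz)
    if length < 1e-12:
        w[int((z_start % lz) / h) % n_bins] = 1.0
        return w
    lo = (min(z_start, z_start + dz)) % lz
    pieces = []
    if lo + length <= lz:
        pieces.append((lo, lo + length))
    else:
        pieces.append((lo, lz))
        pieces.append((0.0, lo + length - lz))
    left = np.arange(n_bins) * h
    right = left + h
    for u, v in pieces:
        w += np.clip(np.minimum(v, right) - np.maximum(u, left), 0.0, None)
    return w / length


def _pair_weight_matrix(
    z0: np.ndarray, dz: np.ndarray, n_bins: int, lz: float
) -> np.ndarray:
    """Vectorised :func:`segment_bin_weights` for P pairs -> (P, n_bins)."""
    h = lz / n_bins
    length = np.abs(dz)
    lo = np.where(dz < 0, z0 + dz, z0) % lz
    hi1 = np.minimum(lo + length, lz)
    lo2 = np.zeros_like(lo)
    hi2 = np.maximum(lo + length - lz, 0.0)
    left = np.arange(n_bins) * h
    right = left + h
    w = np.clip(np.minimum(hi1[:, None], right) - np.maximum(lo[:, None], left), 0, None)
    w += np.clip(np.minimum(hi2[:, None], right) - np.maximum(lo2[:, None], left), 0, None)
    degenerate = length < 1e-12
    if degenerate.any():
        w[degenerate] = 0.0
        idx = ((z0[degenerate] % lz) / h).astype(int) % n_bins
        w[np.flatnonzero(degenerate), idx] = 1.0
        length = np.where(degenerate, 1.0, length)
    return w / length[:, None]


def _resolve_bins(lz: float, bin_width: float) -> int:
    n = max(1, int(round(lz / bin_width)))
    if abs(n * bin_width - lz) > 1e-6 * lz:
        warnings.warn(
            f"bin width {bin_width} Å does not divide the box height {lz} Å; "
            f"using {n} bins of {lz / n:.6f} Å",
            stacklevel=3,
        )
    return n


def local_stress(
    traj: Trajectory,
    forces: PairForces | None = None,
    bin_width: float = 1.0,
    kinetic_mode: str = "velocities",
    temperature: float | None = None,
) -> StressField:
    """Frame-averaged Hardy/IK local stress on a z-grid.

    Parameters
    ----------
    forces
        Per-frame pair-force tables; may be ``None`` only for systems
        without interactions.
    bin_width
        Target slab width in Å (the bilayer-profile convention is 1 Å,
        i.e. 0.1 nm); edges are rescaled to divide the box exactly.
    kinetic_mode
        ``"velocities"`` uses the recorded velocities and masses;
        ``"thermal"`` substitutes the ideal term rho(z) kT I at
        *temperature* (for trajectories stored without velocities).
    """
    if kinetic_mode not in ("velocities", "thermal"):
        raise K2PFlexError(f"unknown kinetic mode: {kinetic_mode!r}")
    if kinetic_mode == "thermal" and temperature is None:
        raise K2PFlexError("thermal kinetic mode requires a temperature")
    first = traj[0]
    box = first.require_box()
    lz = float(box[2])
    n_bins = _resolve_bins(lz, bin_width)
    h = lz / n_bins
    area = float(box[0] * box[1])
    v_bin = area * h

    acc = np.zeros((n_bins, 3, 3))  # kJ/mol, summed over frames
    for k, frame in enumerate(traj):
        fbox = frame.require_box()
        if not np.allclose(fbox, box):
            raise K2PFlexError("local stress assumes a constant box across frames")
        z = frame.positions[:, 2] % lz
        bins = np.minimum((z / h).astype(int), n_bins - 1)
        if kinetic_mode == "velocities":
            if frame.velocities is None or frame.masses is None:
                raise K2PFlexError(
                    f"frame {k}: kinetic term requires velocities and masses "
                    "(or use kinetic_mode='thermal')"
                )
            vv = frame.velocities[:, :, None] * frame.velocities[:, None, :]
            contrib = frame.masses[:, None, None] * vv * _A2_PER_NM2
            np.add.at(acc, bins, contrib)
        else:
            kt = KB_KJ_MOL_K * float(temperature)
            counts = np.bincount(bins, minlength=n_bins).astype(float)
            acc += counts[:, None, None] * (kt * np.eye(3))

        if forces is not None and len(forces.pairs[k]):
            pairs = forces.pairs[k]
            f = forces.forces[k]
            ri = frame.positions[pairs[:, 0]]
            rj = frame.positions[pairs[:, 1]]
            rij = ri - rj
            rij -= box * np.round(rij / box)
            outer = rij[:, :, None] * f[:, None, :]
            w = _pair_weight_matrix(rj[:, 2] % lz, rij[:, 2], n_bins, lz)
            acc += np.einsum("pb,pij->bij", w, outer)

    sigma = -acc / (v_bin * len(traj)) * BAR_PER_KJ_MOL_A3
    return StressField(
        edges=np.arange(n_bins + 1) * h,
        sigma=sigma,
        bin_volume=v_bin,
        n_frames=len(traj),
        kinetic_mode=kinetic_mode,
        metadata={
            "bin_width_A": h,
            "unit_conversion_bar_per_kJ_mol_A3": BAR_PER_KJ_MOL_A3,
            "temperature_K": temperature,
        },
    )


def global_stress(traj: Trajectory, forces: PairForces | None = None) -> np.ndarray:
    """Whole-box virial + kinetic stress (bar), frame-averaged.

    Computed directly without any spatial binning; serves as the
    independent conservation oracle for :func:`local_stress`.
    """
    first = traj[0]
    box = first.require_box()
    vol = float(np.prod(box))
    acc = np.zeros((3, 3))
    for k, frame in enumerate(traj):
        if frame.velocities is not None and frame.masses is not None:
            vv = frame.velocities[:, :, None] * frame.velocities[:, None, :]
            acc += (frame.masses[:, None, None] * vv).sum(axis=0) * _A2_PER_NM2
        if forces is not None and len(forces.pairs[k]):
            pairs = forces.pairs[k]
            f = forces.forces[k]
            rij = frame.positions[pairs[:, 0]] - frame.positions[pairs[:, 1]]
            rij -= box * np.round(rij / box)
            acc += np.einsum("pi,pj->ij", rij, f)
    return -acc / (vol * len(traj)) * BAR_PER_KJ_MOL_A3


@dataclass
class PressureProfile:
    """Lateral pressure profile P_L(z) = P_par(z) - P_perp(z), bar."""

    z: np.ndarray  # bin centres, Å
    p_xx: np.ndarray
    p_yy: np.ndarray
    p_zz: np.ndarray
    n_frames: int
    metadata: dict = field(default_factory=dict)

    @property
    def p_parallel(self) -> np.ndarray:
        return 0.5 * (self.p_xx + self.p_yy)

    @property
    def p_perp(self) -> np.ndarray:
        return self.p_zz

    @property
    def p_lateral(self) -> np.ndarray:
        return self.p_parallel - self.p_perp

    @property
    def surface_tension(self) -> float:
        """gamma = -integral P_L dz, in bar·Å (trapezoidal)."""
        return float(-np.trapezoid(self.p_lateral, self.z))

    @property
    def surface_tension_mN_per_m(self) -> float:
        return self.surface_tension * 0.01  # 1 bar·Å = 0.01 mN/m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_nm": self.z / 10.0,
                "Pxx_bar": self.p_xx,
                "Pyy_bar": self.p_yy,
                "Pzz_bar": self.p_zz,
                "P_par_bar": self.p_parallel,
                "P_perp_bar": self.p_perp,
                "P_L_bar": self.p_lateral,
            }
        )


def pressure_profile(field: StressField) -> PressureProfile:
    """Extract the pressure components (P = -sigma) from a stress field."""
    p = -field.sigma
    return PressureProfile(
        z=field.centres,
        p_xx=p[:, 0, 0],
        p_yy=p[:, 1, 1],
        p_zz=p[:, 2, 2],
        n_frames=field.n_frames,
        metadata=dict(field.metadata, kinetic_mode=field.kinetic_mode),
    )


@dataclass
class ProfileComparison:
    """Per-bin P_L difference (b - a) and region-integrated changes."""

    z: np.ndarray
    delta_p_lateral: np.ndarray  # bar
    region_change: dict[str, float]  # bar·Å, integral of delta over region

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z, "dP_L_bar": self.delta_p_lateral})


DEFAULT_REGIONS = {
    "core": (-10.0, 10.0),
    "interface_lower": (-25.0, -10.0),
    "interface_upper": (10.0, 25.0),
}


def compare_profiles(
    a: PressureProfile,
    b: PressureProfile,
    regions: dict[str, tuple[float, float]] | None = None,
    resample: bool = False,
) -> ProfileComparison:
    """Difference profile ``b - a`` with region-integrated changes.

    Grids must match unless *resample* is set, in which case the finer
    profile is linearly interpolated onto the coarser grid.  Regions are
    z-intervals in Å on the common grid (defaults: bilayer core and the
    two interfacial bands).
    """
    if a.z.shape == b.z.shape and np.allclose(a.z, b.z):
        z, pa, pb = a.z, a.p_lateral, b.p_lateral
    elif resample:
        fine, coarse = (a, b) if a.z.size >= b.z.size else (b, a)
        z = coarse.z
        interp = np.interp(z, fine.z, fine.p_lateral)
        pa = interp if fine is a else coarse.p_lateral
        pb = coarse.p_lateral if fine is a else interp
    else:
        raise K2PFlexError(
            "pressure profiles are on different grids; pass resample=True"
        )
    delta = pb - pa
    changes = {}
    for name, (lo, hi) in (regions or DEFAULT_REGIONS).items():
        mask = (z >= lo) & (z <= hi)
        changes[name] = (
            float(np.trapezoid(delta[mask], z[mask])) if mask.sum() > 1 else 0.0
        )
    return ProfileComparison(z=z, delta_p_lateral=delta, region_change=changes)
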