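"""Seedable rigid-body trajectory generator.

Emulates the statistical structure the analysis consumes — a donor-acceptor
pair at a controlled separation with controlled dipole orientations — so the
whole pipeline is testable without MD output.  The defaults mirror a 5 ns
production run sampled every picosecond (5000 frames, dt = 1 ps) at the
wild-type mean donor-acceptor distance of 9.14 Å; these are statistical
stand-ins only — no force field, no dynamics, no chemistry is claimed.

Orientation models
------------------
frozen
    Both dipoles constant (defaults collinear with the separation axis: the
    maximal-orientation regime, kappa^2 = 4 in every frame).
isotropic
    Each dipole drawn independently, uniformly on the unit sphere, per
    frame; the kappa^2 mean converges to the classic isotropic value 2/3.
cone
    Each dipole uniform within a cone of given half-angle about +z; the
    half-angle -> 180 deg limit recovers the isotropic mean.

Sphere/cone sampling uses the inverse-CDF scheme cos(theta) = 1 - u*(1 -
cos(alpha)), phi = 2*pi*v with u, v consecutive draws from
``numpy.random.default_rng(seed)`` (alpha = 180 deg for the full sphere), so
an independent oracle can replay the exact draws from the seed.  Draw
order per trajectory: distances first (uniform model only), then all donor
dipoles, then all acceptor dipoles.

The separation vector points along +x; its length follows the distance
model (fixed value, uniform range, or strict two-state alternation
R1, R2, R1, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .fret_core import DipoleFrame

__all__ = [
    "FixedDistance",
    "UniformDistance",
    "TwoStateDistance",
    "SyntheticModel",
    "generate",
    "sample_unit_sphere",
    "sample_cone",
    "write_dipole_csv",
    "read_dipole_csv",
    "write_pdb",
]


@dataclass(frozen=True)
class FixedDistance:
    """Constant donor-acceptor distance (Å)."""

    r: float

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError(f"distance must be positive, got {self.r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, self.r)


@dataclass(frozen=True)
class UniformDistance:
    """Distance uniform in [lo, hi] Å, independent per frame."""

    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo <= self.hi:
            raise ValueError(f"need 0 < lo <= hi, got ({self.lo}, {self.hi})")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * rng.random(n)


@dataclass(frozen=True)
class TwoStateDistance:
    """Deterministic alternation r1, r2, r1, r2, ... (Å)."""

    r1: float
    r2: float

    def __post_init__(self):
        if not (self.r1 > 0 and self.r2 > 0):
            raise ValueError("both distances must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        out[0::2] = self.r1
        out[1::2] = self.r2
        return out


DistanceModel = Union[FixedDistance, UniformDistance, TwoStateDistance]

ORIENTATION_MODES = ("frozen", "isotropic", "cone")


@dataclass(frozen=True)
class SyntheticModel:
    """Parameters of one synthetic rigid-body trajectory.

    Defaults emulate a 5 ns run sampled every 1 ps with isotropically
    tumbling, uncorrelated dipoles at the wild-type mean separation.
    """

    n_frames: int = 5000
    dt: float = 0.001
    r_model: DistanceModel = field(default_factory=lambda: FixedDistance(9.14))
    orientation: str = "isotropic"
    cone_half_angle_deg: float = 30.0
    frozen_mu_d: tuple[float, float, float] = (1.0, 0.0, 0.0)
    frozen_mu_a: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.orientation not in ORIENTATION_MODES:
            raise ValueError(
                f"orientation must be one of {ORIENTATION_MODES}, got {self.orientation!r}"
            )
        if self.orientation == "cone" and not 0.0 < self.cone_half_angle_deg <= 180.0:
            raise ValueError(
                f"cone half-angle must be in (0, 180] deg, got {self.cone_half_angle_deg}"
            )


def sample_cone(
    n: int, rng: np.random.Generator, half_angle_deg: float
) -> np.ndarray:
    """n unit vectors uniform within a cone of given half-angle about +z.

    Inverse-CDF scheme: cos(theta) = 1 - u*(1 - cos(alpha)), phi = 2*pi*v,
    with (u_1..u_n, v_1..v_n) consecutive ``rng.random`` draws.
    """
    cos_alpha = np.cos(np.deg2rad(half_angle_deg))
    u = rng.random(n)
    v = rng.random(n)
    cos_t = 1.0 - u * (1.0 - cos_alpha)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = 2.0 * np.pi * v
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def sample_unit_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform on the sphere (cone with half-angle 180 deg)."""
    return sample_cone(n, rng, 180.0)


def _normalize(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("frozen dipole direction must be nonzero")
    return v / n


def generate(model: SyntheticModel) -> list[DipoleFrame]:
    """Generate the trajectory: bit-identical for a fixed seed."""
    rng = np.random.default_rng(model.seed)
    n = model.n_frames
    r = model.r_model.sample(n, rng)
    if model.orientation == "frozen":
        mu_d = np.tile(_normalize(model.frozen_mu_d), (n, 1))
        mu_a = np.tile(_normalize(model.frozen_mu_a), (n, 1))
    elif model.orientation == "isotropic":
        mu_d = sample_unit_sphere(n, rng)
        mu_a = sample_unit_sphere(n, rng)
    else:
        mu_d = sample_cone(n, rng, model.cone_half_angle_deg)
        mu_a = sample_cone(n, rng, model.cone_half_angle_deg)
    # Re-normalize to absorb rounding in the trig pipeline; the DipoleFrame
    # constructor enforces |mu| = 1 to 1e-9.
    mu_d /= np.linalg.norm(mu_d, axis=1)[:, None]
    mu_a /= np.linalg.norm(mu_a, axis=1)[:, None]
    return [
        DipoleFrame(
            mu_d=mu_d[i],
            mu_a=mu_a[i],
            r_da_vec=np.array([r[i], 0.0, 0.0]),
            t=i * model.dt,
        )
        for i in range(n)
    ]


def write_dipole_csv(frames: Sequence[DipoleFrame], path: str | Path) -> None:
    """Write frames as CSV: t_ns, mu_d_{xyz}, mu_a_{xyz}, r_da_vec_{xyz}_A."""
    rows = {
        "t_ns": [f.t for f in frames],
        "mu_d_x": [f.mu_d[0] for f in frames],
        "mu_d_y": [f.mu_d[1] for f in frames],
        "mu_d_z": [f.mu_d[2] for f in frames],
        "mu_a_x": [f.mu_a[0] for f in frames],
        "mu_a_y": [f.mu_a[1] for f in frames],
        "mu_a_z": [f.mu_a[2] for f in frames],
        "r_da_x_A": [f.r_da_vec[0] for f in frames],
        "r_da_y_A": [f.r_da_vec[1] for f in frames],
        "r_da_z_A": [f.r_da_vec[2] for f in frames],
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_dipole_csv(path: str | Path) -> list[DipoleFrame]:
    """Read frames written by :func:`write_dipole_csv`."""
    df = pd.read_csv(path)
    return [
        DipoleFrame(
            mu_d=np.array([row.mu_d_x, row.mu_d_y, row.mu_d_z]) /
            np.linalg.norm([row.mu_d_x, row.mu_d_y, row.mu_d_z]),
            mu_a=np.array([row.mu_a_x, row.mu_a_y, row.mu_a_z]) /
            np.linalg.norm([row.mu_a_x, row.mu_a_y, row.mu_a_z]),
            r_da_vec=np.array([row.r_da_x_A, row.r_da_y_A, row.r_da_z_A]),
            t=row.t_ns,
        )
        for row in df.itertuples()
    ]


# --- minimal multi-frame PDB realization ---------------------------------

_RING_RADIUS = 1.39   # aromatic C-C ring radius, Å
_BRIDGE_HALF = 0.70   # half of the ring-fusion bond length, Å
# Vertex order around the idealized hexagon so that CZ - CG is the +mu_d
# long axis: angle k*60 deg from +mu_d.
_RING_NAMES = ("CZ", "CE1", "CD1", "CG", "CD2", "CE2")
_BRIDGE_NAMES = ("C3A", "C7A")


def _perpendicular(v: np.ndarray) -> np.ndarray:
    probe = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = probe - (probe @ v) * v
    return p / np.linalg.norm(p)


def _frame_coordinates(frame: DipoleFrame) -> np.ndarray:
    """Coordinates (8, 3) of an idealized phenol hexagon + two-atom bridge.

    The hexagon lies in a plane containing mu_d with CG->CZ along mu_d and
    centroid at the origin (the donor site); the bridge bond lies along mu_a
    with midpoint at r_da_vec (the acceptor site).  Purely geometric: it
    realizes the same DipoleFrame under the spectroscopic site convention.
    """
    p = _perpendicular(frame.mu_d)
    angles = np.deg2rad(np.arange(6) * 60.0)
    ring = _RING_RADIUS * (
        np.outer(np.cos(angles), frame.mu_d) + np.outer(np.sin(angles), p)
    )
    site_a = frame.r_da_vec
    bridge = np.vstack(
        [site_a - _BRIDGE_HALF * frame.mu_a, site_a + _BRIDGE_HALF * frame.mu_a]
    )
    return np.vstack([ring, bridge])


def write_pdb(frames: Sequence[DipoleFrame], path: str | Path) -> None:
    """Write a multi-model PDB of the minimal Tyr + FA construct.

    Geometry chosen for testability: reloading the file and applying the
    default :class:`~mdfret.trajectory_io.SiteDefinition` for residues
    A:160 (TYR) and A:201 (FMB) reproduces each frame's R_da and dipoles to
    PDB coordinate precision (1e-3 Å).
    """
    import warnings

    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    coords = np.stack([_frame_coordinates(f) for f in frames]).astype(np.float32)
    n_atoms = 8
    u = mda.Universe.empty(
        n_atoms,
        n_residues=2,
        n_segments=1,
        atom_resindex=[0] * 6 + [1] * 2,
        residue_segindex=[0, 0],
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(_RING_NAMES) + list(_BRIDGE_NAMES))
    u.add_TopologyAttr("resnames", ["TYR", "FMB"])
    u.add_TopologyAttr("resids", [160, 201])
    u.add_TopologyAttr("segids", ["A"])
    u.add_TopologyAttr("chainIDs", ["A"] * n_atoms)
    u.add_TopologyAttr("elements", ["C"] * n_atoms)
    u.add_TopologyAttr("occupancies", [1.0] * n_atoms)
    u.add_TopologyAttr("tempfactors", [0.0] * n_atoms)
    u.load_new(coords, format=MemoryReader)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, multiframe=True) as writer:
            for _ts in u.trajectory:
                writer.write(u.atoms)


def default_pdb_sites():
    """SiteDefinition matching :func:`write_pdb`'s construct."""
    from .trajectory_io import SiteDefinition

    return SiteDefinition(donor_residue="A:160", acceptor_residue="A:201")
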