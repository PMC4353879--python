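"""Trajectory reading and the donor/acceptor site conventions.

The donor site is the unweighted geometric centroid of the tyrosine
phenol-ring carbons; the acceptor site is the midpoint of the bond linking
the six- and five-membered rings of the formycin A bicycle (the
"spectroscopic definition").  The separation vector R_da points from donor
to acceptor.  Transition-dipole directions are the normalized differences of
user-configured ordered atom pairs; the shipped defaults (long-axis pairs
for the tyrosine ring and the FA bicycle) are geometric approximations to
quantum-chemically computed transition moments and should be overridden when
better directions are available.

File handling is delegated to MDAnalysis: a PDB topology with either
multi-model PDB or DCD coordinates.  Coordinates are Å; frame time stamps
are index*dt (0-based), dt in ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import (
    DataError,
    DegenerateGeometryError,
    SiteResolutionError,
)
from .fret_core import DipoleFrame

__all__ = ["SiteDefinition", "Trajectory", "load_trajectory", "frame_to_dipole"]

# Tyrosine aromatic-ring carbons (CHARMM/PDB names), no hydroxyl oxygen.
DEFAULT_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
# Ring-fusion bond of the formycin pyrazolo[4,3-d]pyrimidine bicycle in the
# 1PR1-style ligand dictionary; ligand atom naming varies across PDB
# dialects, so these MUST be treated as configurable defaults.
DEFAULT_BRIDGE_ATOMS = ("C3A", "C7A")


@dataclass(frozen=True)
class SiteDefinition:
    """Names of the atoms defining sites and dipole directions.

    Residue selectors are ``"CHAIN:RESID"`` (e.g. ``"A:160"``) or a bare
    residue number.  ``acceptor_bridge_atoms`` must be exactly two names;
    dipole pairs are ordered (direction is second minus first) and must name
    distinct atoms.
    """

    donor_residue: str
    acceptor_residue: str
    donor_ring_atoms: tuple[str, ...] = DEFAULT_RING_ATOMS
    acceptor_bridge_atoms: tuple[str, str] = DEFAULT_BRIDGE_ATOMS
    donor_dipole_atoms: tuple[str, str] = ("CG", "CZ")
    acceptor_dipole_atoms: tuple[str, str] = DEFAULT_BRIDGE_ATOMS

    def __post_init__(self):
        if len(self.acceptor_bridge_atoms) != 2:
            raise ValueError("acceptor_bridge_atoms must name exactly two atoms")
        for pair_name in ("donor_dipole_atoms", "acceptor_dipole_atoms"):
            pair = getattr(self, pair_name)
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValueError(f"{pair_name} must be two distinct atom names")
        if len(self.donor_ring_atoms) < 3:
            raise ValueError("donor_ring_atoms must name at least three atoms")


def _parse_selector(selector: str) -> tuple[str | None, int]:
    if ":" in selector:
        chain, _, rid = selector.partition(":")
        chain = chain.strip() or None
    else:
        chain, rid = None, selector
    try:
        return chain, int(rid)
    except ValueError as exc:
        raise SiteResolutionError(f"cannot parse residue selector {selector!r}") from exc


class _SiteAtoms:
    """Resolved per-atom indices for fast per-frame lookup."""

    def __init__(self, universe, sites: SiteDefinition):
        self.ring_idx = [
            _resolve_atom(universe, sites.donor_residue, name)
            for name in sites.donor_ring_atoms
        ]
        self.bridge_idx = [
            _resolve_atom(universe, sites.acceptor_residue, name)
            for name in sites.acceptor_bridge_atoms
        ]
        self.mu_d_idx = [
            _resolve_atom(universe, sites.donor_residue, name)
            for name in sites.donor_dipole_atoms
        ]
        self.mu_a_idx = [
            _resolve_atom(universe, sites.acceptor_residue, name)
            for name in sites.acceptor_dipole_atoms
        ]


def _resolve_atom(universe, residue_selector: str, atom_name: str) -> int:
    chain, resid = _parse_selector(residue_selector)
    sel = f"resid {resid} and name {atom_name}"
    if chain is not None:
        sel = f"segid {chain} and {sel}"
    ag = universe.select_atoms(sel)
    if len(ag) == 0:
        raise SiteResolutionError(
            f"atom {atom_name!r} of residue {residue_selector!r} not found in topology"
        )
    if len(ag) > 1:
        altlocs = getattr(ag, "altLocs", None)
        if altlocs is not None and len(set(altlocs)) > 1:
            # Alternate-location records: take the first altloc, warn.
            first = sorted(set(altlocs))[0]
            warnings.warn(
                f"atom {atom_name!r} of {residue_selector!r} has alternate "
                f"locations {sorted(set(altlocs))}; using altloc {first!r}"
            )
            ag = ag[[i for i, a in enumerate(altlocs) if a == first]]
        if len(ag) > 1:
            raise SiteResolutionError(
                f"atom {atom_name!r} of residue {residue_selector!r} is ambiguous "
                f"({len(ag)} matches)"
            )
    return int(ag.ix[0])


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise DegenerateGeometryError(f"{what} atoms are coincident (zero-length dipole)")
    return v / n


def _dipole_from_positions(pos: np.ndarray, atoms: _SiteAtoms, t: float) -> DipoleFrame:
    donor_site = pos[atoms.ring_idx].mean(axis=0)
    acceptor_site = pos[atoms.bridge_idx].mean(axis=0)
    mu_d = _unit(pos[atoms.mu_d_idx[1]] - pos[atoms.mu_d_idx[0]], "donor dipole")
    mu_a = _unit(pos[atoms.mu_a_idx[1]] - pos[atoms.mu_a_idx[0]], "acceptor dipole")
    r_vec = acceptor_site - donor_site
    if np.linalg.norm(r_vec) == 0.0:
        raise DegenerateGeometryError("donor and acceptor sites coincide")
    return DipoleFrame(mu_d=mu_d, mu_a=mu_a, r_da_vec=r_vec, t=t)


@dataclass
class Trajectory:
    """A loaded trajectory: MDAnalysis Universe plus uniform frame spacing."""

    universe: "object"
    dt: float
    topology: Path
    coords: Path | None = None
    _sites_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.universe.trajectory)

    @property
    def n_atoms(self) -> int:
        return len(self.universe.atoms)

    def dipole_frames(self, sites: SiteDefinition) -> list[DipoleFrame]:
        """Evaluate the site/dipole conventions in every frame."""
        return list(self.iter_dipole_frames(sites))

    def iter_dipole_frames(self, sites: SiteDefinition) -> Iterator[DipoleFrame]:
        atoms = _SiteAtoms(self.universe, sites)
        for i, _ts in enumerate(self.universe.trajectory):
            yield _dipole_from_positions(
                self.universe.atoms.positions.astype(float), atoms, t=i * self.dt
            )


def load_trajectory(
    topology: str | Path, coords: str | Path | None = None, dt: float = 0.001
) -> Trajectory:
    """Open a PDB topology with optional multi-frame PDB / DCD coordinates.

    With ``coords=None`` the topology file itself supplies the frames
    (multi-model PDB).  ``dt`` is the uniform frame spacing in ns.  Raises
    :class:`DataError` for unparsable files, atom-count mismatches between
    coordinates and topology, or zero frames.
    """
    import MDAnalysis as mda

    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    topology = Path(topology)
    if not topology.exists():
        raise DataError(f"topology file not found: {topology}")
    args = [str(topology)]
    if coords is not None:
        coords = Path(coords)
        if not coords.exists():
            raise DataError(f"coordinate file not found: {coords}")
        args.append(str(coords))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(*args)
            n_frames = len(universe.trajectory)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"cannot load trajectory {args}: {exc}") from exc
    if n_frames == 0:
        raise DataError(f"trajectory {args} contains zero frames")
    return Trajectory(universe=universe, dt=dt, topology=topology, coords=coords)


def frame_to_dipole(trajectory: Trajectory, sites: SiteDefinition) -> DipoleFrame:
    """Evaluate sites and dipoles in the trajectory's *current* frame."""
    atoms = _SiteAtoms(trajectory.universe, sites)
    ts = trajectory.universe.trajectory.ts
    return _dipole_from_positions(
        trajectory.universe.atoms.positions.astype(float),
        atoms,
        t=ts.frame * trajectory.dt,
    )
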