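"""Core Förster-transfer mathematics.

The non-radiative dipole-dipole coupling model expresses the instantaneous
transfer rate between an excited donor D* and a ground-state acceptor A as

    W_F(t) = 3 kappa^2(t) / (2 tau_d) * (R_F / R_da(t))**6      [ns^-1]

where ``tau_d`` is the donor fluorescence lifetime in the absence of the
acceptor, ``R_F`` the Förster radius and ``R_da`` the donor-acceptor
separation.  The orientation factor

    kappa = mu_d . mu_a - 3 (Rhat . mu_d)(Rhat . mu_a)

couples the two *normalized* transition-dipole directions to the unit
separation vector ``Rhat``; ``kappa**2`` lies in the closed interval [0, 4],
attaining 4 for collinear dipoles along the separation axis and averaging
2/3 for isotropically tumbling, uncorrelated dipoles.  The instantaneous
transfer quantum yield is

    E(t) = 1 / (1 + (W_F(t) tau_d)**-1) = W_F tau_d / (1 + W_F tau_d)

with E := 0 at W_F = 0 (the continuous limit; a zero spectral overlap, hence
R_F = 0, forces W_F = 0 in every frame and a mean efficiency of exactly 0).

Trajectory averages ⟨kappa^2⟩, ⟨W_F⟩, ⟨E⟩ are uniform-weight arithmetic
means over equally spaced frames, reported with the standard error of the
mean.  All distances are Å, times ns, rates ns^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InsufficientDataError

__all__ = [
    "DipoleFrame",
    "PhotophysicsParams",
    "FrameObservables",
    "TrajectorySummary",
    "orientation_factor",
    "orientation_factors",
    "transfer_rate",
    "efficiency",
    "compute_observables",
    "analyze_frames",
    "frames_to_dataframe",
    "summarize_trajectory",
]

_UNIT_TOL = 1e-9


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class DipoleFrame:
    """One trajectory frame's transition-dipole geometry.

    Parameters
    ----------
    mu_d, mu_a
        Unit 3-vectors: donor and acceptor transition-moment directions
        (dimensionless; validated to |mu| = 1 within 1e-9).
    r_da_vec
        3-vector in Å directed from the donor site to the acceptor site.
    t
        Time stamp in ns.
    """

    mu_d: np.ndarray
    mu_a: np.ndarray
    r_da_vec: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        mu_d = _as_vec3(self.mu_d, "mu_d")
        mu_a = _as_vec3(self.mu_a, "mu_a")
        r = _as_vec3(self.r_da_vec, "r_da_vec")
        for name, mu in (("mu_d", mu_d), ("mu_a", mu_a)):
            n = np.linalg.norm(mu)
            if abs(n - 1.0) > _UNIT_TOL:
                raise ValueError(f"{name} must be a unit vector (|{name}| = {n:.12g})")
        if np.linalg.norm(r) == 0.0:
            raise DegenerateGeometryError("r_da_vec has zero length")
        object.__setattr__(self, "mu_d", mu_d)
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "r_da_vec", r)

    @property
    def r_da(self) -> float:
        """Donor-acceptor distance |r_da_vec| in Å."""
        return float(np.linalg.norm(self.r_da_vec))


@dataclass(frozen=True)
class PhotophysicsParams:
    """Donor photophysics driving the transfer rate.

    ``tau_d`` is the donor mean fluorescence lifetime in ns (for the tyrosine
    donor studied here, 2.57 ns).  ``r_forster`` is the Förster radius in Å;
    the value 0 encodes a vanishing spectral overlap integral and forces
    W_F = 0 for every frame.
    """

    tau_d: float
    r_forster: float

    def __post_init__(self):
        if not self.tau_d > 0:
            raise ValueError(f"tau_d must be positive, got {self.tau_d}")
        if self.r_forster < 0:
            raise ValueError(f"r_forster must be >= 0, got {self.r_forster}")


@dataclass(frozen=True)
class FrameObservables:
    """Per-frame FRET observables (distances Å, rates ns^-1)."""

    t: float
    r_da: float
    kappa: float
    kappa_sq: float
    w_f: float
    e: float


@dataclass(frozen=True)
class TrajectorySummary:
    """Time-averaged FRET statistics over one trajectory.

    Each mean carries the standard error of the mean (population std over
    sqrt(N); block-averaged SEMs are available through
    :func:`summarize_trajectory`'s ``block_size``).
    """

    n_frames: int
    duration_T: float
    mean_r_da: float
    sem_r_da: float
    mean_kappa_sq: float
    sem_kappa_sq: float
    max_kappa_sq: float
    mean_w_f: float
    sem_w_f: float
    mean_e: float
    sem_e: float
    block_size: int | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "duration_T_ns": self.duration_T,
            "mean_r_da_A": self.mean_r_da,
            "sem_r_da_A": self.sem_r_da,
            "mean_kappa_sq": self.mean_kappa_sq,
            "sem_kappa_sq": self.sem_kappa_sq,
            "max_kappa_sq": self.max_kappa_sq,
            "mean_w_f_per_ns": self.mean_w_f,
            "sem_w_f_per_ns": self.sem_w_f,
            "mean_e": self.mean_e,
            "sem_e": self.sem_e,
        }

    def report(self) -> str:
        """Flat key/value text report, one summary-statistic row."""
        lines = [f"{k} = {v:.6g}" if isinstance(v, float) else f"{k} = {v}"
                 for k, v in self.to_dict().items()]
        return "\n".join(lines) + "\n"


def orientation_factor(frame: DipoleFrame) -> float:
    """Signed orientation factor kappa for one frame.

    kappa = mu_d . mu_a - 3 (Rhat . mu_d)(Rhat . mu_a), with
    Rhat = r_da_vec / |r_da_vec|.  kappa**2 lies in [0, 4].
    """
    r_norm = np.linalg.norm(frame.r_da_vec)
    if r_norm == 0.0:
        raise DegenerateGeometryError("r_da_vec has zero length")
    rhat = frame.r_da_vec / r_norm
    return float(
        frame.mu_d @ frame.mu_a - 3.0 * (rhat @ frame.mu_d) * (rhat @ frame.mu_a)
    )


def orientation_factors(
    mu_d: np.ndarray, mu_a: np.ndarray, r_da_vec: np.ndarray
) -> np.ndarray:
    """Vectorized signed kappa for stacked geometries.

    Parameters are arrays of shape (N, 3); ``mu_d`` and ``mu_a`` must be
    row-wise unit vectors.  Returns shape (N,).
    """
    mu_d = np.atleast_2d(np.asarray(mu_d, dtype=float))
    mu_a = np.atleast_2d(np.asarray(mu_a, dtype=float))
    r = np.atleast_2d(np.asarray(r_da_vec, dtype=float))
    r_norm = np.linalg.norm(r, axis=1)
    if np.any(r_norm == 0.0):
        raise DegenerateGeometryError("r_da_vec has zero length")
    rhat = r / r_norm[:, None]
    return (
        np.einsum("ij,ij->i", mu_d, mu_a)
        - 3.0 * np.einsum("ij,ij->i", rhat, mu_d) * np.einsum("ij,ij->i", rhat, mu_a)
    )


def transfer_rate(kappa_sq, r_da, params: PhotophysicsParams):
    """Instantaneous transfer rate W_F in ns^-1.

    W_F = 3 kappa_sq / (2 tau_d) * (R_F / R_da)**6.  Returns exactly 0 when
    the Förster radius is 0 (zero spectral overlap).  Accepts scalars or
    arrays for ``kappa_sq`` and ``r_da``.
    """
    kappa_sq = np.asarray(kappa_sq, dtype=float)
    r_da = np.asarray(r_da, dtype=float)
    if np.any(r_da <= 0.0):
        raise DegenerateGeometryError("r_da must be positive")
    if np.any(kappa_sq < 0.0) or np.any(kappa_sq > 4.0):
        raise ValueError("kappa_sq must lie in [0, 4]")
    if params.r_forster == 0.0:
        out = np.zeros_like(np.broadcast_arrays(kappa_sq, r_da)[0])
        return float(out) if out.ndim == 0 else out
    w = 3.0 * kappa_sq / (2.0 * params.tau_d) * (params.r_forster / r_da) ** 6
    return float(w) if w.ndim == 0 else w


def efficiency(w_f, tau_d: float):
    """Instantaneous transfer quantum yield E in [0, 1).

    E = 1 / (1 + (w_f tau_d)**-1), evaluated as w_f tau_d / (1 + w_f tau_d)
    so that the W_F = 0 limit returns exactly 0.  Accepts scalars or arrays.
    """
    if not tau_d > 0:
        raise ValueError(f"tau_d must be positive, got {tau_d}")
    w_f = np.asarray(w_f, dtype=float)
    if np.any(w_f < 0.0):
        raise ValueError("w_f must be nonnegative")
    x = w_f * tau_d
    e = x / (1.0 + x)
    return float(e) if e.ndim == 0 else e


def compute_observables(frame: DipoleFrame, params: PhotophysicsParams) -> FrameObservables:
    """All per-frame observables for one dipole frame."""
    kappa = orientation_factor(frame)
    kappa_sq = kappa * kappa
    r_da = frame.r_da
    w_f = transfer_rate(kappa_sq, r_da, params)
    e = efficiency(w_f, params.tau_d)
    return FrameObservables(t=frame.t, r_da=r_da, kappa=kappa,
                            kappa_sq=kappa_sq, w_f=w_f, e=e)


def analyze_frames(
    frames: Iterable[DipoleFrame], params: PhotophysicsParams
) -> list[FrameObservables]:
    """Per-frame observables for a whole trajectory."""
    return [compute_observables(f, params) for f in frames]


def frames_to_dataframe(observables: Sequence[FrameObservables]) -> pd.DataFrame:
    """Per-frame table with columns t_ns, r_da_A, kappa, kappa_sq, w_f_per_ns, e."""
    return pd.DataFrame(
        {
            "t_ns": [o.t for o in observables],
            "r_da_A": [o.r_da for o in observables],
            "kappa": [o.kappa for o in observables],
            "kappa_sq": [o.kappa_sq for o in observables],
            "w_f_per_ns": [o.w_f for o in observables],
            "e": [o.e for o in observables],
        }
    )


def _mean_sem(x: np.ndarray, block_size: int | None) -> tuple[float, float]:
    # Mean is always over all samples; block averaging only changes the SEM,
    # coarse-graining serial correlation into block means.
    mean = float(np.mean(x))
    if block_size is not None:
        n_blocks = x.size // block_size
        x = x[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    if np.min(x) == np.max(x):
        # A constant series has exactly zero spread; skip the mean
        # subtraction, whose rounding would leave an O(eps) residue.
        return mean, 0.0
    return mean, float(np.std(x, ddof=0) / np.sqrt(x.size))


def summarize_trajectory(
    observables: Sequence[FrameObservables],
    dt: float,
    block_size: int | None = None,
) -> TrajectorySummary:
    """Time averages with SEM over equally spaced frames.

    The continuous time averages are discretized as uniform-weight arithmetic
    means; ``duration_T = N * dt``.  SEM is the population standard deviation
    over sqrt(N).  With ``block_size`` the SEM is instead computed over
    non-overlapping block means (a crude decorrelation for serially
    correlated MD data); at least 2 full blocks are required.

    Raises
    ------
    InsufficientDataError
        For fewer than 2 frames (a single frame has no spread to estimate).
    """
    obs = list(observables)
    if len(obs) < 2:
        raise InsufficientDataError(
            f"need at least 2 frames to summarize, got {len(obs)}"
        )
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if block_size is not None and len(obs) // block_size < 2:
        raise InsufficientDataError(
            f"block_size={block_size} leaves fewer than 2 blocks for {len(obs)} frames"
        )
    r_da = np.array([o.r_da for o in obs])
    kappa_sq = np.array([o.kappa_sq for o in obs])
    w_f = np.array([o.w_f for o in obs])
    e = np.array([o.e for o in obs])
    mean_r, sem_r = _mean_sem(r_da, block_size)
    mean_k2, sem_k2 = _mean_sem(kappa_sq, block_size)
    mean_w, sem_w = _mean_sem(w_f, block_size)
    mean_e, sem_e = _mean_sem(e, block_size)
    return TrajectorySummary(
        n_frames=len(obs),
        duration_T=len(obs) * dt,
        mean_r_da=mean_r,
        sem_r_da=sem_r,
        mean_kappa_sq=mean_k2,
        sem_kappa_sq=sem_k2,
        max_kappa_sq=float(np.max(kappa_sq)),
        mean_w_f=mean_w,
        sem_w_f=sem_w,
        mean_e=mean_e,
        sem_e=sem_e,
        block_size=block_size,
    )
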