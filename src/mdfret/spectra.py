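"""Spectral overlap integral and Förster radius.

The overlap integral between the area-normalized donor emission spectrum
f_D(lambda) [nm^-1] and the acceptor molar extinction curve
eps_A(lambda) [M^-1 cm^-1] is

    J = integral f_D(lambda) eps_A(lambda) lambda**4 dlambda   [M^-1 cm^-1 nm^4]

with lambda in nm.  In these units the Förster radius comes out in Å as

    R_F = 0.2108 * (n**-4 Q_D <kappa^2> J)**(1/6)

where Q_D is the donor fluorescence quantum yield without the acceptor and
n the refractive index of the medium.  A donor whose emission is entirely
red of the acceptor absorption (the tyrosinate-anion situation) has J = 0,
hence R_F = 0 and no transfer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, NormalizationError

__all__ = [
    "Spectrum",
    "ForsterInputs",
    "normalize_emission",
    "overlap_integral",
    "forster_radius",
    "FORSTER_PREFACTOR",
]

#: Prefactor of the Förster-radius formula for J in M^-1 cm^-1 nm^4,
#: lambda in nm and R_F in Å.
FORSTER_PREFACTOR = 0.2108


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-gridded curve: emission intensity or molar extinction.

    ``wavelengths`` (nm) must be strictly increasing with at least 2 points;
    ``values`` are nonnegative (arbitrary units for raw emission, nm^-1 once
    normalized, M^-1 cm^-1 for extinction).  The grid need not be uniform.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.shape != w.shape:
            raise DataError("wavelengths and values must be 1-D arrays of equal length")
        if w.size < 2:
            raise DataError("spectrum needs at least 2 points")
        if np.any(np.diff(w) <= 0):
            raise DataError("wavelength grid must be strictly increasing")
        if np.any(v < 0):
            raise DataError("spectrum values must be nonnegative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)

    def integral(self) -> float:
        """Trapezoidal integral over the grid."""
        return float(np.trapezoid(self.values, self.wavelengths))

    @classmethod
    def from_file(cls, path: str | Path) -> "Spectrum":
        """Read a two-column delimited text file (wavelength nm, value).

        Whitespace- or comma-delimited; lines starting with '#' are comments.
        """
        text = Path(path).read_text()
        try:
            df = pd.read_csv(
                io.StringIO(text), sep=r"[,\s]+", comment="#",
                header=None, engine="python",
            ).dropna(how="all")
        except Exception as exc:
            raise DataError(f"cannot parse spectrum file {path}: {exc}") from exc
        if df.shape[1] < 2:
            raise DataError(f"spectrum file {path} needs two columns")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_file(self, path: str | Path, header: str = "") -> None:
        lines = [f"# {header}"] if header else []
        lines += [f"{w:.6f} {v:.8g}" for w, v in zip(self.wavelengths, self.values)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ForsterInputs:
    """Everything Eq.-of-R_F needs: Q_D, n, ⟨kappa^2⟩ and J.

    ``j`` is in M^-1 cm^-1 nm^4.
    """

    q_d: float
    n_refr: float
    kappa_sq_avg: float
    j: float

    def __post_init__(self):
        if not 0.0 <= self.q_d <= 1.0:
            raise ValueError(f"q_d must be in [0, 1], got {self.q_d}")
        if self.n_refr < 1.0:
            raise ValueError(f"n_refr must be >= 1, got {self.n_refr}")
        if not 0.0 <= self.kappa_sq_avg <= 4.0:
            raise ValueError(f"kappa_sq_avg must be in [0, 4], got {self.kappa_sq_avg}")
        if self.j < 0.0:
            raise ValueError(f"j must be >= 0, got {self.j}")


def normalize_emission(raw: Spectrum) -> Spectrum:
    """Area-normalize a donor emission spectrum to unit trapezoidal integral.

    The result has units nm^-1.  Raises :class:`NormalizationError` for an
    all-zero spectrum.
    """
    area = raw.integral()
    if area <= 0.0:
        raise NormalizationError("emission spectrum has zero integral")
    return Spectrum(raw.wavelengths, raw.values / area)


def overlap_integral(f_d: Spectrum, eps_a: Spectrum) -> float:
    """Spectral overlap integral J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ in M^-1 cm^-1 nm^4.

    Both curves are linearly interpolated onto the union of their grids
    restricted to the intersection of their supports and integrated with the
    trapezoidal rule; disjoint supports give J = 0.
    """
    lo = max(f_d.wavelengths[0], eps_a.wavelengths[0])
    hi = min(f_d.wavelengths[-1], eps_a.wavelengths[-1])
    if lo >= hi:
        return 0.0
    grid = np.union1d(f_d.wavelengths, eps_a.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    grid = np.union1d(grid, [lo, hi])
    fd = np.interp(grid, f_d.wavelengths, f_d.values)
    ea = np.interp(grid, eps_a.wavelengths, eps_a.values)
    return float(np.trapezoid(fd * ea * grid**4, grid))


def forster_radius(inp: ForsterInputs) -> float:
    """Förster radius R_F = 0.2108 (n^-4 Q_D ⟨kappa^2⟩ J)^(1/6) in Å.

    Returns exactly 0 for J = 0 (zero spectral overlap).
    """
    if inp.j == 0.0:
        return 0.0
    return FORSTER_PREFACTOR * (
        inp.n_refr**-4 * inp.q_d * inp.kappa_sq_avg * inp.j
    ) ** (1.0 / 6.0)
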