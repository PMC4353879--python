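"""Excited-state charge patching.

Force-field point charges describe the ground state S0.  To run dynamics
with an electronically excited (or deprotonated) chromophore, the per-atom
change in quantum-mechanical ESP charges between the two states is added on
top of the base force-field charges, preserving the original
parameterization while shifting the electrostatics:

    q_patched(atom) = q_base(atom) + delta_q(atom)

Two bookkeeping modes are supported: an electronic *excitation* of a neutral
species must conserve total charge (|sum of deltas| should be ~0; ESP fits
rarely sum exactly to zero, default tolerance 0.01 e), while a
*deprotonation* changes the total by exactly -1 e.  The patch report flags a
delta table whose total falls outside the mode's expectation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ChargePatchError, DataError

__all__ = [
    "PatchReport",
    "read_charge_table",
    "read_delta_table",
    "write_charge_table",
    "apply_deltas",
]

MODES = ("excitation", "deprotonation")
#: Expected total delta per mode, in e.
_EXPECTED_TOTAL = {"excitation": 0.0, "deprotonation": -1.0}


@dataclass(frozen=True)
class PatchReport:
    """Bookkeeping for one patch: totals, mode, and the conservation flag."""

    n_atoms: int
    n_patched: int
    total_base: float
    total_delta: float
    total_patched: float
    mode: str
    tolerance: float
    flagged: bool

    def report(self) -> str:
        lines = [
            f"atoms_total = {self.n_atoms}",
            f"atoms_patched = {self.n_patched}",
            f"sum_base_e = {self.total_base:.6f}",
            f"sum_delta_e = {self.total_delta:.6f}",
            f"sum_patched_e = {self.total_patched:.6f}",
            f"mode = {self.mode}",
            f"tolerance_e = {self.tolerance}",
            f"flagged = {self.flagged}",
        ]
        if self.flagged:
            lines.append(
                f"warning: |sum_delta - ({_EXPECTED_TOTAL[self.mode]})| exceeds "
                f"tolerance; check the delta table"
            )
        return "\n".join(lines) + "\n"


def _read_table(path: str | Path, n_cols: int, names: list[str]) -> pd.DataFrame:
    text = Path(path).read_text()
    try:
        df = pd.read_csv(
            io.StringIO(text), sep=r"[,\s]+", comment="#",
            header=None, engine="python",
        ).dropna(how="all")
    except Exception as exc:
        raise DataError(f"cannot parse charge table {path}: {exc}") from exc
    if df.shape[1] < n_cols:
        raise DataError(f"charge table {path} needs {n_cols} columns")
    df = df.iloc[:, :n_cols]
    df.columns = names
    df["atom"] = df["atom"].astype(str)
    return df


def read_charge_table(path: str | Path) -> pd.DataFrame:
    """Read a base charge table: columns (atom identifier, charge in e)."""
    df = _read_table(path, 2, ["atom", "charge"])
    df["charge"] = df["charge"].astype(float)
    return df


def read_delta_table(path: str | Path) -> pd.DataFrame:
    """Read a delta table: columns (atom identifier, delta charge in e)."""
    df = _read_table(path, 2, ["atom", "delta"])
    df["delta"] = df["delta"].astype(float)
    return df


def write_charge_table(df: pd.DataFrame, path: str | Path, header: str = "") -> None:
    """Write an (atom, charge) table in the same delimited-text schema."""
    lines = [f"# {header}"] if header else []
    lines += [f"{row.atom} {row.charge:.6f}" for row in df.itertuples()]
    Path(path).write_text("\n".join(lines) + "\n")


def apply_deltas(
    base: pd.DataFrame,
    deltas: pd.DataFrame,
    mode: str = "excitation",
    tolerance: float = 0.01,
) -> tuple[pd.DataFrame, PatchReport]:
    """Add ESP charge deltas onto a base charge table.

    Parameters
    ----------
    base
        DataFrame with columns ``atom`` (unique identifiers) and ``charge`` (e).
    deltas
        DataFrame with columns ``atom`` and ``delta`` (e); every atom must
        exist in ``base`` and appear at most once.
    mode
        ``"excitation"`` (total delta expected ~0) or ``"deprotonation"``
        (total delta expected -1 e exactly).
    tolerance
        Allowed deviation (e) of the total delta from the mode's expectation
        before the report is flagged.

    Returns
    -------
    (patched, report)
        ``patched`` has the same atom order as ``base`` with
        ``charge = base + delta``; ``report`` carries the charge totals and
        the conservation flag.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not tolerance >= 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    if base["atom"].duplicated().any():
        dups = sorted(base.loc[base["atom"].duplicated(), "atom"].unique())
        raise ChargePatchError(f"duplicate atoms in base table: {dups}")
    if deltas["atom"].duplicated().any():
        dups = sorted(deltas.loc[deltas["atom"].duplicated(), "atom"].unique())
        raise ChargePatchError(f"duplicate rows in delta table for atoms: {dups}")
    unknown = set(deltas["atom"]) - set(base["atom"])
    if unknown:
        raise ChargePatchError(
            f"delta table names atoms absent from base table: {sorted(unknown)}"
        )

    delta_by_atom = deltas.set_index("atom")["delta"]
    patched = base.copy()
    add = patched["atom"].map(delta_by_atom).fillna(0.0).to_numpy()
    patched["charge"] = patched["charge"].to_numpy() + add
    n_patched = int(patched["atom"].isin(delta_by_atom.index).sum())

    total_base = float(base["charge"].sum())
    total_delta = float(deltas["delta"].sum())
    total_patched = float(patched["charge"].sum())
    flagged = abs(total_delta - _EXPECTED_TOTAL[mode]) > tolerance
    report = PatchReport(
        n_atoms=len(base),
        n_patched=n_patched,
        total_base=total_base,
        total_delta=total_delta,
        total_patched=total_patched,
        mode=mode,
        tolerance=tolerance,
        flagged=flagged,
    )
    return patched, report
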