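"""Readers and writers for the columnar and structural formats the
pipeline touches: TSV/CSV/XVG trace tables, multi-model PDB residue
trajectories, and TSV result tables.

Residue numbering follows the source PDB author numbering throughout;
coordinates are in Angstrom; experimental times in seconds.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import ResidueTrajectory

__all__ = [
    "TraceTable",
    "TraceParseError",
    "ResidueMismatchError",
    "read_trace_table",
    "write_trace_table",
    "read_residue_trajectory_pdb",
    "write_residue_trajectory_pdb",
    "write_fret_trajectory",
]


class TraceParseError(ValueError):
    """A malformed row in a columnar trace file."""


class ResidueMismatchError(ValueError):
    """Models of a multi-model PDB disagree on the residue set."""


@dataclass
class TraceTable:
    """Time column plus one or more signal channels."""

    time: np.ndarray
    channels: pd.DataFrame
    meta: dict = field(default_factory=dict)
    uniform_dt: bool = True

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time))) if self.time.size > 1 else 0.0


_DIALECT_SEPS = {"tsv": "\t", "csv": ","}


def read_trace_table(path: str | Path, dialect: str | None = None,
                     dt_rtol: float = 1e-6) -> TraceTable:
    """Read a columnar trace file (TSV, CSV, or Gromacs-style XVG).

    The first column is time, the rest are channels.  XVG comment ('#') and
    legend ('@') lines are skipped.  Rows that fail to parse as numbers
    (including NaN) raise :class:`TraceParseError` naming the data row; a
    non-uniform time step beyond tolerance flags the table rather than
    raising.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower() or "tsv"
    if dialect not in ("tsv", "csv", "xvg"):
        raise ValueError(f"unknown dialect {dialect!r}")

    lines = path.read_text().splitlines()
    data_lines: list[str] = []
    header: list[str] | None = None
    for line in lines:
        s = line.strip()
        if not s or s.startswith("#") or (dialect == "xvg" and s.startswith("@")):
            continue
        if header is None and any(c.isalpha() for c in s.split(
                _DIALECT_SEPS.get(dialect, None) or None)[0]):
            header = s.split(_DIALECT_SEPS[dialect]) if dialect in _DIALECT_SEPS \
                else s.split()
            continue
        data_lines.append(s)
    if not data_lines:
        raise TraceParseError(f"{path}: no data rows")

    sep = _DIALECT_SEPS.get(dialect)
    if sep is None:  # XVG: whitespace-delimited; normalize to tabs
        data_lines = ["\t".join(line.split()) for line in data_lines]
        sep = "\t"
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)), sep=sep,
                     header=None, float_precision="round_trip")
    if df.shape[1] < 2:
        raise TraceParseError(f"{path}: need at least 2 columns, "
                              f"got {df.shape[1]}")
    bad = df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax())
        raise TraceParseError(
            f"{path}: malformed value in data row {row + 1}: "
            f"{data_lines[row]!r}")
    df = df.astype(float)
    if header is not None and len(header) == df.shape[1]:
        df.columns = [h.strip() for h in header]
    else:
        df.columns = ["time"] + [f"ch{i}" for i in range(1, df.shape[1])]

    time = df.iloc[:, 0].to_numpy()
    if np.any(np.diff(time) <= 0):
        raise TraceParseError(f"{path}: time column is not strictly increasing")
    diffs = np.diff(time)
    uniform = bool(diffs.size == 0
                   or np.allclose(diffs, diffs[0], rtol=dt_rtol, atol=0))
    if not uniform:
        warnings.warn(f"{path}: non-uniform time step", RuntimeWarning,
                      stacklevel=2)
    return TraceTable(time=time, channels=df.iloc[:, 1:],
                      meta={"path": str(path), "dialect": dialect},
                      uniform_dt=uniform)


def write_trace_table(path: str | Path, time: np.ndarray,
                      channels: dict[str, np.ndarray] | pd.DataFrame,
                      dialect: str = "tsv") -> None:
    """Write a trace table; full float precision so round trips are exact."""
    df = pd.DataFrame(channels)
    df.insert(0, "time", np.asarray(time))
    sep = _DIALECT_SEPS.get(dialect, "\t")
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_fret_trajectory(path: str | Path, traj, dialect: str = "tsv") -> None:
    """Write a FretTrajectory as (time, fret[, state]) columns."""
    cols: dict[str, np.ndarray] = {"fret": traj.values}
    if traj.hidden_states is not None:
        cols["state"] = traj.hidden_states
    write_trace_table(path, traj.times, cols, dialect=dialect)


# --------------------------------------------------------------------------
# multi-model PDB


def read_residue_trajectory_pdb(
    path: str | Path,
    atom_selection: str = "alpha_carbon",
    frame_interval: float = 1.0,
) -> ResidueTrajectory:
    """Read a multi-model PDB as a residue-coordinate trajectory.

    Author residue numbering is preserved, never re-indexed.  Models with
    differing residue sets raise :class:`ResidueMismatchError` listing the
    symmetric difference.  In ``all_atoms`` mode the per-residue atom
    coordinates are kept and the representative coordinate is the atom
    centroid; in ``alpha_carbon`` mode it is the CA position.
    """
    import biotite.structure.io.pdb as pdbio

    if atom_selection not in ("alpha_carbon", "all_atoms"):
        raise ValueError("atom_selection must be 'alpha_carbon' or 'all_atoms'")
    pdb_file = pdbio.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    models = [pdb_file.get_structure(model=i + 1) for i in range(n_models)]

    ref_ids = np.unique(models[0].res_id)
    for i, m in enumerate(models[1:], start=2):
        ids = np.unique(m.res_id)
        if not np.array_equal(ids, ref_ids):
            diff = sorted(set(ref_ids.tolist()) ^ set(ids.tolist()))
            raise ResidueMismatchError(
                f"{path}: model {i} residue set differs from model 1; "
                f"symmetric difference: {diff}")

    if atom_selection == "alpha_carbon":
        coords = np.empty((n_models, ref_ids.size, 3))
        for f, m in enumerate(models):
            ca = m[m.atom_name == "CA"]
            if np.unique(ca.res_id).size != ref_ids.size:
                missing = sorted(set(ref_ids.tolist())
                                 - set(np.unique(ca.res_id).tolist()))
                raise ResidueMismatchError(
                    f"{path}: model {f + 1} lacks CA atoms for residues "
                    f"{missing}")
            order = np.argsort(ca.res_id, kind="stable")
            coords[f] = ca.coord[order]
        return ResidueTrajectory(residue_ids=ref_ids, coords=coords,
                                 frame_interval=frame_interval,
                                 atom_mode="alpha_carbon",
                                 meta={"path": str(path)})

    atom_coords: dict[int, np.ndarray] = {}
    coords = np.empty((n_models, ref_ids.size, 3))
    for j, rid in enumerate(ref_ids):
        per_model = []
        for f, m in enumerate(models):
            sel = m[m.res_id == rid]
            per_model.append(sel.coord)
        n_atoms = {a.shape[0] for a in per_model}
        if len(n_atoms) != 1:
            raise ResidueMismatchError(
                f"{path}: residue {rid} has inconsistent atom counts "
                f"across models: {sorted(n_atoms)}")
        stack = np.stack(per_model)  # (n_models, n_atoms, 3)
        atom_coords[int(rid)] = stack
        coords[:, j, :] = stack.mean(axis=1)
    return ResidueTrajectory(residue_ids=ref_ids, coords=coords,
                             frame_interval=frame_interval,
                             atom_mode="all_atoms", atom_coords=atom_coords,
                             meta={"path": str(path)})


def write_residue_trajectory_pdb(traj: ResidueTrajectory,
                                 path: str | Path) -> None:
    """Write a residue trajectory as a multi-model CA-only PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n_res = traj.n_residues
    template = struc.AtomArray(n_res)
    template.res_id = traj.residue_ids
    template.res_name = np.array(["GLY"] * n_res)
    template.atom_name = np.array(["CA"] * n_res)
    template.element = np.array(["C"] * n_res)
    template.chain_id = np.array(["A"] * n_res)
    template.hetero = np.zeros(n_res, dtype=bool)
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.coords.copy()
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
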