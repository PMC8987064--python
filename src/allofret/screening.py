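"""Docking-result post-processing for fingerprint-guided lead selection.

The selection procedure mirrors a substrate-aware virtual-screening
workflow: parse per-ligand multi-mode docking results (Vina-style PDBQT
with ``REMARK VINA RESULT`` lines), keep ligands whose top two binding
modes differ in affinity by at least a configurable fraction (site-specific
binders), assign each retained ligand the receptor residue closest to its
top pose, and intersect the assignments with a substrate-specific
allosteric fingerprint.  Top-N lead lists from different receptor
conditions can be compared set-wise.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .entropy import ResidueTrajectory

__all__ = [
    "DockingMode",
    "DockingRecord",
    "LeadRow",
    "LeadSelection",
    "ReceptorFrame",
    "parse_vina_results",
    "write_vina_pdbqt",
    "affinity_gap_filter",
    "closest_residue",
    "fingerprint_leads",
    "compare_lead_lists",
    "LeadSelector",
]


@dataclass
class DockingMode:
    """One ranked docked conformation."""

    affinity: float                 # kcal/mol, more negative = stronger
    pose_atoms: np.ndarray          # (n_atoms, 3) Angstrom
    elements: np.ndarray | None = None  # PDBQT atom types, e.g. 'C', 'OA', 'HD'


@dataclass
class DockingRecord:
    """All docking modes of one ligand against one receptor condition."""

    ligand_id: str
    modes: list[DockingMode]
    receptor_label: str = ""

    def __post_init__(self) -> None:
        if len(self.modes) < 1:
            raise ValueError(f"ligand {self.ligand_id}: need at least one mode")
        affs = [m.affinity for m in self.modes]
        if affs != sorted(affs):
            warnings.warn(
                f"ligand {self.ligand_id}: modes out of affinity order; "
                "re-sorting", RuntimeWarning, stacklevel=2)
            self.modes = sorted(self.modes, key=lambda m: m.affinity)

    @property
    def best_affinity(self) -> float:
        return self.modes[0].affinity

    @property
    def gap_fraction(self) -> float | None:
        """|A1 - A2| / |A1|; None for single-mode records."""
        if len(self.modes) < 2:
            return None
        a1 = self.modes[0].affinity
        if a1 == 0:
            return None
        return abs(a1 - self.modes[1].affinity) / abs(a1)


@dataclass
class LeadRow:
    ligand_id: str
    best_affinity: float
    gap_fraction: float | None
    closest_residue_id: int
    closest_distance: float
    fingerprint_hit: bool = False
    single_mode: bool = False


@dataclass
class LeadSelection:
    """Filtered, residue-annotated lead set."""

    rows: list[LeadRow]
    min_gap: float
    n_input: int

    def __post_init__(self) -> None:
        for r in self.rows:
            if r.gap_fraction is not None and r.gap_fraction < self.min_gap:
                raise ValueError(
                    f"ligand {r.ligand_id} retained below the gap threshold")
            if r.closest_distance < 0:
                raise ValueError("distances must be non-negative")

    def ligand_ids(self) -> list[str]:
        return [r.ligand_id for r in self.rows]


@dataclass
class ReceptorFrame:
    """A single receptor conformation as atom coordinates with residue ids."""

    atom_residue_ids: np.ndarray  # (n_atoms,)
    coords: np.ndarray            # (n_atoms, 3)
    elements: np.ndarray | None = None

    @classmethod
    def from_trajectory(cls, traj: ResidueTrajectory, frame: int = 0
                        ) -> "ReceptorFrame":
        if traj.atom_coords is not None:
            ids, xyz = [], []
            for rid in traj.residue_ids:
                atoms = traj.atom_coords[int(rid)][frame]
                ids.extend([int(rid)] * atoms.shape[0])
                xyz.append(atoms)
            return cls(atom_residue_ids=np.asarray(ids, dtype=int),
                       coords=np.concatenate(xyz, axis=0))
        return cls(atom_residue_ids=traj.residue_ids.copy(),
                   coords=traj.coords[frame])


_VINA_REMARK = re.compile(r"REMARK\s+VINA\s+RESULT:\s+(-?\d+\.?\d*)")


def parse_vina_results(paths: list[str | Path],
                       receptor_label: str = "") -> list[DockingRecord]:
    """Parse Vina-output PDBQT files into docking records.

    One record per file; the ligand id is the file stem.  Affinity comes
    from the first numeric field of each MODEL's ``REMARK VINA RESULT``
    line; pose atoms from the ATOM/HETATM records (PDBQT coordinate columns,
    atom type from the trailing type column).
    """
    records = []
    for path in paths:
        path = Path(path)
        text = path.read_text()
        if not text.strip():
            raise ValueError(f"{path}: empty file")
        modes: list[DockingMode] = []
        affinity: float | None = None
        atoms: list[list[float]] = []
        elements: list[str] = []
        in_model = False
        model_index = 0

        def close_model() -> None:
            nonlocal affinity, atoms, elements
            if affinity is None:
                raise ValueError(
                    f"{path}: MODEL {model_index} has no REMARK VINA RESULT")
            modes.append(DockingMode(
                affinity=affinity,
                pose_atoms=np.asarray(atoms, dtype=float).reshape(-1, 3),
                elements=np.asarray(elements, dtype=object)))
            affinity, atoms, elements = None, [], []

        for line in text.splitlines():
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                model_index += 1
            elif rec == "ENDMDL":
                close_model()
                in_model = False
            elif rec == "REMARK" and "VINA RESULT" in line:
                m = _VINA_REMARK.search(line)
                if m:
                    affinity = float(m.group(1))
            elif rec in ("ATOM", "HETATM"):
                atoms.append([float(line[30:38]), float(line[38:46]),
                              float(line[46:54])])
                elements.append(line[77:].strip() or line[12:16].strip())
        if in_model:  # file missing a final ENDMDL
            close_model()
        if not modes:
            # single-model file without MODEL/ENDMDL wrapping
            if atoms:
                close_model()
            else:
                raise ValueError(f"{path}: no docking modes found")
        records.append(DockingRecord(ligand_id=path.stem, modes=modes,
                                     receptor_label=receptor_label))
    return records


def write_vina_pdbqt(record: DockingRecord, path: str | Path) -> None:
    """Write a record in Vina-output PDBQT layout (round-trip counterpart)."""
    lines = []
    for i, mode in enumerate(record.modes, start=1):
        lines.append(f"MODEL {i}")
        lines.append(f"REMARK VINA RESULT:    {mode.affinity:8.1f}"
                     f"      0.000      0.000")
        for j, (x, y, z) in enumerate(mode.pose_atoms, start=1):
            el = "C"
            if mode.elements is not None:
                el = str(mode.elements[j - 1])
            name = (el if len(el) <= 3 else el[:3]) + str(j)
            lines.append(
                f"ATOM  {j:5d} {name:<4s} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    "
                f"+0.000 {el:<2s}")
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\n")


def affinity_gap_filter(records: list[DockingRecord],
                        min_gap: float = 0.10,
                        denominator: str = "best") -> list[DockingRecord]:
    """Keep ligands whose top-two-mode affinity gap is at least ``min_gap``.

    The gap is ``|A1 - A2| / |A1|`` with A1 the best (most negative)
    affinity; ``denominator='second'`` divides by ``|A2|`` instead.
    Single-mode ligands are retained (there is no second mode to compete)
    and ligands with zero best affinity are skipped with a warning.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be non-negative")
    kept = []
    for rec in records:
        a1 = rec.modes[0].affinity
        if a1 == 0:
            warnings.warn(f"ligand {rec.ligand_id}: zero best affinity; "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        if len(rec.modes) < 2:
            kept.append(rec)
            continue
        a2 = rec.modes[1].affinity
        denom = abs(a1) if denominator == "best" else abs(a2)
        if denom == 0:
            warnings.warn(f"ligand {rec.ligand_id}: zero denominator; "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        if abs(a1 - a2) / denom >= min_gap:
            kept.append(rec)
    return kept


def _heavy_mask(elements: np.ndarray | None, n: int) -> np.ndarray:
    if elements is None:
        return np.ones(n, dtype=bool)
    return np.array([not str(e).upper().startswith("H") for e in elements])


def closest_residue(record: DockingRecord, receptor: ReceptorFrame,
                    heavy_only: bool = True,
                    tie_tol: float = 1e-9) -> tuple[int, float]:
    """Receptor residue closest to the ligand's top-mode pose.

    Minimum Euclidean distance over all (ligand atom, receptor atom) pairs
    of the top mode; hydrogens are excluded on both sides by default (PDBQT
    files carry polar hydrogens only).  Ties within ``tie_tol`` break toward
    the lower residue id.
    """
    mode = record.modes[0]
    if mode.pose_atoms.shape[0] == 0:
        raise ValueError(f"ligand {record.ligand_id}: empty top pose")
    lig = mode.pose_atoms
    rec_xyz = receptor.coords
    rec_ids = receptor.atom_residue_ids
    if heavy_only:
        lm = _heavy_mask(mode.elements, lig.shape[0])
        rm = _heavy_mask(receptor.elements, rec_xyz.shape[0])
        lig = lig[lm]
        rec_xyz, rec_ids = rec_xyz[rm], rec_ids[rm]
    if lig.shape[0] == 0 or rec_xyz.shape[0] == 0:
        raise ValueError("no heavy atoms to compare")
    d = cdist(lig, rec_xyz)
    per_atom = d.min(axis=0)
    dmin = per_atom.min()
    tied = rec_ids[per_atom <= dmin + tie_tol]
    return int(tied.min()), float(dmin)


def fingerprint_leads(selection: LeadSelection,
                      fingerprint: frozenset[int] | set[int]) -> LeadSelection:
    """Keep ligands whose closest residue belongs to the fingerprint."""
    if not fingerprint:
        warnings.warn("empty fingerprint: no leads can be retained",
                      RuntimeWarning, stacklevel=2)
    rows = []
    for r in selection.rows:
        hit = r.closest_residue_id in fingerprint
        if hit:
            rows.append(LeadRow(**{**r.__dict__, "fingerprint_hit": True}))
    return LeadSelection(rows=rows, min_gap=selection.min_gap,
                         n_input=len(selection.rows))


def compare_lead_lists(lists: dict[str, list[str]], N: int = 10) -> dict:
    """Unique and shared ligand ids among top-N lists per condition.

    Returns per-condition unique ids, pairwise and (when three or more
    conditions are given) higher-order intersection sizes, Venn-diagram
    style.
    """
    if len(lists) < 2:
        raise ValueError("need at least two conditions to compare")
    tops = {}
    for cond, ids in lists.items():
        if N > len(ids):
            warnings.warn(f"condition {cond}: top-{N} truncated to "
                          f"{len(ids)} available ligands", RuntimeWarning,
                          stacklevel=2)
        tops[cond] = set(ids[:N])
    conds = sorted(tops)
    others = {c: set().union(*(tops[o] for o in conds if o != c))
              for c in conds}
    result: dict = {
        "N": N,
        "unique": {c: sorted(tops[c] - others[c]) for c in conds},
        "pairwise_intersection": {
            f"{a}&{b}": len(tops[a] & tops[b])
            for a, b in combinations(conds, 2)},
    }
    for k in range(3, len(conds) + 1):
        for combo in combinations(conds, k):
            inter = set.intersection(*(tops[c] for c in combo))
            result.setdefault(f"{k}-way_intersection", {})[
                "&".join(combo)] = len(inter)
    return result


class LeadSelector(BaseEstimator):
    """Gap-filter docking records and annotate/intersect with a fingerprint.

    Parameters
    ----------
    min_gap : float
        Minimum top-two-mode affinity gap fraction (default 0.10).
    gap_denominator : str
        'best' (|A1|, default) or 'second' (|A2|).
    fingerprint : set of int, optional
        Substrate-specific allosteric residue ids; when given, ``leads_``
        holds only fingerprint hits.
    heavy_only : bool
        Exclude hydrogens in the closest-residue search.

    Attributes
    ----------
    selection_ : LeadSelection  (gap-filtered, residue-annotated)
    leads_ : LeadSelection      (fingerprint hits; equals selection_ when no
                                 fingerprint is configured)
    """

    def __init__(self, min_gap: float = 0.10, gap_denominator: str = "best",
                 fingerprint: frozenset[int] | set[int] | None = None,
                 heavy_only: bool = True):
        self.min_gap = min_gap
        self.gap_denominator = gap_denominator
        self.fingerprint = fingerprint
        self.heavy_only = heavy_only

    def fit(self, X, receptor: ReceptorFrame | None = None, y=None):
        """Fit on a list of DockingRecord given a receptor frame."""
        if receptor is None:
            raise ValueError("a ReceptorFrame is required")
        retained = affinity_gap_filter(X, min_gap=self.min_gap,
                                       denominator=self.gap_denominator)
        rows = []
        for rec in retained:
            rid, dist = closest_residue(rec, receptor,
                                        heavy_only=self.heavy_only)
            rows.append(LeadRow(
                ligand_id=rec.ligand_id, best_affinity=rec.best_affinity,
                gap_fraction=rec.gap_fraction, closest_residue_id=rid,
                closest_distance=dist,
                fingerprint_hit=(self.fingerprint is not None
                                 and rid in self.fingerprint),
                single_mode=len(rec.modes) < 2))
        self.selection_ = LeadSelection(rows=rows, min_gap=self.min_gap,
                                        n_input=len(X))
        if self.fingerprint is not None:
            self.leads_ = fingerprint_leads(self.selection_,
                                            self.fingerprint)
        else:
            self.leads_ = self.selection_
        return self
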