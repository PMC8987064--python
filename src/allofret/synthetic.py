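"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure of the real inputs:

* anticorrelated donor/acceptor intensity traces driven by the hidden
  two-state process (inverting FRET = I_A/(I_A+I_D));
* residue-coordinate trajectories in which a designated catalytic-motif set
  and a designated allosteric set share a latent AR(1) displacement (the
  planted coupling), applied to both sets when the enzyme is "bound" and to
  the motif only when "free" — a statistical stand-in for correlated
  interdomain motion in MD trajectories;
* docking-record cohorts with controlled top-two-mode affinity gaps and top
  poses planted next to chosen receptor residues.

Every generator is a pure function of (spec, seed) and returns ground-truth
labels next to the data; tests never re-derive truth from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import ResidueTrajectory
from .screening import DockingMode, DockingRecord, ReceptorFrame
from .smfret import IntensityTrace
from .telegraph import TwoStateParams, simulate_trajectory

__all__ = [
    "PlantedCouplingSpec",
    "SyntheticCohortSpec",
    "gen_intensity_traces",
    "gen_residue_trajectory",
    "gen_docking_cohort",
    "default_residue_ids",
]

#: AR(1) coefficient of the latent shared displacement; ~10-frame
#: autocorrelation time so the lag-1 correlation convention detects it.
AR1_COEFF = 0.9

#: Grid spacing of the synthetic backbone layout, Angstrom.
GRID_SPACING = 5.0


def default_residue_ids() -> np.ndarray:
    """60 author-numbered ids: a catalytic stretch spanning the motif
    (210-239) plus a hemopexin stretch (280-309)."""
    return np.concatenate([np.arange(210, 240), np.arange(280, 310)])


@dataclass(frozen=True)
class PlantedCouplingSpec:
    """Planted correlated-motion design for residue trajectories."""

    residue_ids: tuple[int, ...] = tuple(default_residue_ids().tolist())
    motif_ids: tuple[int, ...] = tuple(range(218, 229))
    allosteric_ids: tuple[int, ...] = (281, 285, 292, 300, 307)
    loading: float = 0.8          # shared-factor coefficient in [0, 1]
    noise_sd: float = 1.0         # isotropic positional jitter, Angstrom
    n_frames: int = 4000
    frame_interval: float = 0.005  # ns per frame (5 ps sampling)
    condition: str = "bound"      # {"bound", "free"}

    def __post_init__(self) -> None:
        if set(self.allosteric_ids) & set(self.motif_ids):
            raise ValueError("allosteric and motif sets must be disjoint")
        if not set(self.motif_ids) <= set(self.residue_ids):
            raise ValueError("motif ids must be in residue_ids")
        if not set(self.allosteric_ids) <= set(self.residue_ids):
            raise ValueError("allosteric ids must be in residue_ids")
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [0, 1]")
        if self.condition not in ("bound", "free"):
            raise ValueError("condition must be 'bound' or 'free'")

    @property
    def affected_ids(self) -> frozenset[int]:
        """Residues carrying the shared latent displacement."""
        if self.condition == "bound":
            return frozenset(self.motif_ids) | frozenset(self.allosteric_ids)
        return frozenset(self.motif_ids)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Docking cohort design with planted gaps and pose placement."""

    n_ligands: int = 50
    gap_low: float = 0.0
    gap_high: float = 0.2
    fraction_near_fingerprint: float = 0.1
    n_modes: int = 2
    atoms_per_ligand: int = 8
    affinity_low: float = -11.0
    affinity_high: float = -7.0
    placement_radius: float = 2.0  # Angstrom from the target residue

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_near_fingerprint <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.n_ligands < 1:
            raise ValueError("need at least one ligand")


def gen_intensity_traces(
    params: TwoStateParams,
    total_intensity: float = 100.0,
    n_traj: int = 1,
    n_frames: int = 2000,
    dt: float = 0.1,
    detection_noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[IntensityTrace]:
    """Two-channel intensity traces driven by the hidden two-state process.

    The hidden FRET series (state values without observation noise) is
    inverted into I_A = FRET*total and I_D = total - I_A, then independent
    Gaussian detection noise is added per channel, so the channels are
    anticorrelated by construction whenever the chain switches.
    """
    if total_intensity <= 0:
        raise ValueError("total_intensity must be positive")
    children = np.random.SeedSequence(seed).spawn(n_traj)
    traces = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        traj = simulate_trajectory(params, n_frames, dt, with_noise=False,
                                   rng=rng)
        I_A = traj.values * total_intensity
        I_D = total_intensity - I_A
        if detection_noise_sd > 0:
            I_A = I_A + rng.normal(0, detection_noise_sd, n_frames)
            I_D = I_D + rng.normal(0, detection_noise_sd, n_frames)
        traces.append(IntensityTrace(I_D=I_D, I_A=I_A, dt=dt,
                                     meta={"molecule": i,
                                           "hidden_states": traj.hidden_states}))
    return traces


def _base_positions(n: int) -> np.ndarray:
    """Base backbone positions on a 3-D grid with 5 A spacing (geometry is
    irrelevant to the correlation analysis but keeps PDB output plausible)."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    grid = np.stack(np.meshgrid(*([np.arange(side)] * 3), indexing="ij"),
                    axis=-1).reshape(-1, 3)[:n]
    return grid * GRID_SPACING


def gen_residue_trajectory(
    spec: PlantedCouplingSpec,
    seed: int | None = None,
) -> tuple[ResidueTrajectory, dict]:
    """Residue trajectory with a planted shared-factor coupling.

    Each residue's position is its fixed base position plus isotropic
    Gaussian jitter (``noise_sd``) plus, for affected residues,
    ``loading`` times a shared latent AR(1) displacement (stationary SD 1 A,
    coefficient 0.9) applied along the residue's outward radial direction so
    that radial coordinates pick the coupling up linearly.

    Returns the trajectory and a ground-truth dict.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(spec.residue_ids, dtype=int)
    n_res = ids.size
    base = _base_positions(n_res)
    center = base.mean(axis=0)
    radial = base - center
    norms = np.linalg.norm(radial, axis=1)
    norms[norms == 0] = 1.0
    u = radial / norms[:, None]

    # latent AR(1), stationary SD 1
    innov_sd = np.sqrt(1.0 - AR1_COEFF**2)
    eps = rng.normal(0.0, innov_sd, spec.n_frames)
    z = np.empty(spec.n_frames)
    z[0] = rng.normal()  # stationary start
    for t in range(1, spec.n_frames):
        z[t] = AR1_COEFF * z[t - 1] + eps[t]

    affected = np.isin(ids, list(spec.affected_ids))
    coords = (base[None, :, :]
              + rng.normal(0.0, spec.noise_sd, (spec.n_frames, n_res, 3)))
    coords += (spec.loading * z[:, None, None]) * (u * affected[:, None])[None]

    traj = ResidueTrajectory(
        residue_ids=ids, coords=coords,
        frame_interval=spec.frame_interval, atom_mode="alpha_carbon",
        meta={"condition": spec.condition, "loading": spec.loading},
    )
    truth = {
        "condition": spec.condition,
        "motif_ids": sorted(spec.motif_ids),
        "allosteric_ids": sorted(spec.allosteric_ids),
        "affected_ids": sorted(spec.affected_ids),
        "loading": spec.loading,
        "noise_sd": spec.noise_sd,
    }
    return traj, truth


def gen_docking_cohort(
    spec: SyntheticCohortSpec,
    receptor: ReceptorFrame,
    fingerprint: frozenset[int] | set[int],
    seed: int | None = None,
) -> tuple[list[DockingRecord], dict]:
    """Docking records with planted gaps and planted pose placement.

    Exactly ``round(fraction * n_ligands)`` ligands have their top pose
    placed within ``placement_radius`` of a fingerprint residue; the rest
    next to non-fingerprint residues.  Top-two affinity gaps are drawn
    uniformly from [gap_low, gap_high] and imposed exactly
    (A2 = A1*(1 - gap)).  Ground-truth labels are returned alongside.
    """
    rng = np.random.default_rng(seed)
    fingerprint = frozenset(int(r) for r in fingerprint)
    all_ids = np.unique(receptor.atom_residue_ids)
    fp_ids = np.array(sorted(set(all_ids.tolist()) & fingerprint), dtype=int)
    non_fp = np.array(sorted(set(all_ids.tolist()) - fingerprint), dtype=int)
    n_fp = int(round(spec.fraction_near_fingerprint * spec.n_ligands))
    if n_fp > 0 and fp_ids.size == 0:
        raise ValueError("fingerprint has no residues present in the receptor")
    near_fp = np.zeros(spec.n_ligands, dtype=bool)
    near_fp[rng.choice(spec.n_ligands, size=n_fp, replace=False)] = True

    records, truth_rows = [], []
    for i in range(spec.n_ligands):
        pool = fp_ids if near_fp[i] else non_fp
        target = int(rng.choice(pool))
        target_atoms = receptor.coords[receptor.atom_residue_ids == target]
        anchor = target_atoms[rng.integers(target_atoms.shape[0])]
        # small cloud hugging the target residue atom
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = anchor + direction * (0.4 * spec.placement_radius)
        pose = center + rng.normal(0.0, 0.2, (spec.atoms_per_ligand, 3))

        a1 = rng.uniform(spec.affinity_low, spec.affinity_high)
        gap = rng.uniform(spec.gap_low, spec.gap_high)
        affs = [a1, a1 * (1.0 - gap)]
        while len(affs) < spec.n_modes:
            affs.append(affs[-1] * (1.0 - rng.uniform(0.0, 0.1)))
        modes = []
        for j, a in enumerate(affs):
            if j == 0:
                atoms = pose
            else:
                # secondary modes wander elsewhere on the receptor
                other = receptor.coords[rng.integers(receptor.coords.shape[0])]
                atoms = other + rng.normal(0.0, 0.5, (spec.atoms_per_ligand, 3))
            modes.append(DockingMode(affinity=float(a), pose_atoms=atoms,
                                     elements=np.array(["C"] * atoms.shape[0],
                                                       dtype=object)))
        lig = f"ZINC{i:08d}"
        records.append(DockingRecord(ligand_id=lig, modes=modes))
        truth_rows.append({
            "ligand_id": lig, "gap": float(gap), "target_residue": target,
            "fingerprint_proximal": bool(near_fp[i]),
        })
    truth = {
        "rows": truth_rows,
        "n_fingerprint_proximal": int(n_fp),
        "fingerprint": sorted(fingerprint),
    }
    return records, truth
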