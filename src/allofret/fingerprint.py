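"""Substrate-specific allosteric fingerprints and catalytic-site geometry.

A residue belongs to the allosteric fingerprint of a substrate when its
normalized correlation with the catalytic motif exceeds a threshold in the
substrate-bound enzyme but not in the free enzyme.  For MMP1 the motif is
the zinc-binding sequence HELGHSLGLSH (author-numbered residues 218-228
around the catalytic glutamate E219); the reported fingerprint is restricted
to the hemopexin domain (D279-C466), the domain responsible for substrate
recognition.

Catalytic-site geometry is summarized relative to the catalytic glutamate:
per-residue all-atom centroids expressed in the origin residue's frame and
pairwise motif distances as mean +/- SD over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator

from .entropy import CorrelationMatrix, ResidueTrajectory

__all__ = [
    "MotifSpec",
    "FingerprintResult",
    "CatalyticGeometry",
    "motif_correlations",
    "threshold_from_histogram",
    "extract_fingerprint",
    "catalytic_geometry",
    "compare_geometries",
    "FingerprintExtractor",
]

#: Author-numbered ids of the MMP1 catalytic motif HELGHSLGLSH (H218..H228).
CATALYTIC_MOTIF_IDS: tuple[int, ...] = tuple(range(218, 229))


@dataclass(frozen=True)
class MotifSpec:
    """Catalytic motif definition and domain ranges (author numbering)."""

    motif_residue_ids: tuple[int, ...] = CATALYTIC_MOTIF_IDS
    origin_residue_id: int = 219
    catalytic_range: tuple[int, int] = (100, 260)
    hemopexin_range: tuple[int, int] = (279, 466)

    def __post_init__(self) -> None:
        lo, hi = self.catalytic_range
        if not all(lo <= r <= hi for r in self.motif_residue_ids):
            raise ValueError("motif residues must lie in the catalytic range")
        if self.origin_residue_id not in self.motif_residue_ids:
            raise ValueError("origin residue must belong to the motif")

    def in_hemopexin(self, residue_id: int) -> bool:
        lo, hi = self.hemopexin_range
        return lo <= residue_id <= hi


@dataclass
class FingerprintResult:
    """Threshold-qualified residue sets and the bound-only exclusive set."""

    bound_set: frozenset[int]
    free_set: frozenset[int]
    exclusive_set: frozenset[int]
    threshold: float
    n_repeats_bound: int
    n_repeats_free: int
    min_repeats: int
    scores_bound: dict[int, list[float]] = field(default_factory=dict)
    scores_free: dict[int, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exclusive_set <= self.bound_set:
            raise ValueError("exclusive set must be a subset of the bound set")
        if self.exclusive_set & self.free_set:
            raise ValueError("exclusive set must be disjoint from the free set")


@dataclass
class CatalyticGeometry:
    """Residue geometry relative to the catalytic origin residue."""

    residue_ids: np.ndarray
    mean_rel_position: np.ndarray     # (R, 3) Angstrom, origin residue at 0
    motif_pairs: list[tuple[int, int]]
    pair_mean: np.ndarray             # mean pairwise distance over frames
    pair_sd: np.ndarray               # SD over frames (the spread)
    atom_mode: str = "alpha_carbon"


def motif_correlations(
    corr: CorrelationMatrix,
    motif: MotifSpec | None = None,
    aggregate: str = "max",
) -> dict[int, float]:
    """Per-residue correlation score with the catalytic motif.

    The score of residue r is the max (default) or mean over motif residues
    m of ``corr[r, m]`` — under max-aggregation a single strong channel to
    any motif residue qualifies.  Motif residues themselves are excluded
    from candidacy.
    """
    motif = motif or MotifSpec()
    missing = [m for m in motif.motif_residue_ids
               if m not in set(corr.residue_ids.tolist())]
    if missing:
        raise KeyError(f"motif residue(s) missing from matrix: {missing}")
    cols = [corr.index_of(m) for m in motif.motif_residue_ids]
    sub = corr.values[:, cols]
    agg = {"max": np.max, "mean": np.mean}.get(aggregate)
    if agg is None:
        raise ValueError("aggregate must be 'max' or 'mean'")
    scores = agg(sub, axis=1)
    motif_ids = set(motif.motif_residue_ids)
    return {int(rid): float(s)
            for rid, s in zip(corr.residue_ids, scores)
            if int(rid) not in motif_ids}


def threshold_from_histogram(
    corr_values: np.ndarray | None = None,
    mode: str = "fixed",
    fixed: float = 0.8,
    density: np.ndarray | None = None,
    axis_max: float | None = None,
    reference_values: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Correlation threshold for fingerprint membership.

    ``fixed`` mode returns the configured value (default 0.8).  The
    experimental ``density_peak_rule`` divides the peak probability density
    of the correlation-value distribution by a reference density-axis
    maximum — either ``axis_max``, the peak of ``reference_values``'s
    density, or (degenerately) the peak itself.  Returns ``(threshold,
    experimental_flag)``.
    """
    if mode == "fixed":
        return float(fixed), False
    if mode != "density_peak_rule":
        raise ValueError("mode must be 'fixed' or 'density_peak_rule'")

    def _peak(vals: np.ndarray | None, dens: np.ndarray | None) -> float:
        if dens is not None:
            return float(np.max(dens))
        v = np.asarray(vals, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("empty correlation values")
        if np.ptp(v) == 0:
            return np.inf  # degenerate single-value distribution
        hist, edges = np.histogram(v, bins="auto", density=True)
        return float(hist.max())

    peak = _peak(corr_values, density)
    if axis_max is not None:
        ref = float(axis_max)
    elif reference_values is not None:
        ref = _peak(reference_values, None)
    else:
        ref = peak
    if not np.isfinite(peak) or not np.isfinite(ref):
        return 1.0, True
    return min(peak / ref, 1.0), True


def _qualifying_set(
    matrices: list[CorrelationMatrix],
    motif: MotifSpec,
    threshold: float,
    min_repeats: int,
    aggregate: str,
) -> tuple[frozenset[int], dict[int, list[float]]]:
    counts: dict[int, int] = {}
    scores: dict[int, list[float]] = {}
    for m in matrices:
        for rid, s in motif_correlations(m, motif, aggregate=aggregate).items():
            scores.setdefault(rid, []).append(s)
            if s > threshold:
                counts[rid] = counts.get(rid, 0) + 1
    need = min(min_repeats, len(matrices))
    return frozenset(r for r, c in counts.items() if c >= need), scores


def extract_fingerprint(
    bound: CorrelationMatrix | list[CorrelationMatrix],
    free: CorrelationMatrix | list[CorrelationMatrix],
    motif: MotifSpec | None = None,
    threshold: float = 0.8,
    min_repeats: int = 2,
    aggregate: str = "mean",
) -> FingerprintResult:
    """Bound-only (substrate-specific) allosteric residues.

    With repeat matrices, a residue qualifies in a condition when it exceeds
    the threshold in at least ``min_repeats`` repeats (capped at the number
    supplied).  The exclusive set is ``bound_set - free_set`` restricted to
    the hemopexin range; the unrestricted per-condition sets are kept for
    inspection.
    """
    motif = motif or MotifSpec()
    bound_list = bound if isinstance(bound, list) else [bound]
    free_list = free if isinstance(free, list) else [free]
    ids_b = set(bound_list[0].residue_ids.tolist())
    for m in bound_list + free_list:
        ids = set(m.residue_ids.tolist())
        if ids != ids_b:
            diff = sorted(ids ^ ids_b)
            raise ValueError(f"matrices cover different residues; "
                             f"symmetric difference: {diff}")
    bound_set, scores_b = _qualifying_set(bound_list, motif, threshold,
                                          min_repeats, aggregate)
    free_set, scores_f = _qualifying_set(free_list, motif, threshold,
                                         min_repeats, aggregate)
    exclusive = frozenset(r for r in bound_set - free_set
                          if motif.in_hemopexin(r))
    return FingerprintResult(
        bound_set=bound_set, free_set=free_set, exclusive_set=exclusive,
        threshold=threshold,
        n_repeats_bound=len(bound_list), n_repeats_free=len(free_list),
        min_repeats=min_repeats, scores_bound=scores_b, scores_free=scores_f,
    )


def catalytic_geometry(
    traj: ResidueTrajectory,
    motif: MotifSpec | None = None,
) -> CatalyticGeometry:
    """Residue centroids relative to the origin residue, motif pair spreads.

    Per frame a residue's position is the centroid of its atoms (all-atom
    mode) or its representative coordinate; positions are expressed relative
    to the origin residue's centroid so the origin sits at (0, 0, 0) in
    every frame.  Pairwise motif-residue distances are summarized as mean
    and SD over frames.
    """
    motif = motif or MotifSpec()
    ids = traj.residue_ids
    n_frames = traj.n_frames
    if traj.atom_coords is not None:
        centroids = np.empty((n_frames, ids.size, 3))
        for j, rid in enumerate(ids):
            atoms = traj.atom_coords.get(int(rid))
            if atoms is None or atoms.shape[1] == 0:
                raise ValueError(f"residue {rid} has no atoms")
            centroids[:, j, :] = atoms.mean(axis=1)
        mode = "all_atoms"
    else:
        centroids = traj.coords
        mode = traj.atom_mode
    origin_idx = traj.index_of(motif.origin_residue_id)
    rel = centroids - centroids[:, [origin_idx], :]

    motif_idx = {}
    for m in motif.motif_residue_ids:
        try:
            motif_idx[m] = traj.index_of(m)
        except KeyError as exc:
            raise KeyError(f"motif residue {m} absent from trajectory") from exc
    pairs = list(combinations(motif.motif_residue_ids, 2))
    pair_mean = np.empty(len(pairs))
    pair_sd = np.empty(len(pairs))
    for p, (i, j) in enumerate(pairs):
        d = np.linalg.norm(centroids[:, motif_idx[i], :]
                           - centroids[:, motif_idx[j], :], axis=1)
        pair_mean[p] = d.mean()
        pair_sd[p] = d.std()
    return CatalyticGeometry(
        residue_ids=ids, mean_rel_position=rel.mean(axis=0),
        motif_pairs=pairs, pair_mean=pair_mean, pair_sd=pair_sd,
        atom_mode=mode,
    )


def compare_geometries(free: CatalyticGeometry,
                       bound: CatalyticGeometry) -> dict:
    """Per-motif-pair distance changes between free and bound geometries."""
    if free.motif_pairs != bound.motif_pairs:
        raise ValueError("geometries cover different motif pairs")
    d_mean = bound.pair_mean - free.pair_mean
    d_sd = bound.pair_sd - free.pair_sd
    return {
        "pairs": free.motif_pairs,
        "delta_mean": d_mean,
        "delta_sd": d_sd,
        "configuration_change_norm": float(np.linalg.norm(d_mean)),
    }


class FingerprintExtractor(BaseEstimator):
    """Extract a substrate-specific allosteric fingerprint.

    Parameters
    ----------
    motif : MotifSpec
    threshold : float
        Normalized-correlation threshold (default 0.8).
    min_repeats : int
        Repeat-consensus rule: a residue qualifies in a condition when it
        exceeds the threshold in at least this many repeats.
    aggregate : str
        'max' (default) or 'mean' over motif residues.

    Attributes
    ----------
    result_ : FingerprintResult
    bound_set_, free_set_, exclusive_set_ : frozenset of residue ids
    """

    def __init__(self, motif: MotifSpec | None = None, threshold: float = 0.8,
                 min_repeats: int = 2, aggregate: str = "mean"):
        self.motif = motif
        self.threshold = threshold
        self.min_repeats = min_repeats
        self.aggregate = aggregate

    def fit(self, bound, free=None, y=None):
        """Fit from bound and free correlation matrices (or repeat lists).

        ``bound`` may also be a dict ``{"bound": ..., "free": ...}`` so the
        estimator can sit in a pipeline with a single argument.
        """
        if free is None:
            if not isinstance(bound, dict):
                raise ValueError("provide free matrices or a "
                                 "{'bound':..., 'free':...} dict")
            free = bound["free"]
            bound = bound["bound"]
        self.result_ = extract_fingerprint(
            bound, free, motif=self.motif or MotifSpec(),
            threshold=self.threshold, min_repeats=self.min_repeats,
            aggregate=self.aggregate)
        self.bound_set_ = self.result_.bound_set
        self.free_set_ = self.result_.free_set
        self.exclusive_set_ = self.result_.exclusive_set
        return self
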