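"""Residue-pair correlation maps and GLCM Shannon entropy.

Per-residue scalar trajectories (radial distances of alpha carbons from a
common origin) are divided into non-overlapping windows; within each window
the cross-correlation of mean-subtracted fluctuations is computed at a fixed
lag for every residue pair, symmetrized, averaged over windows, and min/max
normalized to [0, 1].  The normalized map is quantized into levels of width
0.1 and summarized as a 10x10 gray-level co-occurrence matrix (GLCM), whose
Shannon entropy S = -sum p_i ln p_i quantifies how textured (correlated) the
dynamics are: coherent interdomain motion concentrates co-occurrences and
lowers S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .smfret import correlation_single

__all__ = [
    "ResidueTrajectory",
    "CorrelationMatrix",
    "Glcm",
    "EntropyResult",
    "radial_coordinates",
    "windowed_correlation",
    "glcm_from_matrix",
    "shannon_entropy",
    "entropy_timeseries",
    "CorrelationEntropy",
]


@dataclass
class ResidueTrajectory:
    """Per-residue coordinate time series.

    ``coords`` holds one representative point per residue per frame (the
    alpha carbon, or the atom centroid in all-atom mode); ``atom_coords``
    optionally carries the full per-residue atom coordinates, keyed by
    author-numbered residue id.  Residue ids follow the source PDB author
    numbering and are never re-indexed.
    """

    residue_ids: np.ndarray
    coords: np.ndarray  # (n_frames, n_residues, 3), Angstrom
    frame_interval: float = 1.0
    atom_mode: str = "alpha_carbon"
    atom_coords: dict[int, np.ndarray] | None = None  # id -> (n_frames, n_atoms, 3)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_residues, 3)")
        if self.coords.shape[1] != self.residue_ids.size:
            raise ValueError("coords second axis must match residue_ids")
        if self.coords.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain missing or non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.residue_ids.size

    def index_of(self, residue_id: int) -> int:
        idx = np.flatnonzero(self.residue_ids == residue_id)
        if idx.size == 0:
            raise KeyError(f"residue {residue_id} not in trajectory")
        return int(idx[0])


@dataclass
class CorrelationMatrix:
    """Window-averaged residue-pair correlation map."""

    residue_ids: np.ndarray
    values: np.ndarray  # (R, R)
    lag: int
    normalized: bool
    window_summary: int  # number of windows averaged
    flagged_residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.residue_ids.size, self.residue_ids.size):
            raise ValueError("values must be square over residue_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation matrix contains non-finite values")

    def index_of(self, residue_id: int) -> int:
        idx = np.flatnonzero(self.residue_ids == residue_id)
        if idx.size == 0:
            raise KeyError(f"residue {residue_id} not in matrix")
        return int(idx[0])


@dataclass
class Glcm:
    """Co-occurrence probability matrix over quantized correlation levels."""

    P: np.ndarray
    bin_edges: np.ndarray
    offset: tuple[int, int]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if not np.isclose(self.P.sum(), 1.0):
            raise ValueError("GLCM probabilities must sum to 1")
        if np.any(self.P < 0):
            raise ValueError("GLCM probabilities must be non-negative")


@dataclass
class EntropyResult:
    """Shannon entropy in nats, optionally resolved over windows/repeats."""

    S: float
    per_window_S: np.ndarray | None = None
    mean_sd_over_repeats: tuple[float, float] | None = None


def radial_coordinates(
    traj: ResidueTrajectory,
    origin: str | int = "center_of_mass",
) -> np.ndarray:
    """Per-frame distance of every residue from a common origin.

    ``origin`` is either ``"center_of_mass"`` (the mean of the per-residue
    representative coordinates, recomputed each frame) or a residue id whose
    position serves as the origin.  Returns an array of shape
    (n_frames, n_residues) in Angstrom.
    """
    if origin == "center_of_mass":
        origin_xyz = traj.coords.mean(axis=1, keepdims=True)
    else:
        origin_xyz = traj.coords[:, [traj.index_of(int(origin))], :]
    return np.linalg.norm(traj.coords - origin_xyz, axis=2)


def _window_corr(series: np.ndarray, lag: int) -> np.ndarray:
    """Pairwise cross-correlation of one window at the given lag.

    Vectorized form of the cross-correlation with windowed mean subtraction:
    rows of ``A`` are the first factors, rows of ``B`` the lag-shifted second
    factors; the (i, j) entry equals the scalar cross-correlation of series i
    with series j at the lag.
    """
    w = series.shape[0]
    A = series[: w - lag] - series[: w - lag].mean(axis=0)
    B = series[lag:] - series[lag:].mean(axis=0)
    return A.T @ B / (w - lag)


def windowed_correlation(
    series: np.ndarray,
    residue_ids: np.ndarray,
    window_frames: int = 200,
    lag: int = 1,
    normalize: bool = True,
) -> CorrelationMatrix:
    """Window-averaged, symmetrized residue-pair correlation map.

    The series (n_frames, n_residues) is cut into non-overlapping windows of
    ``window_frames`` (a final partial window is dropped); per window the
    pairwise cross-correlation of mean-subtracted series at the given lag is
    computed, symmetrized as (C + C.T)/2, and averaged over windows.  With
    ``normalize`` the averaged matrix is shifted and scaled once so its
    minimum is 0 and maximum is 1.

    A residue whose series is constant within a window contributes nothing
    in that window; its entries are averaged from the remaining windows and
    the residue is flagged.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2-D (n_frames, n_residues)")
    n_frames, n_res = series.shape
    if n_frames < window_frames:
        raise ValueError(
            f"need at least window_frames={window_frames} frames, got {n_frames}"
        )
    if lag >= window_frames:
        raise ValueError("lag must be smaller than window_frames")
    n_windows = n_frames // window_frames

    acc = np.zeros((n_res, n_res))
    weight = np.zeros((n_res, n_res))
    flagged: set[int] = set()
    for w in range(n_windows):
        block = series[w * window_frames:(w + 1) * window_frames]
        C = _window_corr(block, lag)
        C = 0.5 * (C + C.T)
        ok = block.std(axis=0) > 0
        if not ok.all():
            flagged.update(np.asarray(residue_ids)[~ok].tolist())
        mask = np.outer(ok, ok)
        acc[mask] += C[mask]
        weight += mask
    if np.any(weight == 0):
        # a residue constant in every window: define its correlations as 0
        warnings.warn("residue(s) with zero variance in every window; their "
                      "correlations are set to 0", RuntimeWarning, stacklevel=2)
        weight[weight == 0] = 1
    values = acc / weight

    if normalize:
        vmin, vmax = values.min(), values.max()
        if vmax > vmin:
            values = (values - vmin) / (vmax - vmin)
        else:
            values = np.zeros_like(values)
    return CorrelationMatrix(
        residue_ids=np.asarray(residue_ids, dtype=int), values=values,
        lag=lag, normalized=normalize, window_summary=n_windows,
        flagged_residues=tuple(sorted(flagged)),
    )


def glcm_from_matrix(
    corr: CorrelationMatrix | np.ndarray,
    bins: int = 10,
    bin_width: float = 0.1,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
) -> Glcm:
    """Quantize a normalized correlation map and count co-occurrences.

    Each cell is quantized to level ``floor(v / bin_width)`` clipped to
    ``0..bins-1`` (so a value of exactly 1.0 maps to the top level, not an
    overflow level).  Co-occurrences are counted for the cell pair displaced
    by ``offset`` (default: horizontally adjacent) and, when ``symmetric``,
    in both orders — the standard texture-analysis symmetric GLCM.  Counts
    are normalized to probabilities.
    """
    values = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr, float)
    if isinstance(corr, CorrelationMatrix) and not corr.normalized:
        raise ValueError("GLCM requires a normalized correlation matrix")
    levels = np.clip(np.floor(values / bin_width).astype(int), 0, bins - 1)
    dr, dc = offset
    if (dr, dc) == (0, 0):
        raise ValueError("offset must be non-zero")
    nr, nc = levels.shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    ok = (rows + dr >= 0) & (rows + dr < nr) & (cols + dc >= 0) & (cols + dc < nc)
    src = levels[rows[ok], cols[ok]]
    dst = levels[rows[ok] + dr, cols[ok] + dc]
    P = np.zeros((bins, bins))
    np.add.at(P, (src, dst), 1.0)
    if symmetric:
        np.add.at(P, (dst, src), 1.0)
    total = P.sum()
    if total == 0:
        raise ValueError("matrix too small for the requested offset")
    edges = bin_width * np.arange(bins + 1)
    return Glcm(P=P / total, bin_edges=edges, offset=(dr, dc))


def shannon_entropy(glcm: Glcm) -> EntropyResult:
    """Shannon entropy S = -sum p_i ln p_i (nats) over populated GLCM cells."""
    p = glcm.P[glcm.P > 0]
    S = float(-(p * np.log(p)).sum())
    return EntropyResult(S=S)


def entropy_timeseries(
    series: np.ndarray | list[np.ndarray],
    residue_ids: np.ndarray,
    window_frames: int = 200,
    lag: int = 1,
    bins: int = 10,
    bin_width: float = 0.1,
    offset: tuple[int, int] = (0, 1),
) -> EntropyResult:
    """Per-window Shannon entropy, optionally averaged over repeats.

    Each window's correlation matrix is min/max-normalized on its own before
    quantization, so the entropy series reflects the texture of each window
    rather than the pooled scale.  When a list of repeat trajectories is
    given, the windowwise mean and the SD across repeats of the overall mean
    entropy are reported.
    """
    repeats = series if isinstance(series, list) else [series]
    all_windows = []
    for rep in repeats:
        rep = np.asarray(rep, dtype=float)
        n_windows = rep.shape[0] // window_frames
        if n_windows < 1:
            raise ValueError("series shorter than one window")
        ws = []
        for w in range(n_windows):
            block = rep[w * window_frames:(w + 1) * window_frames]
            C = _window_corr(block, lag)
            C = 0.5 * (C + C.T)
            vmin, vmax = C.min(), C.max()
            C = (C - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(C)
            g = glcm_from_matrix(C, bins=bins, bin_width=bin_width, offset=offset)
            ws.append(shannon_entropy(g).S)
        all_windows.append(np.asarray(ws))
    per_window = np.mean(all_windows, axis=0)
    mean_sd = None
    if len(all_windows) > 1:
        per_repeat = np.array([w.mean() for w in all_windows])
        mean_sd = (float(per_repeat.mean()), float(per_repeat.std(ddof=1)))
    return EntropyResult(S=float(per_window.mean()), per_window_S=per_window,
                         mean_sd_over_repeats=mean_sd)


class CorrelationEntropy(BaseEstimator):
    """Correlation-map texture entropy of residue dynamics.

    Fitting computes radial coordinates (if given a trajectory), the
    window-averaged normalized correlation matrix, its GLCM, and the Shannon
    entropy, plus the per-window entropy series.

    Parameters mirror the analysis constants: 200-frame windows, lag 1,
    10 levels of width 0.1, horizontally adjacent symmetric co-occurrences,
    center-of-mass origin.

    Attributes
    ----------
    correlation_ : CorrelationMatrix
    glcm_ : Glcm
    entropy_ : float
    per_window_entropy_ : ndarray
    """

    def __init__(self, window_frames: int = 200, lag: int = 1,
                 bins: int = 10, bin_width: float = 0.1,
                 offset: tuple[int, int] = (0, 1),
                 origin: str | int = "center_of_mass"):
        self.window_frames = window_frames
        self.lag = lag
        self.bins = bins
        self.bin_width = bin_width
        self.offset = offset
        self.origin = origin

    def fit(self, X, y=None):
        """Fit on a ResidueTrajectory or an (n_frames, n_residues) array of
        per-residue scalar series (with residue ids 0..R-1 in the latter
        case unless set via ``residue_ids_``)."""
        if isinstance(X, ResidueTrajectory):
            series = radial_coordinates(X, origin=self.origin)
            residue_ids = X.residue_ids
        else:
            series = np.asarray(X, dtype=float)
            residue_ids = np.arange(series.shape[1])
        self.series_ = series
        self.residue_ids_ = residue_ids
        self.correlation_ = windowed_correlation(
            series, residue_ids, window_frames=self.window_frames,
            lag=self.lag, normalize=True)
        self.glcm_ = glcm_from_matrix(self.correlation_, bins=self.bins,
                                      bin_width=self.bin_width,
                                      offset=self.offset)
        self.entropy_ = shannon_entropy(self.glcm_).S
        self.per_window_entropy_ = entropy_timeseries(
            series, residue_ids, window_frames=self.window_frames,
            lag=self.lag, bins=self.bins, bin_width=self.bin_width,
            offset=self.offset).per_window_S
        return self
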