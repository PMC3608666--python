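"""Transition-state identification and per-residue Phi-value prediction.

A high-temperature unfolding trajectory of a two-state system dwells in a
few conformational basins separated by sharp barriers.  The pipeline here is:

1. pairwise Cα RMSD matrix between strided frames,
2. Sammon nonlinear mapping of that matrix into 2D (stress-minimising
   embedding, so basin structure survives the projection),
3. time-contiguous segmentation of the sequentially connected projection:
   a displacement jump far above the typical step opens a new segment,
4. the transition-state ensemble = frames within a half-window of the
   chosen inter-segment barrier time,
5. Phi-values from native-contact counts in the TS, folded and unfolded
   ensembles: phi_i = (N_i^TS - N_i^U) / (N_i^F - N_i^U).

Phi near 1 means residue i is as structured at the barrier as in the folded
state; near 0, as unstructured as in the unfolded state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import CONTACT_CUTOFF, ContactSet, min_sidechain_distances
from .system_model import Ensemble, pairwise_rmsd

__all__ = [
    "RmsdMatrix",
    "Projection2D",
    "ClusterSegmentation",
    "PhiProfile",
    "rmsd_matrix",
    "sammon_map",
    "segment_by_time",
    "ts_ensemble",
    "phi_values",
]


@dataclass
class RmsdMatrix:
    """Symmetric pairwise Cα RMSD matrix over strided frames."""

    matrix: np.ndarray  # (n, n), Å
    frame_indices: np.ndarray  # indices into the source ensemble
    times: np.ndarray  # ps, per strided frame

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Projection2D:
    """2D Sammon embedding of a distance matrix."""

    points: np.ndarray  # (n, 2)
    stress: float
    n_iter: int
    seed: int
    stress_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ClusterSegmentation:
    """Time-contiguous segments of a projected trajectory.

    ``segments`` holds (start, end, label) with inclusive frame positions in
    the strided series; ``barrier_times`` are the ps midpoints between
    consecutive segments.
    """

    segments: list[tuple[int, int, int]]
    barrier_times: list[float]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def labels(self, n_points: int) -> np.ndarray:
        out = np.empty(n_points, dtype=int)
        for start, end, label in self.segments:
            out[start : end + 1] = label
        return out


@dataclass
class PhiProfile:
    """Per-residue Phi-values with the underlying contact counts."""

    n_ts: np.ndarray  # mean native contacts per residue, TS ensemble
    n_folded: np.ndarray
    n_unfolded: np.ndarray
    phi_raw: np.ndarray  # NaN where undefined
    phi_clamped: np.ndarray  # raw clipped to [0, 1], NaN where undefined

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.phi_raw)


def rmsd_matrix(ensemble: Ensemble, stride: int = 1) -> RmsdMatrix:
    """Pairwise fitted Cα RMSD between every ``stride``-th frame."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.arange(0, ensemble.n_frames, stride)
    if idx.size < 2:
        raise ValueError("fewer than 2 frames after striding")
    ca = ensemble.system.ca_indices()
    frames = ensemble.frames[np.ix_(idx, ca)]
    return RmsdMatrix(
        matrix=pairwise_rmsd(frames, fit=True),
        frame_indices=idx,
        times=ensemble.times[idx].copy(),
    )


def _sammon_stress(dstar: np.ndarray, points: np.ndarray, iu) -> float:
    d = np.sqrt(np.sum((points[iu[0]] - points[iu[1]]) ** 2, axis=1))
    ds = dstar[iu]
    return float(np.sum((ds - d) ** 2 / ds) / np.sum(ds))


def _sammon_gradient(dstar: np.ndarray, points: np.ndarray) -> np.ndarray:
    n = points.shape[0]
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=2))
    np.fill_diagonal(d, 1.0)
    d = np.maximum(d, 1e-12)  # coincident projected points
    ds = dstar.copy()
    np.fill_diagonal(ds, 1.0)
    c = dstar[np.triu_indices(n, k=1)].sum()
    w = (ds - d) / (ds * d)
    np.fill_diagonal(w, 0.0)
    return (-2.0 / c) * np.sum(w[:, :, None] * diff, axis=1)


def _classical_scaling(dstar: np.ndarray) -> np.ndarray:
    """Top-2 classical (Torgerson) metric scaling coordinates."""
    n = dstar.shape[0]
    d2 = dstar**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    vals = np.clip(vals[order], 0.0, None)
    pts = vecs[:, order] * np.sqrt(vals)[None, :]
    # fix eigenvector sign so the embedding is reproducible
    for k in range(2):
        col = pts[:, k]
        i = np.argmax(np.abs(col))
        if col[i] < 0:
            pts[:, k] = -col
    return pts


def sammon_map(
    matrix: RmsdMatrix | np.ndarray,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> Projection2D:
    """2D Sammon nonlinear mapping of a distance matrix.

    Minimises the Sammon stress
    ``E = (1/sum d*_ij) * sum (d*_ij - d_ij)^2 / d*_ij`` (sum over i<j),
    where d* are the input distances and d the projected Euclidean
    distances.  Initialised from classical metric scaling; gradient descent
    with backtracking line search, so the stress never increases across
    accepted iterations.  Deterministic for a given seed (the seed only
    perturbs exact zero distances between distinct frames).
    """
    dstar = matrix.matrix if isinstance(matrix, RmsdMatrix) else np.asarray(matrix, dtype=float)
    dstar = dstar.copy()
    n = dstar.shape[0]
    if n < 3:
        raise ValueError("Sammon mapping needs at least 3 points")
    iu = np.triu_indices(n, k=1)
    if np.any(dstar[iu] <= 0):
        warnings.warn(
            "zero distances between distinct frames; jittering by 1e-6 Å",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(0.5e-6, 1.5e-6, size=iu[0].size)
        vals = np.maximum(dstar[iu], 0.0) + np.where(dstar[iu] <= 0, jitter, 0.0)
        dstar[iu] = vals
        dstar[(iu[1], iu[0])] = vals

    points = _classical_scaling(dstar)
    stress = _sammon_stress(dstar, points, iu)
    history = [stress]
    scale = float(np.mean(dstar[iu]))
    step = 0.3 * scale**2  # scale-aware initial step for the line search
    n_done = 0
    for it in range(max_iter):
        grad = _sammon_gradient(dstar, points)
        accepted = False
        for _ in range(40):
            trial = points - step * grad
            trial_stress = _sammon_stress(dstar, trial, iu)
            if trial_stress < stress:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        improvement = stress - trial_stress
        points, stress = trial, trial_stress
        history.append(stress)
        step *= 1.2
        n_done = it + 1
        if improvement < tol:
            break
    return Projection2D(
        points=points,
        stress=stress,
        n_iter=n_done,
        seed=seed,
        stress_history=np.asarray(history),
    )


def segment_by_time(
    projection: Projection2D,
    times: np.ndarray,
    jump_factor: float = 2.0,
    min_segment_points: int = 3,
) -> ClusterSegmentation:
    """Split the sequentially connected projection into conformational
    segments.

    A new segment opens wherever the consecutive-point displacement exceeds
    ``mean + jump_factor * SD`` of all consecutive displacements.  Segments
    shorter than ``min_segment_points`` are merged into the neighbouring
    segment with the closer centroid, and adjacent segments whose centroids
    are closer than the jump threshold are merged (so small-step threshold
    crossings inside one basin do not fragment it).
    """
    pts = projection.points
    times = np.asarray(times, dtype=float)
    n = pts.shape[0]
    if times.shape != (n,):
        raise ValueError("times must align with projection points")
    if n == 1:
        return ClusterSegmentation(segments=[(0, 0, 0)], barrier_times=[])
    disp = np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1))
    threshold = disp.mean() + jump_factor * disp.std()
    if not np.isfinite(threshold):
        threshold = np.inf
    boundaries = np.flatnonzero(disp > threshold) + 1  # segment starts
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries - 1, [n - 1]])
    segments = [[int(s), int(e)] for s, e in zip(starts, ends)]

    def centroid(seg):
        return pts[seg[0] : seg[1] + 1].mean(axis=0)

    # absorb runt segments into the nearer neighbour
    changed = True
    while changed and len(segments) > 1:
        changed = False
        for i, seg in enumerate(segments):
            if seg[1] - seg[0] + 1 >= min_segment_points:
                continue
            cands = []
            if i > 0:
                cands.append((np.linalg.norm(centroid(seg) - centroid(segments[i - 1])), i - 1))
            if i < len(segments) - 1:
                cands.append((np.linalg.norm(centroid(seg) - centroid(segments[i + 1])), i + 1))
            _, target = min(cands)
            lo, hi = (target, i) if target < i else (i, target)
            segments[lo] = [segments[lo][0], segments[hi][1]]
            del segments[hi]
            changed = True
            break
    # merge adjacent segments that live in the same basin
    changed = True
    while changed and len(segments) > 1:
        changed = False
        for i in range(len(segments) - 1):
            gap = np.linalg.norm(centroid(segments[i]) - centroid(segments[i + 1]))
            if gap <= threshold:
                segments[i] = [segments[i][0], segments[i + 1][1]]
                del segments[i + 1]
                changed = True
                break

    labelled = [(s, e, k) for k, (s, e) in enumerate(segments)]
    barriers = [
        float(0.5 * (times[segments[i][1]] + times[segments[i + 1][0]]))
        for i in range(len(segments) - 1)
    ]
    return ClusterSegmentation(segments=labelled, barrier_times=barriers)


def ts_ensemble(
    ensemble: Ensemble,
    segmentation: ClusterSegmentation,
    barrier_index: int = 0,
    half_window_ps: float = 40.0,
) -> Ensemble:
    """Frames within ``half_window_ps`` of an inter-segment barrier time."""
    if not segmentation.barrier_times:
        raise ValueError("segmentation has no barriers (single segment)")
    try:
        barrier = segmentation.barrier_times[barrier_index]
    except IndexError as exc:
        raise ValueError(
            f"barrier_index {barrier_index} out of range "
            f"({len(segmentation.barrier_times)} barriers)"
        ) from exc
    mask = np.abs(ensemble.times - barrier) <= half_window_ps
    if not np.any(mask):
        raise ValueError(
            f"no frames within {half_window_ps} ps of the barrier at "
            f"{barrier:.1f} ps; widen the window (frame spacing may exceed it)"
        )
    return ensemble.slice_frames(np.flatnonzero(mask))


def _residue_contact_counts(ensemble: Ensemble, native: ContactSet) -> np.ndarray:
    """Mean number of satisfied native contacts per residue over frames."""
    system = ensemble.system
    pairs = np.array(
        [(c.residue_i, c.residue_j) for c in native if c.native], dtype=int
    ).reshape(-1, 2)
    counts = np.zeros(system.n_residues, dtype=float)
    if pairs.size == 0:
        return counts
    for f in range(ensemble.n_frames):
        mind = min_sidechain_distances(ensemble.frames[f], system)
        hit = mind[pairs[:, 0], pairs[:, 1]] < CONTACT_CUTOFF
        np.add.at(counts, pairs[hit, 0], 1.0)
        np.add.at(counts, pairs[hit, 1], 1.0)
    return counts / ensemble.n_frames


def phi_values(
    ts: Ensemble,
    folded: Ensemble,
    unfolded: Ensemble,
    native: ContactSet,
) -> PhiProfile:
    """Per-residue Phi-values from TS / folded / unfolded contact counts.

    phi_i = (N_i^TS - N_i^U) / (N_i^F - N_i^U), where N_i^X is the mean
    number of native contacts of residue i satisfied in ensemble X (6.5 Å
    side-chain criterion).  Undefined (NaN) where the folded and unfolded
    counts coincide or the residue has no native contacts; raw values are
    kept alongside the [0, 1]-clamped profile.
    """
    systems = {id(e.system) for e in (ts, folded, unfolded)}
    if len({e.system.n_atoms for e in (ts, folded, unfolded)}) != 1:
        raise ValueError("ensembles must share one system")
    del systems
    n_ts = _residue_contact_counts(ts, native)
    n_f = _residue_contact_counts(folded, native)
    n_u = _residue_contact_counts(unfolded, native)
    denom = n_f - n_u
    has_contacts = np.zeros_like(n_f, dtype=bool)
    for c in native:
        if c.native:
            has_contacts[c.residue_i] = True
            has_contacts[c.residue_j] = True
    defined = has_contacts & (np.abs(denom) >= 1e-9)
    phi_raw = np.full(n_f.shape, np.nan)
    phi_raw[defined] = (n_ts[defined] - n_u[defined]) / denom[defined]
    phi_clamped = np.clip(phi_raw, 0.0, 1.0)
    return PhiProfile(
        n_ts=n_ts,
        n_folded=n_f,
        n_unfolded=n_u,
        phi_raw=phi_raw,
        phi_clamped=phi_clamped,
    )
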