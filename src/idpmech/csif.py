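"""Conformational selection vs induced fit (CS/IF) deviation statistics.

The question: does a chain's bound conformation pre-exist in its apo
ensemble (conformational selection) or arise only upon binding (induced
fit)?  The analysis compares bound frames of a chain, taken from the
complex, with frames of the same chain's apo ensemble:

* every sampled bound frame is paired with every sampled apo frame
  (default 10 x 10 = 100 pairs); the minimum-RMSD apo frame is each bound
  frame's "most similar" structure;
* after all-Cα superposition, per-atom deviations are resolved by distance
  from the binding-partner centroid in 0.5 Å bins from 0 to 50 Å;
* a two-sample Kolmogorov-Smirnov test per distance bin compares the
  bound-vs-apo deviation distribution against the apo-vs-apo baseline
  (median P and fraction of pairs with P < 0.1 are reported per bin);
* the Δ statistic weighs the CS magnitude (RMSD spread among apo
  conformers, i.e. the diversity available for selection) against the IF
  magnitude (residual RMSD between each bound frame and its most similar
  apo frame).  Δ > 0 means conformational selection dominates at that
  scope; Δ < 0 means induced fit does.  Δ is evaluated globally (all
  atoms) and locally (atoms near the partner centroid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .system_model import Ensemble, SystemModel, superpose

__all__ = [
    "PairAssignment",
    "DistanceBins",
    "KsMap",
    "DeltaStat",
    "CsifResult",
    "evenly_spaced_indices",
    "pair_bound_apo",
    "distance_bins",
    "pair_deviations",
    "local_rmsd_profile",
    "ks_map",
    "delta_statistic",
    "mechanism_verdict",
    "csif_analysis",
]

BIN_WIDTH = 0.5  # Å
MAX_BIN_DISTANCE = 50.0  # Å; atoms at or beyond this go to the overflow group
N_BINS = int(MAX_BIN_DISTANCE / BIN_WIDTH)
LOCAL_CUTOFF = 10.0  # Å from the partner centroid = the "local" scope
P_THRESHOLD = 0.1


@dataclass
class PairAssignment:
    """Bound-apo RMSD grid with each bound frame's most similar apo frame."""

    bound_frames: np.ndarray  # frame indices into the bound ensemble
    apo_frames: np.ndarray  # frame indices into the apo ensemble
    grid: np.ndarray  # (n_bound, n_apo) all-Cα RMSD, Å
    most_similar: np.ndarray  # (n_bound,) position into apo_frames
    rmsd_best: np.ndarray  # (n_bound,) Å

    @property
    def n_pairs(self) -> int:
        return self.grid.size


@dataclass
class DistanceBins:
    """Partition of one chain's atoms by distance from the partner centroid.

    ``bin_index[a]`` is ``floor(d_a / width)`` for ``d_a < max_distance``
    and -1 (overflow, excluded) otherwise.
    """

    centroid: np.ndarray  # (3,)
    distances: np.ndarray  # (n_atoms,) Å
    bin_index: np.ndarray  # (n_atoms,) int, -1 = overflow
    edges: np.ndarray  # (n_bins + 1,)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def members(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.bin_index == b)


@dataclass
class KsMap:
    """Per-bin KS P-values over conformation pairs."""

    p_values: np.ndarray  # (n_bins, n_pairs), NaN where undefined
    median_p: np.ndarray  # (n_bins,)
    fraction_lt: np.ndarray  # (n_bins,) fraction of pairs with P < threshold
    threshold: float = P_THRESHOLD


@dataclass
class DeltaStat:
    """Probability-weighted CS-vs-IF magnitude difference at one scope."""

    scope: str  # global | local
    delta: float  # Å, signed; > 0 => conformational selection dominates
    cs_histogram: list[tuple[float, int]]  # (bin mean RMSD, frequency)
    if_histogram: list[tuple[float, int]]
    n_cs: int
    n_if: int


@dataclass
class CsifResult:
    """Full CS/IF analysis bundle for one chain."""

    chain: str
    pairs: PairAssignment
    edges: np.ndarray
    profile_best: np.ndarray  # (n_bins,) mean local RMSD, 10 most similar pairs
    profile_rest: np.ndarray  # (n_bins,) mean local RMSD, remaining pairs
    ks: KsMap | None
    delta_global: DeltaStat
    delta_local: DeltaStat
    local_atoms: np.ndarray  # atom indices (chain-local) in the local scope
    verdict: str


def evenly_spaced_indices(n_total: int, n_wanted: int) -> np.ndarray:
    """Deterministic, evenly spaced frame positions (first and last included)."""
    if n_wanted >= n_total:
        return np.arange(n_total)
    return np.unique(np.round(np.linspace(0, n_total - 1, n_wanted)).astype(int))


def pair_bound_apo(
    bound: Ensemble,
    apo: Ensemble,
    n_bound: int = 10,
    n_apo: int = 10,
) -> PairAssignment:
    """All-Cα RMSD grid between evenly sampled bound and apo frames.

    Ties in the per-bound-frame argmin are broken toward the earlier apo
    timestamp.  Frame sampling is deterministic (evenly spaced in time),
    so randomness never enters the pairing.
    """
    if bound.system.n_atoms != apo.system.n_atoms:
        raise ValueError("bound and apo ensembles must cover the same chain atoms")
    ca = bound.system.ca_indices()
    b_idx = evenly_spaced_indices(bound.n_frames, n_bound)
    a_idx = evenly_spaced_indices(apo.n_frames, n_apo)
    grid = np.empty((b_idx.size, a_idx.size))
    for i, bf in enumerate(b_idx):
        for j, af in enumerate(a_idx):
            grid[i, j] = superpose(apo.frames[af], bound.frames[bf], ca).rmsd
    best = np.argmin(grid, axis=1)  # first minimum = earliest apo frame
    return PairAssignment(
        bound_frames=b_idx,
        apo_frames=a_idx,
        grid=grid,
        most_similar=best,
        rmsd_best=grid[np.arange(b_idx.size), best],
    )


def distance_bins(
    analyzed_coords: np.ndarray,
    partner_coords: np.ndarray,
    partner_masses: np.ndarray,
    bin_width: float = BIN_WIDTH,
    max_distance: float = MAX_BIN_DISTANCE,
) -> DistanceBins:
    """Assign each analyzed-chain atom to a half-open distance bin
    ``[b*w, (b+1)*w)`` by its distance from the partner's mass-weighted
    centroid in the bound conformation.  Atoms at or beyond
    ``max_distance`` fall in the overflow group (bin index -1)."""
    analyzed_coords = np.asarray(analyzed_coords, dtype=float)
    partner_coords = np.asarray(partner_coords, dtype=float)
    centroid = np.average(partner_coords, axis=0, weights=np.asarray(partner_masses, dtype=float))
    d = np.linalg.norm(analyzed_coords - centroid, axis=1)
    n_bins = int(round(max_distance / bin_width))
    idx = np.floor(d / bin_width).astype(int)
    idx[d >= max_distance] = -1
    edges = np.arange(n_bins + 1) * bin_width
    return DistanceBins(centroid=centroid, distances=d, bin_index=idx, edges=edges)


def pair_deviations(
    mobile_coords: np.ndarray,
    target_coords: np.ndarray,
    ca_indices: np.ndarray,
) -> np.ndarray:
    """Per-atom deviation norms after all-Cα superposition of mobile onto
    target."""
    fit = superpose(mobile_coords, target_coords, ca_indices)
    return np.linalg.norm(fit.apply(mobile_coords) - target_coords, axis=1)


def local_rmsd_profile(deviations: np.ndarray, bins: DistanceBins) -> np.ndarray:
    """Per-bin RMSD over member atoms; NaN for empty bins."""
    out = np.full(bins.n_bins, np.nan)
    for b in range(bins.n_bins):
        members = bins.members(b)
        if members.size:
            out[b] = np.sqrt(np.mean(deviations[members] ** 2))
    return out


def ks_map(
    pair_deviation_list: list[np.ndarray],
    pair_bins: list[DistanceBins],
    baseline_deviation_list: list[np.ndarray],
    threshold: float = P_THRESHOLD,
) -> KsMap:
    """Two-sample KS significance per distance bin.

    For every bound-apo pair and bin, the per-atom deviations in that bin
    are compared against the pooled apo-vs-apo (baseline) deviations of the
    same bin; a small P flags a deviation distribution that the apo
    ensemble's internal spread cannot explain.  Bins with fewer than two
    atoms on either side are undefined (NaN).
    """
    n_pairs = len(pair_deviation_list)
    n_bins = pair_bins[0].n_bins
    p_values = np.full((n_bins, n_pairs), np.nan)
    for p, (dev, bins) in enumerate(zip(pair_deviation_list, pair_bins)):
        for b in range(n_bins):
            members = bins.members(b)
            if members.size < 2:
                continue
            baseline = np.concatenate(
                [base[members] for base in baseline_deviation_list]
            )
            if baseline.size < 2:
                continue
            p_values[b, p] = stats.ks_2samp(dev[members], baseline).pvalue
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median_p = np.nanmedian(p_values, axis=1)
        fraction_lt = np.nanmean(p_values < threshold, axis=1)
    return KsMap(
        p_values=p_values,
        median_p=median_p,
        fraction_lt=fraction_lt,
        threshold=threshold,
    )


def _histogram(values: np.ndarray, bin_width: float) -> list[tuple[float, int]]:
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    out = []
    for b, c in enumerate(counts):
        if c:
            members = values[(values >= edges[b]) & (values < edges[b + 1])]
            out.append((float(members.mean()), int(c)))
    return out


def delta_statistic(
    cs_values: np.ndarray,
    if_values: np.ndarray,
    bin_width: float = 0.25,
    scope: str = "global",
) -> DeltaStat:
    """Δ = probability-weighted mean CS magnitude minus IF magnitude.

    With frequencies f over histogram values x, Δ = Σ f_i x_i / N_CS −
    Σ f_j x_j / N_IF.  Because each histogram value is the mean of its
    bin's members, the weighted mean equals the sample mean and Δ is
    independent of the histogram bin width.
    """
    cs_values = np.asarray(cs_values, dtype=float)
    if_values = np.asarray(if_values, dtype=float)
    if cs_values.size == 0 or if_values.size == 0:
        raise ValueError("both CS and IF magnitude samples must be nonempty")
    cs_hist = _histogram(cs_values, bin_width)
    if_hist = _histogram(if_values, bin_width)
    cs_mean = sum(x * f for x, f in cs_hist) / cs_values.size
    if_mean = sum(x * f for x, f in if_hist) / if_values.size
    return DeltaStat(
        scope=scope,
        delta=float(cs_mean - if_mean),
        cs_histogram=cs_hist,
        if_histogram=if_hist,
        n_cs=int(cs_values.size),
        n_if=int(if_values.size),
    )


def mechanism_verdict(delta_global: float, delta_local: float) -> str:
    """Label the Δ signs: CS where Δ > 0, IF where Δ < 0, per scope."""
    parts = []
    if delta_global > 0:
        parts.append("global conformational selection")
    elif delta_global < 0:
        parts.append("global induced fit")
    if delta_local < 0:
        parts.append("local induced fit")
    elif delta_local > 0:
        parts.append("local conformational selection")
    return " with ".join(parts) if parts else "indeterminate"


def _masked_rmsd(dev: np.ndarray, mask: np.ndarray) -> float:
    return float(np.sqrt(np.mean(dev[mask] ** 2)))


def csif_analysis(
    bound_complex: Ensemble,
    apo: Ensemble,
    chain: str,
    partner_chain: str,
    n_bound: int = 10,
    n_apo: int = 10,
    local_cutoff: float = LOCAL_CUTOFF,
    bin_width: float = BIN_WIDTH,
    max_distance: float = MAX_BIN_DISTANCE,
    compute_ks: bool = True,
) -> CsifResult:
    """End-to-end CS/IF analysis of one chain against its apo ensemble.

    ``bound_complex`` is the two-chain complex ensemble; ``apo`` covers only
    the analyzed chain (same atoms, apo simulation).  Binning uses each
    bound frame's own partner centroid; the local scope pools atoms whose
    mean partner-centroid distance over the sampled bound frames is below
    ``local_cutoff``.
    """
    system = bound_complex.system
    bound_chain = bound_complex.extract_chain(chain)
    if bound_chain.system.n_atoms != apo.system.n_atoms:
        raise ValueError(
            f"apo ensemble atoms ({apo.system.n_atoms}) do not match chain "
            f"{chain} of the complex ({bound_chain.system.n_atoms})"
        )
    partner_atoms = system.chain_atom_indices(partner_chain)
    partner_masses = system.masses[partner_atoms]

    pairs = pair_bound_apo(bound_chain, apo, n_bound=n_bound, n_apo=n_apo)
    ca = bound_chain.system.ca_indices()

    # per-bound-frame binning by distance from the partner centroid
    bins_per_bound = [
        distance_bins(
            bound_chain.frames[bf],
            bound_complex.frames[bf][partner_atoms],
            partner_masses,
            bin_width=bin_width,
            max_distance=max_distance,
        )
        for bf in pairs.bound_frames
    ]

    # bound-vs-apo deviations for every pair in the grid
    pair_devs: list[np.ndarray] = []
    pair_bins: list[DistanceBins] = []
    pair_is_best: list[bool] = []
    for i, bf in enumerate(pairs.bound_frames):
        for j, af in enumerate(pairs.apo_frames):
            dev = pair_deviations(apo.frames[af], bound_chain.frames[bf], ca)
            pair_devs.append(dev)
            pair_bins.append(bins_per_bound[i])
            pair_is_best.append(j == pairs.most_similar[i])

    # apo-vs-apo baseline deviations (the spread available for selection)
    apo_pair_devs: list[np.ndarray] = []
    for i in range(pairs.apo_frames.size):
        for j in range(i + 1, pairs.apo_frames.size):
            apo_pair_devs.append(
                pair_deviations(
                    apo.frames[pairs.apo_frames[j]],
                    apo.frames[pairs.apo_frames[i]],
                    ca,
                )
            )

    profiles = np.array(
        [local_rmsd_profile(dev, bins) for dev, bins in zip(pair_devs, pair_bins)]
    )
    is_best = np.asarray(pair_is_best)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile_best = np.nanmean(profiles[is_best], axis=0)
        profile_rest = (
            np.nanmean(profiles[~is_best], axis=0)
            if np.any(~is_best)
            else np.full(profiles.shape[1], np.nan)
        )

    ks = (
        ks_map(pair_devs, pair_bins, apo_pair_devs)
        if compute_ks
        else None
    )

    # local scope: atoms near the partner centroid in the bound state
    mean_dist = np.mean([b.distances for b in bins_per_bound], axis=0)
    local_mask = mean_dist < local_cutoff
    if not np.any(local_mask):
        raise ValueError(
            f"no atoms within {local_cutoff} Å of the partner centroid; "
            "the local scope is empty"
        )
    local_atoms = np.flatnonzero(local_mask)

    all_mask = np.ones(bound_chain.system.n_atoms, dtype=bool)
    cs_global = np.array([_masked_rmsd(d, all_mask) for d in apo_pair_devs])
    cs_local = np.array([_masked_rmsd(d, local_mask) for d in apo_pair_devs])
    best_devs = [d for d, b in zip(pair_devs, pair_is_best) if b]
    if_global = np.array([_masked_rmsd(d, all_mask) for d in best_devs])
    if_local = np.array([_masked_rmsd(d, local_mask) for d in best_devs])

    delta_global = delta_statistic(cs_global, if_global, scope="global")
    delta_local = delta_statistic(cs_local, if_local, scope="local")

    return CsifResult(
        chain=chain,
        pairs=pairs,
        edges=bins_per_bound[0].edges,
        profile_best=profile_best,
        profile_rest=profile_rest,
        ks=ks,
        delta_global=delta_global,
        delta_local=delta_local,
        local_atoms=local_atoms,
        verdict=mechanism_verdict(delta_global.delta, delta_local.delta),
    )
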