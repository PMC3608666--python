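"""End-to-end orchestration: observables → contacts → kinetics → TS/Φ → CS/IF.

``run_all`` executes every stage over either synthetic ensembles (the
default, driven by a :class:`~idpmech.synthetic_data.SyntheticSpec`) or
user-supplied coordinate files, writes TSV tables plus a machine-readable
JSON summary, and is deterministic: identical config and inputs give an
identical summary.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import contacts as contacts_mod
from . import csif as csif_mod
from . import ensemble_observables as obs_mod
from . import kinetics as kin_mod
from . import synthetic_data as synth_mod
from . import transition_state as ts_mod
from .system_model import Ensemble, SystemModel, read_pdb, read_coordinate_table

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``synthetic`` is set (self-contained run on generated
    ensembles) or the three input paths must point to existing files.
    """

    output_dir: str = "results/run"
    seed: int = 0
    # inputs: synthetic spec, or files
    synthetic: synth_mod.SyntheticSpec | None = None
    mechanism: str = "mixed"
    reference_pdb: str | None = None
    bound_ensemble_path: str | None = None
    apo_ensemble_paths: dict[str, str] = field(default_factory=dict)
    analyzed_chain: str = "A"
    partner_chain: str = "B"
    # thresholds (Å unless noted)
    contact_cutoff: float = contacts_mod.CONTACT_CUTOFF
    electrostatic_cutoff: float = contacts_mod.ELECTROSTATIC_CUTOFF
    bin_width: float = csif_mod.BIN_WIDTH
    max_bin_distance: float = csif_mod.MAX_BIN_DISTANCE
    local_cutoff: float = csif_mod.LOCAL_CUTOFF
    stable_population: float = 0.6  # fraction of frames
    p_threshold: float = 0.1
    # sampling
    n_bound: int = 10
    n_apo: int = 10
    ts_stride: int = 5
    n_unfolding_replicas: int = 3
    ts_half_window_ps: float = 40.0
    jump_factor: float = 2.0

    def validate(self) -> None:
        for name in (
            "contact_cutoff", "electrostatic_cutoff", "bin_width",
            "max_bin_distance", "local_cutoff", "stable_population",
            "p_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.synthetic is None:
            for name in ("reference_pdb", "bound_ensemble_path"):
                path = getattr(self, name)
                if path is None or not os.path.exists(path):
                    raise ValueError(f"config field {name!r}: missing input file {path!r}")
            if self.analyzed_chain not in self.apo_ensemble_paths:
                raise ValueError(
                    f"config field 'apo_ensemble_paths': no apo ensemble for "
                    f"chain {self.analyzed_chain!r}"
                )
            path = self.apo_ensemble_paths[self.analyzed_chain]
            if not os.path.exists(path):
                raise ValueError(
                    f"config field 'apo_ensemble_paths': missing file {path!r}"
                )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        system, _, spec = synth_mod.build_study_complex(config.synthetic)
        bound, apo, truth = synth_mod.sample_csif_ensembles(
            system, spec, mechanism=config.mechanism, chain=config.analyzed_chain
        )
        return system, bound, apo, spec, truth
    system, reference = read_pdb(config.reference_pdb)
    bound_system, bound = (
        read_pdb(config.bound_ensemble_path)
        if config.bound_ensemble_path.endswith(".pdb")
        else (system, read_coordinate_table(config.bound_ensemble_path, system))
    )
    chain = config.analyzed_chain
    apo_sub, _ = system.subset(system.chain_atom_indices(chain))
    apo_path = config.apo_ensemble_paths[chain]
    if apo_path.endswith(".pdb"):
        _, apo = read_pdb(apo_path)
    else:
        apo = read_coordinate_table(apo_path, apo_sub, label=f"apo_{chain}")
    spec = synth_mod.SyntheticSpec(seed=config.seed)
    return system, bound, apo, spec, None


@_stage("contacts")
def _contacts_stage(system: SystemModel, bound: Ensemble, config: RunConfig, outdir: str):
    native = contacts_mod.native_contacts(system.reference_coords, system)
    elec = contacts_mod.assign_electrostatic_contacts(system.reference_coords, system, native=True)
    hbonds = contacts_mod.assign_hbonds(system.reference_coords, system, native=True)
    rows = []
    for cset in (native, elec, hbonds):
        for c in cset:
            pop = contacts_mod.contact_population(bound, c)
            rows.append(
                {
                    "chain_i": system.res_chain[c.residue_i],
                    "resid_i": system.res_index[c.residue_i],
                    "chain_j": system.res_chain[c.residue_j],
                    "resid_j": system.res_index[c.residue_j],
                    "kind": c.kind,
                    "scope": c.scope,
                    "native": c.native,
                    "population": round(pop, 6),
                    "stable": pop > config.stable_population,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(outdir, "contacts.tsv"), sep="\t", index=False)
    n_stable = int(((table["kind"] == "hydrophobic") & table["stable"]).sum())
    return native, {
        "n_native_tertiary": native.n_native_tertiary,
        "n_native_binding": native.n_native_binding,
        "n_electrostatic": len(elec),
        "n_hbonds": len(hbonds),
        "n_stable_hydrophobic": n_stable,
    }


@_stage("observables")
def _observables_stage(bound: Ensemble, apo: Ensemble, config: RunConfig, outdir: str):
    chain = config.analyzed_chain
    bound_chain = bound.extract_chain(chain)
    rmsf_b = obs_mod.ca_rmsf(bound_chain)
    rmsf_a = obs_mod.ca_rmsf(apo)
    table = pd.DataFrame(
        {
            "resid": bound_chain.system.res_index,
            "rmsf_bound": np.round(rmsf_b, 6),
            "rmsf_apo": np.round(rmsf_a, 6),
        }
    )
    table.to_csv(os.path.join(outdir, "rmsf.tsv"), sep="\t", index=False)
    ddm = obs_mod.distance_difference_map(bound_chain, apo)
    np.savetxt(os.path.join(outdir, "distance_difference.tsv"), ddm, delimiter="\t", fmt="%.4f")
    hel_b = obs_mod.helical_content(bound_chain)
    hel_a = obs_mod.helical_content(apo)
    return {
        "mean_rmsf_bound": float(np.round(rmsf_b.mean(), 6)),
        "mean_rmsf_apo": float(np.round(rmsf_a.mean(), 6)),
        "helical_content_bound": float(np.round(hel_b, 6)),
        "helical_content_apo": float(np.round(hel_a, 6)),
    }


@_stage("kinetics")
def _kinetics_stage(system, native, spec, config: RunConfig, outdir: str):
    rng = np.random.default_rng(config.seed)
    replica_seeds = rng.integers(0, 2**31 - 1, size=config.n_unfolding_replicas)
    series = []
    for s in replica_seeds:
        traj = synth_mod.sample_unfolding_trajectory(system, spec, native=native, seed=int(s))
        series.append(contacts_mod.q_series(traj, native))
    rows = []
    fits = {}
    for channel in ("qf", "qb"):
        # fit the first decade of decay; below q ~ 0.1 the per-contact
        # counting floor dominates and the log-space fit is biased
        mean_q = np.mean([s.channel(channel) for s in series], axis=0)
        low = np.flatnonzero(mean_q < 0.1)
        t_end = series[0].times[low[0] - 1] if low.size else series[0].times[-1]
        window = (0.0, float(t_end))
        fit = kin_mod.averaged_fit(series, channel=channel, window=window)
        fits[channel] = fit
        rows.append(
            {
                "channel": channel,
                "rate_per_ps": round(fit.rate, 9),
                "half_time_ps": round(fit.half_time, 4),
                "se_half_time_ps": round(fit.se_half_time, 4),
                "r_squared": round(fit.r_squared, 6),
                "n_points": fit.n_points,
            }
        )
        table = pd.DataFrame(
            {"time_ps": series[0].times, **{f"{channel}_{i}": s.channel(channel)
                                            for i, s in enumerate(series)}}
        )
        table.to_csv(os.path.join(outdir, f"{channel}_series.tsv"), sep="\t",
                     index=False, float_format="%.6f")
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "kinetics.tsv"), sep="\t", index=False)
    traj0 = synth_mod.sample_unfolding_trajectory(
        system, spec, native=native, seed=int(replica_seeds[0])
    )
    return traj0, {
        "unbinding_half_time_ps": round(fits["qb"].half_time, 4),
        "unfolding_half_time_ps": round(fits["qf"].half_time, 4),
        "qb_r_squared": round(fits["qb"].r_squared, 6),
        "qf_r_squared": round(fits["qf"].r_squared, 6),
    }


@_stage("transition_state")
def _ts_stage(unfold_traj, bound, native, config: RunConfig, outdir: str):
    matrix = ts_mod.rmsd_matrix(unfold_traj, stride=config.ts_stride)
    projection = ts_mod.sammon_map(matrix, seed=config.seed)
    segmentation = ts_mod.segment_by_time(
        projection, matrix.times, jump_factor=config.jump_factor
    )
    table = pd.DataFrame(
        {
            "frame": matrix.frame_indices,
            "time_ps": matrix.times,
            "x": np.round(projection.points[:, 0], 6),
            "y": np.round(projection.points[:, 1], 6),
            "segment": segmentation.labels(matrix.n),
        }
    )
    table.to_csv(os.path.join(outdir, "projection.tsv"), sep="\t", index=False)
    ts = ts_mod.ts_ensemble(
        unfold_traj, segmentation, barrier_index=0,
        half_window_ps=max(config.ts_half_window_ps,
                           config.ts_stride * float(np.diff(unfold_traj.times[:2])[0])),
    )
    n_tail = max(1, int(0.2 * unfold_traj.n_frames))
    unfolded = unfold_traj.slice_frames(np.arange(unfold_traj.n_frames - n_tail,
                                                  unfold_traj.n_frames))
    profile = ts_mod.phi_values(ts, bound, unfolded, native)
    system = bound.system
    pd.DataFrame(
        {
            "chain": system.res_chain,
            "resid": system.res_index,
            "n_ts": np.round(profile.n_ts, 6),
            "n_folded": np.round(profile.n_folded, 6),
            "n_unfolded": np.round(profile.n_unfolded, 6),
            "phi_raw": np.round(profile.phi_raw, 6),
            "phi_clamped": np.round(profile.phi_clamped, 6),
        }
    ).to_csv(os.path.join(outdir, "phi_profile.tsv"), sep="\t", index=False)
    defined = profile.defined
    return {
        "n_segments": segmentation.n_segments,
        "barrier_time_ps": (
            round(segmentation.barrier_times[0], 4)
            if segmentation.barrier_times else None
        ),
        "sammon_stress": round(projection.stress, 8),
        "n_ts_frames": ts.n_frames,
        "mean_phi": float(np.round(np.nanmean(profile.phi_clamped[defined]), 6))
        if np.any(defined) else None,
    }


@_stage("csif")
def _csif_stage(bound, apo, config: RunConfig, outdir: str):
    result = csif_mod.csif_analysis(
        bound,
        apo,
        chain=config.analyzed_chain,
        partner_chain=config.partner_chain,
        n_bound=config.n_bound,
        n_apo=config.n_apo,
        local_cutoff=config.local_cutoff,
        bin_width=config.bin_width,
        max_distance=config.max_bin_distance,
    )
    pd.DataFrame(
        {
            "bin_lo": result.edges[:-1],
            "bin_hi": result.edges[1:],
            "rmsd_best10": np.round(result.profile_best, 6),
            "rmsd_other90": np.round(result.profile_rest, 6),
            "median_p": np.round(result.ks.median_p, 6),
            "frac_p_lt_0.1": np.round(result.ks.fraction_lt, 6),
        }
    ).to_csv(os.path.join(outdir, "csif_profile.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"scope": d.scope, "delta": round(d.delta, 6), "n_cs": d.n_cs,
             "n_if": d.n_if}
            for d in (result.delta_global, result.delta_local)
        ]
    ).to_csv(os.path.join(outdir, "delta.tsv"), sep="\t", index=False)
    finite = result.ks.median_p[~np.isnan(result.ks.median_p)]
    return {
        "delta_global": round(result.delta_global.delta, 6),
        "delta_local": round(result.delta_local.delta, 6),
        "verdict": result.verdict,
        "median_p_overall": float(np.round(np.median(finite), 6)) if finite.size else None,
        "n_local_atoms": int(result.local_atoms.size),
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    Fails with the stage name on any stage error; outputs written before
    the failure are preserved.
    """
    config.validate()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    system, bound, apo, spec, truth = _load_inputs(config)
    summary: dict = {"seed": config.seed, "mechanism": config.mechanism
                     if config.synthetic is not None else "from_files"}
    native, summary["contacts"] = _contacts_stage(system, bound, config, outdir)
    summary["observables"] = _observables_stage(bound, apo, config, outdir)
    unfold_traj, summary["kinetics"] = _kinetics_stage(system, native, spec, config, outdir)
    summary["transition_state"] = _ts_stage(unfold_traj, bound, native, config, outdir)
    summary["csif"] = _csif_stage(bound, apo, config, outdir)
    with open(os.path.join(outdir, "summary.json"), "w") as out:
        json.dump(summary, out, indent=2, sort_keys=True)
        out.write("\n")
    return summary
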