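# idpmech

Trajectory-ensemble analysis of coupled folding and binding for
intrinsically disordered proteins (IDPs): does a chain recognise its
partner by **conformational selection** (binding-competent conformers
pre-exist in the apo ensemble and are selected) or by **induced fit** (the
bound conformation arises only upon contact)?

The package is written for structural-bioinformatics work on IDP
complexes such as the p53 transactivation domain bound to the CBP nuclear
coactivator binding domain, where NMR shows both chains disordered alone
and folded together.  It consumes conformational ensembles — multi-model
PDB files or plain-text coordinate tables for the bound complex and for
each apo chain — and provides four analysis stages plus a synthetic
generator that emulates every input so the full pipeline is testable
without MD data.

## The analyses

**Native contacts and (un)binding kinetics.**  Residues are in contact
when their side-chain heavy atoms come within 6.5 Å (electrostatic pairs:
charge-group centres within 11 Å; hydrogen bonds: donor–acceptor < 3.5 Å
and angle > 120°).  Per frame, Qf is the surviving fraction of native
intra-chain contacts and Qb of native inter-chain contacts.  First-order
decay Q(t) = e^(−kt) is fitted as linear least squares of ln Q vs t, with
half-time t½ = ln 2 ∕ k and se(t½) = ln 2 · se(k) ∕ k².

**Transition state and Φ-values.**  The pairwise Cα-RMSD matrix of an
unfolding trajectory is embedded in 2D by Sammon nonlinear mapping
(stress E = (Σd\*ᵢⱼ)⁻¹ Σ (d\*ᵢⱼ − dᵢⱼ)² ∕ d\*ᵢⱼ); the sequentially
connected projection is segmented into time-contiguous clusters wherever
the step displacement jumps far above its typical size, and the
transition-state (TS) ensemble is the frames around the first
inter-cluster barrier.  Per residue,

  Φᵢ = (Nᵢ^TS − Nᵢ^U) ∕ (Nᵢ^F − Nᵢ^U),

where Nᵢ^X is the mean number of residue i's native contacts present in
ensemble X; Φ ≈ 1 means residue i is already structured at the barrier.

**CS vs IF deviation statistics.**  Ten bound frames × ten apo frames are
superposed on all Cα atoms; each atom is binned by its distance from the
binding-partner centroid (0–50 Å, 0.5 Å bins) and per-bin deviation
distributions are compared against the apo-vs-apo baseline with the
two-sample Kolmogorov–Smirnov test (median P and fraction of the 100
pairs with P < 0.1, per bin).  The verdict statistic

  Δ = Σᵢ fᵢxᵢ ∕ N_CS − Σⱼ fⱼxⱼ ∕ N_IF

weighs the CS magnitude (RMSD spread among apo conformers — the diversity
available for selection) against the IF magnitude (residual RMSD between
each bound frame and its most-similar apo conformer).  Δ > 0 ⇒ selection
dominates; Δ < 0 ⇒ induced fit.  Δ is evaluated globally (all atoms) and
locally (atoms within 10 Å of the partner centroid).

## Worked example

```bash
python analysis/01_build_system.py   --seed 1   # toy complex + contact inventory
python analysis/03_unbinding_kinetics.py --seed 1
python analysis/05_cs_vs_if.py       --seed 1   # the Δ verdict
```

The kinetics driver plants a contact-loss rate of 2.4·10⁻⁴ ps⁻¹
(half-time 2888 ps) in ten unfolding trajectories and refits it:

```
qf: half-time 2775 ± 6 ps (r² = 0.9978)
qb: half-time 3072 ± 17 ps (r² = 0.9847)
```

Qf pools 153 tertiary contacts and is tight; Qb rests on only 6 binding
contacts here, so its estimate scatters more.  The mechanism driver then
prints, for the three planted mechanisms:

```
cs_dominant : Δ_global = +3.23 Å, Δ_local = +3.16 Å -> global conformational selection with local conformational selection
if_dominant : Δ_global = -0.50 Å, Δ_local = -2.11 Å -> global induced fit with local induced fit
mixed       : Δ_global = +2.52 Å, Δ_local = -1.79 Å -> global conformational selection with local induced fit
```

The mixed row is the signature of interest: a positive global Δ with a
negative local Δ — the apo ensemble already contains the bound
conformation's global shape, while the interface itself is remodelled on
binding.  `analysis/02_ensemble_observables.py` and
`analysis/04_transition_state.py` produce the descriptive profiles
(RMSF, dihedral variation, distance-difference map, free-energy
landscape) and the Sammon projection / Φ profile tables under `results/`.

`idpmech.pipeline.run_all(RunConfig(...))` runs every stage in one call
and writes a deterministic `summary.json`; point `RunConfig` at your own
reference PDB and ensemble files to analyse real data.

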