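#!/usr/bin/env python
"""Conformational selection vs induced fit: the Δ verdict.

For each planted mechanism (cs_dominant, if_dominant, mixed) this driver
runs the full deviation analysis of chain A against its apo ensemble:
10x10 bound-apo pairing, distance-binned local RMSD profiles, per-bin KS
significance against the apo-apo baseline, and the global/local Δ
statistics whose signs name the mechanism.
"""

import argparse
import os

import numpy as np
import pandas as pd

from idpmech.csif import csif_analysis
from idpmech.synthetic_data import (
    SyntheticSpec,
    build_study_complex,
    sample_csif_ensembles,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=str, default="results")
    args = parser.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    system, _, spec = build_study_complex(SyntheticSpec(seed=args.seed))
    rows = []
    for mechanism in ("cs_dominant", "if_dominant", "mixed"):
        bound, apo, _ = sample_csif_ensembles(system, spec, mechanism=mechanism)
        result = csif_analysis(bound, apo, "A", "B")
        rows.append(
            {
                "planted_mechanism": mechanism,
                "delta_global_A": round(result.delta_global.delta, 3),
                "delta_local_A": round(result.delta_local.delta, 3),
                "n_local_atoms": result.local_atoms.size,
                "verdict": result.verdict,
            }
        )
        print(f"{mechanism:12s}: Δ_global = {result.delta_global.delta:+.2f} Å, "
              f"Δ_local = {result.delta_local.delta:+.2f} Å -> {result.verdict}")
        if mechanism == "mixed":
            profile = pd.DataFrame(
                {
                    "bin_lo": result.edges[:-1],
                    "bin_hi": result.edges[1:],
                    "rmsd_best10": np.round(result.profile_best, 4),
                    "rmsd_other90": np.round(result.profile_rest, 4),
                    "median_p": np.round(result.ks.median_p, 4),
                    "frac_p_lt_0.1": np.round(result.ks.fraction_lt, 4),
                }
            )
            profile.to_csv(os.path.join(args.outdir, "csif_profile_mixed.tsv"),
                           sep="\t", index=False)
            populated = ~np.isnan(result.ks.median_p)
            print(f"    KS map over {populated.sum()} populated bins: "
                  f"median P {np.nanmedian(result.ks.median_p):.3f}, "
                  f"max fraction P<0.1 {np.nanmax(result.ks.fraction_lt):.2f}")

    pd.DataFrame(rows).to_csv(os.path.join(args.outdir, "delta_verdicts.tsv"),
                              sep="\t", index=False)
    print(f"wrote {args.outdir}/delta_verdicts.tsv")


if __name__ == "__main__":
    main()
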