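#!/usr/bin/env python
"""Build the synthetic two-chain study system and inventory its contacts.

Constructs the reduced complex (a three-helix chain A bound to a two-helix
chain B), writes the reference structure as PDB, and tabulates the native
contact inventory by type: hydrophobic/generic 6.5 Å side-chain contacts,
11 Å electrostatic pairs, and geometric hydrogen bonds.
"""

import argparse
import os

import pandas as pd

from idpmech.contacts import (
    assign_electrostatic_contacts,
    assign_hbonds,
    native_contacts,
)
from idpmech.synthetic_data import SyntheticSpec, build_study_complex
from idpmech.system_model import write_pdb


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=str, default="results")
    args = parser.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    system, reference, spec = build_study_complex(SyntheticSpec(seed=args.seed))
    write_pdb(os.path.join(args.outdir, "reference_complex.pdb"), system)
    print(f"built complex: {system.n_residues} residues, {system.n_atoms} atoms "
          f"(builder seed {spec.seed})")

    native = native_contacts(system.reference_coords, system)
    elec = assign_electrostatic_contacts(system.reference_coords, system, native=True)
    hb = assign_hbonds(system.reference_coords, system, native=True)
    rows = []
    for cset in (native, elec, hb):
        for c in cset:
            rows.append(
                {
                    "residue_i": system.residue_label(c.residue_i),
                    "residue_j": system.residue_label(c.residue_j),
                    "kind": c.kind,
                    "scope": c.scope,
                }
            )
    table = pd.DataFrame(rows)
    path = os.path.join(args.outdir, "contact_inventory.tsv")
    table.to_csv(path, sep="\t", index=False)
    print(f"native contacts: {native.n_native_tertiary} tertiary, "
          f"{native.n_native_binding} binding; "
          f"{len(elec)} electrostatic pairs, {len(hb)} hydrogen bonds "
          f"-> {path}")


if __name__ == "__main__":
    main()
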