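#!/usr/bin/env python
"""Drug-likeness panel of the Rac1 inhibitor 1A-116.

Computes the oral drug-likeness screen from the molecular graph alone:
molecular weight, Crippen logP, Lipinski H-bond donor/acceptor counts,
Veber rotatable bonds and Ertl TPSA, with the Lipinski and Veber
verdicts.  Writes results/druglikeness/druglikeness.{json,tsv}.
"""

import argparse
from pathlib import Path

from flexidock.cli import run_druglikeness
from flexidock.ligand_chem import RAC1_INHIBITOR_SMILES


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results/druglikeness"))
    args = parser.parse_args()

    data = run_druglikeness(RAC1_INHIBITOR_SMILES, outdir=args.outdir)
    print(f"1A-116 ({RAC1_INHIBITOR_SMILES})")
    print(f"  molecular weight : {data['molecular_weight']:.2f} g/mol")
    print(f"  logP ({data['logp_method']})  : {data['logp']:.2f}")
    print(f"  H-bond donors    : {data['hbd']}")
    print(f"  H-bond acceptors : {data['hba']}")
    print(f"  rotatable bonds  : {data['rotatable_bonds']}")
    print(f"  TPSA             : {data['tpsa']:.2f} A^2")
    print(f"  Lipinski rule of five: {'pass' if data['lipinski_pass'] else 'FAIL'}")
    print(f"  Veber criteria       : {'pass' if data['veber_pass'] else 'FAIL'}")


if __name__ == "__main__":
    main()
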