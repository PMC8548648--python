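"""ProtParam-style descriptors for every simulated protein.

Writes one row per protein (MW, pI, GRAVY, aliphatic and instability
indices, stability call) and prints the family's ranges.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import STUDY_CONFIG, outdir

from mybkit.protein_properties import protein_properties
from mybkit.synthetic_data import simulate_family_genome


def main() -> None:
    out = outdir("protein_properties")
    pkg = simulate_family_genome(STUDY_CONFIG)
    rows = []
    for pid, seq in sorted(pkg.proteins.items()):
        p = protein_properties(seq, pid)
        rows.append({"protein_id": pid, "mw_kda": round(p.mw / 1000, 2),
                     "pI": round(p.pI, 2), "gravy": round(p.gravy, 3),
                     "aliphatic_index": round(p.aliphatic_index, 2),
                     "instability_index": round(p.instability_index, 2),
                     "stability": p.stability_call})
    table = pd.DataFrame(rows)
    table.to_csv(out / "properties.tsv", sep="\t", index=False)
    print(f"{len(table)} proteins: MW {table.mw_kda.min()}-{table.mw_kda.max()} kDa, "
          f"pI {table.pI.min()}-{table.pI.max()}, "
          f"{(table.stability == 'unstable').sum()} called unstable")


if __name__ == "__main__":
    main()
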