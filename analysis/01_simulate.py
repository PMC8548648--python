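"""Generate the synthetic study genome and write it to results/sim/.

Emits genome/CDS/protein FASTA, a GFF3 of gene models, the count matrix,
and every planted-truth table the later stages are scored against.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import STUDY_CONFIG, outdir

from mybkit.genome import write_fasta, write_gff3
from mybkit.synthetic_data import simulate_family_genome


def main() -> None:
    out = outdir("sim")
    pkg = simulate_family_genome(STUDY_CONFIG)
    write_fasta(pkg.chromosomes, out / "genome.fasta")
    write_fasta(pkg.cds, out / "cds.fasta")
    write_fasta(pkg.proteins, out / "proteins.fasta")
    write_gff3(pkg.gene_models, out / "genes.gff3")
    pkg.truth["counts"].to_csv(out / "counts.tsv", sep="\t")
    pkg.truth["de_truth"].to_csv(out / "de_truth.tsv", sep="\t")
    truth = {k: v for k, v in pkg.truth.items() if k not in ("counts", "de_truth")}
    (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    n_myb = len(pkg.truth["planted_repeats"])
    print(f"simulated {len(pkg.gene_models)} genes on {len(pkg.chromosomes)} "
          f"chromosomes; {n_myb} carry planted MYB repeats, "
          f"{len(pkg.truth['duplicate_truth'])} duplicate pairs, "
          f"{len(pkg.truth['ssr_truth'])} planted SSR loci -> {out}")


if __name__ == "__main__":
    main()
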