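"""Shared study configuration for the analysis drivers.

One deterministic genome package stands in for the pepper genome downloads:
two chromosomes, a MYB family of R2R3/1R/3R members, tandem and segmental
duplicate pairs under purifying selection, SSR plantings matching the
published extreme locus, and a three-stage (EG/MG/Br) x three-replicate
count matrix with 10% planted differential expression.
"""

from pathlib import Path

from mybkit.synthetic_data import (
    DePlanting,
    DuplicationEvent,
    MybPlanting,
    Rearrangement,
    SimulationConfig,
    SsrPlanting,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY_CONFIG = SimulationConfig(
    seed=2026,
    n_chromosomes=2,
    genes_per_chromosome=10,
    myb_plantings=[MybPlanting("R2R3", 5), MybPlanting("1R", 2), MybPlanting("3R", 1)],
    duplication_events=[
        DuplicationEvent("tandem", 0.2, 0.5),
        DuplicationEvent("tandem", 0.6, 0.12),
        DuplicationEvent("segmental", 0.15, 0.6),
    ],
    ssr_plantings=[
        SsrPlanting("AT", 7, "upstream"),
        SsrPlanting("AAG", 6, "genic"),
        SsrPlanting("ATTTTA", 7, "genic"),
    ],
    rearrangements=[Rearrangement("inversion", 8), Rearrangement("translocation", 5)],
    de_plantings=DePlanting(fraction_de=0.1, log2fc_magnitude=2.0, dispersion=0.1),
    n_expression_genes=2000,
)


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
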