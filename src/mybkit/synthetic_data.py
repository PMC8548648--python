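"""Ground-truthed synthetic data for every downstream stage.

Generates genome packages (chromosomes, gene models, CDS, proteins) with
planted MYB repeats, duplicate gene pairs diverged under a codon model with
chosen omega and synonymous divergence, SSR runs in genic/upstream regions,
collinear/rearranged partner gene orders, and negative-binomial count
matrices with planted fold changes across fruit stages.  Everything is
deterministic under the config seed; each component draws from its own
labeled child stream so regenerating one piece never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._rng import child_rng
from .duplication_evolution import (
    GENETIC_CODE,
    STOP_CODONS,
    _jc_correct,
    pathway_differences,
    synonymous_sites,
)
from .genome import GeneModel, GenomePackage
from .myb_identification import AMINO_ACIDS, RepeatProfile, load_default_profile

__all__ = [
    "SimulationConfig",
    "DuplicationEvent",
    "Rearrangement",
    "SsrPlanting",
    "DePlanting",
    "MybPlanting",
    "EvolvedPairTruth",
    "SaturationError",
    "simulate_family_genome",
    "simulate_collinear_pair",
    "evolve_duplicate_pair",
    "synthesize_myb_protein",
    "simulate_counts",
]

NT = "ACGT"
SENSE_CODONS = sorted(GENETIC_CODE)
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c, _aa in GENETIC_CODE.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_c)

UPSTREAM_LEN = 1500
UTR_LEN = 120


class SaturationError(ValueError):
    """Requested synonymous divergence is beyond the Jukes-Cantor correction range."""


@dataclass(frozen=True)
class DuplicationEvent:
    mode: str  # tandem | segmental
    omega: float
    target_ks: float


@dataclass(frozen=True)
class Rearrangement:
    type: str  # inversion | translocation
    span: int  # number of genes


@dataclass(frozen=True)
class SsrPlanting:
    motif: str
    repeats: int
    region: str  # genic | upstream


@dataclass(frozen=True)
class DePlanting:
    fraction_de: float = 0.1
    log2fc_magnitude: float = 2.0
    dispersion: float = 0.1


@dataclass(frozen=True)
class MybPlanting:
    myb_class: str  # 1R | R2R3 | 3R | 4R
    count: int


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated design: three fruit stages (EG/MG/Br) with
    three biological replicates, SSR criteria of 2-6 nt motifs at >= 6
    copies, and duplicate pairs under mostly purifying selection.
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 12
    gene_length_range: tuple[int, int] = (900, 1800)  # CDS bp
    intergenic_range: tuple[int, int] = (2000, 6000)
    duplication_events: list[DuplicationEvent] = field(default_factory=list)
    rearrangements: list[Rearrangement] = field(default_factory=list)
    ssr_plantings: list[SsrPlanting] = field(default_factory=list)
    myb_plantings: list[MybPlanting] = field(
        default_factory=lambda: [MybPlanting("R2R3", 4), MybPlanting("1R", 2)]
    )
    de_plantings: DePlanting = field(default_factory=DePlanting)
    n_stages: int = 3
    n_replicates: int = 3
    n_expression_genes: int = 2000

    def validate(self) -> None:
        for p in self.ssr_plantings:
            if not 2 <= len(p.motif) <= 6 or set(p.motif) - set(NT):
                raise ValueError(f"invalid SSR motif {p.motif!r}")
        for ev in self.duplication_events:
            if ev.omega < 0:
                raise ValueError("omega must be >= 0")
            if ev.mode not in ("tandem", "segmental"):
                raise ValueError(f"invalid duplication mode {ev.mode!r}")
        if not 0.0 <= self.de_plantings.fraction_de <= 1.0:
            raise ValueError("fraction_de must be in [0, 1]")
        if self.de_plantings.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class EvolvedPairTruth:
    omega: float
    target_ks: float
    realized_ks: float
    realized_ka: float
    accepted_syn: int
    accepted_nonsyn: int
    proposals: int


# ---------------------------------------------------------------------------
# sequence-level generators


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random internal sense codons + stop."""
    internal = [c for c in SENSE_CODONS if c != "ATG"]
    body = rng.choice(internal, size=n_codons - 2)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(body) + str(stop)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS encoding ``protein`` with uniformly random synonymous codons."""
    codons = [rng.choice(_CODONS_BY_AA[aa]) for aa in protein]
    return "".join(codons) + str(rng.choice(sorted(STOP_CODONS)))


def synthesize_myb_protein(
    myb_class: str, seed: int, profile: RepeatProfile | None = None
) -> tuple[str, list[dict]]:
    """A synthetic MYB protein of the requested class with planted repeats.

    Repeats are sampled column-wise from the bundled seed-alignment profile
    (anchor columns fixed to their anchor residues); linkers and flanks are
    random sequence free of the aromatic anchor residues, so the planted
    coordinates are the only anchor-bearing windows.
    """
    if profile is None:
        profile = load_default_profile()
    layouts = {"1R": ["R2"], "R2R3": ["R2", "R3"], "3R": ["R2", "R2", "R3"],
               "4R": ["R2", "R2", "R2", "R3"]}
    if myb_class not in layouts:
        raise ValueError(f"invalid MYB class {myb_class!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    rules = {r.name: r for r in profile.rules}
    non_anchor = [aa for aa in AMINO_ACIDS if aa not in "WF"]

    def sample_repeat(rule_name: str) -> str:
        rule = rules[rule_name]
        anchor_res = {c: sorted(res)[-1] for c, res in zip(rule.columns, rule.residues)}
        out = []
        for col in range(rule.length):
            if col in anchor_res:
                out.append(anchor_res[col])
                continue
            weights = profile.weights[col]
            probs = np.array([weights[aa] for aa in non_anchor])
            out.append(rng.choice(non_anchor, p=probs / probs.sum()))
        return "".join(out)

    def flank(lo: int, hi: int) -> str:
        return "".join(rng.choice(non_anchor, size=rng.integers(lo, hi + 1)))

    parts = [flank(15, 40)]
    truth = []
    pos = len(parts[0])
    for i, rule_name in enumerate(layouts[myb_class]):
        if i:
            linker = flank(2, 10)
            parts.append(linker)
            pos += len(linker)
        rep = sample_repeat(rule_name)
        truth.append({"start": pos, "end": pos + len(rep), "type": rule_name})
        parts.append(rep)
        pos += len(rep)
    parts.append(flank(15, 40))
    return "".join(parts), truth


def evolve_duplicate_pair(
    cds: str, omega: float, target_ks: float, seed: int
) -> tuple[str, str, EvolvedPairTruth]:
    """Diverge a duplicate copy of ``cds`` to a planted (Ka, Ks) truth.

    Single-nucleotide codon changes are proposed uniformly; a synonymous
    proposal is accepted while the realized synonymous divergence
    (Nei-Gojobori counting, Jukes-Cantor scale) is below ``target_ks``, a
    nonsynonymous one while the realized Ka is below ``omega * target_ks``;
    proposals creating stop codons are rejected.  The realized dN/dS of the
    returned pair therefore equals ``omega`` up to the granularity of single
    substitutions, which is what makes downstream estimator-recovery tests
    sharp.  Returns (original, evolved, realized-truth record).
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("internal stop codon")
    target_ka = omega * target_ks
    for name, target in [("target_ks", target_ks), ("omega*target_ks", target_ka)]:
        implied_p = 0.75 * (1.0 - math.exp(-4.0 * target / 3.0))
        if implied_p >= 0.70:
            raise SaturationError(
                f"{name}={target:g} implies p={implied_p:.3f}, too close to the "
                "Jukes-Cantor saturation bound of 0.75"
            )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(13,)))
    orig = codons.copy()
    cur = codons.copy()
    n = len(cur)
    s_orig = sum(synonymous_sites(c) for c in orig)
    s_cur = s_orig
    sd = [0.0] * n
    nd = [0.0] * n
    sd_tot = nd_tot = 0.0
    n_sites = 3.0 * n

    def realized() -> tuple[float, float]:
        s_avg = (s_orig + s_cur) / 2.0
        n_avg = n_sites - s_avg
        ks = _jc_correct(sd_tot / s_avg) if s_avg else 0.0
        ka = _jc_correct(nd_tot / n_avg) if n_avg else 0.0
        return ka, ks

    acc_syn = acc_nonsyn = proposals = 0
    max_proposals = 5000 * n + 1000
    ka_now = ks_now = 0.0
    dist = abs(target_ks - ks_now) + abs(target_ka - ka_now)
    tol = 2.0 / n_sites  # half a typical single-substitution increment
    stall = 0
    max_stall = 20 * n
    while dist > tol and stall < max_stall:
        if proposals >= max_proposals:
            raise SaturationError("divergence targets unreachable within the proposal budget")
        proposals += 1
        stall += 1
        i = int(rng.integers(n))
        pos = int(rng.integers(3))
        alt = NT[int(rng.integers(4))]
        old = cur[i]
        if alt == old[pos]:
            continue
        new = old[:pos] + alt + old[pos + 1 :]
        if new in STOP_CODONS:
            continue
        diffs = pathway_differences(orig[i], new)
        if diffs is None:  # would make the codon pair uncountable; skip
            continue
        s_new = s_cur + synonymous_sites(new) - synonymous_sites(old)
        sd_new = sd_tot + diffs[0] - sd[i]
        nd_new = nd_tot + diffs[1] - nd[i]
        s_avg = (s_orig + s_new) / 2.0
        n_avg = n_sites - s_avg
        ks_cand = _jc_correct(sd_new / s_avg) if s_avg else 0.0
        ka_cand = _jc_correct(nd_new / n_avg) if n_avg else 0.0
        if math.isnan(ks_cand) or math.isnan(ka_cand):
            continue
        cand_dist = abs(target_ks - ks_cand) + abs(target_ka - ka_cand)
        if cand_dist >= dist - 1e-12:  # greedy: only moves toward the target point
            continue
        if GENETIC_CODE[new] == GENETIC_CODE[old]:
            acc_syn += 1
        else:
            acc_nonsyn += 1
        s_cur, sd_tot, nd_tot = s_new, sd_new, nd_new
        sd[i], nd[i] = diffs
        cur[i] = new
        ka_now, ks_now, dist = ka_cand, ks_cand, cand_dist
        stall = 0
    truth = EvolvedPairTruth(
        omega, target_ks, ks_now, ka_now, acc_syn, acc_nonsyn, proposals
    )
    tail = cds[3 * len(orig) :]  # the stop codon, when the input carried one
    return "".join(orig) + tail, "".join(cur) + tail, truth


# ---------------------------------------------------------------------------
# genome assembly


def _translate(cds: str) -> str:
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def simulate_family_genome(config: SimulationConfig) -> GenomePackage:
    """Assemble a genome package with all requested plantings and truth tables.

    Each gene occupies UTR5 + CDS + UTR3 and owns a dedicated 1.5-kb
    upstream buffer; duplicated copies are placed adjacent to their source
    (tandem) or on another chromosome (segmental).
    """
    config.validate()
    rng_len = child_rng(config.seed, "gene-lengths")
    rng_cds = child_rng(config.seed, "cds")
    rng_myb = child_rng(config.seed, "myb")
    rng_dup = child_rng(config.seed, "duplication")
    rng_ssr = child_rng(config.seed, "ssr")
    rng_asm = child_rng(config.seed, "assembly")

    n_chrom = config.n_chromosomes
    lo, hi = config.gene_length_range
    if lo < 300:
        raise ValueError("gene_length_range lower bound must be >= 300 bp")

    # 1. base gene roster: CDS per gene, MYB classes assigned round-robin
    myb_roster: list[str] = []
    for planting in config.myb_plantings:
        myb_roster.extend([planting.myb_class] * planting.count)
    n_genes = n_chrom * config.genes_per_chromosome
    if len(myb_roster) > n_genes:
        raise ValueError("more MYB plantings than genes")

    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    planted_repeats: dict[str, list[dict]] = {}
    order: dict[str, list[str]] = {f"chr{c + 1:02d}": [] for c in range(n_chrom)}
    gene_ids = []
    for idx in range(n_genes):
        chrom = f"chr{idx % n_chrom + 1:02d}"
        gid = f"G{idx + 1:04d}"
        gene_ids.append(gid)
        order[chrom].append(gid)
        if idx < len(myb_roster):
            prot, truth = synthesize_myb_protein(
                myb_roster[idx], int(rng_myb.integers(2**31))
            )
            cds[gid] = "ATG" + back_translate(prot, rng_cds)
            proteins[gid] = "M" + prot
            planted_repeats[gid] = [
                {"start": t["start"] + 1, "end": t["end"] + 1, "type": t["type"]}
                for t in truth
            ]
        else:
            n_codons = int(rng_len.integers(lo // 3, hi // 3 + 1))
            cds[gid] = _random_cds(n_codons, rng_cds)
            proteins[gid] = _translate(cds[gid])

    # 2. duplication events: evolve a copy, insert into the gene order
    duplicate_truth = []
    for k, ev in enumerate(config.duplication_events):
        src = gene_ids[int(rng_dup.integers(len(gene_ids)))]
        new_id = f"{src}d{k + 1}"
        _orig, evolved, truth = evolve_duplicate_pair(
            cds[src], ev.omega, ev.target_ks, int(rng_dup.integers(2**31))
        )
        cds[new_id] = evolved
        proteins[new_id] = _translate(evolved)
        if src in planted_repeats:
            # keep only repeats whose anchor residues survived divergence
            rules = {r.name: r for r in load_default_profile().rules}
            kept = []
            for rec in planted_repeats[src]:
                window = proteins[new_id][rec["start"] : rec["end"]]
                rule = rules[rec["type"]]
                if all(
                    c < len(window) and window[c] in allowed
                    for c, allowed in zip(rule.columns, rule.residues)
                ):
                    kept.append(rec)
            if kept:
                planted_repeats[new_id] = kept
        src_chrom = next(c for c, ids in order.items() if src in ids)
        if ev.mode == "tandem":
            order[src_chrom].insert(order[src_chrom].index(src) + 1, new_id)
        else:
            others = [c for c in order if c != src_chrom] or [src_chrom]
            target = others[int(rng_dup.integers(len(others)))]
            order[target].append(new_id)
        duplicate_truth.append(
            {
                "gene_a": src,
                "gene_b": new_id,
                "mode": ev.mode,
                "omega": ev.omega,
                "target_ks": ev.target_ks,
                "realized_ks": truth.realized_ks,
                "realized_ka": truth.realized_ka,
            }
        )

    # 3. assign SSR plantings to host genes (one planting per gene, + strand)
    all_ids = [g for ids in order.values() for g in ids]
    ssr_assignments: dict[str, SsrPlanting] = {}
    for planting, gid in zip(config.ssr_plantings, all_ids):
        ssr_assignments[gid] = planting
    if len(config.ssr_plantings) > len(all_ids):
        raise ValueError("more SSR plantings than genes")

    # 4. materialize chromosomes
    def filler(length: int) -> str:
        return "".join(np.asarray(list(NT))[rng_asm.integers(4, size=length)])

    def plant_run(region: str, at: int, planting: SsrPlanting) -> str:
        """Overwrite ``region[at:at+len(run)]`` with the SSR run, with guard
        bases on both sides so the run cannot extend or shift."""
        run = planting.motif * planting.repeats
        if at < 1 or at + len(run) + 1 > len(region):
            raise ValueError("SSR run does not fit in its host region")
        left_guard = next(b for b in NT if b != planting.motif[-1])
        right_guard = next(b for b in NT if b != planting.motif[0])
        return (
            region[: at - 1] + left_guard + run + right_guard + region[at + len(run) + 1 :]
        )

    chromosomes: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    ssr_truth = []
    strand_rng = child_rng(config.seed, "strands")
    for chrom, ids in order.items():
        parts: list[str] = []
        cursor = 0
        for gid in ids:
            gap = int(rng_asm.integers(*config.intergenic_range))
            parts.append(filler(gap))
            cursor += gap
            planting = ssr_assignments.get(gid)
            has_ssr = planting is not None
            strand = "+" if has_ssr else ("+" if strand_rng.random() < 0.5 else "-")
            upstream = filler(UPSTREAM_LEN)
            utr5 = filler(UTR_LEN)
            utr3 = filler(UTR_LEN)
            if has_ssr:
                if planting.region == "upstream":
                    run_off = 300  # nt into the upstream region (5'->3', gene frame)
                    upstream = plant_run(upstream, run_off, planting)
                elif planting.region == "genic":
                    run_off = 20  # nt into the 3' UTR
                    utr3 = plant_run(utr3, run_off, planting)
                else:
                    raise ValueError(f"invalid SSR region {planting.region!r}")
            gene_seq = utr5 + cds[gid] + utr3
            block = upstream + gene_seq if strand == "+" else str(
                Seq(upstream + gene_seq).reverse_complement()
            )
            if strand == "+":
                gstart0 = cursor + UPSTREAM_LEN
            else:
                gstart0 = cursor
            parts.append(block)
            gene_models.append(
                GeneModel(gid, chrom, gstart0 + 1, gstart0 + len(gene_seq), strand)
            )
            if has_ssr:
                if planting.region == "upstream":
                    # offset within the 1.5-kb upstream region, gene frame
                    truth_off = run_off
                    seqid = f"{gid}:upstream"
                else:
                    truth_off = len(utr5) + len(cds[gid]) + run_off
                    seqid = f"{gid}:genic"
                ssr_truth.append(
                    {
                        "gene_id": gid,
                        "region": planting.region,
                        "sequence_id": seqid,
                        "motif": planting.motif,
                        "repeats": planting.repeats,
                        "offset": truth_off,
                    }
                )
            cursor += len(block)
        chromosomes[chrom] = "".join(parts)
        max_end = max((g.end for g in gene_models if g.chromosome == chrom), default=0)
        if max_end > len(chromosomes[chrom]):
            raise ValueError(f"infeasible packing on {chrom}")

    package = GenomePackage(
        chromosomes=chromosomes,
        gene_models=gene_models,
        cds=cds,
        proteins=proteins,
        truth={
            "planted_repeats": planted_repeats,
            "duplicate_truth": duplicate_truth,
            "ssr_truth": ssr_truth,
            "de_truth": None,
            "segment_truth": [],
        },
    )
    counts, de_truth = simulate_counts(config)
    package.truth["de_truth"] = de_truth
    package.truth["counts"] = counts
    package.validate()
    return package


def simulate_collinear_pair(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[GeneModel], list[tuple[str, str]], list[dict]]:
    """A pair of gene orders related by the configured rearrangements.

    Genome B starts as a mirror of genome A's gene order (ids suffixed
    ``_b``); each inversion reverses a block of genes in B, each
    translocation moves a block to another chromosome.  Returns
    (models_a, models_b, homolog_pairs, segment_truth).
    """
    config.validate()
    rng = child_rng(config.seed, "rearrange")
    n_chrom = config.n_chromosomes
    per = config.genes_per_chromosome
    spacing = 10_000
    models_a: list[GeneModel] = []
    order_b: dict[str, list[tuple[str, str]]] = {}
    for c in range(n_chrom):
        chrom_a = f"chrA{c + 1:02d}"
        chrom_b = f"chrB{c + 1:02d}"
        order_b[chrom_b] = []
        for i in range(per):
            gid = f"A{c + 1:02d}g{i + 1:03d}"
            start = spacing * (i + 1)
            models_a.append(GeneModel(gid, chrom_a, start, start + 999, "+"))
            order_b[chrom_b].append((f"{gid}_b", "+"))

    segment_truth: list[dict] = []
    disturbed: set[str] = set()
    for r in config.rearrangements:
        chroms = sorted(order_b)
        # keep planted blocks disjoint so each truth block stays recoverable
        placement = None
        for _try in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            genes = order_b[chrom]
            if r.span > len(genes):
                continue
            at = int(rng.integers(len(genes) - r.span + 1))
            flanks = genes[max(0, at - 1) : at + r.span + 1]
            if not ({g for g, _ in flanks} & disturbed):
                placement = (chrom, at)
                break
        if placement is None:
            raise ValueError(f"cannot place disjoint rearrangement of span {r.span}")
        chrom, at = placement
        genes = order_b[chrom]
        block = genes[at : at + r.span]
        disturbed |= {g for g, _ in block}
        if r.type == "inversion":
            order_b[chrom][at : at + r.span] = [
                (g, "-" if s == "+" else "+") for g, s in reversed(block)
            ]
            segment_truth.append(
                {"type": "inversion", "genes": [g for g, _ in block], "chrom_b": chrom}
            )
        elif r.type == "translocation":
            del order_b[chrom][at : at + r.span]
            others = [c for c in chroms if c != chrom] or [chrom]
            dest = pos = None
            for _try in range(200):
                dest = others[int(rng.integers(len(others)))]
                pos = int(rng.integers(len(order_b[dest]) + 1))
                # do not split a previously planted block at the insertion point
                neighbors = {
                    g for g, _ in order_b[dest][max(0, pos - 1) : pos + 1]
                }
                if not (neighbors & disturbed):
                    break
            else:
                raise ValueError("cannot place translocation without splitting a block")
            order_b[dest][pos:pos] = block
            segment_truth.append(
                {"type": "translocation", "genes": [g for g, _ in block],
                 "chrom_b": dest, "from": chrom}
            )
        else:
            raise ValueError(f"invalid rearrangement type {r.type!r}")

    models_b: list[GeneModel] = []
    for chrom_b, genes in order_b.items():
        for i, (gid, strand) in enumerate(genes):
            start = spacing * (i + 1)
            models_b.append(GeneModel(gid, chrom_b, start, start + 999, strand))
    homologs = [(g.gene_id, f"{g.gene_id}_b") for g in models_a]
    return models_a, models_b, homologs, segment_truth


# ---------------------------------------------------------------------------
# expression counts


def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted fold changes.

    Gene base means are log-normal; library depths vary uniformly on the log
    scale within +/- 3-fold; a ``fraction_de`` subset of genes carries a
    +/- ``log2fc_magnitude`` fold change in the second stage relative to the
    first.  Returns (counts with a MultiIndex of stage/replicate columns,
    de_truth with the true log2 fold change per gene).
    """
    if config.n_stages < 2 or config.n_replicates < 2:
        raise ValueError("need >= 2 stages and >= 2 replicates")
    de = config.de_plantings
    if de.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = child_rng(config.seed, "counts")
    n_genes = config.n_expression_genes
    stages = ["EG", "MG", "Br", "S4", "S5", "S6"][: config.n_stages]
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]

    base = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=n_genes)
    n_de = int(round(de.fraction_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = signs * de.log2fc_magnitude

    cols = []
    data = []
    gene_len = rng.integers(500, 4000, size=n_genes)
    for s_i, stage in enumerate(stages):
        stage_mult = 2.0**lfc if s_i == 1 else np.ones(n_genes)
        for rep in range(1, config.n_replicates + 1):
            depth = math.exp(rng.uniform(math.log(1 / 3), math.log(3)))
            mu = base * stage_mult * depth
            if de.dispersion == 0:
                counts = rng.poisson(mu)
            else:
                shape = 1.0 / de.dispersion
                counts = rng.poisson(rng.gamma(shape, mu / shape))
            cols.append((stage, rep))
            data.append(counts)
    counts = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index(genes, name="gene_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["stage", "replicate"]),
    )
    de_truth = pd.DataFrame(
        {"gene_id": genes, "true_log2fc": lfc, "length": gene_len}
    ).set_index("gene_id")
    return counts, de_truth
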