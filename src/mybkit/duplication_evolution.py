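"""Duplicate-pair discovery, tandem/segmental classification, NG86 Ka/Ks,
selection classes, molecular-clock dating, and QTL co-localization.

The substitution-rate estimator is the Nei-Gojobori (1986) counting method:
synonymous sites are counted fractionally per codon over the standard genetic
code, differences between aligned codons are averaged over all minimal
mutational pathways with equal weights (pathways through stop codons
excluded), and the per-site proportions are Jukes-Cantor corrected,

    Ka = -(3/4) ln(1 - (4/3) pN),   Ks = -(3/4) ln(1 - (4/3) pS).

Divergence dates assume a synonymous molecular clock, T = Ks / (2 lambda),
with the default clock rate lambda = 6.96e-9 synonymous substitutions per
site per year; T is reported in million years (MYA).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .genome import GeneModel

__all__ = [
    "EvolConfig",
    "AlignmentSummary",
    "SubstitutionCounts",
    "DuplicatePair",
    "QtlInterval",
    "align_protein_pair",
    "find_duplicate_pairs",
    "classify_duplication",
    "codon_align",
    "ng86_ka_ks",
    "divergence_time",
    "classify_selection",
    "qtl_colocalize",
    "analyze_duplicates",
]

NT = "ACGT"
GENETIC_CODE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(GENETIC_CODE))


@dataclass(frozen=True)
class EvolConfig:
    """Thresholds and the synonymous clock rate.

    ``lam`` is in synonymous substitutions per site per year.  Identity and
    coverage minima are strict (>) filters; ``cross_coverage_min`` and
    ``evalue_max`` apply to cross-genome homolog searches.
    """

    lam: float = 6.96e-9
    identity_min: float = 0.75
    coverage_min: float = 0.75
    cross_coverage_min: float = 0.80
    evalue_max: float = 1e-3
    tandem_distance: int = 100_000
    # omega < lo -> purifying, omega > hi -> positive, inside -> neutral;
    # the degenerate default reproduces the published calls (1.027 = positive)
    neutral_band: tuple[float, float] = (1.0, 1.0)


@dataclass(frozen=True)
class AlignmentSummary:
    query_id: str
    subject_id: str
    identity: float  # identical / aligned columns (gaps excluded)
    coverage: float  # aligned query residues / query length (shorter seq = query)
    score: float
    aligned_a: str = ""  # gapped aligned strings (a = first argument)
    aligned_b: str = ""
    start_a: int = 0  # offset of the aligned region within each input
    start_b: int = 0


@dataclass
class SubstitutionCounts:
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    codons: int = 0
    skipped: int = 0  # codon pairs whose every pathway crosses a stop

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N else 0.0


@dataclass
class DuplicatePair:
    gene_a: str
    gene_b: str
    mode: str  # tandem | segmental
    identity: float
    coverage: float
    ka: float  # nan = NA (saturated / undefined)
    ks: float
    omega: float
    t_mya: float
    selection: str


@dataclass(frozen=True)
class QtlInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    trait: str
    name: str


# ---------------------------------------------------------------------------
# protein alignment


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


_ALIGNER = _aligner()


def align_protein_pair(a: str, b: str, id_a: str = "a", id_b: str = "b") -> AlignmentSummary:
    """Smith-Waterman local alignment (BLOSUM62, affine gaps) of two proteins.

    Identity is over aligned (gap-free) columns; coverage treats the shorter
    sequence as the query.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    blocks_a, blocks_b = aln.aligned
    gapped_a: list[str] = []
    gapped_b: list[str] = []
    matches = columns = 0
    prev_a = blocks_a[0][0]
    prev_b = blocks_b[0][0]
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        # residues skipped between blocks pair with gaps on the other strand
        gapped_a.append(a[prev_a:sa] + "-" * (sb - prev_b))
        gapped_b.append("-" * (sa - prev_a) + b[prev_b:sb])
        gapped_a.append(a[sa:ea])
        gapped_b.append(b[sb:eb])
        columns += ea - sa
        matches += sum(x == y for x, y in zip(a[sa:ea], b[sb:eb]))
        prev_a, prev_b = ea, eb
    identity = matches / columns if columns else 0.0
    coverage = columns / min(len(a), len(b))
    return AlignmentSummary(
        id_a,
        id_b,
        identity,
        coverage,
        aln.score,
        "".join(gapped_a),
        "".join(gapped_b),
        int(blocks_a[0][0]),
        int(blocks_b[0][0]),
    )


def find_duplicate_pairs(
    proteome: dict[str, str],
    gene_models: list[GeneModel],
    config: EvolConfig = EvolConfig(),
) -> list[AlignmentSummary]:
    """All unordered protein pairs passing the identity/coverage filters.

    Both filters are strict (identity > identity_min, coverage >
    coverage_min); pairs are returned in lexicographic id order.
    """
    placed = {g.gene_id for g in gene_models}
    missing = sorted(set(proteome) - placed)
    if missing:
        raise KeyError(f"proteins without a gene model: {missing}")
    hits = []
    ids = sorted(proteome)
    for ia, ib in itertools.combinations(ids, 2):
        summ = align_protein_pair(proteome[ia], proteome[ib], ia, ib)
        if summ.identity > config.identity_min and summ.coverage > config.coverage_min:
            hits.append(summ)
    return hits


def classify_duplication(
    gene_a: GeneModel, gene_b: GeneModel, config: EvolConfig = EvolConfig()
) -> str:
    """Tandem iff same chromosome and the inter-span gap < the tandem distance."""
    if gene_a.chromosome != gene_b.chromosome:
        return "segmental"
    (s1, e1), (s2, e2) = sorted([gene_a.span0, gene_b.span0])
    gap = max(0, s2 - e1)
    return "tandem" if gap < config.tandem_distance else "segmental"


# ---------------------------------------------------------------------------
# codon alignment and NG86


def codon_align(
    alignment: AlignmentSummary, cds_a: str, cds_b: str
) -> list[tuple[str, str]]:
    """Back-translate a protein alignment onto the two CDS.

    Gap columns propagate as codon gaps ('---').  The CDS must translate to
    the unaligned proteins (a trailing stop codon is tolerated).
    """

    def check(cds: str, gapped: str, start: int, label: str) -> str:
        prot = str(Seq(cds).translate())
        if prot.endswith("*"):
            prot = prot[:-1]
        ungapped = gapped.replace("-", "")
        if prot[start : start + len(ungapped)] != ungapped:
            raise ValueError(f"CDS {label} does not translate to the aligned protein")
        return cds

    check(cds_a, alignment.aligned_a, alignment.start_a, "a")
    check(cds_b, alignment.aligned_b, alignment.start_b, "b")
    pos_a, pos_b = alignment.start_a, alignment.start_b
    out: list[tuple[str, str]] = []
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if ca == "-":
            cod_a = "---"
        else:
            cod_a = cds_a[3 * pos_a : 3 * pos_a + 3]
            pos_a += 1
        if cb == "-":
            cod_b = "---"
        else:
            cod_b = cds_b[3 * pos_b : 3 * pos_b + 3]
            pos_b += 1
        out.append((cod_a, cod_b))
    return out


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Fractional synonymous sites of a sense codon (changes to stops count
    as nonsynonymous, so S + N = 3 per codon)."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NT:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and GENETIC_CODE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal mutational pathways; pathways whose
    intermediates are stop codons are excluded.  None if no pathway is valid.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    syn_tot = nsyn_tot = 0.0
    n_valid = 0
    for order in itertools.permutations(diff):
        cur = codon_a
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_valid += 1
    if n_valid == 0:
        return None
    return (syn_tot / n_valid, nsyn_tot / n_valid)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def count_substitutions(codon_pairs: list[tuple[str, str]]) -> SubstitutionCounts:
    """NG86 site and difference counts over gap-free sense codon columns."""
    counts = SubstitutionCounts()
    for cod_a, cod_b in codon_pairs:
        if "-" in cod_a or "-" in cod_b:
            continue
        if cod_a in STOP_CODONS or cod_b in STOP_CODONS:
            continue
        diffs = pathway_differences(cod_a, cod_b)
        if diffs is None:
            counts.skipped += 1
            continue
        counts.S += (synonymous_sites(cod_a) + synonymous_sites(cod_b)) / 2.0
        counts.N += 3.0 - (synonymous_sites(cod_a) + synonymous_sites(cod_b)) / 2.0
        counts.Sd += diffs[0]
        counts.Nd += diffs[1]
        counts.codons += 1
    return counts


def ng86_ka_ks(
    codon_pairs: list[tuple[str, str]],
) -> tuple[float, float, SubstitutionCounts]:
    """Nei-Gojobori Ka and Ks (Jukes-Cantor corrected) for an aligned codon pair.

    Saturation (pS or pN >= 0.75) yields nan for the affected rate.
    """
    counts = count_substitutions(codon_pairs)
    if counts.codons == 0:
        raise ValueError("no comparable (gap-free, sense) codon columns")
    return _jc_correct(counts.pN), _jc_correct(counts.pS), counts


def omega_ratio(ka: float, ks: float) -> float:
    """Ka/Ks; nan (NA) when Ks is 0, nan, or Ka is nan."""
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        return math.nan
    return ka / ks


def divergence_time(ks: float, config: EvolConfig = EvolConfig()) -> float:
    """T = Ks / (2 lambda), in million years; nan propagates."""
    if math.isnan(ks):
        return math.nan
    if ks < 0 or math.isinf(ks):
        raise ValueError("Ks must be finite and >= 0")
    return ks / (2.0 * config.lam) / 1e6


def classify_selection(omega: float, config: EvolConfig = EvolConfig()) -> str:
    if math.isnan(omega):
        return "NA"
    lo, hi = config.neutral_band
    if omega < lo:
        return "purifying"
    if omega > hi:
        return "positive"
    return "neutral"


# ---------------------------------------------------------------------------
# pipeline and QTL overlap


def analyze_duplicates(
    proteome: dict[str, str],
    cds: dict[str, str],
    gene_models: list[GeneModel],
    config: EvolConfig = EvolConfig(),
) -> list[DuplicatePair]:
    """Full within-genome pipeline: pair discovery, mode, Ka/Ks, dating."""
    genes = {g.gene_id: g for g in gene_models}
    results = []
    for summ in find_duplicate_pairs(proteome, gene_models, config):
        mode = classify_duplication(genes[summ.query_id], genes[summ.subject_id], config)
        pairs = codon_align(summ, cds[summ.query_id], cds[summ.subject_id])
        ka, ks, _counts = ng86_ka_ks(pairs)
        om = omega_ratio(ka, ks)
        results.append(
            DuplicatePair(
                summ.query_id,
                summ.subject_id,
                mode,
                summ.identity,
                summ.coverage,
                ka,
                ks,
                om,
                divergence_time(ks, config) if not math.isnan(ks) else math.nan,
                classify_selection(om, config),
            )
        )
    return results


def qtl_colocalize(
    gene_models: list[GeneModel],
    qtl_intervals: list[QtlInterval],
    any_overlap: bool = False,
    chromosomes: set[str] | None = None,
) -> pd.DataFrame:
    """Genes whose span lies within a QTL interval on the same chromosome.

    Containment by default ("located within"); ``any_overlap`` relaxes to
    partial overlap.  If ``chromosomes`` is given, QTLs naming an unknown
    chromosome raise KeyError.
    """
    if chromosomes is not None:
        for q in qtl_intervals:
            if q.chromosome not in chromosomes:
                raise KeyError(f"QTL {q.name}: unknown chromosome {q.chromosome}")
    rows = []
    for g in gene_models:
        for q in qtl_intervals:
            if g.chromosome != q.chromosome:
                continue
            if any_overlap:
                hit = g.start <= q.end and g.end >= q.start
            else:
                hit = q.start <= g.start and g.end <= q.end
            if hit:
                rows.append(
                    {"gene_id": g.gene_id, "qtl": q.name, "trait": q.trait,
                     "chromosome": g.chromosome, "gene_start": g.start, "gene_end": g.end}
                )
    return pd.DataFrame(rows, columns=["gene_id", "qtl", "trait", "chromosome",
                                       "gene_start", "gene_end"])
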