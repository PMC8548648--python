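"""Chaining homologous-gene anchors into conserved syntenic segments (CSS).

Anchors are homolog pairs placed at ordinal gene ranks along their
chromosomes.  Within each chromosome pair, maximal-score chains are found by
dynamic programming over rank-sorted anchors, separately for forward (both
ranks increasing) and reversed (second rank decreasing) orientations; each
anchor joins at most one segment (best score first).  Segment summaries
count family-gene-bearing segments, cross-chromosome segments, and reversed
segments, matching the conventional collinearity bookkeeping.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .genome import GeneModel

__all__ = [
    "AnchorPair",
    "SyntenicSegment",
    "ChainConfig",
    "build_anchors",
    "chain_anchors",
    "chain_score",
    "summarize_segments",
]


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    chrom_a: str
    chrom_b: str
    score: float = 1.0  # homology score, used only for tandem-array collapse


@dataclass(frozen=True)
class ChainConfig:
    min_anchors: int = 5
    max_rank_gap: int = 25
    gap_penalty: float = 0.1

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")


@dataclass
class SyntenicSegment:
    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # forward | reversed
    score: float
    span_a: tuple[int, int] | None = None  # bp hull, when gene models are given
    span_b: tuple[int, int] | None = None
    contains_family_gene: bool = False

    def __post_init__(self) -> None:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        assert ra == sorted(ra) and len(set(ra)) == len(ra), "rank_a not increasing"
        if self.orientation == "forward":
            assert rb == sorted(rb) and len(set(rb)) == len(rb), "rank_b not increasing"
        else:
            assert rb == sorted(rb, reverse=True) and len(set(rb)) == len(rb)


def build_anchors(
    homolog_pairs: list[tuple[str, str]],
    gene_models_a: list[GeneModel],
    gene_models_b: list[GeneModel],
    collapse_tandem: bool = True,
    scores: dict[tuple[str, str], float] | None = None,
) -> list[AnchorPair]:
    """Assign per-chromosome ranks (start-coordinate order) and build anchors.

    With ``collapse_tandem``, consecutive genes on one genome hitting the
    same partner gene collapse to the best-scoring anchor before chaining.
    """
    def rank_map(models: list[GeneModel]) -> dict[str, tuple[str, int]]:
        by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
        for g in models:
            by_chrom[g.chromosome].append(g)
        out = {}
        for chrom, genes in by_chrom.items():
            for rank, g in enumerate(sorted(genes, key=lambda g: (g.start, g.gene_id))):
                out[g.gene_id] = (chrom, rank)
        return out

    ranks_a = rank_map(gene_models_a)
    ranks_b = rank_map(gene_models_b)
    anchors = []
    for ga, gb in homolog_pairs:
        if ga not in ranks_a:
            raise KeyError(f"gene {ga} has no placement in genome A")
        if gb not in ranks_b:
            raise KeyError(f"gene {gb} has no placement in genome B")
        ca, ra = ranks_a[ga]
        cb, rb = ranks_b[gb]
        score = scores.get((ga, gb), 1.0) if scores else 1.0
        anchors.append(AnchorPair(ga, gb, ra, rb, ca, cb, score))
    anchors.sort(key=lambda a: (a.chrom_a, a.rank_a, a.chrom_b, a.rank_b))
    if collapse_tandem:
        anchors = _collapse_tandem(anchors)
    return anchors


def _collapse_tandem(anchors: list[AnchorPair]) -> list[AnchorPair]:
    """Merge runs of consecutive same-partner anchors, keeping the best score."""

    def collapse(items: list[AnchorPair], key_run, key_same) -> list[AnchorPair]:
        out: list[AnchorPair] = []
        for a in items:
            if out and key_same(out[-1]) == key_same(a) and abs(
                key_run(a) - key_run(out[-1])
            ) == 1:
                if a.score > out[-1].score:
                    out[-1] = a
            else:
                out.append(a)
        return out

    ordered = sorted(anchors, key=lambda a: (a.chrom_a, a.rank_a))
    ordered = collapse(ordered, lambda a: a.rank_a, lambda a: (a.chrom_b, a.gene_b))
    ordered = sorted(ordered, key=lambda a: (a.chrom_b, a.rank_b))
    ordered = collapse(ordered, lambda a: a.rank_b, lambda a: (a.chrom_a, a.gene_a))
    ordered.sort(key=lambda a: (a.chrom_a, a.rank_a, a.chrom_b, a.rank_b))
    return ordered


def chain_score(chain: list[AnchorPair], config: ChainConfig) -> float:
    """Score of an anchor chain: anchors - gap_penalty * gap events.

    A gap event is a consecutive anchor pair skipping at least one rank on
    either genome (penalizing discontinuities, not their length, in the
    spirit of collinearity chainers).
    """
    gaps = sum(
        1
        for a, b in zip(chain, chain[1:])
        if abs(b.rank_a - a.rank_a) > 1 or abs(b.rank_b - a.rank_b) > 1
    )
    return len(chain) - config.gap_penalty * gaps


def _best_chain(
    anchors: list[AnchorPair], config: ChainConfig, reversed_b: bool
) -> tuple[float, list[int]]:
    """Highest-scoring chain by DP over rank_a-sorted anchors."""
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    best: tuple[float, list[int]] = (0.0, [])
    score = [1.0] * n
    prev = [-1] * n
    for oi, i in enumerate(order):
        ai = anchors[i]
        for j in order[:oi]:
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            db = (aj.rank_b - ai.rank_b) if reversed_b else (ai.rank_b - aj.rank_b)
            if da < 1 or db < 1 or da > config.max_rank_gap or db > config.max_rank_gap:
                continue
            cand = score[j] + 1.0 - config.gap_penalty * (1.0 if da > 1 or db > 1 else 0.0)
            if cand > score[i] + 1e-12:
                score[i] = cand
                prev[i] = j
        if score[i] > best[0]:
            chain = []
            k = i
            while k != -1:
                chain.append(k)
                k = prev[k]
            best = (score[i], chain[::-1])
    return best


def chain_anchors(
    anchors: list[AnchorPair],
    config: ChainConfig = ChainConfig(),
    gene_models_a: list[GeneModel] | None = None,
    gene_models_b: list[GeneModel] | None = None,
) -> list[SyntenicSegment]:
    """Partition anchors into maximal-score syntenic segments.

    Within each (chrom_a, chrom_b) pair, the best forward or reversed chain
    is extracted greedily, its anchors removed, and the search repeated
    until no chain reaches ``min_anchors``.
    """
    spans_a = {g.gene_id: g for g in gene_models_a} if gene_models_a else {}
    spans_b = {g.gene_id: g for g in gene_models_b} if gene_models_b else {}
    by_pair: dict[tuple[str, str], list[AnchorPair]] = defaultdict(list)
    for a in anchors:
        by_pair[(a.chrom_a, a.chrom_b)].append(a)

    segments: list[SyntenicSegment] = []
    for (ca, cb), pool in sorted(by_pair.items()):
        pool = list(pool)
        while len(pool) >= config.min_anchors:
            fwd = _best_chain(pool, config, reversed_b=False)
            rev = _best_chain(pool, config, reversed_b=True)
            (best_score, idxs), orientation = max(
                [(fwd, "forward"), (rev, "reversed")], key=lambda t: t[0][0]
            )
            if len(idxs) < config.min_anchors:
                break
            chain = [pool[i] for i in idxs]
            segment = SyntenicSegment(chain, ca, cb, orientation, best_score)
            if spans_a:
                xs = [spans_a[a.gene_a] for a in chain if a.gene_a in spans_a]
                segment.span_a = (min(g.start for g in xs), max(g.end for g in xs))
            if spans_b:
                xs = [spans_b[a.gene_b] for a in chain if a.gene_b in spans_b]
                segment.span_b = (min(g.start for g in xs), max(g.end for g in xs))
            segments.append(segment)
            used = set(idxs)
            pool = [a for i, a in enumerate(pool) if i not in used]
    _refine_boundaries(segments, config)
    for seg in segments:  # re-assert monotonicity after refinement
        SyntenicSegment(seg.anchors, seg.chrom_a, seg.chrom_b, seg.orientation, seg.score)
    segments.sort(key=lambda s: (s.chrom_a, s.chrom_b, s.anchors[0].rank_a))
    return segments


def _chain_valid(chain: list[AnchorPair], orientation: str, config: ChainConfig) -> bool:
    for a, b in zip(chain, chain[1:]):
        da = b.rank_a - a.rank_a
        db = (a.rank_b - b.rank_b) if orientation == "reversed" else (b.rank_b - a.rank_b)
        if da < 1 or db < 1 or da > config.max_rank_gap or db > config.max_rank_gap:
            return False
    return True


def _refine_boundaries(segments: list[SyntenicSegment], config: ChainConfig) -> None:
    """Move anchors to a segment where they sit rank-contiguously when the
    total score does not decrease.

    The greedy partition can leave global-score ties in which an edge anchor
    of a rearranged block is absorbed by the flanking chain; preferring the
    contiguous placement restores planted blocks exactly without score loss.
    """
    for _ in range(10):
        moved = False
        for s_from in segments:
            if len(s_from.anchors) <= config.min_anchors:
                continue
            for s_to in segments:
                if s_to is s_from or s_to.chrom_a != s_from.chrom_a \
                        or s_to.chrom_b != s_from.chrom_b:
                    continue
                for e in list(s_from.anchors):
                    # contiguity in the donor: skip anchors snug in their chain
                    i = s_from.anchors.index(e)
                    nbrs = [x for x in (i - 1, i + 1) if 0 <= x < len(s_from.anchors)]
                    snug = all(
                        abs(e.rank_a - s_from.anchors[x].rank_a) == 1
                        and abs(e.rank_b - s_from.anchors[x].rank_b) == 1
                        for x in nbrs
                    )
                    if snug:
                        continue
                    for at in (0, len(s_to.anchors)):
                        cand = s_to.anchors[:at] + [e] + s_to.anchors[at:]
                        nb = cand[1] if at == 0 else cand[-2]
                        if abs(e.rank_a - nb.rank_a) != 1 or abs(e.rank_b - nb.rank_b) != 1:
                            continue
                        if not _chain_valid(cand, s_to.orientation, config):
                            continue
                        rest = [x for x in s_from.anchors if x is not e]
                        if not _chain_valid(rest, s_from.orientation, config):
                            continue
                        new_total = chain_score(rest, config) + chain_score(cand, config)
                        old_total = chain_score(s_from.anchors, config) + chain_score(
                            s_to.anchors, config
                        )
                        if new_total < old_total - 1e-9:
                            continue
                        s_from.anchors = rest
                        s_from.score = chain_score(rest, config)
                        s_to.anchors = cand
                        s_to.score = chain_score(cand, config)
                        moved = True
                        break
                    if moved:
                        break
                if moved:
                    break
            if moved:
                break
        if not moved:
            break


def summarize_segments(
    segments: list[SyntenicSegment],
    family_gene_ids: set[str],
    chrom_map: dict[str, str] | None = None,
) -> dict:
    """Family-centric segment statistics.

    Counts segments containing >= 1 family gene (on either genome's side),
    how many of those lie on non-matching chromosome labels (via
    ``chrom_map``: genome-A label -> expected genome-B label), how many are
    reversed, the number of distinct family genes inside segments, and
    per-chromosome collinear family-gene counts.
    """
    fam_segments = []
    fam_genes: set[str] = set()
    per_chrom: Counter = Counter()
    for seg in segments:
        members = {a.gene_a for a in seg.anchors} | {a.gene_b for a in seg.anchors}
        fam = members & family_gene_ids
        seg.contains_family_gene = bool(fam)
        if fam:
            fam_segments.append(seg)
            fam_genes |= fam
            per_chrom[seg.chrom_a] += len({a.gene_a for a in seg.anchors} & family_gene_ids)
    diff_chrom = 0
    if chrom_map is not None:
        diff_chrom = sum(
            1 for s in fam_segments if chrom_map.get(s.chrom_a) != s.chrom_b
        )
    return {
        "n_segments": len(segments),
        "n_family_segments": len(fam_segments),
        "n_diff_chromosome": diff_chrom,
        "n_reversed": sum(1 for s in fam_segments if s.orientation == "reversed"),
        "n_family_genes_in_segments": len(fam_genes),
        "family_genes_per_chromosome": dict(sorted(per_chrom.items())),
    }


def segments_table(segments: list[SyntenicSegment]) -> pd.DataFrame:
    rows = [
        {
            "chrom_a": s.chrom_a,
            "chrom_b": s.chrom_b,
            "orientation": s.orientation,
            "n_anchors": len(s.anchors),
            "score": s.score,
            "first_gene_a": s.anchors[0].gene_a,
            "last_gene_a": s.anchors[-1].gene_a,
        }
        for s in segments
    ]
    return pd.DataFrame(rows)
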