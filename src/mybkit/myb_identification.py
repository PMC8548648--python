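"""MYB repeat detection and classification.

The MYB DNA-binding domain is an imperfect repeat of ~52 amino acids whose
hallmark is a trio of regularly spaced aromatic anchors: the R2-type repeat
carries three tryptophans spaced 20-21 residues apart, while the R3-type
repeat replaces the first tryptophan with a phenylalanine and carries two
tryptophans spaced 19 residues apart.  Proteins are classed by the number of
adjacent repeats: one (1R / MYB-related), two (R2R3), three (3R), four (4R);
repeats that are present but violate adjacency are flagged atypical.

Detection is anchor-driven: candidate windows are generated wherever a chain
of anchor residues with admissible spacings occurs, scored against a bundled
position-weight profile built from a seed alignment, and resolved greedily
(best score first) into a non-overlapping set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "RepeatProfile",
    "MybRepeat",
    "MybClassification",
    "ConservationProfile",
    "load_default_profile",
    "detect_myb_repeats",
    "classify_myb",
    "build_conservation_profile",
    "anchor_spacing_stats",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BACKGROUND = 1.0 / 20.0


class AlphabetError(ValueError):
    """Sequence contains characters outside the amino-acid alphabet."""


@dataclass(frozen=True)
class AnchorRule:
    """One repeat archetype: anchor columns, allowed residues, spacing bounds."""

    name: str
    columns: tuple[int, ...]
    residues: tuple[frozenset[str], ...]
    spacings: tuple[tuple[int, int], ...]  # admissible (lo, hi) per successive gap
    length: int


@dataclass
class RepeatProfile:
    """Column weights plus anchor rules for repeat detection."""

    weights: list[dict[str, float]]  # per column, residue -> probability
    rules: list[AnchorRule]
    score_threshold: float
    max_linker: int

    @property
    def length(self) -> int:
        return len(self.weights)

    def score(self, window: str) -> float:
        """Log-odds (bits) of ``window`` under the profile vs uniform background."""
        total = 0.0
        for col, res in zip(self.weights, window):
            total += math.log2(col.get(res, _BACKGROUND / 4) / _BACKGROUND)
        return total


@dataclass(frozen=True)
class MybRepeat:
    protein_id: str
    start: int  # 0-based half-open aa offsets
    end: int
    anchors: tuple[int, ...]
    score: float
    rule: str = ""

    def __post_init__(self) -> None:
        if not 45 <= self.end - self.start <= 60:
            raise ValueError("repeat length outside [45, 60] aa")
        if list(self.anchors) != sorted(set(self.anchors)):
            raise ValueError("anchors must be strictly increasing")
        if self.anchors and not (self.start <= self.anchors[0] and self.anchors[-1] < self.end):
            raise ValueError("anchors outside repeat span")


@dataclass(frozen=True)
class MybClassification:
    protein_id: str
    n_repeats: int
    myb_class: str  # 1R | R2R3 | 3R | 4R | atypical | none


@dataclass
class ConservationProfile:
    n_sequences: int
    column_stats: list[tuple[str, float]]  # (modal residue, modal frequency)
    conserved_threshold: float
    n_conserved: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_conserved = sum(
            1 for _res, freq in self.column_stats if freq >= self.conserved_threshold
        )


def _build_weights(seed_alignment: list[str], pseudocount: float = 0.5) -> list[dict[str, float]]:
    ncol = len(seed_alignment[0])
    weights = []
    for c in range(ncol):
        counts = Counter(seq[c] for seq in seed_alignment)
        denom = len(seed_alignment) + pseudocount * 20
        weights.append({aa: (counts.get(aa, 0) + pseudocount) / denom for aa in AMINO_ACIDS})
    return weights


def load_default_profile() -> RepeatProfile:
    """Load the bundled repeat profile (seed alignments + anchor rules + threshold)."""
    raw = yaml.safe_load(
        resources.files("mybkit.data").joinpath("repeat_profile.yaml").read_text()
    )
    rules = []
    alignments: list[str] = []
    for name, spec in raw["repeats"].items():
        cols = tuple(a["column"] for a in spec["anchors"])
        residues = tuple(frozenset(a["residues"]) for a in spec["anchors"])
        spacings = tuple(
            (a["spacing"][0], a["spacing"][1]) for a in spec["anchors"][1:]
        )
        rules.append(AnchorRule(name, cols, residues, spacings, spec["length"]))
        alignments.extend(spec["seed_alignment"])
    weights = _build_weights(alignments)
    return RepeatProfile(weights, rules, raw["score_threshold"], raw["max_linker"])


def seed_alignments() -> dict[str, list[str]]:
    """The bundled per-repeat-type seed alignments (synthetic, repo data)."""
    raw = yaml.safe_load(
        resources.files("mybkit.data").joinpath("repeat_profile.yaml").read_text()
    )
    return {name: spec["seed_alignment"] for name, spec in raw["repeats"].items()}


def _check_alphabet(protein: str) -> None:
    bad = set(protein) - set(AMINO_ACIDS) - {"X"}
    if bad:
        raise AlphabetError(f"non-amino-acid characters: {sorted(bad)}")


def _anchor_chains(protein: str, rule: AnchorRule) -> list[tuple[int, ...]]:
    """All anchor-position chains satisfying the rule's residues and spacings."""
    positions = [
        [i for i, aa in enumerate(protein) if aa in allowed] for allowed in rule.residues
    ]
    chains: list[tuple[int, ...]] = []

    def extend(chain: tuple[int, ...], level: int) -> None:
        if level == len(positions):
            chains.append(chain)
            return
        lo, hi = rule.spacings[level - 1]
        for p in positions[level]:
            if lo <= p - chain[-1] <= hi:
                extend(chain + (p,), level + 1)

    for p0 in positions[0]:
        extend((p0,), 1)
    return chains


def detect_myb_repeats(protein: str, profile: RepeatProfile | None = None) -> list[MybRepeat]:
    """Detect non-overlapping MYB repeats in a protein sequence.

    Candidate windows are anchored on chains of anchor residues with
    admissible spacings; each full-length window is scored against the
    profile; windows scoring >= ``score_threshold`` are kept and overlaps
    resolved greedily best-score-first (ties: smaller start).
    """
    if not protein:
        raise ValueError("empty protein sequence")
    _check_alphabet(protein)
    if profile is None:
        profile = load_default_profile()

    candidates: list[MybRepeat] = []
    for rule in profile.rules:
        for chain in _anchor_chains(protein, rule):
            start = chain[0] - rule.columns[0]
            end = start + rule.length
            if start < 0 or end > len(protein):
                continue
            score = profile.score(protein[start:end])
            if score >= profile.score_threshold:
                candidates.append(
                    MybRepeat("", start, end, chain, round(score, 3), rule.name)
                )

    # greedy non-overlap resolution: best score first, ties by smaller start
    candidates.sort(key=lambda r: (-r.score, r.start))
    chosen: list[MybRepeat] = []
    for cand in candidates:
        if all(cand.end <= r.start or cand.start >= r.end for r in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


def classify_myb(
    repeats: list[MybRepeat], protein_length: int, max_linker: int = 25
) -> MybClassification:
    """Class a protein by its number of adjacent repeats.

    ``n`` adjacent repeats (inter-repeat gap <= ``max_linker``) map to
    1R/R2R3/3R/4R; repeats present but violating adjacency (or >4 of them)
    are atypical; zero repeats is the distinct "none" signal.
    """
    pid = repeats[0].protein_id if repeats else ""
    if not repeats:
        return MybClassification(pid, 0, "none")
    ordered = sorted(repeats, key=lambda r: r.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise RuntimeError("overlapping repeats violate the detection contract")
    adjacent = all(b.start - a.end <= max_linker for a, b in zip(ordered, ordered[1:]))
    names = {1: "1R", 2: "R2R3", 3: "3R", 4: "4R"}
    n = len(ordered)
    if adjacent and n in names:
        return MybClassification(pid, n, names[n])
    return MybClassification(pid, n, "atypical")


def build_conservation_profile(
    repeat_blocks: list[str], threshold: float = 0.80
) -> ConservationProfile:
    """Per-column modal residue/frequency over equal-length repeat blocks.

    Gap characters ('-') are excluded from modal counts; a column is
    conserved when its modal frequency >= ``threshold`` (inclusive).
    """
    if len(repeat_blocks) < 2:
        raise ValueError("need at least 2 blocks")
    ncol = len(repeat_blocks[0])
    if any(len(b) != ncol for b in repeat_blocks):
        raise ValueError("blocks must have equal length")
    stats: list[tuple[str, float]] = []
    for c in range(ncol):
        counts = Counter(b[c] for b in repeat_blocks if b[c] != "-")
        if not counts:
            stats.append(("-", 0.0))
            continue
        # deterministic tie-break: highest count, then lexicographic residue
        res, n = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        stats.append((res, n / len(repeat_blocks)))
    return ConservationProfile(len(repeat_blocks), stats, threshold)


def anchor_spacing_stats(repeats: list[MybRepeat]) -> Counter:
    """Histogram of successive anchor spacings (aa) over a repeat set."""
    hist: Counter = Counter()
    for rep in repeats:
        for a, b in zip(rep.anchors, rep.anchors[1:]):
            hist[b - a] += 1
    return hist
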