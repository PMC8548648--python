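"""Strand-aware promoter extraction and SSR / cis-element scanning.

SSRs are perfect tandem repeats of a 2-6 nt period-minimal motif with at
least 6 full copies (mononucleotide runs are excluded by the period-2
floor); runs are maximal and anchored at their leftmost full copy, partial
trailing copies are not counted.  Cis-regulatory elements are matched as
exact IUPAC consensus strings on both strands of the promoter.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import yaml
from Bio.Seq import Seq

from .genome import GeneModel

__all__ = [
    "SSRLocus",
    "CisElementHit",
    "UpstreamRegion",
    "extract_upstream",
    "find_ssrs",
    "summarize_ssrs",
    "scan_cis_elements",
    "load_cis_dictionary",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class AlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class SSRLocus:
    sequence_id: str
    motif: str
    repeats: int
    start: int  # 0-based half-open nt offsets
    end: int
    region: str = ""

    def __post_init__(self) -> None:
        assert self.end - self.start == len(self.motif) * self.repeats


@dataclass(frozen=True)
class CisElementHit:
    element_name: str
    consensus: str
    position: int  # forward-strand offset of the match start
    strand: str


@dataclass(frozen=True)
class UpstreamRegion:
    gene_id: str
    sequence: str  # 5'->3' relative to the gene
    truncated: bool = False


def extract_upstream(
    gene: GeneModel, chromosomes: dict[str, str], length: int = 1500
) -> UpstreamRegion:
    """The ``length`` nt immediately upstream of the gene's TSS, 5'->3' in
    the gene's frame; truncated at the chromosome edge."""
    if gene.chromosome not in chromosomes:
        raise KeyError(f"unknown chromosome {gene.chromosome}")
    chrom = chromosomes[gene.chromosome]
    s0, e0 = gene.span0
    if gene.strand == "+":
        lo = max(0, s0 - length)
        seq = chrom[lo:s0]
        truncated = lo > s0 - length
    else:
        hi = min(len(chrom), e0 + length)
        seq = str(Seq(chrom[e0:hi]).reverse_complement())
        truncated = hi < e0 + length
    return UpstreamRegion(gene.gene_id, seq, truncated)


def _minimal_period(motif: str) -> int:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return p
    return len(motif)


def find_ssrs(
    sequence: str,
    sequence_id: str = "",
    min_motif: int = 2,
    max_motif: int = 6,
    min_repeats: int = 6,
    region: str = "",
) -> list[SSRLocus]:
    """All maximal perfect tandem runs with a period-minimal motif.

    A locus is reported once, anchored at the start of its maximal run, with
    ``repeats`` = floor(run length / period).  Sub-period re-reports of the
    same run are suppressed by period minimality; overlapping runs of
    different minimal periods are all reported.  N is tolerated in the
    sequence but never inside a reported run.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AlphabetError(f"non-DNA characters: {sorted(bad)}")
    n = len(seq)
    loci: list[SSRLocus] = []
    for p in range(min_motif, max_motif + 1):
        i = 0
        while i + p <= n:
            # maximal run of period p starting at i: s[x] == s[x+p]
            if "N" in seq[i : i + p]:
                i += 1
                continue
            j = i
            while j + p < n and seq[j + p] == seq[j] and seq[j + p] != "N":
                j += 1
            run_len = j - i + p  # nt covered by the periodic stretch
            copies = run_len // p
            motif = seq[i : i + p]
            if copies >= min_repeats and _minimal_period(motif) == p:
                loci.append(
                    SSRLocus(sequence_id, motif, copies, i, i + p * copies, region)
                )
            # next candidate start: beyond this periodic stretch
            i = j + 1 if run_len >= 2 * p else i + 1
    loci.sort(key=lambda x: (x.start, len(x.motif)))
    return loci


def summarize_ssrs(loci: list[SSRLocus]) -> dict:
    """Counts by motif length, modal motif (lexicographic tie-break), and the
    longest locus (max repeats x period)."""
    by_period = Counter(len(l.motif) for l in loci)
    tallies = {p: by_period.get(p, 0) for p in range(2, 7)}
    out = {"counts_by_period": tallies, "n_loci": len(loci),
           "modal_motif": None, "modal_count": 0, "longest": None}
    if loci:
        motif_counts = Counter(l.motif for l in loci)
        motif, count = min(motif_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out["modal_motif"] = motif
        out["modal_count"] = count
        out["longest"] = max(loci, key=lambda l: (l.repeats * len(l.motif), -l.start))
    return out


def load_cis_dictionary() -> dict[str, str]:
    """The bundled cis-element dictionary (element name -> IUPAC consensus)."""
    return yaml.safe_load(
        resources.files("mybkit.data").joinpath("cis_elements.yaml").read_text()
    )["elements"]


def _iupac_regex(consensus: str) -> re.Pattern:
    try:
        return re.compile("".join(f"[{IUPAC[c]}]" for c in consensus.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc} in consensus {consensus!r}") from exc


def scan_cis_elements(
    sequence: str, element_dictionary: dict[str, str] | None = None
) -> list[CisElementHit]:
    """All exact IUPAC consensus matches on both strands, sorted by position.

    Minus-strand hits are reported at the forward coordinate of the match
    start (leftmost base of the matched substring).
    """
    if element_dictionary is None:
        element_dictionary = load_cis_dictionary()
    seq = sequence.upper()
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    hits: list[CisElementHit] = []
    for name in sorted(element_dictionary):
        consensus = element_dictionary[name]
        pat = _iupac_regex(consensus)
        for m in pat.finditer(seq):
            hits.append(CisElementHit(name, consensus, m.start(), "+"))
        for m in pat.finditer(rc):
            fwd = n - m.end()  # forward coordinate of the match start
            hits.append(CisElementHit(name, consensus, fwd, "-"))
    hits.sort(key=lambda h: (h.position, h.element_name, h.strand))
    return hits
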