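"""Shared genome containers and FASTA/GFF3 I/O.

Coordinate convention: :class:`GeneModel` carries GFF3-style 1-based
inclusive coordinates (the on-disk convention); internal arithmetic uses the
0-based half-open ``span0`` view.  Converters live only at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["GeneModel", "GenomePackage", "read_fasta", "write_fasta", "read_gff3", "write_gff3"]


@dataclass(frozen=True)
class GeneModel:
    """A gene span on a chromosome (1-based, inclusive, per GFF3)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.gene_id}: invalid span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def span0(self) -> tuple[int, int]:
        """0-based half-open span for internal arithmetic."""
        return self.start - 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomePackage:
    """A genome with gene models, sequences, and (for synthetic data) planted truth."""

    chromosomes: dict[str, str]
    gene_models: list[GeneModel]
    cds: dict[str, str]
    proteins: dict[str, str]
    truth: dict = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._index[gene_id]
        except AttributeError:
            self._index = {g.gene_id: g for g in self.gene_models}
            return self._index[gene_id]

    def validate(self) -> None:
        """Check structural invariants (spans inside chromosomes, CDS/protein closure)."""
        for g in self.gene_models:
            if g.chromosome not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chromosome}")
            if g.end > len(self.chromosomes[g.chromosome]):
                raise ValueError(f"{g.gene_id}: span exceeds chromosome")
        for gid, cds in self.cds.items():
            if len(cds) % 3:
                raise ValueError(f"{gid}: CDS length not a multiple of 3")
            prot = str(Seq(cds).translate())
            if prot.endswith("*"):
                prot = prot[:-1]
            if "*" in prot:
                raise ValueError(f"{gid}: internal stop codon")
            if gid in self.proteins and self.proteins[gid] != prot:
                raise ValueError(f"{gid}: CDS does not translate to stored protein")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "mybkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip(
                "\n"
            ).split("\t")
            if ftype != "gene":
                continue
            gid = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            ).get("ID", f"{chrom}:{start}-{end}")
            genes.append(GeneModel(gid, chrom, int(start), int(end), strand))
    return genes
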