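"""ProtParam-style physicochemical descriptors.

Molecular weight uses average isotopic residue masses; pI is the pH at which
the Henderson-Hasselbalch net charge over the termini and D/E/C/Y/H/K/R side
chains (Bjellqvist pKa set) vanishes; GRAVY is the mean Kyte-Doolittle
hydropathy; the aliphatic index is Ikai's A + 2.9 V + 3.9 (I + L) in mole
percent; the instability index is Guruprasad's (10/L) sum of dipeptide
weights, with >40 called unstable.

Mass, charge, hydropathy and dipeptide tables come from Bio.SeqUtils (the
same conventions as the ProtParam web service); the aliphatic index is
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "ProteinProperties",
    "molecular_weight",
    "isoelectric_point",
    "gravy",
    "aliphatic_index",
    "instability_index",
    "charge_at_pH",
    "protein_properties",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class AlphabetError(ValueError):
    """Sequence contains a residue outside the 20 standard amino acids."""


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    mw: float  # Da
    pI: float
    gravy: float
    aliphatic_index: float
    instability_index: float

    @property
    def stability_call(self) -> str:
        return "unstable" if self.instability_index > 40 else "stable"


def _check(protein: str, min_length: int = 1) -> str:
    if len(protein) < min_length:
        raise ValueError(f"sequence shorter than {min_length} residues")
    bad = set(protein) - STANDARD_AA
    if bad:
        raise AlphabetError(f"non-standard residues: {sorted(bad)}")
    return protein


def molecular_weight(protein: str) -> float:
    """Average isotopic mass in Da (residue masses + one water)."""
    return ProteinAnalysis(_check(protein)).molecular_weight()


def isoelectric_point(protein: str) -> float:
    """pH of zero net charge, by bisection (Bjellqvist pKa set)."""
    return IsoelectricPoint(_check(protein)).pi()


def charge_at_pH(protein: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH."""
    return IsoelectricPoint(_check(protein)).charge_at_pH(pH)


def gravy(protein: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    return ProteinAnalysis(_check(protein)).gravy()


def aliphatic_index(protein: str) -> float:
    """Ikai's aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu),
    with X in mole percent."""
    _check(protein)
    n = len(protein)
    frac = {aa: 100.0 * protein.count(aa) / n for aa in "AVIL"}
    return frac["A"] + 2.9 * frac["V"] + 3.9 * (frac["I"] + frac["L"])


def instability_index(protein: str) -> float:
    """Guruprasad instability index, (10/L) * sum of DIWV dipeptide weights."""
    return ProteinAnalysis(_check(protein, min_length=2)).instability_index()


def protein_properties(protein: str, protein_id: str = "") -> ProteinProperties:
    """All descriptors for one sequence."""
    return ProteinProperties(
        protein_id,
        molecular_weight(protein),
        isoelectric_point(protein),
        gravy(protein),
        aliphatic_index(protein),
        instability_index(protein),
    )
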