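"""In silico tryptic digestion and observable-peptide (OP) counting.

Trypsin cleaves C-terminal to lysine (K) or arginine (R); by default
cleavage is suppressed when the next residue is proline.  A theoretical
peptide is *observable* when its mass lies inside the instrument scan
window, by default 600-3500 Da (an ion-trap m/z range).  OP — the number
of observable peptides of a protein — is the denominator of the emPAI
abundance index, correcting spectral counts for protein size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)

# Residue (not free amino acid) masses.  Monoisotopic values come from the
# pyteomics standard table; average values are derived once from the same
# elemental compositions.
MONO_RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES}
AVG_RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.calculate_mass(sequence=aa, average=True) - WATER_AVG for aa in CANONICAL_RESIDUES
}


class SequenceError(ValueError):
    """Raised for empty sequences or non-canonical residues."""


def validate_sequence(sequence: str) -> str:
    if not sequence:
        raise SequenceError("empty amino-acid sequence")
    for i, aa in enumerate(sequence):
        if aa not in _CANONICAL_SET:
            raise SequenceError(f"non-canonical residue {aa!r} at position {i}")
    return sequence


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the digestion and of the observability filter.

    mass_window bounds are inclusive: a peptide exactly at either edge of
    the scan range is counted as observable.
    """

    missed_cleavages: int = 0
    mass_window: tuple[float, float] = (600.0, 3500.0)
    mass_type: str = "monoisotopic"
    proline_rule: bool = True
    count_unique_only: bool = True

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        low, high = self.mass_window
        if not low < high:
            raise ValueError(f"mass_window low must be < high, got {self.mass_window}")
        if self.mass_type not in ("monoisotopic", "average"):
            raise ValueError(f"mass_type must be 'monoisotopic' or 'average', got {self.mass_type!r}")


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 0-based half-open coordinates in its parent."""

    sequence: str
    mass: float
    start: int
    end: int


def peptide_mass(sequence: str, mass_type: str = "monoisotopic") -> float:
    """Mass of a peptide in Da: sum of residue masses plus one water."""
    validate_sequence(sequence)
    if mass_type == "monoisotopic":
        return sum(MONO_RESIDUE_MASS[aa] for aa in sequence) + WATER_MONO
    if mass_type == "average":
        return sum(AVG_RESIDUE_MASS[aa] for aa in sequence) + WATER_AVG
    raise ValueError(f"unknown mass_type {mass_type!r}")


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Positions after which trypsin cuts (cut between i and i+1).

    The C-terminal residue is never a cut site (there is nothing to cut
    off), so sites are strictly internal.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def tryptic_digest(sequence: str, params: DigestParams = DigestParams()) -> list[Peptide]:
    """All tryptic products spanning at most ``missed_cleavages`` internal sites.

    At missed_cleavages=0 the products partition the protein: concatenated
    in order they reproduce the input sequence.
    """
    validate_sequence(sequence)
    bounds = [0] + cleavage_sites(sequence, params.proline_rule) + [len(sequence)]
    m = params.missed_cleavages
    peptides: list[Peptide] = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + m, len(bounds))):
            start, end = bounds[a], bounds[b]
            pep = sequence[start:end]
            peptides.append(
                Peptide(sequence=pep, mass=peptide_mass(pep, params.mass_type), start=start, end=end)
            )
    return peptides


def count_observable(peptides: Iterable[Peptide], params: DigestParams = DigestParams()) -> int:
    """Number of peptides inside the scan window (unique sequences by default)."""
    low, high = params.mass_window
    kept = [p.sequence for p in peptides if low <= p.mass <= high]
    if params.count_unique_only:
        return len(set(kept))
    return len(kept)


def observable_peptide_count(sequence: str, params: DigestParams = DigestParams()) -> int:
    """OP of one protein: digest then count peptides in the scan window."""
    return count_observable(tryptic_digest(sequence, params), params)


def op_table(sequences: Mapping[str, str], params: DigestParams = DigestParams()) -> dict[str, int]:
    """OP per accession for a whole sequence database."""
    return {acc: observable_peptide_count(seq, params) for acc, seq in sequences.items()}
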